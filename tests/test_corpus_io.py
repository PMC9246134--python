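"""Corpus reading, eligibility filtering and report generation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import litscreen as ls
from litscreen.corpus import EligibilityRules


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text, encoding="utf-8")
    return path


class TestReadCorpus:
    def test_csv_basic(self, tmp_path):
        path = _write(tmp_path, "c.csv",
                      "doc_id,title,abstract,label\n"
                      "d1,Title one,Abstract one,relevant\n"
                      "d2,Title two,Abstract two,IRRELEVANT\n"
                      "d3,Title three,Abstract three,\n")
        records = ls.read_corpus(path)
        assert [r.doc_id for r in records] == ["d1", "d2", "d3"]
        assert [r.label for r in records] == ["relevant", "irrelevant", "unlabeled"]

    def test_tsv_with_column_map(self, tmp_path):
        path = _write(tmp_path, "c.tsv", "id\tTI\tAB\nx1\thello\tworld\n")
        records = ls.read_corpus(
            path, column_map={"doc_id": "id", "title": "TI", "abstract": "AB"}
        )
        assert records[0].title == "hello" and records[0].abstract == "world"

    def test_ris_tags(self, tmp_path):
        path = _write(tmp_path, "c.ris",
                      "TY  - JOUR\nID  - r1\nTI  - HIV among sex workers\n"
                      "AB  - A study abstract.\nPY  - 2012\nLA  - English\n"
                      "KW  - HIV Infections\nKW  - Sex Workers\nER  - \n"
                      "TY  - JOUR\nTI  - Second record\nER  - \n")
        records = ls.read_corpus(path)
        assert records[0].doc_id == "r1"
        assert records[0].title == "HIV among sex workers"
        assert records[0].abstract == "A study abstract."
        assert records[0].year == 2012
        assert records[0].mesh_terms == ["HIV Infections", "Sex Workers"]
        assert records[1].doc_id == "ris-0002"

    def test_duplicate_id_raises(self, tmp_path):
        path = _write(tmp_path, "c.csv",
                      "doc_id,title\nd1,a\nd1,b\n")
        with pytest.raises(ValueError, match="d1"):
            ls.read_corpus(path)

    def test_unknown_format(self, tmp_path):
        path = _write(tmp_path, "c.xml", "<x/>")
        with pytest.raises(ValueError, match="format"):
            ls.read_corpus(path)

    def test_csv_roundtrip_preserves_fields(self, tmp_path, tiny_records):
        out = tmp_path / "rt.csv"
        ls.write_corpus(tiny_records, out)
        back = ls.read_corpus(out)
        for a, b in zip(tiny_records, back):
            assert (a.doc_id, a.title, a.abstract, a.label) == \
                   (b.doc_id, b.title, b.abstract, b.label)


class TestEligibilityFilters:
    def test_empty_abstract_excluded_under_abstract_rule(self):
        rec = ls.DocumentRecord("d1", title="t", abstract="  ", year=2010,
                                language="english")
        retained, report = ls.apply_eligibility_filters([rec])
        assert retained == []
        assert report.counts_excluded_by_rule["abstract"] == 1

    def test_in_range_english_retained(self):
        rec = ls.DocumentRecord("d1", title="t", abstract="a", year=2017,
                                language="English")
        retained, _ = ls.apply_eligibility_filters([rec])
        assert len(retained) == 1

    @pytest.mark.parametrize("year,expected_rule", [(2005, "year"), (2018, "year")])
    def test_out_of_range_year_excluded(self, year, expected_rule):
        rec = ls.DocumentRecord("d1", abstract="a", year=year, language="english")
        _, report = ls.apply_eligibility_filters([rec])
        assert report.counts_excluded_by_rule[expected_rule] == 1

    def test_first_failing_rule_attribution(self):
        # fails both abstract and year: counted once, under abstract
        rec = ls.DocumentRecord("d1", abstract="", year=2005, language="english")
        _, report = ls.apply_eligibility_filters([rec])
        assert report.counts_excluded_by_rule == {"abstract": 1, "year": 0, "language": 0}

    def test_non_english_excluded_missing_language_passes(self):
        recs = [
            ls.DocumentRecord("d1", abstract="a", year=2010, language="french"),
            ls.DocumentRecord("d2", abstract="a", year=2010, language=None),
        ]
        retained, report = ls.apply_eligibility_filters(recs)
        assert [r.doc_id for r in retained] == ["d2"]
        assert report.counts_excluded_by_rule["language"] == 1

    def test_missing_language_configurable(self):
        rec = ls.DocumentRecord("d1", abstract="a", year=2010, language=None)
        rules = EligibilityRules(missing_language_passes=False)
        retained, _ = ls.apply_eligibility_filters([rec], rules)
        assert retained == []

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.tuples(st.booleans(),
                              st.integers(min_value=1990, max_value=2030),
                              st.sampled_from(["english", "french", None]))))
    def test_report_conservation(self, specs):
        records = [
            ls.DocumentRecord(f"d{i}", abstract="text" if has_abs else "",
                              year=year, language=lang)
            for i, (has_abs, year, lang) in enumerate(specs)
        ]
        retained, report = ls.apply_eligibility_filters(records)
        assert report.n_input == len(records)
        assert report.n_input == report.n_retained + \
            sum(report.counts_excluded_by_rule.values())
        assert report.n_retained == len(retained)


class TestRankedList:
    def _read_rows(self, path):
        return [line.split(",") for line in
                path.read_text().strip().split("\n")[1:]]

    def test_descending_score_order(self, tmp_path):
        recs = [ls.DocumentRecord("a", label="relevant"),
                ls.DocumentRecord("b", label="irrelevant")]
        out = tmp_path / "r.csv"
        ls.write_ranked_list(recs, [0.2, 0.9], out)
        assert [row[0] for row in self._read_rows(out)] == ["b", "a"]

    def test_tie_broken_by_doc_id(self, tmp_path):
        recs = [ls.DocumentRecord("b"), ls.DocumentRecord("a")]
        out = tmp_path / "r.csv"
        ls.write_ranked_list(recs, [0.5, 0.5], out)
        assert [row[0] for row in self._read_rows(out)] == ["a", "b"]

    def test_empty_corpus_header_only(self, tmp_path):
        out = tmp_path / "r.csv"
        ls.write_ranked_list([], [], out)
        assert out.read_text().strip() == "doc_id,score,label"

    def test_length_mismatch_raises(self, tmp_path):
        with pytest.raises(ValueError):
            ls.write_ranked_list([ls.DocumentRecord("a")], [0.1, 0.2],
                                 tmp_path / "r.csv")


class TestDisagreementReport:
    def test_largest_discrepancy_first(self):
        recs = [ls.DocumentRecord("a", label="irrelevant"),
                ls.DocumentRecord("b", label="relevant")]
        top = ls.disagreement_report(recs, [0.95, 0.6], k=1)
        assert [r.doc_id for r in top] == ["a"]   # 0.95 vs 0.4

    def test_k_zero_empty(self):
        recs = [ls.DocumentRecord("a", label="relevant")]
        assert ls.disagreement_report(recs, [1.0], k=0) == []

    def test_zero_discrepancy_deterministic_order(self):
        recs = [ls.DocumentRecord(i, label="relevant") for i in ["c", "a", "b"]]
        top = ls.disagreement_report(recs, [1.0, 1.0, 1.0], k=3)
        assert [r.doc_id for r in top] == ["a", "b", "c"]

    def test_unlabeled_record_raises(self):
        recs = [ls.DocumentRecord("a")]
        with pytest.raises(ValueError, match="unlabeled"):
            ls.disagreement_report(recs, [0.5], k=1)


def test_synthetic_corpus_roundtrip(tmp_path):
    records, _ = ls.generate(ls.GeneratorConfig(n_docs=50, seed=9))
    path = tmp_path / "syn.csv"
    ls.write_corpus(records, path)
    back = ls.read_corpus(path)
    assert len(back) == len(records)
    for a, b in zip(records, back):
        assert (a.doc_id, a.title, a.abstract, a.year, a.language, a.label) == \
               (b.doc_id, b.title, b.abstract, b.year, b.language, b.label)
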