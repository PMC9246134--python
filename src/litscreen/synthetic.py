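"""Labeled synthetic bibliographic corpora for end-to-end testing.

The generator emulates the statistical shape a screening corpus presents
to this pipeline — not English prose.  Each document gets:

* a gold label, Bernoulli(prevalence) with prevalence defaulting to 1/11
  (one relevant record per ten irrelevant ones);
* background tokens drawn from a Zipf-like long-tailed distribution over a
  synthetic vocabulary, so document frequencies (and hence IDF) vary
  realistically;
* "planted" discriminative tokens, each present with a class-conditional
  probability (high in relevant documents, low in irrelevant ones) — the
  signal the token-screening stage should recover;
* screening-cluster vocabulary (hiv, violence, fsw, ... surface forms)
  sampled at a boosted rate in relevant documents, so the cluster features
  and the Boolean baseline also carry signal.

All synthetic tokens are constructed to be fixed points of the Porter
stemmer, so planted-token identities survive preprocessing verbatim and
recovery tests need no re-derivation.  A manifest records the planted
tokens, the configuration and the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .corpus import IRRELEVANT, RELEVANT, DocumentRecord, write_corpus

# syllables avoid e/i/s/y endings so generated words are Porter fixed points
_SYLLABLES = (
    "ba", "co", "du", "fa", "go", "hu", "ja", "ko", "lu",
    "ma", "no", "pu", "qa", "ro", "tu", "va", "wo", "za",
)

#: surface forms per screening cluster, sampled into generated text
CLUSTER_LEXICON = {
    "hiv": ["hiv", "aids"],
    "fsw": ["fsw", "prostitution", "sex", "trade"],
    "violence": ["violence", "violent"],
    "offense": ["offense", "crime"],
    "abuse": ["abuse", "abusive"],
    "torture": ["torture"],
    "rape": ["rape"],
    "victim": ["victim", "victims"],
    "assault": ["assault"],
    "harass": ["harassment"],
    "extort": ["extortion"],
    "homicide": ["homicide"],
    "coercion": ["coercion"],
    "ipv": ["ipv"],
    "exploit": ["exploitation"],
}


def background_token(index: int) -> str:
    """Deterministic pseudo-word for background-vocabulary slot ``index``."""
    digits = []
    i = index
    while True:
        digits.append(i % len(_SYLLABLES))
        i //= len(_SYLLABLES)
        if i == 0:
            break
    word = "".join(_SYLLABLES[d] for d in reversed(digits))
    return word + "x"


def planted_token(index: int) -> str:
    """Deterministic pseudo-word for planted-signal slot ``index``."""
    return "zq" + background_token(index)


@dataclass
class GeneratorConfig:
    """Study conditions for a synthetic screening corpus."""

    n_docs: int = 1100
    prevalence: float = 1.0 / 11.0
    vocab_size: int = 150
    n_planted: int = 20
    p_planted_rel: float = 0.5
    p_planted_irr: float = 0.02
    cluster_boost: float = 4.0
    cluster_base_rate: float = 0.05
    doc_length_mean: float = 100.0
    doc_length_dispersion: float = 10.0   # negative-binomial shape; larger = tighter
    zipf_exponent: float = 1.1
    year_range: tuple[int, int] = (2006, 2017)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        for p in (self.p_planted_rel, self.p_planted_irr):
            if not 0.0 <= p <= 1.0:
                raise ValueError("planted-token probabilities must lie in [0, 1]")
        if self.cluster_boost <= 0 or self.cluster_base_rate < 0:
            raise ValueError("invalid cluster rates")


@dataclass
class CorpusManifest:
    """Ground truth accompanying a generated corpus."""

    seed: int
    config: dict
    planted_tokens: list[str]
    n_relevant: int
    n_irrelevant: int
    cluster_lexicon: dict = field(default_factory=lambda: dict(CLUSTER_LEXICON))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CorpusManifest":
        return cls(**json.loads(Path(path).read_text()))


def generate(config: GeneratorConfig) -> tuple[list[DocumentRecord], CorpusManifest]:
    """Generate a labeled corpus and its ground-truth manifest (deterministic)."""
    rng = np.random.default_rng(config.seed)
    vocab = np.array([background_token(i) for i in range(config.vocab_size)])
    planted = [planted_token(i) for i in range(config.n_planted)]
    ranks = np.arange(1, config.vocab_size + 1, dtype=np.float64)
    zipf_p = ranks ** -config.zipf_exponent
    zipf_p /= zipf_p.sum()
    cluster_words = list(CLUSTER_LEXICON.items())
    p_rel_cluster = min(1.0, config.cluster_base_rate * config.cluster_boost)

    records: list[DocumentRecord] = []
    n_rel = 0
    width = len(str(config.n_docs))
    for d in range(config.n_docs):
        relevant = rng.random() < config.prevalence
        n_rel += relevant
        shape = config.doc_length_dispersion
        mean = config.doc_length_mean
        length = int(rng.negative_binomial(shape, shape / (shape + mean))) + 12
        tokens = list(vocab[rng.choice(config.vocab_size, size=length, p=zipf_p)])
        p_planted = config.p_planted_rel if relevant else config.p_planted_irr
        for tok in planted:
            if rng.random() < p_planted:
                tokens.append(tok)
        p_cluster = p_rel_cluster if relevant else config.cluster_base_rate
        for _, words in cluster_words:
            if rng.random() < p_cluster:
                tokens.extend([words[int(rng.integers(len(words)))]]
                              * int(1 + rng.poisson(0.5)))
        perm = rng.permutation(len(tokens))
        tokens = [tokens[i] for i in perm]
        n_title = min(8, max(1, len(tokens) - 1))
        records.append(DocumentRecord(
            doc_id=f"doc{d + 1:0{width}d}",
            title=" ".join(tokens[:n_title]),
            abstract=" ".join(tokens[n_title:]),
            year=int(rng.integers(config.year_range[0], config.year_range[1] + 1)),
            language="english",
            label=RELEVANT if relevant else IRRELEVANT,
        ))
    manifest = CorpusManifest(
        seed=config.seed,
        config={k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(config).items()},
        planted_tokens=planted,
        n_relevant=int(n_rel),
        n_irrelevant=config.n_docs - int(n_rel),
    )
    return records, manifest


def null_config(seed: int = 0, n_docs: int = 1100) -> GeneratorConfig:
    """Label-randomized conditions: no class-conditional structure at all."""
    return GeneratorConfig(
        n_docs=n_docs, seed=seed,
        p_planted_rel=0.05, p_planted_irr=0.05, cluster_boost=1.0,
    )


def separable_config(seed: int = 0, n_docs: int = 1100) -> GeneratorConfig:
    """Strong-signal conditions (the generator defaults)."""
    return GeneratorConfig(n_docs=n_docs, seed=seed)


def make_fixture_suite(out_dir: str | Path) -> dict[str, Path]:
    """Write the canned corpora used by the test suite.

    * ``tiny10.csv`` — 10 hand-checkable documents;
    * ``null.csv`` — label-randomized corpus (chance performance expected);
    * ``separable.csv`` — strong-signal corpus (near-perfect ranking expected);
    * ``corpus1100.csv`` — study-scale-mimicking corpus, ~1:10 imbalance.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    tiny = tiny_corpus()
    paths["tiny10"] = out / "tiny10.csv"
    write_corpus(tiny, paths["tiny10"])

    for name, config in [
        ("null", null_config(seed=11)),
        ("separable", separable_config(seed=12)),
        ("corpus1100", GeneratorConfig(seed=13)),
    ]:
        records, manifest = generate(config)
        paths[name] = out / f"{name}.csv"
        write_corpus(records, paths[name])
        manifest.to_json(out / f"{name}.manifest.json")
    return paths


def tiny_corpus() -> list[DocumentRecord]:
    """Ten tiny hand-checkable documents (5 relevant, 5 irrelevant)."""
    rows = [
        ("t01", "hiv prevalence fsw", "hiv prevalence among sex workers", RELEVANT),
        ("t02", "violence against fsw", "violence abuse victim fsw study", RELEVANT),
        ("t03", "hiv risk sex trade", "hiv hiv risk factors sex trade", RELEVANT),
        ("t04", "fsw rape survey", "rape assault coercion fsw survey", RELEVANT),
        ("t05", "hiv care cascade fsw", "hiv testing treatment fsw cohort", RELEVANT),
        ("t06", "malaria bednet trial", "malaria incidence bednet cluster trial", IRRELEVANT),
        ("t07", "diabetes care model", "diabetes glucose care management", IRRELEVANT),
        ("t08", "vaccine uptake children", "measles vaccine uptake school children", IRRELEVANT),
        ("t09", "cancer screening costs", "breast cancer screening cost analysis", IRRELEVANT),
        ("t10", "hypertension cohort", "blood pressure cohort followup", IRRELEVANT),
    ]
    return [
        DocumentRecord(doc_id=i, title=t, abstract=a, year=2010,
                       language="english", label=lbl)
        for i, t, a, lbl in rows
    ]
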