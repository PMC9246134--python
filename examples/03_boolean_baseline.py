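"""The keyword-guided baseline: FSW AND (HIV OR Violence).

A deterministic Boolean query over MeSH headings and text words, with
trailing-wildcard prefix matching.  Its single operating point (one
recall/precision pair) is what probabilistic classifiers are compared to.
"""

import litscreen as ls

records = ls.tiny_corpus()
predictions = ls.classify_corpus(records)
for rec, hit in zip(records, predictions):
    print(f"  {rec.doc_id} [{rec.label:>10}] -> {'HIT' if hit else 'miss'}  {rec.title}")

point = ls.baseline_operating_point(predictions, ls.labels01(records))
print(f"baseline recall {point['recall']:.3f}, precision {point['precision']:.3f}, "
      f"FPR {point['fpr']:.3f}")
# On this toy corpus the query vocabulary separates classes perfectly; on
# realistic corpora the baseline trades low precision for moderate recall.
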