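"""Reading-workload arithmetic and training-size sensitivity.

workload() turns an operating point (recall, precision) into the number of
documents a reviewer must read; learning_curve() shows how little labeled
data the classifier needs.
"""

import litscreen as ls

wl = ls.workload(n_total=10_000, n_relevant=1_000, recall=0.8, precision=0.4)
print(f"flag {wl.n_flagged} of {wl.n_total} documents "
      f"-> {wl.reduction_pct:.0f}% less manual reading")

flagged, unread = ls.invert_wss(0.55, 0.80)
print(f"a reported WSS@0.80 of 0.55 means reading {flagged:.0%} "
      f"and skipping {unread:.0%} of documents")

records, _ = ls.generate(ls.separable_config(seed=4, n_docs=600))
dtm = ls.build_dtm(ls.tokenize_records(records))
curve = ls.learning_curve(
    lambda: ls.RelevancePipeline(top_n=50, n_trees=200, seed=4),
    dtm, ls.labels01(records),
    proportions=[0.05, 0.20, 0.50], n_replicates=3, seed=4,
)
for p, auc in zip(curve.proportions, curve.mean_auc_roc):
    print(f"train on {p:>4.0%} of labels -> held-out AUC-ROC {auc:.3f}")
# AUC saturates with a small labeled fraction: most of the labeling budget
# in a live review can go to reading, not annotation.
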