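# Methods

This note documents the models, conventions and design decisions behind
`litscreen`, in the order data flows through the pipeline.

## Problem setting

A screening corpus is a set of bibliographic records (title, abstract,
year, language, optional MeSH headings), each manually labeled *relevant*
or *irrelevant* to a review question — here, studies reporting HIV burden
or experienced violence among female sex workers.  Relevant records are
rare (about 1 in 11).  The package learns to rank unlabeled records by
probability of relevance so that manual reading can be prioritized and
truncated.

## Record eligibility

Before modelling, records are filtered by three rules in fixed order:
non-empty abstract, publication year inside 2006–2017 (inclusive), and
language English.  A record excluded by several rules is counted under the
**first** failing rule, which makes the exclusion report deterministic and
conservative (counts sum exactly to input minus retained).  Records with
missing language — and, symmetrically, missing year — pass the respective
rule by default, since absence of metadata is not evidence of
ineligibility; both behaviors are configurable (`EligibilityRules`).
A common real-world rule, excluding studies with sample size below 50,
requires reading the full text and is deliberately not implemented; it
remains a manual step downstream.

## Text normalization

Title and abstract are concatenated and lowercased; tokens are whitespace
runs with all non-letter characters stripped.  Tokens containing
non-ASCII letters are dropped entirely — a deliberately crude proxy for
removing non-English material.  Tokens shorter than 2 characters are
discarded as stripping residue.  Stop words (packaged ~180-word English
list, replaceable) are removed *before* lemmatization, then a two-column
variant→lemma table (packaged list of common English irregulars, in the
spirit of the public lemmatization lists; any TSV can be substituted)
maps inflected forms to lemmas, and finally the classic Porter (1980)
algorithm stems each token.

The Porter implementation follows the published five-step algorithm
exactly — measure-based conditions evaluated on the stem, one
longest-matching rule per rule set — plus the reference implementation's
guard that words of length ≤ 2 are left untouched.  Outputs are
equivalence-class labels, not words ("stay" → "stai").  A packaged
100-word sample of verified word→stem pairs pins the behavior in the test
suite.  Note a subtlety worth knowing: "automation" stems to "autom"
(ATION→ATE in step 2, then ATE removed in step 4); it is "automatic" that
stems to "automat".  Informal descriptions of the stemmer often conflate
these.

Documents that become empty after normalization are kept as all-zero rows
of the document-term matrix (and logged), so document ids stay aligned
across every pipeline stage.

## TF-IDF

The encoding is the plain product `tfidf(i,d) = tf(i,d) · ln(N / df(i))`,
with `df(i)` the number of fitting documents containing token *i* and no
smoothing — a token present in every document is weighted exactly 0.  The
natural log is used; the base only rescales columns monotonically and is
irrelevant to tree-based classifiers.  `tf` is the raw within-document
count by default; a relative-frequency mode (count / document length) is
provided because "scaled token frequency" is ambiguous in common usage.
IDF is always fitted on training documents only and applied to held-out
documents; tokens unseen at fit time are dropped, and tokens whose
training df is 0 after row-subsetting are removed from the fitted
vocabulary so `df ≥ 1` holds for every retained token.  sklearn's
`TfidfTransformer` is intentionally *not* used (it smooths and offsets the
IDF); the direct implementation is cross-checked in tests against a
double-loop oracle and serves the exact formula above.

## Boolean baseline

The keyword-guided classifier evaluates `FSW AND (HIV OR Violence)`.
A category hits if any of its terms hits.  MeSH terms compare
case-insensitively against the record's headings; when a record carries no
headings at all (the usual case outside database exports) MeSH terms
degrade to text matching, configurably.  Text terms match on raw surface
tokens — lowercased, split on any non-letter run (so "HIV/AIDS" matches
"hiv"), with no stop-word removal or stemming.  Multi-word patterns must
match consecutive tokens; a trailing `*` gives prefix (truncation)
matching on the last pattern word, e.g. `violen*` matches "violence" and
"violent".  Acronym terms (sw, fsw, csw, hiv, aids, ipv, ipsv) carry no
wildcard so they only match whole tokens — `sw*` would hit "swab".  The
full term list ships as an editable YAML config.  The baseline emits hard
0/1 labels; for ROC/PR comparison it is a single operating point.

## Cluster features

Fifteen semantic clusters (hiv, fsw, violence, offense, abuse, torture,
rape, victim, assault, harass, extort, homicide, coercion, ipv, exploit)
group stemmed tokens that share a root meaning, repairing cases where
stemming alone either splits synonyms or conflates unrelated words.  The
packaged membership lists are a reconstruction routed from the screening
query vocabulary — the original curated lists were never published — and
are an editable config.  Each vocabulary token joins the *first* cluster
whose exact-or-prefix pattern matches (first-match-wins keeps assignment
deterministic under overlapping patterns).  Per-document cluster counts
are summed member-token counts; cluster-level TF-IDF applies the same
formula with document frequency counted at the cluster level, yielding a
15-dimensional feature vector per document.

## Token screening

For each token, the unpooled (Welch) two-sample t-statistic compares mean
TF-IDF between classes over the full column, zeros included:
`t = (x̄₁ − x̄₂) / sqrt(s₁²/n₁ + s₂²/n₂)` with unbiased variances.  The
statistic is a ranking device only — no p-values or testing at a level.
Tokens are ordered by |t| descending with lexicographic tie-breaking; the
top N (default grid 20/50/100/250/500) become features alongside the 15
clusters, in rank order.  Degenerate columns with zero variance in both
classes get t = 0 when the means agree and a signed infinity (ranking
above all finite values) when they do not.  Screening runs **inside each
training fold** by default; a global mode that screens once on all labels
exists behind an explicit flag for comparison but leaks test-label
information and is not used in any reported number.  Tokens already
assigned to clusters stay eligible for selection (configurable).

## Classifier

The forest grows `n_trees = 500` trees (sklearn `DecisionTreeClassifier`,
per-split candidate features `floor(sqrt(p))`).  Class imbalance is
handled per tree: each tree trains on a balanced bootstrap in which both
classes are resampled with replacement to the minority-class size — the
majority class is thereby down-sampled afresh for every tree.  The
predicted probability is the fraction of trees whose hard vote is
*relevant* (a vote proportion, not an averaged leaf probability), so with
one tree the output is exactly 0 or 1.  All randomness (per-tree sampling
and tree construction) flows from one seeded generator: identical seed and
data give identical predictions.  Hard classification uses the `≥ cutoff`
rule, so a 0.5 vote split at cutoff 0.5 counts as relevant.  A plugin
backend hook accepts any sklearn-style estimator factory for comparisons;
only the balanced forest is a supported, tested backend.

## Evaluation

Curves sweep the unique scores in descending order plus a +∞ sentinel, so
the ROC curve runs from (0,0) to (1,1).  AUC-ROC is the trapezoidal
integral (equal to the Mann-Whitney concordant-pair probability with ties
at 0.5).  AUC-PR is the step-interpolated average-precision integral;
linear interpolation in PR space is optimistic and is not used, so values
may sit slightly below trapezoid-based figures elsewhere.

`WSS@R = R − P/N` is computed at the largest score cutoff reaching recall
≥ R, with P the number of flagged documents and N the corpus size.  The
printed formula uses the *target* recall R, not the (possibly higher)
recall achieved at that cutoff; WSS@R therefore lies in [R−1, R], and a
perfect ranking at R = 1 gives 1 − prevalence.

Cross-validation is stratified k-fold (default k = 5, shuffled with a
fixed seed).  The entire pipeline — IDF fit, cluster TF-IDF, token
screening, forest training — is re-fit inside each fold on that fold's
training rows only.  Headline curves and AUCs come from the pooled
out-of-fold scores; per-fold curves are retained (whether to pool or
average per-fold curves is a genuinely open convention — pooling was
chosen because it yields one well-defined ranking of the whole corpus).
k greater than the minority-class size is an error, which also rules out
leave-one-out with stratification.

The learning curve trains on stratified fractions of the labeled corpus
(default grid 1%–80%) and evaluates on the held-out remainder, over
seeded replicates.  `workload(n_total, n_relevant, recall, precision)`
converts an operating point into reading effort:
`n_flagged = round(recall · n_relevant / precision)` and the percent
reduction versus reading everything.

## Synthetic corpora

The generator emulates the statistical shape the pipeline assumes, not
English prose.  Per document: a Bernoulli(prevalence) label with
prevalence 1/11 by default; a length from a negative binomial (mean 100
tokens, dispersion 10 — roughly a title plus abstract after stop-word
removal); background tokens drawn from a Zipf-like distribution
(exponent 1.1) over a 150-token synthetic vocabulary so document
frequencies and IDFs vary; 20 planted discriminative tokens, each present
with probability 0.5 in relevant vs 0.02 in irrelevant documents; and
cluster vocabulary (surface forms like "hiv", "violence", "fsw") present
per cluster with probability 0.05 in irrelevant documents and 4× that in
relevant ones.  All synthetic token names are constructed to be fixed
points of the Porter stemmer, so the manifest's planted-token identities
survive preprocessing verbatim and recovery tests need no re-derivation.

The background scale was calibrated once, jointly, to the three properties
the generator must exhibit: (i) Welch-t screening recovers all planted
tokens in ≥95% of replicate corpora at n = 1000 — which requires the
rarest background token's per-document presence (~8%) to stay above the
band where accidental absence from all ~90 relevant documents produces
zero-variance t artifacts that outrank weak planted tokens, and requires
cluster enrichment moderate enough (|t| ≈ 3.5) that topical vocabulary is
informative without tying with planted signal; (ii) the label-randomized
configuration (equal planting rates, boost 1) yields chance-level
cross-validated AUC; (iii) the default strong-signal configuration yields
near-perfect AUC.  What passing these tests does *not* show: robustness to
real-language phenomena — synonymy, polysemy, topic drift, non-English
fragments, duplicated records, abstract-length confounding with class —
none of which the generator emulates.  Results on real corpora will be
substantially noisier than on the separable fixture.

## Numerical and degenerate-input conventions

Ranked reading lists sort by score descending with doc_id ascending as
tie-break; disagreement reports sort by |score − label| descending with
the same tie-break.  Tiny negative variances from floating-point
cancellation in the vectorized Welch computation are clipped to zero.
Empty documents produce all-zero TF-IDF rows and survive every stage.
Single-class inputs are errors for screening, training and curve
construction.  All stochastic components (generator, fold shuffling,
learning-curve subsampling, forest) are seeded; every reported quantity is
bit-for-bit reproducible given the seed.

## Known limitations

* Cluster membership lists and the stop-word/lemma lists are
  reconstructions; swapping lists will shift results on real data.
* The unigram bag-of-words has no n-grams or embeddings; the non-ASCII
  heuristic is not language identification.
* The Boolean baseline's wildcard semantics approximate database-specific
  truncation behavior by prefix matching.
* WSS is computed on pooled cross-validation scores, not on a prospective
  held-out stream; live-review stopping heuristics are out of scope.
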