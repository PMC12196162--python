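# Methods

This note documents the modelling choices, defaults and numerical conventions
of the package, and what the synthetic fixtures do and do not demonstrate.

## Problem setting

Senolytic discovery from phenotypic screens yields a small positive class
(validated senolytics across heterogeneous cell models) and a large, noisy
negative pool (compounds inactive in at least one screen, plus compounds used
as inactives in prior virtual-screening studies). The pipeline treats the
positive labels as trustworthy and the negative labels as presumptively
correct but contaminated, which drives two asymmetric curation rules:

* **positive-wins overlap resolution** — a structure present in both tables
  is kept once, labeled active, and logged;
* **negative similarity filter** — a negative whose maximum ECFP (2048 bits,
  radius 2) Tanimoto similarity to any positive is strictly greater than 0.9
  is removed. The boundary is strict: similarity exactly 0.9 is kept. The
  filter never touches positives, and the curation log accounts for every
  removed record.

## Feature views

**Canonicalization.** RDKit isomeric canonical SMILES is the identity
dialect. Multi-fragment inputs (salts/mixtures) are kept intact by default
with a warning; `keep_largest_fragment=True` reduces to the largest fragment
by heavy-atom count. Salt handling can shift third-decimal similarity values
between structure sources, which is why similarity comparisons in the tests
pin explicit isomeric SMILES.

**Fingerprints.** ECFP via RDKit's Morgan generator (default 2048 bits,
radius 2). FP2 (1024-bit, path-based) is an optional backend that shells out
to the Open Babel CLI; the hex-word bit-order convention is fixed and
documented in the code, and the core package works without it.

**Descriptors.** Exactly 200 RDKit descriptors, alphabetically ordered and
frozen in `data/descriptors_200.json` so results are stable across toolkit
upgrades. The toolkit's full list (210 in the pinned version) is reduced by
excluding the eight `BCUT2D_*` descriptors (undefined for molecules without
Gasteiger parameters) and the `Ipc`/`AvgIpc` pair (numeric overflow on large
molecules). Failed or non-finite entries follow an explicit NaN policy
(`flag` by default, `impute_zero`, or `fail`); failures are never silent.

**Embeddings.** All learning and the applicability domain operate on dense
molecular embeddings supplied by any object satisfying the embedder
contract: `embed(batch, seed)` → n×dim matrix, bit-identical under a fixed
seed, *allowed* to vary across unseeded batches. Embeddings are the default
feature because they are the representation under which the dual predictor
and AD are designed to run; fingerprints and descriptors remain selectable
for model-family comparisons.

**Empty-fingerprint similarity.** Tanimoto of two empty bit sets is 0/0;
it is defined here as 0.0 with a warning. For novelty screening this is the
conservative choice — an uninformative query should never be reported as
identical to a training active.

## Oversampling by stochastic embedding

Each positive is embedded k = 5 times in separate unseeded batches;
negatives are embedded once. The replicates are genuinely different feature
rows of the same real compound (batch noise), not interpolated synthetic
points — the reason SMOTE-style augmentation is deliberately absent. When a
run seed is supplied, per-batch child seeds are spawned from it
(`numpy.random.SeedSequence`), so batches still differ from one another
while the whole augmentation is reproducible.

Two modes:

* `leakage_safe` (default): split compounds first, augment only the training
  partition. The per-run assertion that no test compound id appears in any
  training origin row is part of the test-suite.
* `paper_faithful`: augment the full corpus first, then split at the *row*
  level. Replicates of a test active then typically sit in training, and
  recall inflates toward 1.0. The mode exists to reproduce and quantify that
  effect (see the ablation tests); every output labels it.

## The dual predictor

* **SVM**: RBF kernel, C = 20, `class_weight="balanced"`. The signed
  decision score is used directly; predicted label = score > 0 (strict).
  No probability calibration is applied — consensus and ranking consume the
  raw margin, which can exceed 1.
* **MLP**: one hidden layer (width 256 by default; the width is exposed
  because the appropriate capacity depends on the embedding dimension),
  Adam at learning rate 1e-4, cross-entropy loss, at most 3000 epochs.
  Early stopping monitors the *training* loss with patience 100 — there is
  no validation split for stopping; this is documented and configurable.
  The backend is scikit-learn's `MLPClassifier`; it has no dropout layer, so
  the L2 penalty `alpha` is the regularization knob. Divergent training
  (non-finite loss) raises rather than returning a broken model.
* **Ensemble**: 10 sub-models differing only by seed; the ensemble
  probability is their arithmetic mean. Averaging provably does not increase
  across-seed variance, and the n_sub = 1 ensemble is bit-identical to a
  single model.
* **Consensus**: a compound is a hit iff SVM score > 0 *and* ensemble
  probability > 0.5, both strict — scores exactly at threshold are
  negative. Hits are ranked by the raw sum `svm_score + mlp_prob`. The two
  addends live on different scales; the raw sum is the documented default
  because it is the convention the screening tables follow, and a min–max
  normalized alternative is available behind `normalized_rank=True`.

**Grid search** is exhaustive stratified k-fold (default 5) with selection
by mean F1 and ties broken by mean AUC, then grid order — a fixed,
reproducible rule where the underlying protocol left the choice open.

**Metrics.** Accuracy, precision, recall, F1 and MCC are computed from the
confusion counts by their defining formulas; zero-denominator ratios are
reported as 0.0 and flagged `degenerate` (rather than NaN) so averaged
cross-validation reports stay well-defined. AUC on single-class truth is
flagged, not fabricated. auPRC is the trapezoidal area under the
`precision_recall_curve`, and its confidence interval is a percentile
bootstrap over 100 resamples with replacement (resamples missing a class are
redrawn; the interval is widened to contain the point estimate if a quantile
falls inside it).

## Applicability domain

Distance-to-model in the deployed feature space (embeddings): D and σ are
the mean and standard deviation of Euclidean distances over all **unordered
pairs** of training rows, self-distances excluded, with the population
(divide-by-N) convention for σ — both conventions stated because either
choice is defensible and they differ in the third decimal on small sets.
ADT = D + Z·σ with Z = 0.5 by default; a query is inside iff its
nearest-neighbour distance is strictly below ADT. In-AD status is therefore
monotone in Z. The AD reference matrix is one *deterministic base* embedding
row per training compound, not the oversampled matrix: replicate rows sit at
near-zero distances and would bias D downward. Out-of-AD compounds are
reported with `in_ad=False`, never dropped.

## Enrichment

For each source, p = P(X ≥ k) with X hypergeometric(N, K, n); adjustment is
Benjamini–Hochberg across all tested sources (a specific choice of FDR
control). The default universe is the set of compounds with at least one
source mapping — the convention of the widely used enricher interface — and
a caller-supplied universe (e.g. the whole screened library) is accepted.
No minimum/maximum source-size filter is applied by default: real herb
annotations include sources with as few as 3 compounds, which size filters
would silently drop. Sources with zero hits are retained with p = 1 and can
never be flagged enriched.

## Synthetic fixtures: what they emulate, and what they don't

`generate_library` plants actives on 3 (of 4 available) large
heteroaromatic scaffold templates and negatives on 8 disjoint decoy
templates, decorated from a 24-substituent grammar; every combination
parses and canonical structures are unique. Difficulty is controlled by
two knobs, not by embedding geometry:

* `scaffold_overlap` — fraction of negatives built on *active* scaffolds
  (confusable negatives);
* `label_noise` — fraction of labels flipped after construction.

The default spec (n_pos = 50, n_neg = 1000, overlap 0.05, noise 0.02) is the
benchmark condition for end-to-end tests. The active templates are large
enough that two decorations of one scaffold keep ECFP Tanimoto ≥ ~0.54, so
same-scaffold recognition is observable through `match_degree`.

`MockEmbedder` maps a compound to the seeded Gaussian random projection of
its L2-normalized ECFP count vector (so embedding distance tracks structural
similarity) plus per-batch N(0, τ²I) noise (τ = 0.05 by default, dim 768;
τ = 0 makes it fully deterministic). Its batch-to-batch variability is
exactly the property the oversampling stage exploits, and its noise law is
verified by closed-form displacement and chi-square tests.

What passing fixture tests **does not** show: chemical realism (no ADMET,
no drug-likeness, no stereochemistry in generated structures), realistic
activity cliffs, or the representational quality of any real pretrained
embedder. The fixtures validate the statistical machinery — imbalance
handling, leakage hygiene, AD gating, novelty accounting, enrichment — not
biological predictivity.

## Problem sizes and numerical choices

End-to-end tests run the default fixture with a 128-d mock embedder and a
reduced network (width 64, ≤ 400 epochs, 3-model ensemble); these sizes were
chosen as the smallest at which the statistical phenomena of interest are
stable, and the package defaults remain the full-scale settings (768-d,
width 256, 3000 epochs, 10 sub-models). Recovery on the default fixture is
evaluated against the *planted* (pre-noise) labels, since flipped test
labels bound observable AUC regardless of model quality. The
lifespan-extension reporting utility rounds half-up to one decimal, matching
how such rates are printed in survival summaries.

## Known limitations

* The MLP backend approximates the dropout-regularized original with L2;
  at these network sizes the practical difference is regularization
  strength, not architecture.
* The FP2 backend depends on an external executable and a documented but
  backend-specific bit-order convention; FP2 bit indices are not
  interchangeable with other toolkits' FP2 output.
* Bootstrap PR intervals are percentile intervals; no BCa correction.
* Enrichment p-values are exact only under the random-draw null; compound
  libraries have correlated structures, so enriched sources are leads, not
  inferential conclusions.
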