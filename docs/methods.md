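# Methods

`panfuse` implements a subtype-discovery and prognosis workflow for bulk
expression cohorts: consensus pseudo-labels from a five-algorithm voting
ensemble, a CNN + BiLSTM cross-attention classifier trained on those labels,
dual LASSO / random-forest hub-gene selection, and a Cox + random-survival-
forest prognostic risk model with a maximally-selected-rank-statistic cutoff.
This note records the models, the defaults and the design choices that were
genuinely open.

## Consensus pseudo-labels (the scoring network)

Samples are the clustering units and genes the features; subtypes are patient
subgroups, so even though pseudo-labels are sometimes described per gene in
this literature, clustering is always over samples here. Five base algorithms
partition the cohort at a common `k` under a Euclidean metric:

* K-Means (10 restarts) and Ward agglomerative clustering from scikit-learn;
* a full-covariance Gaussian mixture — the one deliberate deviation from a
  pure Euclidean metric, since a GMM has no meaningful "Euclidean" mode; a
  spherical mixture would simply duplicate K-Means;
* K-Medoids (PAM-style): greedy BUILD initialisation followed by alternating
  assignment / medoid-update sweeps to a fixed point, implemented in-repo;
* CLARANS: randomised search over medoid sets (`numlocal = 4`,
  `maxneighbor = max(250, 1.25% · k · (n − k))`), implemented in-repo.

Majority voting over label spaces is only well defined after alignment, which
no description of the voting scheme we know of spells out; we align every
labeling to a reference by the permutation maximising total agreement
(Hungarian assignment on the k×k contingency table). The reference is the
voter with the highest mean silhouette. Each sample's consensus label is the
vote argmax; agreement = max votes / 5. With five voters and k = 3 a 2–2–1
tie is possible: the tie goes to the tied cluster whose consensus centroid
(mean expression over samples with an untied majority) is nearest in
Euclidean distance, then to the lowest label index. Both steps are
deterministic.

`k` is chosen as the argmax of the mean silhouette of the consensus labeling
over a candidate grid (default 2–6), smaller `k` on ties. By default each
gene is z-scored before clustering — Euclidean distance over raw expression
is dominated by high-magnitude genes — and clustering runs on a supplied
gene panel when given, else on the 2000 most variable genes.

## Cross-fusion attention classifier

One expression profile is an ordered gene sequence; the order is fixed by
descending training-set variance and frozen into the model, making the
"sequence" reproducible without pretending genes have an intrinsic order.
The two branches share a token grid of `L = n/4` positions:

* spatial branch: three 1-D convolutions over the raw sequence (channels
  32/64/64, kernel 3, ReLU) with max-pool 2 after the first two layers, so
  the output naturally has length `n/4`;
* temporal branch: a bidirectional LSTM over non-overlapping width-4 windows
  of the same sequence (hidden 32 per direction), forward and backward
  outputs concatenated.

Both are linearly projected to `L × d` (default `d = 64`) and fused:

    Fcg = softmax(Fc · Fgᵀ / √d) · (Fc + Fg)

The √d scaling is the canonical scaled-dot-product choice; a `scale="d"`
flag divides by the feature dimension itself for the literal variant of the
formula. The sum `(Fc + Fg)` is taken literally element-wise (the equal
shapes are enforced by the projections) rather than read as concatenation.
Fused tokens are mean-pooled, dropped out (0.2) and classified by one fully
connected layer + softmax; training minimises mean cross-entropy against the
consensus pseudo-labels with adaptive-moment updates (lr 1e-3, batch 32),
an 80/20 stratified validation split and early stopping (patience 20,
cap 200 epochs). All of these are config fields.

The network runs on a small in-repo reverse-mode autodiff engine over numpy
arrays (elementwise ops, batched matmul, im2col convolution and pooling,
softmax/log-softmax, slicing/concat). Every operator's gradient is checked
against central finite differences in the test suite. No GPU is used or
required at these problem sizes.

Ablation trains CNN-only, BiLSTM-only and full-fusion variants under
identical data, seeds and epoch budget. For the scripted ablation runs the
budget is 25 epochs (patience 6, batch 64): on the separable synthetic
cohorts used throughout, training converges well inside that window and the
three variants remain strictly comparable.

## Hub-gene selection

Two selectors on the same labelled matrix, intersected:

* L1-penalised (multinomial) logistic regression on per-gene standardised
  expression over a 16-point logarithmic penalty grid, 5-fold stratified CV
  on log-loss; the penalty follows the one-standard-error rule (sparsest
  model within one SE of the CV minimum; a `rule="min"` flag takes the
  minimiser). A gene counts as selected if its coefficient is nonzero for
  any class.
* Random-forest permutation importance (default 1000 trees, 3 permutation
  repeats), top 30 genes. Permutation importance was preferred over impurity
  importance because expression features are correlated and impurity
  importance inflates correlated, high-cardinality features.

The hub set is the intersection, ordered by forest importance. An empty
intersection is legal and warns rather than fails.

## Prognostic model

1. **Univariate Cox screen** per gene (Efron tie handling, via lifelines);
   "associated with survival" is operationalised as Wald p < 0.05 — a hazard
   ratio is never numerically 1, so the HR ≠ 1 phrasing adds nothing
   testable. Constant genes yield NA rows, never significance.
2. **Random survival forest** (scikit-survival, log-rank splitting) on the
   screened genes; permutation importance ranks them; the out-of-bag error
   (1 − OOB concordance) is recorded every 25 trees by warm-start growth,
   with a plateau flag when the last quartile of the trajectory spans less
   than 0.02.
3. **Risk function**: the forest supplies the ranking, but the printed
   proportional-hazards form f(t|x) = f0(t)·exp(Σ coefᵢ·geneᵢ) requires
   coefficients, so the top-m genes (default 9) are refit in one
   multivariable Cox model; f0 is the Breslow baseline cumulative hazard
   from that fit. The reported per-sample score is exp(linear predictor),
   the time-free factor; the full cumulative hazard is available by
   composing with the baseline. Forest ensemble mortality remains available
   as an alternative score via the fitted forest object.
4. **Cutoff**: maximally selected rank statistics — the candidate cutpoints
   are midpoints between consecutive sorted unique scores whose split keeps
   both groups ≥ 10% of the cohort; the cutoff maximises the absolute
   standardised log-rank statistic, computed exhaustively (the candidate set
   is at most n−1 points, so there is nothing to approximate). No
   multiplicity correction is applied to the selection itself; the
   Kaplan-Meier log-rank p-value reported for the resulting high/low groups
   is therefore labelled post-selection and should be read descriptively.
5. **Concordance**: Harrell's C with censoring-aware comparability (a pair
   is usable iff the smaller observed time is an event; score ties count
   0.5), computed by vectorised O(n²) pair counting. "Over time" evaluation
   truncates eventhood at a horizon grid (quartiles of observed event times)
   so only pairs comparable by each horizon contribute.

## Synthetic cohorts

The generator emulates a normalised bulk cohort, not counts: the pipeline
consumes log-normalised expression, so simulating at that level is
sufficient (a log-normal option exponentiates the values for heavier tails).
`k` subtypes are planted as mean shifts of ±effect_size/2 on the informative
genes, using mutually orthogonal Sylvester-Hadamard sign patterns so that
every pair of subtype centroids differs by `effect_size` noise-SD per
informative gene — separation scales with one interpretable knob. Noise
genes are standard Gaussian. Survival times are exponential with rate
`baseline_rate · exp(Σ coef · expr)`; censoring is independent uniform on
[0, c] with the cap calibrated by root finding so the expected censored
fraction hits the target. Default conditions used by the scripted analyses:
300 samples, 200 genes, k = 3, 40 informative genes, effect size 3 (the
moderate-separation replicates use 1.5), 20% censoring, baseline rate 0.1.

What the generator does **not** emulate: count noise and library-size
effects, batch effects, gene-gene correlation beyond the planted block
structure, non-proportional hazards, informative censoring. Tests passing on
these cohorts therefore demonstrate correctness of the algorithms under
their stated assumptions, not robustness to real-cohort artefacts.

## Numerical and degenerate-input choices

* Loading refuses NaN, duplicate identifiers and non-numeric cells outright;
  no imputation anywhere, missing model genes are errors.
* Gene symbols are matched case-sensitively and never munged.
* Composite gene panels support both overlap policies: `drop_shared` removes
  symbols named by ≥ 2 pathway lists (a strictly non-overlapping signature);
  the default `keep_annotated` keeps the union and records multi-pathway
  membership as provenance, since multi-pathway genes (e.g. CASP8) are
  typically the biologically interesting ones.
* GMM covariance regularisation 1e-4; silhouette of a single-cluster
  labeling is treated as −1 in the k scan.
* One master seed fans out to per-algorithm / per-stage seeds through
  spawned `SeedSequence`s in fixed order, so all outputs are reproducible
  byte-for-byte and any stage can be rerun independently.
* Attention row-softmax subtracts the row max before exponentiating;
  probabilities are clipped at 1e-12 before logs in CV scoring.

## Known limitations

* CLARANS cost evaluation is exact (full distance matrix), appropriate for
  cohorts of hundreds to a few thousand samples, not for very large n.
* The classifier requires the training gene panel verbatim at prediction
  time; cross-cohort transfer with mismatched panels is deliberately
  unsupported.
* The univariate screen fits genes independently; no multiple-testing
  correction is applied at the screen stage (the screen is a filter, and the
  downstream forest + refit provide the actual model selection).
* The post-selection log-rank p-value after a maxstat cutoff is optimistic
  by construction; a permutation calibration would be needed for honest
  inference on the split.
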