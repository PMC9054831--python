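# Methods

This note records the models, conventions and parameter choices behind
`cardioforest`, and what the synthetic benchmarks do and do not demonstrate.

## Label-transfer model

The classifier stack is transductive: a model is trained *against* a given
query's gene space. Per stage (type, zone, side):

- **Detection filter.** Genes detected (raw count > 0) in fewer than 25 % of
  a dataset's cells are excluded from that dataset's candidate set. Detection
  is evaluated on raw counts; the log-normalized layer is used for all
  variance statistics.
- **Highly variable genes.** Per dataset, CV² = var/mean² of the
  log-normalized values is regressed on 1/mean (Huber-robust linear fit,
  design [1, 1/μ]); genes are ranked by the ratio CV²/fitted and the top
  ⌊n/2⌋ retained. The train and test survivor sets are intersected, in train
  gene order. Fitted values are floored at 1e−12 before division.
- **Scaling.** Per dataset and per gene: subtract the minimum, divide by the
  95th percentile of the min-subtracted values (linear interpolation between
  order statistics, h = (n−1)p). A gene whose 95th percentile is 0 maps to
  all zeros. The percentile is taken after min subtraction; for log1p
  normalized data the minimum is ≥ 0, so the order of the two operations
  cannot change the result. Records of (min, q95) are kept per dataset but
  never transferred between datasets — cross-platform alignment comes from
  each dataset being self-scaled.
- **Quantile normalization (side stage only).** Train and query cells are
  pooled over the stage's gene set; the reference profile is the mean sorted
  value vector over all pooled cells; each cell's values are replaced by the
  reference at their within-cell ranks (stable sort; ties keep input order).
  The reference profile is stored in the trained stage so later queries can
  be mapped onto the same profile before their own scaling.
- **Forests.** scikit-learn `RandomForestClassifier`, `class_weight=
  "balanced"`, seeded, single-threaded. Round one fits on all selected genes
  and ranks them by impurity importance (ties broken by gene id); round two
  refits on the top panel. Defaults: type 300 trees / 500 genes, zone
  300 / 100, side 500 / 100. Argmax ties at prediction break toward the
  lexicographically first class label.
- **Hierarchy.** Zone and side stages are trained on reference cardiomyocytes
  only (cells with missing subgroup labels are dropped with a warning; a
  stage with fewer than two usable classes is skipped) and applied only to
  query cells whose *predicted* type is cardiomyocyte.

Cross-validation uses seeded, stratified-by-type folds; every cell is
predicted exactly once. Hyperparameter sweeps evaluate one seeded stratified
holdout per grid value; the "elbow" is the smallest grid value whose marginal
accuracy gain to the next value is at most 0.5 percentage points, falling
back to the largest value when accuracy keeps climbing — an explicit,
computable stand-in for choosing the elbow of an accuracy curve by eye.

## Anomaly detection

Per type class, the threshold is the minimum over two development datasets of
the 5 % quantile (linear interpolation) of the predicted-class probabilities
of cells *predicted* as that class. Conditioning on the predicted rather than
the true class means calibration needs no labels on the development sets; a
truth-conditioned variant is available when labels exist. A prediction is an
anomaly when its probability is strictly below its class threshold; flagged
cells keep the type call but lose zone/side labels. Thresholds exist for type
classes only — the zone and side stages have no rejection step. By
construction roughly 5 % of a development set's own cells per class fall
below that set's quantile, so the min-of-two rule flags at most about that
share of in-vocabulary cells.

## Multiplet estimation

The estimator treats doublet composition as proportional to constituent-cell
abundance: within-sample weight Σ_j N_j², between-sample weight
Σ_{i>j} N_i N_j (self-pairs effectively counted as ordered, cross pairs as
unordered — the weights are implemented exactly as written; a `combinatorial`
flag switches the within weight to Σ_j C(N_j, 2)). Fractions are computed in
exact rational arithmetic. N counts singlet-*called* cells only: between-
sample doublet calls and negatives are excluded, which makes
D_b = N p_m π_b self-consistent for small p_m. `n_within` rounds half away
from zero. Higher-order multiplets are assumed negligible. When only one
sample has cells, π_b = 0 and the rate is unidentifiable (an error); an
estimate above 1 is reported as computed, with a warning.

The pool simulator draws doublet compositions from the same abundance
weights, so the estimator is consistent with the generative process by
construction; its `doublet_rate` is defined relative to that same N (number
of singlet-called cells), solved self-consistently at generation time so the
estimated and configured rates are directly comparable. Doublet expression
profiles are the sum of two independent cell profiles, giving the ~2×
library-size signal that score-based flagging exploits.

## QC and normalization

Cell filters are inclusive exactly as stated: library ≥ 2000 UMIs,
1000 ≤ detected genes ≤ 8000, mitochondrial fraction ≤ 0.30. Mitochondrial
genes are matched by a configurable regex on gene symbols (default `^MT-`);
whether "mitochondrial reads" should be counted pre- or post-deduplication is
ambiguous in common usage — UMI counts are used here. Gene filter: ≥ 1 count
in ≥ 5 cells. Normalization uses library-size factors (library / mean
library; log1p of count / factor); pooled-deconvolution size factors are an
external method and are *not* re-implemented — the `method` argument leaves
room for plugging in externally computed factors, and every downstream step
only requires a monotone per-cell normalization. Cross-batch scaling
normalization is out of scope; datasets are normalized one batch at a time.

## Synthetic data: what it emulates, and what it does not

Counts are negative binomial (variance μ + φμ², default φ = 0.3) around a
long-tailed per-gene baseline (lognormal, meanlog −0.7, sdlog 1.2 — median
library ≈ 2000 UMIs over 2000 genes), multiplied by marker fold-changes,
thinned binomially for dropout and scaled for depth. Defaults encode the
study conditions used throughout the tests: 4 cell types × 200 reference
cells, 2000 genes; disjoint marker blocks of 50 genes at 8-fold per type,
30 genes at 3-fold per zone, 20 genes at 1.8-fold per side (zone and side
subdivide cardiomyocytes 50/50); the reference platform has depth 1.0 and
dropout 0.1, the default query platform depth 0.5, dropout 0.2 and gene-wise
lognormal scale noise (σ = 0.3), with query groups at 75 % of reference
sizes. The effect-size ladder is chosen to reproduce the qualitative
difficulty ordering (type easiest, laterality hardest) observed in real
fetal-heart transfers, not to match any published accuracy value. Group
means ("biology") derive from the config seed independently of the sampling
noise stream, so reference, query and development sets share identical
population means.

The generator does **not** emulate: continuous differentiation trajectories,
correlated gene modules, batch-effect manifolds, ambient RNA, cell-cycle
structure, or shared/overlapping marker programs. Passing benchmarks
therefore demonstrate the machinery's correctness and its behavior under
platform shift and out-of-vocabulary populations — not expected accuracy on
real tissue, where class boundaries are far less clean.

## Benchmark problem sizes

The shipped benchmarks use 2000 genes with 800 reference + ~600 query cells
per seed (transfer and anomaly experiments; the transfer benchmark in the
acceptance script averages three seeds, the test suite ten), 20 replicate
pools of 10⁴ cells for multiplet-rate recovery, and 50–200 repetitions for
the downsampled DEG design. These sizes give Monte-Carlo errors well inside
the asserted tolerances while keeping a full run in the minutes range on a
single core.

## Known limitations

- The trained model is tied to the query it was trained against (feature
  intersection is transductive); predicting a different query requires the
  same gene space, and retraining is recommended.
- Library-size normalization can be biased under strong composition effects;
  deconvolution factors from an external toolchain are preferable for real
  data with heterogeneous populations.
- The DEG engine inside the resampling design is a per-gene Mann–Whitney test
  with Benjamini–Hochberg control — deliberately simple and pluggable; the
  design under test is the resampling, not the engine.
- Laterality prediction is intrinsically hard (weak markers); on synthetic
  defaults it lands around 60–75 % conditional accuracy, and moderate
  accuracy should likewise be expected on real data.
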