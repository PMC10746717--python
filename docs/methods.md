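# Methods

## Problem setting

Given a label-free tear-proteome quantification table (patients ×
proteins, peak areas) and a per-patient MGD severity grade in {2, 3, 4},
the package identifies proteins whose abundance patterns carry severity
information, by two complementary routes: model explanation (Shapley
attributions of gradient-boosted classifiers, optionally weighted by
prediction confidence) and classical differential abundance (ANOVA +
fold change + FDR). The cohort is treated as the object of study — the
models are explanatory instruments fitted and interrogated on the full
cohort, never validated predictors.

## Preprocessing

The order of operations is fixed and semantically load-bearing:

1. **Sparse-level exclusion** (`min_count=2`): a severity level with a
   single patient cannot support group statistics or stratified
   training; its patients are removed from both tables.
2. **Contaminant removal** by case-insensitive substring match on the
   protein *name*: patterns `keratin`, `dermcidin`, `dermacolin`,
   `dermcolin`, `trypsin`, with keep-patterns for keratins 18 and 19
   (genuine epithelial constituents of tears) taking precedence. The two
   dermacolin spellings are matched as one family. Matching is on names,
   not accessions, because contaminant families are named consistently
   while accessions are arbitrary.
3. **Never-detected removal**: columns that are missing in every
   patient are constant and carry no information.
4. **Special-value encoding**: recorded 0 (protein inference) → 1,
   *then* missing (not detected) → 0. Running these in the stated order
   keeps the two states distinguishable after encoding; the reverse
   order would merge them. Encoded this way, "not detected" sits at the
   bottom of the abundance scale and "inference" just above it.
5. **log1p + standard scaling**: peak areas are right-skewed over
   several orders of magnitude. The natural-log `log1p` is chosen over a
   plain log because the encoded data legitimately contains 0s;
   `log1p(0) = 0` keeps non-detections at the floor and the map is
   monotone everywhere. Scaling uses the population standard deviation
   (divide by n, the ML-scaler convention); constant features map to
   all-zero columns rather than erroring, with `sd` recorded as 0. The
   fitted per-feature (mean, sd) are stored so the identical transform
   can be re-applied to new data bit-for-bit.

The log base and pseudo-count are genuinely open choices for this kind
of data; `log1p` is the package's committed default and any monotone
alternative would leave tree-based models' splits unchanged (trees are
invariant to monotone feature transforms), affecting only the stored
scaling parameters.

## Classifiers

`LGBMClassifier` with `num_leaves=2` and `is_unbalance=True`, all other
hyperparameters at library defaults. With two leaves every boosted tree
is a single-split stump: an intentionally weak learner that (a) resists
overfitting on a wide (p ≫ n) matrix, and (b) makes exact Shapley
attribution cheap (see below). `is_unbalance` counters the skewed level
composition (roughly 13% / 54% / 33% at levels 2/3/4 in the reference
design) in the binary tasks. Training is configured fully deterministic
(`deterministic=True`, `force_row_wise=True`, single thread, explicit
seed). Probability ties at argmax resolve to the lowest class label so
reports are reproducible.

Metrics — balanced accuracy (mean per-class recall), F1
(support-weighted average for multiclass, positive class for binary) and
MCC — are computed on the training cohort itself. These numbers describe
how well the models separate the cohort they explain; they are not
generalization estimates.

## Exact Shapley attribution

Attributions are interventional Shapley values of the raw margin
(log-odds) — the native additive scale of a tree ensemble — with the
coalition value

    v(S) = E_b [ f(x_S, b_{N\S}) ]

taken over a background set (default: the cohort itself). Because v is
linear across trees, the ensemble attribution is the sum of per-tree
attributions. A tree splitting on a single feature j gives the closed
form φ_j = f_t(x_j) − mean_b f_t(b_j); with `num_leaves=2` this covers
every tree, so attribution of a whole analysis costs one pass over the
dumped tree structures. Trees using several features (supported up to
12) fall back to exact subset enumeration. Features unused by every
tree receive exactly 0 (null player); local accuracy holds to machine
precision by construction and is asserted at 1e-8 in the tests.

An independent oracle, `exact_shapley`, evaluates the classic Shapley
formula by full 2^p enumeration against the *booster's own* predict
function, so the test suite cross-checks two independent code paths
(our tree parser vs LightGBM's evaluator) on randomized stump
ensembles.

Binary models natively emit one margin; the attribution tensor exposes
the positive class and its exact negation as the negative class. For
the confidence grouping below, probabilities (softmax/sigmoid of the
margins) are used, while attributions stay on the margin scale — the
grouping and the attribution scale are independent choices.

## Uncertainty weighting

With τ = 0.6 (configurable), each prediction is **Positive** (correct,
predicted probability strictly > τ), **Negative** (wrong, > τ) or
**Borderline** (≤ τ; the boundary value is borderline by definition).
Weighting multiplies attributions by a strictly positive factor, so
signs never flip:

* Positive, predicted class: × 1/(1 − p) — strictly increasing in p,
  ≥ 1/(1 − τ) = 2.5 at the threshold;
* Negative / wrong classes: × (1 − p) — strictly decreasing in p,
  ≤ 1 − τ = 0.4 at the threshold;
* Borderline: unchanged.

Probabilities are clipped to [1e-6, 1 − 1e-6] before the division: tree
ensembles can emit probabilities numerically equal to 1, which would
make the Positive factor unbounded.

For multiclass models the weighting is per class using **each class's
own predicted probability**: on a correct prediction the predicted
class is upweighted and every other class downweighted; on an incorrect
prediction the true class is upweighted (by its own probability, which
may be below τ) and all wrong classes downweighted. The alternative —
using the predicted class's probability for every class — was
considered and rejected: it would downweight a class by a confidence
that is not about that class.

Aggregation modes:

* `incl_bl`: all samples retained; requires ground truth (to tell
  Positive from Negative). Borderline attributions pass through
  unchanged.
* `excl_bl`: borderline samples dropped, everything else left
  *unweighted* — usable without ground truth.

Global importance per protein is Σ over retained samples (and, for
multiclass, classes) of |weighted attribution|. A signed-sum variant is
provided (`signed=True`) because "sum of the attribution values" is
ambiguous between the two; the absolute sum is the default since a
protein pushing different samples in different directions is still
informative. Ranking ties break lexicographically by accession. Two
degenerate identities pin the semantics: τ = 1 makes everything
borderline and `incl_bl` a no-op; a borderline-free cohort makes
`excl_bl` a no-op. Rankings are compared at top-k (default k = 15, a
practical cutoff for expert review); the comparison reports rank shifts
and the proteins newly entering the top-k.

## Differential abundance

Per protein: one-way ANOVA F-test across severity groups on
log-transformed values; Benjamini–Hochberg adjustment; significance ⇔
q ≤ 0.01 and max-fold-change ≥ 2, where max-fold-change =
(largest group mean + 1)/(smallest group mean + 1) on the raw scale
(the pseudo-count of 1 guards a fully-undetected group; on peak-area
scales of 10^3–10^7 it is negligible). ANOVA on the log scale and fold
change on the raw scale is the package's committed reading of the
criteria — the scale for each is not dictated by the criteria
themselves. A column with zero variance overall returns p = 1 by
convention. Pairwise level contrasts use a two-sided Mann–Whitney test
(a Welch t-test is available via `method="ttest"`); markers: `*` for
p < 0.05, `borderline` for 0.05 ≤ p < 0.06.

## Synthetic cohorts

`SimConfig` defaults encode the reference study design: 31/126/76
patients at levels 2/3/4 (233 total) and ~2000 protein features. Per
protein, a mean log2 abundance is drawn N(15, 2.5²) (peak areas
~10^3–10^7, right-skewed and wide on the raw scale); per patient, noise
N(0, 1²) in log2 units is added. Planted effects shift group means by
specified log2 fold changes relative to a baseline level. Missingness
is missing-not-at-random: each entry is detected with logistic
probability in its own log2 abundance (midpoint 10, slope 0.8 → ~7%
missing overall, concentrated in low-abundance proteins — the standard
LC-MS detection-limit mechanism). Detected entries become inference
zeros with probability 0.01. Named contaminants (keratin 1, keratin 18
as a keep-list probe, dermcidin, trypsin-1, putative trypsin-6) are
appended as extra columns. All randomness flows from one seed through
spawned `SeedSequence` streams; no global state.

What the simulator does **not** emulate: peptide-level structure,
correlated protein modules, batch effects, heavy-tailed or multiplicative
error beyond log-normal, or cohort demographics. Tests passing on
synthetic cohorts therefore establish the correctness and calibration of
the *procedures* (filters, encodings, attributions, weighting algebra,
FDR control) — not that real tear proteomes will yield any particular
protein list.

## Problem sizes and numerical choices

The test suite and the acceptance script run on scaled-down cohorts
chosen to exercise every code path at comfortable desk scale: 233
patients × 200–300 proteins for end-to-end signal recovery (10 planted
proteins, |log2FC| up to 1 between extreme levels, medians over 10–20
seeded replicates), 600 proteins × 180 patients for null calibration,
200 replicate datasets for false-discovery control, and 300 planted
instances for power. Oracle equivalence uses ensembles of ≤ 20 stumps
over ≤ 8 features so the 2^p enumeration stays exact and fast.
Tolerances: 1e-6 per entry for oracle agreement (accumulated float
error across trees), 1e-8 for local accuracy, 1e-8 for standardization
moments.

## Known limitations

* Training-set metrics are descriptive, not predictive; no external
  validation exists by design.
* The weighting scheme is a heuristic reweighting, not a calibrated
  uncertainty propagation; its value is assessed via ranking stability
  and planted-signal retention, not probabilistic guarantees.
* Peptide-count filters and spectral normalization (performed upstream
  by vendor software in real workflows) are out of scope; the package
  consumes protein-level tables only.
* Exact attribution assumes numeric `<=` splits (LightGBM's default for
  continuous features); categorical splits are not supported.
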