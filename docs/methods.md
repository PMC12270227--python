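# Methods

`cpscreen` implements the analysis layer of an *activated* Cell Painting
screen: cells are profiled both resting and after broad pathway activation
(a PKC agonist such as PMA), and every downstream statistic is organised
around the question of which compounds become phenotypically visible in
which condition.  This note records the models, the numerical choices, and
what the synthetic data do and do not establish.

## HistDiff fingerprints

For each feature *f* and well *w* on a plate, the per-cell values are
binned into a histogram and compared against the histogram of the pooled
reference-control (DMSO) cells of the same plate:

* **Bins** — 20 uniform bins spanning the plate's pooled per-feature range
  (all scored wells together), half-open with the last bin closed.  Twenty
  bins balance resolution against typical per-well cell counts (~400
  cells).  A zero-variance feature falls back to the range
  [v − 0.5, v + 0.5].
* **Smoothing** — one pass of a 3-tap (0.25, 0.5, 0.25) kernel, truncated
  at the edges, then normalization to unit sum.  A minimal symmetric kernel
  keeps the operation reproducible and exactly documentable.
* **Score** — `sign · Σ_b (T_b − R_b)²`, with the sign taken from the
  bin-midpoint-weighted mean displacement of the treatment histogram
  (positive = shifted toward higher values).  The score is dimensionless,
  0 for identical histograms, and bounded by 2 in magnitude for unit-sum
  histograms (Σ(T−R)² ≤ Σ|T−R| ≤ 2).

The comparison formula is this package's documented reconstruction of the
histogram-difference approach; it sits behind the single `histdiff_score`
seam so an alternative functional can be swapped without touching callers.

**Leave-one-out reference scoring.** Reference wells are scored against
the pooled reference population *excluding their own cells*.  With the
pool included, a reference well's null score is smaller than an untreated
experimental well's by a factor of about (N−1)/(N+1) for N reference
wells — and because the CP Activity Score averages ~500 features (relative
SD ≈ 6%), that small bias is decisive at the threshold, roughly doubling
the false-active rate of untreated wells.  Leave-one-out restores
exchangeability between reference and untreated wells, which is what a
control-derived threshold assumes.

**Block normalization.** Plates with staining stripes are partitioned into
row blocks; each block is fingerprinted independently against only its own
reference wells (bin ranges recomputed per block) and the results are
concatenated.  With one block this reduces exactly to whole-plate
processing.  Each block must contain at least one reference well; the many
randomly placed reference wells (32 by default) make this hold in
practice.

## CP Activity Score and thresholds

`CPscore = (1/n) Σ_i x_i²` over the n finite feature scores x_i of a
fingerprint; missing features are excluded from numerator and denominator.
Three control-derived thresholds are implemented, as printed:

* **IQR** — controls above Q3 (type-7/linear-interpolation quantile,
  recorded in provenance) are outliers; the highest remaining control is
  the threshold.  A conventional Q3 + 1.5·IQR fence is available behind
  `fence="tukey"` for sensitivity analysis.
* **FDR (q = 5%)** — the ⌈q·N⌉ largest controls are excluded (descending
  order, stable index tie-break); the highest remaining control is the
  threshold.  Note the threshold is the (N−k)th order statistic, so the
  null exceedance probability is (k+1)/(N+1) ≈ q + 1/(N+1), slightly above
  q for small control pools — thresholds should be derived from the pooled
  reference wells of the whole screen (128 wells with 4 plates), not one
  plate.
* **Elbow** — all scores sorted ascending; the knee is the point of
  maximum perpendicular distance to the first-to-last chord with both axes
  normalized to [0, 1].  Normalization is what makes the knee invariant
  under affine rescaling of scores; a collinear curve (max distance below
  1e−9) is a degenerate-input error.

Activity is a strict comparison (`score > threshold`).  Cytotoxicity is
flagged when a well's cell count falls strictly below 50% of the mean
reference-control count.  The illumination summary partitions compounds
into active-in-both / activated-only / resting-only / dark.

## Quality control

* **ChP2** (brightfield activation gate) — cells with area > 2,000 μm² or
  brightfield mean < 10,000 are removed; a regularized logistic regression
  on the 23 brightfield features (6 morphology, 9 intensity, 8 SER
  texture), folded into a single raw-feature linear rule, estimates each
  control well's percent activated (100·a/(a+b)).  A plate passes iff at
  most two no-PMA controls exceed 15% activated and at most two PMA
  controls fall below 30% (strict comparisons).  The classifier contract
  is the decision interface, not specific weights — the original
  instrument-trained model is not reproducible.
* **ChP5** (control anomalies after scoring) — abnormal = reference
  control scoring active, or positive control (condition-swapped or JUMP
  well) scoring inactive.  Decisions: **repeat** if >22% of controls are
  abnormal at the outset; else if more than 3 wells are abnormal (the
  printed "10% (3 wells)" rule is a well count), abnormal wells are
  dropped, the threshold recomputed on the remaining reference controls,
  and the plate is **rescreened** if ≥3 stay abnormal, else
  **renormalized**; otherwise **pass**.
* **Paired-condition table** — per-well (resting score, activated score)
  with strict quadrant assignment at the threshold.  Axis convention is
  fixed as x = resting, y = activated and recorded in output metadata.
* **JUMP reproducibility** — all pairwise Pearson correlations of
  replicated positive-control fingerprints, grouped within plate / between
  plates / between batches, exported long-format for violin plots.

## Feature reduction and clustering

Zero-SD features are dropped first.  Collinearity reduction then
iteratively removes, from the currently most-correlated pair with
|Pearson r| > 0.8, the member with the higher mean absolute correlation to
all remaining features (descending-|r| processing, lexicographic
tie-breaks).  The order is fixed so the recorded removal list replays to
the identical retained set; the procedure is idempotent.  Per-condition
reduced fingerprints concatenate column-wise with condition-suffixed names
(482 + 482 → 964 at the default feature count).

UMAP (correlation metric, 10 neighbors, default 100 components, fixed
`random_state`, everything else library defaults) is a library-backed
stage; its parameters are pinned and recorded in provenance, never
re-derived.  Pearson similarity matrices feed HDBSCAN through distance
1 − r (sign-aware, not 1 − |r|: anticorrelated phenotypes are dissimilar
under guilt-by-association logic); `scikit-learn`'s HDBSCAN implementation
is used.  Hierarchical clustering is complete linkage on the same
distance, with deterministic leaf order; exports are a clustered TSV plus
newick trees, an optional compartment-prefix column ordering (ER_, Nuc_,
Mito_, AGP_, RNA_), and a similarity-above-cut edge list for network
viewers.

## Target-class analysis

* **Enrichment** — per class, the in-class pairwise similarities are
  compared to member-to-non-member similarities with a one-sided
  two-sample KS test (alternative: in-class stochastically greater).  Raw
  p < 0.05 is the default significance call; Benjamini–Hochberg-adjusted
  values are reported alongside.  Classes with fewer than two members are
  skipped.
* **Consolidation entropy** — with active compounds clustered per
  condition (HDBSCAN on pairwise Euclidean fingerprint distances), each
  class's entropy is the base-2 Shannon entropy of its members'
  distribution over cluster labels; each noise point (label −1) counts as
  its own singleton cluster, so full scatter is maximal entropy and fusion
  into one cluster is 0 bits.  delta = H(activated) − H(resting) < 0 means
  the class consolidated under activation.  The entropy functional over
  cluster memberships is a reconstruction (the combination of in-class
  distances into an entropy is otherwise unspecified); labels and
  distances are injected so the functional is swappable.

## GR nuclear translocation

A cell is nuclear-enriched iff **all six** ratio criteria hold strictly:
GRnucSum/HoechstNucSum > 0.35, GRnucSum/GRcytoSum > 0.25, and
nuc/cyto > 1.7 for mean, median and 50% quantile, nuc/cyto contrast
> 0.3.  Conjunction is the only reading under which every listed threshold
matters; boundary cells fail.  Cells with a non-positive denominator are
excluded from both numerator and denominator of the well percent.  The
well summary pools cells by default; a per-field average is available
(`per_field=True`), since per-field computation is how instrument
pipelines typically operate.

## The synthetic screen

No image-derived data from an activated screen are publicly deposited, so
the generator plants known truth at realistic screen geometry:

* 384-well plates: dye wells fixed at A01/P24, 64 controls by default
  (32 reference, 24 JUMP wells = 8 compounds × 3 replicates, 8
  condition-swapped activator controls) at randomized positions, 318
  experimental wells.
* Reference features: Normal(μ_f, σ_f) with per-feature parameters drawn
  once per screen (a log-normal option models intensity-like skew); F =
  482 features named with compartment prefixes.
* Activation signature: +1 SD on a random 30% of features, applied to
  **every** activated well — so in-plate reference normalization cancels
  it, which is precisely why HistDiff-vs-in-plate-controls works for
  activated screens.
* Compound effects: location shift (in control-SD units) and SD scaling on
  a planted feature subset, with condition specificity (both /
  activated-only / resting-only / none).  The default screen plants 1,000
  compounds: 50 both, 30 activated-only, 20 resting-only at 1.5 SD on 20
  features, 900 inert; ~10% of actives also kill 60% of cells.  JUMP
  compounds carry fixed condition-independent effects so positive controls
  behave as such.
* Cell counts: negative binomial (mean 400, dispersion 10); over-dispersed
  counts deliberately stress the cytotoxicity flag — with these
  parameters a 60%-kill compound is flagged in roughly three quarters of
  wells, not always, which is the realistic regime.
* Brightfield generator: two overlapping multivariate populations over the
  23 classifier features separated on the discriminative texture/intensity
  subset; junk cells planted outside the prefilter gates.  GR generator:
  criterion ratios sampled from an all-pass regime with the planted
  probability, else with at least one forced violation — so classifier
  recovery is exact and deviations of the well percent from the planted
  fraction are purely binomial.

**What passing tests show, and don't.** The generator produces
well-behaved unimodal per-feature distributions, independent features
within a well, and exchangeable plates.  Real Cell Painting data have
correlated features, batch and edge effects beyond the single planted
stripe, and multimodal per-well populations.  Recovery of planted effects
here validates the *statistical machinery* (normalization, calibration,
thresholds, decision rules), not screen-level biological conclusions; the
original study's headline percentages depend on its unreleased data and
are not reproduced.

## Problem sizes and determinism

Every stochastic operation derives its generator from an explicit seed via
`SeedSequence` spawn keys, so identical seeds give identical outputs
regardless of stage order; UMAP runs with a fixed `random_state`.  The
test suite exercises the full default screen (4 plates × 2 conditions ×
~150k cells × 482 features per plate) over 10 seeds for recovery checks,
with smaller designs (8–60 features, 60–400 cells/well) for calibration
loops; these sizes were chosen so the whole suite completes in minutes on
one CPU while keeping every statistical check at the default screen
geometry where it matters (128 pooled reference wells per condition).

## Known limitations

* The histogram-difference score is a documented reconstruction, not a
  line-for-line port of any external implementation.
* The ChP2 classifier is a generic regularized linear model; only the
  decision interface matches instrument pipelines.
* The consolidation-entropy functional is one defensible reading of an
  under-specified procedure (see above).
* Thresholds derived from small per-plate control pools run above the
  nominal FDR (exceedance (k+1)/(N+1)); pool controls across plates.
* The illumination false-active rate is per condition; across two
  independent conditions the union is necessarily ≈ 2q.
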