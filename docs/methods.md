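# Methods

## Scope and data model

The package analyses two linked data layers from DSP-profiled tumor tissue:

1. **CellTable** — per-ROI classified cell centroids (`roi_id, cell_id,
   x_px, y_px, cls ∈ {tumor, immune, other}`) in pixel coordinates, either
   imported from an external segmentation (QuPath-style exports) or produced
   by the built-in maxima detector (`timetopo.imaging`);
2. **AOIMatrix** — AOI × marker protein counts with per-AOI metadata
   (patient, ROI, segment, nuclei count, area, slide) and marker roles
   (targets, housekeepers, isotype controls, hybridization controls).

Because the cohorts this workflow targets are not publicly distributable,
the synthetic layer (`timetopo.synthetic`) is first-class: it generates both
layers with the exact statistical structure the downstream stages assume,
so every stage is testable against known truth.

## Point-pattern simulation

ROIs are discs of diameter 300 µm (the DSP ROI geometry), reported in
pixels at 0.4 µm/px — the scale at which a 30 px band is 12 µm and a 50 px
band is 20 µm. Three generative topologies:

- **diffuse** — tumor and immune positions drawn independently, uniformly
  on the disc (r = R√u). A diffuse pattern is literally a random labeling
  of a homogeneous point pattern, so its ccr values are 1 in expectation.
- **focal** — immune cells from a Thomas-style parent–offspring process:
  `n_immune_clusters` parent centers uniform on the disc, Gaussian offsets
  with SD `cluster_sd_um`, truncated to the disc by resampling. Tumor cells
  are uniform on the disc *minus* an exclusion disc of radius
  `tumor_exclusion_factor × cluster_sd_um` around each parent. The
  exclusion encodes what a focal niche is histologically: an immune
  aggregate occupying space within the tumor, not an overlay on top of it.
  Without it, immune-cluster edges inflate the permutation null's expected
  tumor–tumor count and push ccr_tt *below* 1, inverting the focal
  phenotype; with it, focal ROIs show ccr_tt > 1 and depressed gdc, the
  direction observed in annotated tissue.
- **insignificant** — diffuse placement with the immune count capped at the
  largest value keeping immune_ratio < 0.2 (a requested larger count is
  capped, not an error, so configs stay composable).

Defaults: `n_tumor = 250`, `n_immune = 80` (immune ratio 0.24, safely above
the insignificance cutoff for infiltrated patterns), 3 clusters,
`cluster_sd_um = 20`, exclusion factor 2.5. Per-ROI cell counts in 300-µm
regions of carcinoma tissue are of order a few hundred; the defaults are
one realization of that order and are fully configurable. All draws flow
from one `numpy` generator seeded per call.

## Count simulation

Natural-log counts per AOI *a*, with size factor
`s_a = log(nuclei_a / 200)`:

| marker class | model |
| --- | --- |
| target m | `baseline + β[group_a, m] + b_pat(a) + s_a + lane_a + ε` |
| housekeeper | `hk_baseline + s_a + lane_a + ε` |
| isotype | `iso_baseline + slope·s_a + lane_a + ε` |
| hybridization control | `hyb_baseline + lane_a + ε_small` |

with `b_pat ~ N(0, patient_sd²)` (default 0.5), `ε ~ N(0, noise_sd²)`
(default 0.2), `lane_a ~ N(0, lane_sd²)` (default 0 — enable to exercise
hybridization normalization), and `background_slope` defaulting to 1 so
isotype background is proportional to cell content, as observed in DSP
protein data. Patient intercepts deliberately enter target markers only:
they represent patient-level biology that must *survive* housekeeper
normalization so the mixed models have something to absorb. Counts are kept
log-normal and continuous; processed DSP protein signals are approximately
normal on the log scale, which this reproduces exactly.

What the generator does **not** emulate: marker–marker biological
correlation, staining/scan artifacts, segmentation errors spilling signal
across AOIs, spatial heterogeneity within an AOI, and discreteness of low
counts. Passing tests therefore demonstrate correctness of the statistical
machinery under the stated model, not robustness to those real-data
failure modes.

## Spatial graphs and statistics

Edges connect cells with centroid distance ≤ threshold (closed boundary —
the common distance-band convention; candidate pairs from a k-d tree,
verified in tests against exhaustive O(n²) enumeration). "other" cells are
nodes but are excluded from every class statistic. Statistics undefined on
degenerate input are NaN, never 0, so downstream models can drop them
explicitly:

- gdc: NaN with a warning when there are no tumor cells;
- assortativity (networkx's Newman coefficient on the tumor/immune
  subgraph, checked against a from-scratch mixing-matrix implementation to
  1e-12): NaN when no classified edges exist or only one class participates;
- ccr: NaN when the permutation-null expectation is zero (e.g. a
  within-class pair with < 2 members).

The ccr null shuffles tumor/immune labels over the fixed node set
(`n_perm` default 1000, seed mandatory and recorded in the feature record),
preserving the spatial intensity surface and class counts — the
least-assumption null. The permutation mean is validated in tests against
the closed-form expectation `E[pairs] = n_edges · w_pair / C(n, 2)`. Both
the 30 px and 50 px records are computed and retained; micron values are
derived only via `px_to_um`.

## Imaging front-end

Preprocessing uses classic rolling-ball background subtraction (radius
default 100 px), clipped at zero; flat images are removed exactly, and
structures much narrower than the ball survive within ~10%. Cell detection
is deliberately simple — Gaussian smoothing, local maxima with a minimum
separation (closer nuclei merge into one detection, by contract), and
fixed-radius disc sampling of PanCk/CD45 evidence for classification, with
ties conservatively assigned to "other". It is a documented stand-in for
external deep-learning segmentation: the pipeline's contract is only a
CellTable, and `render_cell_image` provides the inverse mapping used by the
render-and-recover tests (≥ 95% of cells within 3 px, ≥ 95% correctly
classified at default rendering SNR).

## DSP processing

Order: `hyb_normalize → qc_filter → split_by_segment →
housekeeper_normalize`.

- The hybridization factor is the per-AOI geometric mean of positive
  hybridization controls re-centered at the cohort geometric mean, keeping
  counts on their original scale (the GeoMx-style "control normalization
  factor"). AOIs with non-positive control counts get factor NA and are
  flagged.
- QC removes AOIs with nuclei < 20 or factor > 3 — strict inequalities,
  equality passes — plus NA-factor AOIs; every exclusion is logged with a
  reason, and the filter is idempotent. An empty result raises, prompting
  threshold review.
- Tumor and immune AOIs are normalized separately (immune segments are
  systematically smaller; joint scaling would bias them).
- Housekeeper selection maximizes pairwise Pearson correlation of
  natural-log counts (the scale is a package choice; the selection is
  scale-sensitive only through log). Constant or non-positive candidates
  are ineligible. Scaling each AOI by geomean(GAPDH, S6) is
  scale-equivariant per AOI and removes cell-content signal, including the
  isotype-background vs nuclei correlation (> 0.5 before, < 0.2 after, in
  ≥ 90% of simulations at 100 AOIs).

## Models

**Linear mixed models.** Per marker: `log(signal) ~ fixed effect +
(1 | patient)`, REML via statsmodels MixedLM (optimizer falls back
lbfgs → powell → Nelder–Mead before a marker is flagged non-converged).
Normalized counts are log-transformed before fitting; they are strictly
positive and approximately log-normal. P-values use a between-within
(containment-type) denominator df: `N − n_patients − (p − 1)` for
within-patient effects, `n_patients − p` for between-patient effects
(`ddf_method="z"` restores Wald normal inference). This is the small-sample
adjustment family of lmerTest-style analysis; simulation checks show type-I
error at α = 0.05 within [0.02, 0.09] and 95% CI coverage ≈ 0.95 for a
known β = 1 at 20 patients × 2 AOIs. No multiple-testing correction is
applied to the significance call (raw p < 0.05 is the convention for these
panels); a Benjamini–Hochberg column is emitted for information. Ordinal
covariates (stage I–IV) are coded 1–4; NA stages are dropped.

**Hazard screen.** Mixed-effects proportional hazards has no Python
implementation in the supported stack, so `coxme_screen` fits the standard
marginal alternative: an Andersen–Gill Cox model over AOI-level rows with
patient-clustered robust (sandwich) variance, plus the CR1 small-sample
correction (SE × √(G/(G−1)), Wald statistic on t with G−1 df). Measured
type-I error at 100 patients is ≈ 0.05–0.06, and a simulated halving of
the hazard per covariate SD is recovered in sign with p ≪ 0.05.

**Survival stages.** Kaplan–Meier with a two-sided (multivariate) log-rank
test on one consensus label per patient; requested empty groups are dropped
with a warning; inputs with zero events raise. Immune presence vs survival
uses plain Pearson correlation.

## Classification and calibration

An ROI is **insignificant** when immune_ratio < 0.2 *or* n_immune < 20
(both strict; the 20-cell floor mirrors the segmentation-eligibility rule
for immune AOIs); otherwise **diffuse** when gdc ≥ gdc_threshold *and*
ccr_tt ≤ ccr_tt_threshold, else **focal**. NaN statistics on a
non-insignificant ROI raise rather than silently classifying. The
diffuse/focal thresholds have no universal value — annotation in tissue is
visual — so they are calibrated: independent 1-D sweeps over midpoint
candidates of each feature, maximizing balanced accuracy on labeled
training data (first argmax in sweep order; deterministic given input
order). Calibration must use data independent of the cohort being labeled;
the pipeline simulates a separate training cohort for this. End-to-end
(simulate → features → calibrate → classify) balanced accuracy is ≥ 0.9
under default parameters, typically ≈ 0.97 including the insignificant
class.

Per-patient consensus is a majority vote over that patient's ROI labels
with the fixed tie-break diffuse > focal > insignificant — arbitrary but
fixed, favoring the label with the stronger therapeutic implication.

## Orchestration and provenance

`run_pipeline(PipelineConfig)` validates the full config before writing
anything (missing inputs or a survival request without a clinical source
fail fast), then executes simulate/ingest → features (per threshold) →
calibrate/classify/consensus → normalization → differential expression →
survival. Every table carries a hash of the analysis config (output paths
excluded), the run log records versions, seeds, thresholds and stage order,
and reruns with the same config are byte-identical.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale by design: 100 random
ROIs of ≤ 100 cells for oracle equivalence; 50 matched seeds per topology
for direction recovery; 200 (LMM) and 300 (Cox) null replicates for type-I
calibration — at exactly 100 replicates the empirical rate has a ≈ 7%
chance of leaving [0.02, 0.09] even for a perfectly calibrated test, so
the replicate counts are sized to make the check informative; 100
replicates for CI coverage and normalization studies; 30 training + 60
test ROIs for end-to-end classification. Assortativity comparisons use
1e-12 absolute tolerance; permutation-based quantities are compared within
3 Monte-Carlo standard errors; seeds are fixed and logged everywhere.

## Known limitations

- The detector is not an instance segmenter: overlapping nuclei merge, and
  no shape features are produced.
- The marginal Cox screen estimates population-averaged hazard ratios, not
  the conditional (frailty) ones a true mixed-effects Cox model would give;
  with few patients and strong clustering the two diverge.
- Calibrated thresholds transfer only as far as the training distribution
  resembles the data being classified; rules should be recalibrated per
  staining/scan protocol.
- The synthetic cohort omits the real-data failure modes listed above, so
  green tests do not certify performance on degraded tissue or staining.
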