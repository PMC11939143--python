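# Methods

## Scope

`calfdepth` implements a complete dorsal-depth-image analysis for dairy
calf body weight: rule-based segmentation, body-metric extraction,
segmentation scoring, correlation-structure analysis across age, and two
body-weight prediction protocols. The field data such analyses are built
on (farm video, scale weights) are private as a rule, so the package
treats a synthetic-data generator as a first-class component: it
produces depth scenes with exact ground-truth masks and longitudinal
herds with known generative parameters, and every downstream claim the
tests make is a claim about behaviour on those generated inputs.

## Scene model

A scene is a 720 × 1280 depth map (millimetres from a camera mounted
1510 mm above the floor; 0 marks a missing reading) plus an 8-bit RGB
render. The calf silhouette is the union of two ellipses (body and
head); its dorsal height rises from `edge_height_mm` (350 mm) at the rim
to `dorsal_height_mm` (800 mm) at the spine along an elliptical dome.
Defaults give a contour of ≈160,000 px with bounding sides ≈340 × 690 px,
inside the segmentation filters' working range with margin for the
batch generator's ±8% shape jitter and ±12° posture rotation.

Colorization maps height above the floor to hue through a monotone ramp,
`hue = 30 + 0.1·height_mm` on the 0–179 hue scale, so the floor renders
near hue 30 and the calf above hue 65 — the fixed threshold of 60 then
separates them. The ramp parameters are explicit in `SceneConfig`
because colorization conventions differ between depth-camera toolchains;
any monotone map that straddles the threshold behaves equivalently.

Two defect processes emulate what breaks rule-based segmentation on
farms:

- **Overexposure**: elliptical patches (8–30 px semi-axes) inside the
  calf lose their depth (set to 0) and wash out to white. Patches are
  contiguous on purpose — scattered single-pixel dropout is exactly what
  morphological filling repairs, whereas patch defects eat the
  silhouette rim. Patches are added until the requested fraction of calf
  pixels is reached (realized fraction within ~2% of target).
- **Fence bars**: vertical posts at 420 mm height whose hue lands above
  the threshold, merging with or fragmenting the calf region.

The ground-truth mask is captured before defect injection, so truth is
clean by construction.

## Segmentation

Pipeline: hue extraction → strict `hue > 60` binarization → closing
(5 px square) + flood-fill hole removal + opening (5 px square) →
connected components (8-connectivity) → selection. Selection applies, in
order: template shape dissimilarity ≤ 0.8, filled area in
[80,000, 200,000] px, bounding-rectangle sides in [300, 900] px; among
survivors the largest area wins (one calf is expected per frame). The
first filter to eliminate every candidate names the failure status.
Decisions worth noting:

- Equality at the hue threshold maps to background (strict reading of
  "above").
- Kernel sizes (5 px) and the component/candidate floor (64 px) are
  package defaults; the upstream operator parameters for this kind of
  pipeline are conventionally unstated, and results are insensitive to
  small changes because the filters downstream are coarse.
- The shape score is the classic reciprocal-log Hu-moment form:
  `Σ |1/mᵢ(A) − 1/mᵢ(B)|` over `mᵢ = sign(hᵢ)·log10|hᵢ|`, with
  invariants of magnitude below 1e−5 treated as uninformative
  rasterization noise and skipped. It is invariant to translation,
  scale and rotation; a degenerate (empty) region scores +∞.
- Everything is deterministic; the module contains no randomness.

## Body metrics

Height above floor is `camera_height − depth`, clipped at 0 (sensor
noise can dip below the floor plane). Missing in-contour readings are
imputed with the mean of the valid in-contour heights — computed first,
then applied, so imputation preserves the mean. Volume is the height sum
over the contour and average height is volume/area, making
`volume = avg_height × area` an exact identity that is asserted on every
frame. The phrase "average height derived from the volume" in this
analysis tradition is circular if read literally; the per-pixel-mean
reading used here is the only self-consistent one. Width/length are the
axis-aligned bounding-rectangle sides, canonically width ≤ length.
Per calf and date, frame-level metrics are reduced by the elementwise
median (even group sizes: mean of the middle two).

## Herd model

Body weight follows a random-slope linear growth model,

    BW_ij = (β₀ + b₀ᵢ) + (β₁ + b₁ᵢ)·age_ij + ε_ij,

with independent Gaussian calf effects and residuals. Defaults
(β₀ = 85 lb, β₁ = 1.4 lb/d, σ_intercept = 18 lb, σ_slope = 0.20,
σ_resid = 5 lb; 20 calves, 10 visits at 2–3 d intervals, ages 21–69 d)
are calibrated so the simulated cohort reproduces the moments typical of
a pre-weaned Holstein cohort at these ages — mean BW ≈ 147 lb,
SD ≈ 26 lb — and they are calibration
choices, not measured values. Each body metric links to true BW
affinely with multiplicative log-normal noise; the noise has an
observation-level component and a calf-level "conformation" component
shared across a calf's visits (a calf that is heavy for its contour area
stays so). Default link settings yield metric–BW correlations near 0.9
(contour area ≈ 0.93, volume ≈ 0.91 at n = 200 calves).

`GrowthModelParams.heterogeneous()` names the calf-dominated regime
(σ_intercept = 25 lb, σ_resid = 3 lb, calf-level link bias SD 0.10):
between-calf structure dwarfs observation noise, which is the condition
under which a per-calf random intercept has forecasting value beyond the
metric links. `simulate_lmm_herd` is a separate generator for parameter
recovery testing: predictors drawn independently of BW and BW built from
explicit coefficients, so a mixed-model fit has an unambiguous truth.

## Evaluation and statistics

IoU, Dice and pixel accuracy score masks against truth; both-empty pairs
score 1 (perfect agreement is never penalized). Failed segmentations are
excluded from metric means and surface through the success rate.
Method and model comparisons use one-way ANOVA with
η² = SS_between/SS_total, Bonferroni adjustment with an **explicit**
family size (the family definition is a reporting choice; it is never
inferred), and Tukey HSD condensed to a compact letter display via
maximal cliques of the non-significant-pair graph.

The Mantel test compares two correlation matrices by the Pearson
correlation of their off-diagonal upper triangles, with significance
from simultaneous row/column permutations, one-sided for positive
association, `p = (1 + #{r* ≥ r}) / (1 + n_perm)`; the default 999
permutations make p = 0.001 the smallest attainable value. Age quartiles
use the nearest-rank convention with ties to the lower group.

## Prediction protocols

**Single time point.** Calves — never rows — are shuffled and split into
5 folds (20 calves → 16 train / 4 test), so no animal contributes images
to both sides. Within each repetition, test predictions are pooled over
the 5 folds before computing R², MSE, RMSE, MAE, MAPE (pooling gives one
stable value per repetition; per-fold averaging is the other defensible
choice). R² uses the evaluated set's own mean as baseline. The
gradient-boosted-tree model samples hyperparameters uniformly (learning
rate 0.01–0.9, estimators, L1/L2 regularization 0–1) and selects by
3-fold CV RMSE *within the training split*, so model selection never
sees test calves. The canonical search budget (1000 draws, up to 10,000
estimators) is available via `SearchSpace.full()`; the package default
is a desk profile (50 draws, ≤500 estimators), and the analysis scripts
use a further reduced budget (8 draws, ≤200 estimators) — on these
six-predictor herds the search landscape is flat and the selected
configurations plateau well below the canonical budget.

**Longitudinal.** Per calf, visits are ordered by age and the earliest
⌊X%·n⌋ (clamped to [1, n−1]) train the models; every test visit is
strictly later than every training visit of its calf, asserted on every
iteration. Calves with fewer than 5 visits are dropped. Each iteration
first deletes one uniformly chosen (calf, time point) row (a missed farm
visit), which is also what makes repetition meaningful for a procedure
that is otherwise deterministic. The mixed model has the six fixed
effects plus a per-calf random intercept only (no random slope), fitted
by REML; test rows of training calves use the calf's predicted random
intercept, unseen calves fall back to fixed effects. A boundary fit
(zero between-calf variance) is flagged with a warning and reported as
variance 0. Iteration seeds derive from the master seed by counter.

## Problem sizes and reproducibility

The analysis scripts and the acceptance script run the study at sizes
chosen for a laptop-class single-core run: 30–50 scenes per condition,
20 CV repetitions, 12–15 forecasting iterations per split, and the
reduced search budget above. All randomness flows from a single seed per
run; rendering, segmentation and fitting are deterministic given it.

## What passing tests do and do not show

The generator reproduces the geometry, the defect phenomenology, and the
second-order statistics (growth moments, metric–BW correlation strength,
calf-level heterogeneity) that the analysis logic depends on. It does
not reproduce real coat patterns, posture articulation, feeder occlusion
geometry, sensor-specific depth noise, or breed mixture — so absolute
segmentation scores and prediction accuracies on real recordings will
differ from the synthetic ones, and the package's quantitative claims
(e.g. 100% clean-scene success, forecast R² values) are claims about
the synthetic conditions. The *structural* results — leakage-free
validation, exact filter boundaries, the degradation under defects, and
the mixed model's advantage when calves are heterogeneous — are the
transferable content.

## Known limitations

- The silhouette model is convex-ish and unarticulated; shape-score
  behaviour on strongly articulated postures is untested.
- The hue-based pipeline presumes a height-monotone colorization; depth
  renders with palette colormaps (non-monotone hue) would need a
  different binarization front end.
- MAPE requires strictly positive responses (always true for body
  weight).
- The Mantel permutation space for 6 variables is 720 orderings, so
  p-values below ~0.0014 are granular at 999 permutations.
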