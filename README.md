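# calfdepth

Non-invasive body-weight (BW) monitoring of pre-weaned dairy calves from
overhead depth images. A depth camera mounted 1.51 m above a milk-feeder
stall records 1280 × 720 frames of the calf's back; `calfdepth` segments
the calf with a rule-based hue-threshold pipeline, extracts five body
metrics (width, length, contour area, average height, volume) from the
depth map, and predicts body weight both at single time points
(calf-grouped cross-validation) and forward in time (longitudinal
forecasting with a linear mixed model). Because farm recordings of this
kind are rarely shareable, the package ships a synthetic-data module that
generates depth scenes with exact ground-truth masks and longitudinal
herds with known growth parameters, so every stage is testable end to
end.

Intended users: researchers in precision livestock farming and
image-based animal phenotyping who want a tested, reproducible reference
implementation of this style of analysis.

## The models

**Segmentation.** Each colorized depth frame is converted to HSV and the
hue channel (0–179 scale) thresholded at 60: pixels strictly above are
foreground. Morphological closing plus hole filling and then opening
produce solid candidate regions. The target contour is selected by three
filters in order: Hu-moment template dissimilarity ≤ 0.8 (0 = identical
shapes), filled area within 80,000–200,000 px, and bounding-rectangle
sides within 300–900 px. Failure at any stage is a recorded status, not
an error — on real farm imagery a large fraction of frames fails due to
over-/underexposure and fence interference.

**Body metrics.** With camera height *H* and per-pixel depth *d*, height
above the floor is *h = H − d* (missing readings imputed with the mean
in-contour height). Volume is Σ*h* over the contour, average height is
volume/area, and width/length are the bounding-rectangle sides.

**Growth and prediction.** The synthetic herd follows a random-slope
growth model, BW*ᵢⱼ* = (β₀+b₀ᵢ) + (β₁+b₁ᵢ)·ageᵢⱼ + εᵢⱼ, with body
metrics linked to BW through affine maps with multiplicative noise.
Prediction models: ordinary least squares and gradient-boosted trees
(randomized hyperparameter search) under calf-grouped 5-fold CV, and —
for forecasting — a linear mixed model with the six fixed effects (age +
five metrics) and a per-calf random intercept, fitted by REML. Model
comparisons use one-way ANOVA with η² effect sizes, Bonferroni
adjustment, and Tukey HSD letter displays.

## Worked example

```python
from calfdepth.synthetic_data import (
    CalfShapeParams, SceneConfig, make_template_contour, render_scene,
)
from calfdepth.threshold_segmentation import SegmentationParams, segment
from calfdepth.body_metrics import compute_metrics

config = SceneConfig()                      # 720x1280, camera at 1510 mm
scene, truth = render_scene(CalfShapeParams(), config, seed=11)
params = SegmentationParams(template=make_template_contour(config))
result = segment(scene, params)
print(result.status.value)                  # success
m = compute_metrics(scene, result)
print(round(m.contour_area_px2), round(m.avg_height_mm, 1), round(m.volume_mm_px2 / 1e6, 2))
# 162360 651.6 105.79
```

The segmentation succeeded and measured a 162,360 px² dorsal contour
(inside the 80,000–200,000 px acceptance band) whose surface averages
652 mm above the floor, giving a volume proxy of 105.8 × 10⁶ mm·px² —
the quantity that correlates most strongly with body weight.

The numbered scripts under `analysis/` run the full study on synthetic
data and print their findings; for example `analysis/05_forecast.py`
ends with

```
50:50: R2 {'gbt': 0.712, 'linear': 0.856, 'lmm': 0.967}, eta^2 = 0.996, letters {'lmm': 'a', 'linear': 'b', 'gbt': 'c'}
```

i.e. even when only the first half of each calf's visit history is
available for training, the mixed model forecasts later weights with
R² ≈ 0.97, ahead of ordinary least squares and gradient boosting, and
model choice explains ~99% of the variance in forecast accuracy (Tukey
letters: all three models differ).

## On-disk formats

- depth maps: headerless CSV, one row per image row, millimetres, 0 = missing;
- color renders: 8-bit RGB PNG (hue encodes height above the floor);
- polygon annotations: JSON `{"frame_id": ..., "vertices": [[row, col], ...]}`, 0-based;
- observation tables: CSV with `calf_id, date, age_days, bw_lb` plus metric columns.
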