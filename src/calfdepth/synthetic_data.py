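"""Synthetic dorsal depth scenes and longitudinal herds.

The generator emulates the recording geometry the analysis assumes: a
depth camera mounted 1.51 m above the floor of a milk-feeder stall,
producing 1280 x 720 frames in which the calf's back appears as a smooth
elevated region of 80k-200k pixels. Colorized renders map height above
the floor to hue through a monotone ramp, so the floor sits below the
segmentation hue threshold (60 on the 0-179 scale) and the calf above it.
Defects mimic the two failure modes seen on real farms: overexposed
patches of white coat (missing depth, washed-out color) and fence bars
crossing the frame.

Herd simulation draws per-calf linear growth trajectories

    BW_ij = (beta0 + b0_i) + (beta1 + b1_i) * age_ij + eps_ij

with independent zero-mean Gaussian calf effects and residuals, then
derives the five body metrics from true body weight through affine links
with multiplicative log-normal noise (an observation-level component plus
a calf-level "conformation" component shared across that calf's visits).
Defaults are calibrated to a 20-calf Holstein cohort measured at ages
21-69 d with mean body weight near 147 lb (SD ~26 lb) and metric-weight
correlations near 0.9.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.color import hsv2rgb

from .contours import Contour
from .depth_io import DepthScene, ValidationError, validate_observations

__all__ = [
    "SceneConfig",
    "CalfShapeParams",
    "GrowthModelParams",
    "render_scene",
    "simulate_growth",
    "make_template_contour",
    "simulate_scene_batch",
    "simulate_lmm_herd",
]

HUE_SCALE = 179.0  # hue channel range used throughout: 0..179


@dataclass(frozen=True)
class SceneConfig:
    """Acquisition geometry and colorization of a synthetic scene.

    ``hue_floor`` and ``hue_gain_per_mm`` define the monotone height->hue
    ramp: ``hue = hue_floor + gain * height_mm`` (clipped to [0, 179]), so
    deeper (lower) surfaces get smaller hues. With the defaults the floor
    renders near hue 30 and the calf's back above hue 60.
    """

    image_size: tuple[int, int] = (720, 1280)
    camera_height_mm: float = 1510.0
    floor_noise_sd_mm: float = 8.0
    hue_floor: float = 30.0
    hue_gain_per_mm: float = 0.1
    overexposure_fraction: float = 0.0
    fence_bars: int = 0
    fence_bar_width_px: int = 24
    fence_height_mm: float = 420.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.overexposure_fraction <= 1.0:
            raise ValidationError("overexposure_fraction must be in [0, 1]")
        if self.hue_gain_per_mm <= 0:
            raise ValidationError("hue ramp must be monotone increasing in height")

    def depth_to_hue(self, depth_mm: np.ndarray) -> np.ndarray:
        height = self.camera_height_mm - np.asarray(depth_mm, dtype=float)
        return np.clip(self.hue_floor + self.hue_gain_per_mm * height, 0.0, HUE_SCALE)


@dataclass(frozen=True)
class CalfShapeParams:
    """Geometry of the calf's dorsal silhouette and height profile.

    The body is an ellipse of ``body_length_px`` x ``body_width_px``; the
    head a smaller ellipse offset forward along the body axis. Heights rise
    from ``edge_height_mm`` at the silhouette rim to ``dorsal_height_mm``
    at the spine, so even rim pixels sit well above the floor.
    """

    body_length_px: int = 560
    body_width_px: int = 340
    head_length_px: int = 150
    head_width_px: int = 120
    head_offset: int = 330  # head-center distance ahead of body center, px
    posture_angle_deg: float = 0.0
    dorsal_height_mm: float = 800.0
    edge_height_mm: float = 350.0
    center: tuple[float, float] | None = None  # (row, col); default image center


@dataclass(frozen=True)
class GrowthModelParams:
    """Population growth curve, calf-level variation, and metric links.

    ``metric_links`` maps a metric column to ``(intercept, slope, cv)``:
    metric = (intercept + slope * BW) * exp(N(0, cv) + N(0, sd_calf_link)),
    with the second factor drawn once per calf.
    """

    beta0_lb: float = 85.0
    beta1_lb_per_day: float = 1.4
    sd_intercept_lb: float = 18.0
    sd_slope: float = 0.20
    sd_resid_lb: float = 5.0
    sd_calf_link: float = 0.02
    metric_links: dict = field(
        default_factory=lambda: {
            "contour_area_px2": (60000.0, 450.0, 0.030),
            "volume_mm_px2": (2.0e7, 3.0e5, 0.050),
            "avg_height_mm": (300.0, 1.3, 0.040),
            "width_px": (250.0, 1.0, 0.060),
            "length_px": (420.0, 1.5, 0.060),
        }
    )

    def __post_init__(self) -> None:
        for sd in (self.sd_intercept_lb, self.sd_slope, self.sd_resid_lb, self.sd_calf_link):
            if sd < 0:
                raise ValidationError("standard deviations must be >= 0")

    @classmethod
    def heterogeneous(cls) -> "GrowthModelParams":
        """A herd with pronounced calf-level structure (sigma_b >> sigma_e).

        Calf intercepts and per-calf metric-link biases dominate the
        observation noise, so a model that carries a per-calf random
        intercept has real signal to exploit beyond the metric links.
        """
        return cls(
            sd_intercept_lb=25.0,
            sd_slope=0.25,
            sd_resid_lb=3.0,
            sd_calf_link=0.10,
            metric_links={
                "contour_area_px2": (60000.0, 450.0, 0.050),
                "volume_mm_px2": (2.0e7, 3.0e5, 0.070),
                "avg_height_mm": (300.0, 1.3, 0.060),
                "width_px": (250.0, 1.0, 0.080),
                "length_px": (420.0, 1.5, 0.080),
            },
        )


def _silhouette_and_height(
    shape: CalfShapeParams, config: SceneConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize the calf silhouette and its dorsal height profile (mm)."""
    h_img, w_img = config.image_size
    cr, cc = shape.center if shape.center is not None else ((h_img - 1) / 2, (w_img - 1) / 2)

    # conservative extents of the rotated silhouette around its center
    half_len = max(shape.body_length_px / 2, shape.head_offset + shape.head_length_px / 2)
    half_wid = max(shape.body_width_px, shape.head_width_px) / 2
    theta = np.deg2rad(shape.posture_angle_deg)
    ext_c = half_len * abs(np.cos(theta)) + half_wid * abs(np.sin(theta))
    ext_r = half_len * abs(np.sin(theta)) + half_wid * abs(np.cos(theta))
    if (cc - ext_c < 0 or cc + ext_c > w_img - 1 or cr - ext_r < 0 or cr + ext_r > h_img - 1):
        raise ValidationError("calf shape does not fit in the image at this position")

    rows = np.arange(h_img, dtype=float)[:, None]
    cols = np.arange(w_img, dtype=float)[None, :]
    # axis coords: u along body length, v across width
    u = (cols - cc) * np.cos(theta) + (rows - cr) * np.sin(theta)
    v = -(cols - cc) * np.sin(theta) + (rows - cr) * np.cos(theta)

    r_body = np.sqrt(
        (u / (shape.body_length_px / 2)) ** 2 + (v / (shape.body_width_px / 2)) ** 2
    )
    r_head = np.sqrt(
        ((u - shape.head_offset) / (shape.head_length_px / 2)) ** 2
        + (v / (shape.head_width_px / 2)) ** 2
    )
    r = np.minimum(r_body, r_head)
    mask = r <= 1.0
    dome = np.sqrt(np.clip(1.0 - r**2, 0.0, 1.0))
    height = np.where(
        mask, shape.edge_height_mm + (shape.dorsal_height_mm - shape.edge_height_mm) * dome, 0.0
    )
    return mask, height


def render_scene(
    shape: CalfShapeParams, config: SceneConfig, seed: int, frame_id: str = "synthetic"
) -> tuple[DepthScene, np.ndarray]:
    """Render one scene; returns the scene and its defect-free truth mask.

    Floor pixels carry depth ~ camera height (plus sensor noise); calf
    pixels carry camera height minus the dorsal height profile. The truth
    mask is captured *before* defect injection, so ground truth is clean by
    construction. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    mask, height = _silhouette_and_height(shape, config)
    h_img, w_img = config.image_size

    noise = rng.normal(0.0, config.floor_noise_sd_mm, size=(h_img, w_img))
    depth = np.clip(config.camera_height_mm - height + noise, 1.0, None)

    # fence bars: vertical posts closer to the camera than the floor
    if config.fence_bars > 0:
        cols0 = np.linspace(0, w_img - config.fence_bar_width_px, config.fence_bars + 2)[1:-1]
        for c0 in cols0.astype(int):
            depth[:, c0 : c0 + config.fence_bar_width_px] = (
                config.camera_height_mm - config.fence_height_mm
            )

    hue = config.depth_to_hue(depth)

    # overexposure: white-coat reflections blow out both depth and color in
    # contiguous patches (not isolated pixels), as on a patched Holstein coat
    overexposed = np.zeros((h_img, w_img), dtype=bool)
    if config.overexposure_fraction > 0:
        target = config.overexposure_fraction * mask.sum()
        in_rows, in_cols = np.nonzero(mask)
        rows_g = np.arange(h_img, dtype=float)[:, None]
        cols_g = np.arange(w_img, dtype=float)[None, :]
        for _ in range(1000):
            if (overexposed & mask).sum() >= target:
                break
            j = rng.integers(len(in_rows))
            pr, pc = in_rows[j], in_cols[j]
            ar, ac = rng.uniform(8, 30, size=2)
            patch = ((rows_g - pr) / ar) ** 2 + ((cols_g - pc) / ac) ** 2 <= 1.0
            overexposed |= patch & mask
        depth[overexposed] = 0.0

    hsv = np.stack(
        [hue / HUE_SCALE, np.full_like(hue, 0.9), np.full_like(hue, 0.95)], axis=-1
    )
    color = (hsv2rgb(hsv) * 255).round().astype(np.uint8)
    color[overexposed] = 255  # washed out to white: hue information lost

    scene = DepthScene(
        depth=depth,
        color=color,
        frame_id=frame_id,
        camera_height_mm=config.camera_height_mm,
    )
    return scene, mask.astype(np.uint8)


def make_template_contour(config: SceneConfig | None = None) -> Contour:
    """The ideal calf contour used as the shape-matching template.

    Deterministic: regenerating with the same config gives the same region.
    """
    config = config or SceneConfig()
    mask, _ = _silhouette_and_height(CalfShapeParams(), config)
    return Contour.from_mask(mask)


def simulate_scene_batch(
    n_scenes: int,
    config: SceneConfig | None = None,
    seed: int = 0,
    shape_jitter: float = 0.05,
) -> list[tuple[DepthScene, np.ndarray]]:
    """Render a batch of scenes with mild calf-to-calf shape variation.

    Body dimensions and posture are jittered (relative SD ``shape_jitter``,
    truncated to +/-8% so every silhouette stays inside the frame and
    within the area filter's working range), emulating frame-to-frame
    posture change.
    """
    config = config or SceneConfig()
    rng = np.random.default_rng(seed)
    base = CalfShapeParams()
    out = []
    for i in range(n_scenes):
        f = float(np.clip(rng.normal(1.0, shape_jitter), 0.92, 1.08))
        shape = replace(
            base,
            body_length_px=int(base.body_length_px * f),
            body_width_px=int(base.body_width_px * np.clip(rng.normal(1.0, shape_jitter), 0.92, 1.08)),
            posture_angle_deg=float(rng.uniform(-12.0, 12.0)),
            dorsal_height_mm=float(base.dorsal_height_mm * np.clip(rng.normal(1.0, 0.05), 0.9, 1.1)),
        )
        scene, mask = render_scene(
            shape, config, seed=int(rng.integers(0, 2**31 - 1)), frame_id=f"scene_{i:04d}"
        )
        out.append((scene, mask))
    return out


def simulate_growth(
    params: GrowthModelParams | None = None,
    n_calves: int = 20,
    visits_per_calf: int = 10,
    age_range: tuple[int, int] = (21, 69),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a longitudinal herd table of body weight and body metrics.

    Each calf enters at a random age and is measured ``visits_per_calf``
    times at 2-3 day intervals (2-3 visits/week), staying inside
    ``age_range``. The returned table passes observation validation and is
    sorted by (calf_id, age_days).
    """
    params = params or GrowthModelParams()
    if n_calves < 2 or visits_per_calf < 2:
        raise ValidationError("need n_calves >= 2 and visits_per_calf >= 2")
    lo, hi = age_range
    if not lo < hi:
        raise ValidationError("age_range must be increasing")
    rng = np.random.default_rng(seed)

    max_span = 3 * (visits_per_calf - 1)  # longest possible visit schedule
    if hi - lo < max_span:
        raise ValidationError("age_range too narrow for the visit schedule")

    base_date = pd.Timestamp("2023-01-09")
    records = []
    for i in range(n_calves):
        calf = f"calf_{i:03d}"
        b0 = rng.normal(0.0, params.sd_intercept_lb)
        b1 = rng.normal(0.0, params.sd_slope)
        link_bias = rng.normal(0.0, params.sd_calf_link)
        start = int(rng.integers(lo, hi - max_span + 1))
        gaps = rng.integers(2, 4, size=visits_per_calf - 1)  # 2 or 3 days apart
        ages = start + np.concatenate([[0], np.cumsum(gaps)])
        for age in ages:
            bw = (
                params.beta0_lb
                + b0
                + (params.beta1_lb_per_day + b1) * age
                + rng.normal(0.0, params.sd_resid_lb)
            )
            row = {
                "calf_id": calf,
                "date": (base_date + pd.Timedelta(days=int(age))).date().isoformat(),
                "age_days": int(age),
                "bw_lb": float(bw),
            }
            for col, (c0, c1, cv) in params.metric_links.items():
                row[col] = float((c0 + c1 * bw) * np.exp(link_bias + rng.normal(0.0, cv)))
            records.append(row)
    return validate_observations(pd.DataFrame.from_records(records))


def simulate_lmm_herd(
    n_calves: int = 50,
    visits_per_calf: int = 10,
    beta: dict | None = None,
    sigma_b: float = 10.0,
    sigma_e: float = 3.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a herd from an explicit random-intercept model, for recovery tests.

    Unlike :func:`simulate_growth`, the five body-metric predictors here are
    drawn independently of body weight, and BW is then built as
    ``X @ beta + b0_i + eps`` with known coefficients — so a mixed-model fit
    has a well-defined truth to recover. Returns (table, truth) where truth
    holds the coefficients and variance components used.
    """
    rng = np.random.default_rng(seed)
    beta = dict(beta or {})
    beta.setdefault("intercept", 40.0)
    beta.setdefault("age_days", 1.5)
    beta.setdefault("length_px", 0.02)
    beta.setdefault("width_px", 0.03)
    beta.setdefault("avg_height_mm", 0.05)
    beta.setdefault("volume_mm_px2", 2.0e-7)
    beta.setdefault("contour_area_px2", 1.0e-4)

    predictor_dists = {
        "length_px": (640.0, 40.0),
        "width_px": (400.0, 30.0),
        "avg_height_mm": (490.0, 35.0),
        "volume_mm_px2": (6.4e7, 5e6),
        "contour_area_px2": (126000.0, 9000.0),
    }
    base_date = pd.Timestamp("2023-01-09")
    records = []
    for i in range(n_calves):
        b0 = rng.normal(0.0, sigma_b)
        start = int(rng.integers(21, 40))
        ages = start + 3 * np.arange(visits_per_calf)
        for age in ages:
            row = {
                "calf_id": f"calf_{i:03d}",
                "date": (base_date + pd.Timedelta(days=int(age))).date().isoformat(),
                "age_days": int(age),
            }
            for col, (m, s) in predictor_dists.items():
                row[col] = float(rng.normal(m, s))
            bw = beta["intercept"] + beta["age_days"] * age + b0 + rng.normal(0.0, sigma_e)
            for col in predictor_dists:
                bw += beta[col] * row[col]
            row["bw_lb"] = float(bw)
            records.append(row)
    truth = {"beta": beta, "sigma_b": sigma_b, "sigma_e": sigma_e}
    return validate_observations(pd.DataFrame.from_records(records)), truth
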