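"""Synthetic CT-like phantoms, rater tables and dose cohorts.

The edge phantom emulates the situation the objective image-quality pipeline
is designed for: two homogeneous soft-tissue plateaus (muscle at ~+50 HU,
fat at ~-100 HU) separated by a straight border, with the gray-value
transition modelled as a linear ramp of known steepness (HU/mm). On top of
the noiseless template the generator can add a smooth second-order
polynomial background drift and i.i.d. Gaussian noise. Because every
parameter is known exactly, each downstream estimator (profile slope,
baselines, detrended noise, SNR/CNR) can be tested against ground truth.

The ramp is deliberately linear rather than sigmoid so that "steepest slope"
has a closed-form ground truth, and pixels take the template value at their
center (no area averaging).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, SizingError
from .image import ImageSlice

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "generate_edge_phantom",
    "default_border_points",
    "generate_rater_table",
    "generate_dose_cohort",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a two-tissue edge phantom.

    The border line passes through the image center at ``edge_angle_deg``
    (counter-clockwise from +x). Signed distance to the border is measured
    along the normal obtained by rotating the border direction clockwise by
    90 degrees; the bright plateau (``hu_high``) lies on the negative side,
    so traversing the ramp in the +normal direction goes high -> low and the
    ramp slope is negative.
    """

    width_mm: float = 40.0
    height_mm: float = 40.0
    pixel_spacing_mm: float = 0.5
    hu_high: float = 50.0
    hu_low: float = -100.0
    edge_slope_hu_per_mm: float = -150.0
    edge_angle_deg: float = 90.0
    noise_sd_hu: float = 5.0
    drift_coeffs: tuple[float, float, float, float, float, float] = (
        0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.pixel_spacing_mm > 0):
            raise ConfigError("pixel_spacing_mm must be positive")
        if self.width_mm < 20 or self.height_mm < 20:
            raise ConfigError(
                "phantom must be at least 20 mm x 20 mm to admit a "
                "5 mm x 5 mm analysis window plus margins")
        if not (self.hu_high > self.hu_low):
            raise ConfigError("hu_high must exceed hu_low")
        if not (self.edge_slope_hu_per_mm < 0):
            raise ConfigError(
                "edge_slope_hu_per_mm must be negative (high -> low traversal)")
        if self.noise_sd_hu < 0:
            raise ConfigError("noise_sd_hu must be non-negative")
        if len(self.drift_coeffs) != 6:
            raise ConfigError("drift_coeffs must have six entries (1, x, y, x^2, xy, y^2)")

    @property
    def transition_width_mm(self) -> float:
        return (self.hu_low - self.hu_high) / self.edge_slope_hu_per_mm


@dataclass(frozen=True)
class GroundTruth:
    """Exact parameters of a generated phantom, for oracle-based tests."""

    true_slope_hu_per_mm: float
    true_noise_sd_hu: float
    true_upper_baseline_hu: float
    true_lower_baseline_hu: float
    transition_width_mm: float

    def __post_init__(self) -> None:
        if not (self.transition_width_mm > 0):
            raise ConfigError("transition_width_mm must be positive")

    def to_dict(self) -> dict:
        return {
            "true_slope_hu_per_mm": self.true_slope_hu_per_mm,
            "true_noise_sd_hu": self.true_noise_sd_hu,
            "true_upper_baseline_hu": self.true_upper_baseline_hu,
            "true_lower_baseline_hu": self.true_lower_baseline_hu,
            "transition_width_mm": self.transition_width_mm,
        }


def edge_template(d: np.ndarray, hu_high: float, hu_low: float,
                  slope: float) -> np.ndarray:
    """Noiseless profile value at signed distance ``d`` (mm) from the border.

    Piecewise linear: ``hu_high`` for d <= -w/2, a ramp of exact gradient
    ``slope`` across the transition band of width w, ``hu_low`` beyond.
    """
    w = (hu_low - hu_high) / slope
    ramp = hu_high + slope * (np.asarray(d, dtype=np.float64) + w / 2.0)
    return np.clip(ramp, hu_low, hu_high)


def evaluate_drift(coeffs, x: np.ndarray, y: np.ndarray,
                   center: tuple[float, float]) -> np.ndarray:
    """Second-order 2D polynomial background, coordinates centered on the image."""
    a, bx, by, cxx, cxy, cyy = coeffs
    xr = x - center[0]
    yr = y - center[1]
    return a + bx * xr + by * yr + cxx * xr**2 + cxy * xr * yr + cyy * yr**2


def generate_edge_phantom(spec: PhantomSpec) -> tuple[ImageSlice, GroundTruth]:
    """Rasterize a two-tissue edge phantom with known ground truth.

    Deterministic given ``spec.seed``; raises :class:`SizingError` when the
    transition band does not fit inside the raster.
    """
    s = spec.pixel_spacing_mm
    ncols = int(round(spec.width_mm / s))
    nrows = int(round(spec.height_mm / s))
    w = spec.transition_width_mm
    if w >= min(spec.width_mm, spec.height_mm) / 2.0:
        raise SizingError(
            f"transition width {w:.2f} mm does not fit in a "
            f"{spec.width_mm} x {spec.height_mm} mm raster with margins")

    x = np.arange(ncols) * s
    y = np.arange(nrows) * s
    xx, yy = np.meshgrid(x, y)
    cx = (ncols - 1) * s / 2.0
    cy = (nrows - 1) * s / 2.0

    theta = math.radians(spec.edge_angle_deg)
    # normal = border direction rotated -90 deg: (sin t, -cos t)
    d = (xx - cx) * math.sin(theta) - (yy - cy) * math.cos(theta)

    pixels = edge_template(d, spec.hu_high, spec.hu_low, spec.edge_slope_hu_per_mm)
    pixels = pixels + evaluate_drift(spec.drift_coeffs, xx, yy, (cx, cy))
    if spec.noise_sd_hu > 0:
        rng = np.random.default_rng(spec.seed)
        pixels = pixels + rng.normal(0.0, spec.noise_sd_hu, size=pixels.shape)

    truth = GroundTruth(
        true_slope_hu_per_mm=spec.edge_slope_hu_per_mm,
        true_noise_sd_hu=spec.noise_sd_hu,
        true_upper_baseline_hu=spec.hu_high,
        true_lower_baseline_hu=spec.hu_low,
        transition_width_mm=w,
    )
    return ImageSlice(pixels, s, id=f"phantom-seed{spec.seed}"), truth


def default_border_points(spec: PhantomSpec, length_mm: float = 9.0
                          ) -> tuple[tuple[float, float], tuple[float, float]]:
    """Endpoints (mm) of a border marking centered on the phantom's edge line.

    The segment runs along the true interface through the image center, so
    ten profile stations at the default length are 1 mm apart.
    """
    s = spec.pixel_spacing_mm
    cx = (int(round(spec.width_mm / s)) - 1) * s / 2.0
    cy = (int(round(spec.height_mm / s)) - 1) * s / 2.0
    theta = math.radians(spec.edge_angle_deg)
    ux, uy = math.cos(theta), math.sin(theta)
    h = length_mm / 2.0
    return (cx - h * ux, cy - h * uy), (cx + h * ux, cy + h * uy)


def generate_rater_table(n_items: int, n_raters: int, latent: np.ndarray,
                         disagreement_sd: float, scale_min: int = 1,
                         scale_max: int = 5, seed: int = 0) -> np.ndarray:
    """Simulate an items x raters table of Likert scores.

    Each rating is the item's latent quality plus Gaussian rater noise,
    rounded half-up to an integer and clipped to the scale. With
    ``disagreement_sd=0`` all raters reproduce the rounded latent scores
    exactly. Deterministic given ``seed``.
    """
    if n_raters < 2:
        raise ConfigError("agreement is undefined for fewer than 2 raters")
    if scale_min >= scale_max:
        raise ConfigError("scale_min must be below scale_max")
    latent = np.asarray(latent, dtype=np.float64)
    if latent.shape != (n_items,):
        raise ConfigError("latent must be a vector of length n_items")
    if latent.min() < scale_min or latent.max() > scale_max:
        raise ConfigError("latent scores must lie within the scale")
    if disagreement_sd < 0:
        raise ConfigError("disagreement_sd must be non-negative")

    rng = np.random.default_rng(seed)
    raw = latent[:, None] + rng.normal(0.0, disagreement_sd,
                                       size=(n_items, n_raters))
    scores = np.floor(raw + 0.5)  # round half-up, reproducible across platforms
    return np.clip(scores, scale_min, scale_max).astype(np.int64)


@dataclass(frozen=True)
class DoseRecord:
    """Dose descriptors of one examination: CTDIvol (mGy), scan length (cm),
    and the dose-length product DLP = CTDIvol x scan length (mGy*cm)."""

    ctdivol_mgy: float
    scan_length_cm: float
    dlp_mgy_cm: float | None = None
    exam_id: str = ""

    def __post_init__(self) -> None:
        if self.ctdivol_mgy < 0:
            raise ConfigError("ctdivol must be non-negative")
        if not (self.scan_length_cm > 0):
            raise ConfigError("scan_length must be positive")
        derived = self.ctdivol_mgy * self.scan_length_cm
        if self.dlp_mgy_cm is None:
            object.__setattr__(self, "dlp_mgy_cm", derived)
        elif derived > 0 and abs(self.dlp_mgy_cm - derived) > 0.01 * derived:
            raise ConfigError(
                f"DLP {self.dlp_mgy_cm} inconsistent with CTDIvol x length = "
                f"{derived:.2f} (beyond 1%)")


def generate_dose_cohort(n: int, ctdivol_mean: float, ctdivol_sd: float,
                         scanlen_mean: float, scanlen_sd: float,
                         seed: int = 0) -> list[DoseRecord]:
    """Simulate a cohort of dose records with DLP derived from its defining
    identity. CTDIvol and scan length are truncated at zero (physical floor)."""
    if ctdivol_mean < 0:
        raise ConfigError("ctdivol_mean must be non-negative")
    if scanlen_mean <= 0:
        raise ConfigError("scanlen_mean must be positive")
    rng = np.random.default_rng(seed)
    ctdi = np.maximum(rng.normal(ctdivol_mean, ctdivol_sd, n), 0.0)
    length = np.maximum(rng.normal(scanlen_mean, scanlen_sd, n), 1e-6)
    return [DoseRecord(c, l, exam_id=f"exam{i:04d}")
            for i, (c, l) in enumerate(zip(ctdi, length))]
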