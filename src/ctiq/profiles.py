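"""Perpendicular edge profiles and steepest-slope sharpness estimation.

Given a marked tissue border, ten gray-value profiles are sampled
perpendicular to the marking over +/-4.5 mm. For each profile the two
plateau baselines, the steepest three-point slope of the transition and the
span of that steepest window are estimated; the per-image sharpness summary
is the component-wise median over the ten profiles.

Sign convention: profile position increases from the bright (upper-baseline)
tissue toward the dark one, so transition slopes are negative and steeper
edges have more negative slope. The perpendicular direction is the border
direction ``p_end - p_start`` rotated clockwise by 90 degrees, which places
negative positions on the bright side for borders marked in the phantom's
orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigError, DegenerateProfileError, SamplingError
from .image import ImageSlice

__all__ = [
    "ImageSlice",
    "BorderSpec",
    "Profile",
    "ProfileAnalysis",
    "SharpnessSummary",
    "extract_profiles",
    "estimate_baselines",
    "steepest_slope",
    "analyze_profiles",
    "summarize",
]

log = logging.getLogger("ctiq.profiles")


@dataclass(frozen=True)
class BorderSpec:
    """A line segment marking the tissue interface, in mm coordinates,
    plus the lateral scope to analyze on each side."""

    p_start: tuple[float, float]
    p_end: tuple[float, float]
    n_profiles: int = 10
    half_range_mm: float = 4.5

    def __post_init__(self) -> None:
        if tuple(self.p_start) == tuple(self.p_end):
            raise ConfigError("border endpoints must differ")
        if self.n_profiles < 1:
            raise ConfigError("n_profiles must be at least 1")
        if not (self.half_range_mm > 0):
            raise ConfigError("half_range_mm must be positive")

    def to_dict(self) -> dict:
        return {"p_start": list(self.p_start), "p_end": list(self.p_end),
                "n_profiles": self.n_profiles,
                "half_range_mm": self.half_range_mm}


@dataclass(frozen=True)
class Profile:
    """One perpendicular gray-value profile.

    ``positions`` are signed distances (mm) along the perpendicular, zero at
    the marked border and negative on the bright side; ``values`` are HU
    sampled by bilinear interpolation.
    """

    positions: np.ndarray
    values: np.ndarray
    station_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.float64)
        val = np.asarray(self.values, dtype=np.float64)
        if pos.ndim != 1 or pos.shape != val.shape:
            raise ConfigError("positions and values must be 1D of equal length")
        if np.any(np.diff(pos) <= 0):
            raise ConfigError("positions must be strictly increasing")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "values", val)


@dataclass(frozen=True)
class ProfileAnalysis:
    """Per-profile baselines, steepest slope and steepest-window span.

    ``distance_mm`` is the signed span of the steepest three-point window,
    negative under the high -> low traversal convention. ``no_transition``
    flags flat/inverted profiles on which baselines and slope are not
    meaningful.
    """

    upper_baseline_hu: float
    lower_baseline_hu: float
    steepest_slope_hu_per_mm: float
    slope_window_center_mm: float
    distance_mm: float
    no_transition: bool = False

    def __post_init__(self) -> None:
        if not self.no_transition:
            if not (self.upper_baseline_hu > self.lower_baseline_hu):
                raise ConfigError("upper baseline must exceed lower baseline")
            if self.steepest_slope_hu_per_mm > 0:
                raise ConfigError("transition slope must be <= 0")


@dataclass(frozen=True)
class SharpnessSummary:
    """Component-wise medians over the per-profile analyses."""

    median_slope_hu_per_mm: float
    median_upper_hu: float
    median_lower_hu: float
    median_distance_mm: float
    n_profiles: int

    def to_dict(self) -> dict:
        return {
            "median_slope_hu_per_mm": self.median_slope_hu_per_mm,
            "median_upper_hu": self.median_upper_hu,
            "median_lower_hu": self.median_lower_hu,
            "median_distance_mm": self.median_distance_mm,
            "n_profiles": self.n_profiles,
        }


def _perpendicular(border: BorderSpec) -> tuple[np.ndarray, np.ndarray]:
    """Unit border direction and its clockwise-rotated normal."""
    u = np.asarray(border.p_end, float) - np.asarray(border.p_start, float)
    u = u / np.hypot(*u)
    n = np.array([u[1], -u[0]])
    return u, n


def extract_profiles(image: ImageSlice, border: BorderSpec,
                     step_mm: float | None = None) -> list[Profile]:
    """Sample ``border.n_profiles`` perpendicular profiles across the marking.

    Stations are evenly spaced along the border segment (inclusive of the
    endpoints for n >= 2). Each profile is sampled by bilinear interpolation
    at uniform ``step_mm`` (default: half the pixel spacing) over
    ``+/- half_range_mm``; the half range is realized as the nearest whole
    number of steps.

    Raises :class:`SamplingError` naming the offending station if any sample
    point falls outside the raster.
    """
    s = image.pixel_spacing_mm
    if step_mm is None:
        step_mm = s / 2.0
    if not (step_mm > 0):
        raise ConfigError("step_mm must be positive")

    p0 = np.asarray(border.p_start, float)
    p1 = np.asarray(border.p_end, float)
    if border.n_profiles == 1:
        stations = (p0 + p1)[None, :] / 2.0
    else:
        t = np.linspace(0.0, 1.0, border.n_profiles)[:, None]
        stations = p0 + t * (p1 - p0)

    _, normal = _perpendicular(border)
    m = int(round(border.half_range_mm / step_mm))
    if m < 1:
        raise ConfigError("step_mm too large for the requested half range")
    positions = (np.arange(2 * m + 1) - m) * step_mm

    nrows, ncols = image.shape
    profiles: list[Profile] = []
    for i, st in enumerate(stations):
        pts = st[None, :] + positions[:, None] * normal[None, :]
        col = pts[:, 0] / s
        row = pts[:, 1] / s
        if (col.min() < 0 or col.max() > ncols - 1
                or row.min() < 0 or row.max() > nrows - 1):
            raise SamplingError(
                f"profile station {i} at ({st[0]:.2f}, {st[1]:.2f}) mm "
                "samples outside the image raster")
        vals = ndimage.map_coordinates(image.pixels, np.vstack([row, col]),
                                       order=1, mode="nearest")
        profiles.append(Profile(positions, vals, station_mm=(st[0], st[1])))
    return profiles


def estimate_baselines(profile: Profile,
                       plateau_fraction: float = 0.25) -> tuple[float, float]:
    """Mean HU of the outer ``plateau_fraction`` of samples on each side.

    Returns ``(upper, lower)`` with upper > lower. Raises
    :class:`DegenerateProfileError` on flat or inverted profiles and
    :class:`ConfigError` when fewer than 3 samples per plateau remain.
    """
    if not (0 < plateau_fraction <= 0.5):
        raise ConfigError("plateau_fraction must be in (0, 0.5]")
    pos, val = profile.positions, profile.values
    n_high = int(np.sum(pos < 0))
    n_low = int(np.sum(pos > 0))
    k_high = int(plateau_fraction * n_high)
    k_low = int(plateau_fraction * n_low)
    if k_high < 3 or k_low < 3:
        raise ConfigError(
            "fewer than 3 samples per plateau; lengthen the profile or "
            "raise plateau_fraction")
    upper = float(np.mean(val[:k_high]))
    lower = float(np.mean(val[-k_low:]))
    if not (upper > lower):
        raise DegenerateProfileError(
            f"profile is flat or inverted (upper {upper:.2f} <= lower "
            f"{lower:.2f} HU); no baselines assigned")
    return upper, lower


def _ls_slopes_3pt(positions: np.ndarray, values: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares slope over every window of three consecutive samples.

    For uniform spacing h the 3-point LS slope reduces to the central
    difference (v[i+2] - v[i]) / (2 h).
    """
    steps = np.diff(positions)
    h = steps.mean()
    if not np.allclose(steps, h, rtol=1e-6, atol=1e-12):
        raise ConfigError("steepest_slope requires uniformly sampled profiles")
    slopes = (values[2:] - values[:-2]) / (2.0 * h)
    centers = positions[1:-1]
    return slopes, centers, h


def steepest_slope(profile: Profile,
                   plateau_fraction: float = 0.25) -> ProfileAnalysis:
    """Steepest (most negative) three-point slope of one profile.

    Ties between equally steep windows are broken toward the window whose
    center is nearest the marked border (position 0), then first occurrence.
    Flat or inverted profiles yield a flagged analysis with
    ``no_transition=True`` instead of an error.
    """
    if profile.positions.size < 3:
        raise ConfigError("steepest_slope needs at least 3 samples")
    slopes, centers, h = _ls_slopes_3pt(profile.positions, profile.values)

    m = slopes.min()
    tol = 1e-9 * max(1.0, abs(m))
    tied = np.flatnonzero(slopes <= m + tol)
    best = tied[np.argmin(np.abs(centers[tied]))]
    if len(tied) > 1:
        log.debug("steepest-slope tie among %d windows; chose center %.3f mm",
                  len(tied), centers[best])
    slope = float(slopes[best])
    span = 2.0 * h
    distance = -span if slope < 0 else (span if slope > 0 else 0.0)

    try:
        upper, lower = estimate_baselines(profile, plateau_fraction)
    except DegenerateProfileError:
        mean = float(np.mean(profile.values))
        return ProfileAnalysis(mean, mean, min(slope, 0.0) if slope <= 0 else slope,
                               float(centers[best]), distance, no_transition=True)
    if slope >= 0:
        # a rising steepest slope contradicts the high -> low marking
        return ProfileAnalysis(upper, lower, 0.0, float(centers[best]), 0.0,
                               no_transition=True)
    return ProfileAnalysis(upper, lower, slope, float(centers[best]), distance)


def analyze_profiles(profiles: list[Profile],
                     plateau_fraction: float = 0.25) -> list[ProfileAnalysis]:
    """Apply baseline and steepest-slope estimation to every profile."""
    return [steepest_slope(p, plateau_fraction) for p in profiles]


def summarize(analyses: list[ProfileAnalysis]) -> SharpnessSummary:
    """Component-wise median over per-profile analyses (even count: mean of
    the central pair, numpy convention)."""
    if not analyses:
        raise ConfigError("summarize requires at least one profile analysis")
    return SharpnessSummary(
        median_slope_hu_per_mm=float(np.median(
            [a.steepest_slope_hu_per_mm for a in analyses])),
        median_upper_hu=float(np.median([a.upper_baseline_hu for a in analyses])),
        median_lower_hu=float(np.median([a.lower_baseline_hu for a in analyses])),
        median_distance_mm=float(np.median([a.distance_mm for a in analyses])),
        n_profiles=len(analyses),
    )
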