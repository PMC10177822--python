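"""SNR, CNR and the full image-quality pipeline.

SNR is the upper (brighter-tissue) baseline divided by the noise estimate;
CNR is the baseline difference divided by the noise estimate. The upper
baseline corresponds to muscle in the muscle/fat interface the pipeline
targets. Values are kept at full precision internally and rounded to one
decimal only at serialization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import DegenerateInputError
from .image import ImageSlice
from .noise import build_noise_map, detect_edges, estimate_noise, select_homogeneous_region
from .profiles import BorderSpec, SharpnessSummary, analyze_profiles, extract_profiles, summarize

__all__ = ["QualityReport", "snr", "cnr", "evaluate_image"]

log = logging.getLogger("ctiq.metrics")


def snr(upper_baseline_hu: float, noise_hu: float) -> float:
    """Signal-to-noise ratio: upper baseline / noise."""
    if not (noise_hu > 0):
        raise DegenerateInputError(
            f"SNR undefined for noise {noise_hu!r} HU (must be > 0)")
    return upper_baseline_hu / noise_hu


def cnr(upper_baseline_hu: float, lower_baseline_hu: float,
        noise_hu: float) -> float:
    """Contrast-to-noise ratio: (upper - lower) baseline / noise."""
    if not (noise_hu > 0):
        raise DegenerateInputError(
            f"CNR undefined for noise {noise_hu!r} HU (must be > 0)")
    return (upper_baseline_hu - lower_baseline_hu) / noise_hu


@dataclass(frozen=True)
class QualityReport:
    """Objective image-quality metrics for one slice, with provenance."""

    image_id: str
    snr: float
    cnr: float
    noise_hu: float
    sharpness: SharpnessSummary
    homogeneous_region: dict = field(default_factory=dict)
    border: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    def to_dict(self, decimals: int = 1) -> dict:
        """Serializable form, metrics rounded to ``decimals`` places."""
        r = lambda v: round(float(v), decimals)
        sharp = {k: (r(v) if isinstance(v, float) else v)
                 for k, v in self.sharpness.to_dict().items()}
        return {
            "image_id": self.image_id,
            "snr": r(self.snr),
            "cnr": r(self.cnr),
            "noise_hu": r(self.noise_hu),
            "sharpness": sharp,
            "homogeneous_region": self.homogeneous_region,
            "border": self.border,
            "parameters": self.parameters,
        }


def evaluate_image(image: ImageSlice, border: BorderSpec,
                   step_mm: float | None = None,
                   plateau_fraction: float = 0.25,
                   gradient_threshold_hu_per_mm: float = 50.0,
                   window_mm: float = 5.0, stride_px: int = 1,
                   fit_dof_correction: bool = False) -> QualityReport:
    """Run the whole objective evaluation: profiles -> noise map -> ratios.

    Deterministic for fixed inputs. Stage failures propagate with the stage
    name prefixed; a noise-free image raises :class:`DegenerateInputError`
    because SNR/CNR are undefined at zero noise.
    """
    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise type(exc)(f"[{name}] {exc}") from exc

    profs = stage("profiles", extract_profiles, image, border, step_mm)
    analyses = stage("profiles", analyze_profiles, profs, plateau_fraction)
    sharp = stage("profiles", summarize, analyses)

    edges = stage("noise", detect_edges, image, gradient_threshold_hu_per_mm)
    region = stage("noise", select_homogeneous_region, image, edges, window_mm)
    nmap = stage("noise", build_noise_map, image, edges, window_mm, stride_px,
                 fit_dof_correction)
    noise_hu = stage("noise", estimate_noise, nmap)
    log.debug("noise %.3f HU over %d valid windows", noise_hu, nmap.n_valid)

    snr_v = stage("metrics", snr, sharp.median_upper_hu, noise_hu)
    cnr_v = stage("metrics", cnr, sharp.median_upper_hu, sharp.median_lower_hu,
                  noise_hu)
    return QualityReport(
        image_id=image.id, snr=snr_v, cnr=cnr_v, noise_hu=noise_hu,
        sharpness=sharp,
        homogeneous_region={"row0": region.row0, "col0": region.col0,
                            "size_px": region.size_px,
                            "raw_sd_hu": region.sd_hu},
        border=border.to_dict(),
        parameters={
            "step_mm": step_mm if step_mm is not None
            else image.pixel_spacing_mm / 2.0,
            "plateau_fraction": plateau_fraction,
            "gradient_threshold_hu_per_mm": gradient_threshold_hu_per_mm,
            "window_mm": window_mm, "stride_px": stride_px,
            "fit_dof_correction": fit_dof_correction,
        },
    )
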