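"""Radiation-dose descriptors: DLP normalization and effective dose.

For comparability across examinations of different scan lengths, the
dose-length product DLP = CTDIvol x scan length (mGy*cm) is normalized to a
reference scan length (default 25 cm for neck examinations). Effective dose
(mSv) is the normalized DLP times a body-region conversion factor; the
head-and-neck factor k = 0.0058 mSv/(mGy*cm) is the default. Reported
values are rounded half-up (2 decimals for mSv, 1 for mGy*cm) only at
output; arithmetic is exact internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .errors import ConfigError
from .phantom import DoseRecord

__all__ = [
    "DoseRecord",
    "DoseSummary",
    "K_FACTORS",
    "normalize_dlp",
    "effective_dose",
    "dose_reduction_percent",
    "summarize_cohort",
    "compare_cohorts",
    "round_half_up",
]

#: ICRP conversion factors k (mSv per mGy*cm) by body region, adult.
K_FACTORS: dict[str, float] = {
    "head": 0.0021,
    "neck": 0.0059,
    "head_and_neck": 0.0058,
    "chest": 0.014,
    "abdomen_pelvis": 0.015,
}

DEFAULT_K = K_FACTORS["head_and_neck"]


def round_half_up(value: float, decimals: int) -> float:
    """Round half away from zero, matching printed clinical tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def normalize_dlp(record: DoseRecord, reference_length_cm: float = 25.0) -> float:
    """DLP rescaled to the reference scan length: CTDIvol x reference length."""
    if not (reference_length_cm > 0):
        raise ConfigError("reference length must be positive")
    return record.ctdivol_mgy * reference_length_cm


def effective_dose(dlp_mgy_cm: float, k: float = DEFAULT_K) -> float:
    """Effective dose (mSv) = DLP x k."""
    if dlp_mgy_cm < 0:
        raise ConfigError("DLP must be non-negative")
    if not (k > 0):
        raise ConfigError("conversion factor k must be positive")
    return dlp_mgy_cm * k


def dose_reduction_percent(reference_msv: float, new_msv: float) -> float:
    """Percent reduction of ``new`` relative to ``reference``."""
    if not (reference_msv > 0):
        raise ConfigError("reference dose must be positive")
    return 100.0 * (reference_msv - new_msv) / reference_msv


@dataclass(frozen=True)
class DoseSummary:
    """Cohort means and SDs of the dose descriptors (full precision)."""

    n: int
    ctdivol_mean_mgy: float
    ctdivol_sd_mgy: float
    normalized_dlp_mean_mgy_cm: float
    normalized_dlp_sd_mgy_cm: float
    effective_dose_mean_msv: float
    effective_dose_sd_msv: float
    reference_length_cm: float
    k: float

    def to_dict(self) -> dict:
        """Printed form: mGy/mGy*cm at 1 decimal, mSv at 2 decimals."""
        return {
            "n": self.n,
            "ctdivol_mean_mgy": round_half_up(self.ctdivol_mean_mgy, 1),
            "ctdivol_sd_mgy": round_half_up(self.ctdivol_sd_mgy, 1),
            "normalized_dlp_mean_mgy_cm":
                round_half_up(self.normalized_dlp_mean_mgy_cm, 1),
            "normalized_dlp_sd_mgy_cm":
                round_half_up(self.normalized_dlp_sd_mgy_cm, 1),
            "effective_dose_mean_msv":
                round_half_up(self.effective_dose_mean_msv, 2),
            "effective_dose_sd_msv":
                round_half_up(self.effective_dose_sd_msv, 2),
            "reference_length_cm": self.reference_length_cm,
            "k": self.k,
        }


def summarize_cohort(records: list[DoseRecord],
                     reference_length_cm: float = 25.0,
                     k: float = DEFAULT_K) -> DoseSummary:
    """Mean/SD of CTDIvol, normalized DLP and effective dose over a cohort."""
    if not records:
        raise ConfigError("cohort is empty")
    ctdi = np.array([r.ctdivol_mgy for r in records])
    dlp = np.array([normalize_dlp(r, reference_length_cm) for r in records])
    ed = dlp * k
    sd = lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
    return DoseSummary(
        n=len(records),
        ctdivol_mean_mgy=float(ctdi.mean()), ctdivol_sd_mgy=sd(ctdi),
        normalized_dlp_mean_mgy_cm=float(dlp.mean()),
        normalized_dlp_sd_mgy_cm=sd(dlp),
        effective_dose_mean_msv=float(ed.mean()), effective_dose_sd_msv=sd(ed),
        reference_length_cm=reference_length_cm, k=k,
    )


def compare_cohorts(reference: list[DoseRecord], new: list[DoseRecord],
                    reference_length_cm: float = 25.0,
                    k: float = DEFAULT_K) -> dict:
    """Summaries of two cohorts plus the percent reduction in mean effective
    dose of ``new`` relative to ``reference``."""
    ref = summarize_cohort(reference, reference_length_cm, k)
    cur = summarize_cohort(new, reference_length_cm, k)
    red = dose_reduction_percent(ref.effective_dose_mean_msv,
                                 cur.effective_dose_mean_msv)
    return {"reference": ref, "new": cur, "reduction_percent": red}
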