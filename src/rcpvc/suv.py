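"""Body-weight SUV with optional PVE correction, and metabolic-response classes.

SUV normalises a tissue concentration by injected dose per body weight:
``SUV = C_tissue / (dose / (weight_g))`` with the net dose decay-corrected
from injection to scan start (18F half-life 109.77 min) by default.
Follow-up response uses the EORTC-style percentage change of SUV with
configurable cutoffs (default +/-25%): complete / partial metabolic
response, stable or progressive metabolic disease.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .calibration import RCSurface
from .correction import apply_correction
from .isocontour import LesionMeasurement

__all__ = [
    "SUVParams",
    "ResponseRecord",
    "EORTCCutoffs",
    "compute_suv",
    "corrected_suv",
    "classify_response",
    "F18_HALF_LIFE_MIN",
]

F18_HALF_LIFE_MIN = 109.77


@dataclass
class SUVParams:
    """Dose / patient metadata needed for body-weight SUV.

    ``uptake_time_min`` is the injection-to-scan delay used for decay
    correction of the net dose (set ``decay_correct=False`` to reproduce
    idealized textbook examples that ignore decay).
    """

    injected_activity_mbq: float
    body_weight_kg: float
    residual_activity_mbq: float = 0.0
    uptake_time_min: float = 60.0
    half_life_min: float = F18_HALF_LIFE_MIN
    decay_correct: bool = True

    def __post_init__(self) -> None:
        if self.net_dose_mbq <= 0:
            raise ValueError("net injected dose must be positive")
        if self.body_weight_kg <= 0:
            raise ValueError("body weight must be positive")
        if self.uptake_time_min < 0:
            raise ValueError("scan cannot precede injection")

    @property
    def net_dose_mbq(self) -> float:
        return self.injected_activity_mbq - self.residual_activity_mbq

    @property
    def dose_at_scan_mbq(self) -> float:
        if not self.decay_correct:
            return self.net_dose_mbq
        return self.net_dose_mbq * 2.0 ** (-self.uptake_time_min / self.half_life_min)


def compute_suv(c_tissue_mbq_ml: float, params: SUVParams) -> float:
    """Body-weight SUV (g/mL) of a tissue concentration in MBq/mL."""
    if c_tissue_mbq_ml < 0:
        raise ValueError("tissue concentration must be non-negative")
    dose_per_gram = params.dose_at_scan_mbq / (params.body_weight_kg * 1000.0)
    return c_tissue_mbq_ml / dose_per_gram


def corrected_suv(
    measurement: LesionMeasurement, surface: RCSurface, params: SUVParams
) -> tuple[float, float, float, list[str]]:
    """SUV before/after PVE correction from one measurement.

    Returns ``(suv_uncorrected, suv_corrected, pct_difference, flags)``;
    the percentage difference equals ``100 (F - 1)`` exactly, since both SUVs
    share the same measured concentration.  An RC >= 1 (correction lowers
    SUV) is flagged rather than suppressed.
    """
    result = apply_correction(measurement, surface)
    suv_unc = compute_suv(measurement.c_thr, params)
    suv_cor = compute_suv(result.c_corrected, params)
    pct = 100.0 * (result.f - 1.0)
    flags = list(result.flags)
    if result.rc >= 1.0:
        flags.append("correction decreased SUV (RC >= 1)")
    return suv_unc, suv_cor, pct, flags


@dataclass
class EORTCCutoffs:
    """Response cutoffs on percent SUV change; boundaries classify as SMD."""

    partial_response_pct: float = -25.0
    progression_pct: float = 25.0
    background_suv: float = 1.0  # "complete resolution" equivalence level


@dataclass
class ResponseRecord:
    suv_pre: float
    suv_post: float
    percent_change: float = math.nan
    response_class: str = ""

    def __post_init__(self) -> None:
        if self.suv_pre <= 0:
            raise ValueError("baseline SUV must be positive")
        if math.isnan(self.percent_change):
            self.percent_change = 100.0 * (self.suv_post - self.suv_pre) / self.suv_pre


def classify_response(
    record: ResponseRecord, cutoffs: EORTCCutoffs | None = None
) -> str:
    """Assign CMR / PMR / SMD / PMD from the percent SUV change."""
    cutoffs = cutoffs or EORTCCutoffs()
    if record.suv_post <= cutoffs.background_suv:
        cls = "CMR"
    elif record.percent_change < cutoffs.partial_response_pct:
        cls = "PMR"
    elif record.percent_change > cutoffs.progression_pct:
        cls = "PMD"
    else:
        cls = "SMD"
    record.response_class = cls
    return cls
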