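"""AUC-targeted dose individualization.

For a one-compartment linear model the cumulative AUC of a course is
total administered dose / CL, independent of the interval and infusion
duration.  The dose per administration hitting a cumulative-AUC target is
therefore ``target * CL / n_doses`` — linear in both the target and the
individual clearance.  The recommendation is verified by re-simulating
the recommended regimen through the PK engine.
"""

from __future__ import annotations

from dataclasses import dataclass

from .pk import IndividualParameters, Regimen, auc_cumulative

__all__ = [
    "DoseRecommendation",
    "dose_for_target_auc",
    "per_dose_target_range",
    "cumulative_target_range",
]

#: Conventional cumulative-AUC target for a 16-dose course (mg·h/L).
DEFAULT_TARGET_AUC_CUM = 80.0


@dataclass(frozen=True)
class DoseRecommendation:
    """A per-administration dose recommendation for a cumulative-AUC target."""

    dose: float  # mg per administration, unrounded
    n_doses: int
    interval: float  # h
    infusion_duration: float  # h
    target_auc_cum: float  # mg·h/L
    predicted_auc_cum: float  # re-simulated at the recommendation
    clearance: float  # L/h used for the computation
    model: str = ""

    def regimen(self) -> Regimen:
        return Regimen.uniform(
            dose=self.dose,
            n_doses=self.n_doses,
            interval=self.interval,
            duration=self.infusion_duration,
        )


def dose_for_target_auc(
    clearance: float,
    target_auc_cum: float = DEFAULT_TARGET_AUC_CUM,
    n_doses: int = 16,
    interval: float = 6.0,
    infusion_duration: float = 2.0,
    volume: float | None = None,
    model: str = "",
    round_to: float | None = None,
) -> DoseRecommendation:
    """Dose per administration achieving a cumulative-AUC target.

    dose = target * CL / n_doses.  The returned record carries the
    re-simulated cumulative AUC of the recommended regimen, which equals
    the target exactly (up to floating point) when ``round_to`` is None.
    Rounding to practical increments is off by default because raw
    predicted doses are what model-comparison analyses use.
    """
    if not clearance > 0:
        raise ValueError(f"clearance must be positive, got {clearance}")
    if target_auc_cum < 0:
        raise ValueError(f"target AUC must be >= 0, got {target_auc_cum}")
    if n_doses < 1:
        raise ValueError(f"n_doses must be >= 1, got {n_doses}")

    dose = target_auc_cum * clearance / n_doses
    if round_to is not None and dose > 0:
        dose = round(dose / round_to) * round_to

    if dose > 0:
        params = IndividualParameters(
            clearance=clearance, volume=volume if volume is not None else 1.0
        )
        regimen = Regimen.uniform(
            dose=dose, n_doses=n_doses, interval=interval, duration=infusion_duration
        )
        predicted = auc_cumulative(params, regimen)
    else:
        predicted = 0.0

    return DoseRecommendation(
        dose=dose,
        n_doses=n_doses,
        interval=interval,
        infusion_duration=infusion_duration,
        target_auc_cum=target_auc_cum,
        predicted_auc_cum=predicted,
        clearance=clearance,
        model=model,
    )


def per_dose_target_range(
    auc_cum_range: tuple[float, float], n_doses: int = 16
) -> tuple[float, float]:
    """Per-dose AUC bounds from cumulative bounds (divide by n_doses)."""
    if n_doses < 1:
        raise ValueError("n_doses must be >= 1")
    lo, hi = auc_cum_range
    return (lo / n_doses, hi / n_doses)


def cumulative_target_range(
    per_dose_range: tuple[float, float], n_doses: int = 16
) -> tuple[float, float]:
    """Cumulative AUC bounds from per-dose bounds (multiply by n_doses)."""
    if n_doses < 1:
        raise ValueError("n_doses must be >= 1")
    lo, hi = per_dose_range
    return (lo * n_doses, hi * n_doses)
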