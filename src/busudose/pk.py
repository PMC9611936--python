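"""One-compartment, zero-order-infusion pharmacokinetics.

Closed-form concentration and AUC for multiple-dose intravenous infusion
regimens, by superposition of single-dose solutions.  All quantities are
kept in one canonical unit system — mg for drug mass, L for volume, h for
time, mg/L for concentration — so AUCs come out in mg·h/L.  Concentrations
reported in ng/mL (the usual busulfan assay unit) are divided by 1000 at
the I/O boundary.

For an infusion of rate ``R0 = amount/duration`` starting at time ``s``
with elimination rate constant ``k = CL/V``::

    C(t) = R0/CL * (1 - exp(-k*(t-s)))                      s <= t <= s+d
    C(t) = C(s+d) * exp(-k*(t-s-d))                         t > s+d

Multiple doses superpose linearly.  AUC over an arbitrary window is the
closed-form integral of this curve; cumulative AUC to infinity reduces to
total administered dose / CL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "BUSULFAN_MOLAR_MASS",
    "MIN_INFUSION_DURATION",
    "DoseEvent",
    "Regimen",
    "IndividualParameters",
    "Observation",
    "predict_concentration",
    "auc_interval",
    "auc_cumulative",
    "convert_auc",
]

#: Busulfan molar mass (g/mol), used for µM·min <-> mg·h/L AUC conversion.
BUSULFAN_MOLAR_MASS = 246.30

#: Doses shorter than this (h) are rejected: the engine models infusions,
#: not boluses, and a near-zero duration makes the rate term degenerate.
MIN_INFUSION_DURATION = 1e-6


@dataclass(frozen=True)
class DoseEvent:
    """A single zero-order intravenous infusion.

    Parameters
    ----------
    amount
        Drug mass infused (mg).
    start
        Infusion start, hours since the start of the first dose.
    duration
        Infusion length (h); must exceed ``MIN_INFUSION_DURATION``.
    """

    amount: float
    start: float
    duration: float

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError(f"dose amount must be >= 0, got {self.amount}")
        if self.start < 0:
            raise ValueError(f"dose start must be >= 0, got {self.start}")
        if self.duration <= MIN_INFUSION_DURATION:
            raise ValueError(
                f"infusion duration must exceed {MIN_INFUSION_DURATION} h, "
                f"got {self.duration}; bolus dosing is not supported"
            )

    @property
    def rate(self) -> float:
        """Infusion rate R0 (mg/h)."""
        return self.amount / self.duration

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class Regimen:
    """An ordered sequence of infusion events.

    ``interval`` is the nominal inter-dose interval (h), carried for
    reporting; the prediction code uses only the per-event times.
    """

    events: tuple[DoseEvent, ...]
    interval: float | None = None

    def __post_init__(self) -> None:
        events = tuple(self.events)
        object.__setattr__(self, "events", events)
        if not events:
            raise ValueError("regimen must contain at least one dose event")
        starts = [e.start for e in events]
        if any(b < a for a, b in zip(starts, starts[1:])):
            raise ValueError("dose events must be sorted by start time")
        if len(set(starts)) != len(starts):
            raise ValueError("no two dose events may share a start time")

    @classmethod
    def uniform(
        cls,
        dose: float,
        n_doses: int = 16,
        interval: float = 6.0,
        duration: float = 2.0,
    ) -> "Regimen":
        """Equal doses every ``interval`` hours (default: q6h 2-h infusions x16)."""
        if n_doses < 1:
            raise ValueError("n_doses must be >= 1")
        events = tuple(
            DoseEvent(amount=dose, start=i * interval, duration=duration)
            for i in range(n_doses)
        )
        return cls(events=events, interval=interval)

    @property
    def n_doses(self) -> int:
        return len(self.events)

    @property
    def total_dose(self) -> float:
        return sum(e.amount for e in self.events)

    def first_dose_only(self) -> "Regimen":
        return Regimen(events=(self.events[0],), interval=self.interval)

    def scaled(self, factor: float) -> "Regimen":
        """Same schedule with every amount multiplied by ``factor``."""
        return Regimen(
            events=tuple(
                DoseEvent(e.amount * factor, e.start, e.duration) for e in self.events
            ),
            interval=self.interval,
        )


@dataclass(frozen=True)
class IndividualParameters:
    """Individual one-compartment parameters: clearance and volume.

    The elimination rate constant ``k = CL/V`` is derived, never stored,
    so the identity holds to machine precision by construction.  Models
    parameterized as (Ke, V) are stored as CL = Ke*V.
    """

    clearance: float  # L/h
    volume: float  # L

    def __post_init__(self) -> None:
        if not (self.clearance > 0 and math.isfinite(self.clearance)):
            raise ValueError(f"clearance must be positive, got {self.clearance}")
        if not (self.volume > 0 and math.isfinite(self.volume)):
            raise ValueError(f"volume must be positive, got {self.volume}")

    @property
    def k(self) -> float:
        """Elimination rate constant (1/h)."""
        return self.clearance / self.volume

    @property
    def half_life(self) -> float:
        return math.log(2.0) / self.k


@dataclass(frozen=True)
class Observation:
    """A measured concentration, stored internally in mg/L.

    ``source_unit`` records the unit the value arrived in (1 mg/L =
    1000 ng/mL); it does not affect the stored value.
    """

    time: float  # h since first-dose start
    concentration: float  # mg/L
    source_unit: str = "mg/L"

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"observation time must be >= 0, got {self.time}")
        if self.concentration < 0:
            raise ValueError(
                f"concentration must be >= 0, got {self.concentration}"
            )

    @classmethod
    def from_ng_per_ml(cls, time: float, value_ng_ml: float) -> "Observation":
        return cls(time=time, concentration=value_ng_ml / 1000.0, source_unit="ng/mL")


# ---------------------------------------------------------------------------
# Vectorized kernels.  CL, k and t broadcast against each other, which lets
# the same code serve scalar prediction, time grids and parameter grids
# (e.g. brute-force eta searches).
# ---------------------------------------------------------------------------

def _event_concentration(t, amount, start, duration, cl, k):
    """Concentration contribution of one infusion event; broadcasts."""
    rate = amount / duration
    infused = np.clip(t - start, 0.0, duration)  # time spent infusing
    decayed = np.maximum(t - start - duration, 0.0)  # time since infusion end
    return rate / cl * -np.expm1(-k * infused) * np.exp(-k * decayed)


def _event_auc_from_zero(t, amount, start, duration, cl, k):
    """Integral of one event's concentration from time 0 to t; broadcasts.

    Supports t = inf, where it reduces to amount/CL.
    """
    rate = amount / duration
    infused = np.clip(t - start, 0.0, duration)
    decayed = np.maximum(t - start - duration, 0.0)
    rise = -np.expm1(-k * infused)  # 1 - exp(-k * infused)
    auc_infusion = rate / cl * (infused - rise / k)
    c_at_cutoff = rate / cl * rise  # concentration at min(t, infusion end)
    auc_decay = c_at_cutoff / k * np.where(
        np.isinf(decayed), 1.0, -np.expm1(-k * decayed)
    )
    return auc_infusion + auc_decay


def _superpose(fn, params: IndividualParameters, regimen: Regimen, t):
    cl, k = params.clearance, params.k
    out = np.zeros_like(np.asarray(t, dtype=float))
    for e in regimen.events:
        out = out + fn(t, e.amount, e.start, e.duration, cl, k)
    return out


def predict_concentration(
    params: IndividualParameters,
    regimen: Regimen,
    times: Sequence[float] | np.ndarray | float,
) -> np.ndarray:
    """Predicted concentration (mg/L) at each requested time.

    Superposes the closed-form single-infusion solution over all dose
    events.  Times before the first infusion starts give 0; the curve is
    continuous at every infusion end.  Linear in all dose amounts.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("prediction times must be >= 0")
    return _superpose(_event_concentration, params, regimen, t)


def auc_interval(
    params: IndividualParameters,
    regimen: Regimen,
    t0: float,
    t1: float,
) -> float:
    """Closed-form AUC (mg·h/L) of the superposed curve over [t0, t1].

    ``t1`` may be ``inf``.  Additive over adjacent windows by construction.
    """
    if t0 < 0:
        raise ValueError(f"t0 must be >= 0, got {t0}")
    if not t1 > t0:
        raise ValueError(f"need t1 > t0, got [{t0}, {t1}]")
    upper = float(_superpose(_event_auc_from_zero, params, regimen, t1))
    lower = float(_superpose(_event_auc_from_zero, params, regimen, t0))
    return upper - lower


def auc_cumulative(params: IndividualParameters, regimen: Regimen) -> float:
    """Cumulative AUC (mg·h/L) of the whole course: total dose / CL."""
    return regimen.total_dose / params.clearance


_UNIT_ALIASES = {
    "um*min": "uM*min",
    "um.min": "uM*min",
    "um min": "uM*min",
    "µm·min": "uM*min",
    "um·min": "uM*min",
    "umol/l*min": "uM*min",
    "mg*h/l": "mg*h/L",
    "mg.h/l": "mg*h/L",
    "mg h/l": "mg*h/L",
    "mg·h/l": "mg*h/L",
}


def _normalize_unit(unit: str) -> str:
    key = unit.strip().lower().replace("μ", "µ")
    try:
        return _UNIT_ALIASES[key]
    except KeyError:
        raise ValueError(
            f"unknown AUC unit {unit!r}; expected 'uM*min' or 'mg*h/L'"
        ) from None


def convert_auc(
    value: float,
    from_unit: str,
    to_unit: str,
    molar_mass: float = BUSULFAN_MOLAR_MASS,
) -> float:
    """Convert an AUC between µM·min and mg·h/L.

    mg·h/L = µM·min × molar_mass / 60000 (µmol/L → mg/L via molar mass,
    min → h via 60; the 1000 in µ and the m in mg cancel to 60000).
    Round-trip conversion is the identity.
    """
    if molar_mass <= 0:
        raise ValueError("molar_mass must be positive")
    src = _normalize_unit(from_unit)
    dst = _normalize_unit(to_unit)
    if src == dst:
        return value
    factor = molar_mass / 60000.0
    if src == "uM*min":  # -> mg*h/L
        return value * factor
    return value / factor
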