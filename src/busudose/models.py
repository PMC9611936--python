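"""Covariate-to-parameter models and the nonparametric prior.

Two published one-compartment busulfan models are supported:

* the *parametric* model (Paci et al. type): allometric scaling of CL and
  V to body weight, with a breakpoint in the CL exponent at the 9-kg
  reference weight, log-normal between-subject variability, and a
  combined proportional + additive residual error;

* the *nonparametric* model (Neely et al. type): elimination-rate and
  volume "slope" parameters (KeS, VS) scaled by the lesser of body weight
  and Traub–Johnson ideal body weight, with a discrete prior over
  (KeS, VS) support points and a linear residual-SD rule.

The true support points of the published nonparametric prior are not in
the public domain; only the median, range and CV of each slope parameter
are.  :func:`build_np_prior` therefore reconstructs a *synthetic* discrete
prior — a log-spaced grid weighted by a truncated log-normal density
moment-matched to those summaries — and every spec carries that caveat.

All published constants live in ``data/model_library.yaml``, not in code.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Any

import numpy as np
import yaml

from .pk import IndividualParameters

__all__ = [
    "PatientCovariates",
    "ParametricModelSpec",
    "NonparametricModelSpec",
    "NpPrior",
    "load_model_library",
    "paci_typical_params",
    "traub_johnson_ibw",
    "neely_params",
    "build_np_prior",
    "bsv_omega",
]


def load_model_library() -> dict[str, Any]:
    """Published model constants shipped with the package."""
    text = resources.files("busudose").joinpath("data/model_library.yaml").read_text()
    return yaml.safe_load(text)


_LIBRARY = load_model_library()


@dataclass(frozen=True)
class PatientCovariates:
    """Demographics driving the covariate–parameter equations.

    Height is only needed when ideal body weight enters a model; age and
    sex are carried for reporting but used by neither implemented model.
    """

    body_weight: float  # kg
    height: float | None = None  # cm
    age: float | None = None  # yr
    sex: str | None = None  # 'male' | 'female'

    def __post_init__(self) -> None:
        if not self.body_weight > 0:
            raise ValueError(f"body weight must be > 0, got {self.body_weight}")
        if self.height is not None and not self.height > 0:
            raise ValueError(f"height must be > 0, got {self.height}")
        if self.age is not None and self.age < 0:
            raise ValueError(f"age must be >= 0, got {self.age}")


@dataclass(frozen=True)
class ParametricModelSpec:
    """Constants of the parametric allometric model (see module docstring)."""

    cl_typical: float = _LIBRARY["paci"]["cl_typical"]
    reference_weight: float = _LIBRARY["paci"]["reference_weight"]
    cl_exponent_low: float = _LIBRARY["paci"]["cl_exponent_low"]
    cl_exponent_high: float = _LIBRARY["paci"]["cl_exponent_high"]
    v_exponent: float = _LIBRARY["paci"]["v_exponent"]
    cl_cv: float = _LIBRARY["paci"]["cl_cv"]
    v_cv: float = _LIBRARY["paci"]["v_cv"]
    residual_proportional: float = _LIBRARY["paci"]["residual_proportional"]
    residual_additive: float = _LIBRARY["paci"]["residual_additive"]
    name: str = "paci"

    def __post_init__(self) -> None:
        for f in (
            "cl_typical",
            "reference_weight",
            "cl_exponent_low",
            "cl_exponent_high",
            "v_exponent",
            "cl_cv",
            "v_cv",
        ):
            v = getattr(self, f)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{f} must be positive and finite, got {v}")

    def to_dict(self) -> dict[str, Any]:
        return {
            k: getattr(self, k)
            for k in self.__dataclass_fields__  # noqa: SLF001 - dataclass API
        }


@dataclass(frozen=True)
class NonparametricModelSpec:
    """Summary constants of the nonparametric slope-parameter model."""

    kes_median: float = _LIBRARY["neely"]["kes_median"]
    kes_min: float = _LIBRARY["neely"]["kes_min"]
    kes_max: float = _LIBRARY["neely"]["kes_max"]
    kes_cv: float = _LIBRARY["neely"]["kes_cv"]
    vs_median: float = _LIBRARY["neely"]["vs_median"]
    vs_min: float = _LIBRARY["neely"]["vs_min"]
    vs_max: float = _LIBRARY["neely"]["vs_max"]
    vs_cv: float = _LIBRARY["neely"]["vs_cv"]
    size_exponent_ke: float = _LIBRARY["neely"]["size_exponent_ke"]
    residual_intercept: float = _LIBRARY["neely"]["residual_intercept"]
    residual_slope: float = _LIBRARY["neely"]["residual_slope"]
    name: str = "neely"

    def __post_init__(self) -> None:
        if not (0 < self.kes_min <= self.kes_median <= self.kes_max):
            raise ValueError("KeS summaries must satisfy 0 < min <= median <= max")
        if not (0 < self.vs_min <= self.vs_median <= self.vs_max):
            raise ValueError("VS summaries must satisfy 0 < min <= median <= max")

    def to_dict(self) -> dict[str, Any]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def bsv_omega(cv: float) -> float:
    """Log-normal SD omega from a reported between-subject CV.

    Individual parameter = typical * exp(eta), eta ~ N(0, omega^2) with
    omega^2 = ln(1 + CV^2) — the standard pharmacometric convention that
    keeps parameters positive and reproduces the stated CV.
    """
    if cv < 0:
        raise ValueError("CV must be >= 0")
    return math.sqrt(math.log1p(cv * cv))


def paci_typical_params(
    cov: PatientCovariates, spec: ParametricModelSpec | None = None
) -> IndividualParameters:
    """Typical-value CL and V from body weight under the parametric model.

    CL = 2.18 * (BW/9)^theta with theta = 1.25 below the 9-kg reference
    weight and 0.76 at or above it (continuous at the breakpoint because
    the base equals 1 there); V = BW^0.86.
    """
    spec = spec or ParametricModelSpec()
    bw = cov.body_weight
    ratio = bw / spec.reference_weight
    theta = spec.cl_exponent_low if bw < spec.reference_weight else spec.cl_exponent_high
    cl = spec.cl_typical * ratio**theta
    v = bw**spec.v_exponent
    return IndividualParameters(clearance=cl, volume=v)


def traub_johnson_ibw(
    height: float,
    coefficient: float = _LIBRARY["traub_johnson"]["coefficient"],
    height_bounds: tuple[float, float] = tuple(
        _LIBRARY["traub_johnson"]["height_bounds"]
    ),
) -> float:
    """Pediatric ideal body weight (kg) from height (cm).

    Default form: IBW = height^2 * 1.65 / 1000.  The coefficient is
    configurable because software implementations differ in the exact
    variant they use; the variant applied is recorded in run provenance.
    Heights outside the plausibility bounds warn but still return the
    computed value — never a silent truncation.
    """
    if height <= 0:
        raise ValueError(f"height must be > 0, got {height}")
    lo, hi = height_bounds
    if not lo <= height <= hi:
        warnings.warn(
            f"height {height} cm outside plausible range [{lo}, {hi}] cm; "
            "IBW computed anyway",
            stacklevel=2,
        )
    return coefficient * height * height


def neely_params(
    kes: float,
    vs: float,
    cov: PatientCovariates,
    spec: NonparametricModelSpec | None = None,
) -> IndividualParameters:
    """Individual parameters from slope values under the nonparametric model.

    size = min(BW, IBW); Ke = KeS * size^-0.25; V = VS * size.  Returned
    as CL = Ke * V so both models share one parameter container.  Height
    is mandatory: without it the BW-vs-IBW comparison cannot be made.
    """
    spec = spec or NonparametricModelSpec()
    if not (kes > 0 and vs > 0):
        raise ValueError(f"slope parameters must be positive, got KeS={kes}, VS={vs}")
    if cov.height is None:
        raise ValueError(
            "height is required for the nonparametric model: ideal body weight "
            "must be compared against body weight"
        )
    size = min(cov.body_weight, traub_johnson_ibw(cov.height))
    ke = kes * size**spec.size_exponent_ke
    v = vs * size
    return IndividualParameters(clearance=ke * v, volume=v)


@dataclass(frozen=True)
class NpPrior:
    """A discrete prior over (KeS, VS) support points.

    ``points`` has shape (n, 2) with columns KeS, VS; ``weights`` is the
    matching probability vector (positive, sums to 1).  This is a
    synthetic reconstruction of an unpublished support set: grid
    positions and weights are moment-matched to published summaries, not
    the original points.
    """

    points: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        w = np.asarray(self.weights, dtype=float)
        if pts.shape[1] != 2 or pts.shape[0] != w.shape[0]:
            raise ValueError("points must be (n, 2) with matching weights (n,)")
        if np.any(w <= 0):
            raise ValueError("prior weights must be strictly positive")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "weights", w / w.sum())

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def weighted_median(self, column: int) -> float:
        """Weighted median of KeS (column 0) or VS (column 1).

        Computed on the collapsed marginal (ties merged), interpolating
        the cumulative weight with each value's mass centred on it, so
        the estimate is not quantized to grid positions.
        """
        values, inverse = np.unique(self.points[:, column], return_inverse=True)
        w = np.bincount(inverse, weights=self.weights)
        centred = np.cumsum(w) - 0.5 * w
        return float(np.interp(0.5, centred, values))


def _truncated_lognormal_weights(
    grid: np.ndarray, median: float, cv: float
) -> np.ndarray:
    """Density weights on a log-spaced grid from a truncated log-normal.

    On a log-uniform grid the cell measure is constant in ln x, so the
    weight of each point is simply the normal density of ln x about
    ln median with SD sqrt(ln(1+CV^2)), renormalized (truncation to the
    grid range is implicit).
    """
    sigma = bsv_omega(cv)
    z = (np.log(grid) - math.log(median)) / sigma
    w = np.exp(-0.5 * z * z)
    return w / w.sum()


def build_np_prior(
    spec: NonparametricModelSpec | None = None,
    n_points: int = 625,
    seed: int | None = None,
    jitter: float = 0.0,
) -> NpPrior:
    """Construct the synthetic discrete prior over (KeS, VS).

    A log-spaced grid of about ``n_points`` support points spans the
    published (min, max) box; weights are the product of independent
    truncated log-normal densities matched to each parameter's published
    median and CV.  ``n_points`` is rounded to the nearest perfect square
    (one side per dimension); ``n_points=1`` degenerates to a single
    point at the medians with weight 1.

    ``jitter`` > 0 perturbs grid positions log-uniformly by that fraction
    of a grid step (seeded), which breaks grid artifacts if desired; the
    default is a deterministic grid, so the result is reproducible for
    any fixed seed.
    """
    spec = spec or NonparametricModelSpec()
    if n_points < 1:
        raise ValueError(f"n_points must be >= 1, got {n_points}")
    if n_points == 1:
        return NpPrior(
            points=np.array([[spec.kes_median, spec.vs_median]]),
            weights=np.array([1.0]),
        )

    n_side = max(2, round(math.sqrt(n_points)))
    kes = np.geomspace(spec.kes_min, spec.kes_max, n_side)
    vs = np.geomspace(spec.vs_min, spec.vs_max, n_side)

    if jitter > 0:
        rng = np.random.default_rng(seed)
        step_k = math.log(spec.kes_max / spec.kes_min) / (n_side - 1)
        step_v = math.log(spec.vs_max / spec.vs_min) / (n_side - 1)
        kes = np.clip(
            kes * np.exp(rng.uniform(-jitter, jitter, n_side) * step_k),
            spec.kes_min,
            spec.kes_max,
        )
        vs = np.clip(
            vs * np.exp(rng.uniform(-jitter, jitter, n_side) * step_v),
            spec.vs_min,
            spec.vs_max,
        )

    w_k = _truncated_lognormal_weights(kes, spec.kes_median, spec.kes_cv)
    w_v = _truncated_lognormal_weights(vs, spec.vs_median, spec.vs_cv)

    kk, vv = np.meshgrid(kes, vs, indexing="ij")
    ww = np.outer(w_k, w_v)
    return NpPrior(
        points=np.column_stack([kk.ravel(), vv.ravel()]),
        weights=ww.ravel(),
    )
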