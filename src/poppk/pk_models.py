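"""Closed-form and ODE concentration-time functions for the four supported
compartment models.

Supported models (single dose at t=0, linear kinetics throughout):

``onecomp``
    One-compartment, IV bolus: ``C(t) = (Dose/V) * exp(-(CL/V) * t)``.
``onecomp_abs``
    One-compartment, first-order oral absorption:
    ``C(t) = Dose*Ka / (V*(Ka - ke)) * (exp(-ke*t) - exp(-Ka*t))`` with
    ``ke = CL/V``, switching to the L'Hopital limit
    ``(Dose/V)*Ka*t*exp(-Ka*t)`` in the flip-flop degenerate case Ka -> ke.
``twocomp``
    Two-compartment, IV bolus: biexponential
    ``C(t) = A*exp(-alpha*t) + B*exp(-beta*t)`` with hybrid rate constants
    derived from the micro-constants ``k10 = CL/V1``, ``k12 = Q/V1``,
    ``k21 = Q/V2``.
``twocomp_abs``
    Two-compartment with first-order absorption; solved by stiff-capable
    numerical integration of the mass-balance ODEs (a closed-form
    triexponential equivalent is used internally by the estimation layer).

All functions evaluate element-wise over a vector of sampling times, keep the
caller's time ordering, and raise :class:`~poppk.exceptions.InvalidParameterError`
/ :class:`~poppk.exceptions.InvalidInputError` on bad inputs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import (
    EstimationFailureError,
    InvalidInputError,
    InvalidParameterError,
)

__all__ = [
    "ModelKind",
    "PKParameters",
    "DoseRegimen",
    "TwoCompCoefficients",
    "conc_onecomp_iv",
    "conc_onecomp_abs",
    "twocomp_coefficients",
    "conc_twocomp_iv",
    "conc_twocomp_abs",
    "predict_conc",
]

#: relative |Ka - ke| / ke below which the absorption model switches to the
#: analytic flip-flop limit form (avoids catastrophic cancellation while
#: staying well below fitting tolerance)
FLIP_FLOP_GUARD = 1e-6

#: tolerances for the stiff-capable ODE route (below fitting noise)
ODE_RTOL = 1e-8
ODE_ATOL = 1e-12


class ModelKind(str, enum.Enum):
    """The four supported structural models; route is implied by the tag."""

    ONECOMP = "onecomp"
    ONECOMP_ABS = "onecomp_abs"
    TWOCOMP = "twocomp"
    TWOCOMP_ABS = "twocomp_abs"

    @property
    def has_absorption(self) -> bool:
        return self.value.endswith("_abs")

    @property
    def is_twocomp(self) -> bool:
        return self.value.startswith("twocomp")

    @property
    def route(self) -> str:
        return "oral" if self.has_absorption else "iv_bolus"

    @property
    def parameter_names(self) -> tuple[str, ...]:
        names = ["cl", "v"]
        if self.is_twocomp:
            names += ["v2", "q"]
        if self.has_absorption:
            names.append("ka")
        return tuple(names)


@dataclass(frozen=True)
class PKParameters:
    """Named positive parameter vector for one subject or the population
    typical value.

    ``v`` is the (central) volume; for two-compartment models it is the
    central volume V1 (``v1`` is an alias), with ``v2`` the peripheral volume
    and ``q`` the inter-compartmental clearance.  ``ka`` is present only for
    absorption models.
    """

    cl: float
    v: float
    v2: float | None = None
    q: float | None = None
    ka: float | None = None

    @property
    def v1(self) -> float:
        return self.v

    def validate_for(self, kind: ModelKind) -> None:
        for name in kind.parameter_names:
            value = getattr(self, name)
            if value is None:
                raise InvalidParameterError(
                    f"model '{kind.value}' requires parameter '{name}'"
                )
            if not np.isfinite(value) or value <= 0:
                raise InvalidParameterError(
                    f"parameter '{name}' must be strictly positive, got {value!r}"
                )

    def to_array(self, kind: ModelKind) -> np.ndarray:
        self.validate_for(kind)
        return np.array([getattr(self, n) for n in kind.parameter_names], float)

    @classmethod
    def from_array(cls, values: Sequence[float], kind: ModelKind) -> "PKParameters":
        names = kind.parameter_names
        if len(values) != len(names):
            raise InvalidParameterError(
                f"expected {len(names)} values for '{kind.value}', got {len(values)}"
            )
        return cls(**dict(zip(names, map(float, values))))

    def as_dict(self, kind: ModelKind | None = None) -> dict[str, float]:
        names = (
            kind.parameter_names
            if kind is not None
            else [n for n in ("cl", "v", "v2", "q", "ka") if getattr(self, n) is not None]
        )
        return {n: float(getattr(self, n)) for n in names}

    def scaled(self, factor: float) -> "PKParameters":
        """Multiply every present parameter by ``factor``."""
        kwargs = {
            n: (getattr(self, n) * factor if getattr(self, n) is not None else None)
            for n in ("cl", "v", "v2", "q", "ka")
        }
        return PKParameters(**kwargs)


@dataclass(frozen=True)
class DoseRegimen:
    """A single dose administered at t = 0."""

    amount: float
    route: str = "iv_bolus"

    def __post_init__(self):
        if not np.isfinite(self.amount) or self.amount <= 0:
            raise InvalidInputError(f"dose amount must be positive, got {self.amount!r}")
        if self.route not in ("iv_bolus", "oral"):
            raise InvalidInputError(f"unknown route {self.route!r}")


@dataclass(frozen=True)
class TwoCompCoefficients:
    """Hybrid rate constants and IV-bolus amplitudes of the biexponential
    disposition ``C(t) = A exp(-alpha t) + B exp(-beta t)``.

    Satisfies the Vieta identities ``alpha*beta = k10*k21`` and
    ``alpha + beta = k10 + k12 + k21``, and ``A + B = Dose/V1``.
    """

    alpha: float
    beta: float
    a_coef: float
    b_coef: float
    k10: float
    k12: float
    k21: float


def _check_times(times) -> np.ndarray:
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if t.ndim != 1:
        raise InvalidInputError("times must be one-dimensional")
    if np.any(~np.isfinite(t)) or np.any(t < 0):
        raise InvalidInputError("sampling times must be finite and non-negative")
    return t


def _check_route(dose: DoseRegimen, expected: str) -> None:
    if dose.route != expected:
        raise InvalidInputError(
            f"dose route {dose.route!r} does not match model route {expected!r}"
        )


def conc_onecomp_iv(params: PKParameters, dose: DoseRegimen, times) -> np.ndarray:
    """One-compartment IV bolus concentration, ``(Dose/V) exp(-CL/V t)``."""
    params.validate_for(ModelKind.ONECOMP)
    _check_route(dose, "iv_bolus")
    t = _check_times(times)
    ke = params.cl / params.v
    return (dose.amount / params.v) * np.exp(-ke * t)


def conc_onecomp_abs(params: PKParameters, dose: DoseRegimen, times) -> np.ndarray:
    """One-compartment first-order absorption concentration.

    Uses the Bateman function; near the flip-flop degeneracy ``Ka -> ke``
    the analytic limit ``(Dose/V) Ka t exp(-Ka t)`` is evaluated instead.
    """
    params.validate_for(ModelKind.ONECOMP_ABS)
    _check_route(dose, "oral")
    t = _check_times(times)
    ke = params.cl / params.v
    ka = params.ka
    if abs(ka - ke) / ke < FLIP_FLOP_GUARD:
        return (dose.amount / params.v) * ka * t * np.exp(-ka * t)
    coef = dose.amount * ka / (params.v * (ka - ke))
    return coef * (np.exp(-ke * t) - np.exp(-ka * t))


def twocomp_coefficients(params: PKParameters, dose: DoseRegimen) -> TwoCompCoefficients:
    """Hybrid rate constants and IV-bolus amplitudes for the two-compartment
    model.

    ``alpha, beta`` are the roots of ``s^2 - (k10+k12+k21) s + k10 k21``;
    the amplitudes are the standard IV-bolus forms, uniquely determined by
    ``C(0) = Dose/V1`` and the eigen-decomposition of the disposition matrix.
    A repeated root is handled by a guarded nudge rather than failure.
    """
    params.validate_for(ModelKind.TWOCOMP)
    k10 = params.cl / params.v
    k12 = params.q / params.v
    k21 = params.q / params.v2
    s = k10 + k12 + k21
    disc = s * s - 4.0 * k10 * k21
    root = np.sqrt(max(disc, 0.0))
    alpha = 0.5 * (s + root)
    beta = 0.5 * (s - root)
    if alpha - beta < 1e-12 * alpha:
        # repeated-root guard: split the eigenvalues by a relative nudge far
        # below the ODE/fitting tolerances
        eps = 1e-9 * alpha
        alpha, beta = alpha + eps, beta - eps
    c0 = dose.amount / params.v
    a_coef = c0 * (alpha - k21) / (alpha - beta)
    b_coef = c0 * (k21 - beta) / (alpha - beta)
    return TwoCompCoefficients(alpha, beta, a_coef, b_coef, k10, k12, k21)


def conc_twocomp_iv(params: PKParameters, dose: DoseRegimen, times) -> np.ndarray:
    """Two-compartment IV bolus concentration (analytic biexponential)."""
    _check_route(dose, "iv_bolus")
    t = _check_times(times)
    co = twocomp_coefficients(params, dose)
    return co.a_coef * np.exp(-co.alpha * t) + co.b_coef * np.exp(-co.beta * t)


def _twocomp_abs_rhs(t, y, ka, k10, k12, k21):
    agut, ac, ap = y
    return (
        -ka * agut,
        ka * agut - (k10 + k12) * ac + k21 * ap,
        k12 * ac - k21 * ap,
    )


def conc_twocomp_abs(params: PKParameters, dose: DoseRegimen, times) -> np.ndarray:
    """Two-compartment first-order absorption concentration via stiff-capable
    numerical integration of the mass-balance system

    .. math::

        dA_g/dt = -Ka A_g,\\quad
        dA_c/dt = Ka A_g - (k10+k12) A_c + k21 A_p,\\quad
        dA_p/dt = k12 A_c - k21 A_p,

    with ``C = A_c / V1``.
    """
    params.validate_for(ModelKind.TWOCOMP_ABS)
    _check_route(dose, "oral")
    t = _check_times(times)
    k10 = params.cl / params.v
    k12 = params.q / params.v
    k21 = params.q / params.v2
    order = np.argsort(t, kind="stable")
    t_sorted = t[order]
    t_end = max(t_sorted[-1], 1e-6)
    sol = solve_ivp(
        _twocomp_abs_rhs,
        (0.0, t_end),
        (dose.amount, 0.0, 0.0),
        method="LSODA",
        t_eval=t_sorted,
        args=(params.ka, k10, k12, k21),
        rtol=ODE_RTOL,
        atol=ODE_ATOL,
    )
    if not sol.success:
        raise EstimationFailureError(
            f"ODE integration failed for twocomp_abs: {sol.message}"
        )
    conc_sorted = sol.y[1] / params.v
    conc = np.empty_like(conc_sorted)
    conc[order] = np.clip(conc_sorted, 0.0, None)
    return conc


def _twocomp_abs_closed_form(params: PKParameters, dose: DoseRegimen, times) -> np.ndarray:
    """Closed-form triexponential solution of the two-compartment absorption
    model (identical to :func:`conc_twocomp_abs` to within ODE tolerance; used
    by the estimation and simulation layers for speed).

    Falls back to the ODE route when ``ka`` nearly coincides with ``alpha`` or
    ``beta`` (degenerate exponents).
    """
    params.validate_for(ModelKind.TWOCOMP_ABS)
    _check_route(dose, "oral")
    t = _check_times(times)
    return _fast_twocomp_abs(
        params.to_array(ModelKind.TWOCOMP_ABS), dose.amount, t
    )


_DISPATCH = {
    ModelKind.ONECOMP: conc_onecomp_iv,
    ModelKind.ONECOMP_ABS: conc_onecomp_abs,
    ModelKind.TWOCOMP: conc_twocomp_iv,
    ModelKind.TWOCOMP_ABS: _twocomp_abs_closed_form,
}


# -- raw-array fast paths ---------------------------------------------------
# Used inside optimisation loops where dataclass construction/validation per
# evaluation would dominate the cost.  Each takes (theta, dose_amount, times)
# with theta ordered as ModelKind.parameter_names and already positive, and
# must agree with the public functions above (tested).


def _fast_onecomp_iv(theta, dose, t):
    cl, v = theta
    return (dose / v) * np.exp(-(cl / v) * t)


def _fast_onecomp_abs(theta, dose, t):
    cl, v, ka = theta
    ke = cl / v
    if abs(ka - ke) / ke < FLIP_FLOP_GUARD:
        return (dose / v) * ka * t * np.exp(-ka * t)
    return dose * ka / (v * (ka - ke)) * (np.exp(-ke * t) - np.exp(-ka * t))


def _hybrid_constants(cl, v, v2, q):
    k10 = cl / v
    k21 = q / v2
    s = k10 + q / v + k21
    root = np.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (s + root)
    beta = 0.5 * (s - root)
    if alpha - beta < 1e-12 * alpha:
        eps = 1e-9 * alpha
        alpha, beta = alpha + eps, beta - eps
    return alpha, beta, k21


def _fast_twocomp_iv(theta, dose, t):
    cl, v, v2, q = theta
    alpha, beta, k21 = _hybrid_constants(cl, v, v2, q)
    c0 = dose / v
    a = c0 * (alpha - k21) / (alpha - beta)
    b = c0 * (k21 - beta) / (alpha - beta)
    return a * np.exp(-alpha * t) + b * np.exp(-beta * t)


def _fast_twocomp_abs(theta, dose, t):
    cl, v, v2, q, ka = theta
    alpha, beta, k21 = _hybrid_constants(cl, v, v2, q)
    if min(abs(ka - alpha), abs(ka - beta)) / ka < 1e-9:
        params = PKParameters(cl=cl, v=v, v2=v2, q=q, ka=ka)
        return conc_twocomp_abs(params, DoseRegimen(dose, "oral"), t)
    scale = ka * dose / v
    ca = (k21 - alpha) / ((ka - alpha) * (beta - alpha))
    cb = (k21 - beta) / ((ka - beta) * (alpha - beta))
    ck = (k21 - ka) / ((alpha - ka) * (beta - ka))
    conc = scale * (
        ca * np.exp(-alpha * t) + cb * np.exp(-beta * t) + ck * np.exp(-ka * t)
    )
    # roundoff near t=0 can produce tiny negatives
    return np.maximum(conc, 0.0)


FAST_DISPATCH = {
    ModelKind.ONECOMP: _fast_onecomp_iv,
    ModelKind.ONECOMP_ABS: _fast_onecomp_abs,
    ModelKind.TWOCOMP: _fast_twocomp_iv,
    ModelKind.TWOCOMP_ABS: _fast_twocomp_abs,
}


def predict_conc(
    params: PKParameters, dose: DoseRegimen, times, kind: ModelKind
) -> np.ndarray:
    """Model-dispatch concentration prediction used throughout the package.

    For ``twocomp_abs`` the closed-form triexponential is used (ODE fallback
    near degeneracy); all other kinds use their analytic solutions.
    """
    return _DISPATCH[ModelKind(kind)](params, dose, times)
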