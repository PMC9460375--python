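"""Closed-form solutions of the three-phase body-mass kinetic model.

Body mass is treated as the sum of three concurrent first-order processes:

* a **catabolic** phase — exponential decay of the pre-existing ("old")
  body mass, ``M_old(t) = M_i * exp(-k_v t)``;
* an **anabolic** phase — saturating build-up of "new" mass toward the
  final body mass, ``M_new(t) = M_f * (1 - exp(-k_n t))``;
* a **redistributive** phase — a transient exchange of mass between the
  old and new compartments with first-order elimination, whose total is a
  biexponential bump that vanishes at both time extremes.

All rate constants are in h^-1 and all masses in kg. Time is in hours
throughout this module; file I/O elsewhere converts from days at 24 h/day.

The composite solving equation, evaluated by :func:`composite_mass`, is

    M_c(t) = M_i e^{-k_mi t} + M_f (1 - e^{-k_mf t})
             + (M_i + M_f)(e^{-alpha t} - e^{-beta t})

where ``k_mi``/``k_mf`` are the initial/final metabolic rate constants and
``alpha <= beta`` are the two real positive roots of the redistributive
characteristic quadratic. The metabolic rate constant is inferred from
daily food mass ``M_a`` and body mass ``M_c`` as

    k_m = -(1/24) ln[(M_c - M_a) / M_c].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RedistributiveRates",
    "CompositeParams",
    "RedistributiveState",
    "catabolic_mass",
    "anabolic_mass",
    "roots_alpha_beta",
    "redistributive_state_exact",
    "redistributive_mass_approx",
    "composite_mass",
    "metabolic_constant",
    "food_mass_from_constant",
    "CONSISTENCY_TOL",
    "DEGENERATE_ROOT_TOL",
]

#: Tolerance on the consistency constraint |(k_v - k_vn) - (k_n - k_nv)|.
CONSISTENCY_TOL = 1e-9

#: Below this |beta - alpha| the biexponential forms are degenerate.
DEGENERATE_ROOT_TOL = 1e-12


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class RedistributiveRates:
    """Transfer constants of the two-compartment redistributive system.

    The old compartment V loses mass at rate ``k_v`` (transfer to N at
    ``k_vn`` plus elimination), the new compartment N loses mass at
    ``k_n`` (transfer to V at ``k_nv`` plus elimination). Both
    compartments share the elimination constant
    ``k_e = k_v - k_vn = k_n - k_nv > 0``, and
    ``K = k_v + k_nv = k_n + k_vn`` is the composite transfer constant.
    Under these constraints the characteristic quadratic
    ``(s + k_v)(s + k_n) - k_nv k_vn`` factors exactly as
    ``(s + k_e)(s + K)``, so the slow root equals ``k_e`` and the fast
    root equals ``K``.

    Parameters
    ----------
    k_v, k_n : float
        Total loss rates of the old and new compartments (h^-1), > 0.
    k_vn, k_nv : float
        Transfer rates old->new and new->old (h^-1), > 0.
    """

    k_v: float
    k_n: float
    k_vn: float
    k_nv: float

    def __post_init__(self) -> None:
        for name in ("k_v", "k_n", "k_vn", "k_nv"):
            _require(getattr(self, name) > 0.0, f"{name} must be > 0")
        gap = (self.k_v - self.k_vn) - (self.k_n - self.k_nv)
        _require(
            abs(gap) <= CONSISTENCY_TOL,
            "inconsistent rates: require k_v - k_vn = k_n - k_nv "
            f"(difference {gap:.3e} h^-1 exceeds tolerance {CONSISTENCY_TOL})",
        )
        _require(self.k_v - self.k_vn > 0.0, "elimination rate k_e = k_v - k_vn must be > 0")

    @property
    def k_e(self) -> float:
        """Elimination rate constant k_v - k_vn (= k_n - k_nv), h^-1."""
        return self.k_v - self.k_vn

    @property
    def K(self) -> float:
        """Composite constant k_v + k_nv (= k_n + k_vn), h^-1."""
        return self.k_v + self.k_nv

    @property
    def alpha(self) -> float:
        """Slow characteristic root (h^-1)."""
        return roots_alpha_beta(self)[0]

    @property
    def beta(self) -> float:
        """Fast characteristic root (h^-1)."""
        return roots_alpha_beta(self)[1]


@dataclass(frozen=True)
class CompositeParams:
    """Everything needed to evaluate the composite solving equation.

    ``M_i`` is the body mass at the start of the observations, ``M_f``
    the final body mass, ``k_mi``/``k_mf`` the initial/final metabolic
    rate constants and ``alpha <= beta`` the distributive constants.
    ``k_mi`` and ``k_mf`` may be zero (zero daily food mass yields a zero
    metabolic constant); the distributive roots must be strictly positive.
    """

    M_i: float
    M_f: float
    k_mi: float
    k_mf: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        _require(self.M_i > 0.0, "M_i must be > 0")
        _require(self.M_f > 0.0, "M_f must be > 0")
        _require(self.k_mi >= 0.0, "k_mi must be >= 0")
        _require(self.k_mf >= 0.0, "k_mf must be >= 0")
        _require(self.alpha > 0.0, "alpha must be > 0")
        _require(self.beta > 0.0, "beta must be > 0")
        _require(self.alpha <= self.beta, "require alpha <= beta")


@dataclass(frozen=True)
class RedistributiveState:
    """Compartment masses at one instant of the redistributive transient."""

    V: float
    N: float
    M: float
    t: float

    def __post_init__(self) -> None:
        _require(self.V >= 0.0 and self.N >= 0.0, "compartment masses must be >= 0")


def _check_time(t) -> np.ndarray | float:
    t_arr = np.asarray(t, dtype=float)
    _require(bool(np.all(t_arr >= 0.0)), "time must be >= 0")
    return t_arr


def catabolic_mass(M_i: float, k_v: float, t):
    """Old-compartment mass M_i * exp(-k_v t) at time ``t`` (hours).

    Strictly decreasing in t, from M_i at t = 0 toward 0.
    Accepts a scalar or array ``t``.
    """
    _require(M_i > 0.0, "M_i must be > 0")
    _require(k_v > 0.0, "k_v must be > 0")
    t_arr = _check_time(t)
    out = M_i * np.exp(-k_v * t_arr)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def anabolic_mass(M_f: float, k_n: float, t):
    """New-compartment mass M_f * (1 - exp(-k_n t)) at time ``t`` (hours).

    Strictly increasing in t, from 0 at t = 0 toward the plateau M_f.
    """
    _require(M_f > 0.0, "M_f must be > 0")
    _require(k_n > 0.0, "k_n must be > 0")
    t_arr = _check_time(t)
    out = M_f * -np.expm1(-k_n * t_arr)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def roots_alpha_beta(rates: RedistributiveRates) -> tuple[float, float]:
    """Roots (alpha, beta) of the redistributive characteristic quadratic.

    Solves s^2 + (k_v + k_n) s + (k_v k_n - k_nv k_vn) = 0 and returns the
    magnitudes of its two (negative) roots sorted so alpha <= beta. Under
    the consistency constraint the factorisation is exact:
    alpha = k_e and beta = K.
    """
    b = rates.k_v + rates.k_n
    c = rates.k_v * rates.k_n - rates.k_nv * rates.k_vn
    disc = (rates.k_v - rates.k_n) ** 2 + 4.0 * rates.k_nv * rates.k_vn
    # disc > 0 always; c > 0 under the consistency constraint (c = k_e * K)
    beta = 0.5 * (b + math.sqrt(disc))
    alpha = c / beta  # Vieta: numerically stable small root
    return (alpha, beta) if alpha <= beta else (beta, alpha)


def _exact_tracks(V_x: float, N_x: float, rates: RedistributiveRates, t):
    """Vectorised exact V(t), N(t) from the partial-fraction solution."""
    alpha, beta = roots_alpha_beta(rates)
    _require(
        abs(beta - alpha) > DEGENERATE_ROOT_TOL,
        "degenerate roots: the partial-fraction solution divides by (beta - alpha)",
    )
    t_arr = np.asarray(t, dtype=float)
    ea = np.exp(-alpha * t_arr)
    eb = np.exp(-beta * t_arr)
    d = beta - alpha
    # V(t) = [V_x(k_n - a) + N_x k_nv] e^{-at}/d - [V_x(k_n - b) + N_x k_nv] e^{-bt}/d
    V = ((V_x * (rates.k_n - alpha) + N_x * rates.k_nv) * ea
         - (V_x * (rates.k_n - beta) + N_x * rates.k_nv) * eb) / d
    N = ((N_x * (rates.k_v - alpha) + V_x * rates.k_vn) * ea
         - (N_x * (rates.k_v - beta) + V_x * rates.k_vn) * eb) / d
    return V, N


def redistributive_state_exact(
    V_x: float, N_x: float, rates: RedistributiveRates, t: float
) -> RedistributiveState:
    """Exact two-compartment state during the redistributive transient.

    Evaluates the biexponential partial-fraction solution of

        dV/dt = -k_v V + k_nv N,    dN/dt = -k_n N + k_vn V

    with initial state (V_x, N_x). The total M = V + N decays as
    (V_x + N_x) e^{-k_e t} because dM/dt = -k_e M.

    Raises
    ------
    ValueError
        If the roots are degenerate (|beta - alpha| below tolerance) —
        the printed partial fractions divide by (beta - alpha).
    """
    _require(V_x >= 0.0 and N_x >= 0.0, "initial compartment masses must be >= 0")
    t_arr = _check_time(t)
    _require(t_arr.ndim == 0, "t must be a scalar; use _exact_tracks for grids")
    V, N = _exact_tracks(V_x, N_x, rates, float(t_arr))
    return RedistributiveState(V=float(V), N=float(N), M=float(V + N), t=float(t_arr))


def redistributive_mass_approx(M_i: float, M_f: float, alpha: float, beta: float, t):
    """Approximate redistributive term (M_i + M_f)(e^{-alpha t} - e^{-beta t}).

    Non-negative for alpha <= beta, zero at t = 0 and as t -> inf, with a
    unique maximum at t* = ln(beta/alpha)/(beta - alpha). When the roots
    coincide within tolerance the analytic limit
    (M_i + M_f) * t * (beta - alpha) * e^{-alpha t} (-> 0 as beta -> alpha)
    is returned instead of the 0/0 form.
    """
    _require(M_i > 0.0 and M_f > 0.0, "M_i and M_f must be > 0")
    _require(alpha > 0.0, "alpha must be > 0")
    _require(alpha <= beta, "require alpha <= beta")
    t_arr = _check_time(t)
    amp = M_i + M_f
    if beta - alpha < DEGENERATE_ROOT_TOL:
        out = amp * t_arr * (beta - alpha) * np.exp(-alpha * t_arr)
    else:
        out = amp * (np.exp(-alpha * t_arr) - np.exp(-beta * t_arr))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def composite_mass(params: CompositeParams, t):
    """Composite predicted body mass M_c(t), the sum of the three phases.

    M_c(0) = M_i exactly and M_c(t) -> M_f as t -> inf. Accepts a scalar
    or array ``t`` in hours.
    """
    t_arr = _check_time(t)
    cat = params.M_i * np.exp(-params.k_mi * t_arr)
    ana = params.M_f * -np.expm1(-params.k_mf * t_arr)
    red = redistributive_mass_approx(params.M_i, params.M_f, params.alpha, params.beta, t_arr)
    out = cat + ana + red
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def metabolic_constant(M_c: float, M_a: float) -> float:
    """Hourly metabolic rate constant from body mass and daily food mass.

    k_m = -(1/24) ln[(M_c - M_a) / M_c], with body mass M_c (kg) and
    daily food mass M_a (kg). Zero food gives k_m = 0; the constant grows
    without bound as the food mass approaches the body mass.
    """
    _require(M_c > 0.0, "body mass M_c must be > 0")
    _require(M_a >= 0.0, "food mass M_a must be >= 0")
    _require(M_a < M_c, "food mass must be smaller than body mass (log argument > 0)")
    return -math.log((M_c - M_a) / M_c) / 24.0


def food_mass_from_constant(M_c: float, k_m: float) -> float:
    """Daily food mass consistent with a metabolic constant: the exact
    algebraic inverse of :func:`metabolic_constant` at fixed body mass.

    M_a = M_c (1 - e^{-24 k_m}).
    """
    _require(M_c > 0.0, "body mass M_c must be > 0")
    _require(k_m >= 0.0, "k_m must be >= 0")
    return M_c * -math.expm1(-24.0 * k_m)
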