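"""Per-patient fitting of the composite body-mass equation.

The composite curve is fitted to one subject's longitudinal (time, mass)
record by bounded nonlinear least squares on log-parameterised rates, with
a deterministic multistart grid. Fit quality is summarised by the study's
statistics: deviance Dev = sum (Y_obs - Y_exp)^2, degrees of freedom DF,
and variance Var = Dev / DF.

Two estimation modes are supported. In *paper* mode the endpoint masses
and metabolic constants are measured, not fitted: M_i is the first
observed mass, k_mi and k_mf come from the printed k_m formula applied at
the first and last control visit, M_f is the last observed mass (or a
free parameter, see ``FitConfig.m_f_source``), and only the distributive
roots (alpha, beta) are optimised. In *free* mode k_mi, k_mf, alpha and
beta are all optimised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .model import (
    CompositeParams,
    composite_mass,
    metabolic_constant,
)

__all__ = [
    "PatientSeries",
    "FitConfig",
    "PatientFit",
    "predict_series",
    "deviance",
    "variance_of_fit",
    "degrees_of_freedom",
    "paper_mode_constants",
    "per_visit_metabolic_constants",
    "fit_patient",
]

# Hourly rate bounds for the optimiser: 1e-8 h^-1 is ~ no change over a
# decade; 1.0 h^-1 equilibrates within hours, far below visit spacing.
_RATE_LO = 1e-8
_RATE_HI = 1.0


@dataclass(frozen=True)
class PatientSeries:
    """One subject's longitudinal record.

    ``times`` are hours since the first visit (times[0] == 0, strictly
    increasing), ``masses`` the observed body masses (kg) and
    ``food_mass`` the daily diet mass (kg/day) reported at each visit.
    At least four (time, mass) pairs are required — a curvilinear trend
    cannot be checked with fewer points.
    """

    patient_id: str
    times: np.ndarray
    masses: np.ndarray
    food_mass: np.ndarray
    sex: str = ""
    age: float = float("nan")
    height: float | None = None
    group: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        m = np.asarray(self.masses, dtype=float)
        f = np.asarray(self.food_mass, dtype=float)
        if t.ndim != 1 or t.size < 4:
            raise ValueError(
                f"patient {self.patient_id!r}: at least 4 (time, mass) pairs required, got {t.size}"
            )
        if m.shape != t.shape or f.shape != t.shape:
            raise ValueError(f"patient {self.patient_id!r}: times/masses/food_mass lengths differ")
        if t[0] != 0.0:
            raise ValueError(f"patient {self.patient_id!r}: first visit time must be 0")
        if not np.all(np.diff(t) > 0.0):
            raise ValueError(f"patient {self.patient_id!r}: visit times must be strictly increasing")
        if not np.all(m > 0.0):
            raise ValueError(f"patient {self.patient_id!r}: body masses must be > 0")
        if not np.all(f >= 0.0):
            raise ValueError(f"patient {self.patient_id!r}: food masses must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "masses", m)
        object.__setattr__(self, "food_mass", f)

    @property
    def n_visits(self) -> int:
        return int(self.times.size)

    @property
    def bmi_initial(self) -> float | None:
        if self.height is None or not self.height > 0.0:
            return None
        return float(self.masses[0] / self.height**2)


@dataclass(frozen=True)
class FitConfig:
    """Estimation settings.

    ``mode`` selects which parameters are optimised ('paper': alpha, beta
    only; 'free': also k_mi, k_mf). ``m_f_source`` selects whether M_f is
    pinned to the last observed mass or estimated ('free_parameter', the
    default): M_f is the asymptotic diet-target mass, which the last
    control visit has not reached while the redistributive transient is
    still live, so pinning it to the final observation biases the fit.
    ``df_convention`` is 'pairs' (DF = number of observation pairs, the
    convention behind the 240-DF congruity arithmetic) or
    'pairs_minus_params'. ``multistart`` caps the deterministic grid of
    initial rates; ``seed`` only matters for downstream reproducibility
    bookkeeping — the optimiser itself is deterministic.
    """

    mode: str = "paper"
    m_f_source: str = "free_parameter"
    df_convention: str = "pairs"
    max_iterations: int = 200
    rate_bounds: tuple[float, float] = (_RATE_LO, _RATE_HI)
    multistart: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("paper", "free"):
            raise ValueError("mode must be 'paper' or 'free'")
        if self.m_f_source not in ("last_observation", "free_parameter"):
            raise ValueError("m_f_source must be 'last_observation' or 'free_parameter'")
        if self.df_convention not in ("pairs", "pairs_minus_params"):
            raise ValueError("df_convention must be 'pairs' or 'pairs_minus_params'")
        if not (0 < self.rate_bounds[0] < self.rate_bounds[1]):
            raise ValueError("rate bounds must be positive and ordered")
        if self.multistart < 1:
            raise ValueError("multistart must be >= 1")


@dataclass(frozen=True)
class PatientFit:
    """Fitted parameters and diagnostics for one patient."""

    patient_id: str
    group: str
    params: CompositeParams
    deviance: float
    df: int
    variance: float
    n_obs: int
    converged: bool
    expected: np.ndarray
    n_fitted: int
    degenerate: bool = False
    k_m_per_visit: np.ndarray = field(default_factory=lambda: np.array([]))


def predict_series(params: CompositeParams, times) -> np.ndarray:
    """Composite body mass evaluated at each time (hours)."""
    t = np.asarray(times, dtype=float)
    return np.asarray(composite_mass(params, t), dtype=float).reshape(t.shape)


def deviance(observed, expected) -> float:
    """Sum of squared observed-minus-expected differences (kg^2)."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape or obs.size == 0:
        raise ValueError("observed and expected must be non-empty and equal length")
    return float(np.sum((obs - exp) ** 2))


def variance_of_fit(dev: float, df: int) -> float:
    """Variance Var = Dev / DF (kg^2)."""
    if dev < 0.0:
        raise ValueError("deviance must be >= 0")
    if df <= 0:
        raise ValueError("degrees of freedom must be > 0")
    return dev / df


def degrees_of_freedom(n_pairs: int, n_fitted: int, convention: str = "pairs") -> int:
    """DF under the 'pairs' convention (DF = number of observed-expected
    pairs) or the standard 'pairs_minus_params' alternative."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if n_fitted < 0:
        raise ValueError("n_fitted must be >= 0")
    if convention == "pairs":
        return n_pairs
    if convention == "pairs_minus_params":
        df = n_pairs - n_fitted
        if df <= 0:
            raise ValueError("pairs_minus_params requires n_pairs > n_fitted")
        return df
    raise ValueError(f"unknown DF convention: {convention!r}")


def paper_mode_constants(series: PatientSeries) -> tuple[float, float]:
    """Initial and final metabolic constants from the endpoint visits.

    k_mi is computed from the first observed mass and the food mass
    reported at the first visit; k_mf from the last visit's pair.
    """
    k_mi = metabolic_constant(float(series.masses[0]), float(series.food_mass[0]))
    k_mf = metabolic_constant(float(series.masses[-1]), float(series.food_mass[-1]))
    return k_mi, k_mf


def per_visit_metabolic_constants(series: PatientSeries) -> np.ndarray:
    """Diagnostic k_m sequence: the metabolic constant at every control
    visit (NaN where the food mass is not below the body mass)."""
    out = np.full(series.n_visits, np.nan)
    for i, (m, a) in enumerate(zip(series.masses, series.food_mass)):
        if 0.0 <= a < m:
            out[i] = metabolic_constant(float(m), float(a))
    return out


def _start_grid(T: float, n: int) -> list[tuple[float, float]]:
    """Deterministic multistart grid of (alpha, beta) spanning time scales
    from 0.1/T to 10/T with root ratios 1.5, 3 and 6."""
    alphas = np.geomspace(0.1 / T, 10.0 / T, 4)
    ratios = (1.5, 3.0, 6.0)
    grid = [(float(a), float(a * r)) for a in alphas for r in ratios]
    return grid[:n]


def _clip_rate(x: float, lo: float, hi: float) -> float:
    return min(max(x, lo), hi)


def fit_patient(series: PatientSeries, config: FitConfig | None = None) -> PatientFit:
    """Fit the composite equation to one patient's record.

    Rates are optimised on the log scale with the ordering alpha <= beta
    enforced by parameterising (log alpha, log(beta - alpha)); each start
    of a deterministic multistart grid is solved with bounded least
    squares, and the candidate with the smallest deviance wins (ties:
    smallest alpha, then smallest beta). A fit is flagged ``degenerate``
    when the observed masses are constant, in which case the deviance is
    insensitive to the distributive roots.
    """
    config = config or FitConfig()
    t = series.times
    obs = series.masses
    T = float(t[-1])
    lo, hi = config.rate_bounds
    log_lo, log_hi = math.log(lo), math.log(hi)

    M_i = float(obs[0])
    k_mi, k_mf = paper_mode_constants(series)
    free_mf = config.m_f_source == "free_parameter"
    M_f_pinned = float(obs[-1])

    # parameter vector layout: [log a, log(b - a)] (+ [log kmi, log kmf] in
    # free mode) (+ [log M_f] when M_f is free)
    free_k = config.mode == "free"
    n_fitted = 2 + (2 if free_k else 0) + (1 if free_mf else 0)

    def unpack(theta: np.ndarray) -> CompositeParams:
        a = math.exp(theta[0])
        b = a + math.exp(theta[1])
        i = 2
        if free_k:
            kmi, kmf = math.exp(theta[2]), math.exp(theta[3])
            i = 4
        else:
            kmi, kmf = k_mi, k_mf
        mf = math.exp(theta[i]) if free_mf else M_f_pinned
        return CompositeParams(M_i=M_i, M_f=mf, k_mi=kmi, k_mf=kmf, alpha=a, beta=min(b, 2 * _RATE_HI))

    def residuals(theta: np.ndarray) -> np.ndarray:
        return predict_series(unpack(theta), t) - obs

    lower = [log_lo, math.log(lo * 1e-3)]
    upper = [log_hi, math.log(hi)]
    if free_k:
        lower += [log_lo] * 2
        upper += [log_hi] * 2
    if free_mf:
        lower += [math.log(0.1)]
        upper += [math.log(1000.0)]

    candidates = []
    for a0, b0 in _start_grid(T, config.multistart):
        a0 = _clip_rate(a0, lo, hi)
        gap0 = max(b0 - a0, lo * 1e-2)
        theta0 = [math.log(a0), math.log(gap0)]
        if free_k:
            theta0 += [math.log(_clip_rate(max(k_mi, lo), lo, hi)),
                       math.log(_clip_rate(max(k_mf, lo), lo, hi))]
        if free_mf:
            theta0 += [math.log(M_f_pinned)]
        theta0 = np.clip(theta0, lower, upper)
        res = least_squares(
            residuals,
            theta0,
            bounds=(lower, upper),
            max_nfev=config.max_iterations * len(theta0),
        )
        p = unpack(res.x)
        candidates.append((float(np.sum(res.fun**2)), p.alpha, p.beta, p, bool(res.success)))

    dev_best, _, _, params, success = min(candidates, key=lambda c: (c[0], c[1], c[2]))
    expected = predict_series(params, t)
    dev = deviance(obs, expected)
    df = degrees_of_freedom(series.n_visits, n_fitted, config.df_convention)
    return PatientFit(
        patient_id=series.patient_id,
        group=series.group,
        params=params,
        deviance=dev,
        df=df,
        variance=variance_of_fit(dev, df),
        n_obs=series.n_visits,
        converged=success,
        expected=expected,
        n_fitted=n_fitted,
        degenerate=bool(np.ptp(obs) == 0.0),
        k_m_per_visit=per_visit_metabolic_constants(series),
    )
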