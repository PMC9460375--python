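"""Cohort and fit-report CSV formats.

Cohort files are long format, one row per control visit, with times in
days since the first visit (converted to hours internally at 24 h/day)
and masses serialised at the 0.1 kg balance resolution. Fit reports carry
one row per patient at full precision.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .fitting import PatientFit, PatientSeries
from .synthetic import TrueParams

__all__ = [
    "COHORT_COLUMNS",
    "REPORT_COLUMNS",
    "CohortFormatError",
    "read_cohort",
    "write_cohort",
    "write_fit_report",
    "read_fit_report",
    "write_truth",
]

COHORT_COLUMNS = [
    "patient_id",
    "group",
    "sex",
    "age_years",
    "height_m",
    "visit_index",
    "time_days",
    "body_mass_kg",
    "food_mass_kg_per_day",
]

REPORT_COLUMNS = [
    "patient_id",
    "group",
    "sex",
    "age_years",
    "M_i_kg",
    "bmi",
    "k_mi_per_h",
    "M_f_kg",
    "k_mf_per_h",
    "alpha_per_h",
    "beta_per_h",
    "n_visits",
    "deviance_kg2",
    "df",
    "variance_kg2",
    "converged",
]


class CohortFormatError(ValueError):
    """Raised when a cohort file violates the format contract."""


def write_cohort(series: Iterable[PatientSeries], path: str | Path) -> None:
    """Write a cohort CSV, one row per visit, masses at 0.1 kg precision."""
    rows = []
    for s in series:
        for j in range(s.n_visits):
            rows.append(
                {
                    "patient_id": s.patient_id,
                    "group": s.group,
                    "sex": s.sex,
                    "age_years": s.age,
                    "height_m": "" if s.height is None else f"{s.height:.3f}",
                    "visit_index": j,
                    "time_days": f"{s.times[j] / 24.0:g}",
                    "body_mass_kg": f"{s.masses[j]:.1f}",
                    "food_mass_kg_per_day": f"{s.food_mass[j]:.4f}",
                }
            )
    if not rows:
        raise ValueError("no patients to write")
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)


def read_cohort(path: str | Path) -> list[PatientSeries]:
    """Read and validate a cohort CSV into per-patient series.

    Violations (missing columns, fewer than four visits, non-numeric or
    non-positive masses, non-increasing times) raise
    :class:`CohortFormatError` naming the offending patient or row.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise CohortFormatError(f"{path}: empty file") from exc
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing columns {missing}")
    if df.empty:
        raise CohortFormatError(f"{path}: no data rows")
    for col in ("time_days", "body_mass_kg", "food_mass_kg_per_day"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise CohortFormatError(
                f"{path}: non-numeric {col} at data row {int(bad[0]) + 2}"
            )
        df[col] = coerced
    out: list[PatientSeries] = []
    for pid, g in df.groupby("patient_id", sort=False):
        g = g.sort_values("visit_index")
        idx = g["visit_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(g))):
            raise CohortFormatError(
                f"{path}: patient {pid!r}: visit_index must be contiguous from 0"
            )
        height = g["height_m"].iloc[0]
        height = None if pd.isna(height) else float(height)
        try:
            out.append(
                PatientSeries(
                    patient_id=str(pid),
                    times=g["time_days"].to_numpy(dtype=float) * 24.0,
                    masses=g["body_mass_kg"].to_numpy(dtype=float),
                    food_mass=g["food_mass_kg_per_day"].to_numpy(dtype=float),
                    sex=str(g["sex"].iloc[0]),
                    age=float(g["age_years"].iloc[0]),
                    height=height,
                    group=str(g["group"].iloc[0]),
                )
            )
        except ValueError as exc:
            raise CohortFormatError(f"{path}: {exc}") from exc
    return out


def write_fit_report(fits: Sequence[PatientFit], path: str | Path,
                     heights: dict[str, float] | None = None,
                     demographics: dict[str, tuple[str, float]] | None = None) -> None:
    """Write one full-precision row per patient, ordered by patient id.

    ``heights`` (id -> m) enables the BMI column; ``demographics``
    (id -> (sex, age)) fills the corresponding columns when the fits were
    produced away from their source series.
    """
    if not fits:
        raise ValueError("at least one fit is required")
    heights = heights or {}
    demographics = demographics or {}
    rows = []
    for f in sorted(fits, key=lambda f: f.patient_id):
        h = heights.get(f.patient_id)
        sex, age = demographics.get(f.patient_id, ("", float("nan")))
        p = f.params
        rows.append(
            {
                "patient_id": f.patient_id,
                "group": f.group,
                "sex": sex,
                "age_years": age,
                "M_i_kg": p.M_i,
                "bmi": p.M_i / h**2 if h else "",
                "k_mi_per_h": p.k_mi,
                "M_f_kg": p.M_f,
                "k_mf_per_h": p.k_mf,
                "alpha_per_h": p.alpha,
                "beta_per_h": p.beta,
                "n_visits": f.n_obs,
                "deviance_kg2": f.deviance,
                "df": f.df,
                "variance_kg2": f.variance,
                "converged": f.converged,
            }
        )
    pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(path, index=False)


def read_fit_report(path: str | Path) -> pd.DataFrame:
    """Load a fit report as a DataFrame (columns as written)."""
    df = pd.read_csv(path)
    missing = [c for c in ("patient_id", "group", "df", "variance_kg2", "deviance_kg2", "n_visits")
               if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing fit-report columns {missing}")
    return df


def write_truth(truths: Sequence[TrueParams], path: str | Path) -> None:
    """Write ground-truth parameters of a simulated cohort."""
    rows = [
        {
            "patient_id": t.patient_id,
            "group": t.group,
            "sex": t.sex,
            "age_years": t.age,
            "height_m": t.height,
            "M_i_kg": t.params.M_i,
            "M_f_kg": t.params.M_f,
            "k_mi_per_h": t.params.k_mi,
            "k_mf_per_h": t.params.k_mf,
            "alpha_per_h": t.params.alpha,
            "beta_per_h": t.params.beta,
        }
        for t in truths
    ]
    if not rows:
        raise ValueError("no truths to write")
    pd.DataFrame(rows).to_csv(path, index=False)
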