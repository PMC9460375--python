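"""Cohort-level variance analysis.

Per-patient fits are pooled into pathophysiology-group summaries. A group
mean variance below 1 kg^2 validates the model for that group, provided
the pooled degrees of freedom reach the congruity threshold of 240
observed-expected pairs; below that threshold the verdict is
*indeterminate* — too little data to question or confirm the model —
rather than a failure.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .fitting import PatientFit

__all__ = [
    "Validity",
    "GroupSummary",
    "cohort_variance_table",
    "congruity_check",
    "model_validity",
    "CONGRUITY_DF",
    "VALIDITY_THRESHOLD",
]

#: Minimum pooled degrees of freedom for the variance analysis to be congruous.
CONGRUITY_DF = 240

#: A mean variance below this (kg^2) validates the model at congruous DF.
VALIDITY_THRESHOLD = 1.0


class Validity(Enum):
    VALID = "valid"
    INVALID = "invalid"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class GroupSummary:
    """Pooled fit statistics for one pathophysiology group.

    ``mean_variance`` is the unweighted arithmetic mean of per-patient
    variances; ``pooled_variance`` is the DF-weighted alternative
    Dev_total / DF_total. ``validity`` applies the variance threshold
    gated on the congruity DF; ``valid`` is the plain threshold flag.
    """

    group: str
    n_patients: int
    total_pairs: int
    pooled_df: int
    mean_variance: float
    pooled_variance: float
    valid: bool
    validity: Validity

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.mean_variance < 0.0:
            raise ValueError("mean_variance must be >= 0")


def congruity_check(total_pairs: int, threshold: int = CONGRUITY_DF) -> bool:
    """True iff the dataset holds at least ``threshold`` observed-expected
    pairs (240 by default: 60 patients with 4 controls each suffice)."""
    if total_pairs < 0:
        raise ValueError("total_pairs must be >= 0")
    return total_pairs >= threshold

def model_validity(
    mean_variance: float,
    df: int,
    threshold: float = VALIDITY_THRESHOLD,
    df_gate: int = CONGRUITY_DF,
) -> Validity:
    """Validity verdict for a variance at a given pooled DF.

    Below the DF gate the data cannot support a verdict either way, so the
    result is INDETERMINATE rather than INVALID.
    """
    if mean_variance < 0.0:
        raise ValueError("mean_variance must be >= 0")
    if df <= 0:
        raise ValueError("df must be > 0")
    if df < df_gate:
        return Validity.INDETERMINATE
    return Validity.VALID if mean_variance < threshold else Validity.INVALID


def _summarise(group: str, fits: Sequence[PatientFit],
               threshold: float, df_gate: int) -> GroupSummary:
    variances = np.array([f.variance for f in fits])
    pooled_df = int(sum(f.df for f in fits))
    total_pairs = int(sum(f.n_obs for f in fits))
    total_dev = float(sum(f.deviance for f in fits))
    mean_var = float(variances.mean())
    return GroupSummary(
        group=group,
        n_patients=len(fits),
        total_pairs=total_pairs,
        pooled_df=pooled_df,
        mean_variance=mean_var,
        pooled_variance=total_dev / pooled_df,
        valid=mean_var < threshold,
        validity=model_validity(mean_var, pooled_df, threshold, df_gate),
    )


def cohort_variance_table(
    fits: Iterable[PatientFit],
    threshold: float = VALIDITY_THRESHOLD,
    df_gate: int = CONGRUITY_DF,
) -> list[GroupSummary]:
    """Group-by-group variance summaries plus an 'all' row.

    Groups are ordered by first appearance; the overall row pools every
    patient and is listed last under the label ``"all"``.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("at least one patient fit is required")
    by_group: dict[str, list[PatientFit]] = {}
    for f in fits:
        by_group.setdefault(f.group, []).append(f)
    out = [_summarise(g, fs, threshold, df_gate) for g, fs in by_group.items()]
    out.append(_summarise("all", fits, threshold, df_gate))
    return out
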