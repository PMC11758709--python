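"""Quartile stratification, cross-tabulation, chi-square, needs association.

Patients are binned into LOW / MEDIUM / HIGH strata by the quartiles of a
metric: at or below the first quartile is LOW, at or above the third is
HIGH, the middle half is MEDIUM.  Two stratifications (e.g. scheduling
complexity vs count-based adjustment) are compared on a 3x3 contingency
table with a plain Pearson chi-square (no continuity correction), and the
share of MEDIUM-or-HIGH patients is reported by needs-flag group.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class StratumLabel(enum.Enum):
    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"


STRATUM_ORDER = [StratumLabel.LOW, StratumLabel.MEDIUM, StratumLabel.HIGH]


@dataclass(frozen=True)
class ChiSquareResult:
    """Pearson chi-square statistic, degrees of freedom, and upper-tail p."""

    statistic: float
    degrees_of_freedom: int
    p_value: float


def quartile_bins(values: Mapping[str, float] | Sequence[float]) -> dict | list:
    """Assign LOW / MEDIUM / HIGH strata by quartiles.

    Q1 and Q3 are computed by linear interpolation of order statistics.
    A value v is LOW if v <= Q1, HIGH if v >= Q3, else MEDIUM, so boundary
    patients fall toward the tails.  Degenerate inputs (fewer than 4
    values, or Q1 == Q3) are all MEDIUM with a warning.

    Accepts a mapping (patient_id -> value; returns patient_id -> label)
    or a plain sequence (returns a list of labels in order).
    """
    is_mapping = isinstance(values, Mapping)
    keys = list(values.keys()) if is_mapping else None
    arr = np.asarray(
        list(values.values()) if is_mapping else list(values), dtype=float
    )
    if arr.size == 0:
        raise ValueError("quartile_bins requires at least one value")
    if arr.size < 4:
        warnings.warn(
            f"only {arr.size} value(s); quartile binning is degenerate, "
            "all patients labeled MEDIUM",
            stacklevel=2,
        )
        labels = [StratumLabel.MEDIUM] * arr.size
    else:
        q1, q3 = np.quantile(arr, [0.25, 0.75], method="linear")
        if q1 == q3:
            warnings.warn(
                "Q1 == Q3; quartile binning is degenerate, all MEDIUM",
                stacklevel=2,
            )
            labels = [StratumLabel.MEDIUM] * arr.size
        else:
            labels = [
                StratumLabel.LOW
                if v <= q1
                else StratumLabel.HIGH
                if v >= q3
                else StratumLabel.MEDIUM
                for v in arr
            ]
    if is_mapping:
        return dict(zip(keys, labels))
    return labels


def cross_tabulate(
    labels_a: Mapping[str, StratumLabel],
    labels_b: Mapping[str, StratumLabel],
) -> pd.DataFrame:
    """3x3 contingency table of two stratifications of the same patients.

    Rows are labels_a strata, columns labels_b strata, both in
    LOW/MEDIUM/HIGH order; every cell is a patient count and the grand
    total is the cohort size.  Mismatched patient sets are an error.
    """
    only_a = set(labels_a) - set(labels_b)
    only_b = set(labels_b) - set(labels_a)
    if only_a or only_b:
        raise ValueError(
            "stratifications cover different patients: "
            f"only in first={sorted(only_a)}, only in second={sorted(only_b)}"
        )
    names = [s.value for s in STRATUM_ORDER]
    table = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for pid, a in labels_a.items():
        table.loc[a.value, labels_b[pid].value] += 1
    return table


def pearson_chi_square(table: pd.DataFrame | np.ndarray) -> ChiSquareResult:
    """Plain Pearson chi-square test of independence on a contingency table.

    No continuity correction; df = (rows-1)(cols-1); p is the upper-tail
    chi-square probability.  A zero row or column margin is an error
    (expected counts undefined).
    """
    arr = np.asarray(table, dtype=float)
    if arr.sum() <= 0:
        raise ValueError("contingency table has zero grand total")
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise ValueError(
            "contingency table has a zero row or column margin; "
            "expected counts are undefined"
        )
    res = stats.chi2_contingency(arr, correction=False)
    return ChiSquareResult(
        statistic=float(res.statistic),
        degrees_of_freedom=int(res.dof),
        p_value=float(res.pvalue),
    )


def needs_association(
    labels: Mapping[str, StratumLabel],
    needs_flags: Mapping[str, bool],
) -> pd.DataFrame:
    """Share of MEDIUM-or-HIGH patients by needs-flag group.

    Returns a two-row DataFrame indexed by needs group (True/False) with
    columns ``n_patients``, ``n_medium_or_high``, ``percent`` (one
    decimal).  Every labeled patient must carry a flag.
    """
    missing = [p for p in labels if p not in needs_flags]
    if missing:
        raise ValueError(f"needs flags missing for patients: {sorted(missing)}")
    rows = {}
    for group in (True, False):
        pids = [p for p in labels if bool(needs_flags[p]) is group]
        hits = sum(
            1
            for p in pids
            if labels[p] in (StratumLabel.MEDIUM, StratumLabel.HIGH)
        )
        pct = round(100.0 * hits / len(pids), 1) if pids else float("nan")
        rows[group] = {
            "n_patients": len(pids),
            "n_medium_or_high": hits,
            "percent": pct,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "needs_flag"
    return df
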