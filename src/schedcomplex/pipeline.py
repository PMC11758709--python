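"""Cohort-level computations tying the per-patient metrics together."""

from __future__ import annotations

import datetime as dt
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .complexity import ComplexityConfig, DEFAULT_CONFIG, scheduling_complexity
from .counts import outcome_ratios
from .model import PatientSchedule, window_filter
from .stratify import (
    StratumLabel,
    cross_tabulate,
    needs_association,
    pearson_chi_square,
    quartile_bins,
)

METRIC_COLUMNS = [
    "patient_id",
    "sequence_complexity",
    "resolution_complexity",
    "location_complexity",
    "scheduling_complexity",
    "out_of_order_count",
    "unresolved_count",
    "multi_location_date_count",
    "unique_arrived_date_count",
    "nonarrived_count",
    "total_aids",
    "arrived_ratio",
    "nonarrived_ratio",
    "rescheduled_ratio",
    "canceled_ratio",
    "no_show_ratio",
    "count_based_adjustment",
]


def compute_metrics(
    schedules: Sequence[PatientSchedule],
    config: ComplexityConfig = DEFAULT_CONFIG,
    window_days: Optional[int] = 365,
    fixed_window_start: Optional[dt.date] = None,
    as_of: Optional[dt.date] = None,
) -> pd.DataFrame:
    """Per-patient complexity profiles and count ratios as one table.

    When ``window_days`` is given, each schedule is first restricted to
    ``[start, start + window_days)`` where ``start`` is
    ``fixed_window_start`` or, if None, the patient's diagnosis date; pass
    ``window_days=None`` to skip windowing.  Rows are sorted by patient_id.
    """
    if not schedules:
        raise ValueError("empty cohort")
    rows = []
    for sched in schedules:
        patient_as_of = as_of
        if window_days is not None:
            start = fixed_window_start or sched.diagnosis_date
            sched = window_filter(sched, start, window_days)
            if patient_as_of is None:
                patient_as_of = start + dt.timedelta(days=window_days)
        profile = scheduling_complexity(sched, config, patient_as_of)
        ratios = outcome_ratios(sched, patient_as_of)
        row = profile.as_row()
        row.update({k: v for k, v in ratios.as_row().items() if k != "patient_id"})
        rows.append(row)
    df = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    return df.sort_values("patient_id", kind="stable").reset_index(drop=True)


def compare_metrics(
    metrics: pd.DataFrame,
    needs_flags: Optional[Mapping[str, bool]] = None,
) -> dict:
    """Quartile-bin both composites, cross-tabulate, and test independence.

    Returns a JSON-ready dict with the per-composite bin counts, the 3x3
    contingency table (scheduling-complexity strata as rows, count-based
    strata as columns), the Pearson chi-square result, the diagonal
    agreement count, and — when flags are supplied — the needs-association
    table.
    """
    sched_vals = dict(zip(metrics["patient_id"], metrics["scheduling_complexity"]))
    count_vals = dict(zip(metrics["patient_id"], metrics["count_based_adjustment"]))
    sched_bins = quartile_bins(sched_vals)
    count_bins = quartile_bins(count_vals)
    table = cross_tabulate(sched_bins, count_bins)

    def _bin_counts(bins: Mapping[str, StratumLabel]) -> dict:
        out = {s.value: 0 for s in StratumLabel}
        for lab in bins.values():
            out[lab.value] += 1
        return out

    result: dict = {
        "n_patients": int(len(metrics)),
        "scheduling_bin_counts": _bin_counts(sched_bins),
        "count_based_bin_counts": _bin_counts(count_bins),
        "contingency_table": {
            "rows": "scheduling_complexity",
            "columns": "count_based_adjustment",
            "labels": list(table.index),
            "counts": table.values.tolist(),
        },
        "agreement_diagonal": int(np.trace(table.values)),
    }
    try:
        chi = pearson_chi_square(table)
        result["chi_square"] = {
            "statistic": chi.statistic,
            "degrees_of_freedom": chi.degrees_of_freedom,
            "p_value": chi.p_value,
        }
    except ValueError as exc:
        result["chi_square"] = {"error": str(exc)}

    if needs_flags is not None:
        known = {p: f for p, f in needs_flags.items() if f is not None}
        if set(sched_vals) <= set(known):
            result["needs_association"] = {
                "scheduling_complexity": _needs_rows(sched_bins, known),
                "count_based_adjustment": _needs_rows(count_bins, known),
            }
        else:
            result["needs_association_warning"] = (
                "needs flags missing for some patients; association skipped"
            )
    return result


def _needs_rows(bins: Mapping[str, StratumLabel], flags: Mapping[str, bool]) -> dict:
    df = needs_association(bins, flags)
    return {
        ("needs_indicated" if flag else "needs_not_indicated"): {
            "n_patients": int(df.loc[flag, "n_patients"]),
            "n_medium_or_high": int(df.loc[flag, "n_medium_or_high"]),
            "percent": float(df.loc[flag, "percent"]),
        }
        for flag in (True, False)
    }


def render_report(result: dict) -> str:
    """Plain-text report mirroring the contingency and needs tables."""
    lines = [
        f"Cohort size: {result['n_patients']}",
        "",
        "Stratum sizes (low/medium/high):",
    ]
    for key, label in (
        ("scheduling_bin_counts", "scheduling complexity"),
        ("count_based_bin_counts", "count-based adjustment"),
    ):
        c = result[key]
        lines.append(
            f"  {label:24s} {c['low']:>3d} / {c['medium']:>3d} / {c['high']:>3d}"
        )
    ct = result["contingency_table"]
    lines += [
        "",
        "Scheduling complexity (rows) vs count-based adjustment (columns):",
        "            " + "".join(f"{lab:>8s}" for lab in ct["labels"]),
    ]
    for lab, row in zip(ct["labels"], ct["counts"]):
        lines.append(f"  {lab:>8s}  " + "".join(f"{v:>8d}" for v in row))
    lines.append(f"  agreement on the diagonal: {result['agreement_diagonal']}")
    chi = result["chi_square"]
    if "error" in chi:
        lines.append(f"  chi-square: not computed ({chi['error']})")
    else:
        lines.append(
            f"  chi-square: statistic={chi['statistic']:.3f}, "
            f"df={chi['degrees_of_freedom']}, p={chi['p_value']:.3f}"
        )
    if "needs_association" in result:
        lines += [
            "",
            "Patients with medium or high complexity, by reported needs:",
            "                          needs indicated    needs not indicated",
        ]
        for key, label in (
            ("count_based_adjustment", "Count-based adjustments"),
            ("scheduling_complexity", "Scheduling complexity"),
        ):
            g = result["needs_association"][key]
            yes, no = g["needs_indicated"], g["needs_not_indicated"]
            lines.append(
                f"  {label:24s}"
                f"{yes['n_medium_or_high']:>4d} ({yes['percent']:.1f}%)    "
                f"{no['n_medium_or_high']:>8d} ({no['percent']:.1f}%)"
            )
    elif "needs_association_warning" in result:
        lines += ["", f"note: {result['needs_association_warning']}"]
    return "\n".join(lines) + "\n"
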