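"""Diagnostic-concordance statistics on detection-count tables.

Each detection method (pathological biopsy, routine MRI reading, CNN-assisted
MRI reading, ...) classifies every case in a cohort as cancer or hyperplasia.
This module computes per-method positive rates, Pearson chi-square tests of
method-vs-pathology 2x2 tables, and a combined concordance report including
per-risk-stratum count differences.

Printed positive rates are rounded half-up to the nearest integer percent.
The chi-square test applies no continuity correction by default (expected
counts in cohorts of this size are far above 5); pass ``correction=True``
for the Yates-corrected variant on 2x2 tables.

Reference count tables for an 89-case prostate cohort ship with the package
(:func:`load_detection_table`, :func:`load_strata_table`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from prostseg.risk_strat import RISK_GROUPS

__all__ = [
    "ChiSquareResult",
    "positive_rate",
    "chi_square",
    "concordance_report",
    "load_detection_table",
    "load_strata_table",
]


@dataclass(frozen=True)
class ChiSquareResult:
    """Pearson chi-square test outcome for a contingency table."""

    statistic: float
    df: int
    p_value: float


def positive_rate(n_cancer: int, n_hyperplasia: int, rounded: bool = True) -> float:
    """Percentage of cases called cancer, ``100 * a / (a + b)``.

    Rounded half-up to the nearest integer percent by default (the convention
    used for printed rates); pass ``rounded=False`` for the exact value.
    """
    total = n_cancer + n_hyperplasia
    if n_cancer < 0 or n_hyperplasia < 0:
        raise ValueError("counts must be non-negative")
    if total == 0:
        raise ValueError("positive rate is undefined for an empty cohort")
    rate = 100.0 * n_cancer / total
    if rounded:
        return float(math.floor(rate + 0.5))
    return rate


def chi_square(table, correction: bool = False) -> ChiSquareResult:
    """Pearson chi-square test of independence on an r x k count table.

    Expected counts come from the row/column margins; degrees of freedom are
    ``(r - 1)(k - 1)``.  No continuity correction unless requested.  Raises
    if any margin is zero (expected counts undefined).
    """
    obs = np.asarray(table, dtype=np.float64)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2 x 2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin: expected counts undefined")
    res = chi2_contingency(obs, correction=correction)
    return ChiSquareResult(
        statistic=float(res.statistic), df=int(res.dof), p_value=float(res.pvalue)
    )


def _coerce_detections(detections) -> pd.DataFrame:
    if isinstance(detections, pd.DataFrame):
        df = detections.copy()
    else:
        df = pd.DataFrame(
            [
                {"method": m, "n_cancer": c, "n_hyperplasia": h}
                for m, (c, h) in detections.items()
            ]
        )
    required = {"method", "n_cancer", "n_hyperplasia"}
    if not required <= set(df.columns):
        raise ValueError(f"detection table needs columns {sorted(required)}")
    return df


def concordance_report(
    detections,
    strata=None,
    pathology_method: str = "pathology",
    correction: bool = False,
) -> pd.DataFrame:
    """Compare each detection method against the pathology reference.

    ``detections`` maps method -> (n_cancer, n_hyperplasia) (or an equivalent
    DataFrame); ``strata`` optionally maps method -> {low, medium, high}
    counts.  The report gives, per method: the positive rate (integer
    percent), its absolute difference from the pathology rate, the Pearson
    chi-square statistic and p-value of the method-vs-pathology 2x2 table,
    and, when strata are supplied, the per-stratum count differences from
    pathology.
    """
    df = _coerce_detections(detections)
    if pathology_method not in set(df["method"]):
        raise ValueError(f"pathology row {pathology_method!r} missing")
    path_row = df[df["method"] == pathology_method].iloc[0]
    path_counts = (int(path_row["n_cancer"]), int(path_row["n_hyperplasia"]))
    path_rate = positive_rate(*path_counts)

    rows = []
    for _, r in df.iterrows():
        counts = (int(r["n_cancer"]), int(r["n_hyperplasia"]))
        rate = positive_rate(*counts)
        if r["method"] == pathology_method:
            chi = ChiSquareResult(0.0, 1, 1.0)
        else:
            chi = chi_square([path_counts, counts], correction=correction)
        row = {
            "method": r["method"],
            "n_cancer": counts[0],
            "n_hyperplasia": counts[1],
            "positive_rate_pct": rate,
            "rate_diff_pct": abs(rate - path_rate),
            "chi2_vs_pathology": chi.statistic,
            "p_vs_pathology": chi.p_value,
        }
        rows.append(row)
    report = pd.DataFrame(rows)

    if strata is not None:
        if isinstance(strata, pd.DataFrame):
            strata = {
                r["method"]: {g: int(r[g]) for g in RISK_GROUPS}
                for _, r in strata.iterrows()
            }
        if pathology_method not in strata:
            raise ValueError(f"pathology row {pathology_method!r} missing from strata")
        ref = strata[pathology_method]
        for g in RISK_GROUPS:
            report[f"{g}_count"] = [
                strata.get(m, {}).get(g, np.nan) for m in report["method"]
            ]
            report[f"{g}_diff"] = [
                strata[m][g] - ref[g] if m in strata else np.nan
                for m in report["method"]
            ]
    return report


def _load_csv(name: str) -> pd.DataFrame:
    with resources.files("prostseg.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_detection_table() -> pd.DataFrame:
    """Bundled cancer/hyperplasia detection counts for the 89-case cohort."""
    return _load_csv("table2.csv")


def load_strata_table() -> pd.DataFrame:
    """Bundled risk-stratum counts per detection method."""
    return _load_csv("table3.csv")
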