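"""Descriptive cohort summaries and interval estimates for report tables.

Counts get exact (Garwood, chi-square) Poisson intervals — the normal
approximation can miss the exact bound by a unit at large counts — and
continuous variables get normal-theory mean intervals.  Display rounding
never feeds back into computation: full-precision bounds are retained and
rounded only in the table output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortSummaryRow",
    "poisson_count_ci",
    "normal_mean_ci",
    "summarize_cohort",
]


@dataclass(frozen=True)
class CohortSummaryRow:
    label: str
    statistic: float
    ci_low: float
    ci_high: float
    method: str  # "normal-mean" or "poisson-count"

    def __post_init__(self) -> None:
        if not self.ci_low <= self.statistic <= self.ci_high:
            raise ValueError(f"{self.label!r}: interval does not bracket statistic")


def poisson_count_ci(count: int, level: float = 0.95) -> tuple[float, float]:
    """Exact two-sided Poisson interval via chi-square quantiles.

    lower = chi2(alpha/2, 2k) / 2 (0 when k = 0), upper =
    chi2(1 - alpha/2, 2k + 2) / 2.  Full precision is returned; round for
    table display only.
    """
    if count < 0 or int(count) != count:
        raise ValueError(f"count must be a nonnegative integer, got {count}")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    alpha = 1.0 - level
    lower = 0.0 if count == 0 else float(stats.chi2.ppf(alpha / 2, 2 * count) / 2.0)
    upper = float(stats.chi2.ppf(1.0 - alpha / 2, 2 * count + 2) / 2.0)
    return lower, upper


def normal_mean_ci(values, level: float = 0.95) -> tuple[float, float, float]:
    """Mean with z-based interval mean +/- z * sd / sqrt(n)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values for a mean interval")
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    mean = float(x.mean())
    half = z * float(x.std(ddof=1)) / np.sqrt(x.size)
    return mean, mean - half, mean + half


def summarize_cohort(baseline: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Baseline-characteristics table per starting arm.

    Continuous columns (age) get normal mean intervals; categorical columns
    get raw category counts with exact Poisson intervals.  Percentages are
    not forced to close over categories.
    """
    rows: list[CohortSummaryRow] = []
    for arm, grp in baseline.groupby("arm"):
        mean, lo, hi = normal_mean_ci(grp["age"], level)
        rows.append(CohortSummaryRow(f"{arm}/age_mean", mean, lo, hi, "normal-mean"))
        for col in baseline.columns:
            if col in ("arm", "age"):
                continue
            for cat, k in grp[col].value_counts().items():
                lo_c, hi_c = poisson_count_ci(int(k), level)
                rows.append(
                    CohortSummaryRow(
                        f"{arm}/{col}={cat}", float(k), lo_c, hi_c, "poisson-count"
                    )
                )
    return pd.DataFrame(
        {
            "label": [r.label for r in rows],
            "statistic": [r.statistic for r in rows],
            "ci_low": [r.ci_low for r in rows],
            "ci_high": [r.ci_high for r in rows],
            "method": [r.method for r in rows],
        }
    )
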