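"""Reporting statistics for simulated cohorts."""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .pathway import STAGE_COLUMNS, CohortResult

__all__ = ["SummaryStats", "summarize", "write_summary"]

QUANTILE_LEVELS = (5, 25, 75, 95)


@dataclass(frozen=True)
class SummaryStats:
    """Headline statistics of a simulated cohort.

    ``median_days`` is the midpoint-interpolated sample median of the
    total time to diagnosis; ``pct_emergency`` and ``pct_within_12mo``
    are percentages of the cohort; ``quantiles`` maps percentile level
    to days; ``step_means`` is each stage's mean contribution in days
    (zeros from untaken detours included).
    """

    n: int
    median_days: float
    pct_emergency: float
    pct_within_12mo: float
    quantiles: dict[int, float]
    step_means: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "median_days": self.median_days,
            "pct_emergency": self.pct_emergency,
            "pct_within_12mo": self.pct_within_12mo,
            "quantiles": {str(k): v for k, v in self.quantiles.items()},
            "step_means": dict(self.step_means),
        }


def summarize(result: CohortResult, twelve_months: float = 365.0) -> SummaryStats:
    """Compute the reporting statistics of a cohort.

    "Diagnosed within 12 months" counts totals ``<= twelve_months``
    (inclusive boundary, default 365 days).
    """
    if result.n < 1 or len(result.data) < 1:
        raise ValueError("cannot summarize an empty cohort")
    totals = result.totals
    flags = result.emergency
    return SummaryStats(
        n=result.n,
        median_days=float(np.median(totals)),
        pct_emergency=100.0 * float(np.mean(flags)),
        pct_within_12mo=100.0 * float(np.mean(totals <= twelve_months)),
        quantiles={
            q: float(np.percentile(totals, q)) for q in QUANTILE_LEVELS
        },
        step_means={
            c: float(result.data[c].mean()) for c in STAGE_COLUMNS
        },
    )


def write_summary(stats: SummaryStats, path: str) -> None:
    """Serialize a summary to JSON with fixed key names."""
    with open(path, "w") as fh:
        json.dump(stats.to_dict(), fh, indent=2)
        fh.write("\n")
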