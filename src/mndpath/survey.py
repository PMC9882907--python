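"""Fitting stage-duration distributions to categorical survey responses.

Care-experience surveys report waiting times as ordered duration
categories ("less than 1 month", "between 1 and 3 months", ...).  This
module turns such interval-censored tables into a continuous
:class:`~mndpath.steps.StepSpec` by the sample-then-fit procedure:
draw a large number of durations consistent with the category counts,
then fit a gamma distribution to the draws.

A plain uniform draw within each category overstates the mean whenever
the underlying density is decaying across the bins (the bin midpoint
sits above the conditional mean), so the default fit iterates the
expansion: after an initial uniform expansion and gamma fit, the
within-bin draws are redrawn from the current gamma conditional on the
bin and the fit repeated until the moments stabilise.  The fixed point
approximates the interval-censored maximum-likelihood fit while
keeping the expand-then-fit mechanics.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .steps import StepSpec, gamma_params_from_moments

__all__ = [
    "DAYS_PER_MONTH",
    "DAYS_PER_YEAR",
    "EmptyTableError",
    "SurveyCategory",
    "SurveyTable",
    "standard_categories",
    "bin_durations",
    "expand_categories",
    "fit_gamma_to_samples",
    "fit_survey_table",
    "read_survey_csv",
    "write_survey_csv",
]

# Calendar-average conventions for turning category labels into days.
DAYS_PER_MONTH = 30.44
DAYS_PER_YEAR = 365.25

#: Default width given to the open-ended top category ("2 years or
#: longer"): samples are drawn on [lower, lower + top_width].
DEFAULT_TOP_WIDTH = 365.0


class EmptyTableError(ValueError):
    """A survey table holds no usable responses."""


@dataclass(frozen=True)
class SurveyCategory:
    """One ordered response bin: [lower, upper) days, or open-ended
    above ``lower`` when ``upper`` is None."""

    lower: float
    upper: float | None
    count: int = 0

    @property
    def open_ended(self) -> bool:
        return self.upper is None


@dataclass(frozen=True)
class SurveyTable:
    """An ordered categorical duration table for one survey question.

    ``excluded_count`` records responses dropped as non-informative
    (non-respondents, "I did not see them", "can't remember").
    """

    question: str
    categories: tuple[SurveyCategory, ...]
    excluded_count: int = 0

    def __post_init__(self) -> None:
        if not self.categories:
            raise ValueError("survey table needs at least one category")
        prev_upper = None
        for i, cat in enumerate(self.categories):
            if cat.count < 0:
                raise ValueError(f"category {i}: count must be >= 0, got {cat.count}")
            if cat.open_ended and i != len(self.categories) - 1:
                raise ValueError("only the last category may be open-ended")
            if not cat.open_ended and not cat.upper > cat.lower:
                raise ValueError(
                    f"category {i}: upper ({cat.upper}) must exceed lower ({cat.lower})"
                )
            if prev_upper is not None and cat.lower != prev_upper:
                raise ValueError(
                    f"category {i}: intervals must be contiguous "
                    f"(lower {cat.lower} != previous upper {prev_upper})"
                )
            prev_upper = cat.upper
        if self.excluded_count < 0:
            raise ValueError("excluded_count must be >= 0")

    @property
    def total_count(self) -> int:
        """Number of usable responses."""
        return int(sum(c.count for c in self.categories))

    def with_counts(self, counts: list[int] | np.ndarray) -> "SurveyTable":
        if len(counts) != len(self.categories):
            raise ValueError("counts length must match number of categories")
        cats = tuple(
            SurveyCategory(c.lower, c.upper, int(k))
            for c, k in zip(self.categories, counts)
        )
        return SurveyTable(self.question, cats, self.excluded_count)


def standard_categories(counts: list[int] | None = None) -> tuple[SurveyCategory, ...]:
    """The seven ordered duration bins used by the 2019 MND care survey
    waiting-time questions: <1 month, 1–3 months, 3–6 months, 6–9
    months, 9–12 months, 1–2 years and 2 years or longer."""
    bounds = [
        0.0,
        1 * DAYS_PER_MONTH,
        3 * DAYS_PER_MONTH,
        6 * DAYS_PER_MONTH,
        9 * DAYS_PER_MONTH,
        1 * DAYS_PER_YEAR,
        2 * DAYS_PER_YEAR,
        None,
    ]
    if counts is None:
        counts = [0] * 7
    return tuple(
        SurveyCategory(bounds[i], bounds[i + 1], int(counts[i])) for i in range(7)
    )


def bin_durations(
    samples: np.ndarray,
    categories: tuple[SurveyCategory, ...] | None = None,
    question: str = "binned",
) -> SurveyTable:
    """Bin continuous durations into a categorical survey table.

    Raises ``ValueError`` when a duration falls above the last closed
    bound and no open-ended category exists, or below the first bound.
    """
    if categories is None:
        categories = standard_categories()
    samples = np.asarray(samples, dtype=float)
    table = SurveyTable(question, categories)
    edges = [c.lower for c in categories]
    last = categories[-1]
    if samples.size and samples.min() < edges[0]:
        raise ValueError(f"duration {samples.min()} below first category bound {edges[0]}")
    if not last.open_ended and samples.size and samples.max() >= last.upper:
        raise ValueError(
            f"duration {samples.max()} above last closed bound {last.upper} "
            "and no open-ended category exists"
        )
    idx = np.searchsorted(np.asarray(edges), samples, side="right") - 1
    counts = np.bincount(idx, minlength=len(categories))
    return table.with_counts(counts)


def _category_intervals(
    table: SurveyTable, top_width: float
) -> tuple[np.ndarray, np.ndarray]:
    lowers = np.array([c.lower for c in table.categories])
    uppers = np.array(
        [c.lower + top_width if c.open_ended else c.upper for c in table.categories]
    )
    return lowers, uppers


def expand_categories(
    table: SurveyTable,
    n_samples: int,
    rng: np.random.Generator | int,
    top_width: float = DEFAULT_TOP_WIDTH,
    step: StepSpec | None = None,
) -> np.ndarray:
    """Expand a categorical table into ``n_samples`` continuous durations.

    A category is drawn with probability proportional to its count,
    then a duration is drawn within the category's interval — uniformly
    by default, or from ``step``'s gamma conditioned on the interval
    when ``step`` is given.  The open-ended top category is treated as
    ``[lower, lower + top_width]``.
    """
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples!r}")
    if table.total_count == 0:
        raise EmptyTableError(
            f"survey table {table.question!r} has no usable responses"
        )
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    counts = np.array([c.count for c in table.categories], dtype=float)
    idx = rng.choice(len(counts), size=int(n_samples), p=counts / counts.sum())
    v = rng.random(int(n_samples))
    return _transform_within_bins(table, idx, v, top_width, step)


def _transform_within_bins(
    table: SurveyTable,
    idx: np.ndarray,
    v: np.ndarray,
    top_width: float,
    step: StepSpec | None,
) -> np.ndarray:
    """Map per-sample bin indices and uniforms to durations."""
    lowers, uppers = _category_intervals(table, top_width)
    lo, hi = lowers[idx], uppers[idx]
    if step is None or step.is_degenerate:
        return lo + v * (hi - lo)
    shape, scale = gamma_params_from_moments(step.mean, step.sd)
    dist = stats.gamma(shape, scale=scale)
    a = dist.cdf(np.maximum(lo - step.minimum, 0.0))
    b = dist.cdf(np.maximum(hi - step.minimum, 0.0))
    width = b - a
    out = np.where(
        width > 1e-12,
        step.minimum + dist.ppf(a + v * np.where(width > 1e-12, width, 1.0)),
        lo + v * (hi - lo),  # bin has ~no mass under current fit: keep uniform
    )
    return np.clip(out, lo, hi)


def fit_gamma_to_samples(
    samples: np.ndarray, minimum: float = 0.0, method: str = "mle"
) -> StepSpec:
    """Fit an anchored gamma to continuous duration samples.

    The gamma part is fitted to ``samples - minimum`` by maximum
    likelihood (``method="mle"``, location fixed at zero) or by moment
    matching (``method="moments"``).  Constant samples give back a
    degenerate (sd = 0) spec.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 100:
        raise ValueError(f"need at least 100 samples to fit, got {samples.size}")
    if np.any(samples < minimum):
        raise ValueError(
            f"all samples must be >= minimum ({minimum}), got min {samples.min()}"
        )
    x = samples - minimum
    if np.ptp(x) == 0.0:
        return StepSpec(name="fitted", mean=float(x[0]), sd=0.0, minimum=minimum)
    if method == "moments":
        mean, sd = float(np.mean(x)), float(np.std(x, ddof=1))
    elif method == "mle":
        # floc=0 pins the location; np.maximum guards values at exactly 0
        shape, _, scale = stats.gamma.fit(np.maximum(x, 1e-9), floc=0.0)
        mean, sd = float(shape * scale), float(np.sqrt(shape) * scale)
    else:
        raise ValueError(f"unknown fit method {method!r}")
    return StepSpec(name="fitted", mean=mean, sd=sd, minimum=minimum)


def fit_survey_table(
    table: SurveyTable,
    minimum: float = 0.0,
    n_samples: int = 100_000,
    rng: np.random.Generator | int = 0,
    top_width: float = DEFAULT_TOP_WIDTH,
    method: str = "mle",
    refine: bool = True,
    max_iter: int = 50,
    tol: float = 1e-4,
) -> StepSpec:
    """Expand a survey table and fit an anchored gamma to it.

    With ``refine=True`` (default) the within-bin draws are iteratively
    redrawn from the current gamma fit conditional on each bin, holding
    the underlying uniforms fixed, until mean and sd change by less
    than ``tol`` (relative) or ``max_iter`` iterations; the fixed point
    approximates the interval-censored MLE.  ``refine=False`` performs
    the single uniform-within-bin pass.
    """
    if table.total_count == 0:
        raise EmptyTableError(
            f"survey table {table.question!r} has no usable responses"
        )
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    counts = np.array([c.count for c in table.categories], dtype=float)
    idx = rng.choice(len(counts), size=int(n_samples), p=counts / counts.sum())
    v = rng.random(int(n_samples))

    samples = _transform_within_bins(table, idx, v, top_width, step=None)
    spec = fit_gamma_to_samples(samples, minimum=minimum, method=method)
    if not refine or spec.is_degenerate:
        return spec
    for _ in range(max_iter):
        samples = _transform_within_bins(table, idx, v, top_width, step=spec)
        new = fit_gamma_to_samples(samples, minimum=minimum, method=method)
        if new.is_degenerate:
            return new
        rel = max(
            abs(new.mean - spec.mean) / spec.mean,
            abs(new.sd - spec.sd) / max(spec.sd, 1e-12),
        )
        spec = new
        if rel < tol:
            break
    return spec


def write_survey_csv(table: SurveyTable, path: str) -> None:
    """Write a survey table as CSV.

    Columns: question, lower_days, upper_days (empty for the
    open-ended category), count.  The excluded-response total is kept
    in a ``# excluded_count:`` comment line above the header.
    """
    frame = pd.DataFrame(
        {
            "question": [table.question] * len(table.categories),
            "lower_days": [c.lower for c in table.categories],
            "upper_days": [c.upper for c in table.categories],
            "count": [c.count for c in table.categories],
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# excluded_count: {table.excluded_count}\n")
        frame.to_csv(fh, index=False)


def read_survey_csv(path: str) -> SurveyTable:
    """Read a survey table written by :func:`write_survey_csv`."""
    excluded = 0
    with open(path) as fh:
        text = fh.read()
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            if "excluded_count:" in line:
                excluded = int(line.split("excluded_count:")[1].strip())
        else:
            body_lines.append(line)
    frame = pd.read_csv(
        io.StringIO("\n".join(body_lines)), float_precision="round_trip"
    )
    cats = tuple(
        SurveyCategory(
            lower=float(lo),
            upper=None if pd.isna(up) else float(up),
            count=int(k),
        )
        for lo, up, k in zip(
            frame["lower_days"], frame["upper_days"], frame["count"]
        )
    )
    question = str(frame["question"].iloc[0]) if len(frame) else "survey"
    return SurveyTable(question=question, categories=cats, excluded_count=excluded)
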