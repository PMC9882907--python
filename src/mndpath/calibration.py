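"""Calibrate under-specified baseline parameters to summary targets.

The pre-pandemic pathway is only pinned down by a handful of published
summary statistics (median time to diagnosis, emergency-presentation
percentage, percentage diagnosed within 12 months), while the model
has a dozen free duration and probability parameters.  This module
searches the free parameters so that the simulator reproduces the
targets.  Because every cohort is generated by inverse-CDF transforms
of a fixed uniform block (common random numbers), the objective is a
deterministic, smooth function of the parameters and a derivative-free
optimizer (Nelder-Mead by default, differential evolution as a
fallback) works directly on it.

The problem is deliberately under-determined: many parameter vectors
match three targets.  The package ships one documented solution (see
:func:`mndpath.synthetic.generate_baseline_config`); scenario point
predictions therefore depend on that choice and should be read
qualitatively.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .pathway import PathwayConfig, simulate_cohort
from .summaries import summarize

__all__ = [
    "CalibrationTarget",
    "CalibrationResult",
    "CalibrationError",
    "calibrate_baseline",
    "evaluate_statistics",
]

STATISTICS = ("median_days", "pct_emergency", "pct_within_12mo")


@dataclass(frozen=True)
class CalibrationTarget:
    """One summary statistic the calibrated model must reproduce."""

    statistic: str
    target_value: float
    tolerance: float

    def __post_init__(self) -> None:
        if self.statistic not in STATISTICS:
            raise ValueError(
                f"unknown statistic {self.statistic!r}; expected one of {STATISTICS}"
            )
        if not self.tolerance > 0:
            raise ValueError(f"tolerance must be > 0, got {self.tolerance!r}")


class CalibrationError(RuntimeError):
    """Raised when no parameter vector within bounds meets all targets;
    carries the best residuals found."""

    def __init__(self, message: str, residuals: dict[str, float], achieved: dict[str, float]):
        super().__init__(message)
        self.residuals = residuals
        self.achieved = achieved


@dataclass
class CalibrationResult:
    config: PathwayConfig
    achieved: dict[str, float]
    residuals: dict[str, float]
    targets: tuple[CalibrationTarget, ...]
    success: bool
    n_evaluations: int
    objective: float


def _get_param(config: PathwayConfig, path: str) -> float:
    obj = config
    for part in path.split("."):
        try:
            obj = getattr(obj, part)
        except AttributeError as exc:
            raise ValueError(f"unknown parameter path {path!r}") from exc
    return obj


def _set_param(config: PathwayConfig, path: str, value: float) -> PathwayConfig:
    """Return a copy of ``config`` with the dotted-path field replaced."""
    parts = path.split(".")

    def rebuild(obj, parts):
        if len(parts) == 1:
            return dataclasses.replace(obj, **{parts[0]: value})
        child = getattr(obj, parts[0])
        return dataclasses.replace(obj, **{parts[0]: rebuild(child, parts[1:])})

    try:
        return rebuild(config, parts)
    except (AttributeError, TypeError) as exc:
        raise ValueError(f"unknown parameter path {path!r}") from exc


def apply_parameters(
    config: PathwayConfig, names: list[str], values: np.ndarray
) -> PathwayConfig:
    for name, value in zip(names, values):
        config = _set_param(config, name, float(value))
    return config


def evaluate_statistics(
    config: PathwayConfig, n_sim: int, seed: int
) -> dict[str, float]:
    """Simulate a cohort and return the three calibration statistics."""
    stats = summarize(simulate_cohort(config, n_sim, seed))
    return {s: getattr(stats, s) for s in STATISTICS}


def calibrate_baseline(
    base_config: PathwayConfig,
    free_parameters: dict[str, tuple[float, float]],
    targets: list[CalibrationTarget] | tuple[CalibrationTarget, ...],
    n_sim: int = 100_000,
    seed: int = 0,
    method: str = "nelder-mead",
    x0: dict[str, float] | None = None,
    maxiter: int | None = None,
    raise_on_failure: bool = True,
) -> CalibrationResult:
    """Search the free parameters to meet every target within tolerance.

    Parameters
    ----------
    base_config : PathwayConfig
        Starting configuration; parameters not listed stay fixed.
    free_parameters : dict
        Dotted parameter path (e.g. ``"s2gp.mean"``,
        ``"gp_branch.p_delay"``, ``"ref_branch.delay.sd"``) mapped to
        finite (lower, upper) bounds.
    targets : list of CalibrationTarget
    n_sim : int
        Cohort size per objective evaluation.  Sizes below 10,000
        trigger a warning: Monte Carlo noise may dominate tight
        tolerances.
    seed : int
        Single seed reused for every evaluation (common random
        numbers), making the objective deterministic.
    method : {"nelder-mead", "differential-evolution"}
    x0 : dict, optional
        Starting values per parameter; defaults to the base config's
        current values, clipped to the bounds (Nelder-Mead only).
    raise_on_failure : bool
        When True (default), raise :class:`CalibrationError` listing
        the residuals if the optimum misses any tolerance.

    Returns
    -------
    CalibrationResult
        The calibrated config, achieved statistics and residuals.
    """
    if not free_parameters:
        raise ValueError("at least one free parameter is required")
    if not targets:
        raise ValueError("at least one target is required")
    targets = tuple(targets)
    names = list(free_parameters)
    bounds = []
    for name, (lo, hi) in free_parameters.items():
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError(f"{name}: bounds must be finite with lower < upper")
        bounds.append((float(lo), float(hi)))
    if n_sim < 10_000:
        warnings.warn(
            f"n_sim={n_sim} is small; Monte Carlo noise may dominate the "
            "calibration tolerances",
            stacklevel=2,
        )

    n_evals = 0

    def objective(x: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        cfg = apply_parameters(base_config, names, x)
        achieved = evaluate_statistics(cfg, n_sim, seed)
        return sum(
            ((achieved[t.statistic] - t.target_value) / t.tolerance) ** 2
            for t in targets
        )

    if method == "nelder-mead":
        current = {name: _get_param(base_config, name) for name in names}
        start = np.array(
            [
                np.clip((x0 or current).get(name, current[name]), lo, hi)
                for name, (lo, hi) in zip(names, bounds)
            ]
        )
        budget = maxiter or 400 * len(names)
        res = optimize.minimize(
            objective,
            start,
            method="Nelder-Mead",
            bounds=bounds,
            options={"maxiter": budget, "xatol": 1e-4, "fatol": 1e-4},
        )
        # one restart from the optimum: a fresh simplex escapes the
        # degenerate collapse NM is prone to in narrow curved valleys
        if res.fun > float(len(targets)):
            res = optimize.minimize(
                objective,
                res.x,
                method="Nelder-Mead",
                bounds=bounds,
                options={"maxiter": budget, "xatol": 1e-4, "fatol": 1e-4},
            )
    elif method == "differential-evolution":
        res = optimize.differential_evolution(
            objective,
            bounds,
            seed=seed,
            maxiter=maxiter or 200,
            tol=1e-6,
            polish=True,
        )
    else:
        raise ValueError(f"unknown method {method!r}")

    best = apply_parameters(base_config, names, res.x)
    achieved = evaluate_statistics(best, n_sim, seed)
    residuals = {
        t.statistic: achieved[t.statistic] - t.target_value for t in targets
    }
    success = all(abs(residuals[t.statistic]) <= t.tolerance for t in targets)
    result = CalibrationResult(
        config=best,
        achieved=achieved,
        residuals=residuals,
        targets=targets,
        success=success,
        n_evaluations=n_evals,
        objective=float(res.fun),
    )
    if not success and raise_on_failure:
        detail = ", ".join(
            f"{t.statistic}: residual {residuals[t.statistic]:+.3f} "
            f"(tolerance {t.tolerance})"
            for t in targets
        )
        raise CalibrationError(
            f"calibration failed to meet all targets within bounds: {detail}",
            residuals=residuals,
            achieved=achieved,
        )
    return result
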