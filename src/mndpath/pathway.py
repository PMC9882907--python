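"""Core Monte Carlo engine for the five-node diagnostic pathway.

A virtual patient passes through three sequential stages — symptom
onset to GP presentation (``s2gp``), GP referral to neurology
appointment (``gp2neuro``) and neurology appointment to confirmed
diagnosis (``neuro2diagnosis``) — with two probabilistic detours: a
delay before the patient attends the GP at all (``gp_delay``) and a
delay when the GP consultation does not lead to a referral
(``ref_delay``).  Total time to diagnosis is the sum of the stage
durations that occur.  A simulated patient is classified as an
emergency presentation when that total falls within a configurable
window (default 30 days) of the median survival time from symptom
onset, i.e. the disease has progressed to near end of life before a
diagnosis is reached.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .steps import ParameterError, StepSpec, quantile

__all__ = [
    "BranchSpec",
    "SubtypeSurvival",
    "PathwayConfig",
    "CohortResult",
    "simulate_cohort",
    "classify_emergency",
    "write_cohort",
]

#: Column order of the per-patient stage table.
STAGE_COLUMNS = ("s2gp", "gp_delay", "gp2neuro", "ref_delay", "neuro2diagnosis")


@dataclass(frozen=True)
class BranchSpec:
    """A probabilistic detour: with probability ``p_delay`` the extra
    delay described by ``delay`` is added to the patient's pathway."""

    p_delay: float
    delay: StepSpec

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_delay <= 1.0:
            raise ParameterError(
                f"p_delay must be in [0, 1], got {self.p_delay!r}"
            )


@dataclass(frozen=True)
class SubtypeSurvival:
    """One disease-subtype stratum of a survival mixture."""

    label: str
    median: float
    weight: float

    def __post_init__(self) -> None:
        if not self.median > 0:
            raise ParameterError(f"survival median must be > 0, got {self.median!r}")
        if not 0.0 <= self.weight <= 1.0:
            raise ParameterError(f"mixture weight must be in [0, 1], got {self.weight!r}")


@dataclass(frozen=True)
class PathwayConfig:
    """The full pathway model.

    ``survival_median`` is either a single population median survival
    time from symptom onset (days) or a tuple of
    :class:`SubtypeSurvival` strata whose weights sum to 1.  The
    default of 548 days corresponds to the observation that nearly
    half of people with MND die within 18 months of symptom onset.
    """

    s2gp: StepSpec
    gp2neuro: StepSpec
    neuro2diagnosis: StepSpec
    gp_branch: BranchSpec
    ref_branch: BranchSpec
    survival_median: float | tuple[SubtypeSurvival, ...] = 548.0
    emergency_window: float = 30.0

    def __post_init__(self) -> None:
        if self.has_subtypes:
            total = sum(s.weight for s in self.survival_median)
            if abs(total - 1.0) > 1e-9:
                raise ParameterError(
                    f"subtype mixture weights must sum to 1, got {total!r}"
                )
            if not self.survival_median:
                raise ParameterError("subtype mixture must be non-empty")
        elif not self.survival_median > 0:
            raise ParameterError(
                f"survival_median must be > 0, got {self.survival_median!r}"
            )
        if not self.emergency_window >= 0:
            raise ParameterError(
                f"emergency_window must be >= 0, got {self.emergency_window!r}"
            )

    @property
    def has_subtypes(self) -> bool:
        return isinstance(self.survival_median, tuple)


@dataclass(frozen=True)
class CohortResult:
    """Per-patient stage durations for a simulated cohort.

    ``data`` has one row per virtual patient with the five stage
    columns (days; a branch column is exactly 0 when the detour was
    not taken), ``total_days`` and the boolean ``emergency`` flag,
    plus ``subtype`` when a survival mixture is configured.
    """

    data: pd.DataFrame
    n: int
    seed: int
    config: PathwayConfig = field(repr=False)

    @property
    def totals(self) -> np.ndarray:
        return self.data["total_days"].to_numpy()

    @property
    def emergency(self) -> np.ndarray:
        return self.data["emergency"].to_numpy()


def classify_emergency(
    totals: np.ndarray,
    survival_median: float | np.ndarray,
    window: float = 30.0,
) -> np.ndarray:
    """Flag emergency presentations.

    A patient presents as an emergency when the time to diagnosis
    reaches to within ``window`` days of the median survival time:
    ``total >= survival_median - window`` (closed inequality).

    ``survival_median`` may be a scalar or a per-patient array.
    """
    totals = np.asarray(totals, dtype=float)
    if np.any(totals < 0):
        raise ValueError("totals must be non-negative")
    if np.any(np.asarray(survival_median) <= 0):
        raise ParameterError("survival_median must be > 0")
    if window < 0:
        raise ParameterError(f"window must be >= 0, got {window!r}")
    return totals >= np.asarray(survival_median) - window


def simulate_cohort(config: PathwayConfig, n: int, seed: int) -> CohortResult:
    """Simulate ``n`` virtual patients through the pathway.

    For each patient the three core stage durations are drawn from
    their anchored gamma distributions; two independent uniforms
    ``r1, r2`` decide the detours — the GP-attendance delay is
    incurred iff ``r1 < gp_branch.p_delay`` and the referral delay iff
    ``r2 < ref_branch.p_delay``.  The total time to diagnosis is the
    sum of the stage durations that occurred.

    All stage draws go through the inverse CDF of a single fixed-layout
    uniform block, so a given ``(n, seed)`` pair reuses identical random
    numbers for any parameter values (common random numbers), and the
    result is bit-reproducible.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n!r}")
    rng = np.random.default_rng(seed)
    u = rng.random((int(n), 7))

    cols = {
        "s2gp": quantile(config.s2gp, u[:, 0]),
        "gp_delay": quantile(config.gp_branch.delay, u[:, 1]),
        "gp2neuro": quantile(config.gp2neuro, u[:, 2]),
        "ref_delay": quantile(config.ref_branch.delay, u[:, 3]),
        "neuro2diagnosis": quantile(config.neuro2diagnosis, u[:, 4]),
    }
    cols["gp_delay"] = np.where(u[:, 5] < config.gp_branch.p_delay, cols["gp_delay"], 0.0)
    cols["ref_delay"] = np.where(u[:, 6] < config.ref_branch.p_delay, cols["ref_delay"], 0.0)

    total = sum(cols[c] for c in STAGE_COLUMNS)
    frame = pd.DataFrame(cols, columns=list(STAGE_COLUMNS))
    frame["total_days"] = total

    if config.has_subtypes:
        strata = config.survival_median
        weights = np.array([s.weight for s in strata])
        medians = np.array([s.median for s in strata])
        labels = np.array([s.label for s in strata])
        idx = np.searchsorted(np.cumsum(weights), rng.random(int(n)), side="right")
        idx = np.clip(idx, 0, len(strata) - 1)
        frame["subtype"] = labels[idx]
        patient_median: float | np.ndarray = medians[idx]
    else:
        patient_median = config.survival_median

    frame["emergency"] = classify_emergency(
        total, patient_median, config.emergency_window
    )
    return CohortResult(data=frame, n=int(n), seed=int(seed), config=config)


def config_digest(config: PathwayConfig) -> str:
    """Short stable hash of a config, for provenance sidecars."""
    from .config_io import config_to_dict  # local import: avoid cycle

    payload = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_cohort(result: CohortResult, path: str) -> None:
    """Write a cohort to ``path`` (CSV) with a JSON provenance sidecar.

    The CSV has a ``patient_id`` column followed by the stage columns,
    ``total_days`` and ``emergency``; the sidecar ``<path>.json``
    records the config hash, cohort size and seed.
    """
    frame = result.data.copy()
    frame.insert(0, "patient_id", np.arange(result.n))
    frame.to_csv(path, index=False)
    sidecar = {
        "config_sha256_16": config_digest(result.config),
        "n": result.n,
        "seed": result.seed,
    }
    with open(f"{path}.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
        fh.write("\n")
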