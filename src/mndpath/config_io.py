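"""YAML serialization of pathway configurations.

The on-disk schema uses one canonical key per pathway symbol::

    steps:
      s2gp:            {mean: ..., sd: ..., minimum: ...}
      gp_delay:        {mean: ..., sd: ..., minimum: ...}
      gp2neuro:        {mean: ..., sd: ..., minimum: ...}
      ref_delay:       {mean: ..., sd: ..., minimum: ...}
      neuro2diagnosis: {mean: ..., sd: ..., minimum: ...}
    p_gp_delay: 0.30
    p_ref_delay: 0.25
    survival_median: 548.0        # or a list of {label, median, weight}
    emergency_window: 30.0

Writing is canonical (fixed key order, plain floats), so a
write/read/write round trip is byte-stable after the first
normalization pass.  An optional ``audit`` block (e.g. written by the
calibrator) is carried through untouched.
"""

from __future__ import annotations

from typing import Any

import yaml

from .pathway import BranchSpec, PathwayConfig, SubtypeSurvival
from .steps import ParameterError, StepSpec

__all__ = ["SchemaError", "read_config", "write_config", "config_to_dict"]

STEP_KEYS = ("s2gp", "gp_delay", "gp2neuro", "ref_delay", "neuro2diagnosis")


class SchemaError(ValueError):
    """A config file violates the schema; the message names the field."""


def _require(mapping: dict, key: str, context: str) -> Any:
    if key not in mapping:
        raise SchemaError(f"missing required field `{context}{key}`")
    return mapping[key]


def _number(value: Any, field: str) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise SchemaError(f"{field}: expected a number, got {value!r}")
    return float(value)


def _step_from_dict(name: str, raw: Any) -> StepSpec:
    if not isinstance(raw, dict):
        raise SchemaError(f"steps.{name}: expected a mapping, got {raw!r}")
    mean = _number(_require(raw, "mean", f"steps.{name}."), f"steps.{name}.mean")
    sd = _number(_require(raw, "sd", f"steps.{name}."), f"steps.{name}.sd")
    minimum = _number(raw.get("minimum", 0.0), f"steps.{name}.minimum")
    try:
        return StepSpec(name=name, mean=mean, sd=sd, minimum=minimum)
    except ParameterError as exc:
        raise SchemaError(f"steps.{exc}") from exc


def _probability(value: Any, field: str) -> float:
    p = _number(value, field)
    if not 0.0 <= p <= 1.0:
        raise SchemaError(f"{field}: {p!r} outside [0, 1]")
    return p


def config_from_dict(raw: dict) -> PathwayConfig:
    if not isinstance(raw, dict):
        raise SchemaError(f"config root: expected a mapping, got {raw!r}")
    steps_raw = _require(raw, "steps", "")
    if not isinstance(steps_raw, dict):
        raise SchemaError("steps: expected a mapping")
    steps = {k: _step_from_dict(k, _require(steps_raw, k, "steps.")) for k in STEP_KEYS}

    p1 = _probability(_require(raw, "p_gp_delay", ""), "p_gp_delay")
    p2 = _probability(_require(raw, "p_ref_delay", ""), "p_ref_delay")

    survival_raw = _require(raw, "survival_median", "")
    survival: float | tuple[SubtypeSurvival, ...]
    if isinstance(survival_raw, list):
        strata = []
        for i, item in enumerate(survival_raw):
            if not isinstance(item, dict):
                raise SchemaError(f"survival_median[{i}]: expected a mapping")
            strata.append(
                SubtypeSurvival(
                    label=str(_require(item, "label", f"survival_median[{i}].")),
                    median=_number(
                        _require(item, "median", f"survival_median[{i}]."),
                        f"survival_median[{i}].median",
                    ),
                    weight=_number(
                        _require(item, "weight", f"survival_median[{i}]."),
                        f"survival_median[{i}].weight",
                    ),
                )
            )
        survival = tuple(strata)
    else:
        survival = _number(survival_raw, "survival_median")
        if survival <= 0:
            raise SchemaError(f"survival_median: {survival!r} must be > 0")

    window = _number(raw.get("emergency_window", 30.0), "emergency_window")
    if window < 0:
        raise SchemaError(f"emergency_window: {window!r} must be >= 0")

    try:
        return PathwayConfig(
            s2gp=steps["s2gp"],
            gp2neuro=steps["gp2neuro"],
            neuro2diagnosis=steps["neuro2diagnosis"],
            gp_branch=BranchSpec(p_delay=p1, delay=steps["gp_delay"]),
            ref_branch=BranchSpec(p_delay=p2, delay=steps["ref_delay"]),
            survival_median=survival,
            emergency_window=window,
        )
    except ParameterError as exc:
        raise SchemaError(str(exc)) from exc


def config_to_dict(config: PathwayConfig) -> dict:
    """Canonical plain-dict form of a config (fixed key order)."""

    def step_dict(spec: StepSpec) -> dict:
        return {
            "mean": float(spec.mean),
            "sd": float(spec.sd),
            "minimum": float(spec.minimum),
        }

    if config.has_subtypes:
        survival: Any = [
            {"label": s.label, "median": float(s.median), "weight": float(s.weight)}
            for s in config.survival_median
        ]
    else:
        survival = float(config.survival_median)

    return {
        "steps": {
            "s2gp": step_dict(config.s2gp),
            "gp_delay": step_dict(config.gp_branch.delay),
            "gp2neuro": step_dict(config.gp2neuro),
            "ref_delay": step_dict(config.ref_branch.delay),
            "neuro2diagnosis": step_dict(config.neuro2diagnosis),
        },
        "p_gp_delay": float(config.gp_branch.p_delay),
        "p_ref_delay": float(config.ref_branch.p_delay),
        "survival_median": survival,
        "emergency_window": float(config.emergency_window),
    }


def read_config(path: str) -> PathwayConfig:
    """Read and validate a pathway config from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw)


def write_config(config: PathwayConfig, path: str, audit: dict | None = None) -> None:
    """Write a config in canonical YAML form.

    ``audit`` is an optional free-form block (calibration targets,
    achieved statistics, seed) appended under the ``audit`` key; it is
    ignored by :func:`read_config`.
    """
    doc = config_to_dict(config)
    if audit is not None:
        doc["audit"] = audit
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, default_flow_style=False)
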