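"""Pandemic-delay scenario transforms of a baseline pathway.

A scenario prolongs the stages of one care tier — primary (symptom to
GP, plus the GP-attendance detour), secondary (referral wait,
diagnosis wait and the referral detour) or both — by a fractional time
dilation, and replaces the two detour probabilities with
pandemic-period estimates: roughly 48% of the public avoiding medical
attention and a roughly 50% drop in GP-to-neurology referrals.

Dilation multiplies a stage's mean, sd and minimum by
``1 + delay_fraction``, which is the same as stretching every sampled
duration by that factor; the gamma shape is unchanged.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import pandas as pd

from .pathway import BranchSpec, PathwayConfig, simulate_cohort
from .summaries import summarize

__all__ = ["ScenarioSpec", "apply_scenario", "run_scenario_grid", "TIER_STAGES"]

#: Stage names prolonged by each care tier.
TIER_STAGES = {
    "none": frozenset(),
    "primary": frozenset({"s2gp", "gp_delay"}),
    "secondary": frozenset({"gp2neuro", "ref_delay", "neuro2diagnosis"}),
    "both": frozenset({"s2gp", "gp_delay", "gp2neuro", "ref_delay", "neuro2diagnosis"}),
}

# Pandemic-period detour probabilities estimated from published
# NHS Digital / NHS England reports for the first UK lockdown.
P_NO_GP_COVID = 0.48
P_NO_REFERRAL_COVID = 0.50


class ScenarioError(ValueError):
    """A scenario specification is invalid."""


@dataclass(frozen=True)
class ScenarioSpec:
    """A pandemic transform of the baseline pathway.

    Attributes
    ----------
    tier : {"none", "primary", "secondary", "both"}
        Which care tier's stages are prolonged.
    delay_fraction : float
        Fractional prolongation (0.25 means 25% longer); >= 0.
    p_no_gp, p_no_referral : float or None
        Replacement detour probabilities.  ``None`` keeps the
        baseline value; the defaults are the published pandemic
        estimates (0.48 and 0.50).
    """

    tier: str
    delay_fraction: float
    p_no_gp: float | None = P_NO_GP_COVID
    p_no_referral: float | None = P_NO_REFERRAL_COVID

    def __post_init__(self) -> None:
        if self.tier not in TIER_STAGES:
            raise ScenarioError(
                f"unknown tier {self.tier!r}; expected one of {sorted(TIER_STAGES)}"
            )
        if not self.delay_fraction >= 0:
            raise ScenarioError(
                f"delay_fraction must be >= 0, got {self.delay_fraction!r}"
            )
        for name in ("p_no_gp", "p_no_referral"):
            p = getattr(self, name)
            if p is not None and not 0.0 <= p <= 1.0:
                raise ScenarioError(f"{name} must be in [0, 1], got {p!r}")


def apply_scenario(config: PathwayConfig, scenario: ScenarioSpec) -> PathwayConfig:
    """Return a new config with the scenario applied.

    Stages in the scenario's tier have mean, sd and minimum multiplied
    by ``1 + delay_fraction``; detour probabilities are replaced where
    the scenario provides them.  The input config is not mutated.
    """
    affected = TIER_STAGES[scenario.tier]
    factor = 1.0 + scenario.delay_fraction

    def maybe_scale(step, name):
        return step.scaled(factor) if name in affected and factor != 1.0 else step

    p1 = config.gp_branch.p_delay if scenario.p_no_gp is None else scenario.p_no_gp
    p2 = (
        config.ref_branch.p_delay
        if scenario.p_no_referral is None
        else scenario.p_no_referral
    )
    return dataclasses.replace(
        config,
        s2gp=maybe_scale(config.s2gp, "s2gp"),
        gp2neuro=maybe_scale(config.gp2neuro, "gp2neuro"),
        neuro2diagnosis=maybe_scale(config.neuro2diagnosis, "neuro2diagnosis"),
        gp_branch=BranchSpec(p1, maybe_scale(config.gp_branch.delay, "gp_delay")),
        ref_branch=BranchSpec(p2, maybe_scale(config.ref_branch.delay, "ref_delay")),
    )


def run_scenario_grid(
    config: PathwayConfig,
    tiers: list[str],
    fractions: list[float],
    n: int = 100_000,
    seed: int = 0,
    p_no_gp: float | None = P_NO_GP_COVID,
    p_no_referral: float | None = P_NO_REFERRAL_COVID,
    twelve_months: float = 365.0,
) -> pd.DataFrame:
    """Summarise every tier x fraction scenario over a common cohort.

    All scenarios are simulated with the same ``(n, seed)``, i.e. with
    common random numbers, so differences between rows reflect the
    scenario parameters rather than Monte Carlo noise.  Returns one
    row per scenario: scenario id, tier, fraction, median_days,
    pct_emergency, pct_within_12mo.
    """
    rows = []
    for tier in tiers:
        for frac in fractions:
            spec = ScenarioSpec(
                tier=tier,
                delay_fraction=frac,
                p_no_gp=p_no_gp,
                p_no_referral=p_no_referral,
            )
            result = simulate_cohort(apply_scenario(config, spec), n, seed)
            stats = summarize(result, twelve_months=twelve_months)
            rows.append(
                {
                    "scenario": f"{tier}:{frac:g}",
                    "tier": tier,
                    "fraction": frac,
                    "median_days": stats.median_days,
                    "pct_emergency": stats.pct_emergency,
                    "pct_within_12mo": stats.pct_within_12mo,
                }
            )
    return pd.DataFrame(rows)
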