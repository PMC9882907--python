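"""Re-calibrate a mis-specified baseline to summary targets.

Starts from a deliberately perturbed copy of the shipped baseline and
asks the calibrator to recover three summary statistics of the
original (median days, % emergency, % within 12 months) by adjusting
two stage means and one detour probability.  Because the simulator
reuses the same random numbers at every objective evaluation, the
search is deterministic and a derivative-free optimizer suffices.
"""

import dataclasses

from mndpath import BranchSpec, CalibrationTarget, calibrate_baseline, generate_baseline_config
from mndpath.calibration import evaluate_statistics

config = generate_baseline_config("default-calibrated")
n_sim, seed = 20_000, 9

truth = evaluate_statistics(config, n_sim, seed)
targets = [
    CalibrationTarget("median_days", truth["median_days"], 2.0),
    CalibrationTarget("pct_emergency", truth["pct_emergency"], 0.3),
    CalibrationTarget("pct_within_12mo", truth["pct_within_12mo"], 0.5),
]

perturbed = dataclasses.replace(
    config,
    s2gp=config.s2gp.scaled(1.25),
    gp_branch=BranchSpec(config.gp_branch.p_delay + 0.1, config.gp_branch.delay),
)

result = calibrate_baseline(
    perturbed,
    {
        "s2gp.mean": (30.0, 140.0),
        "gp_branch.p_delay": (0.05, 0.6),
        "gp2neuro.mean": (60.0, 200.0),
    },
    targets,
    n_sim=n_sim,
    seed=seed,
)

print(f"objective evaluations: {result.n_evaluations}")
for t in targets:
    print(
        f"{t.statistic:<16s} target {t.target_value:8.2f}  "
        f"achieved {result.achieved[t.statistic]:8.2f}  "
        f"(tolerance {t.tolerance})"
    )
print("\nThree targets cannot pin down a dozen parameters: the recovered")
print("config is one member of a family that matches the statistics.")
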