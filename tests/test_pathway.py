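"""Cohort simulation mechanics and the emergency-presentation rule."""

import dataclasses

import numpy as np
import pytest

import mndpath as m
from mndpath.pathway import STAGE_COLUMNS


def degenerate_config(p1=0.0, p2=0.0, means=(10.0, 20.0, 30.0), d1=40.0, d2=50.0):
    return m.PathwayConfig(
        s2gp=m.StepSpec("s2gp", means[0], 0.0),
        gp2neuro=m.StepSpec("gp2neuro", means[1], 0.0),
        neuro2diagnosis=m.StepSpec("neuro2diagnosis", means[2], 0.0),
        gp_branch=m.BranchSpec(p1, m.StepSpec("gp_delay", d1, 0.0)),
        ref_branch=m.BranchSpec(p2, m.StepSpec("ref_delay", d2, 0.0)),
        survival_median=548.0,
    )


class TestSimulateCohort:
    def test_degenerate_chain_totals_exact(self):
        result = m.simulate_cohort(degenerate_config(), 100, seed=0)
        np.testing.assert_array_equal(result.totals, np.full(100, 60.0))

    def test_forced_gp_branch_adds_its_delay(self):
        result = m.simulate_cohort(degenerate_config(p1=1.0), 100, seed=0)
        np.testing.assert_array_equal(result.totals, np.full(100, 100.0))

    def test_half_probability_branch_binomial_fraction(self):
        result = m.simulate_cohort(degenerate_config(p1=0.5), 100_000, seed=1)
        frac = np.mean(result.totals == 100.0)
        se = np.sqrt(0.25 / result.n)
        assert abs(frac - 0.5) < 3 * se

    def test_untaken_branch_columns_are_exactly_zero(self, default_config):
        result = m.simulate_cohort(default_config, 5000, seed=2)
        taken = result.data["gp_delay"].to_numpy()
        assert np.all((taken == 0.0) | (taken > 0.0))
        # with p<1 some rows must be exactly zero
        assert np.any(result.data["gp_delay"] == 0.0)
        assert np.any(result.data["ref_delay"] == 0.0)

    def test_total_is_row_sum_of_components(self, default_cohort):
        parts = default_cohort.data[list(STAGE_COLUMNS)].sum(axis=1).to_numpy()
        np.testing.assert_allclose(parts, default_cohort.totals, rtol=1e-12)

    def test_n_below_one_rejected(self, default_config):
        with pytest.raises(ValueError, match="n"):
            m.simulate_cohort(default_config, 0, seed=0)

    def test_fixed_seed_reproducible(self, default_config):
        a = m.simulate_cohort(default_config, 2000, seed=3)
        b = m.simulate_cohort(default_config, 2000, seed=3)
        assert a.data.equals(b.data)

    def test_subtype_mixture_draws_labels_and_thresholds(self):
        cfg = dataclasses.replace(
            degenerate_config(),
            survival_median=(
                m.SubtypeSurvival("bulbar", 70.0, 0.5),
                m.SubtypeSurvival("limb", 1000.0, 0.5),
            ),
        )
        result = m.simulate_cohort(cfg, 20_000, seed=4)
        # totals are 60 for everyone: emergencies are exactly the bulbar half
        flags = result.emergency
        labels = result.data["subtype"].to_numpy()
        assert set(labels) == {"bulbar", "limb"}
        assert np.array_equal(flags, labels == "bulbar")


class TestClassifyEmergency:
    def test_boundary_is_closed(self):
        assert m.classify_emergency(np.array([520.0]), 548.0, 30.0)[0]
        assert not m.classify_emergency(np.array([517.9]), 548.0, 30.0)[0]
        assert m.classify_emergency(np.array([518.0]), 548.0, 30.0)[0]

    def test_negative_totals_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            m.classify_emergency(np.array([-1.0]), 548.0, 30.0)

    def test_brute_force_grid_equivalence(self):
        totals = np.linspace(0.0, 1000.0, 10_001)
        flags = m.classify_emergency(totals, 548.0, 30.0)
        brute = np.array([t >= 548.0 - 30.0 for t in totals])
        np.testing.assert_array_equal(flags, brute)


class TestMonotonicity:
    """Common-random-number comparisons: more delay never helps."""

    def test_scaling_any_step_never_decreases_totals(self, default_config):
        base = m.simulate_cohort(default_config, 20_000, seed=5).totals
        for path in ("s2gp", "gp2neuro", "neuro2diagnosis"):
            step = getattr(default_config, path)
            cfg = dataclasses.replace(default_config, **{path: step.scaled(1.5)})
            up = m.simulate_cohort(cfg, 20_000, seed=5).totals
            assert np.all(up >= base)

    def test_emergency_fraction_monotone_in_branch_probability(self, default_config):
        fracs = []
        for p in (0.1, 0.3, 0.5, 0.8):
            cfg = dataclasses.replace(
                default_config,
                gp_branch=m.BranchSpec(p, default_config.gp_branch.delay),
            )
            fracs.append(m.simulate_cohort(cfg, 100_000, seed=6).emergency.mean())
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))

    def test_emergency_fraction_monotone_in_step_mean(self, default_config):
        fracs = []
        for factor in (1.0, 1.25, 1.5, 2.0):
            cfg = dataclasses.replace(
                default_config, gp2neuro=default_config.gp2neuro.scaled(factor)
            )
            fracs.append(m.simulate_cohort(cfg, 100_000, seed=7).emergency.mean())
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))

    def test_wider_window_never_reduces_emergency_count(self, default_cohort):
        counts = [
            m.classify_emergency(default_cohort.totals, 548.0, w).sum()
            for w in (0.0, 15.0, 30.0, 60.0, 120.0)
        ]
        assert all(a <= b for a, b in zip(counts, counts[1:]))


class TestCohortWriter:
    def test_csv_and_sidecar(self, tmp_path, fast_config):
        result = m.simulate_cohort(fast_config, 50, seed=8)
        path = tmp_path / "cohort.csv"
        m.write_cohort(result, str(path))
        import json
        import pandas as pd

        frame = pd.read_csv(path)
        assert list(frame.columns[:2]) == ["patient_id", "s2gp"]
        assert len(frame) == 50
        sidecar = json.loads((tmp_path / "cohort.csv.json").read_text())
        assert sidecar["n"] == 50 and sidecar["seed"] == 8
        assert len(sidecar["config_sha256_16"]) == 16
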