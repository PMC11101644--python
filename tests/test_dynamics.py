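"""Simulation engine: stepping, trajectories, activity levels, attractors."""

import numpy as np
import pytest

from emtmap.dynamics import (
    ActivityProfile,
    ConfigError,
    ModelSizeError,
    SimulationConfig,
    StateError,
    activity_profile,
    attractors_exhaustive,
    detect_oscillation,
    simulate,
    sync_step,
)
from emtmap.logic import infer_rules
from emtmap.synthetic import SyntheticMapSpec, generate_random_map

from conftest import build_map


def negative_feedback_model():
    # A = NOT B, B = A: the smallest sustained oscillator
    return infer_rules(build_map([("A", "activation", "B"), ("B", "inhibition", "A")]))


def mutual_inhibition_model():
    return infer_rules(build_map([("A", "inhibition", "B"), ("B", "inhibition", "A")]))


class TestSyncStep:
    def test_rule_evaluation(self):
        model = infer_rules(build_map([("A", "activation", "T"), ("I", "inhibition", "T")]))
        out = sync_step(model, {"A": 1, "I": 0, "T": 0})
        assert out["T"] == 1

    def test_fixed_point_identity(self):
        model = mutual_inhibition_model()
        s = {"A": 1, "B": 0}
        assert sync_step(model, s) == s

    def test_missing_node_rejected(self):
        model = mutual_inhibition_model()
        with pytest.raises(StateError):
            sync_step(model, {"A": 1})

    def test_negative_feedback_synchronous_orbit_period_4(self):
        model = negative_feedback_model()
        orbit = [{"A": 1, "B": 0}]
        for _ in range(4):
            orbit.append(sync_step(model, orbit[-1]))
        assert orbit[1:] == [
            {"A": 1, "B": 1},
            {"A": 0, "B": 1},
            {"A": 0, "B": 0},
            {"A": 1, "B": 0},
        ]


class TestSimulate:
    def test_clamp_holds_input_on_every_step(self, emt_model):
        cfg = SimulationConfig(n_steps=300, clamps={"TGFB": 1.0}, initial="random", seed=5)
        traj = simulate(emt_model, cfg)
        assert np.all(traj.series("TGFB")[1:] == 1.0)

    def test_same_seed_identical_trajectories(self, emt_model, markers):
        cfg = SimulationConfig(n_steps=500, clamps={"TGFB": 1.0}, initial="epithelial", seed=11)
        a = simulate(emt_model, cfg, markers)
        b = simulate(emt_model, cfg, markers)
        assert np.array_equal(a.array, b.array)
        assert a.updated_node_log == b.updated_node_log

    def test_binary_closure(self, emt_model, markers):
        cfg = SimulationConfig(n_steps=400, clamps={"TGFB": 0.5}, initial="epithelial", seed=2)
        traj = simulate(emt_model, cfg, markers)
        assert set(np.unique(traj.array)) <= {0, 1}

    def test_trajectory_length_is_steps_plus_one(self, emt_model, markers):
        cfg = SimulationConfig(n_steps=123, clamps={}, initial="epithelial", seed=0)
        assert len(simulate(emt_model, cfg, markers)) == 124

    def test_unknown_preset_rejected(self):
        with pytest.raises(ConfigError, match="preset"):
            SimulationConfig(initial="mesenchymal-ish")

    def test_clamping_non_input_rejected(self, emt_model):
        cfg = SimulationConfig(n_steps=10, clamps={"SNAIL": 1.0}, initial="random", seed=0)
        with pytest.raises(ConfigError, match="not an input"):
            simulate(emt_model, cfg)

    def test_clamp_fidelity_long_run_fraction(self, emt_model):
        p, n_steps = 0.6, 4000
        cfg = SimulationConfig(n_steps=n_steps, clamps={"TGFB": p}, initial="random", seed=7)
        traj = simulate(emt_model, cfg)
        frac = traj.series("TGFB")[1:].mean()
        assert abs(frac - p) <= 3 * np.sqrt(p * (1 - p) / n_steps)


class TestActivityProfile:
    def test_clamped_node_profile_is_constant_one(self, emt_model, markers):
        cfg = SimulationConfig(n_steps=500, clamps={"TGFB": 1.0}, initial="epithelial", seed=3)
        prof = activity_profile(emt_model, cfg, window=50, ensemble=5, markers=markers)
        assert np.allclose(prof.profile("TGFB"), 1.0)

    def test_constitutively_off_node_drops_to_zero(self):
        # T has a single activator that is clamped OFF, so T decays to 0
        model = infer_rules(build_map([("A", "activation", "T")]))
        cfg = SimulationConfig(n_steps=600, clamps={"A": 0.0}, initial={"A": 1, "T": 1}, seed=1)
        prof = activity_profile(model, cfg, window=100, ensemble=20)
        assert prof.profile("T")[-1] == 0.0

    def test_window_larger_than_steps_rejected(self, emt_model, markers):
        cfg = SimulationConfig(n_steps=10, clamps={}, initial="epithelial", seed=0)
        with pytest.raises(ConfigError, match="window"):
            activity_profile(emt_model, cfg, window=11, ensemble=1, markers=markers)

    def test_reproducible_for_fixed_base_seed(self, emt_model, markers):
        cfg = SimulationConfig(n_steps=300, clamps={"TGFB": 1.0}, initial="epithelial", seed=21)
        a = activity_profile(emt_model, cfg, window=50, ensemble=4, markers=markers)
        b = activity_profile(emt_model, cfg, window=50, ensemble=4, markers=markers)
        assert np.array_equal(a.values, b.values)

    def test_values_are_on_fractions(self, emt_model, markers):
        cfg = SimulationConfig(n_steps=400, clamps={"TGFB": 0.5}, initial="epithelial", seed=8)
        prof = activity_profile(emt_model, cfg, window=40, ensemble=3, markers=markers)
        assert prof.values.min() >= 0.0 and prof.values.max() <= 1.0


class TestAttractors:
    def test_self_activator_has_both_fixed_points(self):
        model = infer_rules(build_map([("A", "activation", "A")]))
        ats = attractors_exhaustive(model, "asynchronous")
        fps = sorted(fp["A"] for fp in ats.fixed_points)
        assert fps == [0, 1]

    def test_mutual_inhibition_two_fixed_points(self):
        ats = attractors_exhaustive(mutual_inhibition_model(), "asynchronous")
        assert sorted(a.type for a in ats.attractors) == ["fixed_point", "fixed_point"]
        fps = {tuple(sorted(fp.items())) for fp in ats.fixed_points}
        assert fps == {(("A", 1), ("B", 0)), (("A", 0), ("B", 1))}

    def test_negative_feedback_single_cyclic_attractor(self):
        ats = attractors_exhaustive(negative_feedback_model(), "asynchronous")
        assert len(ats.attractors) == 1
        (a,) = ats.attractors
        assert a.type in ("cycle", "complex")
        assert len(a.states) == 4
        assert not ats.fixed_points

    def test_synchronous_negative_feedback_period_4(self):
        ats = attractors_exhaustive(negative_feedback_model(), "synchronous")
        assert [(a.type, len(a.states)) for a in ats.attractors] == [("cycle", 4)]

    def test_size_limit_enforced(self):
        model = infer_rules(
            generate_random_map(SyntheticMapSpec(n_nodes=21, n_edges=30, seed=0))
        )
        with pytest.raises(ModelSizeError, match="simulate"):
            attractors_exhaustive(model)

    def test_simulation_absorbs_into_exhaustive_attractors(self):
        """Long asynchronous runs from random states end inside an attractor
        reported by the exhaustive analysis (engine/oracle agreement)."""
        rng = np.random.default_rng(0)
        for seed in range(10):
            m = generate_random_map(
                SyntheticMapSpec(n_nodes=7, n_edges=12, inhibition_fraction=0.4, seed=seed)
            )
            model = infer_rules(m)
            ats = attractors_exhaustive(model, "asynchronous")
            union = set().union(*(a.states for a in ats.attractors))
            for _ in range(5):
                init = {n: int(rng.integers(0, 2)) for n in model.node_order}
                cfg = SimulationConfig(n_steps=400, initial=init, seed=int(rng.integers(0, 2**31)))
                final = simulate(model, cfg).final_state
                bm = sum(final[n] << i for i, n in enumerate(ats.node_order))
                assert bm in union


class TestOscillation:
    def _profile(self, series):
        values = np.array(series, dtype=float)[:, None]
        return ActivityProfile(["X"], values, window_size=10, ensemble_size=1, scheme="asynchronous")

    def test_constant_one_not_oscillating(self):
        prof = self._profile([1.0] * 10)
        assert not detect_oscillation(prof, "X").oscillating

    def test_alternating_profile_oscillating(self):
        prof = self._profile([0.3, 0.7] * 5)
        summary = detect_oscillation(prof, "X")
        assert summary.oscillating
        assert summary.eps == 0.05

    def test_monotone_drift_not_oscillating(self):
        prof = self._profile(np.linspace(0.2, 0.8, 10))
        assert not detect_oscillation(prof, "X").oscillating

    def test_unknown_node_rejected(self):
        with pytest.raises(KeyError):
            detect_oscillation(self._profile([0.5] * 5), "Y")

    def test_too_few_windows_rejected(self):
        with pytest.raises(ConfigError):
            detect_oscillation(self._profile([0.5, 0.5]), "X")
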