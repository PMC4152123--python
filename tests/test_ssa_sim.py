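import math

import numpy as np
import pytest

import spnlab as sl
from spnlab.testing import random_conservative_bundle


class TestPropensities:
    def test_unary_mass_action(self):
        b = sl.MatrixBundle(["X"], ["t"], pre=[[1]], post=[[0]],
                            initial_marking=[3], rates=[2.0])
        assert sl.propensities(b, np.array([3])) == pytest.approx([6.0])

    def test_dimerization_counts_distinct_pairs(self):
        # 3 tokens taken 2 at a time: C(3,2) = 3 unordered pairs
        b = sl.MatrixBundle(["X"], ["t"], pre=[[2]], post=[[0]],
                            initial_marking=[3], rates=[1.0])
        assert sl.propensities(b, np.array([3])) == pytest.approx([3.0])

    def test_under_resourced_transition_has_zero_propensity(self):
        b = sl.MatrixBundle(["X"], ["t"], pre=[[2]], post=[[0]],
                            initial_marking=[1], rates=[1.0])
        assert sl.propensities(b, np.array([1])) == pytest.approx([0.0])

    def test_negative_state_rejected(self):
        b = sl.MatrixBundle(["X"], ["t"], pre=[[1]], post=[[0]],
                            initial_marking=[0], rates=[1.0])
        with pytest.raises(sl.DomainError):
            sl.propensities(b, np.array([-1]))


class TestSimulate:
    def test_pure_death_absorbs_after_exactly_five_events(self):
        b = sl.MatrixBundle(["X"], ["die"], pre=[[1]], post=[[0]],
                            initial_marking=[5], rates=[1.0])
        traj = sl.simulate(b, t_max=1e9, seed=3)
        assert traj.n_events == 5
        assert traj.final_marking().tolist() == [0]
        assert traj.absorbed

    def test_same_seed_reproduces_trajectory_exactly(self, immigration_death_bundle):
        a = sl.simulate(immigration_death_bundle, 5.0, seed=42)
        b = sl.simulate(immigration_death_bundle, 5.0, seed=42)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.markings, b.markings)
        assert np.array_equal(a.fired, b.fired)

    def test_invalid_t_max_rejected(self, immigration_death_bundle):
        with pytest.raises(sl.DomainError):
            sl.simulate(immigration_death_bundle, 0.0, seed=1)

    def test_times_strictly_increase_and_markings_nonnegative(
            self, immigration_death_bundle):
        traj = sl.simulate(immigration_death_bundle, 10.0, seed=7)
        assert (np.diff(traj.times) > 0).all()
        assert (traj.markings >= 0).all()

    def test_max_events_caps_the_run(self, immigration_death_bundle):
        traj = sl.simulate(immigration_death_bundle, 1e9, seed=0, max_events=10)
        assert traj.n_events == 10

    def test_immigration_death_long_run_mean_is_rate_ratio(
            self, immigration_death_bundle):
        # stationary law of the M/M/inf chain is Poisson(lambda/mu) = Poisson(10)
        traj = sl.simulate(immigration_death_bundle, 400.0, seed=11)
        mean = traj.time_average(50.0, 400.0)[0]
        assert mean == pytest.approx(10.0, abs=1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_conservative_bundle_keeps_total_tokens(self, seed):
        rng = np.random.default_rng(seed)
        b = random_conservative_bundle(rng)
        traj = sl.simulate(b, 20.0, seed=seed, max_events=2000)
        totals = traj.markings.sum(axis=1)
        assert (totals == totals[0]).all()


class TestGrid:
    def test_last_event_carried_forward(self):
        traj = sl.Trajectory(
            times=np.array([0.0, 1.0, 3.0]),
            markings=np.array([[5], [4], [7]]),
            fired=np.array([0, 1]),
            seed=0,
        )
        grid = sl.sample_on_grid(traj, np.array([0.0, 0.5, 1.0, 2.9, 3.0, 10.0]))
        assert grid[:, 0].tolist() == [5, 5, 4, 4, 7, 7]


class TestEnsemble:
    def test_no_transition_bundle_is_degenerate(self):
        b = sl.MatrixBundle(["A"], [], pre=np.zeros((1, 0), dtype=int),
                            post=np.zeros((1, 0), dtype=int),
                            initial_marking=[4], rates=np.zeros(0))
        summary = sl.simulate_ensemble(b, 5.0, [0.0, 2.5, 5.0], 3, base_seed=0)
        assert (summary.mean == 4).all()
        assert (summary.variance == 0).all()

    def test_empty_grid_rejected(self, immigration_death_bundle):
        with pytest.raises(sl.DomainError):
            sl.simulate_ensemble(immigration_death_bundle, 5.0, [], 3, 0)

    def test_isomerization_stationary_mean_is_half_the_tokens(
            self, isomerization_bundle):
        # symmetric A<->B: stationary law of A is Binomial(10, 1/2), mean 5
        summary = sl.simulate_ensemble(
            isomerization_bundle, 20.0, [10.0, 15.0, 20.0], 100, base_seed=5)
        mean_A = summary.mean[:, 0].mean()
        assert mean_A == pytest.approx(5.0, abs=0.5)

    def test_seeds_are_consecutive_and_recorded(self, immigration_death_bundle):
        summary = sl.simulate_ensemble(
            immigration_death_bundle, 1.0, [1.0], 4, base_seed=9)
        assert summary.seeds == [9, 10, 11, 12]


class TestOutputs:
    def test_trajectory_csv_shape(self, immigration_death_bundle):
        traj = sl.simulate(immigration_death_bundle, 2.0, seed=1)
        text = sl.ssa_sim.trajectory_to_csv(traj, ["X"], comments=["seed: 1"])
        lines = text.strip().split("\n")
        assert lines[0] == "# seed: 1"
        assert lines[1] == "time,X"
        assert len(lines) == 2 + len(traj.times)

    def test_trajectory_json_roundtrips_fields(self, immigration_death_bundle):
        import json
        traj = sl.simulate(immigration_death_bundle, 2.0, seed=1)
        doc = json.loads(sl.ssa_sim.trajectory_to_json(traj, ["X"]))
        assert doc["seed"] == 1
        assert doc["times"] == traj.times.tolist()
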