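"""Path probabilities, historical fitness, and the transfer-matrix DP."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from sensegain import (
    EnumerationLimitError,
    History,
    enumerate_histories,
    env_logprob,
    fitness_common,
    fitness_individual,
    historical_fitness,
    kmax_fitness,
    random_model,
    retrospective_phenotype_dist,
    retrospective_sensing_dist,
    sensing_logprob,
    switching_logprob,
)
from sensegain.histories import enumerate_index_paths
from sensegain.models import EnvironmentModel
from sensegain.paths import (
    fitness_common_batch,
    fitness_individual_batch,
    sensing_logprob_batch,
    switching_logprob_batch,
)


def const_rate_model(c: float, sizes=(2, 2, 2), seed=0):
    """Random kernels but a constant log replication rate c."""
    from dataclasses import replace

    from sensegain.models import ReplicationModel

    m = random_model(sizes, seed)
    k = np.full((sizes[0], sizes[1]), c)
    return replace(m, replication=ReplicationModel(k))


class TestLogProbabilities:
    def test_env_point_mass_two_steps(self, demo):
        env = EnvironmentModel(demo.env.transition, np.array([1.0, 0.0, 0.0]))
        assert env_logprob(env, [0, 0]) == pytest.approx(np.log(0.70))

    def test_one_state_environment_has_probability_one(self):
        env = EnvironmentModel(np.ones((1, 1)), np.ones(1))
        assert env_logprob(env, [0] * 6) == 0.0

    def test_sensing_two_correct_signals(self, demo):
        val = sensing_logprob(demo.sensing, [0, 0], [0, 0])
        assert val == pytest.approx(np.log(0.8 * 0.8))

    def test_switching_two_faithful_switches(self, demo):
        val = switching_logprob(demo.switching, [0, 0], [0, 0])
        assert val == pytest.approx(np.log(0.95 * 0.95))

    @pytest.mark.parametrize("t", [0, 2, 4])
    def test_sensing_and_switching_normalize_over_histories(self, demo, t):
        Yt = np.zeros((1, t + 1), dtype=np.intp)
        Zs = enumerate_index_paths(demo.spaces.nz, t)
        Yrep = np.repeat(Yt, Zs.shape[0], axis=0)
        total = np.exp(sensing_logprob_batch(demo.sensing, Zs, Yrep)).sum()
        assert total == pytest.approx(1.0, abs=1e-12)
        Xs = enumerate_index_paths(demo.spaces.nx, t)
        Zfix = np.zeros((Xs.shape[0], t + 1), dtype=np.intp)
        total = np.exp(switching_logprob_batch(demo.switching, Xs, Zfix)).sum()
        assert total == pytest.approx(1.0, abs=1e-12)


class TestHistoricalFitness:
    def test_zero_horizon_is_zero(self, demo):
        assert historical_fitness(demo.replication, [0], [0]) == 0.0

    def test_adapted_path_accumulates_log_rates(self, demo):
        val = historical_fitness(demo.replication, [0, 0], [0, 0])
        assert val == pytest.approx(np.log(2.24))

    def test_constant_rate_gives_t_times_c(self):
        m = const_rate_model(0.37)
        assert historical_fitness(m.replication, [0, 1, 0, 1], [1, 0, 1, 1]) == pytest.approx(
            3 * 0.37
        )

    def test_kmax_fitness_skips_initial_state(self, demo):
        d = demo.decomposition
        assert kmax_fitness(d, [0]) == 0.0
        assert kmax_fitness(d, [2, 0]) == pytest.approx(np.log(5.12))


class TestFitnessDP:
    def test_individual_matches_enumeration_on_demo(self, demo):
        Y = (0, 0, 0)
        assert fitness_individual(demo, Y) == pytest.approx(
            oracles.psi_individual(demo, Y), rel=1e-10
        )

    def test_common_matches_enumeration_on_demo(self, demo):
        Y, Z = (0, 1), (0, 1)
        assert fitness_common(demo, Y, Z) == pytest.approx(
            oracles.psi_common(demo, Y, Z), rel=1e-10
        )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        seed=st.integers(0, 10**6),
        nx=st.integers(1, 3),
        ny=st.integers(1, 3),
        nz=st.integers(1, 3),
        t=st.integers(0, 3),
    )
    def test_dp_equals_exhaustive_path_sum_on_random_models(self, seed, nx, ny, nz, t):
        """Transfer-matrix recursion == brute-force path sums, both sensing modes."""
        m = random_model((nx, ny, nz), seed)
        rng = np.random.default_rng(seed + 1)
        Y = tuple(rng.integers(0, ny, size=t + 1))
        Z = tuple(rng.integers(0, nz, size=t + 1))
        assert fitness_individual(m, Y) == pytest.approx(
            oracles.psi_individual(m, Y), rel=1e-10
        )
        assert fitness_common(m, Y, Z) == pytest.approx(
            oracles.psi_common(m, Y, Z), rel=1e-10
        )

    def test_constant_rate_fitness_is_deterministic_growth(self):
        m = const_rate_model(0.25, seed=3)
        for Y in itertools.product(range(2), repeat=3):
            assert fitness_individual(m, Y) == pytest.approx(2 * 0.25, abs=1e-12)
            assert fitness_common(m, Y, (0, 1, 0)) == pytest.approx(2 * 0.25, abs=1e-12)

    def test_zero_horizon_fitness_is_zero(self, demo):
        assert fitness_individual(demo, (0,)) == pytest.approx(0.0, abs=1e-12)
        assert fitness_common(demo, (1,), (0,)) == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_sensing_collapses_individual_to_common(self):
        """With z forced by y, both recursions see the same signal path."""
        from dataclasses import replace

        from sensegain.models import SensingModel

        m = random_model((2, 2, 2), seed=9)
        forced = SensingModel(kernel=np.eye(2), initial=np.eye(2))
        m = replace(m, sensing=forced)
        Y = (0, 1, 1, 0)
        assert fitness_individual(m, Y) == pytest.approx(fitness_common(m, Y, Y), rel=1e-12)


class TestRetrospectiveDistributions:
    def test_normalized_and_matches_joint_enumeration(self, demo):
        Y = (0, 0, 0, 0)
        ens = retrospective_sensing_dist(demo, Y)
        probs = ens.probabilities()
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)
        oracle = oracles.retrospective_signal(demo, Y)
        for h, p in zip(ens.histories, probs):
            assert p == pytest.approx(oracle[tuple(h.indices)], rel=1e-9)

    def test_no_selection_means_no_retrospective_bias(self):
        """Constant replication rate: PBi equals the forward sensing law."""
        m = const_rate_model(0.4, seed=5)
        Y = (0, 1, 0)
        ens = retrospective_sensing_dist(m, Y)
        for h, lw in zip(ens.histories, ens.log_weights):
            fwd = oracles.path_product_sensing(m, tuple(h.indices), Y)
            assert np.exp(lw) == pytest.approx(fwd, rel=1e-10)

    def test_phenotype_dist_normalized_and_forward_dominates(self, demo):
        Y, Z = (0, 1, 2, 0), (0, 1, 0, 0)
        ens = retrospective_phenotype_dist(demo, Y, Z)
        assert ens.probabilities().sum() == pytest.approx(1.0, abs=1e-9)
        for h, lw in zip(ens.histories, ens.log_weights):
            fwd = oracles.path_product_switching(demo, tuple(h.indices), Z)
            if fwd == 0.0:
                assert np.isneginf(lw)

    def test_constant_rate_phenotype_dist_is_forward_law(self):
        m = const_rate_model(-0.2, seed=6)
        Y, Z = (0, 1, 1), (1, 0, 1)
        ens = retrospective_phenotype_dist(m, Y, Z)
        for h, lw in zip(ens.histories, ens.log_weights):
            fwd = oracles.path_product_switching(m, tuple(h.indices), Z)
            assert np.exp(lw) == pytest.approx(fwd, rel=1e-10)


class TestEnumeration:
    def test_counts_and_lexicographic_order(self):
        hists = enumerate_histories(("a", "b"), 2)
        assert len(hists) == 8
        assert hists[0].labels == ("a", "a", "a")
        assert hists[1].labels == ("a", "a", "b")
        assert hists[-1].labels == ("b", "b", "b")
        assert len(enumerate_histories(("x",), 5)) == 1
        assert len(enumerate_histories(("a", "b", "c"), 5)) == 729

    def test_guard_raises_with_size_message(self):
        with pytest.raises(EnumerationLimitError, match="exceeds the guard"):
            enumerate_histories(("a", "b"), 40)

    def test_history_validates_alphabet(self):
        with pytest.raises(ValueError):
            History(("q",), ("a", "b"))
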