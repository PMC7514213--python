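"""Fitness gain G, fidelity (sigma, gamma), Bayes kernels, directed info, Dloss."""
from dataclasses import replace

import numpy as np
import pytest

import oracles
from sensegain import (
    bayes_kernels,
    directed_information,
    dloss,
    fitness_gain_G,
    gamma_and_pgamma,
    gamma_total,
    pkfs,
    pointwise_directed_info,
    random_decomposed_model,
    random_model,
    sigma_of_history,
)
from sensegain.errors import UnsupportedModelError
from sensegain.histories import enumerate_index_paths
from sensegain.info import average_fitness, pkfs_log_batch, psb_env_logprob_batch, psb_signal_logprob_batch
from sensegain.models import (
    EnvironmentModel,
    SensingModel,
    SwitchingModel,
    AllocationDecomposition,
    ReplicationModel,
    with_known_initial_environment,
)
from sensegain.paths import (
    env_logprob_batch,
    fitness_individual,
    kmax_fitness,
    sensing_logprob_batch,
)


class TestFitnessGain:
    def test_equals_average_fitness_difference(self, demo):
        """G computed as a path-measure average == <Psi_i> - <Psi_c> (t=3)."""
        avg = average_fitness(demo, 3)
        assert fitness_gain_G(demo, 3) == pytest.approx(
            avg["psi_i"] - avg["psi_c"], abs=1e-10
        )

    def test_deterministic_sensing_gives_zero_gain(self):
        m = random_model((2, 2, 2), seed=9)
        m = replace(m, sensing=SensingModel(kernel=np.eye(2), initial=np.eye(2)))
        assert fitness_gain_G(m, 3) == pytest.approx(0.0, abs=1e-12)

    def test_constant_rate_gives_zero_gain(self):
        m = random_model((2, 2, 2), seed=4)
        m = replace(m, replication=ReplicationModel(np.full((2, 2), 0.3)))
        assert fitness_gain_G(m, 3) == pytest.approx(0.0, abs=1e-12)

    def test_non_negative_on_random_models(self, small_random_models):
        for m in small_random_models:
            assert fitness_gain_G(m, 2) >= -1e-12


class TestFidelity:
    def test_pkfs_normalizes_over_allocation_histories(self, demo):
        t = 2
        Ys = enumerate_index_paths(demo.spaces.ny, t)
        actual = np.repeat(np.array([[0, 1, 2]], dtype=np.intp), Ys.shape[0], axis=0)
        total = np.exp(pkfs_log_batch(demo, Ys, actual)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_pkfs_matches_triple_enumeration(self, demo):
        Y = (0, 0, 0, 0)
        assert pkfs(demo, Y, Y) == pytest.approx(
            oracles.pkfs_probability(demo, Y, Y), rel=1e-10
        )
        Yb = (0, 1, 2, 1)  # shares the (unallocated) initial state
        assert pkfs(demo, Yb, Y) == pytest.approx(
            oracles.pkfs_probability(demo, Yb, Y), rel=1e-10
        )

    def test_one_environment_pkfs_is_one(self):
        m = random_decomposed_model((2, 1, 2), seed=3)
        assert pkfs(m, (0, 0, 0), (0, 0, 0)) == pytest.approx(1.0, rel=1e-12)

    def test_sigma_definition_chain(self, demo):
        """sigma = Psi_i - Psi_0 with Psi_0 = Kmax + ln Q, each piece independent."""
        Y = ("s1y", "s1y", "s1y", "s1y")
        Yi = (0, 0, 0, 0)
        sigma = sigma_of_history(demo, Yi)
        psi_i = fitness_individual(demo, Yi)
        km = kmax_fitness(demo.decomposition, Yi)
        lq = float(env_logprob_batch(demo.env, np.array([Yi]))[0])
        assert sigma == pytest.approx(psi_i - km - lq, abs=1e-10)

    def test_gamma_report_internal_identity(self, demo):
        """<sigma>_Q + D[Q||P_gamma] = gamma_t, all three computed separately."""
        rep = gamma_and_pgamma(demo, 3)
        logQ = env_logprob_batch(demo.env, enumerate_index_paths(3, 3))
        q = np.exp(logQ)
        sigma = np.array([rep.sigma_by_history[h.labels] for h in rep.histories])
        mean_sigma = float(np.sum(q * sigma))
        assert rep.p_gamma.sum() == pytest.approx(1.0, abs=1e-10)
        assert mean_sigma + rep.kl_env_pgamma == pytest.approx(rep.gamma_total, abs=1e-10)

    def test_gamma_transfer_matrix_equals_enumeration(self, demo):
        for t in (1, 2, 4):
            rep = gamma_and_pgamma(demo, t)
            assert gamma_total(demo, t) == pytest.approx(rep.gamma_total, abs=1e-10)

    def test_perfect_machinery_gives_uniform_pgamma(self):
        """Deterministic sensing/switching/allocation decodes every history."""
        n = 2
        env = EnvironmentModel(np.full((n, n), 0.5), np.full(n, 0.5))
        sensing = SensingModel(kernel=np.eye(n), initial=np.eye(n))
        switching = SwitchingModel(kernel=np.eye(n), initial=np.eye(n))
        decomp = AllocationDecomposition(kmax=np.zeros(n), allocation=np.eye(n))
        from sensegain.models import ModelBundle, StateSpaces

        m = ModelBundle(
            StateSpaces(("x0", "x1"), ("y0", "y1"), ("z0", "z1")),
            env, sensing, switching, ReplicationModel(decomp.recompose_lograte()), decomp,
        )
        t = 3
        rep = gamma_and_pgamma(m, t)
        assert rep.gamma_total == pytest.approx((t + 1) * np.log(n), abs=1e-10)
        np.testing.assert_allclose(rep.p_gamma, 1.0 / n ** (t + 1), atol=1e-12)


class TestBayesKernels:
    def test_demo_predictive_and_posterior_values(self, demo):
        bk = bayes_kernels(demo)
        assert bk.signal_predictive[0, 0] == pytest.approx(0.8 * 0.7 + 0.2 * 0.25 + 0.5 * 0.05)
        assert bk.env_posterior[0, 0, 0] == pytest.approx(0.8 * 0.7 / 0.635)

    def test_uninformative_sensing_posterior_equals_prior(self):
        m = random_model((2, 3, 2), seed=8)
        uniform = SensingModel(
            kernel=np.full((3, 2), 0.5), initial=np.full((3, 2), 0.5)
        )
        m = replace(m, sensing=uniform)
        bk = bayes_kernels(m)
        for z in range(2):
            np.testing.assert_allclose(bk.env_posterior[:, z, :], m.env.transition, atol=1e-12)

    def test_reconstruction_identity_over_paths(self, small_random_models):
        """PS[Zt||Yt] Q[Yt] = PSB[Yt||Zt] PSB[Zt||Yt-1] for every joint path."""
        for m in small_random_models:
            if not m.sensing.memoryless:
                continue
            bk = bayes_kernels(m)
            t = 2
            Ys = enumerate_index_paths(m.spaces.ny, t)
            Zs = enumerate_index_paths(m.spaces.nz, t)
            Yrep = np.repeat(Ys, Zs.shape[0], axis=0)
            Zrep = np.tile(Zs, (Ys.shape[0], 1))
            lhs = env_logprob_batch(m.env, Yrep) + sensing_logprob_batch(m.sensing, Zrep, Yrep)
            rhs = psb_env_logprob_batch(bk, Yrep, Zrep) + psb_signal_logprob_batch(bk, Zrep, Yrep)
            np.testing.assert_allclose(np.exp(lhs), np.exp(rhs), atol=1e-12)

    def test_sensing_with_memory_is_rejected(self):
        m = random_model((2, 2, 2), seed=1, memoryless=False)
        with pytest.raises(UnsupportedModelError):
            bayes_kernels(m)


class TestDirectedInformation:
    def test_uninformative_sensing_gives_zero(self):
        m = random_model((2, 3, 2), seed=8)
        m = replace(
            m,
            sensing=SensingModel(kernel=np.full((3, 2), 0.5), initial=np.full((3, 2), 0.5)),
        )
        assert directed_information(m, 3) == pytest.approx(0.0, abs=1e-12)
        assert pointwise_directed_info(m, (0, 1, 0), (1, 1, 2)) == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_sensing_iid_uniform_env_gives_entropy(self):
        """Perfect sensing of a fair-coin environment: ln 2 per time point."""
        env = EnvironmentModel(np.full((2, 2), 0.5), np.full(2, 0.5))
        m = random_model((2, 2, 2), seed=2)
        m = replace(m, env=env, sensing=SensingModel(kernel=np.eye(2), initial=np.eye(2)))
        assert directed_information(m, 1) == pytest.approx(2 * np.log(2), abs=1e-12)

    def test_non_negative_on_random_models(self, small_random_models):
        for m in small_random_models:
            if m.sensing.memoryless:
                assert directed_information(m, 2) >= -1e-12


class TestDloss:
    def test_non_negative_on_demo(self, demo):
        assert dloss(demo, 3) >= 0.0

    def test_balance_identity_on_random_models(self, small_decomposed_models):
        """<Psi_i> = <Psi_0> + I + G - Dloss, every term computed separately."""
        for m in small_decomposed_models:
            t = 2
            avg = average_fitness(m, t)
            lhs = avg["psi_i"]
            rhs = avg["psi_0"] + directed_information(m, t) + fitness_gain_G(m, t) - dloss(m, t)
            assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_zero_at_bayes_optimum_with_known_initial_state(self):
        from sensegain import optimal_strategy

        m = with_known_initial_environment(random_decomposed_model((2, 2, 2), seed=21), 0)
        mopt = optimal_strategy(m).apply(m)
        assert dloss(mopt, 3) == pytest.approx(0.0, abs=1e-10)
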