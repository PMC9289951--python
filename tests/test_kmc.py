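"""Stochastic engines: single steps, recrossing samplers, full ensembles."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

import ktnfpt as kf
from ktnfpt.kmc import _multinormal_counts


class TestKmcStep:
    def test_two_state_always_absorbs_with_exponential_waiting(
        self, two_state_k2, rng
    ):
        rm = two_state_k2.rm
        waits = []
        for _ in range(10_000):
            nxt, w = kf.kmc_step(rm, 1, rng)
            assert nxt == 2
            waits.append(w)
        mean = np.mean(waits)
        stderr = 0.5 / np.sqrt(len(waits))
        assert abs(mean - 0.5) < 3 * stderr

    def test_branching_frequencies_match_probabilities(self):
        rng = np.random.default_rng(2)
        # middle of an asymmetric chain: P = (0.25, 0.75)
        ktn = kf.KTN(
            [kf.Minimum(1, 0.0), kf.Minimum(2, 0.0), kf.Minimum(3, 0.0)],
            [
                kf.TransitionState(1, np.log(4) , 1, 2),   # slow exit to 1
                kf.TransitionState(2, np.log(4 / 3), 2, 3) # fast exit to 3
            ],
        )
        rm = kf.build_rate_model(ktn, 1.0)
        p1 = rm.branching(1, 2)
        assert p1 == pytest.approx(0.25, rel=1e-12)
        n = 100_000
        hits = sum(kf.kmc_step(rm, 2, rng)[0] == 1 for _ in range(n))
        stderr = np.sqrt(0.25 * 0.75 / n)
        assert abs(hits / n - 0.25) < 3 * stderr

    def test_fixed_seed_reproducible(self, two_state_k2):
        a = kf.kmc_step(two_state_k2.rm, 1, np.random.default_rng(7))
        b = kf.kmc_step(two_state_k2.rm, 1, np.random.default_rng(7))
        assert a == b


class TestStandardEnsemble:
    def test_two_state_mean_fpt(self, two_state_k2):
        ens = kf.run_standard_kmc(two_state_k2, 100_000, 11)
        stderr = 0.5 / np.sqrt(len(ens))
        assert abs(ens.t.mean() - 0.5) < 3 * stderr
        assert np.all(ens.end == 2)
        assert np.all(ens.s == 1)

    def test_three_chain_mean_fpt(self, three_chain_problem):
        ens = kf.run_standard_kmc(three_chain_problem, 100_000, 13)
        stderr = ens.t.std() / np.sqrt(len(ens))
        assert abs(ens.t.mean() - 3.0) < 3 * stderr

    def test_reproducible_given_seed(self, three_chain_problem):
        a = kf.run_standard_kmc(three_chain_problem, 100, 5)
        b = kf.run_standard_kmc(three_chain_problem, 100, 5)
        np.testing.assert_array_equal(a.t, b.t)
        np.testing.assert_array_equal(a.s, b.s)

    def test_step_budget_censors_and_reports(self, fixture_problem_T2):
        ens = kf.run_standard_kmc(fixture_problem_T2, 200, 3, max_steps=100)
        assert ens.n_censored > 0
        assert len(ens.t) == 200 - ens.n_censored


class TestLeapfrogTables:
    def test_chain_middle_beta_and_exit(self, three_chain_problem):
        tbl = kf.compute_beta(three_chain_problem.rm, three_chain_problem, 2)
        assert tbl.beta == pytest.approx(0.5, rel=1e-12)
        assert tbl.lf_probs == {3: pytest.approx(1.0)}
        # MFPT from the middle node is conserved by tau_lf
        assert tbl.tau_lf == pytest.approx(2.0, rel=1e-12)

    def test_all_absorbing_neighbors_reduce_to_plain_branching(self):
        ktn = kf.KTN(
            [kf.Minimum(i, 0.0) for i in (1, 2, 3)],
            [kf.TransitionState(1, 0.0, 1, 2), kf.TransitionState(2, 0.0, 1, 3)],
        )
        rm = kf.build_rate_model(ktn, 1.0)
        ap = kf.AbsorbingProblem(rm, A={2, 3}, B={1})
        tbl = kf.compute_beta(rm, ap, 1)
        assert tbl.beta == 0.0
        assert tbl.lf_probs[2] == pytest.approx(rm.branching(2, 1))
        assert tbl.lf_probs[3] == pytest.approx(rm.branching(3, 1))

    def test_stable_identity_matches_subtraction_at_moderate_beta(
        self, fixture_problem_T2
    ):
        rm = fixture_problem_T2.rm
        for node in fixture_problem_T2.nonabs:
            tbl = kf.compute_beta(rm, fixture_problem_T2, node)
            if tbl.beta <= 0.9:
                assert tbl.one_minus_beta == pytest.approx(
                    1.0 - tbl.beta, abs=1e-12
                )

    def test_lf_probs_sum_to_one_on_every_fixture_node(self, fixture_problem_T1):
        rm = fixture_problem_T1.rm
        for node in fixture_problem_T1.nonabs:
            tbl = kf.compute_beta(rm, fixture_problem_T1, node)
            assert sum(tbl.lf_probs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_trapped_pair_with_no_escape_raises(self):
        ktn = kf.KTN(
            [kf.Minimum(i, 0.0) for i in (1, 2, 3)],
            [kf.TransitionState(1, 0.0, 1, 2), kf.TransitionState(2, 0.0, 2, 3)],
        )
        rm = kf.build_rate_model(ktn, 1.0)
        ap = kf.AbsorbingProblem(rm, A={3}, B={1})
        # node 1's only neighbor is 2; drop 2->3 flow to fake a closed pair
        rm.P[rm.index[3], rm.index[2]] = 0.0
        rm.P[rm.index[1], rm.index[2]] = 1.0
        with pytest.raises(FloatingPointError, match="no escape"):
            kf.compute_beta(rm, ap, 1)


class TestRecrossSampler:
    def test_zero_beta_always_zero(self, rng):
        assert all(kf.sample_recross_count(0.0, rng) == 0 for _ in range(100))

    def test_geometric_mean_at_half(self, rng):
        n = 200_000
        draws = np.array([kf.sample_recross_count(0.5, rng) for _ in range(n)])
        # mean beta/(1-beta) = 1, var = beta/(1-beta)^2 = 2
        stderr = np.sqrt(2.0 / n)
        assert abs(draws.mean() - 1.0) < 3 * stderr

    def test_inverse_cdf_integerization(self):
        # a fixed uniform draw x = 0.75 at beta = 0.5 inverts to
        # ln(0.25)/ln(0.5) - 1 = 1 exactly; the floor form gives the same
        class Fixed:
            def random(self):
                return 0.75

        assert kf.sample_recross_count(0.5, Fixed()) == 1

    def test_cdf_identity(self, rng):
        # P(N <= n) = 1 - beta^(n+1)
        beta, n = 0.7, 3
        draws = np.array([kf.sample_recross_count(beta, rng) for _ in range(100_000)])
        emp = np.mean(draws <= n)
        expected = 1 - beta ** (n + 1)
        stderr = np.sqrt(expected * (1 - expected) / len(draws))
        assert abs(emp - expected) < 3 * stderr

    def test_beta_at_float_one_with_stable_complement(self, rng):
        # beta rounds to 1.0 in double precision; the stable complement
        # keeps the sampler finite
        n = kf.sample_recross_count(1.0, rng, one_minus_beta=1e-17)
        assert 0 <= n < 2**62

    def test_invalid_beta_rejected(self, rng):
        with pytest.raises(ValueError):
            kf.sample_recross_count(1.0, rng)


class TestAllocation:
    def test_single_neighbor_gets_everything(self, rng):
        np.testing.assert_array_equal(
            kf.allocate_recrossings(7, np.array([1.0]), rng), [7]
        )

    def test_zero_total_gives_zeros(self, rng):
        np.testing.assert_array_equal(
            kf.allocate_recrossings(0, np.array([0.3, 0.7]), rng), [0, 0]
        )

    @pytest.mark.parametrize("force", ["multinomial", "multinormal"])
    def test_moments_match_multinomial(self, force, rng):
        q = np.array([0.3, 0.7])
        N = 10_000
        draws = np.array([
            kf.allocate_recrossings(N, q, rng, force=force) for _ in range(10_000)
        ])
        assert np.all(draws.sum(axis=1) == N)
        assert np.all(draws >= 0)
        mean = draws.mean(axis=0)
        exp_mean = N * q
        exp_std = np.sqrt(N * q * (1 - q))
        stderr = exp_std / np.sqrt(len(draws))
        assert np.all(np.abs(mean - exp_mean) < 3 * stderr)
        # covariance: cov(X1, X2) = -N q1 q2
        cov = np.cov(draws.T)
        assert cov[0, 1] == pytest.approx(-N * q[0] * q[1], rel=0.1)

    def test_multinormal_three_components(self, rng):
        q = np.array([0.2, 0.3, 0.5])
        draws = np.array([
            _multinormal_counts(5000, q, rng) for _ in range(5000)
        ])
        assert np.all(draws.sum(axis=1) == 5000)
        exp_std = np.sqrt(5000 * q * (1 - q))
        stderr = exp_std / np.sqrt(len(draws))
        assert np.all(np.abs(draws.mean(axis=0) - 5000 * q) < 4 * stderr)

    def test_empty_q_with_positive_n_rejected(self, rng):
        with pytest.raises(ValueError):
            kf.allocate_recrossings(3, np.array([]), rng)


class TestLeapfrogStep:
    def test_chain_middle_exits_to_absorber_conserving_mfpt(
        self, three_chain_problem, rng
    ):
        tbl = kf.compute_beta(three_chain_problem.rm, three_chain_problem, 2)
        times = []
        for _ in range(50_000):
            dest, wait, steps = kf.leapfrog_step(three_chain_problem, tbl, rng)
            assert dest == 3
            times.append(wait)
        # MFPT from the middle node is 2 (hand-solved)
        stderr = np.std(times) / np.sqrt(len(times))
        assert abs(np.mean(times) - 2.0) < 3 * stderr

    def test_vanishing_beta_node_reduces_to_two_chained_steps(self, rng):
        # 1 -> 2 -> {3,4} absorbing: a reversible chain always leaves some
        # return probability, so beta is made negligible (~3e-6) with a high
        # barrier back to 1; the leapfrog move is then two chained hops
        ktn = kf.KTN(
            [kf.Minimum(i, 0.0) for i in (1, 2, 3, 4)],
            [
                kf.TransitionState(1, 12.0, 1, 2),
                kf.TransitionState(2, 0.0, 2, 3),
                kf.TransitionState(3, 0.0, 2, 4),
            ],
        )
        rm = kf.build_rate_model(ktn, 1.0)
        ap = kf.AbsorbingProblem(rm, A={3, 4}, B={1})
        tbl = kf.compute_beta(rm, ap, 1)
        assert tbl.beta == pytest.approx(0.0, abs=1e-5)
        lf_times = np.array([
            kf.leapfrog_step(ap, tbl, rng)[1] for _ in range(30_000)
        ])
        # chained standard steps over the same path
        std_times = []
        for _ in range(30_000):
            _, w1 = kf.kmc_step(rm, 1, rng)
            _, w2 = kf.kmc_step(rm, 2, rng)
            std_times.append(w1 + w2)
        ks = ks_2samp(lf_times, std_times)
        assert ks.pvalue > 0.001

    def test_fixed_seed_reproducible(self, three_chain_problem):
        tbl = kf.compute_beta(three_chain_problem.rm, three_chain_problem, 2)
        a = kf.leapfrog_step(three_chain_problem, tbl, np.random.default_rng(3))
        b = kf.leapfrog_step(three_chain_problem, tbl, np.random.default_rng(3))
        assert a == b


class TestLeapfrogEnsemble:
    def test_agrees_with_standard_kmc_distribution(self, fixture_problem_T2):
        n = 30_000
        lf = kf.run_leapfrog_kmc(fixture_problem_T2, n, 21)
        st = kf.run_standard_kmc(fixture_problem_T2, n, 22)
        ks = ks_2samp(np.log(lf.t), np.log(st.t))
        assert ks.pvalue > 0.001

    def test_mean_matches_gt(self, fixture_problem_T1):
        mfpt_gt, _ = kf.gt_mfpt(fixture_problem_T1)
        lf = kf.run_leapfrog_kmc(fixture_problem_T1, 30_000, 23)
        stderr = lf.t.std() / np.sqrt(len(lf.t))
        assert abs(lf.t.mean() - mfpt_gt) < 3 * stderr

    def test_threshold_insensitivity(self, fixture_problem_T2):
        a = kf.run_leapfrog_kmc(fixture_problem_T2, 30_000, 31, threshold=0.1)
        b = kf.run_leapfrog_kmc(fixture_problem_T2, 30_000, 32, threshold=0.9)
        se = np.sqrt(a.t.var() / len(a.t) + b.t.var() / len(b.t))
        assert abs(a.t.mean() - b.t.mean()) < 3 * se

    def test_dynamical_activity_matches_standard(self, fixture_problem_T2):
        lf = kf.run_leapfrog_kmc(fixture_problem_T2, 30_000, 41)
        st = kf.run_standard_kmc(fixture_problem_T2, 30_000, 42)
        se = np.sqrt(lf.s.var() / len(lf.s) + st.s.var() / len(st.s))
        assert abs(lf.s.mean() - st.s.mean()) < 3 * se

    def test_mean_waiting_mode_also_conserves_mfpt(self, fixture_problem_T2):
        mfpt_gt, _ = kf.gt_mfpt(fixture_problem_T2)
        ens = kf.run_leapfrog_kmc(fixture_problem_T2, 30_000, 51, mean_waiting=True)
        stderr = ens.t.std() / np.sqrt(len(ens.t))
        assert abs(ens.t.mean() - mfpt_gt) < 3 * stderr

    def test_reproducible_given_seed(self, fixture_problem_T2):
        a = kf.run_leapfrog_kmc(fixture_problem_T2, 500, 9)
        b = kf.run_leapfrog_kmc(fixture_problem_T2, 500, 9)
        np.testing.assert_array_equal(a.t, b.t)
        np.testing.assert_array_equal(a.s, b.s)

    def test_invalid_threshold_rejected(self, fixture_problem_T2):
        with pytest.raises(ValueError):
            kf.run_leapfrog_kmc(fixture_problem_T2, 10, 1, threshold=1.5)
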