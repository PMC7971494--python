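import numpy as np
import pytest
from scipy import stats

from copulagm.model_core import Hyperparameters, MixedDataset
from copulagm.gibbs_sampler import (
    log_posterior_omega,
    psrf,
    psrf_report,
    rescale_draws,
    run_chain,
    run_chains,
    sample_psi,
    sample_random_effects,
    sample_scaling,
    sample_shrinkage,
    update_precision_column,
)
from conftest import random_spd


def _toy_data(rng, N=60, p=3, m=3):
    values = rng.standard_normal((N, p))
    return MixedDataset(values=values, var_kind=["continuous"] * p,
                        cluster=rng.integers(0, m, N),
                        missing_mask=np.zeros((N, p), dtype=bool))


class TestRandomEffects:
    def test_single_unit_posterior_mean(self, rng):
        # Psi = Omega = I, one unit at z = (2, 0): mean (I + I)^-1 I z = z/2
        data = MixedDataset(values=np.array([[2.0, 0.0]]),
                            var_kind=["continuous"] * 2,
                            cluster=np.array([0]),
                            missing_mask=np.zeros((1, 2), dtype=bool))
        Z = np.array([[2.0, 0.0]])
        draws = np.array([sample_random_effects(Z, data, np.eye(2), np.eye(2), rng)[0]
                          for _ in range(3000)])
        np.testing.assert_allclose(draws.mean(axis=0), [1.0, 0.0], atol=0.06)
        np.testing.assert_allclose(draws.var(axis=0), [0.5, 0.5], atol=0.06)

    def test_diffuse_prior_limit_recovers_cluster_mean(self, rng):
        z = np.array([[1.0, -2.0], [3.0, 0.0], [2.0, -1.0], [2.0, -1.0]])
        data = MixedDataset(values=z, var_kind=["continuous"] * 2,
                            cluster=np.zeros(4, dtype=int),
                            missing_mask=np.zeros((4, 2), dtype=bool))
        draws = np.array([sample_random_effects(z, data, np.eye(2),
                                                1e6 * np.eye(2), rng)[0]
                          for _ in range(2000)])
        np.testing.assert_allclose(draws.mean(axis=0), z.mean(axis=0), atol=0.05)

    def test_empty_cluster_rejected_at_load(self):
        with pytest.raises(ValueError, match="empty cluster"):
            MixedDataset(values=np.zeros((2, 2)), var_kind=["continuous"] * 2,
                         cluster=np.array([0, 2]),
                         missing_mask=np.zeros((2, 2), dtype=bool))


class TestPsiUpdate:
    def test_no_clusters_gives_prior_draw(self, rng):
        Lam = np.diag([2.0, 3.0])
        draws = np.array([sample_psi(np.zeros((0, 2)), 7.0, Lam, rng)
                          for _ in range(4000)])
        # prior mean Lam / (nu - p - 1) = Lam / 4
        np.testing.assert_allclose(draws.mean(axis=0), Lam / 4.0, atol=0.08)

    def test_posterior_mean_matches_inverse_wishart_closed_form(self, rng):
        B = rng.standard_normal((6, 3))
        nu, Lam = 8.0, np.eye(3)
        m, p = B.shape
        expected = (Lam + B.T @ B) / (nu + m - p - 1)
        draws = np.array([sample_psi(B, nu, Lam, rng) for _ in range(4000)])
        got = draws.mean(axis=0)
        assert np.max(np.abs(got - expected) / (np.abs(expected) + 0.1)) < 0.1

    def test_output_always_spd(self, rng):
        for _ in range(50):
            psi = sample_psi(rng.standard_normal((4, 3)), 6.0, np.eye(3), rng)
            assert np.linalg.eigvalsh(psi)[0] > 0

    def test_insufficient_degrees_of_freedom(self, rng):
        with pytest.raises(ValueError):
            sample_psi(np.zeros((0, 3)), 1.0, np.eye(3), rng)


class TestShrinkageUpdate:
    def test_conditional_mean_at_zero_omega(self, rng):
        # omega_ij = 0, s = 0.01, t = 1e-4: mean (1 + s) / t = 10100
        omega = np.eye(2) * 0.0
        draws = np.array([sample_shrinkage(omega, 0.01, 1e-4, rng)[0, 1]
                          for _ in range(4000)])
        # Gamma(1.01, rate 1e-4): sd/sqrt(n) ~ 10050/63
        assert draws.mean() == pytest.approx(10100, abs=3 * 10050 / np.sqrt(4000))

    def test_unit_rate_limit(self, rng):
        omega = np.array([[0.0, 1.0], [1.0, 0.0]])
        draws = np.array([sample_shrinkage(omega, 1e-9, 1e-9, rng)[0, 1]
                          for _ in range(4000)])
        assert draws.mean() == pytest.approx(1.0, abs=3 / np.sqrt(4000))

    def test_conditional_distribution_is_gamma(self, rng):
        s, t, w = 0.01, 1e-4, 0.5
        omega = np.array([[1.0, w], [w, 1.0]])
        draws = np.array([sample_shrinkage(omega, s, t, rng)[0, 1]
                          for _ in range(10_000)])
        ks = stats.kstest(draws, stats.gamma(a=1 + s, scale=1 / (w + t)).cdf)
        assert ks.pvalue > 1e-3

    def test_symmetry_and_positivity(self, rng):
        lam = sample_shrinkage(random_spd(rng, 5), 0.01, 1e-4, rng)
        np.testing.assert_array_equal(lam, lam.T)
        assert np.all(lam > 0)


class TestScalingUpdate:
    def test_support_and_zero_diagonal(self, rng):
        omega = random_spd(rng, 4)
        lam = np.full((4, 4), 2.0)
        tau = sample_scaling(omega, lam, rng)
        assert np.all(np.diag(tau) == 0)
        off = tau[~np.eye(4, dtype=bool)]
        assert np.all(off > 0)

    def test_reciprocal_mean_matches_inverse_gaussian(self, rng):
        # 1/tau is the inverse-Gaussian draw itself: mean lam / |omega|
        lam_v, w = 2.0, 0.5
        p = 450  # ~1e5 upper-triangular elements in one call
        omega = np.full((p, p), w)
        np.fill_diagonal(omega, 1.0)
        lam = np.full((p, p), lam_v)
        tau = sample_scaling(omega, lam, rng)
        iu = np.triu_indices(p, k=1)
        recip = 1.0 / tau[iu]
        n = recip.size
        mu = lam_v / w
        se = np.sqrt(mu ** 3 / lam_v ** 2 / n)  # IG variance mu^3 / shape
        assert n >= 100_000
        assert abs(recip.mean() - mu) < 3 * se

    def test_zero_omega_entry_is_floored(self, rng):
        omega = np.eye(2)  # off-diagonal exactly zero
        tau = sample_scaling(omega, np.full((2, 2), 2.0), rng)
        assert np.isfinite(tau[0, 1]) and tau[0, 1] > 0


class TestPrecisionColumnUpdate:
    def test_prior_only_conditional(self, rng):
        # S = 0, N = 0: gamma ~ Gamma(1, lam22/2), beta ~ N(0, C)
        p, lam22 = 3, 4.0
        omega = np.eye(p)
        lam = np.full((p, p), lam22)
        tau = np.full((p, p), 0.7)
        np.fill_diagonal(tau, 0.0)
        gammas, betas = [], []
        for _ in range(4000):
            out = update_precision_column(omega, np.zeros((p, p)), tau, lam,
                                          2, 0, rng)
            keep = [0, 1]
            b = out[keep, 2]
            gammas.append(out[2, 2] - b @ np.linalg.inv(omega[np.ix_(keep, keep)]) @ b)
            betas.append(b)
        mean_gamma = np.mean(gammas)
        assert mean_gamma == pytest.approx(2 / lam22, abs=3 * (2 / lam22) / np.sqrt(4000))
        np.testing.assert_allclose(np.mean(betas, axis=0), 0.0, atol=0.03)

    def test_output_spd_across_random_updates(self, rng):
        for _ in range(1000):
            p = int(rng.integers(2, 6))
            omega = random_spd(rng, p)
            A = rng.standard_normal((p + 2, p))
            S = A.T @ A
            tau = np.abs(rng.standard_normal((p, p))) + 0.1
            tau = (tau + tau.T) / 2
            np.fill_diagonal(tau, 0.0)
            lam = np.full((p, p), 2.0)
            l = int(rng.integers(p))
            out = update_precision_column(omega, S, tau, lam, l, p + 2, rng)
            assert np.linalg.eigvalsh(out)[0] > 0

    def test_long_run_moments_match_metropolis_oracle(self):
        # p = 2, fixed S / lambda / tau: the repeated column update is an
        # exact Gibbs sampler whose stationary law we can also target with
        # an independent random-walk Metropolis sampler.
        rng = np.random.default_rng(99)
        N = 30
        A = rng.standard_normal((N, 2)) @ np.array([[1.0, 0.4], [0.0, 0.9]])
        S = A.T @ A
        lam = np.array([[2.0, 3.0], [3.0, 2.5]])
        tau_var = 0.4
        tau = np.array([[0.0, tau_var], [tau_var, 0.0]])

        def log_target(w11, w12, w22):
            det = w11 * w22 - w12 * w12
            if det <= 0 or w11 <= 0:
                return -np.inf
            return (0.5 * N * np.log(det)
                    - 0.5 * (S[0, 0] * w11 + 2 * S[0, 1] * w12 + S[1, 1] * w22)
                    - w12 ** 2 / (2 * tau_var)
                    - 0.5 * (lam[0, 0] * w11 + lam[1, 1] * w22))

        # route 1: the package's block Gibbs update
        omega = np.eye(2)
        gibbs = np.empty((20_000, 2))
        for i in range(22_000):
            for l in range(2):
                omega = update_precision_column(omega, S, tau, lam, l, N, rng)
            if i >= 2000:
                gibbs[i - 2000] = omega[0, 1], omega[0, 0]

        # route 2: independent random-walk Metropolis on (w11, w12, w22)
        x = np.array([1.0, 0.0, 1.0])
        lp = log_target(*x)
        mh = np.empty((120_000, 2))
        step = 0.12
        rng2 = np.random.default_rng(7)
        props = rng2.normal(scale=step, size=(140_000, 3))
        logu = np.log(rng2.random(140_000))
        for i in range(140_000):
            cand = x + props[i]
            lp_c = log_target(*cand)
            if lp_c - lp > logu[i]:
                x, lp = cand, lp_c
            if i >= 20_000:
                mh[i - 20_000] = x[1], x[0]

        for k, name in enumerate(("omega12", "omega11")):
            se = (gibbs[:, k].std() / np.sqrt(2000)
                  + mh[:, k].std() / np.sqrt(2000))  # conservative ESS guess
            assert abs(gibbs[:, k].mean() - mh[:, k].mean()) < 4 * se + 0.01, name

    def test_non_finite_block_rejected(self, rng):
        omega = np.eye(3)
        omega[1, 1] = np.inf
        tau = np.full((3, 3), 0.5)
        np.fill_diagonal(tau, 0.0)
        with pytest.raises(ValueError):
            update_precision_column(omega, np.eye(3), tau, np.full((3, 3), 2.0),
                                    0, 5, rng)

    def test_degenerate_block_is_repaired_to_spd(self, rng):
        # a singular Omega_11 block is eigen-clipped rather than fatal
        omega = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        tau = np.full((3, 3), 0.5)
        np.fill_diagonal(tau, 0.0)
        out = update_precision_column(omega, np.eye(3), tau,
                                      np.full((3, 3), 2.0), 0, 5, rng)
        assert np.isfinite(out).all()


class TestRescale:
    def test_identity_halves(self):
        G, P, B = rescale_draws(np.eye(3), np.eye(3), np.ones((2, 3)))
        np.testing.assert_allclose(G, np.eye(3) / 2)
        np.testing.assert_allclose(P, np.eye(3) / 2)
        np.testing.assert_allclose(B, np.ones((2, 3)) / np.sqrt(2))

    def test_idempotent_on_rescaled_input(self, rng):
        G0, P0 = random_spd(rng, 4), random_spd(rng, 4)
        B0 = rng.standard_normal((3, 4))
        G, P, B = rescale_draws(G0, P0, B0)
        np.testing.assert_allclose(np.diag(G) + np.diag(P), 1.0, atol=1e-14)
        G2, P2, B2 = rescale_draws(G, P, B)
        np.testing.assert_allclose(G2, G, atol=1e-14)
        np.testing.assert_allclose(P2, P, atol=1e-14)
        np.testing.assert_allclose(B2, B, atol=1e-14)

    def test_sign_pattern_unchanged(self, rng):
        for _ in range(25):
            G0, P0 = random_spd(rng, 5), random_spd(rng, 5)
            G, P, _ = rescale_draws(G0, P0, np.zeros((1, 5)))
            assert np.array_equal(np.sign(G), np.sign(G0))
            assert np.array_equal(np.sign(P), np.sign(P0))


class TestChains:
    def test_same_seed_bit_identical(self, rng):
        data = _toy_data(rng)
        hp = Hyperparameters(n_iter=40, burn_frac=0.25, thin=2, seed=5)
        d1 = run_chain(data, hp)
        d2 = run_chain(data, hp)
        assert np.array_equal(d1.Omega, d2.Omega)
        assert np.array_equal(d1.B, d2.B)

    def test_single_variable_chain_runs(self, rng):
        values = rng.standard_normal((50, 1))
        data = MixedDataset(values=values, var_kind=["continuous"],
                            cluster=rng.integers(0, 2, 50),
                            missing_mask=np.zeros((50, 1), dtype=bool))
        hp = Hyperparameters(n_iter=30, burn_frac=0.3, thin=1, seed=1)
        d = run_chain(data, hp)
        assert d.Omega.shape[1:] == (1, 1)
        assert np.all(d.Omega > 0)

    def test_draws_live_on_identified_scale(self, rng):
        data = _toy_data(rng)
        hp = Hyperparameters(n_iter=40, burn_frac=0.25, thin=2, seed=5)
        d = run_chain(data, hp)
        for k in range(d.n_draws):
            np.testing.assert_allclose(
                np.diag(d.Gamma[k]) + np.diag(d.Psi[k]), 1.0, atol=1e-10)
            assert np.linalg.eigvalsh(d.Gamma[k])[0] > 0
            np.testing.assert_allclose(
                d.Omega[k] @ d.Gamma[k], np.eye(3), atol=1e-8)

    def test_run_chains_produces_report(self, rng):
        data = _toy_data(rng)
        hp = Hyperparameters(n_iter=60, burn_frac=0.5, thin=1, seed=9,
                             n_chains=2)
        draws_list, report = run_chains(data, hp)
        assert len(draws_list) == 2
        # chains must genuinely differ
        assert not np.array_equal(draws_list[0].Omega, draws_list[1].Omega)
        assert set(report.matrix) == {"Omega", "Psi"}
        assert "frac_above" in report.attrs


class TestPSRF:
    def test_identical_chains_give_one(self):
        x = np.sin(np.arange(200.0))
        assert psrf(np.stack([x, x, x])) == pytest.approx(1.0, abs=1e-6)

    def test_separated_chains_explode(self, rng):
        a = rng.standard_normal(300)
        assert psrf(np.stack([a, a + 50.0])) > 10

    def test_white_noise_near_one(self, rng):
        chains = rng.standard_normal((3, 1000))
        assert psrf(chains) == pytest.approx(1.0, abs=0.05)


class TestLogPosterior:
    def test_outside_cone_is_minus_inf(self):
        S = np.eye(2)
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        assert log_posterior_omega(bad, S, 10, 1.0) == -np.inf

    def test_penalty_direction(self):
        S = np.eye(2) * 10
        om = np.array([[1.0, 0.4], [0.4, 1.0]])
        dense = log_posterior_omega(om, S, 10, 0.1)
        denser_penalty = log_posterior_omega(om, S, 10, 10.0)
        assert denser_penalty < dense
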