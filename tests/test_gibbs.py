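"""Gibbs full conditionals against brute-force conjugate/joint-Gaussian oracles."""

import numpy as np
import pytest
from scipy.integrate import quad

from mogpfa import kernel, simulate
from mogpfa.gibbs import (
    FactorBlockCache,
    GibbsConfig,
    _PanelCache,
    _PatternOps,
    posterior_predictive,
    run_gibbs,
    update_factor_block,
    update_loadings,
    update_means_and_noise,
)
from mogpfa.model import BiomarkerPanel, LatentState, PriorConfig, model_mean

from conftest import exact_factor_conditional, make_state


def repeat_update(update, state, n, rng, pick):
    """Apply a conditional update repeatedly from the same start; collect stats."""
    out = []
    for _ in range(n):
        st = state.copy()
        update(st, rng)
        out.append(pick(st))
    return np.asarray(out)


class TestMeansAndNoise:
    def test_mu_conjugate_update(self, tiny_panel, tiny_state, tiny_priors, rng):
        i, g = 0, 1
        draws = repeat_update(
            lambda st, r: update_means_and_noise(st, tiny_panel, tiny_priors, r),
            tiny_state, 4000, rng, lambda st: st.M[i, g],
        )
        s = tiny_state
        resid = tiny_panel.X[i][g] - (s.L @ s.Yaug[i][:, tiny_panel.obs_idx[i]])[g]
        prec = 1 / s.sigma2[g] + tiny_panel.q_i[i] / s.phi2[g]
        mean = (tiny_priors.mu_g[g] / s.sigma2[g] + resid.sum() / s.phi2[g]) / prec
        se = 1 / np.sqrt(prec * 4000)
        assert abs(draws.mean() - mean) < 4 * se
        assert draws.var() == pytest.approx(1 / prec, rel=0.15)

    def test_prior_dominated_limit(self, tiny_panel, tiny_state, tiny_priors, rng):
        tiny_state.sigma2[:] = 1e-12
        update_means_and_noise(tiny_state, tiny_panel, tiny_priors, rng)
        assert np.allclose(tiny_state.M, tiny_priors.mu_g[None, :], atol=1e-4)

    def test_variance_updates_match_inverse_gamma_moments(
        self, tiny_panel, tiny_state, tiny_priors, rng
    ):
        n_rep = 6000
        sig = repeat_update(
            lambda st, r: update_means_and_noise(st, tiny_panel, tiny_priors, r),
            tiny_state, n_rep, rng, lambda st: st.sigma2[0],
        )
        # sigma2 drawn after M: E[sigma2 | M] = (d2 + .5 sum (M-mu)^2)/(c2 + n/2 - 1);
        # average over the M draw by iterated expectation via the sampled pairs
        phi = repeat_update(
            lambda st, r: update_means_and_noise(st, tiny_panel, tiny_priors, r),
            tiny_state, n_rep, rng,
            lambda st: (st.phi2[0],
                        float(sum(((tiny_panel.X[i][0]
                                    - model_mean(st, tiny_panel, i)[0]) ** 2).sum()
                                  for i in range(tiny_panel.n)))),
        )
        shape = tiny_priors.c3 + 0.5 * tiny_panel.q_i.sum()
        want = (tiny_priors.d3 + 0.5 * phi[:, 1]) / (shape - 1)
        assert phi[:, 0].mean() == pytest.approx(want.mean(), rel=0.1)
        assert np.isfinite(sig).all() and (sig > 0).all()


class TestLoadings:
    def _one_point_model(self):
        panel = BiomarkerPanel(["s"], ["g"], np.array([0.0]),
                               [np.array([0])], [np.array([[1.7]])])
        state = LatentState(
            A=np.array([[0.4]]), Z=np.array([[1]]), M=np.array([[0.2]]),
            Yaug=np.array([[[0.9]]]), pi=np.array([0.3]), rho2=np.array([1.5]),
            sigma2=np.array([1.0]), phi2=np.array([0.3]),
        )
        priors = PriorConfig(c0=2, d0=2, mu_g=np.array([0.2]))
        return panel, state, priors

    def test_inclusion_probability_matches_enumeration_oracle(self, rng):
        panel, state, priors = self._one_point_model()
        x, mu, y = 1.7, 0.2, 0.9
        rho2, phi2, pi = 1.5, 0.3, 0.3

        def lik(A):
            return np.exp(-0.5 * (x - mu - A * y) ** 2 / phi2) / np.sqrt(
                2 * np.pi * phi2
            )

        marg1, _ = quad(
            lambda A: lik(A) * np.exp(-0.5 * A**2 / rho2) / np.sqrt(2 * np.pi * rho2),
            -np.inf, np.inf,
        )
        marg0 = lik(0.0)
        p1 = pi * marg1 / (pi * marg1 + (1 - pi) * marg0)
        n_rep = 8000
        zs = repeat_update(
            lambda st, r: update_loadings(st, panel, priors, r),
            state, n_rep, rng, lambda st: st.Z[0, 0],
        )
        se = np.sqrt(p1 * (1 - p1) / n_rep)
        assert abs(zs.mean() - p1) < 4 * se

    def test_no_signal_and_vanishing_pi_excludes(self, rng):
        panel, state, priors = self._one_point_model()
        state.pi[:] = 1e-8
        state.Yaug[:] = 0.0   # zero residual correlation with the factor
        zs = repeat_update(
            lambda st, r: update_loadings(st, panel, priors, r),
            state, 500, rng, lambda st: st.Z[0, 0],
        )
        assert zs.mean() == 0.0

    def test_pi_update_count_bookkeeping(self, rng):
        ds = simulate.generate(
            simulate.SimConfig(n=4, p=6, k=1, correlation=np.eye(1)), seed=0
        )
        state = make_state(ds.panel, 1, rng)
        priors = PriorConfig(c0=2.0, d0=3.0, mu_g=ds.panel.biomarker_means())
        state.Yaug[:] = 0.0
        state.pi[:] = 1 - 1e-12   # forces Z to stay all ones
        pis = repeat_update(
            lambda st, r: update_loadings(st, ds.panel, priors, r),
            state, 4000, rng, lambda st: st.pi[0],
        )
        # Beta(c0 + p, d0) once every biomarker is included
        want = (2.0 + 6) / (2.0 + 6 + 3.0)
        assert pis.mean() == pytest.approx(want, abs=0.02)

    def test_slab_draw_matches_conjugate_normal(self, rng):
        panel, state, priors = self._one_point_model()
        state.pi[:] = 1 - 1e-12
        a_draws = repeat_update(
            lambda st, r: update_loadings(st, panel, priors, r),
            state, 6000, rng, lambda st: st.A[0, 0],
        )
        P = 1 / 1.5 + 0.9**2 / 0.3
        m = ((1.7 - 0.2) * 0.9 / 0.3) / P
        assert a_draws.mean() == pytest.approx(m, abs=4 / np.sqrt(P * 6000))
        assert a_draws.var() == pytest.approx(1 / P, rel=0.1)


class TestFactorBlock:
    def test_scalar_conjugacy(self, rng):
        panel = BiomarkerPanel(["s"], ["g"], np.array([0.0]),
                               [np.array([0])], [np.array([[2.0]])])
        th = kernel.MOGPHyperparams(
            (kernel.FactorKernelParams(0.9, 0.3, 1.0, 1.0),), 0.05, (0.4,)
        )
        var0 = kernel.stationary_variance(th.per_factor[0], 0.05)
        state = LatentState(
            A=np.array([[1.5]]), Z=np.array([[1]]), M=np.array([[0.1]]),
            Yaug=np.zeros((1, 1, 1)), pi=np.array([0.5]), rho2=np.array([1.0]),
            sigma2=np.array([1.0]), phi2=np.array([0.2]),
        )
        cache = FactorBlockCache(th, panel)
        draws = repeat_update(
            lambda st, r: update_factor_block(st, panel, cache, 0, r),
            state, 8000, rng, lambda st: st.Yaug[0, 0, 0],
        )
        prec = 1 / var0 + 1.5**2 / 0.2
        mean = (0.4 / var0 + 1.5 * (2.0 - 0.1) / 0.2) / prec
        assert draws.mean() == pytest.approx(mean, abs=4 / np.sqrt(prec * 8000))
        assert draws.var() == pytest.approx(1 / prec, rel=0.1)

    def test_block_update_matches_joint_gaussian_oracle(self, rng, theta_k2):
        panel = BiomarkerPanel(
            ["s"], ["g1", "g2", "g3"], np.array([0.0, 1.0, 2.5]),
            [np.array([0, 2])], [rng.normal(loc=1.0, size=(3, 2))],
        )
        state = make_state(panel, 2, rng)
        cache = FactorBlockCache(theta_k2, panel)
        n_rep = 20000
        draws = repeat_update(
            lambda st, r: update_factor_block(st, panel, cache, 0, r),
            state, n_rep, rng, lambda st: st.Yaug[0].reshape(-1),
        )
        mean, cov = exact_factor_conditional(panel, state, theta_k2, 0)
        se = np.sqrt(np.diag(cov) / n_rep)
        assert np.all(np.abs(draws.mean(0) - mean) < 4 * se)
        emp_cov = np.cov(draws.T)
        assert np.allclose(emp_cov, cov, atol=6 * np.abs(cov).max() / np.sqrt(n_rep))

    def test_no_observation_pattern_draws_from_prior(self, rng, theta_k2):
        grid = np.array([0.0, 1.0])
        sigma = kernel.build_covariance(theta_k2, grid)
        mean = kernel.mean_vector(theta_k2, 2)
        ops = _PatternOps(sigma, mean, np.array([], dtype=int), 2, 2)
        assert ops.A_cond is None and ops.qi == 0
        draws = mean[:, None] + ops.prior_chol @ rng.standard_normal((4, 20000))
        assert np.allclose(draws.mean(1), mean, atol=4 * np.sqrt(np.diag(sigma) / 20000))
        assert np.allclose(np.cov(draws), sigma, atol=0.08)

    def test_noiseless_limit_concentrates_on_truth(self, rng, theta_k2):
        # loadings dense in both columns so every factor is identified
        grid = np.arange(8.0)
        L = rng.normal(2.0, 0.5, size=(12, 2)) * rng.choice([-1, 1], size=(12, 2))
        cov = kernel.build_covariance(theta_k2, grid)
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(16))
        Ytrue = [(chol @ rng.standard_normal(16)).reshape(2, 8) for _ in range(3)]
        M = rng.normal(size=(3, 12))
        panel = BiomarkerPanel(
            [f"s{i}" for i in range(3)], [f"g{g}" for g in range(12)], grid,
            [np.arange(8)] * 3,
            [M[i][:, None] + L @ Ytrue[i] for i in range(3)],
        )
        state = make_state(panel, 2, rng)
        state.A, state.Z, state.M = L, np.ones((12, 2), int), M
        state.phi2[:] = 1e-10
        cache = FactorBlockCache(theta_k2, panel)
        for i in range(3):
            update_factor_block(state, panel, cache, i, rng)
            assert np.allclose(state.Yaug[i], Ytrue[i], atol=1e-3)


class TestRunGibbs:
    def test_fixed_seed_reproduces_chain(self, theta_k2):
        ds = simulate.generate(
            simulate.SimConfig(n=4, p=6, k=2, y_mode="mogp", theta=theta_k2), seed=1
        )
        priors = PriorConfig.default(ds.panel)
        cfg = GibbsConfig(n_iter=30, thin=2, n_chains=2, seed=99)
        s1 = run_gibbs(ds.panel, theta_k2, priors, cfg)
        s2 = run_gibbs(ds.panel, theta_k2, priors, cfg)
        for c in range(2):
            assert np.array_equal(s1.chains[c]["L"], s2.chains[c]["L"])
            assert np.array_equal(s1.chains[c]["Yaug"], s2.chains[c]["Yaug"])
        assert not np.array_equal(s1.chains[0]["L"], s1.chains[1]["L"])

    def test_sample_frames_carry_chain_and_draw_indices(self, theta_k2):
        ds = simulate.generate(
            simulate.SimConfig(n=3, p=4, k=2, y_mode="mogp", theta=theta_k2), seed=1
        )
        priors = PriorConfig.default(ds.panel)
        s = run_gibbs(ds.panel, theta_k2, priors,
                      GibbsConfig(n_iter=20, thin=2, n_chains=2, seed=0))
        lf = s.loadings_frame(ds.panel.biomarkers)
        n_draws = s.n_draws()
        assert len(lf) == 2 * n_draws * 4 * 2
        assert set(lf["chain"]) == {0, 1}
        sf = s.scores_frame(ds.panel.subjects, ds.panel.grid)
        assert len(sf) == 2 * n_draws * 3 * 2 * ds.panel.q

    def test_loading_recovery_improves_with_n(self, theta_k2):
        from mogpfa.align import align_draws, enumerate_signed_permutations
        from mogpfa.gibbs import init_state_data_driven

        maes = []
        for n in (6, 60):
            ds = simulate.generate(
                simulate.SimConfig(n=n, p=20, k=2, y_mode="mogp", theta=theta_k2),
                seed=8,
            )
            priors = PriorConfig.default(ds.panel)
            init = init_state_data_driven(ds.panel, 2, priors, theta_k2,
                                          np.random.default_rng(0))
            samples = run_gibbs(ds.panel, theta_k2, priors,
                                GibbsConfig(n_iter=250, thin=2, seed=4),
                                init_state=init)
            align_draws(samples)
            Lhat = samples.chains[0]["L"].mean(axis=0)
            best = min(
                np.abs(
                    Lhat[:, list(sp.perm)] * np.asarray(sp.signs)[None, :]
                    - ds.truth.L
                ).mean()
                for sp in enumerate_signed_permutations(2)
            )
            maes.append(best)
        assert maes[1] < maes[0]


class TestPosteriorPredictive:
    def _samples(self, panel, theta, n_iter=60):
        priors = PriorConfig.default(panel)
        return run_gibbs(panel, theta, priors, GibbsConfig(n_iter=n_iter, seed=2))

    def test_single_draw_band_width_zero(self, theta_k2):
        ds = simulate.generate(
            simulate.SimConfig(n=3, p=5, k=2, y_mode="mogp", theta=theta_k2), seed=3
        )
        samples = self._samples(ds.panel, theta_k2, n_iter=26)
        for c in samples.chains:
            for f in c:
                c[f] = c[f][-1:]
        band = posterior_predictive(samples, theta_k2, ds.panel,
                                    ds.panel.subjects[0], ds.panel.biomarkers[0],
                                    ds.panel.grid)
        assert np.allclose(band["lower"], band["upper"])
        assert np.allclose(band["median"], band["lower"])

    def test_zero_loadings_center_on_subject_mean(self, theta_k2):
        ds = simulate.generate(
            simulate.SimConfig(n=3, p=5, k=2, y_mode="mogp", theta=theta_k2), seed=3
        )
        samples = self._samples(ds.panel, theta_k2, n_iter=40)
        for c in samples.chains:
            c["L"] = np.zeros_like(c["L"])
        band = posterior_predictive(samples, theta_k2, ds.panel, 0, 1, ds.panel.grid)
        mus = samples.chains[0]["M"][:, 0, 1]
        assert np.allclose(band["median"], np.median(mus))

    def test_off_grid_times_interpolate(self, theta_k2):
        ds = simulate.generate(
            simulate.SimConfig(n=3, p=5, k=2, y_mode="mogp", theta=theta_k2), seed=3
        )
        samples = self._samples(ds.panel, theta_k2, n_iter=40)
        grid = np.array([0.5, 3.25, 9.75])
        band = posterior_predictive(samples, theta_k2, ds.panel, 0, 0, grid)
        assert np.isfinite(band["median"]).all()
        assert np.all(band["lower"] <= band["upper"])

    def test_credible_band_covers_true_trajectories(self, theta_k2):
        """Pointwise 95% bands cover well over 90% of true mean-curve points
        on well-specified synthetic data."""
        ds = simulate.generate(
            simulate.SimConfig(n=16, p=10, k=2, y_mode="mogp", theta=theta_k2),
            seed=1,
        )
        priors = PriorConfig.default(ds.panel)
        samples = run_gibbs(ds.panel, theta_k2, priors,
                            GibbsConfig(n_iter=500, burn_in_frac=0.3, thin=2,
                                        seed=1))
        inside = total = 0
        for i in range(0, 16, 2):
            for g in range(0, 10, 2):
                band = posterior_predictive(samples, theta_k2, ds.panel, i, g,
                                            ds.panel.grid, seed=1)
                tc = ds.truth.M[i, g] + ds.truth.L[g] @ ds.truth.Y[i]
                inside += int(((tc >= band["lower"]) & (tc <= band["upper"])).sum())
                total += tc.size
        assert inside / total >= 0.90

    def test_unknown_subject_rejected(self, theta_k2):
        ds = simulate.generate(
            simulate.SimConfig(n=3, p=5, k=2, y_mode="mogp", theta=theta_k2), seed=3
        )
        samples = self._samples(ds.panel, theta_k2, n_iter=26)
        with pytest.raises(KeyError):
            posterior_predictive(samples, theta_k2, ds.panel, "nope", 0, ds.panel.grid)
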