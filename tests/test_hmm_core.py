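import numpy as np
import pandas as pd
import pytest
from scipy import integrate, special, stats

from divehmm import hmm_core as hc
from divehmm.hmm_core import (
    EmissionParams,
    HMMParameters,
    ModelSpec,
    TransitionCoefficients,
    emission_logdensity,
    fit,
    forward_loglik,
    gamma_shape_scale,
    gamma_logpdf_musigma,
    natural_from_working,
    relabel_states,
    stationary_distribution,
    transition_matrix,
    vonmises_logdensity,
    working_from_natural,
)

from conftest import brute_force_loglik, make_obs_frame, make_params


class TestGammaShapeScale:
    def test_algebra(self):
        assert gamma_shape_scale(2.0, 1.0) == (4.0, 0.5)

    def test_exponential_boundary(self):
        shape, _ = gamma_shape_scale(3.0, 3.0)
        assert shape == pytest.approx(1.0)

    def test_round_trip(self, rng):
        mu = rng.uniform(0.5, 50, 20)
        sigma = rng.uniform(0.1, 20, 20)
        shape, scale = gamma_shape_scale(mu, sigma)
        np.testing.assert_allclose(shape * scale, mu, rtol=1e-12)
        np.testing.assert_allclose(np.sqrt(shape) * scale, sigma, rtol=1e-12)

    def test_nonpositive_raises(self):
        with pytest.raises(ValueError):
            gamma_shape_scale(-1.0, 1.0)
        with pytest.raises(ValueError):
            gamma_shape_scale(1.0, 0.0)

    def test_logpdf_matches_scipy(self, rng):
        x = rng.gamma(4, 3, 50)
        mu, sigma = 11.0, 4.5
        a, s = gamma_shape_scale(mu, sigma)
        np.testing.assert_allclose(
            gamma_logpdf_musigma(x, mu, sigma),
            stats.gamma.logpdf(x, a, scale=s),
            rtol=1e-12,
        )


class TestVonMises:
    def test_uniform_limit(self):
        assert np.exp(vonmises_logdensity(1.234, 0.0, 0.0)) == pytest.approx(
            1 / (2 * np.pi)
        )

    def test_symmetry(self):
        m = 0.7
        for a in [0.1, 0.5, 2.0]:
            assert vonmises_logdensity(m + a, m, 1.7) == pytest.approx(
                vonmises_logdensity(m - a, m, 1.7)
            )

    def test_mode_value_kappa_one(self):
        expected = np.e / (2 * np.pi * special.i0(1.0))
        assert np.exp(vonmises_logdensity(0.3, 0.3, 1.0)) == pytest.approx(expected)
        assert expected == pytest.approx(0.3417, abs=5e-4)

    def test_integrates_to_one(self):
        val, _ = integrate.quad(
            lambda a: np.exp(vonmises_logdensity(a, 0.8, 2.5)), -np.pi, np.pi
        )
        assert val == pytest.approx(1.0, abs=1e-9)

    def test_matches_scipy(self, rng):
        x = rng.uniform(-np.pi, np.pi, 30)
        np.testing.assert_allclose(
            vonmises_logdensity(x, 0.4, 2.2),
            stats.vonmises.logpdf(x, 2.2, loc=0.4),
            rtol=1e-10,
        )

    def test_large_kappa_stable(self):
        assert np.isfinite(vonmises_logdensity(0.0, 0.0, 1e6))


class TestEmissionLogdensity:
    def test_all_missing_is_zero(self):
        params = make_params()
        assert emission_logdensity({}, params.emission, 0) == 0.0

    def test_single_channel_additivity(self):
        params = make_params()
        em = params.emission
        v = emission_logdensity({"max_depth": 8.0}, em, 1)
        assert v == pytest.approx(
            float(gamma_logpdf_musigma(8.0, em.mu[1, 0], em.sigma[1, 0]))
        )

    def test_product_oracle(self, rng):
        params = make_params(seed=3)
        em = params.emission
        obs = {
            "max_depth": 9.0,
            "dive_duration": 30.0,
            "surface_duration": 22.0,
            "step_length": 40.0,
            "turning_angle": 0.5,
        }
        total = emission_logdensity(obs, em, 2)
        logdens = 0.0
        for c, name in enumerate(
            ("max_depth", "dive_duration", "surface_duration", "step_length")
        ):
            a, s = gamma_shape_scale(em.mu[2, c], em.sigma[2, c])
            logdens += stats.gamma.logpdf(obs[name], a, scale=s)
        logdens += stats.vonmises.logpdf(
            obs["turning_angle"], em.angle_kappa[2], loc=em.angle_mean[2]
        )
        assert total == pytest.approx(logdens, rel=1e-10)

    def test_nonpositive_gamma_value_raises(self):
        params = make_params()
        with pytest.raises(ValueError):
            emission_logdensity({"max_depth": -1.0}, params.emission, 0)


class TestTransitionMatrix:
    def test_zero_beta_uniform(self):
        G = transition_matrix(np.zeros((3, 3, 1)), [])
        np.testing.assert_allclose(G, np.full((3, 3), 1 / 3), atol=1e-14)

    def test_large_negative_intercepts_identity(self):
        beta = np.zeros((3, 3, 1))
        beta[:, :, 0] = -50.0
        G = transition_matrix(beta, [])
        np.testing.assert_allclose(G, np.eye(3), atol=1e-12)

    def test_two_state_scalar_logistic(self):
        beta = np.zeros((2, 2, 1))
        beta[0, 1, 0] = 0.5
        beta[1, 0, 0] = -1.0
        G = transition_matrix(beta, [])
        e = np.exp(0.5)
        np.testing.assert_allclose(G[0], [1 / (1 + e), e / (1 + e)], rtol=1e-12)
        np.testing.assert_allclose(
            G[1], [np.exp(-1) / (1 + np.exp(-1)), 1 / (1 + np.exp(-1))], rtol=1e-12
        )
        assert G[0, 0] == pytest.approx(0.3775, abs=5e-5)
        assert G[1, 0] == pytest.approx(0.2689, abs=5e-5)

    def test_rows_sum_to_one(self, rng):
        for _ in range(20):
            beta = rng.normal(0, 2, size=(3, 3, 4))
            z = rng.normal(size=3)
            G = transition_matrix(beta, z)
            np.testing.assert_allclose(G.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(G > 0) and np.all(G < 1)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            transition_matrix(np.zeros((3, 3, 2)), [0.1, 0.2])

    def test_overflow_safe(self):
        beta = np.zeros((3, 3, 2))
        beta[0, 1] = [500.0, 300.0]
        G = transition_matrix(beta, [2.0])
        assert np.all(np.isfinite(G))
        np.testing.assert_allclose(G.sum(axis=1), 1.0)


class TestStationaryDistribution:
    def test_uniform(self):
        pi = stationary_distribution(np.full((3, 3), 1 / 3))
        np.testing.assert_allclose(pi, [1 / 3] * 3, atol=1e-12)

    def test_identity_raises(self):
        with pytest.raises(ValueError, match="not unique"):
            stationary_distribution(np.eye(3))

    def test_two_state_closed_form(self):
        a, b = 0.2, 0.1
        G = np.array([[1 - a, a], [b, 1 - b]])
        np.testing.assert_allclose(
            stationary_distribution(G), [b / (a + b), a / (a + b)], atol=1e-12
        )
        np.testing.assert_allclose(stationary_distribution(G), [1 / 3, 2 / 3], atol=1e-12)

    def test_fixed_point(self, rng):
        G = transition_matrix(rng.normal(0, 1, (3, 3, 1)), [])
        pi = stationary_distribution(G)
        np.testing.assert_allclose(pi @ G, pi, atol=1e-12)
        assert pi.sum() == pytest.approx(1.0)


class TestForwardLoglik:
    def test_single_batch_closed_form(self):
        params = make_params(n_states=2, seed=7)
        params = HMMParameters(params.emission, params.transition, "uniform")
        df = make_obs_frame(2, 0, 1, seed=7, missing_angle_first=False)
        ll = forward_loglik(params, df)
        dens = 0.0
        obs = df.iloc[0][
            ["max_depth", "dive_duration", "surface_duration", "step_length", "turning_angle"]
        ].to_dict()
        for i in range(2):
            dens += 0.5 * np.exp(emission_logdensity(obs, params.emission, i))
        assert ll == pytest.approx(np.log(dens), rel=1e-10)

    def test_identical_emissions_beta_independent(self, rng):
        em = EmissionParams(
            np.tile([10.0, 20.0, 30.0, 40.0], (3, 1)),
            np.tile([3.0, 5.0, 7.0, 9.0], (3, 1)),
            np.zeros(3),
            np.ones(3),
        )
        df = make_obs_frame(3, 0, 12, seed=9)
        lls = []
        for s in range(3):
            beta = TransitionCoefficients(rng.normal(0, 1, (3, 3, 1)))
            lls.append(forward_loglik(HMMParameters(em, beta), df))
        assert max(lls) - min(lls) < 1e-10

    def test_brute_force_small(self):
        params = make_params(n_states=2, p=1, seed=11)
        df = make_obs_frame(2, 1, 3, seed=11)
        ll = forward_loglik(params, df, design_columns=["z1"])
        assert ll == pytest.approx(brute_force_loglik(params, df, ["z1"]), abs=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_brute_force_random_fixtures(self, seed):
        r = np.random.default_rng(seed)
        N = int(r.integers(2, 4))
        T = int(r.integers(2, 7))
        p = int(r.integers(0, 3))
        params = make_params(N, p, seed=seed)
        df = make_obs_frame(N, p, T, seed=seed)
        cols = [f"z{j + 1}" for j in range(p)]
        ll = forward_loglik(params, df, design_columns=cols)
        assert ll == pytest.approx(brute_force_loglik(params, df, cols), abs=1e-8)

    def test_multiple_segments_sum(self):
        params = make_params(3, 0, seed=13)
        df1 = make_obs_frame(3, 0, 4, seed=13)
        df2 = make_obs_frame(3, 0, 3, seed=14)
        df2["segment_id"] = "s1"
        both = pd.concat([df1, df2], ignore_index=True)
        assert forward_loglik(params, both) == pytest.approx(
            forward_loglik(params, df1) + forward_loglik(params, df2), rel=1e-12
        )

    def test_empty_raises(self):
        params = make_params()
        with pytest.raises(ValueError):
            forward_loglik(params, pd.DataFrame())

    def test_state_permutation_invariance(self):
        params = make_params(3, 1, seed=21)
        df = make_obs_frame(3, 1, 8, seed=21)
        ll = forward_loglik(params, df, design_columns=["z1"])
        perm = np.array([2, 0, 1])
        permuted = relabel_states(params, perm=perm)
        ll_p = forward_loglik(permuted, df, design_columns=["z1"])
        assert ll_p == pytest.approx(ll, rel=1e-12)

    def test_missing_angle_equals_kappa_zero_imputation(self):
        # imputing any angle with kappa = 0 in all states shifts logL by
        # exactly -log(2 pi) per imputed angle
        params = make_params(3, 0, seed=23)
        em = params.emission
        em0 = EmissionParams(em.mu, em.sigma, em.angle_mean, np.zeros(3))
        params0 = HMMParameters(em0, params.transition)
        df = make_obs_frame(3, 0, 6, seed=23)
        df.loc[[0, 3], "turning_angle"] = np.nan
        ll_missing = forward_loglik(params0, df)
        df_imp = df.copy()
        df_imp.loc[[0, 3], "turning_angle"] = [0.77, -2.1]
        ll_imputed = forward_loglik(params0, df_imp)
        assert ll_imputed == pytest.approx(ll_missing - 2 * np.log(2 * np.pi), rel=1e-10)


class TestWorkingTransform:
    def test_round_trip(self):
        for seed in range(5):
            params = make_params(3, 2, seed=seed)
            w = working_from_natural(params)
            back = natural_from_working(w, 3, 2)
            np.testing.assert_allclose(back.emission.mu, params.emission.mu, rtol=1e-10)
            np.testing.assert_allclose(back.emission.sigma, params.emission.sigma, rtol=1e-10)
            np.testing.assert_allclose(
                back.emission.angle_kappa, params.emission.angle_kappa, atol=1e-10
            )
            np.testing.assert_allclose(
                np.angle(np.exp(1j * (back.emission.angle_mean - params.emission.angle_mean))),
                0.0,
                atol=1e-10,
            )
            np.testing.assert_allclose(
                back.transition.beta, params.transition.beta, atol=1e-12
            )

    def test_kappa_zero_guard(self):
        params = make_params()
        params.emission.angle_kappa[:] = 0.0
        w = working_from_natural(params)
        assert np.all(np.isfinite(w))
        back = natural_from_working(w, 3, 0)
        np.testing.assert_allclose(back.emission.angle_kappa, 0.0, atol=1e-12)

    def test_beta_untouched(self, rng):
        params = make_params(3, 3, seed=31)
        w = working_from_natural(params)
        nb = 3 * 2 * (1 + 3)
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_array_equal(w[-nb:], params.transition.beta[off].ravel())

    def test_nonfinite_raises(self):
        with pytest.raises(ValueError):
            natural_from_working(np.full(hc.n_working(3, 0), np.nan), 3, 0)


class TestGradient:
    @pytest.mark.parametrize("rule", ["stationary", "uniform"])
    def test_matches_finite_differences(self, rule):
        params = make_params(3, 1, seed=41)
        df = make_obs_frame(3, 1, 15, seed=41)
        packed = hc.pack_batches(df, ["z1"])
        w = working_from_natural(params)
        _, g = hc._nll_and_grad(w, packed, 3, 1, rule)
        for j in range(0, w.size, 3):
            h = 1e-6 * max(1.0, abs(w[j]))
            wp, wm = w.copy(), w.copy()
            wp[j] += h
            wm[j] -= h
            fp, _ = hc._nll_and_grad(wp, packed, 3, 1, rule)
            fm, _ = hc._nll_and_grad(wm, packed, 3, 1, rule)
            assert g[j] == pytest.approx((fp - fm) / (2 * h), rel=2e-5, abs=1e-7)


@pytest.fixture(scope="module")
def small_fit():
    import warnings

    from divehmm.synthetic_data import SimulationConfig, example_parameters, simulate_batch_table

    cfg = SimulationConfig(
        seed=77, params=example_parameters(0), n_individuals=3,
        batches_per_individual=400,
    )
    table = simulate_batch_table(cfg)
    spec = ModelSpec(3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fm = fit(spec, table, restarts=3, seed=5, compute_cov=True)
    return cfg, table, spec, fm


class TestFit:
    def test_converges_near_truth(self, small_fit):
        cfg, _, _, fm = small_fit
        assert fm.converged
        rel = np.abs(fm.params.emission.mu - cfg.params.emission.mu) / cfg.params.emission.mu
        assert rel.max() < 0.10

    def test_mle_dominates_truth(self, small_fit):
        cfg, table, _, fm = small_fit
        ll_true = forward_loglik(cfg.params, table)
        assert fm.loglik >= ll_true - 1e-6

    def test_deterministic_given_seed(self, small_fit):
        import warnings

        cfg, table, spec, fm = small_fit
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fm2 = fit(spec, table, restarts=3, seed=5, compute_cov=False)
        assert fm2.loglik == pytest.approx(fm.loglik, abs=1e-8)

    def test_canonical_state_order(self, small_fit):
        _, _, _, fm = small_fit
        step_means = fm.params.emission.mu[:, 3]
        assert np.all(np.diff(step_means) > 0)

    def test_parameter_count(self, small_fit):
        _, _, _, fm = small_fit
        assert fm.k == 36

    def test_covariance_shape_and_finiteness(self, small_fit):
        _, _, _, fm = small_fit
        assert fm.cov.shape == (len(fm.working), len(fm.working))
        assert np.all(np.isfinite(fm.cov))

    def test_serialization_round_trip(self, small_fit, tmp_path):
        from divehmm.hmm_core import FittedModel

        _, _, _, fm = small_fit
        path = tmp_path / "model.json"
        fm.save(path)
        loaded = FittedModel.load(path)
        assert loaded.loglik == fm.loglik
        np.testing.assert_array_equal(loaded.working, np.asarray(fm.working))
        np.testing.assert_array_equal(
            loaded.params.transition.beta, fm.params.transition.beta
        )

    def test_underpowered_warns(self):
        from divehmm.synthetic_data import SimulationConfig, example_parameters, simulate_batch_table

        cfg = SimulationConfig(
            seed=9, params=example_parameters(0), n_individuals=1,
            batches_per_individual=60,
        )
        table = simulate_batch_table(cfg)
        with pytest.warns(UserWarning, match="batches"):
            fit(ModelSpec(3), table, restarts=1, seed=1, compute_cov=False, maxiter=30)
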