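import numpy as np
import pandas as pd
import pytest

from proxnet.brn import (MODELS, MODEL_ORDER, FitResult, McmcSettings, ModelSpec,
                         PriorSpec, check_convergence, compute_dic, dic_table,
                         fit_mixed_model, predict_reaction_norms,
                         prior_sensitivity, repeatability, select_model,
                         standardize_density)
from proxnet.synthetic import simulate_observation_table


def obs_table(n=12, s2_id=1.0, s2_res=1.0, seed=0, **kw):
    obs, _ = simulate_observation_table(n, sigma2_id=s2_id, sigma2_resid=s2_res,
                                        seed=seed, **kw)
    return obs


class TestStandardizeDensity:
    def test_mean_zero_sd_one(self):
        obs = obs_table()
        out = standardize_density(obs)
        assert out["x"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["x"].std(ddof=0) == pytest.approx(1.0)
        assert np.allclose(out["x2"], out["x"] ** 2)

    def test_single_density_rejected(self):
        obs = obs_table().copy()
        obs["density"] = 1.0
        with pytest.raises(ValueError, match="single density"):
            standardize_density(obs)

    def test_male_density_gradient_hand_calculation(self):
        dens = [0.75, 0.75, 1.02, 1.02, 1.49, 1.49]
        obs = pd.DataFrame({"individual": ["A"] * 6, "density": dens,
                            "replicate": [1, 2] * 3, "value": range(6)})
        out = standardize_density(obs)
        mean = sum(dens) / 6
        sd = (sum((d - mean) ** 2 for d in dens) / 6) ** 0.5
        expected = [(d - mean) / sd for d in dens]
        assert np.allclose(out["x"], expected)


class TestGibbsSampler:
    def test_matches_conjugate_closed_form_posterior(self):
        # intercept-only model with the residual variance pinned: the exact
        # posterior of the mean is N(sum(y)/prec, 1/prec)
        obs = obs_table(seed=11, s2_id=0.3)
        fit = fit_mixed_model(obs, MODELS["M1"],
                              mcmc=McmcSettings(200_000, 1, 0, seed=3),
                              fix_sigma2=1.0)
        y = obs["value"].to_numpy()
        prec = y.size / 1.0 + 1e-10
        assert fit.beta.mean() == pytest.approx(y.sum() / prec, abs=1e-3)
        assert fit.beta.std() == pytest.approx(np.sqrt(1 / prec), abs=1e-3)

    def test_intercept_posterior_near_sample_mean(self):
        obs = obs_table(seed=1)
        fit = fit_mixed_model(obs, MODELS["M1"], mcmc=McmcSettings.desk(seed=2))
        y = obs["value"].to_numpy()
        se = y.std(ddof=1) / np.sqrt(y.size)
        assert abs(fit.beta.mean() - y.mean()) < 3 * se

    def test_variance_component_recovery(self):
        # n=50 individuals x 6 obs, sigma2_id=2, sigma2_resid=1
        id_hats, res_hats = [], []
        for seed in range(10):
            obs = obs_table(n=50, s2_id=2.0, s2_res=1.0, seed=seed)
            fit = fit_mixed_model(obs, MODELS["M2"],
                                  mcmc=McmcSettings.desk(seed=600 + seed))
            id_hats.append(fit.G[:, 0, 0].mean())
            res_hats.append(fit.sigma2.mean())
        assert np.mean(id_hats) == pytest.approx(2.0, rel=0.15)
        assert np.mean(res_hats) == pytest.approx(1.0, rel=0.15)

    def test_deterministic_given_seed(self):
        obs = obs_table(seed=5)
        a = fit_mixed_model(obs, MODELS["M4"], mcmc=McmcSettings.quick(seed=7))
        b = fit_mixed_model(obs, MODELS["M4"], mcmc=McmcSettings.quick(seed=7))
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.G, b.G)
        assert np.array_equal(a.sigma2, b.sigma2)

    def test_affine_response_rescaling_leaves_r_unchanged(self):
        obs = obs_table(seed=9)
        scaled = obs.copy()
        scaled["value"] = 10.0 * scaled["value"] + 3.0
        r1 = repeatability(fit_mixed_model(obs, MODELS["M2"],
                                           mcmc=McmcSettings.quick(seed=4))).draws
        r2 = repeatability(fit_mixed_model(scaled, MODELS["M2"],
                                           mcmc=McmcSettings.quick(seed=4))).draws
        assert np.allclose(r1, r2, rtol=1e-8)

    def test_fixed_density_terms_center_near_zero_without_density_effect(self):
        # data generated with no density effect: M4's density betas ~ 0
        obs = obs_table(n=20, seed=13)
        fit = fit_mixed_model(obs, MODELS["M4"], mcmc=McmcSettings.desk(seed=14))
        for k in (1, 2):
            mean, sd = fit.beta[:, k].mean(), fit.beta[:, k].std()
            assert abs(mean) < 3 * sd

    def test_zero_variance_response_degenerate(self):
        obs = obs_table().copy()
        obs["value"] = 11.0  # e.g. every female associating with all others
        with pytest.warns(UserWarning, match="zero-variance"):
            fit = fit_mixed_model(obs, MODELS["M2"], mcmc=McmcSettings.quick(seed=1))
        assert fit.degenerate
        assert not repeatability(fit).defined

    def test_nonfinite_response_rejected(self):
        obs = obs_table().copy()
        obs.loc[obs.index[0], "value"] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            fit_mixed_model(obs, MODELS["M2"], mcmc=McmcSettings.quick(seed=1))

    def test_random_slopes_need_repeated_measures(self):
        obs = obs_table().groupby("individual", as_index=False).first()
        obs["metric"] = "strength"
        with pytest.raises(ValueError, match=">= 2 observations"):
            fit_mixed_model(obs, MODELS["M5"], mcmc=McmcSettings.quick(seed=1))


class TestDic:
    def test_identical_fits_identical_dic(self):
        obs = obs_table(seed=3)
        a = fit_mixed_model(obs, MODELS["M2"], mcmc=McmcSettings.quick(seed=5))
        b = fit_mixed_model(obs, MODELS["M2"], mcmc=McmcSettings.quick(seed=5))
        assert compute_dic(a) == compute_dic(b)

    def test_strong_id_effect_favors_m2(self):
        wins = 0
        for seed in range(10):
            obs = obs_table(s2_id=4.0, s2_res=1.0, seed=seed)
            d1 = compute_dic(fit_mixed_model(obs, MODELS["M1"],
                                             mcmc=McmcSettings.quick(seed=30 + seed)))
            d2 = compute_dic(fit_mixed_model(obs, MODELS["M2"],
                                             mcmc=McmcSettings.quick(seed=60 + seed)))
            wins += d2 < d1
        assert wins >= 9

    def test_pure_noise_does_not_favor_m2(self):
        close = 0
        for seed in range(10):
            obs = obs_table(s2_id=0.0, s2_res=1.0, seed=seed)
            d1 = compute_dic(fit_mixed_model(obs, MODELS["M1"],
                                             mcmc=McmcSettings.quick(seed=30 + seed)))
            d2 = compute_dic(fit_mixed_model(obs, MODELS["M2"],
                                             mcmc=McmcSettings.quick(seed=60 + seed)))
            close += d1 <= d2 + 2
        assert close >= 6


class TestModelSelection:
    @pytest.mark.parametrize("dics,expected", [
        ({"M1": 100.0, "M4": 99.5, "M6": 105.0}, "M4"),
        ({"M1": 0.0, "M2": 10.0, "M3": 10.0, "M4": 10.0, "M5": 10.0, "M6": 10.0},
         "M1"),
        ({"M4": 0.0, "M6": 1.9}, "M6"),
    ])
    def test_within_two_most_complex_rule(self, dics, expected):
        assert select_model(dics) == expected

    def test_no_finite_dic_rejected(self):
        with pytest.raises(ValueError):
            select_model({"M1": float("nan")})

    def test_dic_table_zero_at_minimum(self):
        tab = dic_table({"M1": 10.0, "M2": 8.0, "M3": 9.5})
        assert tab.loc[tab["model"] == "M2", "dDIC"].item() == 0.0


def make_fit(G_draws, sigma2_draws, random=("intercept",), x=(-1.0, 0.0, 1.0)):
    """Hand-built FitResult with prescribed G and sigma2 chains."""
    spec = ModelSpec("M2", ("intercept",), tuple(random))
    D = len(sigma2_draws)
    q = len(random)
    xs = np.asarray(x, float)
    return FitResult(
        spec=spec, prior=PriorSpec(), mcmc=McmcSettings.quick(),
        individuals=["A", "B", "C"], x_values=np.tile(xs, 3),
        density_mean=1.0, density_sd=0.3, y=np.zeros(9),
        X=np.ones((9, 1)), Z_cols=np.ones((9, q)),
        id_index=np.repeat(np.arange(3), 3),
        beta=np.zeros((D, 1)), u=np.zeros((D, 3, q)),
        G=np.asarray(G_draws, float).reshape(D, q, q),
        sigma2=np.asarray(sigma2_draws, float))


class TestRepeatability:
    def test_equal_variances_give_half(self):
        fit = make_fit(G_draws=[[[1.0]]] * 4, sigma2_draws=[1.0] * 4)
        est = repeatability(fit)
        assert est.r == pytest.approx(0.5)
        assert est.ci_low == pytest.approx(0.5)

    def test_zero_among_variance_gives_zero(self):
        fit = make_fit(G_draws=[[[0.0]]] * 4, sigma2_draws=[1.0] * 4)
        assert repeatability(fit).r == pytest.approx(0.0)

    def test_undefined_without_random_effects(self):
        obs = obs_table(seed=2)
        fit = fit_mixed_model(obs, MODELS["M1"], mcmc=McmcSettings.quick(seed=3))
        assert not repeatability(fit).defined

    def test_slope_marginalization_matches_manual_quadratic_form(self):
        rng = np.random.default_rng(8)
        D, q = 50, 3
        A = rng.standard_normal((D, q, q))
        G = A @ A.transpose(0, 2, 1)
        s2 = rng.gamma(2.0, 1.0, D)
        xs = np.array([-1.2, -0.1, 1.3])
        spec = ModelSpec("M6", ("intercept", "density", "density2"),
                         ("intercept", "density", "density2"))
        fit = make_fit(G, s2, random=spec.random, x=xs)
        fit.spec = spec
        est = repeatability(fit, covariate_values=xs)
        manual = []
        for d in range(D):
            vals = []
            for x in xs:
                w = np.array([1.0, x, x * x])
                vals.append(w @ G[d] @ w)
            s_among = np.mean(vals)
            manual.append(s_among / (s_among + s2[d]))
        assert np.allclose(est.draws, manual)
        assert est.partition["intercept"] == pytest.approx(G[:, 0, 0].mean())
        assert est.partition["density"] == pytest.approx(
            np.mean(xs ** 2) * G[:, 1, 1].mean())

    def test_partition_sums_to_among_variance_with_covariances(self):
        fit = make_fit(G_draws=[np.eye(2).tolist()] * 5, sigma2_draws=[1.0] * 5,
                       random=("intercept", "density"))
        fit.spec = ModelSpec("M5", ("intercept",), ("intercept", "density"))
        est = repeatability(fit, covariate_values=[-1.0, 0.0, 1.0])
        total = sum(est.partition.values()) + est.covariance_contribution
        assert total == pytest.approx(est.s2_among)


class TestPriorSensitivity:
    def test_single_divisor_single_row(self):
        obs = obs_table(seed=6)
        tab = prior_sensitivity(obs, MODELS["M2"], divisors=(2,),
                                mcmc=McmcSettings.quick(seed=1))
        assert len(tab) == 1
        assert tab.attrs["max_pairwise_diff"] == 0.0

    def test_same_divisor_and_seed_reproducible(self):
        obs = obs_table(seed=6)
        t1 = prior_sensitivity(obs, MODELS["M2"], divisors=(4,),
                               mcmc=McmcSettings.quick(seed=9))
        t2 = prior_sensitivity(obs, MODELS["M2"], divisors=(4,),
                               mcmc=McmcSettings.quick(seed=9))
        assert t1["r"].item() == t2["r"].item()

    def test_results_robust_to_prior_scale_at_moderate_n(self):
        obs = obs_table(n=50, s2_id=1.0, s2_res=1.0, seed=8)
        tab = prior_sensitivity(obs, MODELS["M2"], divisors=(2, 4, 6),
                                mcmc=McmcSettings.desk(seed=10))
        assert tab.attrs["max_pairwise_diff"] < 0.05


class TestPredictReactionNorms:
    def test_random_intercept_curves_parallel(self):
        obs = obs_table(seed=4, s2_id=2.0)
        fit = fit_mixed_model(obs, MODELS["M4"], mcmc=McmcSettings.quick(seed=4))
        preds = predict_reaction_norms(fit, [0.71, 1.05, 1.43])
        wide = preds.pivot(index="individual", columns="density",
                           values="predicted")
        pop = wide.loc["population"]
        offsets = wide.drop("population") - pop
        assert np.allclose(offsets.std(axis=1), 0.0, atol=1e-10)

    def test_random_slopes_give_nonparallel_curves(self):
        obs, _ = simulate_observation_table(12, sigma2_id=1.0, sigma2_slope=1.0,
                                            sigma2_resid=0.3, seed=15)
        fit = fit_mixed_model(obs, MODELS["M6"], mcmc=McmcSettings.desk(seed=16))
        preds = predict_reaction_norms(fit, [0.71, 1.05, 1.43])
        wide = preds.pivot(index="individual", columns="density",
                           values="predicted")
        offsets = wide.drop("population") - wide.loc["population"]
        assert offsets.std(axis=1).max() > 0.1

    def test_single_point_grid(self):
        obs = obs_table(seed=4)
        fit = fit_mixed_model(obs, MODELS["M2"], mcmc=McmcSettings.quick(seed=4))
        preds = predict_reaction_norms(fit, [1.0])
        assert (preds.groupby("individual").size() == 1).all()


class TestConvergence:
    def test_iid_chain_passes(self):
        rng = np.random.default_rng(0)
        fit = make_fit(G_draws=rng.gamma(2, 1, 1000).reshape(-1, 1, 1),
                       sigma2_draws=rng.gamma(2, 1, 1000))
        report = check_convergence(fit)
        g_row = report[report["parameter"] == "G[intercept,intercept]"].iloc[0]
        assert abs(g_row["lag1_autocorr"]) < 0.1
        assert not g_row["flagged"]

    def test_duplicated_entries_flagged(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(500)
        dup = np.repeat(base, 2)  # pathological thin=1 duplicate chain
        fit = make_fit(G_draws=np.exp(dup).reshape(-1, 1, 1),
                       sigma2_draws=np.exp(dup))
        report = check_convergence(fit)
        assert report["flagged"].all()

    def test_constant_chain_flagged(self):
        fit = make_fit(G_draws=[[[1.0]]] * 100, sigma2_draws=[1.0] * 100)
        report = check_convergence(fit)
        assert report[report["parameter"] == "sigma2_resid"]["flagged"].item()

    def test_model_specs_match_candidate_set(self):
        assert MODEL_ORDER == ("M1", "M2", "M3", "M4", "M5", "M6")
        assert MODELS["M4"].fixed == ("intercept", "density", "density2")
        assert MODELS["M4"].random == ("intercept",)
        assert MODELS["M6"].random == ("intercept", "density", "density2")
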