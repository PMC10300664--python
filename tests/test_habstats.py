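"""Habitat summaries, the three models, subsampling, contrasts, bootstrap."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from batforage import habstats
from batforage.habstats import (SubsampleSpec, fit_altitude_model,
                                fit_attack_model, fit_null_model,
                                fit_speed_model, pairwise_contrasts,
                                parametric_bootstrap_test, subsample_balanced,
                                summarize_habitats)


def make_track(n_per, values=None, speeds=None):
    rows = []
    for h, n in n_per.items():
        for i in range(n):
            rows.append({
                "habitat": h,
                "alt_agl_m": 0.0 if values is None else values[h][i],
                "speed_ms": 0.0 if speeds is None else speeds[h][i],
            })
    return pd.DataFrame(rows)


class TestSummaries:
    def test_attack_percentages_from_counts(self):
        track = make_track({"river": 600, "mountain": 600, "urban": 480})
        attacks = pd.DataFrame({"habitat": ["river"] * 69 + ["mountain"] * 43
                                + ["urban"] * 8})
        s = summarize_habitats(track, attacks).set_index("habitat")
        assert s.loc["mountain", "attack_pct"] == 35.8
        assert s.loc["urban", "attack_pct"] == 6.7
        assert s.loc["river", "attack_pct"] == 57.5  # 69/120, exactly
        assert s["attacks"].sum() == 120

    def test_attack_rate_is_count_over_minutes(self):
        track = make_track({"urban": 480})  # 480 s = 8 minutes
        attacks = pd.DataFrame({"habitat": ["urban"] * 8})
        s = summarize_habitats(track, attacks)
        assert s["attack_rate_per_min"].iloc[0] == pytest.approx(1.0)

    def test_attack_without_habitat_rejected(self):
        with pytest.raises(ValueError):
            summarize_habitats(make_track({"river": 10}),
                               pd.DataFrame({"x": [1]}))


class TestSubsample:
    def test_balanced_subsample_row_count(self):
        df = make_track({"river": 300, "mountain": 300, "urban": 300})
        out = subsample_balanced(df, SubsampleSpec(76, seed=0))
        assert len(out) == 228
        assert (out["habitat"].value_counts() == 76).all()

    def test_n_equal_to_group_size_is_identity(self):
        df = make_track({"river": 40, "mountain": 40, "urban": 40})
        out = subsample_balanced(df, SubsampleSpec(40, seed=1))
        assert len(out) == 120

    def test_same_seed_same_subset(self):
        rng = np.random.default_rng(3)
        df = make_track({"river": 200, "mountain": 200, "urban": 200},
                        values={h: rng.normal(size=200) for h in
                                ("river", "mountain", "urban")})
        a = subsample_balanced(df, SubsampleSpec(50, seed=5))
        b = subsample_balanced(df, SubsampleSpec(50, seed=5))
        pd.testing.assert_frame_equal(a, b)

    def test_insufficient_data_names_habitat(self):
        df = make_track({"river": 10, "mountain": 100, "urban": 100})
        with pytest.raises(ValueError, match="river"):
            subsample_balanced(df, SubsampleSpec(40))


def bernoulli_outcomes(counts):
    """(y, labels) with exact per-habitat attack frequencies."""
    y, labels = [], []
    for h, (k, n) in counts.items():
        y += [1.0] * k + [0.0] * (n - k)
        labels += [h] * n
    return np.array(y), np.array(labels)


class TestAttackModel:
    def test_worked_odds_ratio_mountain_vs_river(self):
        # fitted on frequencies 0.049 and 0.055 the mountain/river OR is 0.89
        y, labels = bernoulli_outcomes({"mountain": (49, 1000),
                                        "river": (55, 1000)})
        fit = fit_attack_model(y, labels)
        ors = fit.contrasts.set_index("contrast")["odds_ratio"]
        assert round(ors["mountain/river"], 2) == 0.89

    def test_saturated_model_reproduces_raw_frequencies(self):
        y, labels = bernoulli_outcomes({"mountain": (43, 870),
                                        "river": (69, 1260),
                                        "urban": (8, 480)})
        fit = fit_attack_model(y, labels)
        est = fit.estimates.set_index("habitat")["estimate"]
        assert est["mountain"] == pytest.approx(43 / 870, abs=1e-9)
        assert est["river"] == pytest.approx(69 / 1260, abs=1e-9)
        assert est["urban"] == pytest.approx(8 / 480, abs=1e-9)

    def test_equal_frequencies_give_unit_odds_ratios(self):
        y, labels = bernoulli_outcomes({"mountain": (20, 400),
                                        "river": (20, 400),
                                        "urban": (20, 400)})
        fit = fit_attack_model(y, labels)
        assert np.allclose(fit.contrasts["odds_ratio"], 1.0, atol=1e-9)

    def test_cis_contain_estimates_and_df_inf(self):
        y, labels = bernoulli_outcomes({"mountain": (43, 870),
                                        "river": (69, 1260)})
        fit = fit_attack_model(y, labels)
        est = fit.estimates
        assert ((est["ci_lo"] < est["estimate"])
                & (est["estimate"] < est["ci_hi"])).all()
        assert np.isinf(est["df"]).all()

    def test_complete_separation_diagnosed(self):
        y, labels = bernoulli_outcomes({"mountain": (0, 50), "river": (5, 50)})
        with pytest.raises(ValueError, match="separation"):
            fit_attack_model(y, labels)

    def test_non_binary_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_attack_model(np.array([0.0, 0.5]), np.array(["a", "b"]))


class TestAltitudeModel:
    def test_closed_form_equals_numerical_ml(self):
        # independent oracle: direct numerical maximization of the
        # heteroscedastic Gaussian likelihood
        rng = np.random.default_rng(4)
        y = np.concatenate([rng.normal(159, 90, 40), rng.normal(-12, 14, 40),
                            rng.normal(73, 31, 40)])
        labels = np.repeat(["mountain", "river", "urban"], 40)
        fit = fit_altitude_model(y, labels)
        levels = fit.levels

        def nll(theta):
            mu = dict(zip(levels, theta[:3]))
            lv = dict(zip(levels, theta[3:]))
            out = 0.0
            for h in levels:
                g = y[labels == h]
                out += 0.5 * np.sum(np.log(2 * np.pi) + lv[h]
                                    + (g - mu[h]) ** 2 / np.exp(lv[h]))
            return out

        x0 = np.concatenate([[y.mean()] * 3, [np.log(y.var())] * 3])
        opt = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10,
                                         "maxiter": 20000})
        mu_hat = dict(zip(levels, opt.x[:3]))
        var_hat = dict(zip(levels, np.exp(opt.x[3:])))
        for h in levels:
            assert fit.params["means"][h] == pytest.approx(mu_hat[h], abs=1e-3)
            assert fit.params["variances"][h] == pytest.approx(var_hat[h], rel=1e-3)
        assert fit.loglik == pytest.approx(-opt.fun, abs=1e-6)

    def test_group_estimates_are_sample_means_and_biased_variances(self):
        rng = np.random.default_rng(5)
        y = rng.normal(10, 3, 60)
        labels = np.repeat(["a", "b", "c"], 20)
        fit = fit_altitude_model(y, labels)
        for h in fit.levels:
            g = y[labels == h]
            assert fit.params["means"][h] == pytest.approx(g.mean())
            assert fit.params["variances"][h] == pytest.approx(
                np.mean((g - g.mean()) ** 2))

    def test_equal_groups_null_contrasts_and_unit_variance_ratios(self):
        rng = np.random.default_rng(6)
        base = rng.normal(50, 10, 60)
        y = np.concatenate([base, base, base])
        labels = np.repeat(["a", "b", "c"], 60)
        fit = fit_altitude_model(y, labels)
        assert np.allclose(fit.contrasts["estimate"], 0.0, atol=1e-9)
        v = fit.dispersion.set_index("habitat")["variance"]
        assert v["a"] / v["b"] == pytest.approx(1.0)

    def test_residual_df_counts_means_and_variances(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=120)
        labels = np.repeat(["a", "b", "c"], 40)
        fit = fit_altitude_model(y, labels)
        assert fit.estimates["df"].iloc[0] == 114  # n - 2k


class TestSpeedModel:
    def test_group_estimates_are_sample_means(self):
        rng = np.random.default_rng(8)
        vals = {"a": rng.normal(5.7, 2, 76), "b": rng.normal(6.1, 2, 76),
                "c": rng.normal(8.9, 2, 76)}
        y = np.concatenate(list(vals.values()))
        labels = np.repeat(list(vals), 76)
        fit = fit_speed_model(y, labels)
        for h in fit.levels:
            assert fit.estimates.set_index("habitat").loc[h, "estimate"] == \
                pytest.approx(vals[h].mean())

    def test_contrast_se_is_pooled_closed_form(self):
        rng = np.random.default_rng(9)
        y = rng.normal(6.0, 2.0, 228)
        labels = np.repeat(["a", "b", "c"], 76)
        fit = fit_speed_model(y, labels)
        s = np.sqrt(fit.params["mse"])
        assert np.allclose(fit.contrasts["se"], s * np.sqrt(2 / 76), rtol=1e-9)

    def test_null_f_statistic_calibrated(self):
        # under equal means the F statistic averages near its null expectation
        rng = np.random.default_rng(10)
        fstats = []
        for _ in range(200):
            y = rng.normal(0, 1, 120)
            labels = np.repeat(["a", "b", "c"], 40)
            fstats.append(fit_speed_model(y, labels).overall["stat"])
        # E[F(2, 117)] = 117/115
        assert np.mean(fstats) == pytest.approx(117 / 115, abs=0.25)


class TestContrastsAndBootstrap:
    def test_three_levels_three_bonferroni_contrasts(self):
        raw = pd.DataFrame({"contrast": ["a-b", "a-c", "b-c"],
                            "p_raw": [0.004, 0.9, 0.02]})
        adj = pairwise_contrasts(raw)
        assert len(adj) == 3
        assert adj["p_adj"].tolist() == pytest.approx([0.012, 1.0, 0.06])

    def test_bootstrap_rejects_degenerate_and_non_nested(self):
        rng = np.random.default_rng(11)
        y = rng.normal(0, 1, 90)
        labels = np.repeat(["a", "b", "c"], 30)
        fit_v = fit_speed_model(y, labels)
        fit_h = fit_altitude_model(y, labels)
        with pytest.raises(ValueError):
            parametric_bootstrap_test(fit_v, fit_null_model(fit_v), B=0)
        with pytest.raises(ValueError, match="nested"):
            parametric_bootstrap_test(fit_v, fit_null_model(fit_h), B=10)

    def test_strong_effect_hits_p_floor(self):
        rng = np.random.default_rng(12)
        y = np.concatenate([rng.normal(0, 1, 60), rng.normal(5, 1, 60),
                            rng.normal(10, 1, 60)])
        labels = np.repeat(["a", "b", "c"], 60)
        fit = fit_speed_model(y, labels)
        out = parametric_bootstrap_test(fit, fit_null_model(fit), B=99, seed=0)
        assert out["p"] == pytest.approx(1 / 100)

    def test_null_p_values_uniform(self):
        # calibration: fitted on data simulated under the null, the bootstrap
        # p-value is uniform on (0, 1]
        rng = np.random.default_rng(13)
        pvals = []
        for rep in range(100):
            y = rng.normal(6.0, 2.0, 90)
            labels = np.repeat(["a", "b", "c"], 30)
            fit = fit_speed_model(y, labels)
            out = parametric_bootstrap_test(fit, fit_null_model(fit),
                                            B=99, seed=rep)
            pvals.append(out["p"])
        d, p = stats.kstest(pvals, "uniform")
        assert p > 1e-3
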