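"""Conditional-logistic core, kernel fitting/updating, model selection
and relative selection strength."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

from quollmove.issf import (
    CLogitFit,
    SeparationError,
    TentativeKernel,
    fit_clogit,
    fit_tentative_kernel,
    log_rss,
    sample_available_steps,
    select_models,
    update_kernel,
    vonmises_kappa_mle,
    _clogit_loglik,
    _prepare_strata,
)


def steps_frame(strata, z, case, extra=None):
    df = pd.DataFrame({
        "stratum_id": strata,
        "case": np.where(case, "observed", "available"),
        "z": np.asarray(z, dtype=float),
        "individual_id": "A",
    })
    if extra:
        for k, v in extra.items():
            df[k] = v
    return df


class TestTentativeKernel:
    def test_gamma_recovery(self):
        rng = np.random.default_rng(0)
        sl = rng.gamma(2.0, 100.0, 10_000)
        df = pd.DataFrame({"case": "observed", "sl": sl, "ta": 0.0})
        df.loc[:, "ta"] = rng.vonmises(0, 1.0, len(df))
        kern = fit_tentative_kernel(df)
        assert 1.9 <= kern.gamma_shape <= 2.1

    def test_uniform_angles_give_zero_kappa(self):
        assert vonmises_kappa_mle(0.0) == 0.0
        assert vonmises_kappa_mle(-0.2) == 0.0

    def test_degenerate_angles_hit_the_cap(self):
        assert vonmises_kappa_mle(1.0) == 500.0

    def test_kappa_solves_bessel_ratio(self):
        for target in (0.1, 0.5, 0.9):
            k = vonmises_kappa_mle(target)
            assert special.i1e(k) / special.i0e(k) == pytest.approx(target, abs=1e-9)

    def test_too_few_steps_rejected(self):
        df = pd.DataFrame({"case": "observed", "sl": [10.0] * 5, "ta": 0.0})
        with pytest.raises(ValueError):
            fit_tentative_kernel(df)


class TestAvailableSteps:
    @pytest.fixture()
    def observed(self):
        rng = np.random.default_rng(1)
        n = 1000
        return pd.DataFrame({
            "stratum_id": np.arange(n),
            "individual_id": "A",
            "season": "breeding",
            "age": 1.0,
            "case": "observed",
            "burst_id": 0,
            "start_x": rng.uniform(0, 1000, n),
            "start_y": rng.uniform(0, 1000, n),
            "end_x": 0.0, "end_y": 0.0,
            "t_start": pd.Timestamp("2021-09-01T18:00:00+00:00"),
            "t_end": pd.Timestamp("2021-09-01T18:30:00+00:00"),
            "sl": rng.gamma(2, 50, n),
            "ta": rng.vonmises(0, 1, n),
            "prev_heading": rng.uniform(-np.pi, np.pi, n),
        })

    def test_design_counts(self, observed):
        kern = TentativeKernel(2.0, 50.0, 1.0)
        full = sample_available_steps(observed, kern, n=5, seed=0)
        counts = full.groupby("stratum_id")["case"].value_counts().unstack()
        assert (counts["observed"] == 1).all()
        assert (counts["available"] == 5).all()

    def test_lengths_follow_tentative_gamma(self, observed):
        kern = TentativeKernel(2.0, 50.0, 1.0)
        full = sample_available_steps(observed, kern, n=5, seed=0)
        sl = full.loc[full["case"] == "available", "sl"].to_numpy()[:5000]
        _, p = stats.kstest(sl, stats.gamma(2.0, scale=50.0).cdf)
        assert p > 0.01

    def test_seeded_determinism(self, observed):
        kern = TentativeKernel(2.0, 50.0, 1.0)
        a = sample_available_steps(observed, kern, n=5, seed=9)
        b = sample_available_steps(observed, kern, n=5, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestClogit:
    def test_null_loglik_is_uniform_choice(self):
        rng = np.random.default_rng(2)
        S, m = 100, 6
        df = steps_frame(np.repeat(np.arange(S), m), rng.normal(size=S * m),
                         np.tile([True] + [False] * (m - 1), S))
        X, case, gi, S_, _ = _prepare_strata(df, ["z"])
        ll, _, _ = _clogit_loglik(np.zeros(1), X, case, gi, S_)
        assert ll == pytest.approx(S * np.log(1.0 / 6.0), rel=1e-12)

    def test_two_strata_toy_matches_brute_force(self):
        """Newton MLE equals 1-D golden-section likelihood maximisation."""
        z = [1, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0]
        case = [True] + [False] * 5 + [True] + [False] * 5
        df = steps_frame(np.repeat([0, 1], 6), z, case)
        fit = fit_clogit(df, ["z"])

        def nll(b):
            s1 = np.exp(b) / (np.exp(b) + 5)
            s2 = 1.0 / (1 + np.exp(b) + 4)
            return -(np.log(s1) + np.log(s2))

        res = optimize.minimize_scalar(nll, bounds=(-10, 10), method="bounded",
                                       options={"xatol": 1e-10})
        assert fit.beta[0] == pytest.approx(res.x, abs=1e-4)

    def test_duplicating_strata_doubles_loglik(self):
        rng = np.random.default_rng(3)
        S, m = 50, 6
        df = steps_frame(np.repeat(np.arange(S), m), rng.normal(size=S * m),
                         np.tile([True] + [False] * (m - 1), S))
        fit1 = fit_clogit(df, ["z"])
        dup = df.copy()
        dup["stratum_id"] = dup["stratum_id"] + S
        fit2 = fit_clogit(pd.concat([df, dup], ignore_index=True), ["z"])
        assert fit2.loglik == pytest.approx(2 * fit1.loglik, rel=1e-8)
        assert fit2.beta[0] == pytest.approx(fit1.beta[0], abs=1e-8)

    def test_matches_statsmodels_conditional_logit(self):
        """Independent cross-check against an established implementation."""
        from statsmodels.discrete.conditional_models import ConditionalLogit

        rng = np.random.default_rng(4)
        S, m = 200, 6
        z1 = rng.normal(size=S * m)
        z2 = rng.binomial(1, 0.3, S * m).astype(float)
        strata = np.repeat(np.arange(S), m)
        beta_true = np.array([0.8, -0.5])
        eta = 0.8 * z1 - 0.5 * z2
        case = np.zeros(S * m, dtype=bool)
        for s in range(S):
            sl = slice(s * m, (s + 1) * m)
            p = np.exp(eta[sl])
            case[s * m + rng.choice(m, p=p / p.sum())] = True
        df = steps_frame(strata, z1, case, extra={"z2": z2})
        fit = fit_clogit(df, ["z", "z2"])
        ref = ConditionalLogit(case.astype(float),
                               np.column_stack([z1, z2]), groups=strata).fit(disp=0)
        # agreement is limited by statsmodels' own convergence tolerance
        np.testing.assert_allclose(fit.beta, ref.params, atol=1e-3)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-2)

    def test_covariate_shift_invariance(self):
        rng = np.random.default_rng(5)
        S, m = 80, 6
        df = steps_frame(np.repeat(np.arange(S), m), rng.normal(size=S * m),
                         np.tile([True] + [False] * (m - 1), S))
        fit1 = fit_clogit(df, ["z"])
        df2 = df.copy()
        df2["z"] = df2["z"] + 7.5
        fit2 = fit_clogit(df2, ["z"])
        assert fit2.beta[0] == pytest.approx(fit1.beta[0], abs=1e-8)
        assert fit2.loglik == pytest.approx(fit1.loglik, rel=1e-10)

    def test_stratum_order_invariance(self):
        rng = np.random.default_rng(6)
        S, m = 60, 6
        df = steps_frame(np.repeat(np.arange(S), m), rng.normal(size=S * m),
                         np.tile([True] + [False] * (m - 1), S))
        fit1 = fit_clogit(df, ["z"])
        fit2 = fit_clogit(df.sample(frac=1.0, random_state=1), ["z"])
        assert fit2.beta[0] == pytest.approx(fit1.beta[0], abs=1e-8)
        assert fit2.loglik == pytest.approx(fit1.loglik, rel=1e-10)

    def test_complete_separation_detected(self):
        S, m = 40, 6
        z = np.tile([1.0] + [0.0] * (m - 1), S)
        case = np.tile([True] + [False] * (m - 1), S)
        df = steps_frame(np.repeat(np.arange(S), m), z, case)
        with pytest.raises(SeparationError, match="z"):
            fit_clogit(df, ["z"])


class TestModelSelection:
    def test_aicc_arithmetic(self):
        fit = CLogitFit(["a", "b"], np.zeros(2), np.eye(2), loglik=-10.0, n_strata=50)
        assert fit.aicc == pytest.approx(20 + 4 + 12 / 47, rel=1e-12)
        assert fit.aicc == pytest.approx(24.25531914893617, rel=1e-10)

    def test_identical_candidates_tie(self):
        rng = np.random.default_rng(7)
        S, m = 60, 6
        df = steps_frame(np.repeat(np.arange(S), m), rng.normal(size=S * m),
                         np.tile([True] + [False] * (m - 1), S))
        table = select_models(df, {"m1": ["z"], "m2": ["z"]})
        assert table["dAICc"].max() == pytest.approx(0.0, abs=1e-10)

    def test_strong_effect_supports_global_over_null(self):
        rng = np.random.default_rng(8)
        S, m = 300, 6
        z = rng.normal(size=S * m)
        strata = np.repeat(np.arange(S), m)
        case = np.zeros(S * m, dtype=bool)
        for s in range(S):
            sl = slice(s * m, (s + 1) * m)
            p = np.exp(1.5 * z[sl])
            case[s * m + rng.choice(m, p=p / p.sum())] = True
        df = steps_frame(strata, z, case)
        table = select_models(df, {"global": ["z"], "null": []})
        assert table.iloc[0]["model"] == "global"
        assert not table[table["model"] == "null"]["support"].iloc[0]


class TestKernelUpdate:
    def test_zero_coefficients_leave_kernel_unchanged(self):
        tent = TentativeKernel(2.0, 100.0, 1.0)
        fit = CLogitFit(["log10_sl", "cos_ta"], np.zeros(2), np.eye(2), -1.0, 10)
        upd = update_kernel(tent, fit)
        assert (upd.gamma_shape, upd.gamma_scale, upd.vm_kappa) == (2.0, 100.0, 1.0)

    def test_log10_coefficient_converts_by_ln10(self):
        tent = TentativeKernel(2.0, 100.0, 1.0)
        fit = CLogitFit(["log10_sl"], np.array([1.1513]), np.eye(1), -1.0, 10)
        upd = update_kernel(tent, fit)
        assert upd.gamma_shape == pytest.approx(2.0 + 1.1513 / np.log(10.0), rel=1e-10)
        assert upd.gamma_shape == pytest.approx(2.5000, abs=1e-4)
        assert upd.gamma_scale == 100.0

    def test_cos_ta_adds_to_kappa(self):
        tent = TentativeKernel(2.0, 100.0, 1.0)
        fit = CLogitFit(["cos_ta"], np.array([0.4]), np.eye(1), -1.0, 10)
        assert update_kernel(tent, fit).vm_kappa == pytest.approx(1.4)

    def test_invalid_update_flagged(self):
        tent = TentativeKernel(0.5, 100.0, 0.1)
        fit = CLogitFit(["log10_sl", "cos_ta"], np.array([-2.0, -0.5]), np.eye(2), -1.0, 10)
        assert not update_kernel(tent, fit).valid


class TestRss:
    def make_fit(self):
        cov = np.array([[0.04, 0.01], [0.01, 0.09]])
        return CLogitFit(["spinifex", "tri"], np.array([-0.5, 0.3]), cov, -1.0, 100)

    def test_same_point_gives_unit_rss(self):
        fit = self.make_fit()
        res = log_rss(fit, {"spinifex": 1.0, "tri": 0.5}, {"spinifex": 1.0, "tri": 0.5})
        assert res.rss == 1.0
        assert res.ci[0] <= 1.0 <= res.ci[1]

    def test_single_habitat_contrast(self):
        fit = self.make_fit()
        res = log_rss(fit, {"spinifex": 1.0}, {})
        assert res.rss == pytest.approx(np.exp(-0.5), rel=1e-12)
        assert res.rss == pytest.approx(0.6065, abs=1e-4)

    def test_delta_method_ci_matches_parametric_bootstrap(self):
        fit = self.make_fit()
        x1 = {"spinifex": 1.0, "tri": 2.0}
        x2 = {"spinifex": 0.0, "tri": 0.5}
        res = log_rss(fit, x1, x2)
        rng = np.random.default_rng(9)
        draws = rng.multivariate_normal(fit.beta, fit.cov, 100_000)
        dz = np.array([1.0, 1.5])
        boot = draws @ dz
        lo, hi = np.exp(np.quantile(boot, [0.025, 0.975]))
        assert res.ci[0] == pytest.approx(lo, rel=0.02)
        assert res.ci[1] == pytest.approx(hi, rel=0.02)
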