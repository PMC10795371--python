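"""Path models: partial correlations, effect decomposition, relevant
ranges, conditional R^2 and the season model."""

import numpy as np
import pandas as pd
import pytest

from quollmove.energetics import (
    EffectDecomposition,
    fisher_c,
    fit_path_model,
    fit_season_model,
    partial_correlation,
    relevant_range,
    step_env_covariates,
    total_effect,
)
from quollmove.landscape import HABITAT_CODES, Landscape
from quollmove.raster import RasterGrid


def steps_table(env, sl, vedba, temp=None, ind=None, season=None):
    n = len(env)
    return pd.DataFrame({
        "individual_id": ind if ind is not None else np.repeat(
            [f"I{g}" for g in range(6)], n // 6),
        "case": "observed",
        "env": env, "sl": sl, "mean_vedba": vedba,
        "mean_temperature": temp if temp is not None else np.zeros(n),
        "season": season if season is not None else "breeding",
    })


class TestPartialCorrelation:
    def test_exact_linear_dependence(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=100)
        c = rng.normal(size=100)
        b = a + c
        assert partial_correlation(a, b, c) == pytest.approx(1.0, abs=1e-10)

    def test_independent_variables_near_zero(self):
        rng = np.random.default_rng(42)
        n = 10_000
        r = partial_correlation(rng.normal(size=n), rng.normal(size=n),
                                rng.normal(size=n))
        assert abs(r) < 3 / np.sqrt(n)

    def test_matches_closed_form(self):
        """Residual method equals (r_ab - r_ac r_bc)/sqrt((1-r_ac^2)(1-r_bc^2))."""
        rng = np.random.default_rng(2)
        x = rng.normal(size=(500, 3))
        x[:, 1] += 0.5 * x[:, 0] + 0.3 * x[:, 2]
        x[:, 0] += 0.4 * x[:, 2]
        a, b, c = x[:, 0], x[:, 1], x[:, 2]
        r_ab = np.corrcoef(a, b)[0, 1]
        r_ac = np.corrcoef(a, c)[0, 1]
        r_bc = np.corrcoef(b, c)[0, 1]
        closed = (r_ab - r_ac * r_bc) / np.sqrt((1 - r_ac**2) * (1 - r_bc**2))
        assert partial_correlation(a, b, c) == pytest.approx(closed, abs=1e-12)


class TestTotalEffect:
    def test_sum_is_direct_plus_indirect(self):
        d = EffectDecomposition("env", 0.1, 0.2)
        assert d.total == pytest.approx(0.3)

    def test_pure_mediation_has_null_direct_effect(self):
        """env lengthens steps, steps raise VeDBA, no direct arrow."""
        rng = np.random.default_rng(3)
        n = 3000
        env = rng.normal(size=n)
        sl = 2.0 * env + rng.normal(size=n)
        vedba = 3.0 * sl + rng.normal(size=n)
        eff = total_effect(steps_table(env, sl, vedba), "env")
        assert abs(eff.direct) < 0.06
        assert eff.indirect > 0.5
        assert eff.total > 0.5

    def test_unrelated_env_leaves_only_indirect(self):
        rng = np.random.default_rng(4)
        n = 3000
        env = rng.normal(size=n)
        sl = rng.normal(size=n)
        vedba = 2.0 * sl + rng.normal(size=n)
        eff = total_effect(steps_table(env, sl, vedba), "env")
        assert abs(eff.direct) < 0.06
        assert eff.total == pytest.approx(eff.indirect, abs=0.06)


class TestPathModel:
    def test_mediation_structure_recovered(self):
        rng = np.random.default_rng(5)
        n = 1200
        ind = np.repeat([f"I{g}" for g in range(6)], n // 6)
        u = np.repeat(rng.normal(0, 0.5, 6), n // 6)
        env = rng.normal(size=n)
        temp = rng.normal(size=n)
        sl = 2.0 * env - 0.5 * temp + u + rng.normal(size=n)
        vedba = 3.0 * sl + u + rng.normal(size=n)
        df = steps_table(env, sl, vedba, temp, ind)
        fit = fit_path_model(df, "env")
        assert fit.sl_model.coef["env"] == pytest.approx(2.0, abs=0.15)
        lo = fit.vedba_model.coef["env"] - 1.96 * fit.vedba_model.se["env"]
        hi = fit.vedba_model.coef["env"] + 1.96 * fit.vedba_model.se["env"]
        assert lo <= 0.0 <= hi                      # no direct env -> VeDBA path
        assert fit.vedba_model.coef["sl"] == pytest.approx(3.0, abs=0.15)

    def test_conditional_r2_arithmetic(self):
        # R2c = (var_fixed + var_random) / (var_fixed + var_random + var_resid)
        from quollmove.energetics import EquationFit

        eq = EquationFit("y", {}, {}, {}, sigma_u2=1.0, sigma_e2=2.0, loglik=0.0,
                         r2_conditional=(1.0 + 1.0) / (1.0 + 1.0 + 2.0),
                         r2_marginal=1.0 / 4.0)
        assert eq.r2_conditional == pytest.approx(0.5)

    def test_zero_group_variance_makes_r2c_equal_marginal(self):
        rng = np.random.default_rng(6)
        n = 600
        ind = np.repeat([f"I{g}" for g in range(6)], n // 6)
        env = rng.normal(size=n)
        noise = rng.normal(size=n)
        noise -= pd.Series(noise).groupby(ind).transform("mean").to_numpy()
        sl = 2.0 * env + noise
        vedba = 3.0 * sl + rng.normal(size=n)
        fit = fit_path_model(steps_table(env, sl, vedba, ind=ind), "env")
        assert fit.sl_model.sigma_u2 == 0.0
        assert fit.sl_model.r2_conditional == pytest.approx(fit.sl_model.r2_marginal)

    def test_constant_env_rejected(self):
        df = steps_table(np.zeros(60), np.ones(60), np.ones(60))
        with pytest.raises(ValueError, match="constant"):
            fit_path_model(df, "env")


class TestSeasonModel:
    def make_df(self, rng, season_effect_sl=0.0, season_effect_temp=0.0):
        n = 1200
        ind = np.repeat([f"I{g}" for g in range(6)], n // 6)
        season = np.where(np.arange(n) % 2 == 0, "breeding", "non-breeding")
        breeding = (season == "breeding").astype(float)
        temp = 25.0 + season_effect_temp * breeding + rng.normal(size=n)
        sl = 100.0 + season_effect_sl * breeding - 1.0 * (temp - 25.0) + rng.normal(0, 10, n)
        vedba = 0.005 * sl + rng.normal(0, 0.1, n)
        return steps_table(np.zeros(n), sl, vedba, temp, ind, season)

    def test_identical_seasons_give_null_effects(self):
        df = self.make_df(np.random.default_rng(0))
        fit = fit_season_model(df)
        for eq in (fit.temperature_model, fit.sl_model):
            b, s = eq.coef["season_breeding"], eq.se["season_breeding"]
            assert abs(b) < 2.5 * s + 1e-6

    def test_breeding_steps_twice_as_long_raise_vedba(self):
        rng = np.random.default_rng(8)
        df = self.make_df(rng, season_effect_sl=100.0)
        df["season_breeding"] = (df["season"] == "breeding").astype(float)
        eff = total_effect(df, "season_breeding")
        assert eff.total > 0.1

    def test_temperature_offset_recovered(self):
        df = self.make_df(np.random.default_rng(9), season_effect_temp=3.0)
        fit = fit_season_model(df)
        assert fit.temperature_model.coef["season_breeding"] == pytest.approx(3.0, rel=0.10)


class TestRelevantRange:
    def test_definition(self):
        from quollmove.energetics import RangeCoefficient

        rc = RangeCoefficient("y", "x", beta=2.0, predictor_range=0.5, response_range=10.0)
        assert rc.standardized == pytest.approx(0.1)
        assert np.sign(rc.standardized) == np.sign(rc.beta)

    def test_rescaling_predictor_is_invariant(self):
        rng = np.random.default_rng(10)
        n = 600
        ind = np.repeat([f"I{g}" for g in range(6)], n // 6)
        env = rng.normal(size=n)
        temp = rng.normal(size=n)
        sl = 2.0 * env + 0.5 * temp + rng.normal(size=n)
        vedba = 3.0 * sl + rng.normal(size=n)
        df1 = steps_table(env, sl, vedba, temp, ind)
        df2 = steps_table(env * 100.0, sl, vedba, temp, ind)
        r1 = {(c.response, c.predictor): c.standardized
              for c in relevant_range(fit_path_model(df1, "env"), df1)}
        r2 = {(c.response, c.predictor): c.standardized
              for c in relevant_range(fit_path_model(df2, "env"), df2)}
        for key in r1:
            assert r1[key] == pytest.approx(r2[key], rel=1e-6), key

    def test_matches_refit_on_minmax_scaled_variables(self):
        """Standardised value equals the raw coefficient of a refit on
        min-max-scaled predictor and response (OLS equivariance)."""
        rng = np.random.default_rng(11)
        n = 400
        env = rng.normal(size=n)
        temp = rng.normal(size=n)
        y = 2.0 * env + 0.5 * temp + rng.normal(size=n)

        def rng_of(v):
            return v.max() - v.min()

        X = np.column_stack([np.ones(n), env, temp])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        scaled = np.column_stack([
            np.ones(n), env / rng_of(env), temp / rng_of(temp)])
        beta_s = np.linalg.lstsq(scaled, y / rng_of(y), rcond=None)[0]
        assert beta[1] * rng_of(env) / rng_of(y) == pytest.approx(beta_s[1], abs=1e-8)


class TestStepEnvCovariates:
    def make_land(self, vals, cell=10.0):
        n = vals.shape[0]
        habitat = RasterGrid(0, n * cell, cell, vals, name="habitat")
        ones = RasterGrid(0, n * cell, cell, np.ones_like(vals), name="tri")
        zeros = RasterGrid(0, n * cell, cell, np.zeros_like(vals))
        return Landscape(habitat, ones, zeros, zeros)

    def steps(self, segments):
        rows = []
        for i, (sx, sy, ex, ey) in enumerate(segments):
            rows.append({"individual_id": "A", "case": "observed", "stratum_id": i,
                         "start_x": sx, "start_y": sy, "end_x": ex, "end_y": ey})
        return pd.DataFrame(rows)

    def test_step_within_one_patch(self):
        land = self.make_land(np.full((20, 20), float(HABITAT_CODES["rocky"])))
        out = step_env_covariates(self.steps([(20, 100, 120, 100)]), land)
        assert out["prop_rocky"].iloc[0] == pytest.approx(1.0)

    def test_step_crossing_5050_boundary(self):
        vals = np.zeros((20, 20))
        vals[:, 10:] = HABITAT_CODES["rocky"]
        land = self.make_land(vals)
        out = step_env_covariates(self.steps([(50, 100, 150, 100)]), land)
        # perpendicular crossing: half the samples each side (+- one sample)
        assert out["prop_rocky"].iloc[0] == pytest.approx(0.5, abs=0.05)

    def test_proportions_sum_to_one(self, small_landscape):
        rng = np.random.default_rng(12)
        segs = [(x, y, x + dx, y + dy) for x, y, dx, dy in
                zip(rng.uniform(200, 900, 20), rng.uniform(200, 900, 20),
                    rng.normal(0, 80, 20), rng.normal(0, 80, 20))]
        out = step_env_covariates(self.steps(segs), small_landscape)
        total = sum(out[f"prop_{name}"] for name in HABITAT_CODES)
        np.testing.assert_allclose(total, 1.0, atol=1e-9)


def test_fisher_c_null_behaviour():
    c, df, p = fisher_c([])
    assert (c, df, p) == (0.0, 0, 1.0)
    c, df, p = fisher_c([0.5, 0.5])
    assert df == 4 and 0.0 < p < 1.0
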