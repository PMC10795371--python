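"""Piecewise path models of energy expenditure.

For each environmental variable ``env`` (per-step habitat proportions,
median TRI, mean distances), a two-equation path model is fit on the
observed steps:

    GLMM-1:  step length ~ env + mean temperature       + (1 | individual)
    GLMM-2:  mean VeDBA ~ env + mean temperature + step length + (1 | individual)

Both equations are Gaussian mixed models estimated by ML on the same
complete-case subset.  Effects of ``env`` on mean VeDBA decompose as

    direct   = partial_corr(env, VeDBA | step length)
    indirect = partial_corr(step length, VeDBA | env)
    total    = direct + indirect

Coefficients are also reported as relevant-range standardised values
``beta * range(x) / range(y)`` (observed min-max ranges), which put the
arrows of the path diagram on a common scale, and each equation carries
a conditional R^2 = (var_fixed + var_random) / (var_fixed + var_random
+ var_residual).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .broad_models import fit_lmm
from .landscape import HABITAT_CODES, Landscape

__all__ = [
    "EquationFit",
    "PathModelFit",
    "EffectDecomposition",
    "RangeCoefficient",
    "step_env_covariates",
    "partial_correlation",
    "fit_path_model",
    "total_effect",
    "fit_season_model",
    "relevant_range",
    "fisher_c",
]

ENV_VARIABLES = [
    "prop_spinifex", "prop_riparian", "prop_rocky", "prop_pits_waste",
    "prop_other_disturbed", "median_tri", "mean_dist_disturbance",
    "mean_dist_rocky",
]


@dataclass
class EquationFit:
    response: str
    coef: dict[str, float]
    se: dict[str, float]
    pvalues: dict[str, float]
    sigma_u2: float
    sigma_e2: float
    loglik: float
    r2_conditional: float
    r2_marginal: float


@dataclass
class PathModelFit:
    env_variable: str
    sl_model: EquationFit
    vedba_model: EquationFit
    n_steps: int
    temperature_model: EquationFit | None = None   # season model only


@dataclass
class EffectDecomposition:
    env_variable: str
    direct: float
    indirect: float

    @property
    def total(self) -> float:
        return self.direct + self.indirect


@dataclass
class RangeCoefficient:
    response: str
    predictor: str
    beta: float
    predictor_range: float
    response_range: float

    @property
    def standardized(self) -> float:
        return self.beta * self.predictor_range / self.response_range


# ---------------------------------------------------------------------------
# per-step environmental summaries

def step_env_covariates(steps: pd.DataFrame, landscape: Landscape) -> pd.DataFrame:
    """Along-path environmental summaries for each observed step.

    The straight start-to-end segment is sampled at half the habitat
    cell size (both endpoints inclusive); habitat proportions are the
    fraction of samples in each class, and TRI / distance layers are
    summarised over the same sample points (median for TRI, mean for
    distances).
    """
    steps = steps[steps["case"] == "observed"].copy() if "case" in steps else steps.copy()
    spacing = landscape.habitat.cell_size / 2.0
    sx, sy = steps["start_x"].to_numpy(), steps["start_y"].to_numpy()
    ex, ey = steps["end_x"].to_numpy(), steps["end_y"].to_numpy()
    sl = np.hypot(ex - sx, ey - sy)
    n_samples = np.maximum(np.ceil(sl / spacing).astype(int) + 1, 2)

    prop_cols = {f"prop_{name}": np.zeros(len(steps)) for name in HABITAT_CODES}
    med_tri = np.zeros(len(steps))
    mean_dd = np.zeros(len(steps))
    mean_dr = np.zeros(len(steps))
    hab_grid = landscape.habitat
    for i in range(len(steps)):
        t = np.linspace(0.0, 1.0, n_samples[i])
        px = sx[i] + t * (ex[i] - sx[i])
        py = sy[i] + t * (ey[i] - sy[i])
        hab = np.asarray(hab_grid.value_at(px, py))
        mapped = hab != hab_grid.nodata
        denom = max(int(mapped.sum()), 1)
        for name, code in HABITAT_CODES.items():
            prop_cols[f"prop_{name}"][i] = float((hab[mapped] == code).sum()) / denom
        tri = np.asarray(landscape.tri.value_at(px, py))
        tri = tri[tri != landscape.tri.nodata]
        med_tri[i] = np.median(tri) if tri.size else np.nan
        dd = np.asarray(landscape.dist_disturbance.value_at(px, py))
        mean_dd[i] = dd[dd != landscape.dist_disturbance.nodata].mean() if mapped.any() else np.nan
        dr = np.asarray(landscape.dist_rocky.value_at(px, py))
        mean_dr[i] = dr[dr != landscape.dist_rocky.nodata].mean() if mapped.any() else np.nan
    for col, vals in prop_cols.items():
        steps[col] = vals
    steps["median_tri"] = med_tri
    steps["mean_dist_disturbance"] = mean_dd
    steps["mean_dist_rocky"] = mean_dr
    return steps


# ---------------------------------------------------------------------------
# partial correlations and effect decomposition

def partial_correlation(a, b, control, group=None) -> float:
    """Partial Pearson correlation of ``a`` and ``b`` given ``control``.

    Computed as the correlation of OLS residuals of ``a ~ control`` and
    ``b ~ control``.  With ``group`` given, variables are first centred
    on group (individual) means, removing between-individual structure.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(control, dtype=float)
    if group is not None:
        df = pd.DataFrame({"a": a, "b": b, "c": c, "g": group})
        means = df.groupby("g").transform("mean")
        a = a - means["a"].to_numpy()
        b = b - means["b"].to_numpy()
        c = c - means["c"].to_numpy()
    X = np.column_stack([np.ones(len(c)), c])
    ra = a - X @ np.linalg.lstsq(X, a, rcond=None)[0]
    rb = b - X @ np.linalg.lstsq(X, b, rcond=None)[0]
    denom = np.sqrt((ra**2).sum() * (rb**2).sum())
    if denom == 0:
        return 0.0 if not np.allclose(ra, rb) else 1.0
    return float((ra * rb).sum() / denom)


def total_effect(steps: pd.DataFrame, env_variable: str,
                 within_individuals: bool = False) -> EffectDecomposition:
    """Direct + step-length-mediated effect of ``env`` on mean VeDBA."""
    df = steps.dropna(subset=[env_variable, "sl", "mean_vedba"])
    group = df["individual_id"].to_numpy() if within_individuals else None
    direct = partial_correlation(df[env_variable], df["mean_vedba"], df["sl"], group)
    indirect = partial_correlation(df["sl"], df["mean_vedba"], df[env_variable], group)
    return EffectDecomposition(env_variable, direct, indirect)


# ---------------------------------------------------------------------------
# component GLMMs

def _fit_equation(df: pd.DataFrame, response: str, predictors: list[str]) -> EquationFit:
    y = df[response].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df))] + [df[p].to_numpy(dtype=float) for p in predictors])
    names = ["intercept"] + predictors
    coef, se, sigma_u2, sigma_e2, llf, _ = fit_lmm(y, X, df["individual_id"].to_numpy(), names)
    z = {n: coef[n] / se[n] if se[n] > 0 else np.nan for n in names}
    pvals = {n: 2 * stats.norm.sf(abs(z[n])) for n in names}
    beta = np.array([coef[n] for n in names])
    var_fixed = float(np.var(X @ beta))
    denom = var_fixed + sigma_u2 + sigma_e2
    return EquationFit(
        response=response, coef=coef, se=se, pvalues=pvals,
        sigma_u2=sigma_u2, sigma_e2=sigma_e2, loglik=llf,
        r2_conditional=(var_fixed + sigma_u2) / denom if denom > 0 else np.nan,
        r2_marginal=var_fixed / denom if denom > 0 else np.nan,
    )


def fit_path_model(steps: pd.DataFrame, env_variable: str) -> PathModelFit:
    """Two-equation path model for one environmental variable.

    Complete cases only; both equations share the identical step subset.
    """
    needed = [env_variable, "sl", "mean_vedba", "mean_temperature"]
    df = steps.dropna(subset=needed)
    if df[env_variable].nunique() < 2:
        raise ValueError(f"{env_variable} is constant across steps; unidentifiable")
    sl_model = _fit_equation(df, "sl", [env_variable, "mean_temperature"])
    vedba_model = _fit_equation(df, "mean_vedba", [env_variable, "mean_temperature", "sl"])
    return PathModelFit(env_variable, sl_model, vedba_model, n_steps=len(df))


def fit_season_model(steps: pd.DataFrame) -> PathModelFit:
    """Path model with season (breeding = 1) exogenous to temperature,
    step length and mean VeDBA."""
    df = steps.dropna(subset=["sl", "mean_vedba", "mean_temperature", "season"]).copy()
    df["season_breeding"] = (df["season"] == "breeding").astype(float)
    temp_model = _fit_equation(df, "mean_temperature", ["season_breeding"])
    sl_model = _fit_equation(df, "sl", ["season_breeding", "mean_temperature"])
    vedba_model = _fit_equation(
        df, "mean_vedba", ["season_breeding", "mean_temperature", "sl"])
    fit = PathModelFit("season_breeding", sl_model, vedba_model, n_steps=len(df),
                       temperature_model=temp_model)
    return fit


def relevant_range(fit: PathModelFit, steps: pd.DataFrame) -> list[RangeCoefficient]:
    """Relevant-range standardised coefficients for both equations.

    Each raw coefficient is scaled by the observed (max - min) range of
    its predictor over the range of its response, making arrow widths
    comparable across predictors with different units.
    """
    env = fit.env_variable
    df = steps.dropna(subset=[c for c in (env, "sl", "mean_vedba", "mean_temperature")
                              if c in steps.columns])
    if env == "season_breeding" and env not in df.columns:
        df = df.copy()
        df[env] = (df["season"] == "breeding").astype(float)

    def rng(col):
        v = df[col].to_numpy(dtype=float)
        return float(v.max() - v.min())

    out = []
    models = [fit.sl_model, fit.vedba_model]
    if fit.temperature_model is not None:
        models.insert(0, fit.temperature_model)
    for eq in models:
        for name, b in eq.coef.items():
            if name == "intercept":
                continue
            out.append(RangeCoefficient(eq.response, name, b, rng(name), rng(eq.response)))
    return out


def fisher_c(pvalues) -> tuple[float, int, float]:
    """Fisher's C over the d-separation claim p-values (optional
    diagnostic): C = -2 sum(ln p), df = 2k, upper-tail chi-square p."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return 0.0, 0, 1.0
    c = float(-2.0 * np.log(np.clip(p, 1e-300, 1.0)).sum())
    df = 2 * len(p)
    return c, df, float(stats.chi2.sf(c, df))
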