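"""Integrated step-selection functions.

The estimator follows the standard used/available step design: a
tentative selection-free movement kernel (gamma step lengths, von Mises
turning angles) is fit to the observed steps, five available steps per
observed step are drawn from it, end-of-step covariates are attached,
and the selection coefficients are estimated by maximising the
stratified conditional-logistic partial likelihood

    L(beta) = prod_s exp(beta.z_obs) / sum_j exp(beta.z_j)

with Newton-Raphson on the analytic score and Hessian.  Including
log10(step length) and cos(turning angle) as covariates lets the fitted
coefficients correct the tentative kernel (shape update
``k = k0 + beta_log10_sl / ln 10``, concentration update
``kappa = kappa0 + beta_cos_ta``), and relative selection strength
(RSS) between two locations is ``exp(beta.(z1 - z2))`` with delta-method
confidence intervals.

Habitat is dummy-coded with rocky as the reference class, so each
habitat coefficient is a log-RSS against rocky terrain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .landscape import HABITAT_CODES, Landscape

__all__ = [
    "TentativeKernel",
    "CLogitFit",
    "UpdatedKernel",
    "RSSResult",
    "SeparationError",
    "fit_tentative_kernel",
    "sample_available_steps",
    "attach_covariates",
    "fit_clogit",
    "select_models",
    "update_kernel",
    "log_rss",
    "GLOBAL_FORMULA",
    "DEFAULT_CANDIDATES",
]

HABITAT_DUMMIES = ("spinifex", "riparian", "pits_waste", "other_disturbed")

GLOBAL_FORMULA = list(HABITAT_DUMMIES) + [
    "tri", "dist_disturbance", "dist_rocky", "log10_sl", "cos_ta",
]

#: simplified-model menu (config-driven; the global model plus nested variants)
DEFAULT_CANDIDATES = {
    "global": GLOBAL_FORMULA,
    "habitat_only": list(HABITAT_DUMMIES) + ["log10_sl", "cos_ta"],
    "terrain_only": ["tri", "dist_disturbance", "dist_rocky", "log10_sl", "cos_ta"],
    "movement_only": ["log10_sl", "cos_ta"],
    "null": [],
}


class SeparationError(RuntimeError):
    """Raised when a covariate perfectly ranks cases (divergent beta)."""


@dataclass
class TentativeKernel:
    gamma_shape: float
    gamma_scale: float
    vm_kappa: float

    def __post_init__(self) -> None:
        if self.gamma_shape <= 0 or self.gamma_scale <= 0:
            raise ValueError("gamma parameters must be > 0")
        if self.vm_kappa < 0:
            raise ValueError("vm_kappa must be >= 0")


@dataclass
class UpdatedKernel:
    gamma_shape: float
    gamma_scale: float
    vm_kappa: float
    valid: bool


@dataclass
class CLogitFit:
    terms: list[str]
    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    n_strata: int
    n_dropped_strata: int = 0

    @property
    def k_params(self) -> int:
        return len(self.terms)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0, np.inf))

    @property
    def aicc(self) -> float:
        k, n = self.k_params, self.n_strata
        penalty = 2 * k * (k + 1) / (n - k - 1) if n - k - 1 > 0 else np.inf
        return -2 * self.loglik + 2 * k + penalty

    def coef(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])

    def ci(self, term: str, z: float = 1.96) -> tuple[float, float]:
        i = self.terms.index(term)
        return (float(self.beta[i] - z * self.se[i]), float(self.beta[i] + z * self.se[i]))


# ---------------------------------------------------------------------------
# tentative kernel

def vonmises_kappa_mle(mean_cos: float, kappa_max: float = 500.0) -> float:
    """Solve I1(kappa)/I0(kappa) = mean_cos for kappa (mean angle fixed at 0)."""
    if mean_cos <= 0.0:
        return 0.0
    ratio = lambda k: special.i1e(k) / special.i0e(k) - mean_cos
    if ratio(kappa_max) < 0:
        import logging

        logging.getLogger("quollmove").warning(
            "turning angles nearly degenerate; kappa capped at %g", kappa_max)
        return kappa_max
    return float(optimize.brentq(ratio, 1e-12, kappa_max))


def fit_tentative_kernel(steps: pd.DataFrame) -> TentativeKernel:
    """ML gamma fit to observed step lengths and von Mises concentration
    (mean fixed at 0) to observed turning angles."""
    obs = steps[steps["case"] == "observed"] if "case" in steps else steps
    sl = obs["sl"].to_numpy(dtype=float)
    sl = sl[np.isfinite(sl) & (sl > 0)]
    if len(sl) < 10:
        raise ValueError("need at least 10 observed steps to fit the kernel")
    shape, _, scale = stats.gamma.fit(sl, floc=0.0)
    ta = obs["ta"].to_numpy(dtype=float)
    ta = ta[np.isfinite(ta)]
    kappa = vonmises_kappa_mle(float(np.cos(ta).mean())) if len(ta) else 0.0
    return TentativeKernel(float(shape), float(scale), kappa)


# ---------------------------------------------------------------------------
# available steps + covariates

def sample_available_steps(observed: pd.DataFrame, kernel: TentativeKernel,
                           n: int = 5, seed: int = 0) -> pd.DataFrame:
    """Draw ``n`` available steps per observed step from the tentative
    kernel, sharing the observed step's start point and stratum.

    Turning angles are relative to the previous step's heading; at burst
    starts (no previous heading) a uniform random heading is used.
    """
    obs = observed[observed["case"] == "observed"].reset_index(drop=True)
    rng = np.random.default_rng(seed)
    m = len(obs)
    lengths = rng.gamma(kernel.gamma_shape, kernel.gamma_scale, (m, n))
    turns = rng.vonmises(0.0, kernel.vm_kappa, (m, n)) if kernel.vm_kappa > 0 \
        else rng.uniform(-np.pi, np.pi, (m, n))
    prev = obs["prev_heading"].to_numpy(dtype=float)
    prev = np.where(np.isfinite(prev), prev, rng.uniform(-np.pi, np.pi, m))
    headings = prev[:, None] + turns
    end_x = obs["start_x"].to_numpy()[:, None] + lengths * np.cos(headings)
    end_y = obs["start_y"].to_numpy()[:, None] + lengths * np.sin(headings)

    rep = lambda col: np.repeat(obs[col].to_numpy(), n)
    avail = pd.DataFrame(
        {
            "stratum_id": rep("stratum_id"),
            "individual_id": rep("individual_id"),
            "season": rep("season"),
            "age": rep("age"),
            "case": "available",
            "burst_id": rep("burst_id"),
            "start_x": rep("start_x"), "start_y": rep("start_y"),
            "end_x": end_x.ravel(), "end_y": end_y.ravel(),
            "t_start": rep("t_start"), "t_end": rep("t_end"),
            "sl": lengths.ravel(),
            "ta": turns.ravel(),
            "prev_heading": np.repeat(prev, n),
        }
    )
    with np.errstate(divide="ignore"):
        avail["log10_sl"] = np.log10(avail["sl"])
    avail["cos_ta"] = np.cos(avail["ta"])
    out = pd.concat([obs, avail], ignore_index=True)
    return out.sort_values(["stratum_id", "case"], ascending=[True, False],
                           kind="stable").reset_index(drop=True)


def attach_covariates(steps: pd.DataFrame, landscape: Landscape) -> pd.DataFrame:
    """End-of-step covariate lookup; flags off-raster and water endpoints.

    Flagged steps carry ``drop_flag = True``: they are excluded from
    fitting (the whole stratum goes if the observed step is flagged).
    """
    steps = steps.copy()
    x, y = steps["end_x"].to_numpy(), steps["end_y"].to_numpy()
    cov = landscape.covariates_at(x, y)
    hab = np.asarray(cov["habitat"])
    off = hab == landscape.habitat.nodata
    water = hab == HABITAT_CODES["water"]
    steps["habitat"] = hab
    for name in HABITAT_DUMMIES:
        steps[name] = (hab == HABITAT_CODES[name]).astype(float)
    for name in ("tri", "dist_disturbance", "dist_rocky"):
        steps[name] = np.asarray(cov[name])
    steps["drop_flag"] = off | water
    return steps


# ---------------------------------------------------------------------------
# conditional logistic fitting

def build_design(steps: pd.DataFrame, terms: list[str]) -> np.ndarray:
    cols = []
    for term in terms:
        if ":" in term:
            a, b = term.split(":", 1)
            cols.append(steps[a].to_numpy(dtype=float) * steps[b].to_numpy(dtype=float))
        else:
            cols.append(steps[term].to_numpy(dtype=float))
    return np.column_stack(cols) if cols else np.empty((len(steps), 0))


def _prepare_strata(steps: pd.DataFrame, terms: list[str]):
    """Apply the stratum dropping rules and return (X, case, group_idx, S, dropped)."""
    df = steps
    if "drop_flag" in df.columns:
        flagged_obs = df.loc[(df["case"] == "observed") & df["drop_flag"], "stratum_id"]
        df = df[~df["stratum_id"].isin(set(flagged_obs))]
        df = df[~df["drop_flag"].astype(bool)]
    X = build_design(df, terms)
    finite = np.isfinite(X).all(axis=1) if X.size else np.ones(len(df), dtype=bool)
    obs_bad = df.loc[(df["case"] == "observed").to_numpy() & ~finite, "stratum_id"]
    keep = finite & ~df["stratum_id"].isin(set(obs_bad)).to_numpy()
    df, X = df[keep], X[keep]

    # strata need one observed case and >= 1 available alternative
    counts = df.groupby("stratum_id")["case"].agg(
        n_obs=lambda s: (s == "observed").sum(), n=lambda s: len(s))
    valid = counts[(counts["n_obs"] == 1) & (counts["n"] >= 2)].index
    df_fit = df[df["stratum_id"].isin(valid)]
    X = build_design(df_fit, terms)

    # drop zero-information strata (identical covariate rows throughout)
    sid = df_fit["stratum_id"].to_numpy()
    order = np.argsort(sid, kind="stable")
    sid, X = sid[order], X[order]
    case = (df_fit["case"].to_numpy() == "observed")[order]
    _, group_idx = np.unique(sid, return_inverse=True)
    n_strata_all = group_idx.max() + 1 if len(group_idx) else 0
    informative = np.zeros(n_strata_all, dtype=bool)
    if X.size:
        first = np.zeros((n_strata_all, X.shape[1]))
        starts = np.r_[True, group_idx[1:] != group_idx[:-1]]
        first[group_idx[starts]] = X[starts]
        diff = np.abs(X - first[group_idx]).max(axis=1) if X.shape[1] else np.zeros(len(X))
        np.maximum.at(informative, group_idx, diff > 0)
    else:
        informative[:] = True  # null model: every stratum contributes ln(1/m)
    keep_rows = informative[group_idx]
    X, case, sid = X[keep_rows], case[keep_rows], sid[keep_rows]
    _, group_idx = np.unique(sid, return_inverse=True)
    S = group_idx.max() + 1 if len(group_idx) else 0
    dropped = int(n_strata_all - informative.sum())
    return X, case, group_idx, S, dropped


def _clogit_loglik(beta, X, case, group_idx, S):
    eta = X @ beta
    m = np.full(S, -np.inf)
    np.maximum.at(m, group_idx, eta)
    e = np.exp(eta - m[group_idx])
    denom = np.zeros(S)
    np.add.at(denom, group_idx, e)
    ll = float(eta[case].sum() - (m + np.log(denom)).sum())
    p = e / denom[group_idx]
    xbar = np.zeros((S, X.shape[1]))
    np.add.at(xbar, group_idx, p[:, None] * X)
    score = X[case].sum(axis=0) - xbar.sum(axis=0)
    hess = -(X.T @ (p[:, None] * X) - xbar.T @ xbar)
    return ll, score, hess


def fit_clogit(steps: pd.DataFrame, terms: list[str] | None = None,
               tol: float = 1e-8, max_iter: int = 100,
               beta_max: float = 15.0) -> CLogitFit:
    """Stratified conditional logistic regression by Newton-Raphson.

    Converged when ``max |score| < tol``; covariance is the inverse
    negative Hessian at the optimum.  Divergence (any ``|beta| >
    beta_max``) raises :class:`SeparationError` naming the covariate:
    under complete separation the partial likelihood is monotone in the
    offending coefficient and its score decays like ``exp(-beta)``, so
    a moderate cutoff catches it long before numerical overflow.
    """
    terms = GLOBAL_FORMULA if terms is None else list(terms)
    X, case, group_idx, S, dropped = _prepare_strata(steps, terms)
    if S == 0:
        raise ValueError("no informative strata to fit")
    if not terms:
        counts = np.bincount(group_idx)
        ll = float(-np.log(counts).sum())
        return CLogitFit([], np.empty(0), np.empty((0, 0)), ll, S, dropped)

    beta = np.zeros(len(terms))
    ll, score, hess = _clogit_loglik(beta, X, case, group_idx, S)
    for _ in range(max_iter):
        if np.abs(score).max() < tol:
            break
        try:
            step = np.linalg.solve(hess, -score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, -score, rcond=None)[0]
        # step-halving line search
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, score_new, hess_new = _clogit_loglik(cand, X, case, group_idx, S)
            if ll_new >= ll - 1e-12:
                beta, ll, score, hess = cand, ll_new, score_new, hess_new
                break
            factor /= 2.0
        else:
            break
        if np.abs(beta).max() > beta_max:
            offender = terms[int(np.argmax(np.abs(beta)))]
            raise SeparationError(
                f"covariate '{offender}' appears completely separated (|beta| > {beta_max})"
            )
    else:
        if np.abs(score).max() >= tol:
            raise RuntimeError("conditional logistic fit did not converge")
    cov = np.linalg.inv(-hess)
    return CLogitFit(terms, beta, cov, ll, S, dropped)


def select_models(steps: pd.DataFrame, candidates: dict[str, list[str]] | None = None,
                  delta_support: float = 2.0) -> pd.DataFrame:
    """Fit each candidate formula and rank by AICc (support: dAICc < 2)."""
    candidates = DEFAULT_CANDIDATES if candidates is None else candidates
    rows = []
    fits = {}
    for name, terms in candidates.items():
        fit = fit_clogit(steps, terms)
        fits[name] = fit
        rows.append({"model": name, "K": fit.k_params, "loglik": fit.loglik,
                     "n_strata": fit.n_strata, "AICc": fit.aicc})
    table = pd.DataFrame(rows).sort_values("AICc", kind="stable").reset_index(drop=True)
    table["dAICc"] = table["AICc"] - table["AICc"].min()
    table["support"] = table["dAICc"] < delta_support
    table.attrs["fits"] = fits
    return table


# ---------------------------------------------------------------------------
# kernel updating + RSS

def update_kernel(tentative: TentativeKernel, fit: CLogitFit) -> UpdatedKernel:
    """Correct the tentative kernel with the fitted movement coefficients.

    ``log10(sl)`` enters the design on the base-10 scale, so the gamma
    shape update divides by ln 10; the scale is untouched because no
    linear step-length covariate is in the model.
    """
    b_sl = fit.coef("log10_sl") if "log10_sl" in fit.terms else 0.0
    b_ta = fit.coef("cos_ta") if "cos_ta" in fit.terms else 0.0
    k = tentative.gamma_shape + b_sl / np.log(10.0)
    kappa = tentative.vm_kappa + b_ta
    return UpdatedKernel(k, tentative.gamma_scale, kappa, valid=(k > 0 and kappa >= 0))


@dataclass
class RSSResult:
    log_rss: float
    se: float
    rss: float
    ci: tuple[float, float]            # on the RSS scale

    @property
    def log_ci(self) -> tuple[float, float]:
        return (self.log_rss - 1.96 * self.se, self.log_rss + 1.96 * self.se)


def log_rss(fit: CLogitFit, x1: dict[str, float], x2: dict[str, float]) -> RSSResult:
    """Relative selection strength between covariate vectors x1 and x2.

    ``log RSS = beta . (z1 - z2)`` with a delta-method standard error
    from the coefficient covariance; terms absent from a dict are 0.
    """
    dz = np.array([x1.get(t, 0.0) - x2.get(t, 0.0) for t in fit.terms])
    lr = float(fit.beta @ dz)
    se = float(np.sqrt(dz @ fit.cov @ dz))
    return RSSResult(lr, se, float(np.exp(lr)),
                     (float(np.exp(lr - 1.96 * se)), float(np.exp(lr + 1.96 * se))))
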