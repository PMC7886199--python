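"""Before-After-Control-Impact inference with a heteroscedastic mixed model.

The response is one value per (site, reach, year) cell — a seasonal
thermal-regime descriptor or a reach-mean shade/light metric — for reaches
(upstream reference, thinned, downstream) and years (pre, post).  The model is

    value ~ Reach + Year + Reach:Year,  random intercept by Site,

with stratum-specific residual variances (by default one variance per
Reach x Year cell, relaxing homoscedasticity among reaches and years; the
strata are configurable to Reach-only or Year-only).  The marginal Gaussian
likelihood is maximized directly (ML or REML) over log-variances with the
fixed effects profiled out.

The treatment effects are the two double differences

    thinned:    (ThinnedPost - ThinnedPre) - (UpstreamPost - UpstreamPre)
    downstream: (DownstreamPost - DownstreamPre) - (UpstreamPost - UpstreamPre)

which under reference coding (upstream, pre) equal the Reach:Year interaction
coefficients.  Confidence intervals are Wald (t reference) or a cluster
bootstrap that resamples whole sites, the site being the independent
replicate.  An effect is called significant when its 95% CI excludes zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger("streamtherm")

REACH_LEVELS = ("upstream", "thinned", "downstream")
YEAR_LEVELS = ("pre", "post")
FIXED_NAMES = [
    "Intercept",
    "reach[thinned]",
    "reach[downstream]",
    "year[post]",
    "reach[thinned]:year[post]",
    "reach[downstream]:year[post]",
]
CONTRAST_COEF = {
    "thinned": "reach[thinned]:year[post]",
    "downstream": "reach[downstream]:year[post]",
}

_LOG_VAR_BOUNDS = (-30.0, 10.0)


class ConvergenceWarning(UserWarning):
    pass


def validate_baci_data(data: pd.DataFrame) -> pd.DataFrame:
    """Check the (site, reach, year, value) layout of a BACI table."""
    required = {"site", "reach", "year", "value"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"BACI table missing columns {sorted(missing)}")
    if not set(data["reach"]).issubset(REACH_LEVELS):
        raise ValueError(f"reach labels must be among {REACH_LEVELS}")
    if not set(data["year"]).issubset(YEAR_LEVELS):
        raise ValueError(f"year labels must be 'pre'/'post'")
    if data.duplicated(["site", "reach", "year"]).any():
        raise ValueError("one value per (site, reach, year) is required")
    if data["site"].nunique() < 2:
        raise ValueError("at least 2 sites are required")
    return data.dropna(subset=["value"]).reset_index(drop=True)


def _design(data: pd.DataFrame, var_structure: str):
    """Fixed-effect design matrix, stratum index and site codes."""
    thin = (data["reach"] == "thinned").to_numpy(float)
    down = (data["reach"] == "downstream").to_numpy(float)
    post = (data["year"] == "post").to_numpy(float)
    X = np.column_stack(
        [np.ones(len(data)), thin, down, post, thin * post, down * post]
    )
    reach_idx = data["reach"].map({r: i for i, r in enumerate(REACH_LEVELS)}).to_numpy()
    year_idx = post.astype(int)
    if var_structure == "reach_year":
        strata = reach_idx * 2 + year_idx
        n_strata = 6
    elif var_structure == "reach":
        strata, n_strata = reach_idx, 3
    elif var_structure == "year":
        strata, n_strata = year_idx, 2
    else:
        raise ValueError(f"unknown var_structure {var_structure!r}")
    sites, site_codes = np.unique(data["site"].to_numpy(), return_inverse=True)
    return X, strata.astype(int), n_strata, sites, site_codes


@dataclass
class BACIFit:
    """A converged (or best-effort) heteroscedastic mixed-model fit."""

    beta: pd.Series
    cov_beta: pd.DataFrame
    sigma2_site: float
    sigma2_strata: dict
    loglik: float
    method: str
    var_structure: str
    converged: bool
    grad_norm: float
    n_obs: int
    n_sites: int
    fitted: np.ndarray
    residuals: np.ndarray
    data: pd.DataFrame = field(repr=False)
    _strata: np.ndarray = field(repr=False, default=None)
    _site_codes: np.ndarray = field(repr=False, default=None)

    @property
    def cell_means(self) -> pd.DataFrame:
        """Model-implied cell means on the (reach, year) grid."""
        b = self.beta
        rows = {}
        for r in REACH_LEVELS:
            base = b["Intercept"] + (b.get(f"reach[{r}]", 0.0) if r != "upstream" else 0.0)
            inter = b.get(f"reach[{r}]:year[post]", 0.0) if r != "upstream" else 0.0
            rows[r] = {"pre": base, "post": base + b["year[post]"] + inter}
        return pd.DataFrame(rows).T.loc[list(REACH_LEVELS), list(YEAR_LEVELS)]


def _neg2loglik(theta, y, X, strata, n_strata, site_codes, n_sites, reml):
    s2_site = np.exp(theta[0])
    s2_g = np.exp(theta[1:])
    sig = s2_g[strata]
    n, p = X.shape
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    logdet = 0.0
    quads = []
    rows_by_site = [np.nonzero(site_codes == s)[0] for s in range(n_sites)]
    for rows in rows_by_site:
        d = sig[rows]
        Vi = np.diag(d) + s2_site
        L = np.linalg.cholesky(Vi)
        logdet += 2.0 * np.log(np.diag(L)).sum()
        Xi = X[rows]
        yi = y[rows]
        sol = np.linalg.solve(Vi, np.column_stack([Xi, yi]))
        XtVX += Xi.T @ sol[:, :p]
        XtVy += Xi.T @ sol[:, p]
        quads.append((rows, Vi))
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(XtVX, XtVy, rcond=None)[0]
    quad = 0.0
    for rows, Vi in quads:
        r = y[rows] - X[rows] @ beta
        quad += r @ np.linalg.solve(Vi, r)
    out = logdet + quad + n * np.log(2 * np.pi)
    if reml:
        sign, ld = np.linalg.slogdet(XtVX)
        out += ld - p * np.log(2 * np.pi)
    return out, beta, XtVX


def _start_values(y, X, strata, n_strata, site_codes, n_sites):
    site_means = np.array([y[site_codes == s].mean() for s in range(n_sites)])
    resid = y - site_means[site_codes]
    # remove cell structure via OLS on the saturated design
    b, *_ = np.linalg.lstsq(X, resid, rcond=None)
    resid = resid - X @ b
    s2_g = np.array(
        [max(np.var(resid[strata == g], ddof=0), 1e-4) if (strata == g).sum() else 0.05
         for g in range(n_strata)]
    )
    s2_site = max(np.var(site_means, ddof=1) - s2_g.mean() / max((strata >= 0).sum() / n_sites, 1), 1e-4)
    return np.log(np.concatenate([[s2_site], s2_g]))


def fit_baci_lmm(
    data: pd.DataFrame,
    method: str = "REML",
    var_structure: str = "reach_year",
    tol: float = 1e-8,
    max_starts: int = 3,
) -> BACIFit:
    """Fit the BACI mixed model by direct likelihood maximization.

    Variance parameters (site-intercept variance and one residual variance
    per stratum) are optimized on the log scale with the fixed effects
    profiled out; on optimizer failure up to ``max_starts`` jittered restarts
    are tried and the best point is returned with ``converged=False``.
    """
    if method not in ("ML", "REML"):
        raise ValueError("method must be 'ML' or 'REML'")
    data = validate_baci_data(data)
    y = data["value"].to_numpy(float)
    X, strata, n_strata, sites, site_codes = _design(data, var_structure)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular fixed-effect design (missing cells)")
    n_sites = len(sites)
    reml = method == "REML"

    def obj(theta):
        return _neg2loglik(theta, y, X, strata, n_strata, site_codes, n_sites, reml)[0]

    theta0 = _start_values(y, X, strata, n_strata, site_codes, n_sites)
    # scale-aware bounds keep near-zero variances representable without
    # driving the weighted cross-products matrix numerically singular
    log_scale = np.log(max(np.var(y), 1e-12))
    bounds = (log_scale - 16.0, log_scale + 8.0)
    best = None
    rng = np.random.default_rng(12345)
    for attempt in range(max_starts):
        start = theta0 if attempt == 0 else theta0 + rng.normal(0, 1.0, theta0.shape)
        res = optimize.minimize(
            obj,
            np.clip(start, *bounds),
            method="L-BFGS-B",
            bounds=[bounds] * len(theta0),
            options={"ftol": tol, "gtol": 1e-8, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
        if res.success:
            best = res if res.fun <= best.fun + 1e-10 else best
            break
    converged = bool(best.success)
    if not converged:
        logger.warning("BACI mixed-model optimizer did not converge; best point kept")

    theta = best.x
    neg2, beta, XtVX = _neg2loglik(
        theta, y, X, strata, n_strata, site_codes, n_sites, reml
    )
    grad_norm = float(np.max(np.abs(getattr(best, "jac", np.zeros(1)))))
    cov_beta = np.linalg.inv(XtVX)
    fitted = X @ beta
    beta_s = pd.Series(beta, index=FIXED_NAMES)
    strata_names = _strata_names(var_structure)
    return BACIFit(
        beta=beta_s,
        cov_beta=pd.DataFrame(cov_beta, index=FIXED_NAMES, columns=FIXED_NAMES),
        sigma2_site=float(np.exp(theta[0])),
        sigma2_strata={nm: float(np.exp(v)) for nm, v in zip(strata_names, theta[1:])},
        loglik=-0.5 * neg2,
        method=method,
        var_structure=var_structure,
        converged=converged,
        grad_norm=grad_norm,
        n_obs=len(y),
        n_sites=n_sites,
        fitted=fitted,
        residuals=y - fitted,
        data=data,
        _strata=strata,
        _site_codes=site_codes,
    )


def _strata_names(var_structure: str) -> list[str]:
    if var_structure == "reach_year":
        return [f"{r}:{yl}" for r in REACH_LEVELS for yl in YEAR_LEVELS]
    if var_structure == "reach":
        return list(REACH_LEVELS)
    return list(YEAR_LEVELS)


@dataclass
class BACIDifference:
    """A BACI double-difference estimate with its 95% CI."""

    contrast: str
    estimate: float
    lower: float
    upper: float
    ci_method: str
    significant: bool
    se: float | None = None
    df: float | None = None
    n_boot: int | None = None
    seed: int | None = None
    diagnostics: dict | None = None
    flag: str = "baci"

    def __post_init__(self) -> None:
        if not (self.lower <= self.estimate <= self.upper):
            raise ValueError("CI must bracket the estimate")


def observed_cell_means(data: pd.DataFrame) -> pd.DataFrame:
    """Sample mean per (reach, year) cell."""
    return (
        data.pivot_table(index="reach", columns="year", values="value", aggfunc="mean")
        .reindex(index=list(REACH_LEVELS), columns=list(YEAR_LEVELS))
    )


def double_difference(cell_means: pd.DataFrame, contrast: str) -> float:
    """(TreatedPost - TreatedPre) - (UpstreamPost - UpstreamPre)."""
    if contrast not in ("thinned", "downstream"):
        raise ValueError(f"unknown contrast {contrast!r}")
    cm = cell_means
    return float(
        (cm.loc[contrast, "post"] - cm.loc[contrast, "pre"])
        - (cm.loc["upstream", "post"] - cm.loc["upstream", "pre"])
    )


def baci_difference(
    fit: BACIFit, contrast: str, alpha: float = 0.05
) -> BACIDifference:
    """Wald CI for a BACI contrast from the fitted mixed model.

    Uses a t reference with containment denominator degrees of freedom
    n_obs - n_fixed - n_sites + 1, a small-sample-conservative choice for
    designs with ~10 sites.
    """
    coef = CONTRAST_COEF.get(contrast)
    if coef is None:
        raise ValueError(f"unknown contrast {contrast!r}")
    est = float(fit.beta[coef])
    se = float(np.sqrt(fit.cov_beta.loc[coef, coef]))
    df = max(fit.n_obs - len(fit.beta) - fit.n_sites + 1, 1)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    lo, hi = est - tcrit * se, est + tcrit * se
    return BACIDifference(
        contrast=contrast,
        estimate=est,
        lower=lo,
        upper=hi,
        ci_method="wald",
        significant=not (lo <= 0.0 <= hi),
        se=se,
        df=float(df),
    )


def _site_double_diffs(data: pd.DataFrame, contrast: str) -> np.ndarray:
    """Per-site plug-in double differences (requires all four cells)."""
    wide = data.pivot_table(
        index="site", columns=["reach", "year"], values="value", aggfunc="mean"
    )
    need = [(contrast, "post"), (contrast, "pre"), ("upstream", "post"), ("upstream", "pre")]
    wide = wide.dropna(subset=[c for c in need if c in wide.columns])
    for c in need:
        if c not in wide.columns:
            raise ValueError(f"cell {c} absent from BACI table")
    return (
        wide[(contrast, "post")]
        - wide[(contrast, "pre")]
        - wide[("upstream", "post")]
        + wide[("upstream", "pre")]
    ).to_numpy(float)


def bootstrap_ci(
    data: pd.DataFrame,
    contrast: str,
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
    method: str = "studentized",
) -> BACIDifference:
    """Cluster-bootstrap CI for the plug-in BACI double difference.

    Whole sites are resampled with replacement (the site is the independent
    replicate) and the double difference of resampled cell means recomputed
    per replicate.  ``method='studentized'`` (default) uses the bootstrap-t
    interval, whose small-sample coverage is close to nominal at ~10 sites;
    ``method='percentile'`` gives the plain percentile interval.
    """
    if contrast not in ("thinned", "downstream"):
        raise ValueError(f"unknown contrast {contrast!r}")
    data = validate_baci_data(data)
    d = _site_double_diffs(data, contrast)
    m = len(d)
    if m < 2:
        raise ValueError("cluster bootstrap requires at least 2 distinct sites")
    est = float(d.mean())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, m, size=(n_boot, m))
    boots = d[idx]
    theta = boots.mean(axis=1)
    if method == "percentile":
        lo, hi = np.quantile(theta, [alpha / 2, 1 - alpha / 2])
    elif method == "studentized":
        se_hat = d.std(ddof=1) / np.sqrt(m)
        if se_hat == 0:
            lo = hi = est
        else:
            se_b = boots.std(axis=1, ddof=1) / np.sqrt(m)
            t = np.where(se_b > 0, (theta - est) / np.where(se_b > 0, se_b, 1.0), 0.0)
            t_lo, t_hi = np.quantile(t, [alpha / 2, 1 - alpha / 2])
            lo, hi = est - t_hi * se_hat, est - t_lo * se_hat
    else:
        raise ValueError(f"unknown bootstrap method {method!r}")
    lo, hi = float(min(lo, est)), float(max(hi, est))
    return BACIDifference(
        contrast=contrast,
        estimate=est,
        lower=lo,
        upper=hi,
        ci_method=f"bootstrap_{method}",
        significant=not (lo <= 0.0 <= hi),
        n_boot=n_boot,
        seed=seed,
    )


def post_only_difference(
    data: pd.DataFrame, contrast: str, alpha: float = 0.05
) -> BACIDifference:
    """Post-treatment reach-minus-upstream difference (no pre-year data).

    Used when a season lacks pre-treatment coverage; flagged ``post_only`` so
    it is never read as a BACI double difference.
    """
    post = data[data["year"] == "post"]
    wide = post.pivot_table(index="site", columns="reach", values="value")
    diffs = (wide[contrast] - wide["upstream"]).dropna().to_numpy(float)
    if len(diffs) < 2:
        raise ValueError("need at least 2 sites with both reaches")
    est = float(diffs.mean())
    se = float(diffs.std(ddof=1) / np.sqrt(len(diffs)))
    tcrit = stats.t.ppf(1 - alpha / 2, len(diffs) - 1)
    return BACIDifference(
        contrast=contrast,
        estimate=est,
        lower=est - tcrit * se,
        upper=est + tcrit * se,
        ci_method="wald",
        significant=abs(est) > tcrit * se,
        se=se,
        df=float(len(diffs) - 1),
        flag="post_only",
    )


def residual_diagnostics(fit: BACIFit, alpha: float = 0.05) -> dict:
    """Normality and variance-homogeneity checks on conditional residuals.

    Site effects are removed by their BLUPs, residuals standardized by their
    stratum SDs, then tested with Shapiro-Wilk; the per-stratum variance
    ratio (max/min of standardized-residual variances) summarizes remaining
    heteroscedasticity.  Recommends the bootstrap CI when normality is
    rejected or the residuals are degenerate.
    """
    sig2 = np.array(list(fit.sigma2_strata.values()))[fit._strata]
    resid = fit.residuals.copy()
    # BLUP of each site intercept under the fitted variances
    for s in range(fit.n_sites):
        rows = fit._site_codes == s
        v = sig2[rows]
        w = 1.0 / v
        b = fit.sigma2_site * (w @ resid[rows]) / (1.0 + fit.sigma2_site * w.sum())
        resid[rows] -= b
    std = resid / np.sqrt(sig2)
    out: dict = {"n": len(std)}
    scale = max(np.ptp(fit.data["value"].to_numpy(float)), 1.0)
    if np.ptp(fit.residuals) < 1e-9 * scale:
        out.update(
            normality_stat=np.nan,
            normality_p=np.nan,
            normal=False,
            degenerate=True,
            recommend_bootstrap=True,
            variance_ratio=np.nan,
        )
        return out
    W, p = stats.shapiro(std)
    variances = [
        np.var(std[fit._strata == g], ddof=1)
        for g in np.unique(fit._strata)
        if (fit._strata == g).sum() > 1
    ]
    vr = float(max(variances) / max(min(variances), 1e-12)) if variances else np.nan
    out.update(
        normality_stat=float(W),
        normality_p=float(p),
        normal=bool(p >= alpha),
        degenerate=False,
        recommend_bootstrap=bool(p < alpha),
        variance_ratio=vr,
    )
    return out
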