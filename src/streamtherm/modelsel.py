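"""Environmental-covariate screening and AICc model selection.

Candidate fixed-effect models for a thermal response (e.g. summer MWMT) are
screened for collinearity — any set containing a covariate pair with
|Pearson r| above 0.6 is rejected, and variance inflation factors are checked
within sets — then fit by maximum likelihood, ranked by the small-sample
Akaike criterion

    AICc = -2 logL + 2k + 2k(k+1) / (n - k - 1),

and the best-supported model is refit by REML for reported coefficients.
``k`` counts fixed effects plus the residual variance (plus the random-
intercept variance when a grouping factor is used); the shared constant
cancels in rankings.  ``n`` is the number of response rows, which in this
design are pseudo-replicated reach-season observations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger("streamtherm")

#: covariates considered in the default candidate set
COVARIATES = [
    "shade",
    "light",
    "upstream_temp",
    "air_temp",
    "proximity_upstream_treatment_m",
    "distance_upstream_m",
    "reach_length_m",
    "bankfull_width_m",
    "gradient_pct",
    "aspect_deg",
    "elevation_m",
]


def correlation_matrix(df: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Pearson correlations among covariates and responses.

    Zero-variance variables get NaN rows/columns with a warning; needs at
    least 3 complete observations per pair.
    """
    cols = columns or list(df.columns)
    sub = df[cols]
    counts = sub.notna().astype(int).T @ sub.notna().astype(int)
    if (counts.to_numpy() < 3).any():
        raise ValueError("need >= 3 complete rows per variable pair")
    constant = [c for c in cols if sub[c].nunique(dropna=True) <= 1]
    if constant:
        warnings.warn(f"zero-variance variable(s), correlation undefined: {constant}")
    return sub.corr(method="pearson")


def prune_correlated(
    candidate_sets: list[tuple[str, ...]],
    corr: pd.DataFrame,
    r_threshold: float = 0.6,
) -> tuple[list[tuple[str, ...]], list[dict]]:
    """Reject candidate sets containing a highly correlated covariate pair.

    Returns (kept, rejected) where each rejection names the offending pair
    and its correlation.
    """
    kept, rejected = [], []
    for cand in candidate_sets:
        offending = None
        for i, a in enumerate(cand):
            for b in cand[i + 1 :]:
                if a in corr.index and b in corr.columns:
                    r = corr.loc[a, b]
                    if np.isfinite(r) and abs(r) > r_threshold:
                        offending = (a, b, float(r))
                        break
            if offending:
                break
        if offending:
            rejected.append(
                {"candidate": cand, "pair": offending[:2], "r": offending[2]}
            )
        else:
            kept.append(cand)
    return kept, rejected


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per covariate: 1 / (1 - R^2_j).

    Perfect collinearity yields ``inf`` for the affected covariates.
    """
    X = design.to_numpy(float)
    n, p = X.shape
    if n < p + 2:
        raise ValueError("need at least p + 2 rows for p covariates")
    out = {}
    for j, name in enumerate(design.columns):
        yj = X[:, j]
        Xo = sm.add_constant(np.delete(X, j, axis=1))
        r2 = sm.OLS(yj, Xo).fit().rsquared
        out[name] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def aicc(loglik: float, k: int, n: int) -> float:
    """AICc = -2 logL + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise ValueError("AICc undefined: n - k - 1 <= 0")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values: np.ndarray) -> np.ndarray:
    delta = np.asarray(aicc_values, float) - np.min(aicc_values)
    w = np.exp(-0.5 * delta)
    return w / w.sum()


@dataclass
class RankedModel:
    name: str
    covariates: tuple[str, ...]
    k: int
    loglik: float
    aicc: float
    delta_aicc: float
    weight: float
    formula: str


def _formula(response: str, covariates: tuple[str, ...]) -> str:
    rhs = " + ".join(covariates) if covariates else "1"
    return f"{response} ~ {rhs}"


def default_candidates(available: list[str]) -> dict[str, tuple[str, ...]]:
    """The a priori candidate list: singletons, two ecologically motivated
    combinations, the null (intercept) model and the BACI Reach:Year model."""
    cands: dict[str, tuple[str, ...]] = {"null": ()}
    for c in available:
        cands[c] = (c,)
    if "shade" in available and "upstream_temp" in available:
        cands["shade+upstream"] = ("shade", "upstream_temp")
        if "proximity_upstream_treatment_m" in available:
            cands["shade+upstream+proximity"] = (
                "shade",
                "upstream_temp",
                "proximity_upstream_treatment_m",
            )
    return cands


def rank_models(
    data: pd.DataFrame,
    response: str,
    candidates: dict[str, tuple[str, ...]],
    group: str | None = None,
) -> tuple[pd.DataFrame, object]:
    """Fit candidates by ML, rank by AICc, refit the best by REML.

    All candidates share the response rows and the random structure (a random
    intercept on ``group`` when given, otherwise ordinary least squares, in
    which case the "REML refit" is the same OLS fit).  Candidates with
    n - k - 1 <= 0 are excluded with a warning.  Ties (delta AICc < 1e-6) are
    broken in favor of fewer parameters.  Returns the ranked table and the
    refit best model results object.
    """
    rows: list[RankedModel] = []
    n = len(data)
    fits = {}
    for name, cov in candidates.items():
        formula = _formula(response, cov)
        # k: intercept + covariates + residual variance (+ site variance)
        k = len(cov) + 2 + (1 if group else 0)
        if n - k - 1 <= 0:
            warnings.warn(f"candidate {name!r} excluded: n - k - 1 <= 0")
            continue
        if group:
            model = smf.mixedlm(formula, data, groups=data[group])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = model.fit(reml=False, method="lbfgs")
            ll = fit.llf
        else:
            fit = smf.ols(formula, data).fit()
            ll = fit.llf
        fits[name] = fit
        rows.append(
            RankedModel(
                name=name,
                covariates=tuple(cov),
                k=k,
                loglik=float(ll),
                aicc=aicc(float(ll), k, n),
                delta_aicc=0.0,
                weight=0.0,
                formula=formula,
            )
        )
    if not rows:
        raise ValueError("no fittable candidate models")
    table = pd.DataFrame([r.__dict__ for r in rows])
    table["delta_aicc"] = table["aicc"] - table["aicc"].min()
    table["weight"] = akaike_weights(table["aicc"].to_numpy())
    # ties (delta AICc below 1e-6) resolve toward the smaller model
    table["_key"] = np.round(table["aicc"] / 1e-6).astype(np.int64)
    table = (
        table.sort_values(["_key", "k"], kind="stable")
        .drop(columns="_key")
        .reset_index(drop=True)
    )

    best = table.iloc[0]
    if group:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            refit = smf.mixedlm(
                best["formula"], data, groups=data[group]
            ).fit(reml=True, method="lbfgs")
    else:
        refit = fits[best["name"]]
    logger.info("best supported model: %s (AICc %.2f)", best["name"], best["aicc"])
    return table, refit
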