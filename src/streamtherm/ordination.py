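"""Multivariate structure of thermal regimes: NMS ordination and PerMANOVA.

Rows of the regime matrix are (site, reach, water-year, season) combinations;
columns are the selected descriptors (the 14 named magnitude / variability /
frequency / duration descriptors by default).  Because descriptors mix units
(degC, degC^2, day counts) the columns are z-standardized before Euclidean
distances are formed; raw mode is available.

Ordination is non-metric multidimensional scaling in two dimensions
minimizing Kruskal stress-1, run as best-of-many random restarts (up to 999)
seeded additionally with the classical metric-MDS configuration, stopping
early once two restarts agree to 1e-4 stress.

The Reach, Year and Reach:Year effects on the distance structure are tested
by PerMANOVA: squared Euclidean distances are partitioned by the sequential
design projections (McArdle-Anderson), pseudo-F per term, significance by
free permutation of rows (a restricted within-site scheme is available and
more conservative).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2
from sklearn.manifold import smacof

logger = logging.getLogger("streamtherm")

#: the named descriptor suite used for the default regime matrix
DEFAULT_DESCRIPTORS = [
    "avg_daily_max",
    "mwmt",
    "avg_daily_mean",
    "mwat",
    "degree_days",
    "avg_daily_min",
    "avg_daily_range",
    "max_daily_range",
    "avg_variance",
    "max_variance",
    "days_gt_16",
    "consec_days_gt_16",
    "days_gt_20",
    "consec_days_gt_20",
]


@dataclass
class RegimeMatrix:
    values: np.ndarray  # rows x descriptors, standardized unless raw
    labels: pd.DataFrame  # site, reach, water_year, season per row
    columns: list[str]
    means: np.ndarray | None
    sds: np.ndarray | None
    standardized: bool

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]


def build_matrix(
    descriptor_table: pd.DataFrame,
    descriptor_list: list[str] | None = None,
    season: str | None = None,
    standardize: bool = True,
) -> RegimeMatrix:
    """Assemble the (rows x descriptors) regime matrix.

    Rows with any unavailable descriptor are dropped with a logged count;
    constant columns cannot be z-scored and are dropped with a warning.
    """
    cols = list(descriptor_list or DEFAULT_DESCRIPTORS)
    df = descriptor_table
    if season is not None:
        df = df[df["season"] == season]
    missing = [c for c in cols if c not in df.columns or df[c].isna().all()]
    if missing:
        raise ValueError(f"descriptor(s) absent for all rows: {missing}")
    keep = df.dropna(subset=cols)
    dropped = len(df) - len(keep)
    if dropped:
        logger.info("dropped %d rows with unavailable descriptors", dropped)
    if keep.empty:
        raise ValueError("no complete rows for the requested descriptors")
    X = keep[cols].to_numpy(float)
    means = sds = None
    if standardize:
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=0)
        const = sds == 0
        if const.any():
            names = [c for c, is_c in zip(cols, const) if is_c]
            warnings.warn(f"constant descriptor column(s) dropped: {names}")
            X = X[:, ~const]
            cols = [c for c in cols if c not in names]
            means, sds = means[~const], sds[~const]
        X = (X - means) / sds
    label_cols = [c for c in ("site", "reach", "water_year", "season") if c in keep]
    return RegimeMatrix(
        values=X,
        labels=keep[label_cols].reset_index(drop=True),
        columns=cols,
        means=means,
        sds=sds,
        standardized=standardize,
    )


@dataclass
class OrdinationResult:
    coordinates: np.ndarray
    stress: float
    n_restarts: int
    converged: bool
    seed: int
    labels: pd.DataFrame | None = None


def _classical_mds(D: np.ndarray, dims: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(G)
    order = np.argsort(w)[::-1][:dims]
    w = np.clip(w[order], 0, None)
    return V[:, order] * np.sqrt(w)


def kruskal_stress(D: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against target distances."""
    d = pdist(coords)
    target = squareform(D, checks=False)
    denom = (d**2).sum()
    if denom == 0:
        return 0.0 if np.allclose(target, 0) else 1.0
    return float(np.sqrt(((d - target) ** 2).sum() / denom))


def nms_ordination(
    matrix: RegimeMatrix | np.ndarray,
    dims: int = 2,
    max_restarts: int = 999,
    seed: int = 0,
    early_stop_tol: float = 1e-4,
) -> OrdinationResult:
    """Best-of-restarts non-metric MDS on Euclidean descriptor distances.

    The first start is the classical (metric) MDS configuration — which also
    guarantees the non-metric solution is never worse than metric MDS on the
    same distances — followed by random starts; stops once the two best
    stresses agree within ``early_stop_tol``.
    """
    X = matrix.values if isinstance(matrix, RegimeMatrix) else np.asarray(matrix, float)
    labels = matrix.labels if isinstance(matrix, RegimeMatrix) else None
    n = X.shape[0]
    if n < dims + 1:
        raise ValueError(f"need at least {dims + 1} rows for a {dims}-D ordination")
    D = squareform(pdist(X))
    if np.allclose(D, 0):
        raise ValueError("degenerate input: all rows identical")
    rng = np.random.default_rng(seed)
    best_coords, stresses = None, []
    converged = False
    n_done = 0
    for r in range(max_restarts):
        init = _classical_mds(D, dims) if r == 0 else rng.normal(size=(n, dims))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords, stress = smacof(
                D,
                metric=False,
                n_components=dims,
                init=init,
                n_init=1,
                max_iter=300,
                eps=1e-9,
                random_state=0,
                normalized_stress=True,
            )
        stresses.append(stress)
        n_done = r + 1
        if best_coords is None or stress < min(stresses[:-1], default=np.inf):
            best_coords = coords
        top2 = sorted(stresses)[:2]
        if len(top2) == 2 and top2[1] - top2[0] <= early_stop_tol:
            converged = True
            break
    best_coords = best_coords - best_coords.mean(axis=0)
    return OrdinationResult(
        coordinates=best_coords,
        stress=float(min(stresses)),
        n_restarts=n_done,
        converged=converged,
        seed=seed,
        labels=labels,
    )


@dataclass
class GroupEllipse:
    group: str
    center: np.ndarray
    cov: np.ndarray
    radius: float  # chi-square radius for the confidence level
    degenerate: bool


def group_ellipses(
    ordination: OrdinationResult, labels: np.ndarray | pd.Series, conf: float = 0.95
) -> dict[str, GroupEllipse]:
    """Normal-theory confidence ellipse of the point cloud per group.

    Groups with fewer than 3 points are skipped with a warning; collinear
    groups are returned flagged degenerate.
    """
    labels = np.asarray(labels)
    radius = float(np.sqrt(chi2.ppf(conf, df=2)))
    out: dict[str, GroupEllipse] = {}
    for g in pd.unique(labels):
        pts = ordination.coordinates[labels == g]
        if len(pts) < 3:
            warnings.warn(f"group {g!r} has < 3 points; ellipse skipped")
            continue
        cov = np.cov(pts.T)
        degenerate = bool(np.linalg.eigvalsh(cov).min() < 1e-12)
        out[str(g)] = GroupEllipse(
            group=str(g),
            center=pts.mean(axis=0),
            cov=cov,
            radius=radius,
            degenerate=degenerate,
        )
    return out


@dataclass
class PerMANOVAResult:
    table: pd.DataFrame  # term, df, SS, pseudo_F, p
    n_perm: int
    seed: int
    total_ss: float
    residual_ss: float
    residual_df: int


def _gower(D2: np.ndarray) -> np.ndarray:
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ D2 @ J


def _hat(X: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(X)
    return Q @ Q.T


def permanova(
    matrix: RegimeMatrix,
    n_perm: int = 999,
    seed: int = 0,
    permute_within: str | None = None,
) -> PerMANOVAResult:
    """Distance-based two-factor PerMANOVA of Reach, Year and Reach:Year.

    Sequential (balanced designs: orthogonal) sums of squares of the Gower-
    centered squared Euclidean distance matrix; pseudo-F per term against the
    residual; p = (#{F_perm >= F_obs} + 1) / (n_perm + 1) under free row
    permutation (or permutation within levels of ``permute_within``, e.g.
    'site', which is more conservative).
    """
    lab = matrix.labels
    for col in ("reach", "water_year"):
        if col not in lab:
            raise ValueError(f"label column {col!r} required for the BACI design")
    n = matrix.n_rows
    reach = pd.get_dummies(lab["reach"], drop_first=True).to_numpy(float)
    year = pd.get_dummies(lab["water_year"].astype(str), drop_first=True).to_numpy(float)
    inter = np.einsum("ij,ik->ijk", reach, year).reshape(n, -1)
    ones = np.ones((n, 1))
    designs = [
        ("reach", np.hstack([ones, reach])),
        ("water_year", np.hstack([ones, reach, year])),
        ("reach:water_year", np.hstack([ones, reach, year, inter])),
    ]
    dfs = [reach.shape[1], year.shape[1], inter.shape[1]]
    df_res = n - 1 - sum(dfs)
    if df_res <= 0:
        raise ValueError("fewer residual df than the design requires")

    D2 = squareform(pdist(matrix.values)) ** 2
    G = _gower(D2)
    H_prev = _hat(ones)
    increments = []
    for (_, Xk), dfk in zip(designs, dfs):
        Hk = _hat(Xk)
        increments.append(Hk - H_prev)
        H_prev = Hk
    R = np.eye(n) - H_prev  # residual projector

    def ss_terms(Gp):
        ss = np.array([np.sum(inc * Gp) for inc in increments])
        ss_res = np.sum(R * Gp)
        return ss, ss_res

    ss_obs, ss_res = ss_terms(G)
    F_obs = (ss_obs / dfs) / (ss_res / df_res)

    rng = np.random.default_rng(seed)
    count = np.zeros(len(dfs))
    groups = None
    if permute_within is not None:
        groups = lab[permute_within].to_numpy()
    for _ in range(n_perm):
        if groups is None:
            perm = rng.permutation(n)
        else:
            perm = np.arange(n)
            for g in pd.unique(groups):
                idx = np.nonzero(groups == g)[0]
                perm[idx] = idx[rng.permutation(len(idx))]
        Gp = G[np.ix_(perm, perm)]
        ss_p, ss_res_p = ss_terms(Gp)
        F_p = (ss_p / dfs) / (ss_res_p / df_res)
        count += F_p >= F_obs
    p = (count + 1) / (n_perm + 1)

    table = pd.DataFrame(
        {
            "term": [name for name, _ in designs],
            "df": dfs,
            "ss": ss_obs,
            "pseudo_F": F_obs,
            "p": p,
        }
    )
    return PerMANOVAResult(
        table=table,
        n_perm=n_perm,
        seed=seed,
        total_ss=float(np.trace(G)),
        residual_ss=float(ss_res),
        residual_df=int(df_res),
    )
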