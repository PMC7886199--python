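"""Regime matrix, NMS ordination, ellipses and PerMANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from streamtherm import ordination as od


def _toy_table(n_sites=10, seasons=("Summer",), rng=None):
    rng = rng or np.random.default_rng(0)
    rows = []
    for s in range(n_sites):
        for reach in ("upstream", "thinned", "downstream"):
            for wy in (2016, 2018):
                for season in seasons:
                    row = {"site": f"S{s}", "reach": reach, "water_year": wy,
                           "season": season}
                    for c in od.DEFAULT_DESCRIPTORS:
                        row[c] = rng.normal()
                    rows.append(row)
    return pd.DataFrame(rows)


def test_matrix_row_count_and_standardization():
    tab = _toy_table()
    m = od.build_matrix(tab, season="Summer")
    assert m.n_rows == 60
    np.testing.assert_allclose(m.values.mean(axis=0), 0.0, atol=1e-12)
    np.testing.assert_allclose(m.values.std(axis=0), 1.0, atol=1e-12)


def test_constant_column_dropped_with_warning():
    tab = _toy_table()
    tab["days_gt_20"] = 0.0
    with pytest.warns(UserWarning, match="days_gt_20"):
        m = od.build_matrix(tab, season="Summer")
    assert "days_gt_20" not in m.columns


def test_absent_descriptor_errors():
    tab = _toy_table().drop(columns=["mwat"])
    with pytest.raises(ValueError, match="mwat"):
        od.build_matrix(tab, season="Summer")


def test_rows_with_missing_descriptors_dropped():
    tab = _toy_table()
    tab.loc[tab.index[:5], "mwmt"] = np.nan
    m = od.build_matrix(tab, season="Summer")
    assert m.n_rows == 55


# ------------------------------------------------------------------- NMS
def test_planar_data_embeds_with_negligible_stress():
    rng = np.random.default_rng(1)
    plane = rng.normal(size=(30, 2))
    X = plane @ rng.normal(size=(2, 8))  # exact 2-D structure in 8-D
    res = od.nms_ordination(X, seed=0, max_restarts=8)
    assert res.stress < 0.01


def test_equilateral_triangle_zero_stress():
    X = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
    res = od.nms_ordination(X, seed=0, max_restarts=4)
    assert res.stress == pytest.approx(0.0, abs=1e-4)


def test_nms_beats_or_matches_metric_mds():
    """Metric-MDS oracle: its configuration's stress-1 is an upper bound."""
    rng = np.random.default_rng(2)
    for _ in range(5):
        X = rng.normal(size=(30, 5))
        D = squareform(pdist(X))
        metric_cfg = od._classical_mds(D, 2)
        metric_stress = od.kruskal_stress(D, metric_cfg)
        res = od.nms_ordination(X, seed=0, max_restarts=4)
        assert res.stress <= metric_stress + 1e-9


def test_nms_preserves_distance_rank_order():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(25, 4))
    res = od.nms_ordination(X, seed=1, max_restarts=8)
    if res.stress < 0.1:
        from scipy.stats import spearmanr

        rho = spearmanr(pdist(X), pdist(res.coordinates)).statistic
        assert rho > 0.95


def test_nms_seed_reproducible_and_centered():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(20, 6))
    r1 = od.nms_ordination(X, seed=9, max_restarts=6)
    r2 = od.nms_ordination(X, seed=9, max_restarts=6)
    np.testing.assert_array_equal(r1.coordinates, r2.coordinates)
    np.testing.assert_allclose(r1.coordinates.mean(axis=0), 0.0, atol=1e-9)


def test_degenerate_identical_rows_rejected():
    with pytest.raises(ValueError, match="identical"):
        od.nms_ordination(np.ones((5, 3)), seed=0)


# -------------------------------------------------------------- ellipses
def test_ellipse_containment_isotropic_gaussian():
    rng = np.random.default_rng(5)
    pts = rng.normal(size=(4000, 2))
    res = od.OrdinationResult(coordinates=pts, stress=0.0, n_restarts=1,
                              converged=True, seed=0)
    ell = od.group_ellipses(res, np.repeat("a", len(pts)))["a"]
    # near-circular and contains ~95% of the sample
    evals = np.linalg.eigvalsh(ell.cov)
    assert evals[1] / evals[0] < 1.2
    d = pts - ell.center
    cov_inv = np.linalg.inv(ell.cov)
    maha2 = np.einsum("ij,jk,ik->i", d, cov_inv, d)
    inside = (maha2 <= ell.radius**2).mean()
    assert inside == pytest.approx(0.95, abs=0.015)


def test_identical_groups_congruent_ellipses():
    rng = np.random.default_rng(6)
    pts = rng.normal(size=(30, 2))
    coords = np.vstack([pts, pts])
    labels = np.array(["a"] * 30 + ["b"] * 30)
    res = od.OrdinationResult(coords, 0.0, 1, True, 0)
    e = od.group_ellipses(res, labels)
    np.testing.assert_allclose(e["a"].center, e["b"].center)
    np.testing.assert_allclose(e["a"].cov, e["b"].cov)


def test_collinear_group_flagged_small_group_skipped():
    coords = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [5.0, 0.0], [6.0, 1.0]])
    labels = np.array(["line"] * 3 + ["tiny"] * 2)
    res = od.OrdinationResult(coords, 0.0, 1, True, 0)
    with pytest.warns(UserWarning, match="tiny"):
        e = od.group_ellipses(res, labels)
    assert e["line"].degenerate and "tiny" not in e


# -------------------------------------------------------------- PerMANOVA
def test_permanova_partitions_total_ss():
    m = od.build_matrix(_toy_table(), season="Summer")
    res = od.permanova(m, n_perm=49, seed=0)
    assert res.table["ss"].sum() + res.residual_ss == pytest.approx(
        res.total_ss, abs=1e-8
    )


def test_permanova_separated_groups_minimal_p():
    tab = _toy_table()
    # translate post-treatment thinned rows far away -> strong interaction
    mask = (tab.reach == "thinned") & (tab.water_year == 2018)
    tab.loc[mask, od.DEFAULT_DESCRIPTORS] += 100.0
    m = od.build_matrix(tab, season="Summer")
    res = od.permanova(m, n_perm=199, seed=0)
    inter = res.table.set_index("term").loc["reach:water_year"]
    assert inter["p"] == pytest.approx(1 / 200)


def test_permanova_seed_reproducible():
    m = od.build_matrix(_toy_table(), season="Summer")
    p1 = od.permanova(m, n_perm=99, seed=5).table["p"]
    p2 = od.permanova(m, n_perm=99, seed=5).table["p"]
    pd.testing.assert_series_equal(p1, p2)


def test_permanova_one_way_f_matches_scikit_bio():
    """Cross-check the pseudo-F computation against the independent
    scikit-bio implementation on a one-way design."""
    skbio_stats = pytest.importorskip("skbio.stats.distance")
    rng = np.random.default_rng(8)
    X = rng.normal(size=(24, 4))
    X[:12] += 1.5
    labels = ["a"] * 12 + ["b"] * 12
    tab = pd.DataFrame(X, columns=od.DEFAULT_DESCRIPTORS[:4])
    tab["site"] = [f"S{i}" for i in range(24)]
    tab["reach"] = labels
    tab["water_year"] = 2016
    tab["season"] = "Summer"
    # one-way: use reach only by collapsing year variation (single level)
    m = od.build_matrix(tab, descriptor_list=od.DEFAULT_DESCRIPTORS[:4],
                        standardize=False)
    # direct recomputation of the reach term against skbio's one-way F
    dm = skbio_stats.DistanceMatrix(squareform(pdist(X)))
    sk = skbio_stats.permanova(dm, grouping=labels, permutations=99)
    n = 24
    ones = np.ones((n, 1))
    reach = pd.get_dummies(pd.Series(labels), drop_first=True).to_numpy(float)
    G = od._gower(squareform(pdist(X)) ** 2)
    H = od._hat(np.hstack([ones, reach]))
    ss_t = np.sum((H - od._hat(ones)) * G)
    ss_r = np.sum((np.eye(n) - H) * G)
    F_ours = (ss_t / 1) / (ss_r / (n - 2))
    assert F_ours == pytest.approx(sk["test statistic"], rel=1e-10)


def test_permanova_duplicated_rows_match_direct_recomputation():
    """Duplicating every row: our result equals a direct one-way
    recomputation on the duplicated data (invariance of the SS algebra)."""
    skbio_stats = pytest.importorskip("skbio.stats.distance")
    rng = np.random.default_rng(9)
    X = rng.normal(size=(12, 3))
    labels = ["a"] * 6 + ["b"] * 6
    X2 = np.vstack([X, X])
    labels2 = labels + labels
    n = len(labels2)
    ones = np.ones((n, 1))
    g = pd.get_dummies(pd.Series(labels2), drop_first=True).to_numpy(float)
    G = od._gower(squareform(pdist(X2)) ** 2)
    H = od._hat(np.hstack([ones, g]))
    ss_t = np.sum((H - od._hat(ones)) * G)
    ss_r = np.sum((np.eye(n) - H) * G)
    F_ours = ss_t / (ss_r / (n - 2))
    dm = skbio_stats.DistanceMatrix(squareform(pdist(X2)))
    sk = skbio_stats.permanova(dm, grouping=labels2, permutations=49)
    assert F_ours == pytest.approx(sk["test statistic"], rel=1e-10)
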