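"""End-to-end orchestration: generate or load data, then run every stage.

The stages mirror the analysis workflow of a replicated three-reach thinning
experiment: seasonal descriptor tables from hourly series, BACI mixed-model
contrasts per descriptor and season (bootstrap CIs when residual normality is
rejected), anchored longitudinal profiles, NMS + PerMANOVA on the seasonal
regime matrix, and AICc covariate selection for the summer responses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import baci as _baci
from . import descriptors as _desc
from . import modelsel as _ms
from . import ordination as _ord
from . import profiles as _prof
from . import shade as _shade
from . import synth as _synth
from .io import HourlyTempSeries

logger = logging.getLogger("streamtherm")


@dataclass
class SyntheticStudy:
    config: _synth.SyntheticConfig
    temps: list[HourlyTempSeries]
    truth: _synth.SyntheticTruth
    shade: pd.DataFrame
    light: pd.DataFrame
    covariates: pd.DataFrame


def generate_study(cfg: _synth.SyntheticConfig) -> SyntheticStudy:
    """Simulate the complete study: temperatures, shade, light, covariates."""
    temps, truth = _synth.generate_hourly_temperature(cfg)
    shade, light = _synth.generate_shade_light(cfg)
    covariates = _synth.generate_covariates(cfg)
    return SyntheticStudy(cfg, temps, truth, shade, light, covariates)


def reach_rows(descriptor_table: pd.DataFrame) -> pd.DataFrame:
    """Reach-level descriptor series: the sensor at each reach's downstream
    extent, which integrates thermal exposure over the reach."""
    return descriptor_table[descriptor_table["position"] == "reach_bottom"].copy()


def baci_table(
    reach_desc: pd.DataFrame,
    descriptor: str,
    season: str,
    pre_year: int,
    post_year: int,
    sites: list[str] | None = None,
) -> pd.DataFrame:
    """Assemble the (site, reach, year, value) table for one response."""
    sub = reach_desc[reach_desc["season"] == season]
    if sites is not None:
        sub = sub[sub["site"].isin(sites)]
    sub = sub[sub["water_year"].isin([pre_year, post_year])]
    out = pd.DataFrame(
        {
            "site": sub["site"].to_numpy(),
            "reach": sub["reach"].to_numpy(),
            "year": np.where(sub["water_year"] == pre_year, "pre", "post"),
            "value": sub[descriptor].to_numpy(float),
        }
    )
    return out.dropna(subset=["value"]).reset_index(drop=True)


def analyze_response(
    data: pd.DataFrame,
    contrasts: tuple[str, ...] = ("thinned", "downstream"),
    ci: str = "auto",
    n_boot: int = 2000,
    seed: int = 0,
) -> list[_baci.BACIDifference]:
    """BACI contrasts for one response table.

    ``ci='auto'`` follows the residual diagnostics: Wald intervals when
    normality is not rejected, cluster-bootstrap otherwise.  ``'wald'`` and
    ``'bootstrap'`` force a method.  When a contrast lacks pre-treatment data
    the post-only reach difference is reported, flagged ``post_only``.
    """
    has_pre = (data["year"] == "pre").any()
    out = []
    if not has_pre:
        for contrast in contrasts:
            out.append(_baci.post_only_difference(data, contrast))
        return out
    fit = _baci.fit_baci_lmm(data, method="REML")
    diag = _baci.residual_diagnostics(fit)
    use_boot = ci == "bootstrap" or (ci == "auto" and diag["recommend_bootstrap"])
    for contrast in contrasts:
        if use_boot:
            d = _baci.bootstrap_ci(data, contrast, n_boot=n_boot, seed=seed)
        else:
            d = _baci.baci_difference(fit, contrast)
        d.diagnostics = diag
        out.append(d)
    return out


def run_baci_suite(
    reach_desc: pd.DataFrame,
    pre_year: int,
    post_year: int,
    descriptors: list[str] | None = None,
    seasons: tuple[str, ...] = _desc.SEASONS,
    sites: list[str] | None = None,
    ci: str = "auto",
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """The machine analog of the thinned/downstream response tables:
    one row per (response descriptor, season, contrast)."""
    descriptors = descriptors or _desc.DESCRIPTORS
    rows = []
    for season in seasons:
        for descriptor in descriptors:
            data = baci_table(reach_desc, descriptor, season, pre_year, post_year, sites)
            if data.empty or data["site"].nunique() < 2:
                continue
            try:
                results = analyze_response(
                    data, ci=ci, n_boot=n_boot, seed=seed
                )
            except ValueError as exc:
                logger.warning("skipping %s/%s: %s", descriptor, season, exc)
                continue
            for d in results:
                rows.append(
                    {
                        "response": descriptor,
                        "season": season,
                        "contrast": d.contrast,
                        "estimate": d.estimate,
                        "lower": d.lower,
                        "upper": d.upper,
                        "ci_method": d.ci_method,
                        "significant": d.significant,
                        "flag": d.flag,
                    }
                )
    return pd.DataFrame(rows)


def shade_light_baci(
    study: SyntheticStudy, ci: str = "auto", n_boot: int = 2000, seed: int = 0
) -> pd.DataFrame:
    """BACI contrasts for reach-mean closure, effective shade, transmission."""
    summary = _shade.summarize_reach(study.shade, study.light)
    pre, post = study.config.years
    rows = []
    for metric in ("canopy_closure_pct", "effective_shade_pct", "transmission_pct"):
        data = pd.DataFrame(
            {
                "site": summary["site"],
                "reach": summary["reach"],
                "year": np.where(summary["year"] == pre, "pre", "post"),
                "value": summary[metric],
            }
        ).dropna(subset=["value"])
        for d in analyze_response(data, ci=ci, n_boot=n_boot, seed=seed):
            rows.append(
                {
                    "response": metric,
                    "contrast": d.contrast,
                    "estimate": d.estimate,
                    "lower": d.lower,
                    "upper": d.upper,
                    "ci_method": d.ci_method,
                    "significant": d.significant,
                }
            )
    return pd.DataFrame(rows)


def run_profiles(
    descriptor_table: pd.DataFrame,
    descriptor: str = "mwmt",
    seasons: tuple[str, ...] = _desc.SEASONS,
    tol: float = 0.2,
) -> tuple[list[_prof.LongitudinalProfile], pd.DataFrame]:
    """Anchored profiles and trajectory labels for every site and season."""
    profs, rows = [], []
    for site in sorted(descriptor_table["site"].unique()):
        for season in seasons:
            try:
                p = _prof.build_profile(descriptor_table, site, season, descriptor)
            except ValueError:
                continue
            profs.append(p)
            try:
                label = _prof.classify_trajectory(p, tol=tol)
            except ValueError:
                label = "unclassified"
            rows.append({"site": site, "season": season, "trajectory": label})
    return profs, pd.DataFrame(rows)


def run_ordination(
    reach_desc: pd.DataFrame,
    season: str,
    seed: int = 0,
    n_perm: int = 999,
    max_restarts: int = 999,
    descriptor_list: list[str] | None = None,
) -> tuple[_ord.OrdinationResult, dict, _ord.PerMANOVAResult]:
    """NMS ordination, reach ellipses and the Reach:Year PerMANOVA for one
    season's regime matrix."""
    matrix = _ord.build_matrix(reach_desc, descriptor_list=descriptor_list, season=season)
    ordn = _ord.nms_ordination(matrix, seed=seed, max_restarts=max_restarts)
    ellipses = _ord.group_ellipses(ordn, matrix.labels["reach"])
    perm = _ord.permanova(matrix, n_perm=n_perm, seed=seed)
    return ordn, ellipses, perm


def model_selection_table(
    study: SyntheticStudy,
    reach_desc: pd.DataFrame,
    response_descriptor: str = "mwmt",
    season: str = "Summer",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Covariate screening and AICc ranking for a summer thermal response.

    The response is the per-site thinned-reach change (post - pre) in the
    descriptor; covariates combine the physical site table with observed
    shade and light changes.  Returns (ranked AICc table, correlation
    matrix).
    """
    pre, post = study.config.years
    data = baci_table(reach_desc, response_descriptor, season, pre, post)
    per_site = data.pivot_table(index="site", columns=["reach", "year"], values="value")
    response = (
        per_site[("thinned", "post")]
        - per_site[("thinned", "pre")]
        - per_site[("upstream", "post")]
        + per_site[("upstream", "pre")]
    ).rename("response")

    summary = _shade.summarize_reach(study.shade, study.light)
    thin = summary[summary["reach"] == "thinned"].pivot_table(
        index="site",
        columns="year",
        values=["canopy_closure_pct", "transmission_pct"],
    )
    shade_change = (
        thin[("canopy_closure_pct", post)] - thin[("canopy_closure_pct", pre)]
    ).rename("shade")
    light_change = (
        thin[("transmission_pct", post)] - thin[("transmission_pct", pre)]
    ).rename("light")

    cov = study.covariates.set_index("site")
    df = pd.concat([response, shade_change, light_change], axis=1).join(cov)
    df = df.rename(
        columns={
            "upstream_temp_mean_C": "upstream_temp",
            "air_temp_mean_C": "air_temp",
        }
    ).dropna(subset=["response"])

    covars = [
        "shade",
        "light",
        "upstream_temp",
        "air_temp",
        "proximity_upstream_treatment_m",
        "gradient_pct",
    ]
    corr = _ms.correlation_matrix(df, ["response"] + covars)
    candidates = _ms.default_candidates(covars)
    kept, rejected = _ms.prune_correlated(
        list(candidates.values()), corr.loc[covars, covars]
    )
    kept_named = {n: c for n, c in candidates.items() if c in kept}
    if rejected:
        logger.info("rejected %d collinear candidate set(s)", len(rejected))
    table, _ = _ms.rank_models(df.reset_index(), "response", kept_named)
    return table, corr


@dataclass
class StudyReport:
    """Everything the end-to-end run produces."""

    descriptor_table: pd.DataFrame
    reach_descriptors: pd.DataFrame
    temperature_baci: pd.DataFrame
    shade_light_baci: pd.DataFrame
    profiles: list = field(default_factory=list)
    trajectories: pd.DataFrame | None = None
    ordination: object | None = None
    permanova: object | None = None
    model_selection: pd.DataFrame | None = None
    truth: object | None = None


def run_study(
    cfg: _synth.SyntheticConfig,
    n_boot: int = 2000,
    seed: int | None = None,
    n_perm: int = 999,
    nms_restarts: int = 50,
    ordination_season: str = "Summer",
) -> StudyReport:
    """Generate a synthetic study and run every analysis stage on it."""
    seed = cfg.seed if seed is None else seed
    study = generate_study(cfg)
    table = _desc.descriptor_table(study.temps)
    reach_desc = reach_rows(table)
    pre, post = cfg.years
    temp_baci = run_baci_suite(reach_desc, pre, post, n_boot=n_boot, seed=seed)
    sl_baci = shade_light_baci(study, n_boot=n_boot, seed=seed)
    profs, traj = run_profiles(table)
    ordn, _, perm = run_ordination(
        reach_desc, ordination_season, seed=seed, n_perm=n_perm, max_restarts=nms_restarts
    )
    ms_table, _ = model_selection_table(study, reach_desc)
    return StudyReport(
        descriptor_table=table,
        reach_descriptors=reach_desc,
        temperature_baci=temp_baci,
        shade_light_baci=sl_baci,
        profiles=profs,
        trajectories=traj,
        ordination=ordn,
        permanova=perm,
        model_selection=ms_table,
        truth=study.truth,
    )
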