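"""Reading/writing pipeline tables, run configuration and the end-to-end run.

All yields are carried internally in t/ha; kg/ha figures appear only in the
run report. Environments are identified as "SITE_YEAR" throughout.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import kinship, stability, stage1, stage2, synthetic_data, trend
from .errors import NoTrialsRetainedError, SchemaError

logger = logging.getLogger(__name__)

REQUIRED_PHENOTYPE_COLUMNS = ["trial", "genotype", "rep", "block", "yield_t_ha"]
OPTIONAL_PHENOTYPE_COLUMNS = ["site", "country", "year", "ecology", "dtf_days", "height_cm"]


def read_phenotypes(path) -> pd.DataFrame:
    """Read a plot-level phenotype CSV into typed plot records.

    Rows whose yield is not numeric are dropped with a logged count; a
    missing required column raises a :class:`SchemaError` naming it.
    """
    df = pd.read_csv(path, dtype={"genotype": str, "trial": str})
    for col in REQUIRED_PHENOTYPE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"phenotype file {path} is missing required column {col!r}")
    y = pd.to_numeric(df["yield_t_ha"], errors="coerce")
    n_bad = int((y.isna() & df["yield_t_ha"].notna()).sum() + df["yield_t_ha"].isna().sum())
    if n_bad:
        logger.warning("read_phenotypes: dropping %d row(s) with non-numeric yield", n_bad)
    df = df.assign(yield_t_ha=y)[y.notna()].reset_index(drop=True)
    df["rep"] = df["rep"].astype(int)
    df["block"] = df["block"].astype(int)
    for col in ("dtf_days", "height_cm"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


read_pedigree = kinship.Pedigree.from_csv


@dataclass
class RunConfig:
    """Everything one end-to-end run needs; YAML/JSON loadable."""

    output_dir: str = "eratrend_out"
    phenotypes: str | None = None   # CSV path; None -> simulate the preset
    pedigree: str | None = None     # CSV path; None with simulation -> simulated
    ecology: str = "rainfed_lowland"
    covariates: tuple[str, ...] = ("dtf", "height")
    h2_min: float = 0.1
    r2_min: float = 0.15
    use_nrm: bool = True
    weighted: bool = True
    fa_order: int = 2
    a1: int | None = None
    an: int | None = None
    ci_level: float = 0.95
    outlier_threshold: float | None = 4.0
    seed: int = 0

    def __post_init__(self):
        for name in ("h2_min", "r2_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        data.pop("_comment", None)
        if "covariates" in data and data["covariates"] is not None:
            data["covariates"] = tuple(data["covariates"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariates"] = list(self.covariates)
        return d


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Simulate-or-read -> stage 1 -> QC -> stage 2 -> stability -> trend.

    Writes every module's output table under ``config.output_dir`` plus a
    JSON run report, and returns the report as a dict. Deterministic for a
    given config and seed.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "seed": config.seed, "stages": {}}

    # --- data -------------------------------------------------------------
    truth = None
    if config.phenotypes is None:
        preset = synthetic_data.ecology_preset(config.ecology, seed=config.seed)
        pedigree = synthetic_data.simulate_pedigree(
            preset.n_founders, preset.n_families, preset.family_sizes, seed=config.seed
        )
        plots, truth = synthetic_data.simulate_met(preset, pedigree, seed=config.seed)
        pedigree = synthetic_data.pedigree_with_release_years(pedigree, truth)
        write_phenotypes(plots, out / "phenotypes.csv")
        pedigree.to_csv(out / "pedigree.csv")
        truth.to_json(out / "truth.json")
        report["stages"]["simulate"] = {
            "ecology": config.ecology,
            "n_genotypes": preset.n_genotypes,
            "n_envs": preset.n_envs,
            "true_beta_t_ha_yr": preset.true_beta,
        }
    else:
        plots = read_phenotypes(config.phenotypes)
        pedigree = read_pedigree(config.pedigree) if config.pedigree else None

    # --- stage 1 ------------------------------------------------------------
    results = stage1.analyze_trials(plots, config.covariates, config.outlier_threshold)
    summary = stage1.stage1_summary(results)
    summary.to_csv(out / "stage1_summary.csv", index=False)
    retained = stage1.qc_filter(results, config.h2_min, config.r2_min)
    kept_ids = {r.trial for r in retained}
    dropped = [
        {"trial": r.trial, "h2_cullis": r.h2_cullis, "reliability": r.reliability,
         "reason": "H2/reliability below QC thresholds"}
        for r in results if r.trial not in kept_ids
    ]
    report["stages"]["stage1"] = {
        "n_trials": len(results),
        "n_retained": len(retained),
        "dropped_trials": dropped,
        "outliers_removed": {r.trial: r.n_outliers_removed for r in results
                             if r.n_outliers_removed},
        "convergence": {r.trial: r.converged for r in results},
    }
    if not retained:
        raise NoTrialsRetainedError(
            f"no trials retained: all {len(results)} trials fail "
            f"H2 > {config.h2_min} and r2 > {config.r2_min}"
        )

    # --- stage 2 ------------------------------------------------------------
    table = stage2.build_gxe_table(retained)
    table.to_csv(out / "gxe_table.csv")
    conn = stage2.pairwise_connectivity(table)
    conn.to_csv(out / "connectivity.csv", index_label="trial")

    nrm = None
    if config.use_nrm and pedigree is not None:
        nrm_full = kinship.build_nrm(pedigree)
        kinship.nrm_to_csv(nrm_full, out / "nrm.csv")
        nrm = kinship.subset_nrm(nrm_full, table.genotypes)
        report["stages"]["kinship"] = {
            "n_individuals": len(pedigree),
            "sibships_among_entries": kinship.count_sibships(nrm),
        }
    fit = stage2.fit_stage2_fa2(table, nrm=nrm, n_factors=config.fa_order,
                                weighted=config.weighted)
    corr = stage2.genetic_correlation_matrix(fit)
    corr.to_csv(out / "genetic_correlations.csv", index_label="trial")
    fit.breeding_values.to_csv(out / "breeding_values.csv", index=False)
    off = corr.to_numpy()[np.triu_indices(len(corr), k=1)]
    report["stages"]["stage2"] = {
        "n_factors": fit.n_factors,
        "used_nrm": fit.used_nrm,
        "nrm_fallback": fit.nrm_fallback,
        "converged": fit.converged,
        "sigma2_g": fit.sigma2_g,
        "sigma2_theta": fit.sigma2_theta,
        "boundary_flags": fit.boundary_flags,
        "mean_genetic_correlation": float(np.nanmean(off)) if off.size else None,
    }

    # --- stability ----------------------------------------------------------
    fw = stability.fit_fw(table)
    anova = stability.fw_anova(table, fw)
    ranking = stability.stability_ranking(fw)
    pd.DataFrame({"genotype": fw.means.index, "mean": fw.means.to_numpy(),
                  "b": fw.sensitivity.to_numpy(), "mse": fw.mse.to_numpy()}
                 ).to_csv(out / "fw_results.csv", index=False)
    anova.to_csv(out / "fw_anova.csv")
    ranking.to_csv(out / "fw_ranking.csv", index=False)
    report["stages"]["stability"] = {
        "excluded_genotypes": fw.excluded,
        "regression_p": _json_safe(anova.table.loc["Regression", "p"]),
        "top5": ranking.head(5).to_dict("records"),
    }

    # --- trend ----------------------------------------------------------------
    bv = fit.breeding_values.set_index("genotype")["value"]
    if pedigree is not None:
        years = pedigree.records.set_index("genotype")["release_year"]
    elif truth is not None:
        years = truth.release_years
    else:
        raise SchemaError("genetic trend needs release years (pedigree CSV)")
    years = years.reindex(bv.index)
    known = years.notna()
    if (~known).any():
        logger.warning("trend: dropping %d genotype(s) without release year",
                       int((~known).sum()))
    tr = trend.fit_genetic_trend(bv[known], years[known].astype(int),
                                 a1=config.a1, an=config.an, ci_level=config.ci_level)
    trend.trend_table(tr, label=config.ecology).to_csv(out / "trend_table.csv", index=False)
    trend.genotype_trend_points(bv[known], years[known].astype(int)).to_csv(
        out / "trend_points.csv", index=False
    )
    report["stages"]["trend"] = {
        "gamma": tr.gamma,
        "beta_t_ha_yr": tr.beta,
        "beta_kg_ha_yr": tr.beta_kg_ha_yr,
        "se_beta_t_ha_yr": tr.se_beta,
        "r2": tr.r2,
        "a1": tr.a1,
        "an": tr.an,
        "gg_first_pct": tr.gg_first,
        "gg_first_range": list(tr.gg_first_range),
        "gg_mean_pct": tr.gg_mean,
        "gg_mean_range": list(tr.gg_mean_range),
        "beta_ci_t_ha_yr": list(tr.beta_ci),
        "n_genotypes": tr.n,
    }
    if truth is not None:
        report["truth"] = {"beta_t_ha_yr": truth.beta, "gamma": truth.gamma}

    report = _json_safe(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report
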