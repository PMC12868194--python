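"""Stage 1: per-trial linear mixed-model analysis of plot yields.

For each trial (a site x year combination) the plot model is

    y_ijk = mu + r_i + b_j(r_i) + g_k + Cov + theta_ijk

with replicates r_i and incomplete blocks b_j(r_i) random, genotypes g_k
fixed (for BLUEs) or random (for variance components and heritability), and
optional days-to-flowering / plant-height covariates. Variance components
are REML estimates; two mean-basis heritabilities are reported:

    H2_Cullis = 1 - vdBLUP / (2 sigma2_g)
    H2_Piepho = sigma2_g / (sigma2_g + vdBLUE / 2)

where vdBLUP / vdBLUE are the average variances of a difference of two
genotypic BLUPs / BLUEs. Reliability is the mean BLUP reliability
1 - PEV_k / sigma2_g. Trials are then screened on (H2, reliability).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateDataError
from .reml import (
    REMLFit,
    VarianceComponentsModel,
    blup,
    fit_reml,
    mean_pairwise_difference_variance,
)

logger = logging.getLogger(__name__)

COVARIATE_COLUMNS = {"dtf": "dtf_days", "height": "height_cm"}

#: variance-component order used throughout this module
COMPONENTS = ("rep", "block", "genotype", "residual")


@dataclass
class TrialFit:
    """Internals of one REML fit (either genotype role) on one trial."""

    trial: str
    genotype_role: str
    genotypes: list[str]
    varcomp: dict[str, float]
    fit: REMLFit = field(repr=False)
    blues: pd.DataFrame | None = None  # genotype, blue, se (fixed role)
    vcov_blues: np.ndarray | None = field(default=None, repr=False)
    blups: pd.DataFrame | None = None  # genotype, blup, pev (random role)
    pev: np.ndarray | None = field(default=None, repr=False)
    covariate_coefs: dict[str, float] = field(default_factory=dict)
    dropped_covariates: list[str] = field(default_factory=list)
    n_obs: int = 0
    converged: bool = True
    loglik: float = np.nan


@dataclass
class Stage1Result:
    """Per-trial summary feeding stage 2 and the QC filter."""

    trial: str
    blues: pd.DataFrame  # columns: genotype, blue, se
    varcomp: dict[str, float]
    h2_cullis: float
    h2_piepho: float
    reliability: float
    trial_mean: float
    covariate_coefs: dict[str, float]
    n_obs: int
    converged: bool = True
    flags: list[str] = field(default_factory=list)
    n_outliers_removed: int = 0

    def summary_row(self) -> dict:
        return {
            "trial": self.trial,
            "n_obs": self.n_obs,
            "mean_yield_t_ha": self.trial_mean,
            "h2_cullis": self.h2_cullis,
            "h2_piepho": self.h2_piepho,
            "reliability": self.reliability,
            "sigma2_g": self.varcomp.get("genotype", np.nan),
            "sigma2_error": self.varcomp["residual"],
        }


def _dummy(codes: pd.Series) -> tuple[np.ndarray, list[str]]:
    levels = sorted(codes.unique())
    Z = (codes.to_numpy()[:, None] == np.array(levels)[None, :]).astype(float)
    return Z, [str(l) for l in levels]


def _prepare(records: pd.DataFrame, covariates) -> tuple[pd.DataFrame, list[str], list[str]]:
    df = records.copy()
    df["genotype"] = df["genotype"].astype(str)
    df = df[np.isfinite(df["yield_t_ha"])]
    if df["genotype"].nunique() < 2:
        raise DegenerateDataError("need >= 2 genotypes per trial")
    if df["rep"].nunique() < 2:
        raise DegenerateDataError("need >= 2 replicates per trial")
    use, dropped = [], []
    for name in covariates:
        col = COVARIATE_COLUMNS.get(name, name)
        if col not in df.columns or df[col].isna().all():
            logger.warning("trial %s: covariate %s missing entirely; dropped",
                           df["trial"].iloc[0], name)
            dropped.append(name)
        elif np.std(df[col].to_numpy(dtype=float)) < 1e-12:
            logger.warning("trial %s: covariate %s constant; inestimable, dropped",
                           df["trial"].iloc[0], name)
            dropped.append(name)
        else:
            use.append(name)
    return df, use, dropped


def _design(df: pd.DataFrame, genotype_role: str, covariates: list[str]):
    y = df["yield_t_ha"].to_numpy(dtype=float)
    n = len(y)
    geno_codes = df["genotype"]
    Zg, genotypes = _dummy(geno_codes)

    # replicate and block-within-replicate random designs
    rep_key = df["rep"].astype(str)
    Zr, _ = _dummy(rep_key)
    block_key = rep_key + ":" + df["block"].astype(str)
    # single block per rep => block indistinguishable from rep: collapse
    blocks_per_rep = df.groupby(rep_key, observed=True)["block"].nunique()
    has_blocks = (blocks_per_rep > 1).any()
    Zb = _dummy(block_key)[0] if has_blocks else None

    cov_cols = []
    Xcov = np.empty((n, 0))
    if covariates:
        cols = [COVARIATE_COLUMNS.get(c, c) for c in covariates]
        M = df[cols].to_numpy(dtype=float)
        M = np.where(np.isfinite(M), M, np.nanmean(M, axis=0))
        Xcov = M - M.mean(axis=0)  # centered: BLUEs are means at average covariates
        cov_cols = covariates

    if genotype_role == "fixed":
        X = np.hstack([np.ones((n, 1)), Zg[:, 1:], Xcov])
        Z_list = [Zr] + ([Zb] if Zb is not None else [])
        names = ["rep"] + (["block"] if Zb is not None else [])
    else:
        X = np.hstack([np.ones((n, 1)), Xcov])
        Z_list = [Zr] + ([Zb] if Zb is not None else []) + [Zg]
        names = ["rep"] + (["block"] if Zb is not None else []) + ["genotype"]
    return y, X, Z_list, names, Zg, genotypes, cov_cols


def fit_trial_lmm(
    records: pd.DataFrame,
    genotype_role: str = "fixed",
    covariates=("dtf", "height"),
    fixed_components: dict[str, float] | None = None,
) -> TrialFit:
    """REML fit of the stage-1 plot model for a single trial.

    ``fixed_components`` freezes named variance components ("rep", "block",
    "genotype", "residual") at given values instead of estimating them; this
    is how closed-form checks impose a known design.
    """
    if genotype_role not in ("fixed", "random"):
        raise ValueError("genotype_role must be 'fixed' or 'random'")
    df, use_cov, dropped = _prepare(records, covariates)
    trial = str(df["trial"].iloc[0])
    y, X, Z_list, names, Zg, genotypes, cov_cols = _design(df, genotype_role, use_cov)

    fixed_idx = {}
    if fixed_components:
        for name, value in fixed_components.items():
            if name == "residual":
                fixed_idx[len(Z_list)] = float(value)
            elif name in names:
                fixed_idx[names.index(name)] = float(value)
    model = VarianceComponentsModel(Z_list, len(y), fixed=fixed_idx)
    fit = fit_reml(y, X, model, raise_on_failure=False)
    sig = model.variances(fit.theta)
    varcomp = {name: float(sig[k]) for k, name in enumerate(names)}
    varcomp["residual"] = float(sig[-1])
    varcomp.setdefault("block", 0.0)

    out = TrialFit(
        trial=trial,
        genotype_role=genotype_role,
        genotypes=genotypes,
        varcomp=varcomp,
        fit=fit,
        covariate_coefs={},
        dropped_covariates=dropped,
        n_obs=len(y),
        converged=fit.converged,
        loglik=fit.loglik,
    )

    m = len(genotypes)
    if genotype_role == "fixed":
        # contrast matrix mapping beta -> genotype BLUEs (mu + g_k)
        L = np.zeros((m, X.shape[1]))
        L[:, 0] = 1.0
        for k in range(1, m):
            L[k, k] = 1.0
        blue = L @ fit.beta
        C = L @ fit.vcov_beta @ L.T
        out.blues = pd.DataFrame(
            {"genotype": genotypes, "blue": blue, "se": np.sqrt(np.diag(C))}
        )
        out.vcov_blues = C
        for j, name in enumerate(cov_cols):
            out.covariate_coefs[name] = float(fit.beta[m + j])
    else:
        G = varcomp["genotype"] * np.eye(m)
        u, pev = blup(y, X, fit.beta, Zg, G, fit.Vinv)
        out.blups = pd.DataFrame(
            {"genotype": genotypes, "blup": u, "pev": np.diag(pev)}
        )
        out.pev = pev
        for j, name in enumerate(cov_cols):
            out.covariate_coefs[name] = float(fit.beta[1 + j])
    return out


def estimate_heritability(fit_random: TrialFit, fit_fixed: TrialFit | None = None):
    """(H2_Cullis, H2_Piepho, reliability) from stage-1 fits.

    The Cullis form and the reliability need the genotype-random fit; the
    Piepho form needs the BLUE difference variances from the genotype-fixed
    fit (if omitted, vdBLUE is approximated from the random fit's residual
    structure by refitting is NOT done -- pass both fits for exact values).
    Returns (0, 0, 0) with a log flag when sigma2_g is zero.
    """
    sigma2_g = fit_random.varcomp.get("genotype", 0.0)
    if sigma2_g <= 1e-12:
        logger.warning("trial %s: sigma2_g ~ 0; heritability set to 0", fit_random.trial)
        return 0.0, 0.0, 0.0
    vd_blup = mean_pairwise_difference_variance(fit_random.pev)
    h2_cullis = 1.0 - vd_blup / (2.0 * sigma2_g)

    if fit_fixed is not None and fit_fixed.vcov_blues is not None:
        vd_blue = mean_pairwise_difference_variance(fit_fixed.vcov_blues)
    else:
        vd_blue = vd_blup  # fallback; exact only in the balanced limit
    h2_piepho = sigma2_g / (sigma2_g + vd_blue / 2.0)

    pev_diag = np.diag(fit_random.pev)
    reliability = float(np.mean(1.0 - pev_diag / sigma2_g))

    clamp = lambda v: float(min(1.0, max(0.0, v)))
    return clamp(h2_cullis), clamp(h2_piepho), clamp(reliability)


def _studentized_outliers(df, fit_fixed: TrialFit, threshold: float) -> pd.Index:
    """Indices of observations with |studentized marginal residual| > threshold."""
    sub = df[np.isfinite(df["yield_t_ha"])]
    resid = fit_fixed.fit.resid
    var_marg = np.diag(fit_fixed.fit.V)
    denom = np.sqrt(np.maximum(var_marg, 1e-12))
    t = resid / denom
    return sub.index[np.abs(t) > threshold]


def analyze_trial(
    records: pd.DataFrame,
    covariates=("dtf", "height"),
    outlier_threshold: float | None = 4.0,
) -> Stage1Result:
    """Full stage-1 analysis of one trial: outlier screen, both fits, H2."""
    df = records.copy()
    n_outliers = 0
    fit_fixed = fit_trial_lmm(df, "fixed", covariates)
    if outlier_threshold is not None:
        bad = _studentized_outliers(df, fit_fixed, outlier_threshold)
        if len(bad):
            logger.warning(
                "trial %s: %d plot(s) flagged as outliers (|t| > %.1f) and set missing",
                fit_fixed.trial, len(bad), outlier_threshold,
            )
            df = df.drop(index=bad)
            n_outliers = len(bad)
            fit_fixed = fit_trial_lmm(df, "fixed", covariates)
    fit_random = fit_trial_lmm(df, "random", covariates)
    h2c, h2p, rel = estimate_heritability(fit_random, fit_fixed)

    flags = []
    if not (fit_fixed.converged and fit_random.converged):
        flags.append("non-convergence")
    if fit_random.varcomp.get("genotype", 0.0) <= 1e-12:
        flags.append("zero-genetic-variance")
    if fit_fixed.dropped_covariates:
        flags.append("dropped-covariates:" + ",".join(fit_fixed.dropped_covariates))

    observed = df.loc[np.isfinite(df["yield_t_ha"]), "yield_t_ha"]
    return Stage1Result(
        trial=fit_fixed.trial,
        blues=fit_fixed.blues,
        varcomp=fit_random.varcomp,
        h2_cullis=h2c,
        h2_piepho=h2p,
        reliability=rel,
        trial_mean=float(observed.mean()),
        covariate_coefs=fit_fixed.covariate_coefs,
        n_obs=int(len(observed)),
        converged=fit_fixed.converged and fit_random.converged,
        flags=flags,
        n_outliers_removed=n_outliers,
    )


def analyze_trials(
    records: pd.DataFrame,
    covariates=("dtf", "height"),
    outlier_threshold: float | None = 4.0,
) -> list[Stage1Result]:
    """Run :func:`analyze_trial` on every trial in a plot-record table."""
    results = []
    for trial, sub in records.groupby("trial", sort=True):
        results.append(analyze_trial(sub, covariates, outlier_threshold))
    return results


def qc_filter(
    results: list[Stage1Result],
    h2_min: float = 0.1,
    r2_min: float = 0.15,
    h2_measure: str = "cullis",
) -> list[Stage1Result]:
    """Retain high-quality trials: H2 > h2_min AND reliability > r2_min.

    Strict inequalities; each exclusion is logged with its values.
    """
    kept = []
    for res in results:
        h2 = res.h2_cullis if h2_measure == "cullis" else res.h2_piepho
        if h2 > h2_min and res.reliability > r2_min:
            kept.append(res)
        else:
            logger.info(
                "qc_filter: dropping trial %s (H2=%.3f, r2=%.3f; thresholds %.2f/%.2f)",
                res.trial, h2, res.reliability, h2_min, r2_min,
            )
    return kept


def stage1_summary(results: list[Stage1Result]) -> pd.DataFrame:
    """Per-trial summary table (mean yield, both H2, reliability)."""
    return pd.DataFrame([r.summary_row() for r in results])
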