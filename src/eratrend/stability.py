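"""Finlay-Wilkinson joint regression: stability and the regression ANOVA.

Each genotype's cell means are regressed on an environmental index (the
centered environment means of the BLUE table):

    y_ij = G_i + b_i E_j + eps_ij

b_i is the environmental sensitivity: b = 1 is average responsiveness,
b > 1 means above-average response to good environments, b < 1 stability
in the defensive sense. The genotype-by-environment interaction is then
partitioned into heterogeneity of regressions (variation of b_i around 1)
and residual, as in the classical joint-regression ANOVA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError
from .stage2 import GxETable

logger = logging.getLogger(__name__)


@dataclass
class FWResult:
    """Joint-regression fit: per-genotype means, sensitivities, residual MS."""

    means: pd.Series          # G_i, t/ha (genotype mean performance)
    sensitivity: pd.Series    # b_i, dimensionless, mean 1
    mse: pd.Series            # per-genotype residual mean square (NaN if df=0)
    env_index: pd.Series      # E_j, t/ha, centered (sums to 0)
    n_iter: int
    excluded: list[str] = field(default_factory=list)


@dataclass
class FWAnova:
    """Four-row joint-regression ANOVA (Environment/Variety/Regression/Error)."""

    table: pd.DataFrame  # index: source; columns: df, ss, ms, F, p

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="source")


def _row_regressions(Y: np.ndarray, E: np.ndarray):
    """Per-row OLS of observed cells on E (with intercept).

    Returns (G, b, sse, df) arrays; rows are assumed to have >= 2 observed
    cells with non-constant E among them.
    """
    m = Y.shape[0]
    G = np.empty(m)
    b = np.empty(m)
    sse = np.empty(m)
    dfr = np.empty(m, dtype=int)
    for i in range(m):
        obs = np.isfinite(Y[i])
        y, e = Y[i, obs], E[obs]
        sxx = np.sum((e - e.mean()) ** 2)
        if sxx < 1e-14:
            bi = 0.0  # index constant over this genotype's environments
        else:
            bi = np.sum((e - e.mean()) * (y - y.mean())) / sxx
        gi = y.mean() - bi * e.mean()
        fit = gi + bi * e
        G[i], b[i] = gi, bi
        sse[i] = np.sum((y - fit) ** 2)
        dfr[i] = obs.sum() - 2
    return G, b, sse, dfr


def fit_fw(table: GxETable, max_iter: int = 100, tol: float = 1e-10) -> FWResult:
    """Fit the joint regression by (alternating) least squares.

    The environmental index starts at the centered environment means of the
    observed cells. On a complete table the per-genotype regressions on this
    index are already the least-squares solution, so a single pass is taken;
    with missing cells, index and regressions are alternated to joint
    convergence (max |change in b| < ``tol``). After each update the index is
    re-centered and b rescaled so mean(b) = 1 (the product b_i E_j is
    invariant to this normalisation).
    """
    blues = table.blues
    counts = blues.notna().sum(axis=1)
    excluded = list(counts.index[counts < 2])
    if excluded:
        logger.warning("fit_fw: excluding genotypes in < 2 environments: %s", excluded)
        blues = blues.drop(index=excluded)
    Y = blues.to_numpy(dtype=float)
    trials = list(blues.columns)
    grand = np.nanmean(Y)
    E = np.nanmean(Y, axis=0) - grand
    if np.std(E) < 1e-12:
        raise DegenerateDataError("environmental index has zero variance")

    complete = np.isfinite(Y).all()
    G, b, sse, dfr = _row_regressions(Y, E)
    n_iter = 1
    if not complete:
        for n_iter in range(2, max_iter + 2):
            # update index: E_j = sum_i b_i (y_ij - G_i) / sum_i b_i^2
            E_new = np.empty_like(E)
            for j in range(Y.shape[1]):
                obs = np.isfinite(Y[:, j])
                denom = np.sum(b[obs] ** 2)
                E_new[j] = np.sum(b[obs] * (Y[obs, j] - G[obs])) / max(denom, 1e-14)
            E_new = E_new - E_new.mean()
            G_new, b_new, sse, dfr = _row_regressions(Y, E_new)
            scale = b_new.mean()
            if abs(scale) < 1e-12:
                raise DegenerateDataError("mean sensitivity degenerated to zero")
            b_new = b_new / scale
            E_new = E_new * scale
            delta = np.max(np.abs(b_new - b))
            E, G, b = E_new, G_new, b_new
            if delta < tol:
                break

    genos = list(blues.index)
    with np.errstate(invalid="ignore", divide="ignore"):
        mse = np.where(dfr > 0, sse / np.maximum(dfr, 1), np.nan)
    return FWResult(
        means=pd.Series(G, index=genos, name="mean"),
        sensitivity=pd.Series(b, index=genos, name="b"),
        mse=pd.Series(mse, index=genos, name="mse"),
        env_index=pd.Series(E, index=trials, name="E"),
        n_iter=n_iter,
        excluded=excluded,
    )


def fw_anova(table: GxETable, fw: FWResult) -> FWAnova:
    """Joint-regression ANOVA partitioning the G x E interaction.

    Sums of squares: Environment (index), Variety (genotype means),
    Regression (heterogeneity of the b_i around 1) and Error (deviations
    from the genotype regressions). On complete tables the four terms add
    to the corrected total exactly; with missing cells the partition is the
    analogous sequential one over observed cells. All three effect rows are
    F-tested against the Error mean square; error df = observed cells minus
    fitted parameters (1 + (n_env - 1) + 2 (n_gen - 1)).
    """
    blues = table.blues.loc[fw.means.index]
    Y = blues.to_numpy(dtype=float)
    obs = np.isfinite(Y)
    E = fw.env_index.to_numpy()
    G = fw.means.to_numpy()
    b = fw.sensitivity.to_numpy()
    grand = np.nanmean(Y)

    n_gen, n_env = Y.shape
    n_obs = int(obs.sum())

    ss_env = float(np.sum((np.ones((n_gen, 1)) * E[None, :])[obs] ** 2))
    ss_var = float(np.sum(((G - grand)[:, None] * np.ones((1, n_env)))[obs] ** 2))
    per_geno_sxx = np.array([np.sum(E[obs[i]] ** 2) for i in range(n_gen)])
    ss_reg = float(np.sum((b - 1.0) ** 2 * per_geno_sxx))
    resid = Y - (G[:, None] + np.outer(b, E))
    ss_err = float(np.nansum(resid**2))

    df_env = n_env - 1
    df_var = n_gen - 1
    df_reg = n_gen - 1
    df_err = n_obs - (1 + df_env + 2 * df_var)

    rows = []
    ms_err = ss_err / df_err if df_err > 0 else np.nan
    for source, df, ss in (
        ("Environment", df_env, ss_env),
        ("Variety", df_var, ss_var),
        ("Regression", df_reg, ss_reg),
        ("Error", df_err, ss_err),
    ):
        ms = ss / df if df > 0 else np.nan
        if source != "Error" and df_err > 0 and ms_err > 0:
            F = ms / ms_err
            p = float(stats.f.sf(F, df, df_err))
        else:
            F, p = np.nan, np.nan
        rows.append({"source": source, "df": df, "ss": ss, "ms": ms, "F": F, "p": p})
    return FWAnova(pd.DataFrame(rows).set_index("source"))


def stability_ranking(fw: FWResult, top_n: int | None = None) -> pd.DataFrame:
    """Genotypes ranked by mean performance, with sensitivities alongside.

    Sorted by mean descending, ties broken by genotype id (ascending), so a
    "high and stable" selection is mean near the top with b near 1. If
    ``top_n`` exceeds the number of genotypes, all are returned (logged).
    """
    df = pd.DataFrame({"mean": fw.means, "b": fw.sensitivity})
    df = df.rename_axis("genotype").reset_index()
    df = df.sort_values(["mean", "genotype"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    if top_n is not None:
        if top_n > len(df):
            logger.info("stability_ranking: top_n=%d > %d genotypes; returning all",
                        top_n, len(df))
        df = df.head(top_n)
    return df
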