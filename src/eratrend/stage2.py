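"""Stage 2: across-environment mixed model with factor-analytic G x E.

Stage-1 BLUEs y_ij (genotype i, trial j) are combined in

    y_ij = mu + y_j + g_i + (g x y)_ij + theta_ij

with trials fixed, genotype main effects g ~ N(0, A sigma2_g) (A the
pedigree NRM when supplied, identity otherwise), G x E effects whose
covariance across environments is the second-order factor-analytic (FA2)
structure Lambda Lambda' + Psi, and residuals weighted by the squared
stage-1 standard errors (theta_ij ~ N(0, se_ij^2 sigma2_theta)). The FA
structure captures genetic heteroscedasticity and between-environment
genetic correlation with few parameters.

If the pedigree-correlated fit fails (singular/boundary), the model is
automatically refit with an identity genotype covariance and the fallback is
flagged -- matching how such singularities are handled in practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConnectivityError, ConvergenceError, InvalidConfigError, SchemaError
from .reml import LOG_LO, LOG_HI, fit_reml
from .stage1 import Stage1Result

logger = logging.getLogger(__name__)


@dataclass
class GxETable:
    """Genotype x environment matrix of stage-1 BLUEs with their SEs.

    ``blues`` and ``ses`` are aligned DataFrames (genotypes x trials); a
    missing cell is NaN in both. ``meta`` optionally carries per-trial
    metadata (site, country, year, ecology).
    """

    blues: pd.DataFrame = field(repr=False)
    ses: pd.DataFrame = field(repr=False)
    meta: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        if not self.blues.index.equals(self.ses.index) or not self.blues.columns.equals(
            self.ses.columns
        ):
            raise SchemaError("blues and ses must share index and columns")
        for df in (self.blues, self.ses):
            df.index = df.index.astype(str).rename("genotype")
            df.columns = df.columns.astype(str).rename("trial")
        mask = self.blues.notna()
        if not mask.equals(self.ses.notna()):
            raise SchemaError("blues and ses must have identical missing cells")
        if (self.ses.to_numpy()[mask.to_numpy()] <= 0).any():
            raise SchemaError("all SEs must be > 0 where a BLUE is present")
        counts = mask.sum(axis=1)
        if (counts < 1).any():
            bad = list(counts.index[counts < 1])
            raise SchemaError(f"genotypes observed in no environment: {bad}")
        env_counts = mask.sum(axis=0)
        if (env_counts < 2).any():
            bad = list(env_counts.index[env_counts < 2])
            raise SchemaError(f"environments with < 2 genotypes: {bad}")

    @property
    def mask(self) -> pd.DataFrame:
        return self.blues.notna()

    @property
    def genotypes(self) -> list[str]:
        return list(self.blues.index)

    @property
    def trials(self) -> list[str]:
        return list(self.blues.columns)

    def to_csv(self, path) -> None:
        """Long-format serialization (genotype, trial, blue, se)."""
        long = (
            self.blues.stack().rename("blue").to_frame()
            .join(self.ses.stack().rename("se"))
            .reset_index()
        )
        long.columns = ["genotype", "trial", "blue", "se"]
        long.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GxETable":
        long = pd.read_csv(path, dtype={"genotype": str, "trial": str})
        blues = long.pivot(index="genotype", columns="trial", values="blue")
        ses = long.pivot(index="genotype", columns="trial", values="se")
        return cls(blues, ses)


@dataclass
class FA2Fit:
    """Converged stage-2 fit: FA loadings, variances and breeding values."""

    loadings: pd.DataFrame       # trials x n_factors, t/ha
    psi: pd.Series               # per-trial specific variances
    sigma2_g: float
    sigma2_theta: float          # residual multiplier on the squared SEs
    mu: float                    # intercept + mean environment effect
    env_effects: pd.Series       # fixed trial effects (first trial = 0)
    breeding_values: pd.DataFrame  # genotype, value (mu + BLUP), se
    G_env: pd.DataFrame          # Lambda Lambda' + Psi
    used_nrm: bool
    nrm_fallback: bool
    n_factors: int
    converged: bool
    loglik: float
    boundary_flags: list[str] = field(default_factory=list)

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik


def build_gxe_table(results: list[Stage1Result]) -> GxETable:
    """Assemble stage-1 BLUEs/SEs into the genotype x environment table."""
    blues, ses, meta = {}, {}, []
    for res in results:
        if res.blues["genotype"].duplicated().any():
            dup = res.blues.loc[res.blues["genotype"].duplicated(), "genotype"].tolist()
            raise SchemaError(f"duplicate genotype(s) {dup} in trial {res.trial}")
        blues[res.trial] = res.blues.set_index("genotype")["blue"]
        ses[res.trial] = res.blues.set_index("genotype")["se"]
        meta.append({"trial": res.trial, "mean_yield_t_ha": res.trial_mean,
                     "h2_cullis": res.h2_cullis, "reliability": res.reliability})
    blues = pd.DataFrame(blues).sort_index()
    ses = pd.DataFrame(ses).reindex(blues.index)
    return GxETable(blues, ses, meta=pd.DataFrame(meta).set_index("trial"))


def pairwise_connectivity(table: GxETable) -> pd.DataFrame:
    """Environment x environment counts of shared genotypes.

    Entry (j, k) is the number of genotypes observed in both trials; the
    diagonal holds per-trial genotype counts.
    """
    m = table.mask.to_numpy().astype(int)
    counts = m.T @ m
    return pd.DataFrame(counts, index=table.trials, columns=table.trials)


def _check_connected(table: GxETable) -> None:
    g = nx.Graph()
    g.add_nodes_from(("env", t) for t in table.trials)
    mask = table.mask
    for geno, row in mask.iterrows():
        envs = [t for t in table.trials if row[t]]
        for a, b in zip(envs[:-1], envs[1:]):
            g.add_edge(("env", a), ("env", b))
        if envs:
            g.add_node(("env", envs[0]))
    comps = [sorted(t for _, t in c) for c in nx.connected_components(g)]
    if len(comps) > 1:
        raise ConnectivityError(
            f"G x E table is disconnected; components: {comps}", components=comps
        )


class _FACovarianceModel:
    """Marginal covariance of the stage-2 model on the observed cells.

    theta = [log sigma2_g,
             lambda column 1 (k entries),
             lambda column 2 (k - 1 entries; loading (1,2) fixed at 0),
             log psi (k entries),
             log sigma2_theta]
    """

    def __init__(self, gi, ei, weights, A, n_envs, n_factors=2):
        self.gi = np.asarray(gi)
        self.ei = np.asarray(ei)
        self.w = np.asarray(weights, dtype=float)
        self.A = np.asarray(A, dtype=float)
        self.k = int(n_envs)
        self.q = int(n_factors)
        self.n = len(self.gi)
        self.Agg = self.A[np.ix_(self.gi, self.gi)]
        self.same_g = (self.gi[:, None] == self.gi[None, :]).astype(float)
        self.lam_index = [(j, r) for r in range(self.q) for j in range(self.k)
                          if not (r == 1 and j == 0)]
        self.n_params = 1 + len(self.lam_index) + self.k + 1

    def unpack(self, theta):
        sigma2_g = np.exp(theta[0])
        lam = np.zeros((self.k, self.q))
        for t, (j, r) in enumerate(self.lam_index):
            lam[j, r] = theta[1 + t]
        off = 1 + len(self.lam_index)
        psi = np.exp(theta[off: off + self.k])
        sigma2_t = np.exp(theta[off + self.k])
        return sigma2_g, lam, psi, sigma2_t

    def bounds(self):
        b = [(LOG_LO, LOG_HI)]
        b += [(-20.0, 20.0)] * len(self.lam_index)
        b += [(LOG_LO, LOG_HI)] * self.k
        b += [(LOG_LO, LOG_HI)]
        return b

    def pack(self, sigma2_g, lam, psi, sigma2_t):
        theta = np.empty(self.n_params)
        theta[0] = np.log(max(sigma2_g, 1e-10))
        for t, (j, r) in enumerate(self.lam_index):
            theta[1 + t] = lam[j, r]
        off = 1 + len(self.lam_index)
        theta[off: off + self.k] = np.log(np.maximum(psi, 1e-10))
        theta[off + self.k] = np.log(max(sigma2_t, 1e-10))
        return theta

    def initial(self, y, X):
        # moment-flavoured start: split the cell variance (beyond the SE part)
        # between main effect, common factor and specific variances
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        v = max(float(np.var(resid)), 1e-4)
        # start with the shared variance in sigma2_g and small loadings: the
        # main effect and a constant factor column are aliased when A = I, so
        # the start decides where a flat ridge settles
        lam = np.zeros((self.k, self.q))
        lam[:, 0] = 0.15 * np.sqrt(v)
        if self.q > 1:
            lam[1:, 1] = 0.1 * np.sqrt(v) * np.where(np.arange(1, self.k) % 2, 1, -1)
        psi = np.full(self.k, 0.4 * v)
        return self.pack(0.4 * v, lam, psi, 1.0)

    def V_and_dV(self, theta):
        sigma2_g, lam, psi, sigma2_t = self.unpack(theta)
        G = lam @ lam.T + np.diag(psi)
        Gee = G[np.ix_(self.ei, self.ei)]
        V = sigma2_g * self.Agg + self.same_g * Gee + np.diag(self.w * sigma2_t)

        dVs = [sigma2_g * self.Agg]
        for (j, r) in self.lam_index:
            u = (self.ei == j).astype(float)
            v = lam[self.ei, r]
            dVs.append(self.same_g * (np.outer(u, v) + np.outer(v, u)))
        for j in range(self.k):
            u = (self.ei == j).astype(float)
            dVs.append(self.same_g * np.outer(u, u) * psi[j])
        dVs.append(np.diag(self.w * sigma2_t))
        return V, dVs


def _sign_convention(lam: np.ndarray) -> np.ndarray:
    """Flip factor signs so each column's first nonzero loading is positive."""
    lam = lam.copy()
    for r in range(lam.shape[1]):
        col = lam[:, r]
        nz = np.nonzero(np.abs(col) > 1e-10)[0]
        if len(nz) and col[nz[0]] < 0:
            lam[:, r] = -col
    return lam


def fit_stage2_fa2(
    table: GxETable,
    nrm: pd.DataFrame | None = None,
    n_factors: int = 2,
    weighted: bool = True,
    max_iter: int = 500,
    start_jitter: float = 0.0,
    start_seed: int = 0,
) -> FA2Fit:
    """Weighted REML fit of the FA(2) stage-2 model.

    With fewer than 4 environments an FA2 structure is not identifiable in
    any stable way alongside the specific variances, so the model falls back
    to FA1 and logs it. If the pedigree-correlated fit fails, the model is
    refit with an identity genotype covariance (fallback flagged).
    """
    _check_connected(table)
    k = len(table.trials)
    if k < 2:
        raise InvalidConfigError("stage 2 needs >= 2 environments")
    if n_factors == 2 and k < 4:
        logger.warning("only %d environments: falling back from FA2 to FA1", k)
        n_factors = 1

    long = (
        table.blues.stack().rename("blue").to_frame()
        .join(table.ses.stack().rename("se"))
        .reset_index()
    )
    long.columns = ["genotype", "trial", "blue", "se"]
    genotypes, trials = table.genotypes, table.trials
    gpos = {g: i for i, g in enumerate(genotypes)}
    tpos = {t: j for j, t in enumerate(trials)}
    gi = long["genotype"].map(gpos).to_numpy()
    ei = long["trial"].map(tpos).to_numpy()
    y = long["blue"].to_numpy(dtype=float)
    w = long["se"].to_numpy(dtype=float) ** 2 if weighted else np.ones(len(long))

    n = len(y)
    X = np.zeros((n, k))
    X[:, 0] = 1.0
    for j in range(1, k):
        X[ei == j, j] = 1.0  # trial fixed effects, first trial as reference

    def _fit(A, flag_used):
        model = _FACovarianceModel(gi, ei, w, A, k, n_factors)
        theta0 = model.initial(y, X)
        if start_jitter > 0:
            rng = np.random.default_rng(start_seed)
            theta0 = theta0 + rng.normal(0.0, start_jitter, size=theta0.shape)
        fit = fit_reml(y, X, model, theta0=theta0, max_iter=max_iter)
        return model, fit, flag_used

    used_nrm, fallback = False, False
    A_id = np.eye(len(genotypes))
    if nrm is not None:
        A = nrm.loc[genotypes, genotypes].to_numpy()
        try:
            model, fit, used_nrm = _fit(A, True)
        except (ConvergenceError, np.linalg.LinAlgError) as exc:
            logger.warning("stage 2 with NRM failed (%s); refitting without A", exc)
            model, fit, _ = _fit(A_id, False)
            fallback = True
    else:
        model, fit, _ = _fit(A_id, False)

    sigma2_g, lam, psi, sigma2_t = model.unpack(fit.theta)
    lam = _sign_convention(lam)
    G = lam @ lam.T + np.diag(psi)

    boundary = []
    if fit.theta[0] <= LOG_LO + 1e-6:
        boundary.append("sigma2_g at lower bound")
    off = 1 + len(model.lam_index)
    for j in range(k):
        if fit.theta[off + j] <= LOG_LO + 1e-6:
            boundary.append(f"psi[{trials[j]}] at lower bound")
    if boundary:
        logger.warning("stage 2 boundary fit: %s", "; ".join(boundary))

    # Breeding value of genotype i: main effect plus its average G x E
    # effect, p_i = g_i + (1/k) sum_j ge_ij, predicted by BLUP. Averaging
    # the interaction in makes the prediction invariant to the flat ridge
    # between sigma2_g and a constant loading column (aliased when A = I).
    m = len(genotypes)
    A_used = (nrm.loc[genotypes, genotypes].to_numpy()
              if (nrm is not None and used_nrm) else A_id)
    c = G.sum(axis=0) / k            # (1/k) * G 1, per environment
    q_var = G.sum() / k**2           # var of the averaged G x E effect
    # Cov(p, p') and Cov(p_i, y_cell)
    C_pp = sigma2_g * A_used + q_var * np.eye(m)
    same = (np.arange(m)[:, None] == gi[None, :]).astype(float)
    C_py = sigma2_g * A_used[:, gi] + same * c[ei][None, :]
    r = y - X @ fit.beta
    u = C_py @ (fit.Vinv @ r)
    pev = C_pp - C_py @ fit.P @ C_py.T

    env_eff = pd.Series(np.concatenate([[0.0], fit.beta[1:]]), index=trials)
    mu = float(fit.beta[0] + env_eff.mean())
    bv = pd.DataFrame(
        {
            "genotype": genotypes,
            "value": mu + u,
            "se": np.sqrt(np.maximum(np.diag(pev), 0.0)),
        }
    )

    return FA2Fit(
        loadings=pd.DataFrame(lam, index=trials,
                              columns=[f"factor{r + 1}" for r in range(n_factors)]),
        psi=pd.Series(psi, index=trials, name="psi"),
        sigma2_g=float(sigma2_g),
        sigma2_theta=float(sigma2_t),
        mu=mu,
        env_effects=env_eff,
        breeding_values=bv,
        G_env=pd.DataFrame(G, index=trials, columns=trials),
        used_nrm=used_nrm,
        nrm_fallback=fallback,
        n_factors=n_factors,
        converged=fit.converged,
        loglik=fit.loglik,
        boundary_flags=boundary,
    )


def genetic_correlation_matrix(fit: FA2Fit) -> pd.DataFrame:
    """Between-environment genetic correlations.

    corr(j, k) = C_jk / sqrt(C_jj C_kk) where C = sigma2_g + Lambda Lambda'
    + Psi is the total genetic covariance of one genotype's performance in
    two environments (main effect plus G x E). The main-effect variance is
    included because with an identity genotype covariance it is aliased with
    a constant loading column -- only their sum is identified, so a
    correlation built from the factor part alone would depend on where a
    flat likelihood ridge happened to stop. Environments with zero total
    genetic variance get NaN rows/columns (undefined); the diagonal is
    exactly 1 where defined.
    """
    G = fit.sigma2_g + fit.G_env.to_numpy()
    d = np.sqrt(np.diag(G))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = G / np.outer(d, d)
    corr[~np.isfinite(corr)] = np.nan
    np.fill_diagonal(corr, np.where(d > 0, 1.0, np.nan))
    return pd.DataFrame(corr, index=fit.G_env.index, columns=fit.G_env.columns)
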