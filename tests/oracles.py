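"""Independent oracles used by the tests.

Everything here is deliberately implemented by a different route than the
package (coancestry recursion instead of the tabular method, pseudo-inverse
GLS instead of Cholesky REML machinery, direct slogdet likelihood instead of
the fitting engine) so agreement is meaningful.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def coancestry_nrm(records: pd.DataFrame) -> pd.DataFrame:
    """NRM via the kinship (coancestry) recursion, memoised.

    phi(i, i) = 1/2 (1 + 1/2 phi(p, q));  phi(i, j) = 1/2 (phi(p1, j) + phi(p2, j))
    where i is the later-introduced individual; a_ij = 2 phi(i, j).
    """
    ids = list(records["genotype"])
    order = {g: k for k, g in enumerate(ids)}
    parents = {
        r.genotype: (r.parent1 or None, r.parent2 or None)
        for r in records.itertuples(index=False)
    }
    for g, (p1, p2) in parents.items():
        parents[g] = (p1 if p1 in order else None, p2 if p2 in order else None)

    cache: dict[tuple[str, str], float] = {}

    def phi(i, j):
        if i is None or j is None:
            return 0.0
        key = (i, j) if order[i] >= order[j] else (j, i)
        if key in cache:
            return cache[key]
        a, b = key  # a is the later individual
        p1, p2 = parents[a]
        if a == b:
            # inbreeding F_a equals the coancestry of a's parents
            val = 0.5 * (1.0 + (phi(p1, p2) if p1 and p2 else 0.0))
        else:
            val = 0.5 * (phi(p1, b) + phi(p2, b))
        cache[key] = val
        return val

    n = len(ids)
    a = np.empty((n, n))
    for i, gi in enumerate(ids):
        for j, gj in enumerate(ids):
            a[i, j] = 2.0 * phi(gi, gj)
    return pd.DataFrame(a, index=ids, columns=ids)


def random_pedigree(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Random acyclic pedigree of n individuals (parents drawn from earlier ones)."""
    rows = []
    for k in range(n):
        gid = f"I{k:02d}"
        if k == 0 or rng.random() < 0.3:
            rows.append((gid, "", ""))
        else:
            p1 = f"I{rng.integers(0, k):02d}"
            # allow selfing and single unknown parents
            u = rng.random()
            if u < 0.15:
                p2 = p1
            elif u < 0.3:
                p2 = ""
            else:
                p2 = f"I{rng.integers(0, k):02d}"
            rows.append((gid, p1, p2))
    return pd.DataFrame(rows, columns=["genotype", "parent1", "parent2"])


def gls_from_components(df: pd.DataFrame, varcomp: dict, covariates=()) -> pd.DataFrame:
    """Genotype BLUEs by explicit pseudo-inverse GLS at given variance components.

    Builds V = s2_rep Zr Zr' + s2_block Zb Zb' + s2_err I from pandas dummies
    and solves the normal equations with np.linalg.pinv; returns a DataFrame
    (genotype, blue, se) at trial-mean covariate values.
    """
    df = df[np.isfinite(df["yield_t_ha"])].reset_index(drop=True)
    y = df["yield_t_ha"].to_numpy(float)
    n = len(df)
    genos = sorted(df["genotype"].astype(str).unique())
    Dg = pd.get_dummies(pd.Categorical(df["genotype"].astype(str), categories=genos)).to_numpy(float)
    X = np.hstack([np.ones((n, 1)), Dg[:, 1:]])
    for c in covariates:
        col = {"dtf": "dtf_days", "height": "height_cm"}[c]
        v = df[col].to_numpy(float)
        X = np.hstack([X, (v - v.mean())[:, None]])
    Zr = pd.get_dummies(df["rep"].astype(str)).to_numpy(float)
    Zb = pd.get_dummies(df["rep"].astype(str) + ":" + df["block"].astype(str)).to_numpy(float)
    V = (varcomp.get("rep", 0.0) * Zr @ Zr.T
         + varcomp.get("block", 0.0) * Zb @ Zb.T
         + varcomp["residual"] * np.eye(n))
    Vi = np.linalg.pinv(V)
    C = np.linalg.pinv(X.T @ Vi @ X)
    beta = C @ X.T @ Vi @ y
    m = len(genos)
    L = np.zeros((m, X.shape[1]))
    L[:, 0] = 1.0
    L[np.arange(1, m), np.arange(1, m)] = 1.0
    blue = L @ beta
    se = np.sqrt(np.diag(L @ C @ L.T))
    return pd.DataFrame({"genotype": genos, "blue": blue, "se": se})


def neg2_restricted_loglik(y, X, V) -> float:
    """-2 REML log-likelihood (constant-free) by direct slogdet/inv algebra."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    _, ld_v = np.linalg.slogdet(V)
    _, ld_x = np.linalg.slogdet(XtViX)
    return float(ld_v + ld_x + r @ Vi @ r)


def stage2_marginal_V(gi, ei, w, sigma2_g, lam, psi, sigma2_t, A=None):
    """Dense stage-2 covariance built independently (loops, no masks)."""
    gi = np.asarray(gi)
    ei = np.asarray(ei)
    n = len(gi)
    lam = np.asarray(lam, float)
    G = lam @ lam.T + np.diag(np.asarray(psi, float))
    if A is None:
        A = np.eye(gi.max() + 1)
    V = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            V[a, b] = sigma2_g * A[gi[a], gi[b]]
            if gi[a] == gi[b]:
                V[a, b] += G[ei[a], ei[b]]
            if a == b:
                V[a, b] += w[a] * sigma2_t
    return V
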