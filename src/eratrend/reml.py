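"""Dense REML machinery for small mixed models.

Trial datasets here are small (tens to a few hundred observations), so the
restricted likelihood is evaluated on the dense marginal covariance

    V(theta) = sum_k  C_k(theta)          (model-specific components)

with

    -2 l_R(theta) = log|V| + log|X' V^-1 X| + y' P y + const,
    P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1,

and the analytic gradient  d(-2 l_R)/d theta_k = tr(P dV_k) - y'P dV_k P y.
Variance parameters are optimised on the log scale (quasi-Newton L-BFGS-B),
which keeps them positive; components driven to zero are pinned at the lower
bound of the log grid rather than removed.

A covariance model is any object with

    n_params           -- number of unconstrained parameters
    initial(y, X)      -- starting parameter vector
    bounds()           -- list of (lo, hi) box bounds for the optimizer
    V_and_dV(theta)    -- (V, [dV_1, ..., dV_p]) dense matrices
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
from scipy.optimize import minimize

from .errors import ConvergenceError

# log-variance box: e^-23 ~ 1e-10 pins a vanishing component at the boundary
LOG_LO, LOG_HI = -23.0, 12.0


@dataclass
class REMLFit:
    """Converged REML fit with the quantities downstream stages consume."""

    theta: np.ndarray
    loglik: float  # restricted log-likelihood (up to an additive constant)
    converged: bool
    n_iter: int
    beta: np.ndarray
    vcov_beta: np.ndarray
    V: np.ndarray = field(repr=False)
    Vinv: np.ndarray = field(repr=False)
    P: np.ndarray = field(repr=False)
    resid: np.ndarray = field(repr=False)
    message: str = ""

    @property
    def deviance(self) -> float:
        """-2 * restricted log-likelihood (same constant convention)."""
        return -2.0 * self.loglik


def _neg2_reml(y, X, V, dVs=None):
    """(-2 restricted loglik, gradient, solved pieces) for fixed V."""
    n, p = X.shape
    cf = sla.cho_factor(V, lower=True, check_finite=False)
    logdet_v = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Vi_X = sla.cho_solve(cf, X, check_finite=False)
    Vi_y = sla.cho_solve(cf, y, check_finite=False)
    XtViX = X.T @ Vi_X
    cfx = sla.cho_factor(XtViX, lower=True, check_finite=False)
    logdet_x = 2.0 * np.sum(np.log(np.diag(cfx[0])))
    beta = sla.cho_solve(cfx, X.T @ Vi_y, check_finite=False)
    Py = Vi_y - Vi_X @ beta
    ypy = float(y @ Py)
    neg2 = logdet_v + logdet_x + ypy
    if dVs is None:
        return neg2, None, (cf, cfx, Vi_X, beta, Py)
    # P = V^-1 - Vi_X (X'ViX)^-1 Vi_X'
    Vinv = sla.cho_solve(cf, np.eye(n), check_finite=False)
    W = sla.cho_solve(cfx, Vi_X.T, check_finite=False)
    P = Vinv - Vi_X @ W
    grad = np.empty(len(dVs))
    for k, dV in enumerate(dVs):
        grad[k] = float(np.sum(P * dV) - Py @ dV @ Py)
    return neg2, grad, (cf, cfx, Vi_X, beta, Py)


def fit_reml(
    y: np.ndarray,
    X: np.ndarray,
    cov_model,
    theta0: np.ndarray | None = None,
    *,
    max_iter: int = 200,
    tol: float = 1e-8,
    raise_on_failure: bool = True,
) -> REMLFit:
    """Maximise the restricted likelihood of y = X beta + (noise ~ N(0, V(theta))).

    ``tol`` is the relative change in -2 log-likelihood at convergence.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if theta0 is None:
        theta0 = cov_model.initial(y, X)
    theta0 = np.asarray(theta0, dtype=float)

    if theta0.size == 0:
        # every component fixed: nothing to optimise, just evaluate
        V, _ = cov_model.V_and_dV(theta0)
        neg2, _, (cf, cfx, Vi_X, beta, Py) = _neg2_reml(y, X, V)
        n = len(y)
        Vinv = sla.cho_solve(cf, np.eye(n), check_finite=False)
        W = sla.cho_solve(cfx, Vi_X.T, check_finite=False)
        vcov_beta = sla.cho_solve(cfx, np.eye(X.shape[1]), check_finite=False)
        return REMLFit(
            theta=theta0, loglik=-0.5 * neg2, converged=True, n_iter=0,
            beta=beta, vcov_beta=0.5 * (vcov_beta + vcov_beta.T),
            V=V, Vinv=Vinv, P=Vinv - Vi_X @ W, resid=y - X @ beta,
            message="all components fixed",
        )

    def objective(theta):
        V, dVs = cov_model.V_and_dV(theta)
        try:
            neg2, grad, _ = _neg2_reml(y, X, V, dVs)
        except np.linalg.LinAlgError:
            return np.inf, np.zeros_like(theta)
        if not np.isfinite(neg2):
            return np.inf, np.zeros_like(theta)
        return neg2, grad

    res = minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=cov_model.bounds(),
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8},
    )
    converged = bool(res.success) and np.isfinite(res.fun)
    if not converged and raise_on_failure:
        raise ConvergenceError(
            f"REML did not converge: {res.message}",
            last_iterate=res.x,
            diagnostics={"fun": float(res.fun), "nit": int(res.nit)},
        )

    V, _ = cov_model.V_and_dV(res.x)
    neg2, _, (cf, cfx, Vi_X, beta, Py) = _neg2_reml(y, X, V)
    n = len(y)
    Vinv = sla.cho_solve(cf, np.eye(n), check_finite=False)
    W = sla.cho_solve(cfx, Vi_X.T, check_finite=False)
    P = Vinv - Vi_X @ W
    vcov_beta = sla.cho_solve(cfx, np.eye(X.shape[1]), check_finite=False)
    return REMLFit(
        theta=res.x,
        loglik=-0.5 * neg2,
        converged=converged,
        n_iter=int(res.nit),
        beta=beta,
        vcov_beta=0.5 * (vcov_beta + vcov_beta.T),
        V=V,
        Vinv=Vinv,
        P=P,
        resid=y - X @ beta,
        message=str(res.message),
    )


class VarianceComponentsModel:
    """V = sum_k exp(theta_k) Z_k Z_k' + exp(theta_e) I  (linear structure).

    ``Z_list`` are the random-effect design matrices (one per component);
    the final parameter is always the residual variance. Components may be
    frozen at fixed values via ``fixed`` (mapping component index -> variance),
    which removes them from the optimisation.
    """

    def __init__(self, Z_list, n_obs, fixed: dict[int, float] | None = None):
        self.Z_list = [np.asarray(Z, dtype=float) for Z in Z_list]
        self.n_obs = int(n_obs)
        self.fixed = dict(fixed or {})
        self._ZZt = [Z @ Z.T for Z in self.Z_list]
        self.free = [k for k in range(len(Z_list) + 1) if k not in self.fixed]
        # index len(Z_list) is the residual

    @property
    def n_params(self):
        return len(self.free)

    def bounds(self):
        return [(LOG_LO, LOG_HI)] * self.n_params

    def initial(self, y, X):
        # spread the raw variance equally across free components
        v = max(float(np.var(y)), 1e-6) / (len(self.Z_list) + 1)
        return np.full(self.n_params, np.log(v))

    def variances(self, theta):
        """Full variance vector (components..., residual) on the raw scale."""
        out = np.empty(len(self.Z_list) + 1)
        it = iter(theta)
        for k in range(len(self.Z_list) + 1):
            out[k] = self.fixed[k] if k in self.fixed else np.exp(next(it))
        return out

    def V_and_dV(self, theta):
        sig = self.variances(theta)
        V = sig[-1] * np.eye(self.n_obs)
        for k, ZZt in enumerate(self._ZZt):
            if sig[k] != 0.0:
                V = V + sig[k] * ZZt
        dVs = []
        for k in self.free:
            if k == len(self.Z_list):
                dVs.append(sig[-1] * np.eye(self.n_obs))
            else:
                dVs.append(sig[k] * self._ZZt[k])
        return V, dVs


def gls_blue(y, X, V):
    """Generalised least squares at a known covariance (used as plumbing and,
    independently re-derived, as a test oracle)."""
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    C = np.linalg.inv(XtViX)
    beta = C @ X.T @ Vi @ y
    return beta, C


def blup(y, X, beta, Z, G, Vinv, Vi_X=None, XtViX_inv=None):
    """BLUPs of u ~ N(0, G) with design Z, and their PEV matrix.

    u_hat = G Z' V^-1 (y - X beta);  PEV = G - G Z' P Z G with P the usual
    REML projection (so PEV accounts for the estimation of beta).
    """
    r = y - X @ beta
    GZt = G @ Z.T
    u = GZt @ (Vinv @ r)
    if Vi_X is None:
        Vi_X = Vinv @ X
    if XtViX_inv is None:
        XtViX_inv = np.linalg.inv(X.T @ Vi_X)
    P = Vinv - Vi_X @ XtViX_inv @ Vi_X.T
    pev = G - GZt @ P @ GZt.T
    return u, 0.5 * (pev + pev.T)


def mean_pairwise_difference_variance(C: np.ndarray) -> float:
    """Average of Var(d_i - d_j) = C_ii + C_jj - 2 C_ij over all i < j."""
    m = C.shape[0]
    if m < 2:
        return 0.0
    d = np.diag(C)
    # sum over ordered pairs: sum_{i,j} (Cii + Cjj - 2Cij) = 2m*sum(d) - 2*sum(C)
    s = 2.0 * m * d.sum() - 2.0 * C.sum()
    return float(s / (m * (m - 1)))
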