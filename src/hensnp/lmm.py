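"""Linear mixed model with a single random intercept, fitted by profiled REML.

All three models in this package share one structure: a handful of fixed
effects (generation, layer line, optionally a SNP term) plus a random
intercept for sire, modelling the covariance among paternal half-sibs:

    y = X beta + Z u + e,   u ~ N(0, sigma_u^2 I_q),   e ~ N(0, sigma_e^2 I_n)

with Z the sire incidence matrix.  Because there is only one variance
component, the restricted likelihood can be profiled down to a univariate
function of the variance ratio lambda = sigma_u^2 / sigma_e^2 and maximised
by bounded scalar search.  For a grouped random intercept every quantity
(GLS cross-products, log-determinants, BLUPs) has a closed form per group,
so a fit is O(n p^2) with no general-purpose optimiser involved.  The
profiled log-likelihood is maximised to a tolerance of 1e-8.

Variance-component standard errors come from the observed information of
the restricted log-likelihood in (sigma_u^2, sigma_e^2), obtained by central
finite differences; they are asymptotic and, as always for variances, only
meaningful away from the sigma_u^2 = 0 boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["LmmFit", "fit_random_intercept", "contrast"]

# Bounds for log(lambda) in the profile search; lambda below exp(-25) is
# numerically indistinguishable from a zero sire variance.
_LOG_LAMBDA_LO = -25.0
_LOG_LAMBDA_HI = 15.0


@dataclass
class LmmFit:
    """Result of a random-intercept REML fit."""

    beta: pd.Series
    cov_beta: pd.DataFrame
    sigma2_u: float
    sigma2_e: float
    se_sigma2_u: float
    se_sigma2_e: float
    blups: pd.Series  # predicted random effect per group level
    resid_marginal: np.ndarray  # y - X beta_hat
    resid_conditional: np.ndarray  # y - X beta_hat - Z u_hat
    loglik: float  # restricted log-likelihood at the optimum
    n: int
    df_resid: int  # n - rank(X), used for t-tests
    converged: bool

    @property
    def se_beta(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_beta.values)), index=self.beta.index)


class _Workspace:
    """Per-dataset sufficient statistics reused across lambda evaluations."""

    def __init__(self, y: np.ndarray, X: np.ndarray, group_idx: np.ndarray, n_groups: int):
        self.y = y
        self.X = X
        self.n, self.p = X.shape
        self.n_groups = n_groups
        self.group_idx = group_idx
        # per-group counts and sums
        self.sizes = np.bincount(group_idx, minlength=n_groups).astype(float)
        self.Sx = np.zeros((n_groups, self.p))
        for j in range(self.p):
            self.Sx[:, j] = np.bincount(group_idx, weights=X[:, j], minlength=n_groups)
        self.Sy = np.bincount(group_idx, weights=y, minlength=n_groups)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def gls(self, lam: float):
        """GLS quantities for V = I + lam Z Z'. Returns beta, rVr, logdets."""
        c = lam / (1.0 + lam * self.sizes)  # per-group shrinkage weight
        XtVX = self.XtX - (self.Sx * c[:, None]).T @ self.Sx
        XtVy = self.Xty - (self.Sx * c[:, None]).T @ self.Sy
        ytVy = self.yty - float((c * self.Sy) @ self.Sy)
        beta = np.linalg.solve(XtVX, XtVy)
        rVr = ytVy - float(beta @ XtVy)  # (y-Xb)' Vbar^-1 (y-Xb) at GLS optimum
        logdet_V = float(np.sum(np.log1p(lam * self.sizes)))
        sign, logdet_XtVX = np.linalg.slogdet(XtVX)
        if sign <= 0:
            raise np.linalg.LinAlgError("X'V^-1X not positive definite")
        return beta, XtVX, rVr, logdet_V, logdet_XtVX

    def neg_profile_reml(self, log_lam: float) -> float:
        lam = np.exp(log_lam)
        _, _, rVr, logdet_V, logdet_XtVX = self.gls(lam)
        nmp = self.n - self.p
        sigma2_e = rVr / nmp
        # restricted log-likelihood profiled over beta and sigma_e^2
        ll = -0.5 * (nmp * np.log(sigma2_e) + logdet_V + logdet_XtVX + nmp)
        return -ll

    def reml_loglik(self, sigma2_u: float, sigma2_e: float) -> float:
        """Unprofiled restricted log-likelihood at a variance pair."""
        lam = sigma2_u / sigma2_e
        _, _, rVr, logdet_V, logdet_XtVX = self.gls(lam)
        nmp = self.n - self.p
        return -0.5 * (
            nmp * np.log(sigma2_e)
            + logdet_V
            + logdet_XtVX
            + rVr / sigma2_e
        )


def _design_rank(X: np.ndarray) -> int:
    return int(np.linalg.matrix_rank(X))


def fit_random_intercept(
    y,
    X,
    groups,
    names: list[str] | None = None,
    tol: float = 1e-8,
) -> LmmFit:
    """Fit ``y = X beta + Z u + e`` with a grouped random intercept by REML.

    Parameters
    ----------
    y : array-like, shape (n,)
        Response.  Must be finite.
    X : array-like or DataFrame, shape (n, p)
        Fixed-effect design, full column rank expected (a deficient design
        raises ``LinAlgError``).
    groups : array-like, shape (n,)
        Group label per observation (the sire of each hen).
    names : list of str, optional
        Column names when ``X`` is a bare array.
    tol : float
        Absolute tolerance on the profiled log-likelihood maximisation.

    Returns
    -------
    LmmFit
        Estimates, covariances, BLUPs and both flavours of residuals.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if names is None:
            names = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise ValueError("y and X have incompatible shapes")
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X)):
        raise ValueError("y and X must be finite (drop missing values first)")

    group_labels, group_idx = np.unique(np.asarray(groups), return_inverse=True)
    ws = _Workspace(y, X, group_idx, len(group_labels))
    rank = _design_rank(X)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"fixed-effect design is rank deficient (rank {rank} < {X.shape[1]})"
        )

    res = optimize.minimize_scalar(
        ws.neg_profile_reml,
        bounds=(_LOG_LAMBDA_LO, _LOG_LAMBDA_HI),
        method="bounded",
        options={"xatol": 1e-10},
    )
    # the profile can be monotone decreasing towards the lambda -> 0 boundary
    log_lam = float(res.x)
    for boundary in (_LOG_LAMBDA_LO,):
        if ws.neg_profile_reml(boundary) < res.fun - tol:
            log_lam = boundary
    lam = float(np.exp(log_lam))

    beta, XtVX, rVr, _, _ = ws.gls(lam)
    nmp = ws.n - ws.p
    sigma2_e = rVr / nmp
    sigma2_u = lam * sigma2_e
    at_boundary = log_lam <= _LOG_LAMBDA_LO + 5.0  # lambda below ~2e-9: singular
    if at_boundary:
        sigma2_u = 0.0
        warnings.warn(
            "sire variance estimated at the zero boundary (singular fit)",
            RuntimeWarning,
            stacklevel=2,
        )

    cov_beta = sigma2_e * np.linalg.inv(XtVX)
    resid_marginal = y - X @ beta
    c = lam / (1.0 + lam * ws.sizes)
    group_resid_sum = np.bincount(group_idx, weights=resid_marginal, minlength=ws.n_groups)
    blup = lam * group_resid_sum / (1.0 + lam * ws.sizes) if lam > 0 else np.zeros(ws.n_groups)
    resid_conditional = resid_marginal - blup[group_idx]

    se_u, se_e = _variance_ses(ws, sigma2_u, sigma2_e, at_boundary)

    return LmmFit(
        beta=pd.Series(beta, index=names),
        cov_beta=pd.DataFrame(cov_beta, index=names, columns=names),
        sigma2_u=float(sigma2_u),
        sigma2_e=float(sigma2_e),
        se_sigma2_u=se_u,
        se_sigma2_e=se_e,
        blups=pd.Series(blup, index=group_labels),
        resid_marginal=resid_marginal,
        resid_conditional=resid_conditional,
        loglik=-float(res.fun),
        n=ws.n,
        df_resid=ws.n - rank,
        converged=bool(res.success),
    )


def _variance_ses(ws: _Workspace, s2u: float, s2e: float, at_boundary: bool):
    """Asymptotic SEs from the observed information of the restricted loglik."""
    if s2e <= 0:  # perfect fit; no curvature to invert
        return float("nan"), float("nan")
    if at_boundary:
        # information for sigma_u^2 is one-sided at the boundary; report NaN
        h = 1e-3 * s2e
        f0 = ws.reml_loglik(0.0, s2e)
        d2 = (ws.reml_loglik(0.0, s2e + h) - 2 * f0 + ws.reml_loglik(0.0, s2e - h)) / h**2
        se_e = float(np.sqrt(-1.0 / d2)) if d2 < 0 else float("nan")
        return float("nan"), se_e
    # relative step 1e-3: small enough for curvature, large enough that the
    # O(1e-13) round-off in the log-likelihood does not pollute the quotient
    hu = 1e-3 * max(s2u, 1e-8)
    he = 1e-3 * s2e
    f = ws.reml_loglik
    f0 = f(s2u, s2e)
    d2uu = (f(s2u + hu, s2e) - 2 * f0 + f(s2u - hu, s2e)) / hu**2
    d2ee = (f(s2u, s2e + he) - 2 * f0 + f(s2u, s2e - he)) / he**2
    d2ue = (
        f(s2u + hu, s2e + he) - f(s2u + hu, s2e - he) - f(s2u - hu, s2e + he) + f(s2u - hu, s2e - he)
    ) / (4 * hu * he)
    info = -np.array([[d2uu, d2ue], [d2ue, d2ee]])
    try:
        cov = np.linalg.inv(info)
        if cov[0, 0] <= 0 or cov[1, 1] <= 0:
            return float("nan"), float("nan")
        return float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:
        return float("nan"), float("nan")


def contrast(fit: LmmFit, c) -> tuple[float, float, float, float]:
    """Estimate, SE, t and two-sided p for the linear contrast ``c' beta``.

    Degrees of freedom are residual-based (n minus the rank of the fixed
    design); with hundreds of hens and a handful of coefficients this is
    close to any of the fancier approximations.
    """
    c = np.asarray(c, dtype=float)
    if c.shape != (len(fit.beta),):
        raise ValueError("contrast length does not match the coefficient vector")
    est = float(c @ fit.beta.values)
    var = float(c @ fit.cov_beta.values @ c)
    if var <= 0:
        return est, float("nan"), float("nan"), float("nan")
    se = float(np.sqrt(var))
    t = est / se
    p = float(2 * stats.t.sf(abs(t), fit.df_resid))
    return est, se, t, p
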