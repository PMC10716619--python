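"""Two-level nested random-intercept linear mixed model.

Fits ``y = X b + u_city + v_child + e`` with children nested in cities, by
REML (estimates, Wald inference) or ML (AIC screening).  The covariance
``V = s2e*I + s2c*Zc Zc' + s2L*ZL ZL'`` is inverted analytically through
the nested block structure (two Woodbury steps), so a fit costs O(n * p)
per likelihood evaluation and the optimum can be located to near machine
precision.  Denominator degrees of freedom use a Satterthwaite
approximation from the numerically differentiated REML information; if the
information matrix is not positive definite the fit falls back to a normal
approximation and says so in ``df_method``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = ["NestedLmmFit", "fit_nested_lmm", "SingularDesignError"]

_LOG2PI = np.log(2.0 * np.pi)


class SingularDesignError(ValueError):
    """Design matrix is rank deficient; offending columns are named."""


class ConvergenceError(RuntimeError):
    pass


@dataclass
class NestedLmmFit:
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    df: np.ndarray  # per-coefficient denominator df (inf under normal approx)
    tvalues: np.ndarray
    pvalues: np.ndarray
    cov_beta: np.ndarray
    sigma2_city: float
    sigma2_child: float
    sigma2_resid: float
    loglik: float
    method: str  # "reml" | "ml"
    df_method: str  # "satterthwaite" | "normal"
    converged: bool
    n: int
    p: int
    aic: Optional[float] = None  # ML only
    degenerate: bool = False

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        q = np.array([
            stats.t.ppf(1 - alpha / 2, d) if np.isfinite(d)
            else stats.norm.ppf(1 - alpha / 2)
            for d in self.df
        ])
        return np.column_stack([self.beta - q * self.se, self.beta + q * self.se])


class _NestedStructure:
    """Index bookkeeping and O(n) solves with W = I + lc*ZcZc' + lL*ZLZL'."""

    def __init__(self, city: np.ndarray, child: np.ndarray):
        self.city_codes, city_idx = np.unique(city, return_inverse=True)
        # children globally unique; verify nesting
        self.child_codes, child_idx = np.unique(child, return_inverse=True)
        self.n = len(city_idx)
        self.city_idx = city_idx
        self.child_idx = child_idx
        self.n_city = len(self.city_codes)
        self.n_child = len(self.child_codes)
        city_of_child = np.full(self.n_child, -1, dtype=int)
        for j, i in zip(child_idx, city_idx):
            if city_of_child[j] == -1:
                city_of_child[j] = i
            elif city_of_child[j] != i:
                raise ValueError("children must be nested within cities")
        self.city_of_child = city_of_child
        self.n_per_child = np.bincount(child_idx, minlength=self.n_child).astype(float)

    def solve(self, M: np.ndarray, lam_child: float, lam_city: float):
        """Return (W^-1 M, log|W|) for M of shape (n,) or (n, m)."""
        one_d = M.ndim == 1
        X = M[:, None] if one_d else M
        a = 1.0 + lam_child * self.n_per_child  # per child
        # per-child row sums
        S = np.zeros((self.n_child, X.shape[1]))
        np.add.at(S, self.child_idx, X)
        t = X - (lam_child / a)[self.child_idx, None] * S[self.child_idx]
        # city-level rank-one correction
        d = np.bincount(
            self.city_of_child, weights=self.n_per_child / a, minlength=self.n_city
        )
        C = np.zeros((self.n_city, X.shape[1]))
        np.add.at(C, self.city_of_child, S / a[:, None])
        scale = lam_city / (1.0 + lam_city * d)
        out = t - scale[self.city_idx, None] * C[self.city_idx] / a[self.child_idx, None]
        logdet = float(np.sum(np.log(a)) + np.sum(np.log1p(lam_city * d)))
        return (out[:, 0] if one_d else out), logdet


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        aliased = [names[j] for j in np.where(diag < tol)[0]]
        raise SingularDesignError(f"aliased design column(s): {aliased or 'unknown'}")


def _profiled_crit(lam, struct, X, y, reml):
    """Profiled -2 log-likelihood up to a constant, as a function of
    (lam_child, lam_city) = variance ratios relative to the residual."""
    lc, ll = lam
    n, p = X.shape
    WiX, logdetW = struct.solve(X, lc, ll)
    Wiy, _ = struct.solve(y, lc, ll)
    XtWiX = X.T @ WiX
    XtWiy = X.T @ Wiy
    try:
        beta = np.linalg.solve(XtWiX, XtWiy)
    except np.linalg.LinAlgError:
        return np.inf, None
    q = float(y @ Wiy - beta @ XtWiy)
    if q <= 0:
        return np.inf, None
    if reml:
        sign, logdet_xx = np.linalg.slogdet(XtWiX)
        if sign <= 0:
            return np.inf, None
        crit = (n - p) * np.log(q) + logdetW + logdet_xx
    else:
        crit = n * np.log(q) + logdetW
    return crit, (beta, q, XtWiX, logdetW)


def _neg2_loglik_theta(theta, struct, X, y, reml):
    """-2 log-likelihood as a function of (s2_city, s2_child, s2_resid)."""
    s2L, s2c, s2e = theta
    if s2e <= 0 or s2L < 0 or s2c < 0:
        return np.inf
    n, p = X.shape
    lam = (s2c / s2e, s2L / s2e)
    crit, aux = _profiled_crit(lam, struct, X, y, reml)
    if aux is None:
        return np.inf
    beta, q, XtWiX, logdetW = aux
    if reml:
        sign, logdet_xx = np.linalg.slogdet(XtWiX)
        return (n - p) * (np.log(s2e) + _LOG2PI) + logdetW + logdet_xx + q / s2e
    return n * (np.log(s2e) + _LOG2PI) + logdetW + q / s2e


def fit_nested_lmm(
    y: np.ndarray,
    X: np.ndarray,
    city: np.ndarray,
    child: np.ndarray,
    names: Optional[Sequence[str]] = None,
    reml: bool = True,
    df_method: str = "satterthwaite",
) -> NestedLmmFit:
    """Fit the nested random-intercept model.

    Parameters are the response (already log-transformed by the caller), a
    dense fixed-effects design including its intercept column, and the city
    and child grouping labels (one pair per row, children nested).
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    names = list(names) if names is not None else [f"x{j}" for j in range(p)]
    _check_rank(X, names)
    struct = _NestedStructure(np.asarray(city), np.asarray(child))

    # degenerate: outcome exactly explained by the fixed effects
    beta_ols, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ols
    if float(resid @ resid) < 1e-12 * max(1.0, float(y @ y)):
        zeros = np.zeros(p)
        return NestedLmmFit(
            names=names, beta=beta_ols, se=zeros, df=np.full(p, np.inf),
            tvalues=np.full(p, np.nan), pvalues=np.full(p, np.nan),
            cov_beta=np.zeros((p, p)), sigma2_city=0.0, sigma2_child=0.0,
            sigma2_resid=0.0, loglik=np.inf, method="reml" if reml else "ml",
            df_method="normal", converged=True, n=n, p=p, degenerate=True,
            aic=None if reml else -np.inf,
        )

    def crit_s(s):  # sqrt parametrisation keeps the search unconstrained
        return _profiled_crit((s[0] ** 2, s[1] ** 2), struct, X, y, reml)[0]

    best = None
    for s0 in ([0.7, 0.4], [0.05, 0.05]):
        res = optimize.minimize(
            crit_s, np.asarray(s0, float), method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 600},
        )
        if best is None or res.fun < best.fun:
            best = res
    # local polish to near machine precision (cheap from a good start)
    polish = optimize.minimize(
        crit_s, best.x, method="Nelder-Mead",
        options={"xatol": 1e-13, "fatol": 1e-14, "maxiter": 1500},
    )
    if polish.fun <= best.fun:
        best = polish
    converged = bool(best.success or best.fun < np.inf)
    lam = (best.x[0] ** 2, best.x[1] ** 2)
    crit, aux = _profiled_crit(lam, struct, X, y, reml)
    if aux is None:
        raise ConvergenceError("mixed-model fit failed to converge")
    beta, q, XtWiX, logdetW = aux
    dof = n - p if reml else n
    s2e = q / dof
    s2c = lam[0] * s2e
    s2L = lam[1] * s2e
    cov_beta = s2e * np.linalg.inv(XtWiX)
    se = np.sqrt(np.diag(cov_beta))

    if reml:
        sign, logdet_xx = np.linalg.slogdet(XtWiX)
        loglik = -0.5 * ((n - p) * (np.log(s2e) + _LOG2PI + 1.0)
                         + logdetW + logdet_xx)
        aic = None
    else:
        loglik = -0.5 * (n * (np.log(s2e) + _LOG2PI + 1.0) + logdetW)
        aic = 2.0 * (p + 3) - 2.0 * loglik

    used_df_method = "normal"
    dfs = np.full(p, np.inf)
    if df_method == "satterthwaite" and reml:
        dfs_s = _satterthwaite_df(np.array([s2L, s2c, s2e]), struct, X, y)
        if dfs_s is not None:
            dfs = dfs_s
            used_df_method = "satterthwaite"

    tvals = beta / se
    pvals = np.array([
        2 * stats.t.sf(abs(t), d) if np.isfinite(d) else 2 * stats.norm.sf(abs(t))
        for t, d in zip(tvals, dfs)
    ])
    return NestedLmmFit(
        names=names, beta=beta, se=se, df=dfs, tvalues=tvals, pvalues=pvals,
        cov_beta=cov_beta, sigma2_city=s2L, sigma2_child=s2c, sigma2_resid=s2e,
        loglik=loglik, method="reml" if reml else "ml",
        df_method=used_df_method if reml else "normal",
        converged=converged, n=n, p=p, aic=aic,
    )


def _cov_diag(theta, struct, X):
    s2L, s2c, s2e = theta
    WiX, _ = struct.solve(X, s2c / s2e, s2L / s2e)
    return s2e * np.diag(np.linalg.inv(X.T @ WiX))


def _satterthwaite_df(theta, struct, X, y) -> Optional[np.ndarray]:
    """Satterthwaite df per coefficient via the REML observed information."""
    p = X.shape[1]
    # keep only variance components away from the zero boundary
    active = [k for k in range(3) if theta[k] > 1e-10 * theta[2] or k == 2]
    h = np.array([max(1e-8, 1e-4 * theta[k]) for k in range(3)])

    def f(th):
        return _neg2_loglik_theta(th, struct, X, y, reml=True)

    m = len(active)
    H = np.zeros((m, m))
    f0 = f(theta)
    if not np.isfinite(f0):
        return None
    for a_pos, a in enumerate(active):
        for b_pos, b in enumerate(active):
            if b_pos < a_pos:
                continue
            ta, tb = np.zeros(3), np.zeros(3)
            ta[a], tb[b] = h[a], h[b]
            if a == b:
                val = (f(theta + ta) - 2 * f0 + f(theta - ta)) / h[a] ** 2
            else:
                val = (
                    f(theta + ta + tb) - f(theta + ta - tb)
                    - f(theta - ta + tb) + f(theta - ta - tb)
                ) / (4 * h[a] * h[b])
            H[a_pos, b_pos] = H[b_pos, a_pos] = val
    if not np.all(np.isfinite(H)):
        return None
    try:
        var_theta = 2.0 * np.linalg.inv(H)  # information = H/2
    except np.linalg.LinAlgError:
        return None
    if np.any(np.diag(var_theta) <= 0):
        return None

    g0 = _cov_diag(theta, struct, X)
    grad = np.zeros((m, p))
    for a_pos, a in enumerate(active):
        ta = np.zeros(3)
        ta[a] = h[a]
        grad[a_pos] = (_cov_diag(theta + ta, struct, X)
                       - _cov_diag(theta - ta, struct, X)) / (2 * h[a])
    dfs = np.empty(p)
    for j in range(p):
        denom = grad[:, j] @ var_theta @ grad[:, j]
        dfs[j] = 2.0 * g0[j] ** 2 / denom if denom > 0 else np.inf
    return np.clip(dfs, 1.0, np.inf)
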