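"""Random-intercept linear mixed model with REML and Satterthwaite df.

The model is ``y_ij = x_ij' beta + u_i + e_ij`` with ``u_i ~ N(0, sb2)``
and ``e_ij ~ N(0, se2 / w_ij)`` for known observation weights ``w``.
Because the only random term is a scalar intercept per group, every
quantity reduces to per-group sums via the Sherman-Morrison identity, so
a fit is a one-dimensional REML profile over the variance ratio
``lam = sb2 / se2`` — fast enough to sit inside a penalized
quasi-likelihood loop.

Wald inference on a between-group covariate (here: genotype dosage, which
is constant within a person) with ~15 groups cannot rely on normal
quantiles; the engine therefore reports a t statistic with Satterthwaite
degrees of freedom derived from the curvature of the restricted
likelihood in the two variance components.  In the degenerate limit
``sb2 -> 0`` the fit, standard error and df collapse to ordinary least
squares exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

_LOG_LAM_LO, _LOG_LAM_HI = -14.0, 10.0


@dataclass
class LMMFit:
    beta: np.ndarray
    se: np.ndarray
    sigma2_e: float
    sigma2_b: float
    lam: float
    df: np.ndarray          # Satterthwaite df per coefficient
    blups: np.ndarray       # one predicted intercept per group
    converged: bool
    n_obs: int
    n_groups: int

    def t_pvalue(self, k: int) -> float:
        t = self.beta[k] / self.se[k]
        return float(2.0 * stats.t.sf(abs(t), self.df[k]))


class _Workspace:
    """Pre-aggregated sums for repeated criterion evaluations."""

    def __init__(self, y, X, groups, weights):
        self.y = np.asarray(y, float)
        self.X = np.asarray(X, float)
        self.n, self.p = self.X.shape
        self.groups = np.asarray(groups)
        codes, self.uniq = _codes(self.groups)
        self.codes = codes
        self.m = len(self.uniq)
        self.w = np.ones(self.n) if weights is None else np.asarray(weights, float)
        if (self.w <= 0).any():
            raise ValueError("weights must be positive")
        wX = self.X * self.w[:, None]
        self.XtWX = self.X.T @ wX
        self.XtWy = wX.T @ self.y
        self.ytWy = float(self.y @ (self.w * self.y))
        self.Sx = np.zeros((self.m, self.p))
        for j in range(self.p):
            self.Sx[:, j] = np.bincount(codes, wX[:, j], minlength=self.m)
        self.Sy = np.bincount(codes, self.w * self.y, minlength=self.m)
        self.s = np.bincount(codes, self.w, minlength=self.m)
        self.sum_log_w = float(np.log(self.w).sum())

    def core(self, lam: float):
        """A = X'Vt^-1 X, b = X'Vt^-1 y, q = y'Vt^-1 y, logdet Vt; Vt = D + lam ZZ'."""
        c = lam / (1.0 + lam * self.s)
        A = self.XtWX - (self.Sx * c[:, None]).T @ self.Sx
        b = self.XtWy - self.Sx.T @ (c * self.Sy)
        q = self.ytWy - float(c @ (self.Sy**2))
        logdet = -self.sum_log_w + float(np.log1p(lam * self.s).sum())
        return A, b, q, logdet

    def reml_profile(self, lam: float) -> float:
        """-2 * restricted loglik profiled over beta and sigma2_e (+const)."""
        A, b, q, logdet = self.core(lam)
        beta = np.linalg.solve(A, b)
        rq = max(q - float(b @ beta), 1e-300)
        sign, logdetA = np.linalg.slogdet(A)
        return logdet + logdetA + (self.n - self.p) * np.log(rq)

    def reml_full(self, sigma2_b: float, sigma2_e: float) -> float:
        """-2 * restricted loglik at explicit variance components (+const)."""
        lam = sigma2_b / sigma2_e
        A, b, q, logdet = self.core(lam)
        beta = np.linalg.solve(A, b)
        rq = max(q - float(b @ beta), 1e-300)
        _, logdetA = np.linalg.slogdet(A / sigma2_e)
        return self.n * np.log(sigma2_e) + logdet + logdetA + rq / sigma2_e

    def se2_at(self, sigma2_b: float, sigma2_e: float, k: int) -> float:
        lam = sigma2_b / sigma2_e
        A, _, _, _ = self.core(lam)
        return sigma2_e * float(np.linalg.inv(A)[k, k])


def _codes(groups):
    uniq, codes = np.unique(groups, return_inverse=True)
    return codes.astype(np.intp), uniq


def fit_random_intercept(
    y,
    X,
    groups,
    weights=None,
    satterthwaite: bool = True,
) -> LMMFit:
    """REML fit of a random-intercept LMM.

    Parameters
    ----------
    y, X
        Response vector and fixed-effect design (including intercept).
    groups
        Group label per observation (the random-intercept factor).
    weights
        Optional positive precision weights (residual variance of
        observation ``ij`` is ``sigma2_e / w_ij``).
    satterthwaite
        Compute Satterthwaite df per coefficient; otherwise df falls back
        to ``n_groups - p``.
    """
    ws = _Workspace(y, X, groups, weights)
    n, p, m = ws.n, ws.p, ws.m
    if n <= p:
        raise ValueError("more parameters than observations")
    if m < 2:
        raise ValueError("need at least 2 groups")

    # coarse grid then local refinement on log(lam); lam = 0 checked separately
    grid = np.linspace(_LOG_LAM_LO, _LOG_LAM_HI, 19)
    vals = [ws.reml_profile(np.exp(g)) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda u: ws.reml_profile(np.exp(u)), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6},
    )
    lam = float(np.exp(res.x))
    if ws.reml_profile(0.0) <= res.fun + 1e-10 or lam < 1e-10:
        lam = 0.0

    A, b, q, _ = ws.core(lam)
    Ainv = np.linalg.inv(A)
    beta = Ainv @ b
    rq = max(q - float(b @ beta), 1e-300)
    sigma2_e = rq / (n - p)
    sigma2_b = lam * sigma2_e
    cov = sigma2_e * Ainv
    se = np.sqrt(np.diag(cov))

    # BLUP of the group intercepts
    resid = ws.y - ws.X @ beta
    Sr = np.bincount(ws.codes, ws.w * resid, minlength=m)
    blups = (lam / (1.0 + lam * ws.s)) * Sr

    df = np.full(p, float(max(m - p, 1)))
    if lam == 0.0:
        df = np.full(p, float(n - p))
    elif satterthwaite:
        df = _satterthwaite_df(ws, sigma2_b, sigma2_e, se)
    return LMMFit(
        beta=beta, se=se, sigma2_e=sigma2_e, sigma2_b=sigma2_b, lam=lam,
        df=df, blups=blups, converged=True, n_obs=n, n_groups=m,
    )


def _satterthwaite_df(ws: _Workspace, sb2: float, se2: float, se: np.ndarray) -> np.ndarray:
    """df_k = 2 (se_k^2)^2 / g' H^{-1} g with H the observed REML information
    in (sigma2_b, sigma2_e) and g the gradient of se_k^2."""
    n, p = ws.n, ws.p
    theta = np.array([sb2, se2])
    h = np.maximum(1e-4 * theta, 1e-8)
    try:
        H = np.empty((2, 2))
        f0 = ws.reml_full(*theta)
        for a in range(2):
            for c in range(a, 2):
                ta = theta.copy()
                if a == c:
                    ta[a] += h[a]
                    fp = ws.reml_full(*ta)
                    ta[a] -= 2 * h[a]
                    fm = ws.reml_full(*np.maximum(ta, 1e-12))
                    H[a, a] = (fp - 2 * f0 + fm) / h[a] ** 2
                else:
                    tpp = theta + [h[0], h[1]]
                    tpm = theta + [h[0], -h[1]]
                    tmp = theta + [-h[0], h[1]]
                    tmm = theta - [h[0], h[1]]
                    H[a, c] = H[c, a] = (
                        ws.reml_full(*tpp) - ws.reml_full(*np.maximum(tpm, 1e-12))
                        - ws.reml_full(*np.maximum(tmp, 1e-12))
                        + ws.reml_full(*np.maximum(tmm, 1e-12))
                    ) / (4 * h[0] * h[1])
        # reml_full returns -2*loglik, so information = H / 2
        Acov = np.linalg.inv(H / 2.0)
    except np.linalg.LinAlgError:
        return np.full(p, float(max(ws.m - p, 1)))
    df = np.empty(p)
    for k in range(p):
        g = np.empty(2)
        for a in range(2):
            tp = theta.copy()
            tp[a] += h[a]
            tm = np.maximum(theta - np.eye(2)[a] * h[a], 1e-12)
            g[a] = (ws.se2_at(tp[0], tp[1], k) - ws.se2_at(tm[0], tm[1], k)) / (tp[a] - tm[a])
        denom = float(g @ Acov @ g)
        if denom <= 0:
            df[k] = float(max(ws.m - p, 1))
        else:
            df[k] = float(np.clip(2.0 * (se[k] ** 2) ** 2 / denom, 1.0, n - p))
    return df
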