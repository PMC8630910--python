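"""Dropout-aware eQTL association methods and multiplicity control.

Single-cell qPCR expression is zero-inflated (non-detection below the LOD)
and strongly correlated within a person; treating cells as independent
units (the naive per-cell Mann-Whitney scan) grossly inflates type I
error.  Four complementary methods address this, each with the person as
a random effect or the unit of analysis:

``tweedie``
    Mixed model with a Tweedie-type mean-variance relationship
    (``Var = phi * mu^p``, ``1 < p < 2``: point mass at zero plus a
    continuous positive part) and log link, fitted by penalized
    quasi-likelihood with a random intercept per individual.  Models the
    full zero-inflated response in one pass.
``logistic``
    Random-intercept logistic mixed model on the detected/not-detected
    indicator, fitted by Gauss-Hermite maximum likelihood.  Genes that
    are "on" in essentially every cell (average on-proportion > 98%) are
    dropped from this analysis only.
``gaussian_nonzero``
    Random-intercept linear mixed model (REML, Satterthwaite df) on the
    nonzero expression values only.
``proportion_anova``
    One-way ANOVA of per-individual on-proportions on genotype category
    — the individual, not the cell, is the unit, so no random effect is
    needed.

Genotype enters the three regressions as an additive minor-allele dosage
(0/1/2); the ANOVA treats it as a factor.  Wald tests in the mixed models
use a t reference: Satterthwaite degrees of freedom for the Gaussian
model and between-within df (individuals minus fixed effects) for the
quasi-/marginal-likelihood fits, since dosage varies only between people.
Benjamini-Hochberg FDR is applied within each (cell type, method) family.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from monoqtl.datamodel import (
    EQTL_RESULT_COLUMNS,
    ExpressionMatrix,
    GenotypeTable,
    check_individuals_covered,
)
from monoqtl.mixedlm import fit_random_intercept
from monoqtl.qc import drop_saturated_genes, on_proportions

METHODS = ("tweedie", "logistic", "gaussian_nonzero", "proportion_anova")
DEFAULT_TWEEDIE_GRID = (1.1, 1.3, 1.5, 1.7, 1.9)


@dataclass
class ModelFit:
    """Outcome of one association fit for a (SNP, gene, cell type) triple."""

    method: str
    effect: float = math.nan
    se: float = math.nan
    p_value: float = math.nan
    converged: bool = False
    n_individuals: int = 0
    n_cells: int = 0
    skip_reason: str = ""
    extra: dict = field(default_factory=dict)

    @property
    def direction(self) -> str:
        if not np.isfinite(self.effect) or self.effect == 0.0:
            return "undefined"
        return "+" if self.effect > 0 else "-"

    @classmethod
    def skipped(cls, method: str, reason: str, n_individuals: int = 0, n_cells: int = 0):
        return cls(method=method, skip_reason=reason,
                   n_individuals=n_individuals, n_cells=n_cells)


def _as_arrays(values, dosage, individual):
    y = np.asarray(values, float)
    d = np.asarray(dosage, float)
    g = np.asarray(individual)
    if not (len(y) == len(d) == len(g)):
        raise ValueError("values, dosage and individual must have equal length")
    return y, d, g


def _check_contrast(dosage, individual) -> None:
    per_ind = pd.Series(dosage).groupby(pd.Series(individual)).first()
    if per_ind.nunique() < 2:
        raise ValueError("dosage is constant across individuals: no genotype contrast")


# ---------------------------------------------------------------------------
# Gaussian mixed model on the nonzero values


def fit_gaussian_nonzero_mixed(values, dosage, individual) -> ModelFit:
    """Linear mixed model on the nonzero expression values.

    ``values`` may contain zeros; they are removed here.  Requires at
    least 3 individuals contributing a nonzero cell and a genotype
    contrast among them.  Wald p uses Satterthwaite df, which collapses
    to the OLS t test when the random-intercept variance vanishes.
    """
    y, d, g = _as_arrays(values, dosage, individual)
    _check_contrast(d, g)
    nz = y > 0
    y, d, g = y[nz], d[nz], g[nz]
    n_ind = len(np.unique(g))
    if n_ind < 3:
        return ModelFit.skipped("gaussian_nonzero",
                                "fewer than 3 individuals with nonzero cells",
                                n_ind, len(y))
    if np.ptp(y) == 0:
        return ModelFit.skipped("gaussian_nonzero", "zero residual variance",
                                n_ind, len(y))
    if len(np.unique(d)) < 2:
        return ModelFit.skipped("gaussian_nonzero",
                                "no genotype contrast among nonzero cells",
                                n_ind, len(y))
    X = np.column_stack([np.ones_like(y), d])
    fit = fit_random_intercept(y, X, g)
    return ModelFit(
        method="gaussian_nonzero",
        effect=float(fit.beta[1]),
        se=float(fit.se[1]),
        p_value=fit.t_pvalue(1),
        converged=fit.converged,
        n_individuals=n_ind,
        n_cells=len(y),
        extra={"df": float(fit.df[1]), "sigma2_b": fit.sigma2_b,
               "sigma2_e": fit.sigma2_e},
    )


# ---------------------------------------------------------------------------
# Logistic mixed model (Gauss-Hermite maximum likelihood)


def _gh_nodes(n_quad: int):
    t, w = np.polynomial.hermite.hermgauss(n_quad)
    return t, np.log(w)


def _logistic_negll(params, y, x, codes, m, nodes, log_w):
    """Negative marginal log-likelihood via adaptive Gauss-Hermite.

    The person intercept is integrated out with quadrature nodes centered
    and scaled at each person's conditional mode (plain quadrature is
    badly inaccurate once the intercept sd exceeds ~1 with tens of cells
    per person)."""
    b0, b1, log_s = params
    s = np.exp(log_s)
    eta = b0 + b1 * x
    # inner Newton for the conditional mode of each person's intercept
    u = np.zeros(m)
    for _ in range(25):
        p = special.expit(eta + s * u[codes])
        grad = s * np.bincount(codes, y - p, minlength=m) - u
        hess = -(s**2) * np.bincount(codes, p * (1 - p), minlength=m) - 1.0
        step = grad / hess
        u -= step
        if np.max(np.abs(step)) < 1e-9:
            break
    p = special.expit(eta + s * u[codes])
    tau = 1.0 / np.sqrt((s**2) * np.bincount(codes, p * (1 - p), minlength=m) + 1.0)
    # log integral_i = log(sqrt(2) tau_i) + logsumexp_k [log w_k + t_k^2 + h_i(u_ik)]
    # with h_i(u) = sum_j ll_ij(u) - u^2/2 - log(2 pi)/2
    K = len(nodes)
    h = np.empty((m, K))
    for k in range(K):
        uk = u + np.sqrt(2.0) * tau * nodes[k]
        etank = eta + s * uk[codes]
        ll = y * etank - np.logaddexp(0.0, etank)
        h[:, k] = np.bincount(codes, ll, minlength=m) - 0.5 * uk**2
    h += log_w[None, :] + (nodes**2)[None, :]
    log_int = (np.log(np.sqrt(2.0) * tau) - 0.5 * np.log(2 * np.pi)
               + special.logsumexp(h, axis=1))
    return -float(log_int.sum())


def fit_logistic_mixed(on, dosage, individual, n_quad: int = 21) -> ModelFit:
    """Random-intercept logistic mixed model on the on/off indicator.

    The marginal likelihood integrates the person intercept out with
    ``n_quad``-node Gauss-Hermite quadrature; the effect is the additive
    log-odds of detection per minor allele.
    """
    y, d, g = _as_arrays(on, dosage, individual)
    y = (y > 0).astype(float)
    _check_contrast(d, g)
    uniq, codes = np.unique(g, return_inverse=True)
    m = len(uniq)
    if y.min() == y.max():
        return ModelFit.skipped("logistic", "single-class outcome", m, len(y))
    nodes, log_w = _gh_nodes(n_quad)
    pbar = min(max(y.mean(), 1e-3), 1 - 1e-3)
    x0 = np.array([np.log(pbar / (1 - pbar)), 0.0, 0.0])
    bounds = [(-30, 30), (-15, 15), (-5.0, 3.0)]
    args = (y, d, codes, m, nodes, log_w)
    res = optimize.minimize(
        _logistic_negll, x0, args=args,
        method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 300, "ftol": 1e-10},
    )
    success = bool(res.success)
    if not success:
        # the numeric gradient can stall the line search near the optimum;
        # a simplex polish from the current point settles it
        res2 = optimize.minimize(_logistic_negll, res.x, args=args,
                                 method="Nelder-Mead",
                                 options={"xatol": 1e-6, "fatol": 1e-8,
                                          "maxiter": 400})
        if res2.fun <= res.fun + 1e-9:
            res = res2
            success = bool(res2.success)
    b1 = float(res.x[1])
    se, ok = _numeric_se(_logistic_negll, res.x, args, k=1)
    converged = success and ok and se > 1e-6 and abs(b1) < 10.0
    df = max(m - 2, 1)
    p = float(2 * stats.t.sf(abs(b1 / se), df)) if se > 0 else math.nan
    return ModelFit(
        method="logistic", effect=b1, se=se, p_value=p, converged=converged,
        n_individuals=m, n_cells=len(y),
        extra={"sigma_b": float(np.exp(res.x[2])), "df": float(df),
               "possible_separation": abs(b1) >= 10.0},
    )


def _numeric_se(negll, x, args, k: int) -> tuple[float, bool]:
    """Wald SE of parameter ``k`` from a central-difference Hessian."""
    npar = len(x)
    h = 1e-3 * (1.0 + np.abs(x))
    H = np.empty((npar, npar))
    for a in range(npar):
        for b in range(a, npar):
            xa, xb = np.eye(npar)[a] * h[a], np.eye(npar)[b] * h[b]
            if a == b:
                H[a, a] = (negll(x + xa, *args) - 2 * negll(x, *args)
                           + negll(x - xa, *args)) / h[a] ** 2
            else:
                H[a, b] = H[b, a] = (
                    negll(x + xa + xb, *args) - negll(x + xa - xb, *args)
                    - negll(x - xa + xb, *args) + negll(x - xa - xb, *args)
                ) / (4 * h[a] * h[b])
    try:
        cov = np.linalg.inv(H)
        v = cov[k, k]
        if v <= 0 or not np.isfinite(v):
            return math.nan, False
        return float(np.sqrt(v)), True
    except np.linalg.LinAlgError:
        return math.nan, False


# ---------------------------------------------------------------------------
# Tweedie mixed model (penalized quasi-likelihood)


def _tweedie_deviance(y, mu, p):
    """Unit deviance of the Tweedie family for 1 < p < 2 (finite at y = 0)."""
    term1 = np.where(y > 0, y ** (2 - p) / ((1 - p) * (2 - p)), 0.0)
    term2 = np.where(y > 0, y * mu ** (1 - p) / (1 - p), 0.0)
    term3 = mu ** (2 - p) / (2 - p)
    return 2.0 * (term1 - term2 + term3)


def _pql_fit(y, X, groups, p, max_iter=60, tol=1e-7):
    mu = y + 0.5 * max(y.mean(), 0.1)
    eta = np.log(mu)
    beta_old = None
    fit = None
    for it in range(max_iter):
        mu = np.exp(np.clip(eta, -20.0, 10.0))
        z = eta + (y - mu) / mu
        w = mu ** (2.0 - p)
        fit = fit_random_intercept(z, X, groups, weights=w, satterthwaite=False)
        codes = pd.Series(groups).astype("category").cat.codes.to_numpy()
        eta = X @ fit.beta + fit.blups[codes]
        if beta_old is not None and np.max(np.abs(fit.beta - beta_old)) < tol:
            return fit, np.exp(np.clip(eta, -20.0, 10.0)), True
        beta_old = fit.beta.copy()
    return fit, np.exp(np.clip(eta, -20.0, 10.0)), False


def _eql(y, mu, p):
    """Extended quasi-likelihood used only to profile the power index."""
    ystar = np.where(y > 0, y, max(y[y > 0].min() if (y > 0).any() else 0.1, 0.1) / 6.0)
    dev = _tweedie_deviance(y, mu, p)
    phi = max(float(np.mean((y - mu) ** 2 / mu**p)), 1e-8)
    return -0.5 * float(np.sum(dev / phi + np.log(2 * np.pi * phi * ystar**p)))


def fit_tweedie_mixed(
    values,
    dosage,
    individual,
    power: float | None = None,
    power_grid: Sequence[float] = DEFAULT_TWEEDIE_GRID,
) -> ModelFit:
    """Tweedie-type mixed model on the full zero-inflated expression.

    Fits a log-link quasi-model with variance function ``mu^p`` and a
    random intercept per individual by penalized quasi-likelihood; the
    effect is the additive log-mean shift per minor allele.  When
    ``power`` is None, the power index is profiled over ``power_grid``
    by extended quasi-likelihood.
    """
    y, d, g = _as_arrays(values, dosage, individual)
    _check_contrast(d, g)
    n_ind = len(np.unique(g))
    if not (y > 0).any():
        return ModelFit.skipped("tweedie", "all-zero gene", n_ind, len(y))
    if (y < 0).any():
        raise ValueError("negative expression values")
    X = np.column_stack([np.ones_like(y), d])
    grid = [power] if power is not None else list(power_grid)
    best = None
    for p in grid:
        if not 1.0 < p < 2.0:
            raise ValueError(f"tweedie power must be in (1, 2), got {p}")
        try:
            fit, mu, conv = _pql_fit(y, X, g, p)
        except (np.linalg.LinAlgError, ValueError):
            continue
        score = _eql(y, mu, p) if power is None else 0.0
        if best is None or score > best[0]:
            best = (score, p, fit, conv)
    if best is None:
        return ModelFit.skipped("tweedie", "PQL failed on all power values", n_ind, len(y))
    _, p_used, fit, conv = best
    df = max(n_ind - 2, 1)
    tstat = fit.beta[1] / fit.se[1]
    return ModelFit(
        method="tweedie",
        effect=float(fit.beta[1]),
        se=float(fit.se[1]),
        p_value=float(2 * stats.t.sf(abs(tstat), df)),
        converged=conv,
        n_individuals=n_ind,
        n_cells=len(y),
        extra={"power": p_used, "df": float(df), "sigma2_b": fit.sigma2_b},
    )


# ---------------------------------------------------------------------------
# Proportion ANOVA


def fit_proportion_anova(
    proportions, dosage, min_per_group: int = 2
) -> ModelFit:
    """One-way ANOVA of per-individual on-proportions on genotype category.

    Genotype is a factor with levels {0, 1, 2}; a homozygous-minor group
    with fewer than ``min_per_group`` individuals is merged with the
    heterozygotes (dominant collapse), which is recorded in ``extra``.
    The reported effect is the mean on-proportion difference between
    minor-allele carriers and major-allele homozygotes, which supplies
    the direction of association.
    """
    pr = np.asarray(proportions, float)
    d = np.asarray(dosage, float)
    if len(pr) != len(d):
        raise ValueError("proportions and dosage must align per individual")
    keep = np.isfinite(pr)
    pr, d = pr[keep], d[keep]
    n = len(pr)
    collapsed = False
    if (d == 2).sum() < min_per_group and (d == 2).any():
        d = np.where(d == 2, 1, d)
        collapsed = True
    levels = np.unique(d)
    if len(levels) < 2:
        return ModelFit.skipped("proportion_anova", "single genotype group", n, n)
    groups = [pr[d == lev] for lev in levels]
    grand = pr.mean()
    ssb = sum(len(gk) * (gk.mean() - grand) ** 2 for gk in groups)
    ssw = sum(((gk - gk.mean()) ** 2).sum() for gk in groups)
    df_b, df_w = len(levels) - 1, n - len(levels)
    carriers, majors = pr[d > 0], pr[d == 0]
    effect = float(carriers.mean() - majors.mean()) if len(carriers) and len(majors) else math.nan
    if df_w < 1:
        return ModelFit.skipped("proportion_anova", "no within-group df", n, n)
    if ssw <= 1e-300:
        if ssb <= 1e-300:
            return ModelFit(method="proportion_anova", effect=0.0, se=math.nan,
                            p_value=1.0, converged=True, n_individuals=n, n_cells=n,
                            extra={"F": 0.0, "collapsed": collapsed})
        return ModelFit.skipped("proportion_anova",
                                "zero within-group variance", n, n)
    F = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return ModelFit(
        method="proportion_anova", effect=effect, se=math.nan, p_value=p,
        converged=True, n_individuals=n, n_cells=n,
        extra={"F": float(F), "df": (df_b, df_w), "collapsed": collapsed},
    )


# ---------------------------------------------------------------------------
# Naive per-cell Mann-Whitney scan


def naive_mw_fit(values, dosage) -> ModelFit:
    """Two-sided Mann-Whitney U on cells: major-allele homozygotes vs carriers.

    Cells are deliberately treated as independent units — this is the
    pseudoreplicating univariate scan whose inflated type I error
    motivates the mixed models; it is retained only for that comparison.
    """
    y = np.asarray(values, float)
    d = np.asarray(dosage, float)
    a, b = y[d == 0], y[d > 0]
    if len(a) == 0 or len(b) == 0:
        return ModelFit.skipped("naive_mw", "empty genotype group", 0, len(y))
    if np.ptp(y) == 0:
        return ModelFit(method="naive_mw", effect=0.0, se=math.nan, p_value=1.0,
                        converged=True, n_cells=len(y))
    res = stats.mannwhitneyu(b, a, alternative="two-sided")
    return ModelFit(
        method="naive_mw",
        effect=float(b.mean() - a.mean()),
        se=math.nan,
        p_value=float(res.pvalue),
        converged=True,
        n_cells=len(y),
        extra={"U": float(res.statistic)},
    )


def naive_mw_scan(
    expr: ExpressionMatrix, genotypes: GenotypeTable, cell_type: str | None = None
) -> pd.DataFrame:
    """Mann-Whitney scan of every (SNP, gene) pair on per-cell expression."""
    records = []
    cts = [cell_type] if cell_type else sorted(expr.cell_meta["cell_type"].unique())
    for ct in cts:
        sub = expr.for_cell_type(ct)
        inds = sub.cell_meta["individual_id"]
        n_ind = inds.nunique()
        for rsid in genotypes.rsids:
            dose = inds.map(genotypes.dosages[rsid]).to_numpy(float)
            for gene in sub.gene_ids:
                mf = naive_mw_fit(sub.values[gene].to_numpy(), dose)
                records.append(_record(rsid, gene, ct, mf, n_ind))
    return _finalize(records, fdr_q=None)


# ---------------------------------------------------------------------------
# Multiplicity control


def bh_fdr(p_values, q: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted q-values and retention mask.

    Missing p-values are excluded from the correction and come back as
    NaN / not retained.  Retention is strict: ``adjusted < q``.
    """
    p = np.asarray(p_values, float)
    qvals = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    m = int(ok.sum())
    if m == 0:
        return qvals, np.zeros(p.shape, bool)
    pv = p[ok]
    if (pv < 0).any() or (pv > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    qvals[ok] = out
    retained = np.zeros(p.shape, bool)
    retained[ok] = qvals[ok] < q
    return qvals, retained


def bonferroni_threshold(n_genes: int, n_snps: int, alpha: float = 0.05) -> float:
    """Per-test significance threshold, ``alpha / (n_genes * n_snps)``."""
    if n_genes <= 0 or n_snps <= 0:
        raise ValueError("comparison counts must be positive")
    return alpha / (n_genes * n_snps)


# ---------------------------------------------------------------------------
# Scan driver


def _record(rsid, gene, cell_type, mf: ModelFit, n_individuals=None) -> dict:
    return {
        "rsid": rsid,
        "gene": gene,
        "cell_type": cell_type,
        "method": mf.method,
        "effect": mf.effect,
        "se": mf.se,
        "p_value": mf.p_value,
        "fdr_q": math.nan,
        "direction": mf.direction,
        "significant": False,
        "n_individuals": n_individuals if n_individuals is not None else mf.n_individuals,
        "n_cells": mf.n_cells,
        "converged": mf.converged,
        "skip_reason": mf.skip_reason,
    }


def _finalize(records: list[dict], fdr_q: float | None) -> pd.DataFrame:
    table = pd.DataFrame(records, columns=EQTL_RESULT_COLUMNS)
    if fdr_q is None or table.empty:
        return table
    for (ct, method), idx in table.groupby(["cell_type", "method"]).groups.items():
        sub = table.loc[idx]
        usable = sub["converged"] & sub["p_value"].notna()
        pvals = sub["p_value"].where(usable, np.nan).to_numpy(float)
        qvals, retained = bh_fdr(pvals, q=fdr_q)
        table.loc[idx, "fdr_q"] = qvals
        table.loc[idx, "significant"] = retained
    return table


def run_eqtl_scan(
    expr: ExpressionMatrix,
    genotypes: GenotypeTable,
    methods: Sequence[str] = METHODS,
    fdr_q: float = 0.1,
    tweedie_power: float | None = None,
    saturation_threshold: float = 0.98,
) -> pd.DataFrame:
    """Fit every (SNP, gene, cell type, method) combination and apply FDR.

    BH correction runs within each (cell type, method) family over all
    SNP-gene pairs; ``significant`` marks rows retained at
    ``fdr_q`` — a pair is an eQTL if at least one method retains it.
    Fits that are skipped or fail to converge never enter the FDR ranks;
    their reasons stay in ``skip_reason``.
    """
    unknown = set(methods) - set(METHODS) - {"naive_mw"}
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    check_individuals_covered(expr, genotypes)
    records: list[dict] = []
    for ct in sorted(expr.cell_meta["cell_type"].unique()):
        sub = expr.for_cell_type(ct)
        inds = sub.cell_meta["individual_id"]
        n_ind = inds.nunique()
        if "logistic" in methods:
            logit_genes, _ = drop_saturated_genes(sub, saturation_threshold)
            logit_genes = set(logit_genes)
        props = (
            on_proportions(sub, "individual") if "proportion_anova" in methods else None
        )
        for rsid in genotypes.rsids:
            dose = inds.map(genotypes.dosages[rsid]).to_numpy(float)
            per_ind_dose = (
                genotypes.dosages[rsid].reindex(props.index).to_numpy(float)
                if props is not None else None
            )
            contrast = len(np.unique(dose)) > 1
            for gene in sub.gene_ids:
                y = sub.values[gene].to_numpy(float)
                for method in methods:
                    if not contrast:
                        mf = ModelFit.skipped(method, "no genotype contrast",
                                              n_ind, len(y))
                    elif method == "logistic" and gene not in logit_genes:
                        mf = ModelFit.skipped(method, "saturated gene (>98% on)",
                                              n_ind, len(y))
                    else:
                        mf = _dispatch(method, y, dose, inds.to_numpy(),
                                       props, per_ind_dose, gene, tweedie_power)
                    records.append(_record(rsid, gene, ct, mf, n_ind))
    return _finalize(records, fdr_q)


def _dispatch(method, y, dose, inds, props, per_ind_dose, gene, tweedie_power) -> ModelFit:
    try:
        if method == "tweedie":
            return fit_tweedie_mixed(y, dose, inds, power=tweedie_power)
        if method == "logistic":
            return fit_logistic_mixed(y, dose, inds)
        if method == "gaussian_nonzero":
            return fit_gaussian_nonzero_mixed(y, dose, inds)
        if method == "proportion_anova":
            return fit_proportion_anova(props[gene].to_numpy(float), per_ind_dose)
        if method == "naive_mw":
            return naive_mw_fit(y, dose)
    except Exception as exc:  # propagate as a recorded skip, never abort the scan
        warnings.warn(f"{method} fit failed: {exc}", stacklevel=2)
        return ModelFit.skipped(method, f"error: {exc}")
    raise AssertionError(method)


def significant_hits(table: pd.DataFrame) -> pd.DataFrame:
    """Rows retained by the FDR step, one per (SNP, gene, cell type, method)."""
    return table[table["significant"]].reset_index(drop=True)
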