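"""Individual-averaged gene-gene correlation PCA and module extraction.

Pooling cells from all donors before computing gene-gene correlations
confounds co-expression with between-person expression differences: a
gene pair shifted up together in some donors looks correlated even if
independent within every donor.  The remedy used here computes a Pearson
correlation matrix *within* each individual's cells, averages the
matrices element-wise across individuals, and eigendecomposes the mean
matrix.  Cells are then projected onto the resulting axes; gene modules
are the genes whose loading magnitude on a highly explanatory component
exceeds a threshold (default 0.7), where the loading is the gene-PC
correlation, eigenvector entry times the square root of its eigenvalue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from monoqtl.datamodel import ExpressionMatrix


@dataclass
class CoexpressionResult:
    cell_type: str
    gene_universe: list[str]
    per_individual: dict[str, pd.DataFrame]
    mean_correlation: pd.DataFrame
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray            # columns, same order as eigenvalues
    variance_explained: np.ndarray
    loadings: pd.DataFrame              # genes x PCs
    cell_scores: pd.DataFrame | None = None
    modules: dict[str, list[str]] = field(default_factory=dict)


def common_gene_universe(expr: ExpressionMatrix, cell_type: str) -> list[str]:
    """Genes whose correlation is defined within every individual.

    A gene qualifies when every individual's cells of ``cell_type`` show
    nonzero expression variance for it (a gene that is all-zero, or
    constant, in any one individual has no defined correlation there).
    Raises with a per-individual diagnostic if no gene survives.
    """
    sub = expr.for_cell_type(cell_type)
    inds = sub.cell_meta["individual_id"]
    if inds.nunique() < 2:
        raise ValueError("need at least 2 individuals")
    variances = sub.values.groupby(inds).var(ddof=1)
    ok = (variances > 0).all(axis=0)
    universe = [g for g in sub.gene_ids if ok[g]]
    if not universe:
        n_bad = (~(variances > 0)).sum(axis=1).to_dict()
        raise ValueError(
            f"no gene has variance in every individual; "
            f"constant-gene counts per individual: {n_bad}"
        )
    return universe


def per_individual_correlations(
    expr: ExpressionMatrix, cell_type: str, gene_universe: list[str] | None = None
) -> dict[str, pd.DataFrame]:
    """Pearson correlation matrix of each individual's cells (zeros included)."""
    sub = expr.for_cell_type(cell_type)
    if gene_universe is None:
        gene_universe = common_gene_universe(expr, cell_type)
    out = {}
    for ind, idx in sub.cell_meta.groupby("individual_id").groups.items():
        mat = sub.values.loc[idx, gene_universe]
        out[str(ind)] = mat.corr(method="pearson")
    return out


def average_correlation(per_individual: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Element-wise unweighted mean of per-individual correlation matrices."""
    mats = list(per_individual.values())
    if not mats:
        raise ValueError("no correlation matrices")
    ref = mats[0]
    for m in mats[1:]:
        if not (m.index.equals(ref.index) and m.columns.equals(ref.columns)):
            raise ValueError("correlation matrices are not on the same gene universe")
    return sum(mats) / len(mats)


def pca_from_correlation(mean_corr: pd.DataFrame):
    """Eigendecomposition of a correlation matrix, ordered and sign-fixed.

    Returns ``(eigenvalues, eigenvectors, variance_explained, loadings)``
    with eigenvalues descending, variance_explained_i = lambda_i / p, and
    loadings = eigenvector * sqrt(max(lambda, 0)).  The sign of each
    eigenvector is fixed so its largest-magnitude loading is positive.
    """
    M = np.asarray(mean_corr, float)
    if M.shape[0] != M.shape[1] or not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("input must be a symmetric matrix")
    lam, vec = np.linalg.eigh(M)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    for j in range(vec.shape[1]):
        k = np.argmax(np.abs(vec[:, j]))
        if vec[k, j] < 0:
            vec[:, j] = -vec[:, j]
    var_explained = lam / M.shape[0]
    loadings = vec * np.sqrt(np.clip(lam, 0.0, None))[None, :]
    genes = list(mean_corr.index) if isinstance(mean_corr, pd.DataFrame) else None
    pcs = [f"PC{i + 1}" for i in range(len(lam))]
    loadings = pd.DataFrame(loadings, index=genes, columns=pcs)
    return lam, vec, var_explained, loadings


def project_cells(
    expr: ExpressionMatrix,
    cell_type: str,
    gene_universe: list[str],
    eigenvectors: np.ndarray,
    n_components: int | None = None,
) -> pd.DataFrame:
    """Project standardized cells onto principal axes.

    Expression is standardized per gene with the *pooled* mean/sd over
    all cells of the cell type (per-individual centering would trivially
    erase individual effects and defeat the comparison the projection is
    for); the score of a cell is its standardized row times the
    eigenvector.
    """
    sub = expr.for_cell_type(cell_type)
    missing = [g for g in gene_universe if g not in sub.values.columns]
    if missing:
        raise ValueError(f"genes absent from expression matrix: {missing}")
    X = sub.values[gene_universe].to_numpy(float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("a universe gene has zero pooled variance")
    Z = (X - mu) / sd
    k = eigenvectors.shape[1] if n_components is None else n_components
    scores = Z @ eigenvectors[:, :k]
    out = pd.DataFrame(scores, index=sub.values.index,
                       columns=[f"PC{i + 1}" for i in range(k)])
    out.insert(0, "individual_id", sub.cell_meta["individual_id"].to_numpy())
    return out


def select_pcs(variance_explained: np.ndarray, rule: str = "pc1",
               factor: float = 10.0) -> list[int]:
    """Choose the "highly explanatory" components (0-based indices).

    ``pc1`` keeps the first component only (the leading component
    typically explains an order of magnitude more variance than the
    next); ``dominant`` keeps components whose variance share is at
    least ``factor`` times the median share.
    """
    if rule == "pc1":
        return [0]
    if rule == "dominant":
        med = float(np.median(variance_explained))
        return [i for i, v in enumerate(variance_explained) if v >= factor * med] or [0]
    raise ValueError(f"unknown PC selection rule {rule!r}")


def extract_modules(
    loadings: pd.DataFrame,
    variance_explained: np.ndarray,
    threshold: float = 0.7,
    pc_selection: str = "pc1",
) -> dict[str, list[str]]:
    """Genes with |loading| > ``threshold`` on each selected component."""
    out = {}
    for i in select_pcs(variance_explained, pc_selection):
        pc = f"PC{i + 1}"
        col = loadings[pc]
        out[pc] = list(col.index[col.abs() > threshold])
    return out


def module_partition(cl_module: list[str], ncl_module: list[str]) -> dict[str, list[str]]:
    """Partition two cell types' modules into shared and unique gene sets."""
    cl, ncl = set(cl_module), set(ncl_module)
    return {
        "classical": sorted(cl - ncl),
        "shared": sorted(cl & ncl),
        "non_classical": sorted(ncl - cl),
    }


def eta_squared(scores: pd.Series | np.ndarray, individual) -> float:
    """Fraction of score variance explained by individual identity (eta^2)."""
    s = pd.Series(np.asarray(scores, float))
    g = pd.Series(np.asarray(individual)).reset_index(drop=True)
    grand = s.mean()
    ssb = sum(len(v) * (v.mean() - grand) ** 2 for _, v in s.groupby(g))
    sst = float(((s - grand) ** 2).sum())
    return float(ssb / sst) if sst > 0 else float("nan")


def analyze_coexpression(
    expr: ExpressionMatrix,
    cell_type: str,
    threshold: float = 0.7,
    pc_selection: str = "pc1",
) -> CoexpressionResult:
    """Full averaged-correlation PCA for one cell type."""
    universe = common_gene_universe(expr, cell_type)
    per_ind = per_individual_correlations(expr, cell_type, universe)
    mean_corr = average_correlation(per_ind)
    lam, vec, var_exp, loadings = pca_from_correlation(mean_corr)
    scores = project_cells(expr, cell_type, universe, vec, n_components=min(5, len(lam)))
    modules = extract_modules(loadings, var_exp, threshold, pc_selection)
    return CoexpressionResult(
        cell_type=cell_type,
        gene_universe=universe,
        per_individual=per_ind,
        mean_correlation=mean_corr,
        eigenvalues=lam,
        eigenvectors=vec,
        variance_explained=var_exp,
        loadings=loadings,
        cell_scores=scores,
        modules=modules,
    )
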