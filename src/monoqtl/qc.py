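"""Cell- and gene-level quality control and the CT-to-expression transform.

qPCR reports a threshold cycle (CT) per reaction: fewer cycles means more
transcript.  Expression is re-expressed as cycles of amplification above
threshold, ``total_cycles - CT``, so that higher numbers mean more
expression, with a limit of detection (LOD): any CT at or above the LOD —
or a failed reaction — is scored as 0 ("off").  Failed cells are flagged
by their failure score, the per-cell sum of CT values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from monoqtl.datamodel import CTMatrix, ExpressionMatrix


class ConfigurationError(ValueError):
    pass


@dataclass
class QCReport:
    """Per-cell failure scores and exclusion flags, per-gene on-proportions.

    ``cell_table`` has one row per input cell with columns
    ``failure_score``, ``excluded`` and ``reason`` (empty string, or the
    single primary reason among ``doublet``/``empty``/``failure_score``).
    """

    cell_table: pd.DataFrame
    k_sd: float
    group_stats: pd.DataFrame

    @property
    def excluded_cells(self) -> list[str]:
        return list(self.cell_table.index[self.cell_table["excluded"]])

    def to_json_dict(self) -> dict:
        return {
            "n_cells": int(len(self.cell_table)),
            "n_excluded": int(self.cell_table["excluded"].sum()),
            "reasons": self.cell_table.loc[
                self.cell_table["excluded"], "reason"
            ].value_counts().to_dict(),
            "k_sd": self.k_sd,
        }


def ct_to_expression(
    ct: CTMatrix, total_cycles: float = 40.0, lod: float = 28.0
) -> ExpressionMatrix:
    """Transform CT values to expression (cycles above threshold).

    expression = total_cycles - CT when CT < lod; 0 when CT >= lod or the
    reaction failed (missing CT).
    """
    if not total_cycles > lod > 0:
        raise ConfigurationError(
            f"need total_cycles > lod > 0, got total_cycles={total_cycles}, lod={lod}"
        )
    v = ct.values.to_numpy(dtype=float)
    detected = ~np.isnan(v) & (v < lod)
    expr = np.where(detected, total_cycles - v, 0.0)
    values = pd.DataFrame(expr, index=ct.values.index, columns=ct.values.columns)
    return ExpressionMatrix(values, ct.cell_meta.copy(), lod=lod, total_cycles=total_cycles)


def failure_score_filter(
    ct: CTMatrix,
    k_sd: float = 2.0,
    total_cycles: float = 40.0,
    missing_as_total: bool = True,
    per_run: bool = True,
) -> QCReport:
    """Flag cells whose failure score exceeds mean + ``k_sd`` * sd.

    The failure score is the per-cell sum of CT values; missing CTs
    contribute ``total_cycles`` by default so that low-yield cells are
    penalized.  Non-singlet capture flags take precedence as the primary
    exclusion reason.  Statistics are computed per capture run
    (individual x cell type) by default to absorb batch effects on CT
    totals; pass ``per_run=False`` for a single global mean/sd.
    """
    if ct.n_cells < 3:
        raise ValueError("failure-score filter needs at least 3 cells")
    v = ct.values.to_numpy(dtype=float)
    filled = np.where(np.isnan(v), total_cycles if missing_as_total else 0.0, v)
    scores = pd.Series(filled.sum(axis=1), index=ct.values.index, name="failure_score")

    meta = ct.cell_meta
    reason = pd.Series("", index=scores.index, dtype=object)
    reason[meta["capture_flag"] == "doublet"] = "doublet"
    reason[meta["capture_flag"] == "empty"] = "empty"

    candidates = reason == ""  # failure statistics over singlet cells
    if per_run:
        groups = meta.loc[candidates, ["individual_id", "cell_type"]].apply(tuple, axis=1)
    else:
        groups = pd.Series("all", index=scores.index[candidates])

    stats_rows = []
    for key, idx in scores.loc[candidates].groupby(groups).groups.items():
        sub = scores.loc[idx]
        mu, sd = float(sub.mean()), float(sub.std(ddof=1)) if len(sub) > 1 else 0.0
        if np.isnan(sd):
            sd = 0.0
        cutoff = mu + k_sd * sd
        flagged = sub.index[sub > cutoff] if sd > 0 else []
        reason[flagged] = "failure_score"
        stats_rows.append({"group": key, "mean": mu, "sd": sd, "cutoff": cutoff,
                           "n_cells": len(sub), "n_flagged": len(flagged)})

    table = pd.DataFrame(
        {"failure_score": scores, "excluded": reason != "", "reason": reason}
    )
    if table["excluded"].all():
        raise ValueError("all cells excluded by QC: degenerate input")
    return QCReport(table, k_sd=k_sd, group_stats=pd.DataFrame(stats_rows))


def exclude_nonsinglets(ct: CTMatrix) -> CTMatrix:
    """Retain only cells whose capture flag is ``singlet``."""
    mask = ct.cell_meta["capture_flag"] == "singlet"
    if not mask.any():
        warnings.warn("no singlet cells remain", stacklevel=2)
    return ct.subset_cells(mask)


def apply_qc(
    ct: CTMatrix,
    k_sd: float = 2.0,
    total_cycles: float = 40.0,
    per_run: bool = True,
) -> tuple[CTMatrix, QCReport]:
    """Drop doublets/empties and failure-score outliers in one pass."""
    report = failure_score_filter(ct, k_sd=k_sd, total_cycles=total_cycles, per_run=per_run)
    keep = ~report.cell_table["excluded"]
    return ct.subset_cells(keep), report


def on_proportions(
    expr: ExpressionMatrix, group_by: str = "individual"
) -> pd.DataFrame:
    """Fraction of cells with nonzero expression, per group and gene.

    ``group_by`` is ``individual``, ``cell_type`` or
    ``individual_x_cell_type``.  Empty groups yield missing proportions.
    """
    keys = {
        "individual": ["individual_id"],
        "cell_type": ["cell_type"],
        "individual_x_cell_type": ["individual_id", "cell_type"],
    }
    if group_by not in keys:
        raise ValueError(f"unknown grouping {group_by!r}")
    on = (expr.values > 0).astype(float)
    grouping = [expr.cell_meta[k] for k in keys[group_by]]
    return on.groupby(grouping).mean()


def drop_saturated_genes(
    expr: ExpressionMatrix, threshold: float = 0.98
) -> tuple[list[str], list[str]]:
    """Partition genes into (kept, dropped) by average on-proportion.

    A gene whose on-proportion, averaged across individuals, strictly
    exceeds ``threshold`` carries almost no on/off signal and is dropped
    from the binary (logistic) analysis only.  A gene at exactly the
    threshold is kept; an all-off gene is kept (proportion 0).
    """
    avg = on_proportions(expr, "individual").mean(axis=0)
    dropped = [g for g in expr.gene_ids if avg[g] > threshold]
    kept = [g for g in expr.gene_ids if g not in set(dropped)]
    return kept, dropped


def detect_on_off_genes(
    expr: ExpressionMatrix,
    low: float = 0.0,
    high: float = 0.5,
    min_individuals: int = 2,
) -> pd.DataFrame:
    """Flag genes with a person-level on/off expression pattern.

    A gene is flagged when at least ``min_individuals`` individuals express
    it in at most a fraction ``low`` of their cells (the "off" people)
    while at least ``min_individuals`` others express it in at least
    ``high`` of their cells (the "on" people) — the bimodal pattern in
    which a transcript is absent from every cell of some donors yet
    present in most cells of others.

    Returns a DataFrame indexed by gene with columns ``flagged``,
    ``n_off``, ``n_on`` and ``status`` (per-individual dict of
    "off"/"on"/"intermediate").
    """
    props = on_proportions(expr, "individual")
    if len(props) < 2 * min_individuals:
        raise ValueError(
            f"need at least {2 * min_individuals} individuals, have {len(props)}"
        )
    rows = []
    for gene in expr.gene_ids:
        p = props[gene].dropna()
        off = p.index[p <= low]
        on = p.index[p >= high]
        status = {
            ind: ("off" if ind in set(off) else "on" if ind in set(on) else "intermediate")
            for ind in p.index
        }
        rows.append(
            {
                "gene": gene,
                "flagged": len(off) >= min_individuals and len(on) >= min_individuals,
                "n_off": len(off),
                "n_on": len(on),
                "status": status,
            }
        )
    return pd.DataFrame(rows).set_index("gene")
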