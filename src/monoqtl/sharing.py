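"""Cross-cell-type and cross-SNP eQTL sharing bookkeeping.

An eQTL (SNP, transcript) pair is *shared* between the classical (CL)
and non-classical (NCL) monocyte subsets when it meets the significance
cutoff in both subsets with the same direction of association; otherwise
it is exclusive to the subset where it was found.  Within a cell type,
the module also reports transcripts associated with more than one SNP
(convergence of distinct risk alleles on the same transcript).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

#: Published reference list of 25 significant single-cell eQTL associations
#: (FDR < 0.1) between SLE-risk SNPs and transcripts in classical (CL) and
#: non-classical (NCL) monocytes, used as the worked bookkeeping example.
#: Columns: locus, rsid, gene, method, cell_type.  Directions are not part
#: of the published list; the one pair found in both subsets is taken as
#: concordant.
PUBLISHED_HITS = pd.DataFrame(
    [
        ("ITGAM", "rs1143679", "TLR7", "logistic", "CL"),
        ("ITGAM", "rs1143683", "JAK1", "logistic", "CL"),
        ("TNFAIP3", "rs2230926", "IRF8", "proportion_anova", "CL"),
        ("SPP1", "rs9138", "ARG1", "logistic", "CL"),
        ("SPP1", "rs9138", "IRF1", "logistic", "CL"),
        ("SPP1", "rs9138", "IRF4", "logistic", "CL"),
        ("IRF5", "rs10488631", "IRF1", "logistic", "NCL"),
        ("IRF7", "rs1061502", "IRF1", "logistic", "NCL"),
        ("ITGAM", "rs1143679", "ARG1", "gaussian_nonzero", "NCL"),
        ("ITGAM", "rs1143679", "TCF4", "logistic", "NCL"),
        ("ITGAM", "rs1143683", "IL1B", "gaussian_nonzero", "NCL"),
        ("ITGAM", "rs1143683", "TNFA", "gaussian_nonzero", "NCL"),
        ("TNFAIP3", "rs2230926", "CD274", "logistic", "NCL"),
        ("TNFAIP3", "rs2230926", "FCER1G", "proportion_anova", "NCL"),
        ("TNFAIP3", "rs2230926", "IL7R", "proportion_anova", "NCL"),
        ("TNFAIP3", "rs2230926", "STAT1", "proportion_anova", "NCL"),
        ("TNFAIP3", "rs2230926", "STAT2", "tweedie", "NCL"),
        ("TNFAIP3", "rs2230926", "TNFA", "logistic", "NCL"),
        ("TNFAIP3", "rs2230926", "TYK2", "proportion_anova", "NCL"),
        ("PTPN22", "rs2476601", "IL5", "logistic", "NCL"),
        ("SPP1", "rs9138", "IFIT5", "proportion_anova", "NCL"),
        ("SPP1", "rs9138", "IL1A", "proportion_anova", "NCL"),
        ("SPP1", "rs9138", "IRF1", "logistic", "NCL"),
        ("SPP1", "rs9138", "TLR3", "proportion_anova", "NCL"),
        ("SPP1", "rs9138", "TYK2", "proportion_anova", "NCL"),
    ],
    columns=["locus", "rsid", "gene", "method", "cell_type"],
).assign(direction="+")


@dataclass
class SharingSummary:
    """Venn-style counts of eQTL sharing between the two monocyte subsets."""

    n_records: int
    n_cl_exclusive: int
    n_ncl_exclusive: int
    n_shared: int
    n_discordant: int
    shared_pairs: list[tuple[str, str, str]]        # (rsid, gene, direction)
    discordant_pairs: list[tuple[str, str]]
    cl_pairs: set[tuple[str, str]]
    ncl_pairs: set[tuple[str, str]]
    per_snp: pd.DataFrame = field(repr=False)
    multi_snp_transcripts: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    method_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_distinct_pairs(self) -> int:
        return len(self.cl_pairs | self.ncl_pairs)

    def to_json_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "n_distinct_pairs": self.n_distinct_pairs,
            "n_cl_exclusive": self.n_cl_exclusive,
            "n_ncl_exclusive": self.n_ncl_exclusive,
            "n_shared": self.n_shared,
            "n_discordant": self.n_discordant,
            "shared_pairs": [list(t) for t in self.shared_pairs],
            "discordant_pairs": [list(t) for t in self.discordant_pairs],
            "per_snp": self.per_snp.to_dict(orient="records"),
            "multi_snp_transcripts": self.multi_snp_transcripts,
            "method_counts": self.method_counts,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)


def _canonical_directions(hits: pd.DataFrame) -> pd.DataFrame:
    """One direction per (rsid, gene, cell_type): the best-FDR method's sign.

    Hits found by several methods may disagree in sign; the sharing rule
    needs one canonical sign per pair and cell type, taken from the
    method with the smallest FDR q (smallest p as fallback, then first
    listed).
    """
    hits = hits.copy()
    sort_cols = [c for c in ("fdr_q", "p_value") if c in hits.columns]
    if sort_cols:
        hits = hits.sort_values(sort_cols, na_position="last", kind="stable")
    return hits.drop_duplicates(["rsid", "gene", "cell_type"], keep="first")


def sharing_analysis(hits: pd.DataFrame) -> SharingSummary:
    """Classify significant eQTL pairs as CL-exclusive, NCL-exclusive or shared.

    Parameters
    ----------
    hits
        Table of significant records with at least ``rsid``, ``gene``,
        ``cell_type`` and ``direction`` columns (e.g. the output of
        :func:`monoqtl.eqtl.significant_hits`, or a published hit list).
        A pair significant in both subsets with *opposite* directions is
        counted exclusive in each and flagged discordant.
    """
    required = {"rsid", "gene", "cell_type", "direction"}
    missing = required - set(hits.columns)
    if missing:
        raise ValueError(f"hit table lacks columns: {sorted(missing)}")
    canon = _canonical_directions(hits)
    pairs = {
        ct: set(map(tuple, canon.loc[canon["cell_type"] == ct, ["rsid", "gene"]].to_numpy()))
        for ct in ("CL", "NCL")
    }
    dirs = {
        (r.rsid, r.gene, r.cell_type): r.direction for r in canon.itertuples()
    }
    both = pairs["CL"] & pairs["NCL"]
    shared, discordant = [], []
    for rsid, gene in sorted(both):
        d_cl, d_ncl = dirs[(rsid, gene, "CL")], dirs[(rsid, gene, "NCL")]
        if d_cl == d_ncl and d_cl in ("+", "-"):
            shared.append((rsid, gene, d_cl))
        else:
            discordant.append((rsid, gene))
    shared_set = {(r, g) for r, g, _ in shared}
    n_cl_excl = len(pairs["CL"] - shared_set)
    n_ncl_excl = len(pairs["NCL"] - shared_set)

    per_snp_rows = []
    for rsid in sorted({r for r, _ in pairs["CL"] | pairs["NCL"]}):
        cl_g = {g for r, g in pairs["CL"] if r == rsid}
        ncl_g = {g for r, g in pairs["NCL"] if r == rsid}
        sh_g = {g for r, g in shared_set if r == rsid}
        per_snp_rows.append({
            "rsid": rsid,
            "n_cl_exclusive": len(cl_g - sh_g),
            "n_ncl_exclusive": len(ncl_g - sh_g),
            "n_shared": len(sh_g),
        })

    multi: dict[str, dict[str, list[str]]] = {}
    for ct in ("CL", "NCL"):
        by_gene: dict[str, list[str]] = {}
        for rsid, gene in sorted(pairs[ct]):
            by_gene.setdefault(gene, []).append(rsid)
        multi[ct] = {g: snps for g, snps in by_gene.items() if len(snps) > 1}

    method_counts = (
        hits["method"].value_counts().to_dict() if "method" in hits.columns else {}
    )
    return SharingSummary(
        n_records=len(hits),
        n_cl_exclusive=n_cl_excl,
        n_ncl_exclusive=n_ncl_excl,
        n_shared=len(shared),
        n_discordant=len(discordant),
        shared_pairs=shared,
        discordant_pairs=discordant,
        cl_pairs=pairs["CL"],
        ncl_pairs=pairs["NCL"],
        per_snp=pd.DataFrame(per_snp_rows),
        multi_snp_transcripts=multi,
        method_counts=method_counts,
    )


def sharing_test(n_shared: int, n_distinct_pairs: int, null_prop: float = 0.5) -> float:
    """Two-sided exact binomial test of the shared fraction against ``null_prop``."""
    if n_distinct_pairs <= 0:
        raise ValueError("need at least one distinct eQTL pair")
    if not 0 <= n_shared <= n_distinct_pairs:
        raise ValueError("n_shared must lie in [0, n_distinct_pairs]")
    return float(stats.binomtest(n_shared, n_distinct_pairs, null_prop).pvalue)


def celltype_imbalance_test(n_cl_hits: int, n_ncl_hits: int) -> float:
    """Two-sided exact binomial test of the NCL share of hits against 0.5."""
    total = n_cl_hits + n_ncl_hits
    if total <= 0:
        raise ValueError("no hits")
    return float(stats.binomtest(n_ncl_hits, total, 0.5).pvalue)
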