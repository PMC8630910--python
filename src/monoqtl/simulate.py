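"""Synthetic single-cell qPCR data with known ground truth.

The generator emulates the statistical structure the analysis assumes:
per-gene latent log-means with person-level heterogeneity (a shared
person factor across genes plus a gene-specific person intercept),
detection that depends on the latent mean (missing-not-at-random dropout,
as in qPCR, with an MCAR toggle for oracle checks), biallelic SNP
genotypes drawn at Hardy-Weinberg proportions, optional planted genotype
effects on either the mean or the detection channel, person-level on/off
switch genes, and latent-factor co-expression blocks.  Detected cells
receive ``CT = total_cycles - expression`` with expression drawn from a
truncated normal above the detection limit; non-detected cells receive a
CT at or above the LOD, so the zero pattern of the transformed data is
exact by construction.

Defaults mirror the study design the pipeline targets: 15 individuals,
two monocyte subsets with ~30 cells each, 90 genes, 7 SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from monoqtl.datamodel import CTMatrix, GenotypeTable


@dataclass(frozen=True)
class PlantedEffect:
    """A genotype effect planted in the generator.

    ``channel`` is ``mean`` (additive shift of the latent log-mean per
    minor allele) or ``detection`` (additive shift of the detection
    log-odds per minor allele).  ``cell_type`` restricts the plant to one
    subset; None plants it in both.
    """

    gene: str
    snp: str
    channel: str
    size: float
    cell_type: str | None = None


@dataclass(frozen=True)
class CoexpressionBlock:
    """Genes sharing a per-cell latent factor.

    ``loading`` is the factor amplitude in cycles on the expression
    scale: each block gene's detected expression gains
    ``loading * f_cell`` with ``f ~ N(0, 1)`` per cell, so the within-
    block correlation of detected expression is approximately
    ``loading^2 / (loading^2 + within_cell_sd^2)`` away from the
    detection-window rails (e.g. amplitude 4.0 at within-cell sd 2.0
    plants r ~ 0.8)."""

    genes: tuple[str, ...]
    loading: float


@dataclass
class SimConfig:
    n_individuals: int = 15
    cells_per_individual: int = 30          # per cell type
    n_genes: int = 90
    cell_types: tuple[str, ...] = ("CL", "NCL")
    snp_mafs: tuple[float, ...] = (0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40)
    total_cycles: float = 40.0
    lod: float = 28.0
    baseline_log_mean: tuple[float, float] = (2.6, 3.4)   # exp: ~13.5-30 cycles
    within_cell_sd: float = 2.0             # cycles, positive component
    person_intercept_sd: float = 1.0        # log-mean scale, per gene x person
    person_shared_sd: float = 0.5           # log-mean scale, shared across genes
    detection_intercept: float = -1.6
    detection_slope: float = 1.0
    mcar_detection_prob: float | None = None
    planted_effects: tuple[PlantedEffect, ...] = ()
    on_off_genes: Mapping[str, float] = field(default_factory=dict)
    coexpression_blocks: tuple[CoexpressionBlock, ...] = ()

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:03d}" for i in range(self.n_genes)]

    @property
    def rsids(self) -> list[str]:
        return [f"rs{i + 1:04d}" for i in range(len(self.snp_mafs))]

    @property
    def individual_ids(self) -> list[str]:
        return [f"I{i + 1:02d}" for i in range(self.n_individuals)]

    def validate(self) -> None:
        genes, snps = set(self.gene_ids), set(self.rsids)
        if not self.total_cycles > self.lod > 0:
            raise ValueError("need total_cycles > lod > 0")
        for maf in self.snp_mafs:
            if not 0.0 < maf < 0.5:
                raise ValueError(f"MAF must be in (0, 0.5), got {maf}")
        for pe in self.planted_effects:
            if pe.gene not in genes:
                raise ValueError(f"planted effect on unknown gene {pe.gene}")
            if pe.snp not in snps:
                raise ValueError(f"planted effect on unknown SNP {pe.snp}")
            if pe.channel not in ("mean", "detection"):
                raise ValueError(f"unknown channel {pe.channel!r}")
            if pe.cell_type is not None and pe.cell_type not in self.cell_types:
                raise ValueError(f"unknown cell type {pe.cell_type!r}")
        for g, prob in self.on_off_genes.items():
            if g not in genes:
                raise ValueError(f"on/off entry for unknown gene {g}")
            if not 0.0 <= prob <= 1.0:
                raise ValueError("off probability must be in [0, 1]")
        for blk in self.coexpression_blocks:
            unknown = set(blk.genes) - genes
            if unknown:
                raise ValueError(f"block contains unknown genes {sorted(unknown)}")
        if self.mcar_detection_prob is not None and not 0 < self.mcar_detection_prob <= 1:
            raise ValueError("mcar_detection_prob must be in (0, 1]")


@dataclass
class SimTruth:
    """Ground truth serialized alongside every generated dataset."""

    seed: int
    config: SimConfig
    genotypes: GenotypeTable
    person_shared: pd.Series                 # shared person factor
    person_intercepts: pd.DataFrame          # individuals x genes
    gene_baselines: pd.Series
    off_states: pd.DataFrame                 # individuals x on/off genes (bool)
    planted_effects: tuple[PlantedEffect, ...]

    def to_json_dict(self) -> dict:
        cfg = asdict(self.config)
        cfg["on_off_genes"] = dict(self.config.on_off_genes)
        return {
            "seed": self.seed,
            "config": cfg,
            "planted_effects": [asdict(p) for p in self.planted_effects],
            "block_genes": [list(b.genes) for b in self.config.coexpression_blocks],
            "off_states": self.off_states.astype(bool).to_dict()
            if not self.off_states.empty else {},
        }


def simulate_genotypes(maf: float, n_individuals: int, rng: np.random.Generator) -> np.ndarray:
    """Minor-allele dosages drawn at Hardy-Weinberg proportions."""
    if not 0.0 < maf < 0.5:
        raise ValueError(f"MAF must be in (0, 0.5), got {maf}")
    probs = [(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2]
    return rng.choice([0, 1, 2], size=n_individuals, p=probs)


def _truncnorm(rng, mean, sd, lo, hi):
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)


def simulate_expression(config: SimConfig, seed: int) -> tuple[CTMatrix, SimTruth]:
    """Generate a CT matrix and its ground truth from ``config``.

    The same (config, seed) pair always yields an identical dataset.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    genes = config.gene_ids
    inds = config.individual_ids
    n_g, n_i = len(genes), len(inds)

    dosages = pd.DataFrame(
        {rs: simulate_genotypes(maf, n_i, rng)
         for rs, maf in zip(config.rsids, config.snp_mafs)},
        index=pd.Index(inds, name="individual_id"),
    )
    genotypes = GenotypeTable(dosages)

    baselines = pd.Series(
        rng.uniform(*config.baseline_log_mean, size=n_g), index=genes
    )
    u_shared = pd.Series(rng.normal(0.0, config.person_shared_sd, size=n_i), index=inds)
    b_pg = pd.DataFrame(
        rng.normal(0.0, config.person_intercept_sd, size=(n_i, n_g)),
        index=inds, columns=genes,
    )
    onoff_genes = list(config.on_off_genes)
    off_states = pd.DataFrame(False, index=inds, columns=onoff_genes)
    for g in onoff_genes:
        off_states[g] = rng.random(n_i) < config.on_off_genes[g]

    gene_pos = {g: j for j, g in enumerate(genes)}
    lod_gap = config.total_cycles - config.lod

    rows, meta_rows, index = [], [], []
    for ct in config.cell_types:
        for i, ind in enumerate(inds):
            nc = config.cells_per_individual
            eta = np.tile(baselines.to_numpy() + u_shared[ind] + b_pg.loc[ind].to_numpy(),
                          (nc, 1))
            det_shift = np.zeros((nc, n_g))
            for pe in config.planted_effects:
                if pe.cell_type is not None and pe.cell_type != ct:
                    continue
                dose = dosages.loc[ind, pe.snp]
                j = gene_pos[pe.gene]
                if pe.channel == "mean":
                    eta[:, j] += pe.size * dose
                else:
                    det_shift[:, j] += pe.size * dose
            block_shift = np.zeros((nc, n_g))
            for blk in config.coexpression_blocks:
                f = rng.normal(0.0, 1.0, size=nc)
                for g in blk.genes:
                    block_shift[:, gene_pos[g]] += blk.loading * f

            if config.mcar_detection_prob is not None:
                # MCAR toggle: detection ignores the latent mean; planted
                # detection effects still apply on the logit scale.
                pm = min(config.mcar_detection_prob, 1 - 1e-12)
                logit = np.log(pm / (1 - pm)) + det_shift
                p_det = 1.0 / (1.0 + np.exp(-logit))
            else:
                logit = config.detection_intercept + config.detection_slope * eta + det_shift
                p_det = 1.0 / (1.0 + np.exp(-logit))
            detected = rng.random((nc, n_g)) < p_det
            for g in onoff_genes:
                if off_states.loc[ind, g]:
                    detected[:, gene_pos[g]] = False

            mean_pos = np.clip(np.exp(eta), 1.0,
                               config.total_cycles + 3 * config.within_cell_sd)
            mean_pos = mean_pos + block_shift
            expr = _truncnorm(
                rng, mean_pos, config.within_cell_sd,
                lod_gap + 1e-6, config.total_cycles,
            )
            ct_detected = config.total_cycles - expr
            ct_missing = rng.uniform(config.lod, config.total_cycles, size=(nc, n_g))
            ct_vals = np.where(detected, ct_detected, ct_missing)

            for k in range(nc):
                cid = f"{ind}_{ct}_{k + 1:03d}"
                index.append(cid)
                rows.append(ct_vals[k])
                meta_rows.append(
                    {"individual_id": ind, "cell_type": ct, "capture_flag": "singlet"}
                )

    values = pd.DataFrame(rows, index=pd.Index(index, name="cell_id"), columns=genes)
    meta = pd.DataFrame(meta_rows, index=values.index)
    truth = SimTruth(
        seed=seed, config=config, genotypes=genotypes,
        person_shared=u_shared, person_intercepts=b_pg,
        gene_baselines=baselines, off_states=off_states,
        planted_effects=config.planted_effects,
    )
    return CTMatrix(values, meta), truth


# ---------------------------------------------------------------------------
# canned fixtures


def make_null_fixture(
    seed: int,
    n_individuals: int = 15,
    cells_per_individual: int = 30,
    n_genes: int = 12,
    snp_mafs: Sequence[float] = (0.2, 0.3, 0.4),
    cell_types: tuple[str, ...] = ("CL",),
    person_intercept_sd: float = 1.0,
) -> tuple[CTMatrix, SimTruth]:
    """A dataset with no planted effects (complete null) and strong
    within-person correlation.  Gene and SNP counts are reduced from the
    90 x 7 study panel so that repeated null scans stay cheap; the
    per-individual design (15 donors, 30 cells) matches the study."""
    config = SimConfig(
        n_individuals=n_individuals,
        cells_per_individual=cells_per_individual,
        n_genes=n_genes,
        snp_mafs=tuple(snp_mafs),
        cell_types=cell_types,
        person_intercept_sd=person_intercept_sd,
    )
    return simulate_expression(config, seed)


#: Plants used by :func:`make_powered_fixture`; sizes are on the model
#: scales the fitters estimate (log-odds and log-mean per minor allele)
#: and are chosen as genuine positive controls at the study scale
#: (15 donors, person-level heterogeneity sd 1.0).
POWERED_PLANTS = (
    PlantedEffect(gene="G001", snp="rs0001", channel="detection", size=1.5,
                  cell_type="NCL"),
    PlantedEffect(gene="G002", snp="rs0002", channel="mean", size=1.2,
                  cell_type="NCL"),
)


def make_block_fixture(
    seed: int,
    n_genes: int = 30,
    block_size: int = 10,
    amplitude: float = 4.0,
) -> tuple[CTMatrix, SimTruth]:
    """30 genes with a planted 10-gene co-expression block plus person effects.

    The block factor amplitude (4.0 cycles at within-cell sd 2.0) plants a
    within-block correlation of 0.8 away from the detection-window rails;
    censoring at the window edges attenuates the realized average
    correlation to ~0.6-0.7, which still leaves the block genes far above
    any background loading.  Person effects (gene-specific sd 0.3, shared
    sd 0.5 on the log-mean scale) are strong enough that a pooled-cell
    correlation PCA is dominated by donor identity, the contrast the
    averaged-correlation PCA is designed to remove.
    """
    block = CoexpressionBlock(tuple(f"G{i + 1:03d}" for i in range(block_size)),
                              amplitude)
    config = SimConfig(
        n_individuals=15,
        cells_per_individual=30,
        n_genes=n_genes,
        snp_mafs=(0.3,),
        cell_types=("CL",),
        baseline_log_mean=(3.0, 3.2),
        person_intercept_sd=0.3,
        person_shared_sd=0.5,
        detection_intercept=8.0,
        coexpression_blocks=(block,),
    )
    return simulate_expression(config, seed)


def make_powered_fixture(
    seed: int,
    n_individuals: int = 15,
    cells_per_individual: int = 30,
    n_genes: int = 10,
    snp_mafs: Sequence[float] = (0.4, 0.3),
    cell_types: tuple[str, ...] = ("CL", "NCL"),
) -> tuple[CTMatrix, SimTruth]:
    """A dataset with two documented planted eQTLs (see POWERED_PLANTS):
    a detection-channel (on/off) effect and a mean-channel effect, both
    in non-classical cells only.

    Detection is centered near 50% (``detection_intercept = -3.0``) so
    the planted log-odds acts on the informative part of the logistic
    curve rather than at saturation; everything else is at study scale.
    """
    config = SimConfig(
        n_individuals=n_individuals,
        cells_per_individual=cells_per_individual,
        n_genes=n_genes,
        snp_mafs=tuple(snp_mafs),
        cell_types=cell_types,
        detection_intercept=-3.0,
        planted_effects=POWERED_PLANTS,
    )
    return simulate_expression(config, seed)
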