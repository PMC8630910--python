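"""Domain types, file I/O, and validation for the pipeline.

Single-cell qPCR data arrive as a cells x genes matrix of threshold-cycle
(CT) values plus per-cell metadata (donor, monocyte subset, capture flag).
Genotypes arrive as a small individuals x SNPs table of minor-allele
dosages.  Both are plain CSV/TSV; Fluidigm export dialects vary, so the
reader accepts metadata either in leading columns or in a sidecar file and
a configurable list of missing-CT sentinels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CELL_TYPES = ("CL", "NCL")
CAPTURE_FLAGS = ("singlet", "doublet", "empty")
META_COLUMNS = ("individual_id", "cell_type", "capture_flag")

#: Tokens treated as a missing CT on input.  Fluidigm software emits "999"
#: for failed reactions; spreadsheet round-trips produce "" and "NA".
DEFAULT_MISSING_TOKENS = ("", "NA", "NaN", "nan", "999")


class FormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(ValueError):
    """Parsed data violate a domain invariant."""


def _check_meta(cell_meta: pd.DataFrame) -> None:
    for col in META_COLUMNS:
        if col not in cell_meta.columns:
            raise FormatError(f"cell metadata lacks required column {col!r}")
    bad_ct = set(cell_meta["cell_type"]) - set(CELL_TYPES)
    if bad_ct:
        raise ValidationError(f"unknown cell_type values: {sorted(bad_ct)}")
    bad_cf = set(cell_meta["capture_flag"]) - set(CAPTURE_FLAGS)
    if bad_cf:
        raise ValidationError(f"unknown capture_flag values: {sorted(bad_cf)}")


@dataclass
class CTMatrix:
    """Raw per-cell, per-gene qPCR threshold-cycle values.

    Parameters
    ----------
    values
        cells x genes DataFrame of CT values (cycles); NaN marks a
        reaction with no detected amplification.
    cell_meta
        One row per cell, indexed like ``values``; must carry
        ``individual_id``, ``cell_type`` (CL or NCL) and ``capture_flag``
        (singlet / doublet / empty).
    """

    values: pd.DataFrame
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if len(self.values) != len(self.cell_meta):
            raise ValidationError(
                f"{len(self.values)} value rows vs {len(self.cell_meta)} metadata rows"
            )
        if not self.values.index.equals(self.cell_meta.index):
            raise ValidationError("values and cell_meta must share the cell index")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate gene names: {dups}")
        _check_meta(self.cell_meta)
        with np.errstate(invalid="ignore"):
            if (self.values.to_numpy() < 0).any():
                raise ValidationError("CT values must be missing or >= 0")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_cells(self) -> int:
        return len(self.values)

    def subset_cells(self, mask) -> "CTMatrix":
        return CTMatrix(self.values.loc[mask], self.cell_meta.loc[mask])


@dataclass
class ExpressionMatrix:
    """Expression values: cycles of amplification above the detection limit.

    A value of 0 encodes non-detection (source CT missing or >= ``lod``);
    any nonzero value equals ``total_cycles - CT``.
    """

    values: pd.DataFrame
    cell_meta: pd.DataFrame
    lod: float
    total_cycles: float

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if len(self.values) != len(self.cell_meta):
            raise ValidationError("values/cell_meta row mismatch")
        _check_meta(self.cell_meta)
        v = self.values.to_numpy()
        if np.isnan(v).any() or (v < 0).any():
            raise ValidationError("expression values must be finite and >= 0")
        nz = v[v > 0]
        if nz.size and (nz <= self.total_cycles - self.lod - 1e-9).any():
            raise ValidationError(
                "nonzero expression below total_cycles - lod is inconsistent "
                "with the detection rule"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def individuals(self) -> list[str]:
        return sorted(self.cell_meta["individual_id"].unique())

    def subset_cells(self, mask) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[mask], self.cell_meta.loc[mask], self.lod, self.total_cycles
        )

    def for_cell_type(self, cell_type: str) -> "ExpressionMatrix":
        mask = self.cell_meta["cell_type"] == cell_type
        return self.subset_cells(mask)


@dataclass
class GenotypeTable:
    """Per-individual minor-allele dosages for a panel of biallelic SNPs.

    ``dosages`` is individuals x SNPs with entries in {0, 1, 2}; allele
    labels live in ``snp_meta`` and are metadata only — every model
    downstream consumes the dosage.
    """

    dosages: pd.DataFrame
    snp_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        d = self.dosages.to_numpy()
        if d.size == 0:
            raise ValidationError("empty genotype table")
        if not np.isin(d, [0, 1, 2]).all():
            raise ValidationError("dosages must be integers in {0, 1, 2}")
        self.dosages = self.dosages.astype(int)
        if self.dosages.index.duplicated().any():
            dups = self.dosages.index[self.dosages.index.duplicated()].tolist()
            raise ValidationError(f"duplicated individuals: {dups}")
        if self.dosages.columns.duplicated().any():
            raise ValidationError("duplicated rsids")
        if self.snp_meta is None:
            self.snp_meta = pd.DataFrame(
                {"rsid": list(self.dosages.columns)}
            ).set_index("rsid")

    @property
    def rsids(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def individuals(self) -> list[str]:
        return list(self.dosages.index)

    def genotype_counts(self, rsid: str) -> tuple[int, int, int]:
        """(n_hom_major, n_het, n_hom_minor) for one SNP."""
        d = self.dosages[rsid]
        return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())


# ---------------------------------------------------------------------------
# readers / writers


def _read_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix in {".tsv", ".tab"} else ","
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    return df


def read_ct_matrix(
    path: str | Path,
    meta_path: str | Path | None = None,
    missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS,
    sep: str | None = None,
) -> CTMatrix:
    """Read a CT matrix CSV/TSV.

    The file must have a ``cell_id`` column; cell metadata
    (individual_id, cell_type, capture_flag) either follows in leading
    columns or is supplied as a sidecar table via ``meta_path``.
    Unparseable or sentinel CT entries become missing.
    """
    df = _read_table(path, sep)
    if "cell_id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'cell_id'")
    df = df.set_index("cell_id")
    if meta_path is None:
        for col in META_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"{path}: missing required column {col!r}")
        meta = df[list(META_COLUMNS)].copy()
        value_cols = [c for c in df.columns if c not in META_COLUMNS]
    else:
        meta = _read_table(meta_path, sep)
        if "cell_id" not in meta.columns:
            raise FormatError(f"{meta_path}: missing required column 'cell_id'")
        meta = meta.set_index("cell_id")
        for col in META_COLUMNS:
            if col not in meta.columns:
                raise FormatError(f"{meta_path}: missing required column {col!r}")
        meta = meta.loc[df.index, list(META_COLUMNS)]
        value_cols = list(df.columns)
    raw = df[value_cols].replace(dict.fromkeys(missing_tokens, np.nan))
    values = raw.apply(pd.to_numeric, errors="coerce")
    return CTMatrix(values, meta)


def write_ct_matrix(ct: CTMatrix, path: str | Path, missing_token: str = "NA") -> None:
    """Write a CT matrix with metadata in leading columns (round-trippable)."""
    out = pd.concat([ct.cell_meta[list(META_COLUMNS)], ct.values], axis=1)
    out.index.name = "cell_id"
    out.to_csv(path, na_rep=missing_token)


def read_genotypes(path: str | Path, sep: str | None = None) -> GenotypeTable:
    """Read an individuals x SNPs dosage table (one row per individual)."""
    df = _read_table(path, sep)
    if "individual_id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'individual_id'")
    df = df.set_index("individual_id")
    if df.empty:
        raise ValidationError(f"{path}: no individuals")
    try:
        dosages = df.apply(pd.to_numeric).astype(float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric dosage entry") from exc
    if not np.isin(dosages.to_numpy(), [0.0, 1.0, 2.0]).all():
        raise ValidationError(f"{path}: dosages must be in {{0,1,2}}")
    return GenotypeTable(dosages.astype(int))


def write_genotypes(gt: GenotypeTable, path: str | Path) -> None:
    out = gt.dosages.copy()
    out.index.name = "individual_id"
    out.to_csv(path, sep="\t")


#: Fixed column order of the flat eQTL result table.
EQTL_RESULT_COLUMNS = [
    "rsid",
    "gene",
    "cell_type",
    "method",
    "effect",
    "se",
    "p_value",
    "fdr_q",
    "direction",
    "significant",
    "n_individuals",
    "n_cells",
    "converged",
    "skip_reason",
]


def check_individuals_covered(expr: ExpressionMatrix, gt: GenotypeTable) -> None:
    """Every individual with cells must be genotyped."""
    missing = set(expr.cell_meta["individual_id"]) - set(gt.individuals)
    if missing:
        raise ValidationError(f"individuals without genotypes: {sorted(missing)}")


# ---------------------------------------------------------------------------
# Hardy-Weinberg


def hwe_test(dosage_counts: Iterable[int]) -> tuple[float, float]:
    """Chi-square goodness-of-fit test against Hardy-Weinberg proportions.

    Parameters
    ----------
    dosage_counts
        ``(n_hom_major, n_het, n_hom_minor)`` observed genotype counts.

    Returns
    -------
    (chi_square, p_value)
        1-df chi-square statistic comparing observed counts with the HWE
        expectation at the sample allele frequency, and its upper-tail
        p-value.  A monomorphic SNP returns ``(0.0, 1.0)`` with a warning.
    """
    n_aa, n_ab, n_bb = (int(c) for c in dosage_counts)
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("no genotyped individuals")
    q = (n_ab + 2 * n_bb) / (2 * n)  # minor-allele frequency in the sample
    if q in (0.0, 1.0):
        warnings.warn("monomorphic SNP: HWE test degenerate", stacklevel=2)
        return 0.0, 1.0
    expected = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2]) * n
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p
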