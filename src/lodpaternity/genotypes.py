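"""Genotype matrix I/O, validation, and population allele frequencies.

Genotypes are biallelic and coded as the count of alternate alleles:
0 = homozygous reference, 1 = heterozygous, 2 = homozygous alternate.
Missing genotypes are written and read as ``NA`` (any case) or an empty
cell.  The on-disk layout is one row per individual with an ``id`` first
column, an optional ``sex`` second column, and one column per locus; a
transposed dialect (loci as rows) is supported on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_TOKENS = frozenset({"", "na"})
VALID_CODES = frozenset({"0", "1", "2"})

_SEX_ALIASES = {
    "m": "male",
    "male": "male",
    "f": "female",
    "female": "female",
    "u": "unknown",
    "unknown": "unknown",
    "": "unknown",
    "na": "unknown",
}


class GenotypeFileError(ValueError):
    """Raised when a genotype file is malformed."""


@dataclass
class GenotypeMatrix:
    """Individuals x loci table of biallelic genotype codes.

    Parameters
    ----------
    genotypes
        DataFrame with nullable integer dtype; index = individual IDs,
        columns = locus IDs, values in {0, 1, 2} or missing (``pd.NA``).
    sex
        Optional per-individual labels in {"male", "female", "unknown"},
        aligned to ``genotypes.index``.
    """

    genotypes: pd.DataFrame
    sex: pd.Series | None = None

    def __post_init__(self) -> None:
        gt = self.genotypes
        if gt.index.has_duplicates:
            dup = gt.index[gt.index.duplicated()][0]
            raise GenotypeFileError(f"duplicate individual ID: {dup!r}")
        if gt.columns.has_duplicates:
            dup = gt.columns[gt.columns.duplicated()][0]
            raise GenotypeFileError(f"duplicate locus ID: {dup!r}")
        vals = gt.to_numpy(dtype="float64", na_value=np.nan)
        bad = ~(np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0)))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeFileError(
                f"invalid genotype code {vals[i, j]!r} for individual "
                f"{gt.index[i]!r} at locus {gt.columns[j]!r}"
            )
        self.genotypes = gt.astype("Int8")
        if self.sex is not None:
            self.sex = self.sex.reindex(gt.index)
            bad_sex = ~self.sex.isin(["male", "female", "unknown"])
            if bad_sex.any():
                who = self.sex.index[bad_sex][0]
                raise GenotypeFileError(
                    f"invalid sex label {self.sex[who]!r} for individual {who!r}"
                )

    @property
    def individual_ids(self) -> list[str]:
        return list(self.genotypes.index)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.genotypes.columns)

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def genotype(self, individual_id: str, locus_id: str) -> int | None:
        """Return the code at one cell, or None if missing."""
        v = self.genotypes.at[individual_id, locus_id]
        return None if pd.isna(v) else int(v)

    def row(self, individual_id: str) -> np.ndarray:
        """One individual's genotypes as float64 with NaN for missing."""
        if individual_id not in self.genotypes.index:
            raise KeyError(f"unknown individual ID: {individual_id!r}")
        return self.genotypes.loc[individual_id].to_numpy(
            dtype="float64", na_value=np.nan
        )

    def males(self) -> list[str]:
        if self.sex is None:
            return []
        return list(self.sex.index[self.sex == "male"])


@dataclass
class AlleleFrequencyTable:
    """Per-locus reference-allele frequencies estimated from a matrix.

    ``p_ref`` is the reference-allele frequency (NaN when no alleles were
    observed); ``n_alleles`` counts the non-missing alleles (2 per typed
    genotype); ``monomorphic`` flags loci with p_ref in {0, 1} or no data,
    which carry no paternity information and are skipped downstream.
    """

    table: pd.DataFrame = field(repr=False)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.table.index)

    def p_ref(self, locus_id: str) -> float:
        return float(self.table.at[locus_id, "p_ref"])

    def is_monomorphic(self, locus_id: str) -> bool:
        return bool(self.table.at[locus_id, "monomorphic"])

    @property
    def p_ref_array(self) -> np.ndarray:
        return self.table["p_ref"].to_numpy(dtype="float64")

    @property
    def monomorphic_array(self) -> np.ndarray:
        return self.table["monomorphic"].to_numpy(dtype=bool)


def _sniff_delimiter(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return ","
    if suffix in (".tsv", ".tab"):
        return "\t"
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def _parse_code(token: str, individual: str, locus: str) -> object:
    tok = token.strip()
    if tok.lower() in MISSING_TOKENS:
        return pd.NA
    if tok in VALID_CODES:
        return np.int8(tok)
    raise GenotypeFileError(
        f"invalid genotype code {token!r} for individual {individual!r} "
        f"at locus {locus!r} (expected 0, 1, 2, NA, or empty)"
    )


def read_genotype_matrix(path: str | Path, transpose: bool = False) -> GenotypeMatrix:
    """Read a delimited genotype matrix (CSV or TSV, auto-detected).

    The default layout is rows = individuals: a header row of locus names,
    an ``id`` first column, and an optional ``sex`` second column.  With
    ``transpose=True`` the file has loci as rows and individuals as columns
    (no sex column in that dialect).

    Raises
    ------
    GenotypeFileError
        On an empty file, a duplicate ID, or any cell that is not
        0/1/2/NA/empty (the error names the individual, locus, and token).
    """
    path = Path(path)
    if not path.exists():
        raise GenotypeFileError(f"genotype file not found: {path}")
    sep = _sniff_delimiter(path)
    try:
        raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                          index_col=0)
    except pd.errors.EmptyDataError:
        raise GenotypeFileError(f"empty genotype file: {path}") from None
    if raw.shape[0] == 0:
        raise GenotypeFileError(f"genotype file has no data rows: {path}")
    if transpose:
        raw = raw.T
    raw.index = raw.index.astype(str).str.strip()
    raw.columns = raw.columns.astype(str).str.strip()

    sex = None
    if "sex" in (c.lower() for c in raw.columns):
        sex_col = next(c for c in raw.columns if c.lower() == "sex")
        labels = raw[sex_col].str.strip().str.lower()
        unknown = ~labels.isin(_SEX_ALIASES)
        if unknown.any():
            who = labels.index[unknown][0]
            raise GenotypeFileError(
                f"invalid sex label {raw.at[who, sex_col]!r} for individual {who!r}"
            )
        sex = labels.map(_SEX_ALIASES)
        raw = raw.drop(columns=[sex_col])

    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise GenotypeFileError(f"duplicate individual ID: {dup!r}")
    if raw.columns.has_duplicates:
        dup = raw.columns[raw.columns.duplicated()][0]
        raise GenotypeFileError(f"duplicate locus ID: {dup!r}")

    parsed = pd.DataFrame(
        {
            locus: [
                _parse_code(raw.at[ind, locus], ind, locus) for ind in raw.index
            ]
            for locus in raw.columns
        },
        index=raw.index,
        dtype="Int8",
    )
    return GenotypeMatrix(genotypes=parsed, sex=sex)


def write_genotype_matrix(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a matrix in the same dialect ``read_genotype_matrix`` reads.

    Round-trips exactly: codes as bare integers, missing cells as ``NA``.
    """
    path = Path(path)
    sep = _sniff_delimiter_for_write(path)
    out = matrix.genotypes.astype("string").fillna("NA")
    if matrix.sex is not None:
        out.insert(0, "sex", matrix.sex)
    out.index.name = "id"
    out.to_csv(path, sep=sep)


def _sniff_delimiter_for_write(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def compute_allele_frequencies(matrix: GenotypeMatrix) -> AlleleFrequencyTable:
    """Estimate per-locus reference-allele frequencies by allele counting.

    Every individual in the matrix contributes (offspring and candidates
    included): p_ref = (2*n0 + n1) / (2*(n0 + n1 + n2)) over non-missing
    genotypes.  Loci where only one allele was observed, or where no
    genotype was observed at all, are flagged monomorphic; an all-missing
    locus gets p_ref = NaN.
    """
    vals = matrix.genotypes.to_numpy(dtype="float64", na_value=np.nan)
    typed = ~np.isnan(vals)
    n_typed = typed.sum(axis=0)
    n_alleles = 2 * n_typed
    with np.errstate(invalid="ignore"):
        alt_count = np.nansum(vals, axis=0)
        p_ref = np.where(n_alleles > 0, (n_alleles - alt_count) / n_alleles, np.nan)
    monomorphic = (n_alleles == 0) | (p_ref == 0.0) | (p_ref == 1.0)
    table = pd.DataFrame(
        {
            "p_ref": p_ref,
            "n_alleles": n_alleles.astype(int),
            "monomorphic": monomorphic,
        },
        index=pd.Index(matrix.locus_ids, name="locus"),
    )
    n_mono = int(monomorphic.sum())
    if n_mono:
        logger.info("%d of %d loci are monomorphic and will be skipped",
                    n_mono, matrix.n_loci)
    return AlleleFrequencyTable(table=table)
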