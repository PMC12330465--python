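"""Readers and writers for the external tables the pipeline consumes.

All on-disk formats are plain tab-separated UTF-8 text with ``.`` decimals.
The precursor matrix dialect defaults to the wide-matrix convention of DIA-NN
(``Precursor.Id``, ``Stripped.Sequence``, ... one intensity column per run),
but every column name can be remapped so other search engines' output can be
ingested without editing files.

Intensity cells that are empty, ``NA``, ``NaN`` or exactly ``0`` are treated
as *missing*: a zero ion intensity is not observable in label-free DIA data,
and keeping zeros would distort the fraction-of-total normalisation
downstream.
"""

from __future__ import annotations

import fnmatch
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .constants import AMINO_ACIDS, DEFAULT_HISTONE_PATTERNS

__all__ = [
    "DEFAULT_DIALECT",
    "PrecursorTable",
    "SampleSheet",
    "ProteinRecord",
    "AffinityTable",
    "read_sample_sheet",
    "read_precursor_matrix",
    "read_fasta_proteins",
    "read_affinity_table",
    "read_cluster_labels",
    "write_matrix_tsv",
    "read_matrix_tsv",
]

#: Logical column name -> DIA-NN wide-matrix header.
DEFAULT_DIALECT: dict[str, str] = {
    "precursor_id": "Precursor.Id",
    "stripped_sequence": "Stripped.Sequence",
    "modified_sequence": "Modified.Sequence",
    "charge": "Precursor.Charge",
    "protein_group": "Protein.Group",
    "gene": "Genes",
    "pg_q_value": "Global.PG.Q.Value",
}

_SEQ_RE = re.compile(rf"^[{AMINO_ACIDS}]+$")

_MISSING_TOKENS = {"", "na", "nan", "null", "none"}


class FormatError(ValueError):
    """Raised when an input table violates its contract."""


@dataclass
class SampleSheet:
    """Sample annotation: identifier, condition and replicate number."""

    table: pd.DataFrame  # columns: sample_id, condition, replicate

    def __post_init__(self) -> None:
        required = {"sample_id", "condition", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            dups = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise FormatError(f"duplicate sample ids: {sorted(set(dups))}")
        if (self.table["replicate"].astype(int) < 1).any():
            raise FormatError("replicate numbers must be positive integers")

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.table["condition"]))

    def samples_for(self, condition: str) -> list[str]:
        mask = self.table["condition"] == condition
        return list(self.table.loc[mask, "sample_id"])


@dataclass
class PrecursorTable:
    """Precursor-level intensities plus identity metadata.

    ``data`` holds one row per precursor with the metadata columns
    ``precursor_id, stripped_sequence, modified_sequence, charge,
    protein_group, gene, pg_q_value`` followed by one float column per sample
    (NaN encodes missing).
    """

    data: pd.DataFrame
    samples: list[str]

    META_COLUMNS = (
        "precursor_id",
        "stripped_sequence",
        "modified_sequence",
        "charge",
        "protein_group",
        "gene",
        "pg_q_value",
    )

    def __post_init__(self) -> None:
        for col in self.META_COLUMNS:
            if col not in self.data.columns:
                raise FormatError(f"precursor table missing column {col!r}")
        for s in self.samples:
            if s not in self.data.columns:
                raise FormatError(f"declared sample {s!r} absent from table")
        if self.data["precursor_id"].duplicated().any():
            dups = self.data.loc[self.data["precursor_id"].duplicated(), "precursor_id"]
            raise FormatError(f"duplicate precursor ids: {sorted(set(dups))[:5]}")
        bad = ~self.data["stripped_sequence"].map(lambda s: bool(_SEQ_RE.match(str(s))))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"malformed stripped sequence at row {row}: "
                f"{self.data['stripped_sequence'].iloc[row]!r}"
            )
        vals = self.data[self.samples]
        if (vals.to_numpy(dtype=float) == 0).any():
            raise FormatError("zero intensities must be encoded as missing (NaN)")

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def intensities(self) -> pd.DataFrame:
        """Sample intensity block (float, NaN = missing)."""
        return self.data[self.samples].astype(float)


@dataclass(frozen=True)
class ProteinRecord:
    """One database protein with its histone flag."""

    accession: str
    gene: str
    sequence: str
    is_histone: bool

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"protein {self.accession}: empty sequence")


@dataclass
class AffinityTable:
    """Predicted peptide-allele binding affinities in nM (lower = stronger)."""

    table: pd.DataFrame  # columns: peptide, allele, affinity_nM

    def __post_init__(self) -> None:
        required = {"peptide", "allele", "affinity_nM"}
        if not required <= set(self.table.columns):
            raise FormatError(f"affinity table needs columns {sorted(required)}")
        if (self.table["affinity_nM"] <= 0).any():
            raise FormatError("affinities must be positive (nM)")

    def min_affinity(self, alleles: Sequence[str]) -> pd.Series:
        """Per-peptide minimum affinity over the given alleles."""
        if len(alleles) == 0:
            raise ValueError("allele list must be non-empty")
        sub = self.table[self.table["allele"].isin(alleles)]
        return sub.groupby("peptide")["affinity_nM"].min()


def _coerce_intensity(raw: pd.Series) -> pd.Series:
    """Parse an intensity column; empty/NA/0 become NaN, negatives error."""
    as_str = raw.astype(str).str.strip().str.lower()
    missing = as_str.isin(_MISSING_TOKENS)
    out = pd.to_numeric(raw.where(~missing), errors="coerce")
    out = out.mask(out == 0)
    neg = out < 0
    if neg.any():
        row = int(np.flatnonzero(neg.to_numpy())[0])
        raise FormatError(f"negative intensity at row {row}")
    return out.astype(float)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    return SampleSheet(df)


def read_precursor_matrix(
    path: str | Path,
    sample_sheet: SampleSheet,
    dialect: Mapping[str, str] | None = None,
) -> PrecursorTable:
    """Read a wide search-engine precursor (or protein-group) matrix.

    Parameters
    ----------
    path
        Tab-separated file whose header contains the dialect's metadata
        columns and one intensity column per sample in ``sample_sheet``.
    sample_sheet
        Declares which header columns are samples; every declared sample must
        be present.
    dialect
        Logical-name -> header-name mapping; defaults to the DIA-NN wide
        matrix convention.
    """
    dialect = dict(DEFAULT_DIALECT, **(dialect or {}))
    df = pd.read_csv(path, sep="\t", dtype=str)
    rename = {v: k for k, v in dialect.items() if v in df.columns}
    df = df.rename(columns=rename)

    missing_meta = [k for k in PrecursorTable.META_COLUMNS if k not in df.columns]
    # pg_q_value is optional on disk; synthesise an absent column.
    if "pg_q_value" in missing_meta:
        df["pg_q_value"] = np.nan
        missing_meta.remove("pg_q_value")
    if missing_meta:
        raise FormatError(
            f"header lacks metadata columns (dialect {sorted(missing_meta)}): "
            f"expected {[dialect[m] for m in missing_meta]}"
        )

    unmatched = [s for s in sample_sheet.samples if s not in df.columns]
    if unmatched:
        raise FormatError(f"sample columns absent from header: {unmatched}")

    out = df[list(PrecursorTable.META_COLUMNS)].copy()
    out["charge"] = out["charge"].astype(int)
    out["pg_q_value"] = pd.to_numeric(out["pg_q_value"], errors="coerce")
    for s in sample_sheet.samples:
        out[s] = _coerce_intensity(df[s])
    return PrecursorTable(out, list(sample_sheet.samples))


def _parse_uniprot_header(description: str, index: int) -> tuple[str, str]:
    """Extract (accession, gene) from a UniProt-style FASTA description."""
    name = description.split()[0]
    parts = name.split("|")
    if len(parts) >= 3:
        accession = parts[1]
    elif len(parts) == 1 and name:
        accession = name
    else:
        raise FormatError(f"unparseable FASTA header at record {index}: {description!r}")
    m = re.search(r"\bGN=(\S+)", description)
    gene = m.group(1) if m else ""
    return accession, gene


def default_histone_rule(
    gene: str, patterns: Iterable[str] = DEFAULT_HISTONE_PATTERNS
) -> bool:
    """True when the gene symbol matches a configured histone glob pattern."""
    g = gene.upper()
    return any(fnmatch.fnmatchcase(g, p.upper()) for p in patterns)


def read_fasta_proteins(path: str | Path, histone_rule=default_histone_rule) -> list[ProteinRecord]:
    """Read a protein FASTA with UniProt-style headers.

    Duplicate accessions are collapsed (first wins) with a warning; the
    histone flag is assigned by ``histone_rule(gene)``.
    """
    records: dict[str, ProteinRecord] = {}
    n = 0
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        n += 1
        accession, gene = _parse_uniprot_header(rec.description, i)
        if accession in records:
            warnings.warn(f"duplicate accession {accession}; keeping first occurrence")
            continue
        records[accession] = ProteinRecord(
            accession=accession,
            gene=gene,
            sequence=str(rec.seq).upper(),
            is_histone=bool(histone_rule(gene)),
        )
    if n == 0:
        raise FormatError(f"no FASTA records in {path}")
    return list(records.values())


def read_affinity_table(path: str | Path) -> AffinityTable:
    """Read peptide-allele affinity predictions; duplicates keep the lowest nM."""
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "allele": str})
    if "affinity_nM" not in df.columns:
        raise FormatError("affinity table needs an affinity_nM column")
    df["affinity_nM"] = pd.to_numeric(df["affinity_nM"])
    df = (
        df.sort_values("affinity_nM", kind="stable")
        .drop_duplicates(subset=["peptide", "allele"], keep="first")
        .reset_index(drop=True)
    )
    return AffinityTable(df)


def read_cluster_labels(path: str | Path) -> pd.Series:
    """Read an external peptide -> cluster label table (e.g. GibbsCluster)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"peptide", "cluster"} <= set(df.columns):
        raise FormatError("cluster table needs columns peptide, cluster")
    return df.set_index("peptide")["cluster"]


def write_matrix_tsv(df: pd.DataFrame, path: str | Path, index_label: str = "feature") -> None:
    """Write a feature x sample matrix as TSV with stable column order.

    ``repr``-round-trippable float formatting keeps a write/read cycle
    bit-identical for finite values; NaN cells are written empty.
    """
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.17g", na_rep="")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return df.astype(float)
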