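"""From precursor intensities to absolute antigen pseudocounts per cell.

The chain is:

1. filter precursors on the global protein-group q-value (strict ``<``),
2. sum charge/modification variants of the same peptide
   (:func:`aggregate_precursors`),
3. convert the matched proteome into absolute copies per cell with the
   histone *proteomic ruler*: total histone MS signal is assumed to report
   the chromatin mass, whose DNA content per diploid cell is known, so

   .. math:: c_{i,s} = \\frac{I_{i,s}}{\\sum_{h\\in H} I_{h,s}}
             \\cdot \\frac{m_{DNA} N_A}{M_i}

4. anchor the immunopeptidome to B2M: each antigen's fractional
   contribution to the sample's total peptide signal, times the per-cell
   B2M copy number of that sample's matched proteome, gives *pseudocounts
   per cell*. One B2M molecule is required per surface peptide-MHC complex,
   so per-cell B2M copies bound the presented repertoire size.

Fractions are computed over *all* quantified peptides of a sample before any
length or binder filter, so per-sample totals are well defined; filters
apply downstream. Both the ruler and the anchoring are ratios within one
sample, which removes per-sample global intensity scale (variable input
amounts) exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .constants import AVERAGE_RESIDUE_MASS, AVOGADRO, DNA_MASS_DIPLOID_HUMAN, WATER_MASS
from .io_formats import PrecursorTable, ProteinRecord

__all__ = [
    "PeptideIntensityMatrix",
    "CopyNumberMatrix",
    "PseudocountMatrix",
    "filter_by_pg_q_value",
    "aggregate_precursors",
    "molar_mass",
    "proteomic_ruler",
    "b2m_pseudocounts",
]


@dataclass
class PeptideIntensityMatrix:
    """Feature x sample intensity matrix after precursor aggregation.

    ``level`` distinguishes immunopeptide matrices (rows are peptide
    sequences) from protein-group matrices. ``feature_meta`` carries the
    gene / protein-group annotation surviving aggregation.
    """

    intensities: pd.DataFrame  # index: feature id, columns: samples, NaN = missing
    level: Literal["immunopeptide", "protein_group"]
    feature_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.intensities.index.duplicated().any():
            raise ValueError("feature ids must be unique")
        if (self.intensities.to_numpy(dtype=float) == 0).any():
            raise ValueError("zero intensities must be missing (NaN)")

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns)


@dataclass
class CopyNumberMatrix:
    """Absolute protein copies per cell from the proteomic ruler."""

    copies: pd.DataFrame  # index: protein group, columns: samples
    molar_mass: pd.Series  # g/mol per protein group
    feature_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    dna_mass_per_cell: float = DNA_MASS_DIPLOID_HUMAN

    def __post_init__(self) -> None:
        if (self.molar_mass <= 0).any():
            raise ValueError("molar masses must be positive")
        with np.errstate(invalid="ignore"):
            if (self.copies.to_numpy(dtype=float) < 0).any():
                raise ValueError("copy numbers must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.copies.columns)

    def gene_copies(self, gene: str) -> pd.Series:
        """Copies-per-cell row for a gene symbol (errors if not unique)."""
        if "gene" not in self.feature_meta.columns:
            raise KeyError("no gene annotation available")
        hits = self.feature_meta.index[self.feature_meta["gene"] == gene]
        if len(hits) == 0:
            raise KeyError(f"gene {gene!r} not in copy-number matrix")
        if len(hits) > 1:
            raise KeyError(f"gene {gene!r} maps to {len(hits)} protein groups")
        return self.copies.loc[hits[0]]


@dataclass
class PseudocountMatrix:
    """Absolute antigen pseudocounts per cell, anchored to B2M."""

    pseudocounts: pd.DataFrame  # antigen x sample, molecules per cell
    fraction: pd.DataFrame  # antigen x sample, in [0, 1]
    b2m_copies: pd.Series  # per sample
    feature_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if (self.b2m_copies <= 0).any():
            raise ValueError("B2M copies must be positive in every sample")
        totals = self.fraction.sum(axis=0, skipna=True)
        if not np.allclose(totals, 1.0, rtol=1e-9):
            raise ValueError("per-sample fractions must sum to 1 over observed antigens")

    @property
    def samples(self) -> list[str]:
        return list(self.pseudocounts.columns)


def filter_by_pg_q_value(table: PrecursorTable, threshold: float = 0.01) -> PrecursorTable:
    """Keep precursors whose global protein-group q-value is strictly below
    ``threshold``; rows without a q-value are dropped with a counted warning."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    q = table.data["pg_q_value"]
    absent = q.isna()
    if absent.any():
        warnings.warn(f"{int(absent.sum())} precursors without q-value dropped")
    keep = q < threshold  # NaN compares False
    return PrecursorTable(table.data.loc[keep].reset_index(drop=True), list(table.samples))


def aggregate_precursors(
    table: PrecursorTable,
    key: Literal["stripped", "modified", "protein_group"] = "stripped",
) -> PeptideIntensityMatrix:
    """Sum intensities of all precursor variants sharing the aggregation key.

    A cell is missing only when *every* contributing precursor is missing in
    that sample; otherwise observed variants are summed and missing ones
    contribute nothing.
    """
    key_col = {
        "stripped": "stripped_sequence",
        "modified": "modified_sequence",
        "protein_group": "protein_group",
    }[key]
    level = "protein_group" if key == "protein_group" else "immunopeptide"

    grouped = table.data.groupby(key_col, sort=True)
    sums = grouped[table.samples].sum(min_count=1)  # all-NaN -> NaN, not 0

    meta = grouped.agg(
        gene=("gene", "first"),
        protein_group=("protein_group", "first"),
        n_precursors=("precursor_id", "size"),
    )
    return PeptideIntensityMatrix(sums, level=level, feature_meta=meta)


def molar_mass(sequence: str) -> float:
    """Average molar mass of a peptide/protein chain in g/mol."""
    if not sequence:
        raise ValueError("empty sequence")
    try:
        mass = sum(AVERAGE_RESIDUE_MASS[a] for a in sequence)
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc.args[0]!r} in sequence") from None
    return mass + WATER_MASS


def proteomic_ruler(
    proteins: PeptideIntensityMatrix,
    records: Sequence[ProteinRecord],
    dna_mass_per_cell: float = DNA_MASS_DIPLOID_HUMAN,
    avogadro: float = AVOGADRO,
) -> CopyNumberMatrix:
    """Convert protein-group intensities to absolute copies per cell.

    The summed MS signal of all histones in a sample is taken to represent
    ``dna_mass_per_cell`` grams of chromatin-bound protein, giving a
    signal-to-mass conversion; dividing each protein's implied mass per cell
    by its molar mass yields copies per cell.
    """
    if proteins.level != "protein_group":
        raise ValueError("proteomic ruler needs a protein_group level matrix")
    by_acc = {r.accession: r for r in records}

    mm = {}
    histone_ids = []
    for pid in proteins.intensities.index:
        rec = by_acc.get(pid)
        if rec is None:
            raise ValueError(f"protein group {pid!r} has no sequence record (molar mass unknown)")
        mm[pid] = molar_mass(rec.sequence)
        if rec.is_histone:
            histone_ids.append(pid)
    mm = pd.Series(mm, name="molar_mass")

    if not histone_ids:
        raise ValueError("no histone protein observed: the ruler cannot be anchored")
    hist = proteins.intensities.loc[histone_ids].sum(axis=0, skipna=True)
    dead = hist[~(hist > 0)]
    if len(dead):
        raise ValueError(f"no histone signal in sample(s) {list(dead.index)}")

    # copies_{i,s} = I_{i,s} / sum_h I_{h,s} * m_DNA * N_A / M_i
    scale = dna_mass_per_cell * avogadro
    copies = proteins.intensities.div(hist, axis=1).mul(scale).div(mm, axis=0)

    meta = proteins.feature_meta.copy()
    if not meta.empty:
        meta = meta.loc[proteins.intensities.index]
    meta["is_histone"] = [pid in set(histone_ids) for pid in proteins.intensities.index]
    return CopyNumberMatrix(copies, mm, feature_meta=meta, dna_mass_per_cell=dna_mass_per_cell)


def b2m_pseudocounts(
    antigens: PeptideIntensityMatrix,
    copies: CopyNumberMatrix,
    b2m: str = "B2M",
    cross_sample_mean: bool = False,
) -> PseudocountMatrix:
    """Scale per-sample antigen fractions by per-cell B2M copies.

    Parameters
    ----------
    antigens
        Immunopeptide-level intensity matrix; fractions are taken over all
        observed peptides per sample.
    copies
        Matched proteome copy numbers (same samples).
    b2m
        Accession or gene symbol of beta-2-microglobulin in ``copies``.
    cross_sample_mean
        When True, anchor every sample to the across-sample mean B2M copy
        number instead of its own matched proteome (one global scale).
    """
    if antigens.level != "immunopeptide":
        raise ValueError("pseudocounts need an immunopeptide level matrix")
    missing_samples = [s for s in antigens.samples if s not in copies.samples]
    if missing_samples:
        raise ValueError(f"samples without matched proteome: {missing_samples}")

    if b2m in copies.copies.index:
        b2m_row = copies.copies.loc[b2m]
    else:
        b2m_row = copies.gene_copies(b2m)
    b2m_row = b2m_row[antigens.samples]
    bad = b2m_row[~(b2m_row > 0)]
    if len(bad):
        raise ValueError(f"B2M copies unavailable in sample(s) {list(bad.index)}")

    totals = antigens.intensities.sum(axis=0, skipna=True)
    empty = totals[~(totals > 0)]
    if len(empty):
        raise ValueError(f"no observed antigens in sample(s) {list(empty.index)}")

    fraction = antigens.intensities.div(totals, axis=1)
    anchor = pd.Series(float(b2m_row.mean()), index=b2m_row.index) if cross_sample_mean else b2m_row
    pseudo = fraction.mul(anchor, axis=1)
    return PseudocountMatrix(
        pseudocounts=pseudo,
        fraction=fraction,
        b2m_copies=anchor.astype(float),
        feature_meta=antigens.feature_meta.copy(),
    )
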