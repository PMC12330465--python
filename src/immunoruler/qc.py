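"""Immunopeptidome quality control.

MHC class I ligands are 8-12-mers peaked at length 9 with conserved anchor
residues at position 2 and the C-terminus; deviations from that signature
(flat length profiles, protease-style terminal biases) indicate digestion
artifacts rather than eluted antigens. This module quantifies those
signatures: length histograms, position frequency matrices with per-position
information content, terminal cleavage-bias screens, and predicted-affinity
binder filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import AMINO_ACIDS
from .io_formats import AffinityTable

__all__ = [
    "LengthDistribution",
    "PositionFrequencyMatrix",
    "CleavageReport",
    "length_distribution",
    "position_frequency_matrix",
    "anchor_enrichment",
    "cleavage_artifact_score",
    "filter_binders",
    "PROTEASE_RULES",
]

MAX_IC = float(np.log2(20))


@dataclass
class LengthDistribution:
    counts: pd.Series  # index: length, values: int
    fraction_length9: float

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class PositionFrequencyMatrix:
    """Residue frequencies per position for fixed-length peptides.

    ``freq`` is (L positions x 20 residues); ``information_content`` is the
    per-position Shannon information in bits, ``log2(20) - H_p``.
    """

    freq: pd.DataFrame  # index: position 1..L, columns: residues
    n_sequences: int
    information_content: pd.Series

    def __post_init__(self) -> None:
        sums = self.freq.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-12):
            raise ValueError("position frequencies must sum to 1")
        ic = self.information_content
        if ((ic < -1e-12) | (ic > MAX_IC + 1e-12)).any():
            raise ValueError("information content out of [0, log2 20]")

    def consensus(self) -> str:
        return "".join(self.freq.idxmax(axis=1))


def length_distribution(
    peptides: Iterable[str], length_range: tuple[int, int] = (7, 15)
) -> LengthDistribution:
    """Histogram of peptide lengths over the configured range.

    Also reports the fraction of in-range peptides with length 9, the
    hallmark of an MHC-I ligandome.
    """
    lo, hi = length_range
    counts = pd.Series(0, index=pd.RangeIndex(lo, hi + 1, name="length"), dtype=int)
    for p in peptides:
        n = len(p)
        if lo <= n <= hi:
            counts[n] += 1
    total = int(counts.sum())
    frac9 = float(counts.get(9, 0) / total) if total else 0.0
    return LengthDistribution(counts=counts, fraction_length9=frac9)


def position_frequency_matrix(
    peptides: Iterable[str], length: int, pseudocount: float = 0.0
) -> PositionFrequencyMatrix:
    """Build a PFM from the peptides of exactly the requested length.

    ``pseudocount`` adds alpha to every cell count before normalising
    (0 = raw frequencies, matching published ligandome logos).
    """
    seqs = [p for p in peptides if len(p) == length]
    if not seqs:
        raise ValueError(f"no peptide of length {length}")
    residues = list(AMINO_ACIDS)
    counts = np.full((length, 20), float(pseudocount))
    idx = {a: j for j, a in enumerate(residues)}
    for s in seqs:
        for pos, a in enumerate(s):
            counts[pos, idx[a]] += 1
    freq = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    entropy = -plogp.sum(axis=1)
    ic = np.clip(MAX_IC - entropy, 0.0, MAX_IC)
    positions = pd.RangeIndex(1, length + 1, name="position")
    return PositionFrequencyMatrix(
        freq=pd.DataFrame(freq, index=positions, columns=residues),
        n_sequences=len(seqs),
        information_content=pd.Series(ic, index=positions, name="ic_bits"),
    )


def anchor_enrichment(
    pfm: PositionFrequencyMatrix, anchor_positions: Sequence[int] | None = None
) -> float:
    """Mean information content at anchor positions minus the mean over
    non-anchor, non-terminal positions.

    Defaults to positions 2 and L (the canonical MHC-I anchors). Positive
    values indicate an allele-like motif; near zero indicates either random
    sequences or a fully conserved set (both symmetric across positions).
    """
    L = len(pfm.freq)
    anchors = list(anchor_positions) if anchor_positions is not None else [2, L]
    terminal = {1, L}
    background = [p for p in range(1, L + 1) if p not in anchors and p not in terminal]
    ic = pfm.information_content
    if not background:
        return 0.0
    return float(ic.loc[anchors].mean() - ic.loc[background].mean())


#: Built-in protease signatures: (terminus, preferred residues).
PROTEASE_RULES: dict[str, tuple[str, frozenset[str]]] = {
    # Trypsin cleaves C-terminal to K/R -> products end in K or R.
    "tryptic": ("C", frozenset("KR")),
    # Dispase cleaves N-terminal to hydrophobic residues -> products start
    # with a hydrophobic residue.
    "dispase": ("N", frozenset("FLIVAM")),
}


@dataclass
class CleavageReport:
    rule: str
    terminus: str
    residues: frozenset[str]
    terminal_fraction: float
    background_fraction: float
    log2_enrichment: float
    flagged: bool


def cleavage_artifact_score(
    peptides: Sequence[str],
    protease_rule: str | tuple[str, Iterable[str]] = "tryptic",
    flag_threshold: float = 1.0,
) -> CleavageReport:
    """Screen a peptide set for a protease-style terminal residue bias.

    Compares the frequency of the rule's residues at the relevant terminus
    with their frequency across all positions of all peptides; a log2
    enrichment above ``flag_threshold`` flags the sample as likely
    contaminated with digestion products.
    """
    if isinstance(protease_rule, str):
        if protease_rule not in PROTEASE_RULES:
            raise ValueError(
                f"unknown protease rule {protease_rule!r}; known: {sorted(PROTEASE_RULES)}"
            )
        name = protease_rule
        terminus, residues = PROTEASE_RULES[protease_rule]
    else:
        terminus, res = protease_rule
        if terminus not in ("N", "C"):
            raise ValueError("terminus must be 'N' or 'C'")
        name = "custom"
        residues = frozenset(res)

    peptides = [p for p in peptides if p]
    if not peptides:
        raise ValueError("no peptides to screen")
    term_idx = 0 if terminus == "N" else -1
    term_hits = sum(1 for p in peptides if p[term_idx] in residues)
    terminal_fraction = term_hits / len(peptides)
    all_res = "".join(peptides)
    background_fraction = sum(1 for a in all_res if a in residues) / len(all_res)

    if terminal_fraction == 0 or background_fraction == 0:
        log2_enr = -np.inf if terminal_fraction == 0 else np.inf
    else:
        log2_enr = float(np.log2(terminal_fraction / background_fraction))
    return CleavageReport(
        rule=name,
        terminus=terminus,
        residues=residues,
        terminal_fraction=terminal_fraction,
        background_fraction=background_fraction,
        log2_enrichment=log2_enr,
        flagged=bool(log2_enr > flag_threshold),
    )


def subset_by_cluster(
    peptides: Sequence[str],
    cluster_labels: "pd.Series",
    keep_clusters: Sequence[str] | None = None,
) -> list[str]:
    """Subset peptides using labels from an external sequence-clustering
    tool (e.g. GibbsCluster), keeping only the clusters judged to carry a
    genuine MHC-I motif.

    ``keep_clusters=None`` keeps every labelled peptide (drops unlabelled
    ones, which the clustering tool set aside as outliers). The rule for
    which clusters are "biologically relevant" is entirely the caller's:
    the clustering itself is never performed here.
    """
    labelled = [p for p in peptides if p in cluster_labels.index]
    if keep_clusters is None:
        return labelled
    keep = set(map(str, keep_clusters))
    return [p for p in labelled if str(cluster_labels[p]) in keep]


def filter_binders(
    peptides: Sequence[str],
    affinities: AffinityTable,
    alleles: Sequence[str],
    threshold_nM: float = 100.0,
) -> list[str]:
    """Keep peptides predicted to bind one of the sample's alleles with
    affinity strictly below ``threshold_nM`` (strong binders).

    The minimum predicted affinity over the given alleles is used (best
    binding allele); peptides without any prediction are dropped with a
    counted warning.
    """
    if threshold_nM <= 0:
        raise ValueError("threshold_nM must be positive")
    if len(alleles) == 0:
        raise ValueError("allele list must be non-empty")
    best = affinities.min_affinity(alleles)
    missing = [p for p in peptides if p not in best.index]
    if missing:
        warnings.warn(f"{len(missing)} peptides without affinity prediction dropped")
    return [p for p in peptides if p in best.index and best[p] < threshold_nM]
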