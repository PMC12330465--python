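"""Physical constants and amino-acid mass tables.

Average (not monoisotopic) residue masses are used throughout: the proteomic
ruler converts MS signal into protein mass per cell, and the molar mass of a
protein is the sum of average residue masses plus one water.
"""

from __future__ import annotations

AVOGADRO: float = 6.02214076e23
"""Avogadro constant, 1/mol (exact, 2019 SI)."""

DNA_MASS_DIPLOID_HUMAN: float = 6.5e-12
"""DNA mass per diploid human cell in grams (~6.5 pg)."""

WATER_MASS: float = 18.0153
"""Average mass of one water molecule in g/mol (added once per chain)."""

# Average residue masses (g/mol), i.e. amino acid minus water.
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788,
    "R": 156.1875,
    "N": 114.1038,
    "D": 115.0886,
    "C": 103.1388,
    "E": 129.1155,
    "Q": 128.1307,
    "G": 57.0519,
    "H": 137.1411,
    "I": 113.1594,
    "L": 113.1594,
    "K": 128.1741,
    "M": 131.1926,
    "F": 147.1766,
    "P": 97.1167,
    "S": 87.0782,
    "T": 101.1051,
    "W": 186.2132,
    "Y": 163.1760,
    "V": 99.1326,
}

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

# Gene-symbol glob patterns identifying human histones (replication-dependent
# HIST* / H1-H4 cluster nomenclature plus common variants). Configurable in
# the readers; B2M and other genes never match.
DEFAULT_HISTONE_PATTERNS: tuple[str, ...] = (
    "H1-*",
    "H1F*",
    "H2A*",
    "H2B*",
    "H3-*",
    "H3C*",
    "H3F*",
    "H4C*",
    "H4F*",
    "HIST*",
    "MACROH2A*",
    "CENPA",
)
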