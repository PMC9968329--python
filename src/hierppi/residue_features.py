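"""Residue-level physicochemical property table (version 1).

Seven properties per standard amino acid, in fixed column order:

==================  =====================================================
column              meaning / units
==================  =====================================================
pI                  isoelectric point of the free amino acid
polarity            1 polar side chain, 0 nonpolar
acid_base           -1 acidic, 0 neutral, +1 basic side chain
hb_acceptor         hydrogen-bond acceptor count
hb_donor            hydrogen-bond donor count
kow                 octanol-water partition coefficient (Crippen logP)
tpsa                topological polar surface area (A^2)
==================  =====================================================

Isoelectric points and polarity/acid-base classes follow standard
biochemistry references; acceptor/donor counts, KOW and TPSA were computed
once with RDKit on the free amino acids and frozen here so the package
carries no runtime chemistry dependency.
"""

from __future__ import annotations

import numpy as np

FEATURE_NAMES = (
    "pI", "polarity", "acid_base", "hb_acceptor", "hb_donor", "kow", "tpsa",
)
N_FEATURES = len(FEATURE_NAMES)

#                pI    pol  a/b  hba  hbd   kow     tpsa
_TABLE = {
    "ALA": (6.01, 0.0, 0.0, 2.0, 2.0, -0.5818, 63.32),
    "ARG": (10.76, 1.0, 1.0, 3.0, 4.0, -1.5481, 127.72),
    "ASN": (5.41, 1.0, 0.0, 3.0, 3.0, -1.7263, 106.41),
    "ASP": (2.77, 1.0, -1.0, 3.0, 3.0, -1.1270, 100.62),
    "CYS": (5.07, 1.0, 0.0, 3.0, 3.0, -0.6719, 63.32),
    "GLN": (5.65, 1.0, 0.0, 3.0, 3.0, -1.3362, 106.41),
    "GLU": (3.22, 1.0, -1.0, 3.0, 3.0, -0.7369, 100.62),
    "GLY": (5.97, 0.0, 0.0, 2.0, 2.0, -0.9703, 63.32),
    "HIS": (7.59, 1.0, 1.0, 3.0, 3.0, -0.6359, 92.00),
    "ILE": (6.02, 0.0, 0.0, 2.0, 2.0, 0.4444, 63.32),
    "LEU": (5.98, 0.0, 0.0, 2.0, 2.0, 0.4444, 63.32),
    "LYS": (9.74, 1.0, 1.0, 3.0, 3.0, -0.4727, 89.34),
    "MET": (5.74, 0.0, 0.0, 3.0, 2.0, 0.1514, 63.32),
    "PHE": (5.48, 0.0, 0.0, 2.0, 2.0, 0.6410, 63.32),
    "PRO": (6.48, 0.0, 0.0, 2.0, 2.0, -0.1770, 49.33),
    "SER": (5.68, 1.0, 0.0, 3.0, 3.0, -1.6094, 83.55),
    "THR": (5.87, 1.0, 0.0, 3.0, 3.0, -1.2209, 83.55),
    "TRP": (5.89, 0.0, 0.0, 2.0, 3.0, 1.1223, 79.11),
    "TYR": (5.66, 1.0, 0.0, 3.0, 3.0, 0.3466, 83.55),
    "VAL": (5.97, 0.0, 0.0, 2.0, 2.0, 0.0543, 63.32),
}

STANDARD_AMINO_ACIDS = tuple(sorted(_TABLE))

# non-standard residue codes mapped onto their parent standard residue
PARENT_CODE = {
    "MSE": "MET",  # selenomethionine
    "SEC": "CYS",  # selenocysteine
    "PYL": "LYS",  # pyrrolysine
    "HYP": "PRO",  # hydroxyproline
    "SEP": "SER", "TPO": "THR", "PTR": "TYR",  # phosphorylated
    "CSO": "CYS", "MLY": "LYS", "M3L": "LYS",
}


class ResidueFeatureTable:
    """The 20 x 7 property table, raw or per-column z-scored.

    Standardization is over the 20-residue alphabet (population statistics),
    so each standardized column has mean 0 and sd 1 across amino acids.
    """

    def __init__(self, standardized: bool = True):
        self.standardized = standardized
        raw = np.array([_TABLE[aa] for aa in STANDARD_AMINO_ACIDS], dtype=np.float64)
        self._raw = raw
        mu = raw.mean(axis=0)
        sd = raw.std(axis=0)
        self._z = (raw - mu) / sd
        self._index = {aa: i for i, aa in enumerate(STANDARD_AMINO_ACIDS)}

    @property
    def values(self) -> np.ndarray:
        return (self._z if self.standardized else self._raw).copy()

    def row(self, three_letter_code: str) -> tuple[np.ndarray, bool]:
        """Feature row for a residue code.

        Returns ``(row, mapped)``; unmappable codes get the alphabet-mean row
        (all-zero when standardized) and ``mapped=False``.
        """
        code = three_letter_code.upper()
        code = PARENT_CODE.get(code, code)
        table = self._z if self.standardized else self._raw
        if code in self._index:
            return table[self._index[code]].copy(), True
        return table.mean(axis=0), False
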