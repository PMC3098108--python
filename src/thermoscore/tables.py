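"""Published per-residue property tables and default residue-class sets.

Every table covers exactly the 20 standard amino acids (one-letter codes).
Values are data, kept here apart from any computation so they can be
overridden through :class:`thermoscore.features.ResidueClassConfig`.

Sources
-------
* Kyte-Doolittle hydropathy and the dipeptide instability weight table are
  taken from Biopython (``Bio.SeqUtils.ProtParamData``), which ships the
  original published values (Kyte & Doolittle 1982; Guruprasad et al. 1990).
* ``MAX_ASA``: theoretical maximum solvent-accessible surface area of residue
  X in an extended Gly-X-Gly tripeptide, in square angstroms (Tien et al.
  2013, theoretical set).
* ``SOLUBILITY``: solubility of the free amino acid in water at 25 degrees C,
  g per 100 g water, as compiled in CRC handbook style references.  Lysine is
  listed as freely soluble in the compilations; a nominal 100 is used.
* ``PK_SIDECHAIN`` / termini: ProtParam-lineage ionizable-group pK values
  (Bjellqvist et al. 1993, generic termini).
* ``RESIDUE_PI``: isoelectric points of the free amino acids (Lehninger
  compilation).
"""

from __future__ import annotations

from Bio.SeqUtils.ProtParamData import DIWV as _DIWV
from Bio.SeqUtils.ProtParamData import kd as _KD

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS_AA = "BJXZUO"

#: Kyte-Doolittle hydropathy index.
KD_HYDROPATHY: dict[str, float] = dict(_KD)

#: Dipeptide instability weight values, DIWV[first][second].
DIPEPTIDE_INSTABILITY: dict[str, dict[str, float]] = {
    a: dict(row) for a, row in _DIWV.items()
}

#: Theoretical maximum accessible surface area (A^2), Tien et al. 2013.
MAX_ASA: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: Aqueous solubility of the free amino acids, g / 100 g water at 25 C.
SOLUBILITY: dict[str, float] = {
    "A": 16.65, "R": 18.60, "N": 3.53, "D": 0.778, "C": 16.0,
    "E": 0.864, "Q": 2.50, "G": 24.99, "H": 4.29, "I": 4.117,
    "L": 2.426, "K": 100.0, "M": 3.381, "F": 2.965, "P": 162.3,
    "S": 5.023, "T": 13.20, "W": 1.136, "Y": 0.0453, "V": 8.85,
}

#: Side-chain pK values for the ionizable residues (ProtParam lineage).
PK_SIDECHAIN: dict[str, float] = {
    "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,
    "H": 5.98, "K": 10.0, "R": 12.0,
}
PK_NTERM = 7.5
PK_CTERM = 3.55

#: Isoelectric points of the free amino acids.
RESIDUE_PI: dict[str, float] = {
    "A": 6.01, "R": 10.76, "N": 5.41, "D": 2.77, "C": 5.07,
    "E": 3.22, "Q": 5.65, "G": 5.97, "H": 7.59, "I": 6.02,
    "L": 5.98, "K": 9.74, "M": 5.74, "F": 5.48, "P": 6.48,
    "S": 5.68, "T": 5.87, "W": 5.89, "Y": 5.66, "V": 5.97,
}

# Default residue-class sets.  Small and tiny follow the unusual printed
# convention of the feature table this package implements (small = {T, D},
# tiny = {G, A, S, P}); His is excluded from the charged classes at neutral
# pH.  All of these are overridable per analysis.
POSITIVE = frozenset("KR")
NEGATIVE = frozenset("DE")
SMALL = frozenset("TD")
TINY = frozenset("GASP")
AROMATIC = frozenset("FHYW")
ALIPHATIC = frozenset("AVIL")
HYDROPHOBIC = frozenset("ACFILMV")  # positive Kyte-Doolittle hydropathy
POLAR = frozenset("CDEHKNQRSTWY")
HBOND_SIDECHAIN = frozenset("CDEHKNQRSTWY")
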