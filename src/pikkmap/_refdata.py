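"""Shared reference tables: amino-acid codes, vdW radii, per-residue maximal SASA."""

from __future__ import annotations

#: Standard one-letter amino-acid codes.
AA1 = set("ACDEFGHIKLMNPQRSTVWY")

#: Three-letter -> one-letter residue names.
AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

#: Van der Waals radii in Angstrom (Bondi-type set). Hydrogens are excluded
#: from SASA by default but a radius is listed for completeness.
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
}

#: Theoretical maximal solvent-accessible surface area per residue type
#: (Angstrom^2), used to normalise absolute SASA into relative SASA.
#: Values follow the widely used theoretical (Gly-X-Gly tripeptide) scale.
MAX_SASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}
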