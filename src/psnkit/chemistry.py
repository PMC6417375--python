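"""Residue-level chemical annotations used by the interaction detectors.

Atom masses follow standard atomic weights. The hydrophobic residue set,
charged-group and donor/acceptor tables mirror the defaults of common
residue-interaction-network tooling; all of them can be overridden through
the configuration layer, and the precise membership of these sets is an
assumption documented in the methods note.
"""

from __future__ import annotations

# Standard atomic weights (u). CA here is the calcium *element*.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "CA": 40.078,
    "MG": 24.305,
    "ZN": 65.38,
    "NA": 22.990,
    "K": 39.098,
    "CL": 35.45,
    "FE": 55.845,
}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: Aliphatic/aromatic side chains treated as hydrophobic interaction partners.
HYDROPHOBIC_RESIDUES: frozenset[str] = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "PHE", "PRO", "TRP", "MET"}
)

#: Backbone atom names excluded from side-chain geometry (Gly falls back to CA).
BACKBONE_ATOMS: frozenset[str] = frozenset(
    {"N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3", "HA", "HA1",
     "HA2", "HA3", "HN", "HXT"}
)

#: Charged side-chain groups: residue name -> (sign, heavy atom names).
CHARGED_GROUPS: dict[str, tuple[int, tuple[str, ...]]] = {
    "ASP": (-1, ("OD1", "OD2")),
    "GLU": (-1, ("OE1", "OE2")),
    "LYS": (+1, ("NZ",)),
    "ARG": (+1, ("NE", "NH1", "NH2")),
    "HIS": (+1, ("ND1", "NE2")),  # protonated-His convention
}

#: Side-chain hydrogen-bond donor heavy atoms per residue.
HBOND_DONORS: dict[str, tuple[str, ...]] = {
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "CYS": ("SG",),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "TRP": ("NE1",),
    "HIS": ("ND1", "NE2"),
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
}

#: Side-chain hydrogen-bond acceptor atoms per residue.
HBOND_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "CYS": ("SG",),
    "MET": ("SD",),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "HIS": ("ND1", "NE2"),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

#: Clustal strong similarity groups (one-letter codes).
CLUSTAL_STRONG_GROUPS: tuple[frozenset[str], ...] = tuple(
    frozenset(g) for g in
    ("STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW")
)

AMINO_ACIDS: frozenset[str] = frozenset("ACDEFGHIKLMNPQRSTVWY")


def element_mass(element: str) -> float:
    """Mass of an element symbol; unknown elements raise ``KeyError``."""
    return ELEMENT_MASSES[element.upper()]


def guess_element(atom_name: str) -> str:
    """Infer the element from a PDB atom name when the element column is blank."""
    name = atom_name.strip()
    if not name:
        raise ValueError("empty atom name")
    if name[0].isdigit():  # e.g. 1HG1
        name = name.lstrip("0123456789")
    if name[:2].upper() in ("CL", "NA", "MG", "ZN", "FE") and len(name) == 2:
        return name.upper()
    return name[0].upper()


def same_strong_group(a: str, b: str) -> bool:
    """True if two one-letter residues fall in a common Clustal strong group."""
    return any(a in g and b in g for g in CLUSTAL_STRONG_GROUPS)
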