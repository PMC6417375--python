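"""Core domain containers and format I/O.

Defines the three containers every other module works on — :class:`Topology`
(residues, ions and acyl pseudo-residues with their atoms), :class:`Ensemble`
(an ordered stack of coordinate frames over one topology) and :class:`MSA`
(a parsed multiple sequence alignment with a designated seed) — together with
the readers and writers for multi-model PDB, aligned FASTA / Clustal and
GraphML, and the flat key/value configuration layer.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from Bio import AlignIO
from Bio.PDB import PDBParser

from . import chemistry


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class ConfigError(ValueError):
    """Raised for unknown or out-of-range configuration values."""


# ---------------------------------------------------------------------------
# Topology / Ensemble
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    mass: float


@dataclass(frozen=True)
class Residue:
    """One node of the network: a residue, an ion, or an acyl pseudo-residue.

    ``index`` is the 1-based author numbering from the PDB, preserved verbatim,
    and ``chain`` disambiguates protein vs. peptide nodes. ``kind`` is one of
    ``"residue"``, ``"ion"`` or ``"acyl"``; the latter two are the special
    nodes (bound calcium, N-terminal myristoyl) that participate in the
    network alongside amino acids.
    """

    index: int
    chain: str
    name: str
    atoms: tuple[Atom, ...]
    kind: str = "residue"
    atom_offset: int = 0  # index of first atom in the ensemble coordinate array

    @property
    def label(self) -> str:
        one = chemistry.THREE_TO_ONE.get(self.name, self.name)
        return f"{self.chain}:{one}{self.index}"

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def atom_indices(self, names: Iterable[str]) -> list[int]:
        """Global coordinate-array indices of the named atoms (present ones)."""
        lookup = {a.name: i for i, a in enumerate(self.atoms)}
        return [self.atom_offset + lookup[n] for n in names if n in lookup]

    def sidechain_indices(self) -> list[int]:
        """Global indices of side-chain atoms; Gly and single-atom special
        nodes fall back to all their atoms (for Gly that is the Cα)."""
        if self.kind != "residue":
            return list(range(self.atom_offset, self.atom_offset + self.n_atoms))
        idx = [self.atom_offset + i for i, a in enumerate(self.atoms)
               if a.name not in chemistry.BACKBONE_ATOMS]
        if not idx:  # glycine
            idx = self.atom_indices(["CA"])
        if not idx:
            raise ValueError(f"residue {self.label} has no side-chain atoms and no CA")
        return idx

    def sidechain_masses(self) -> np.ndarray:
        off = self.atom_offset
        return np.array([self.atoms[i - off].mass for i in self.sidechain_indices()])


@dataclass
class Topology:
    """Ordered residues plus special nodes; the atom order matches frames."""

    residues: list[Residue]

    def __post_init__(self) -> None:
        per_chain: dict[str, int] = {}
        for r in self.residues:
            if r.kind == "residue":
                prev = per_chain.get(r.chain)
                if prev is not None and r.index <= prev:
                    raise FormatError(
                        f"residue indices not strictly increasing in chain "
                        f"{r.chain!r}: {prev} then {r.index}")
                per_chain[r.chain] = r.index
            for a in r.atoms:
                if not a.mass > 0:
                    raise FormatError(f"non-positive mass for atom {a.name} "
                                      f"in {r.label}")

    @property
    def n_atoms(self) -> int:
        return sum(r.n_atoms for r in self.residues)

    @property
    def protein_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.kind == "residue"]

    @property
    def special_nodes(self) -> list[Residue]:
        return [r for r in self.residues if r.kind != "residue"]

    def node_labels(self) -> list[str]:
        return [r.label for r in self.residues]

    def by_label(self, label: str) -> Residue:
        for r in self.residues:
            if r.label == label:
                return r
        raise KeyError(f"no node labelled {label!r}")

    def ca_indices(self) -> list[int]:
        """Global indices of Cα atoms of protein residues, in order."""
        out: list[int] = []
        for r in self.protein_residues:
            idx = r.atom_indices(["CA"])
            if idx:
                out.append(idx[0])
        return out


@dataclass
class Ensemble:
    """A conformational ensemble: one topology, ``(n_frames, n_atoms, 3)``
    coordinates in Å, and a provenance label (e.g. replica id)."""

    topology: Topology
    coords: np.ndarray
    label: str = "ensemble"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise FormatError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise FormatError("ensemble must contain at least one frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise FormatError(
                f"frame atom count {self.coords.shape[1]} != topology atom "
                f"count {self.topology.n_atoms}")
        if not np.all(np.isfinite(self.coords)):
            raise FormatError("non-finite coordinates in ensemble")

    @property
    def n_frames(self) -> int:
        return int(self.coords.shape[0])

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]


def concatenate(ensembles: Sequence[Ensemble], label: str = "concatenated") -> Ensemble:
    """Stack replicas that share a topology into one ensemble, in order."""
    if not ensembles:
        raise ValueError("no ensembles to concatenate")
    n0 = ensembles[0].topology.n_atoms
    for e in ensembles[1:]:
        if e.topology.n_atoms != n0:
            raise FormatError("ensembles have mismatching atom counts")
    coords = np.concatenate([e.coords for e in ensembles], axis=0)
    return Ensemble(ensembles[0].topology, coords, label=label)


# ---------------------------------------------------------------------------
# Multi-model PDB
# ---------------------------------------------------------------------------

def read_multimodel_pdb(path: str | Path,
                        ion_residues: Iterable[str] = ("CA", "CAL"),
                        acyl_residues: Iterable[str] = ("MYR",),
                        strict_het: bool = False,
                        label: str | None = None) -> Ensemble:
    """Read a (possibly multi-model) PDB file into an :class:`Ensemble`.

    One frame per MODEL record, in file order; the topology is built from the
    first model. HETATM residues named in ``ion_residues`` become ion nodes
    and those in ``acyl_residues`` become acyl pseudo-residues; any other
    het residue raises :class:`FormatError` when ``strict_het`` is true and is
    skipped (with a warning) otherwise. Waters are always skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ions = {s.upper() for s in ion_residues}
    acyls = {s.upper() for s in acyl_residues}

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # Bio.PDB is chatty about minor issues
        structure = PDBParser(QUIET=True).get_structure(path.stem, str(path))
    models = list(structure)
    if not models:
        raise FormatError(f"{path}: no coordinate models found")

    residues: list[Residue] = []
    offset = 0
    keyed: list[tuple] = []  # (chain, resid, het) keys, aligned with residues
    for bres in models[0].get_residues():
        hetflag, resid, _icode = bres.id
        resname = bres.get_resname().strip().upper()
        if resname in ("HOH", "WAT"):
            continue
        if hetflag.strip() and resname not in chemistry.THREE_TO_ONE:
            if resname in ions:
                kind = "ion"
            elif resname in acyls:
                kind = "acyl"
            elif strict_het:
                raise FormatError(
                    f"{path}: unknown het residue {resname!r}; add it to the "
                    f"ion/acyl mapping or disable strict het handling")
            else:
                warnings.warn(f"{path}: skipping unmapped het residue {resname}")
                continue
        else:
            kind = "residue"
        atoms = []
        for batom in bres.get_atoms():
            element = (batom.element or "").strip() or chemistry.guess_element(
                batom.get_name())
            try:
                mass = chemistry.element_mass(element)
            except KeyError:
                mass = float(batom.mass) if batom.mass and batom.mass > 0 else 12.011
            atoms.append(Atom(batom.get_name(), element.upper(), mass))
        chain_id = bres.get_parent().id.strip() or "A"
        residues.append(Residue(resid, chain_id, resname, tuple(atoms),
                                kind=kind, atom_offset=offset))
        keyed.append((chain_id, bres.id, resname))
        offset += len(atoms)

    topology = Topology(residues)
    n_atoms = topology.n_atoms
    frames = np.empty((len(models), n_atoms, 3), dtype=float)
    for m, model in enumerate(models):
        pos = 0
        for (chain_id, res_id, resname), res in zip(keyed, residues):
            try:
                bres = model[chain_id][res_id]
            except KeyError:
                raise FormatError(
                    f"{path}: MODEL {m + 1} is missing residue {res.label}")
            coords = [a.get_coord() for a in bres.get_atoms()]
            if len(coords) != res.n_atoms:
                raise FormatError(
                    f"{path}: atom-count mismatch in MODEL {m + 1} at residue "
                    f"{res.label} ({len(coords)} vs {res.n_atoms})")
            frames[m, pos:pos + res.n_atoms] = coords
            pos += res.n_atoms
        if pos != n_atoms:
            raise FormatError(f"{path}: MODEL {m + 1} has {pos} atoms, "
                              f"expected {n_atoms}")
    return Ensemble(topology, frames, label=label or path.stem)


def write_multimodel_pdb(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB (fixed-width ATOM/HETATM)."""
    path = Path(path)
    lines: list[str] = []
    for m in range(ensemble.n_frames):
        lines.append(f"MODEL     {m + 1:4d}")
        serial = 1
        frame = ensemble.coords[m]
        for res in ensemble.topology.residues:
            record = "ATOM  " if res.kind == "residue" else "HETATM"
            for j, atom in enumerate(res.atoms):
                x, y, z = frame[res.atom_offset + j]
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                lines.append(
                    f"{record}{serial:5d} {name:<4s} {res.name:<3s} "
                    f"{res.chain:1s}{res.index:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {atom.element:>2s}")
                serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

@dataclass
class MSA:
    """A parsed alignment: (identifier, aligned sequence) pairs and a seed id."""

    sequences: list[tuple[str, str]]
    seed_id: str

    def __post_init__(self) -> None:
        if not self.sequences:
            raise FormatError("alignment contains no sequences")
        length = len(self.sequences[0][1])
        for ident, seq in self.sequences:
            if len(seq) != length:
                raise FormatError(f"ragged alignment: sequence {ident!r} has "
                                  f"length {len(seq)}, expected {length}")
        if self.seed_id not in {i for i, _ in self.sequences}:
            raise FormatError(f"seed id {self.seed_id!r} not present in alignment")
        if not self.seed_sequence.replace("-", ""):
            raise FormatError("seed sequence is all gaps")

    @property
    def length(self) -> int:
        return len(self.sequences[0][1])

    @property
    def seed_sequence(self) -> str:
        return dict(self.sequences)[self.seed_id]

    def seed_columns(self) -> list[int]:
        """Alignment columns occupied by the seed, in ungapped-residue order."""
        return [c for c, ch in enumerate(self.seed_sequence) if ch != "-"]


def read_alignment(path: str | Path, dialect: str = "aligned-fasta",
                   seed_id: str | None = None) -> MSA:
    """Parse an aligned FASTA or Clustal file; the first sequence is the seed
    unless ``seed_id`` names another one. Gap characters are preserved."""
    fmt = {"aligned-fasta": "fasta", "clustal": "clustal"}.get(dialect)
    if fmt is None:
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    sequences = [(rec.id, str(rec.seq).upper()) for rec in aln]
    return MSA(sequences, seed_id=seed_id or sequences[0][0])


def write_alignment_fasta(msa: MSA, path: str | Path) -> None:
    with open(path, "w") as fh:
        for ident, seq in msa.sequences:
            fh.write(f">{ident}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


# ---------------------------------------------------------------------------
# GraphML
# ---------------------------------------------------------------------------

def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    """Serialize a network with its node attributes (label, degree, hub flag)
    and the persistence threshold graph attribute; round-trips losslessly."""
    g = nx.Graph()
    g.graph.update({k: v for k, v in graph.graph.items()})
    for node, data in graph.nodes(data=True):
        attrs = dict(data)
        attrs.setdefault("degree", graph.degree(node))
        g.add_node(node, **attrs)
    g.add_edges_from(graph.edges(data=True))
    nx.write_graphml(g, str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class Parameters:
    """Validated analysis parameters with the pipeline defaults.

    Distances in Å, angles in degrees, persistences in percent.
    """

    schema_version: str = "1"
    hydrophobic_cutoff: float = 5.0
    salt_bridge_cutoff: float = 4.5
    hbond_distance_cutoff: float = 3.5
    hbond_angle_cutoff: float = 120.0
    ion_cutoff: float = 3.0
    persistence_step: float = 0.1
    hub_min_degree: int = 4
    es_dimension: int = 20
    exclude_adjacent: int = 1          # |i-j| <= this are skipped, same chain
    pt_rounding: str = "down"          # "down" | "nearest"
    conservation_mode: str = "identity"  # "identity" | "similarity-groups"
    variance_test: str = "breusch-pagan"  # or "levene"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    ion_residues: tuple[str, ...] = ("CA", "CAL")
    acyl_residues: tuple[str, ...] = ("MYR",)
    hydrophobic_residues: tuple[str, ...] = tuple(sorted(chemistry.HYDROPHOBIC_RESIDUES))
    max_paths: int = 100_000
    cr_top_k: int = 5

    def __post_init__(self) -> None:
        for key in ("hydrophobic_cutoff", "salt_bridge_cutoff",
                    "hbond_distance_cutoff", "ion_cutoff", "persistence_step"):
            if not getattr(self, key) > 0:
                raise ConfigError(f"{key} must be positive")
        if not 0 < self.hbond_angle_cutoff <= 180:
            raise ConfigError("hbond_angle_cutoff must be in (0, 180]")
        if self.hub_min_degree < 1:
            raise ConfigError("hub_min_degree must be >= 1")
        if self.es_dimension < 1:
            raise ConfigError("es_dimension must be >= 1")
        if self.pt_rounding not in ("down", "nearest"):
            raise ConfigError("pt_rounding must be 'down' or 'nearest'")
        if self.conservation_mode not in ("identity", "similarity-groups"):
            raise ConfigError("conservation_mode must be 'identity' or "
                              "'similarity-groups'")
        if self.variance_test not in ("breusch-pagan", "levene"):
            raise ConfigError("variance_test must be 'breusch-pagan' or 'levene'")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ConfigError("gap penalties must be >= 0")
        if self.exclude_adjacent < 0:
            raise ConfigError("exclude_adjacent must be >= 0")

    def asdict(self) -> dict:
        return dataclasses.asdict(self)


_TUPLE_KEYS = {"ion_residues", "acyl_residues", "hydrophobic_residues"}
_INT_KEYS = {"hub_min_degree", "es_dimension", "exclude_adjacent", "max_paths",
             "cr_top_k"}
_STR_KEYS = {"schema_version", "pt_rounding", "conservation_mode",
             "variance_test"}


def load_config(path: str | Path | None = None, **overrides) -> Parameters:
    """Load the flat ``key = value`` configuration file, apply defaults.

    Lines starting with ``#`` and blank lines are ignored. List-valued keys
    take comma-separated values. Unknown keys and out-of-range values raise
    :class:`ConfigError`.
    """
    values: dict = {}
    if path is not None:
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
            key, _, val = (p.strip() for p in line.partition("="))
            values[key] = val
    values.update({k: v for k, v in overrides.items() if v is not None})

    valid = {f.name for f in dataclasses.fields(Parameters)}
    parsed: dict = {}
    for key, val in values.items():
        if key not in valid:
            raise ConfigError(f"unknown configuration key {key!r}")
        if isinstance(val, str):
            if key in _TUPLE_KEYS:
                parsed[key] = tuple(s.strip().upper() for s in val.split(",") if s.strip())
            elif key in _INT_KEYS:
                parsed[key] = int(val)
            elif key in _STR_KEYS:
                parsed[key] = val
            else:
                parsed[key] = float(val)
        else:
            parsed[key] = val
    return Parameters(**parsed)
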