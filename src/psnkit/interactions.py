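"""Per-frame non-covalent interaction detection and persistence reduction.

An ensemble frame is scanned for side-chain hydrophobic contacts, salt
bridges, hydrogen bonds and ion coordination; across frames each (pair, type)
is reduced to a persistence — the percentage of frames in which the
geometric criterion holds. Side-chain-only by construction: backbone atoms
never enter any criterion, and sequence-adjacent residues are excluded by
default so the network is not dominated by trivially persistent neighbours.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import chemistry
from .io import Ensemble, Parameters, Residue, Topology

log = logging.getLogger(__name__)

INTERACTION_TYPES = ("hydrophobic", "salt-bridge", "hydrogen-bond",
                     "ion-coordination")

#: covalently bonded H search radius around a donor heavy atom (Å)
_H_BOND_RADIUS = 1.25


@dataclass(frozen=True)
class InteractionRecord:
    node_i: str
    node_j: str
    type: str
    persistence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.persistence <= 100.0:
            raise ValueError("persistence outside [0, 100]")


@dataclass
class PersistenceTable:
    records: list[InteractionRecord]
    frame_count: int
    params: Parameters = field(default_factory=Parameters)

    def __post_init__(self) -> None:
        if self.frame_count < 1:
            raise ValueError("frame_count must be >= 1")
        keys = [(r.node_i, r.node_j, r.type) for r in self.records]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (pair, type) records")

    def filtered(self, min_persistence: float) -> "PersistenceTable":
        return PersistenceTable(
            [r for r in self.records if r.persistence >= min_persistence],
            self.frame_count, self.params)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("node_i\tnode_j\ttype\tpersistence\n")
            for r in sorted(self.records,
                            key=lambda r: (-r.persistence, r.node_i, r.node_j)):
                fh.write(f"{r.node_i}\t{r.node_j}\t{r.type}\t"
                         f"{r.persistence:.1f}\n")


def _ordered(a: Residue, b: Residue) -> tuple[str, str]:
    """Canonical pair ordering so results are independent of argument order."""
    la, lb = a.label, b.label
    ka = (a.chain, a.index, la)
    kb = (b.chain, b.index, lb)
    return (la, lb) if ka <= kb else (lb, la)


def _adjacent(a: Residue, b: Residue, exclude: int) -> bool:
    return (a.chain == b.chain and a.kind == b.kind == "residue"
            and abs(a.index - b.index) <= exclude)


def sidechain_center(residue: Residue, frame: np.ndarray) -> np.ndarray:
    """Mass-weighted centroid of the side-chain atoms (Gly: the Cα)."""
    idx = residue.sidechain_indices()
    masses = residue.sidechain_masses()
    return np.average(frame[idx], axis=0, weights=masses)


def _sidechain_center_traj(residue: Residue, coords: np.ndarray) -> np.ndarray:
    """(n_frames, 3) centroid trajectory, vectorised over frames."""
    idx = residue.sidechain_indices()
    masses = residue.sidechain_masses()
    return np.einsum("fai,a->fi", coords[:, idx], masses) / masses.sum()


def hydrophobic_contacts(frame: np.ndarray, topology: Topology,
                         cutoff: float = 5.0,
                         hydrophobic_set: frozenset[str] | None = None,
                         exclude_adjacent: int = 1) -> set[tuple[str, str]]:
    """Pairs of hydrophobic residues (or acyl pseudo-residues) whose
    side-chain mass centroids are within ``cutoff`` Å."""
    hset = hydrophobic_set or chemistry.HYDROPHOBIC_RESIDUES
    members = [r for r in topology.residues
               if r.name in hset or r.kind == "acyl"]
    centers = {r.label: sidechain_center(r, frame) for r in members}
    out: set[tuple[str, str]] = set()
    for i, a in enumerate(members):
        for b in members[i + 1:]:
            if _adjacent(a, b, exclude_adjacent):
                continue
            if np.linalg.norm(centers[a.label] - centers[b.label]) <= cutoff:
                out.add(_ordered(a, b))
    return out


def _charged_atoms(residue: Residue) -> tuple[int, list[int]] | None:
    entry = chemistry.CHARGED_GROUPS.get(residue.name)
    if entry is None:
        return None
    sign, names = entry
    idx = residue.atom_indices(names)
    return (sign, idx) if idx else None


def salt_bridges(frame: np.ndarray, topology: Topology,
                 cutoff: float = 4.5,
                 exclude_adjacent: int = 1) -> set[tuple[str, str]]:
    """Oppositely charged residue pairs with any charged-group atoms within
    ``cutoff`` Å of each other."""
    charged = [(r, *cg) for r in topology.protein_residues
               if (cg := _charged_atoms(r)) is not None]
    out: set[tuple[str, str]] = set()
    for i, (a, sa, ia) in enumerate(charged):
        for b, sb, ib in charged[i + 1:]:
            if sa * sb >= 0 or _adjacent(a, b, exclude_adjacent):
                continue
            d = np.linalg.norm(frame[ia][:, None, :] - frame[ib][None, :, :],
                               axis=-1)
            if d.min() <= cutoff:
                out.add(_ordered(a, b))
    return out


def _donor_h_map(residue: Residue, frame: np.ndarray) -> dict[int, list[int]]:
    """Map donor heavy-atom global index -> bonded hydrogen global indices,
    found geometrically (H within 1.25 Å of the donor)."""
    names = chemistry.HBOND_DONORS.get(residue.name, ())
    donors = residue.atom_indices(names)
    hyd = [residue.atom_offset + i for i, a in enumerate(residue.atoms)
           if a.element == "H" and a.name not in chemistry.BACKBONE_ATOMS]
    out: dict[int, list[int]] = {}
    for d in donors:
        out[d] = [h for h in hyd
                  if np.linalg.norm(frame[d] - frame[h]) <= _H_BOND_RADIUS]
    return out


def hydrogen_bonds(frame: np.ndarray, topology: Topology,
                   d_cut: float = 3.5, angle_cut: float = 120.0,
                   exclude_adjacent: int = 1) -> set[tuple[str, str]]:
    """Side-chain–side-chain hydrogen bonds.

    A pair qualifies if some donor/acceptor combination has D···A distance
    ≤ ``d_cut`` and D–H···A angle ≥ ``angle_cut``. When the model carries no
    explicit hydrogens at all, the criterion degrades to distance-only with
    a logged warning; in a model that does have hydrogens, a donor lacking
    its hydrogen is skipped (warned once per residue).
    """
    residues = topology.protein_residues
    model_has_h = any(a.element == "H" and a.name not in chemistry.BACKBONE_ATOMS
                      for r in residues for a in r.atoms)
    donors_of = {r.label: _donor_h_map(r, frame) for r in residues}
    acceptors_of = {
        r.label: r.atom_indices(chemistry.HBOND_ACCEPTORS.get(r.name, ()))
        for r in residues}
    warned: set[str] = set()
    out: set[tuple[str, str]] = set()
    for i, a in enumerate(residues):
        for b in residues[i + 1:]:
            if _adjacent(a, b, exclude_adjacent):
                continue
            hit = False
            for da, ra in ((a, b), (b, a)):
                for d_idx, h_list in donors_of[da.label].items():
                    for acc_idx in acceptors_of[ra.label]:
                        if acc_idx == d_idx:
                            continue
                        dist = np.linalg.norm(frame[d_idx] - frame[acc_idx])
                        if dist > d_cut:
                            continue
                        if not h_list:
                            if da.label not in warned:
                                warned.add(da.label)
                                log.warning(
                                    "donor %s has no explicit hydrogen; %s",
                                    da.label,
                                    "using distance-only criterion"
                                    if not model_has_h else "skipping donor")
                            if not model_has_h:
                                hit = True
                        else:
                            for h_idx in h_list:
                                v1 = frame[d_idx] - frame[h_idx]
                                v2 = frame[acc_idx] - frame[h_idx]
                                cosang = np.dot(v1, v2) / (
                                    np.linalg.norm(v1) * np.linalg.norm(v2))
                                ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                                if ang >= angle_cut:
                                    hit = True
                                    break
                        if hit:
                            break
                    if hit:
                        break
                if hit:
                    break
            if hit:
                out.add(_ordered(a, b))
    return out


def ion_coordination(frame: np.ndarray, topology: Topology,
                     cutoff: float = 3.0) -> set[tuple[str, str]]:
    """(ion node, residue) pairs with any side-chain O/N within ``cutoff`` Å
    of the ion."""
    ions = [r for r in topology.special_nodes if r.kind == "ion"]
    out: set[tuple[str, str]] = set()
    for ion in ions:
        ion_pos = frame[ion.atom_offset]
        for res in topology.protein_residues:
            on_idx = [k for k in res.sidechain_indices()
                      if res.atoms[k - res.atom_offset].element in ("O", "N")]
            if not on_idx:
                continue
            if np.linalg.norm(frame[on_idx] - ion_pos, axis=1).min() <= cutoff:
                out.add(_ordered(ion, res))
    return out


def frame_interactions(frame: np.ndarray, topology: Topology,
                       params: Parameters) -> dict[str, set[tuple[str, str]]]:
    """All four detectors on one frame, keyed by interaction type."""
    hset = frozenset(params.hydrophobic_residues)
    return {
        "hydrophobic": hydrophobic_contacts(
            frame, topology, params.hydrophobic_cutoff, hset,
            params.exclude_adjacent),
        "salt-bridge": salt_bridges(
            frame, topology, params.salt_bridge_cutoff, params.exclude_adjacent),
        "hydrogen-bond": hydrogen_bonds(
            frame, topology, params.hbond_distance_cutoff,
            params.hbond_angle_cutoff, params.exclude_adjacent),
        "ion-coordination": ion_coordination(frame, topology, params.ion_cutoff),
    }


def persistence_table(ensemble: Ensemble,
                      params: Parameters | None = None) -> PersistenceTable:
    """Reduce per-frame detections to persistence percentages.

    persistence = 100 × (frames where the criterion holds) / frame count;
    pairs never satisfied in any frame are omitted from the table. The
    hydrophobic criterion is evaluated on vectorised centroid trajectories
    (it dominates the frame count on large ensembles); the remaining types
    go through the per-frame detectors.
    """
    params = params or Parameters()
    if ensemble.n_frames < 1:
        raise ValueError("empty ensemble")
    topo = ensemble.topology
    n = ensemble.n_frames
    counts: dict[tuple[str, str, str], int] = {}

    # hydrophobic: vectorised over frames
    hset = frozenset(params.hydrophobic_residues)
    members = [r for r in topo.residues if r.name in hset or r.kind == "acyl"]
    if members:
        centers = np.stack([_sidechain_center_traj(r, ensemble.coords)
                            for r in members], axis=1)  # (F, M, 3)
        for i, a in enumerate(members):
            for j in range(i + 1, len(members)):
                b = members[j]
                if _adjacent(a, b, params.exclude_adjacent):
                    continue
                d = np.linalg.norm(centers[:, i] - centers[:, j], axis=1)
                c = int(np.count_nonzero(d <= params.hydrophobic_cutoff))
                if c:
                    counts[(*_ordered(a, b), "hydrophobic")] = c

    for f in range(n):
        frame = ensemble.coords[f]
        dets = {
            "salt-bridge": salt_bridges(
                frame, topo, params.salt_bridge_cutoff, params.exclude_adjacent),
            "hydrogen-bond": hydrogen_bonds(
                frame, topo, params.hbond_distance_cutoff,
                params.hbond_angle_cutoff, params.exclude_adjacent),
            "ion-coordination": ion_coordination(frame, topo, params.ion_cutoff),
        }
        for itype, pairs in dets.items():
            for pair in pairs:
                key = (*pair, itype)
                counts[key] = counts.get(key, 0) + 1

    records = [InteractionRecord(i, j, t, 100.0 * c / n)
               for (i, j, t), c in sorted(counts.items())]
    return PersistenceTable(records, n, params)
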