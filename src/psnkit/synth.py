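"""Synthetic inputs with the statistical structure each pipeline stage assumes.

Real inputs to this pipeline are molecular-dynamics ensembles, which are
expensive and rarely shippable. Each generator here plants a known ground
truth that the corresponding analysis stage must recover:

* :func:`make_contact_ensemble` — frames in which specified residue pairs
  satisfy their interaction's geometric criterion in an independent
  Bernoulli fashion, so measured persistence has an exact binomial law;
* :func:`make_mode_ensemble` / :func:`make_replica_set` — Gaussian
  fluctuations along prescribed orthonormal modes, so PCA must recover the
  planted variances and directions, and replicas with a controllable mean
  offset probe the discriminant consistency test;
* :func:`make_msa` — alignments with a prescribed per-column conservation
  probability; and
* :func:`make_cluster_curve` — noisy logistic cluster-size curves with a
  known inflection for the threshold estimator.

All generators are deterministic given their seed; seeds are mandatory and
no global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import chemistry
from .io import Atom, Ensemble, MSA, Residue, Topology
from .psn import ClusterCurve


class GenerationError(ValueError):
    """A contact spec demands geometrically incompatible placements."""


# default criterion cutoffs used to realise planted geometry
_CUTOFFS = {"hydrophobic": 5.0, "salt-bridge": 4.5, "hydrogen-bond": 3.5,
            "ion-coordination": 3.0}
_LATTICE_SPACING = 100.0  # Å; far beyond every criterion cutoff
_OFF_MARGIN = 5.0         # OFF contacts sit cutoff + 5 Å apart


@dataclass(frozen=True)
class ContactSpec:
    """Planted contacts: (i, j, interaction type, target persistence %).

    Node indices are 1-based residue numbers. Per frame, each pair is ON
    with independent probability q/100 (Bernoulli occupancy).
    """

    pairs: tuple[tuple[int, int, str, float], ...]

    def __post_init__(self) -> None:
        seen = set()
        for i, j, itype, q in self.pairs:
            if i == j:
                raise ValueError("contact pair must join distinct nodes")
            if itype not in _CUTOFFS:
                raise ValueError(f"unknown interaction type {itype!r}")
            if not 0.0 <= q <= 100.0:
                raise ValueError("target persistence must be in [0, 100]")
            key = (min(i, j), max(i, j), itype)
            if key in seen:
                raise ValueError(f"duplicate pair {key}")
            seen.add(key)


@dataclass
class ModeSpec:
    """Planted essential dynamics: orthonormal Cα displacement modes with
    per-mode variances (Å²) about a mean structure."""

    mean: np.ndarray            # (N, 3) Cα mean structure
    modes: np.ndarray           # (K, 3N) orthonormal rows
    variances: np.ndarray       # (K,) Å²

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.modes = np.asarray(self.modes, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if self.modes.ndim != 2 or self.modes.shape[1] != self.mean.size:
            raise ValueError("modes must be (K, 3N) over the mean structure")
        if self.variances.shape != (self.modes.shape[0],):
            raise ValueError("one variance per mode required")
        if np.any(self.variances < 0):
            raise ValueError("variances must be >= 0")
        gram = self.modes @ self.modes.T
        if not np.allclose(gram, np.eye(self.modes.shape[0]), atol=1e-8):
            raise ValueError("modes must be mutually orthonormal")


def orthonormal_shape_modes(mean: np.ndarray, k: int) -> np.ndarray:
    """Deterministic orthonormal *shape* modes over a mean structure.

    Rigid-body superposition removes global translations and rotations, so
    planted modes must be internal deformations or the downstream PCA and
    replica diagnostics would see nothing. Candidates are polynomial
    displacement patterns along each axis; the six rigid modes (three
    translations, three infinitesimal rotations about the centroid) are
    projected out and the remainder Gram-Schmidt orthonormalised.
    """
    mean = np.asarray(mean, dtype=float)
    n = mean.shape[0]
    dim = 3 * n
    centred = mean - mean.mean(axis=0)
    rigid = []
    for ax in range(3):
        t = np.zeros((n, 3))
        t[:, ax] = 1.0
        rigid.append(t.ravel())
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        rigid.append(np.cross(np.broadcast_to(e, (n, 3)), centred).ravel())
    basis: list[np.ndarray] = []
    for b in rigid:
        for prev in basis:
            b = b - (b @ prev) * prev
        norm = np.linalg.norm(b)
        if norm > 1e-10:
            basis.append(b / norm)
    n_rigid = len(basis)
    modes: list[np.ndarray] = []
    s = np.linspace(-1.0, 1.0, n)
    degree, axis = 1, 0
    while len(modes) < k:
        cand = np.zeros((n, 3))
        cand[:, axis] = s ** degree
        v = cand.ravel()
        for prev in basis:
            v = v - (v @ prev) * prev
        norm = np.linalg.norm(v)
        axis += 1
        if axis == 3:
            axis = 0
            degree += 1
            if degree > dim:
                raise ValueError("cannot construct enough shape modes")
        if norm > 1e-8:
            v = v / norm
            basis.append(v)
            modes.append(v)
    del n_rigid
    return np.vstack(modes)


def _lattice(n: int) -> np.ndarray:
    """Sparse cubic lattice home positions, spacing beyond every cutoff."""
    side = int(np.ceil(n ** (1 / 3)))
    pts = []
    for a in range(side):
        for b in range(side):
            for c in range(side):
                pts.append((a, b, c))
                if len(pts) == n:
                    return np.array(pts, dtype=float) * _LATTICE_SPACING
    return np.array(pts, dtype=float) * _LATTICE_SPACING


# residue templates used to realise each interaction type; the "probe" atom
# is the one whose placement switches the criterion on and off
_TEMPLATES = {
    "hydrophobic": ("LEU", ("CD1",), "C"),
    "neg": ("ASP", ("OD1",), "O"),
    "pos": ("LYS", ("NZ",), "N"),
    "donor": ("SER", ("OG",), "O"),
    "acceptor": ("THR", ("OG1",), "O"),
    "coord": ("GLU", ("OE1",), "O"),
    "inert": ("GLY", (), ""),
}


def _role_pair(itype: str) -> tuple[str, str]:
    return {"hydrophobic": ("hydrophobic", "hydrophobic"),
            "salt-bridge": ("neg", "pos"),
            "hydrogen-bond": ("donor", "acceptor"),
            "ion-coordination": ("ion", "coord")}[itype]


def _build_residue(index: int, role: str, offset: int) -> Residue:
    if role == "ion":
        return Residue(index, "A", "CAL",
                       (Atom("CA", "CA", chemistry.element_mass("CA")),),
                       kind="ion", atom_offset=offset)
    name, extra, elem = _TEMPLATES[role]
    atoms = [Atom("N", "N", 14.007), Atom("CA", "C", 12.011),
             Atom("C", "C", 12.011), Atom("O", "O", 15.999)]
    for nm in extra:
        atoms.append(Atom(nm, elem, chemistry.element_mass(elem)))
    return Residue(index, "A", name, tuple(atoms), atom_offset=offset)


def make_contact_ensemble(n_residues: int, n_frames: int, spec: ContactSpec,
                          seed: int) -> Ensemble:
    """Frames in which each planted pair meets its criterion iff its
    Bernoulli(q/100) draw fires, and no unplanted pair ever does.

    Residues sit on a lattice whose spacing exceeds every cutoff; a pair's
    contact is realised by moving the *second* node of the pair next to the
    first ("anchor → mobile"). A node that would have to follow two anchors
    at once, or a cyclic anchor chain, raises :class:`GenerationError` — the
    planted graph must be a forest oriented away from its anchors (every
    matching or tree spec qualifies).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if seed is None:
        raise ValueError("seed is mandatory")
    max_node = max((max(i, j) for i, j, _, _ in spec.pairs), default=0)
    if max_node > n_residues:
        raise ValueError("spec references a node beyond n_residues")

    # assign a role to every node, catching contradictory type demands
    roles: dict[int, str] = {}
    for i, j, itype, _q in spec.pairs:
        ra, rb = _role_pair(itype)
        for node, role in ((i, ra), (j, rb)):
            if roles.setdefault(node, role) != role:
                raise GenerationError(
                    f"node {node} would need both role {roles[node]!r} and "
                    f"{role!r}")
    mobile_of: dict[int, tuple[int, str, float]] = {}
    for i, j, itype, q in spec.pairs:
        if j in mobile_of:
            raise GenerationError(
                f"node {j} is the mobile partner of two pairs; "
                "planted contacts must form an anchor-oriented forest")
        mobile_of[j] = (i, itype, q)
    # topological order over anchor chains; cycles are unrealisable
    order: list[int] = []
    state: dict[int, int] = {}

    def visit(node: int) -> None:
        if state.get(node) == 1:
            raise GenerationError("cyclic anchor chain in contact spec")
        if state.get(node) == 2:
            return
        state[node] = 1
        if node in mobile_of:
            visit(mobile_of[node][0])
        state[node] = 2
        order.append(node)

    for node in range(1, n_residues + 1):
        visit(node)

    # per-edge displacement directions: within one connected component of the
    # planted forest, edges take mutually orthogonal axes so that no
    # unplanted node pair can come within any cutoff (axis-aligned offsets
    # compose to separations >= sqrt(2) x cutoff). A component with more than
    # three edges cannot be realised this way.
    parent = {n: n for n in range(1, n_residues + 1)}

    def find(n: int) -> int:
        while parent[n] != n:
            parent[n] = parent[parent[n]]
            n = parent[n]
        return n

    for i, j, _t, _q in spec.pairs:
        parent[find(i)] = find(j)
    _axes = (np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]),
             np.array([0.0, 0.0, 1.0]))
    used: dict[int, int] = {}
    direction: dict[int, np.ndarray] = {}
    for i, j, _t, _q in spec.pairs:
        comp = find(i)
        k = used.get(comp, 0)
        if k >= len(_axes):
            raise GenerationError(
                "a planted component has more than three contacts; not "
                "realisable with orthogonal-axis placement")
        direction[j] = _axes[k]
        used[comp] = k + 1

    residues: list[Residue] = []
    offset = 0
    for idx in range(1, n_residues + 1):
        res = _build_residue(idx, roles.get(idx, "inert"), offset)
        residues.append(res)
        offset += res.n_atoms
    topo = Topology(residues)
    by_index = {r.index: r for r in residues}

    rng = np.random.default_rng(seed)
    draws = {(i, j): rng.random(n_frames) < q / 100.0
             for i, j, _t, q in spec.pairs}

    home = _lattice(n_residues)
    coords = np.zeros((n_frames, topo.n_atoms, 3))
    # residue-internal template offsets: probe atom 1.5 Å from the base
    for f in range(n_frames):
        base: dict[int, np.ndarray] = {}
        for node in order:
            if node in mobile_of:
                anchor, itype, _q = mobile_of[node]
                pair = next((i, j) for i, j, t, _ in spec.pairs
                            if j == node and i == anchor and t == itype)
                on = draws[pair][f]
                cutoff = _CUTOFFS[itype]
                gap = cutoff - 0.5 if on else cutoff + _OFF_MARGIN
                base[node] = base[anchor] + gap * direction[node]
            else:
                base[node] = home[node - 1]
        for res in residues:
            b = base[res.index]
            for k, atom in enumerate(res.atoms):
                # place every atom at the base; probe/side-chain atoms too,
                # so pair separation equals the criterion distance exactly
                coords[f, res.atom_offset + k] = b
    return Ensemble(topo, coords, label=f"synthetic-contacts-seed{seed}")


def make_mode_ensemble(spec: ModeSpec, n_frames: int, seed: int,
                       label: str | None = None) -> Ensemble:
    """Gaussian sampling along planted orthonormal Cα modes.

    frame_t = mean + Σ_k a_k(t) mode_k with a_k(t) ~ N(0, variance_k),
    independent across modes and frames; no global rotation or translation
    is added. The topology is Cα-only (one glycine per site).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    n_sites = spec.mean.shape[0]
    residues = []
    for i in range(n_sites):
        residues.append(Residue(i + 1, "A", "GLY",
                                (Atom("CA", "C", 12.011),), atom_offset=i))
    topo = Topology(residues)
    amps = rng.standard_normal((n_frames, spec.modes.shape[0]))
    amps *= np.sqrt(spec.variances)[None, :]
    disp = amps @ spec.modes  # (n_frames, 3N)
    coords = spec.mean.ravel()[None, :] + disp
    return Ensemble(topo, coords.reshape(n_frames, n_sites, 3),
                    label=label or f"synthetic-modes-seed{seed}")


def make_replica_set(spec: ModeSpec, n_replicas: int, n_frames: int,
                     offset: float, seed: int) -> list[Ensemble]:
    """Replicas sharing the planted modes, with replica r's mean shifted by
    ``r * offset`` Å along the first mode. ``offset=0`` gives statistically
    exchangeable replicas; a large offset makes them cleanly separable."""
    if n_replicas < 2:
        raise ValueError("n_replicas must be >= 2")
    out = []
    for r in range(n_replicas):
        shift = (r * offset) * spec.modes[0]
        shifted = ModeSpec(spec.mean + shift.reshape(spec.mean.shape),
                           spec.modes, spec.variances)
        out.append(make_mode_ensemble(shifted, n_frames, seed + r,
                                      label=f"replica-{r + 1}"))
    return out


_AA = sorted(chemistry.AMINO_ACIDS)


def make_msa(seed_sequence: str, n_sequences: int,
             conservation_profile: np.ndarray, seed: int) -> MSA:
    """Cluster alignment with planted per-column conservation.

    Each of the ``n_sequences`` non-seed sequences keeps the seed residue at
    column c with probability ``conservation_profile[c]`` and otherwise
    substitutes a uniformly random different residue. No gaps are
    introduced.
    """
    if not seed_sequence:
        raise ValueError("seed sequence is empty")
    profile = np.asarray(conservation_profile, dtype=float)
    if profile.shape != (len(seed_sequence),):
        raise ValueError("profile length must equal sequence length")
    if np.any((profile < 0) | (profile > 1)):
        raise ValueError("profile probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    seqs: list[tuple[str, str]] = [("seed", seed_sequence.upper())]
    for s in range(n_sequences):
        chars = []
        keep = rng.random(len(seed_sequence)) < profile
        for c, ch in enumerate(seed_sequence.upper()):
            if keep[c]:
                chars.append(ch)
            else:
                alternatives = [a for a in _AA if a != ch]
                chars.append(alternatives[rng.integers(len(alternatives))])
        seqs.append((f"homolog_{s + 1}", "".join(chars)))
    return MSA(seqs, seed_id="seed")


def make_cluster_curve(p0: float, steepness: float, y_max: float,
                       noise_sd: float, seed: int,
                       step: float = 0.1) -> ClusterCurve:
    """Logistic largest-cluster-size curve with known inflection ``p0``.

    y(p) = 1 + (y_max − 1)/(1 + exp(steepness (p − p0))) on the persistence
    grid, plus i.i.d. Gaussian noise of s.d. ``noise_sd``; the threshold
    estimator must recover ``p0``.
    """
    if not 0.0 < p0 < 100.0:
        raise ValueError("p0 must lie strictly inside (0, 100)")
    rng = np.random.default_rng(seed)
    n_grid = int(round(100.0 / step)) + 1
    t = np.round(np.arange(n_grid) * step, 10)
    y = 1.0 + (y_max - 1.0) / (1.0 + np.exp(
        np.clip(steepness * (t - p0), -500, 500)))
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
        y = np.clip(y, 0.0, None)
    return ClusterCurve(t, y)
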