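"""Geometric interaction criteria and persistence arithmetic.

Small hand-built topologies place atoms at exact distances so boundary
behaviour is unambiguous; randomized frames are checked against brute-force
all-pairs recomputation.
"""

import numpy as np
import pytest

from psnkit import chemistry
from psnkit.interactions import (hydrogen_bonds, hydrophobic_contacts,
                                 ion_coordination, persistence_table,
                                 salt_bridges, sidechain_center)
from psnkit.io import Atom, Ensemble, Parameters, Residue, Topology


def res(index, name, atoms, kind="residue", offset=0, chain="A"):
    return Residue(index, chain, name,
                   tuple(Atom(n, e, chemistry.element_mass(e))
                         for n, e in atoms), kind=kind, atom_offset=offset)


def chain_topology(specs):
    """specs: list of (name, [(atom, element), ...], kind) tuples."""
    residues = []
    offset = 0
    for i, (name, atoms, kind) in enumerate(specs, start=1):
        r = res(i, name, atoms, kind=kind, offset=offset)
        residues.append(r)
        offset += r.n_atoms
    return Topology(residues)


class TestSidechainCenter:
    def test_single_atom_is_identity(self):
        topo = chain_topology([("SER", [("CA", "C"), ("OG", "O")], "residue")])
        frame = np.array([[0.0, 0, 0], [1.0, 2, 3]])
        np.testing.assert_allclose(
            sidechain_center(topo.residues[0], frame), [1.0, 2, 3])

    def test_equal_masses_midpoint(self):
        topo = chain_topology([("LEU", [("CD1", "C"), ("CD2", "C")], "residue")])
        frame = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        np.testing.assert_allclose(
            sidechain_center(topo.residues[0], frame), [1.0, 0, 0])

    def test_mass_weighted_mean_matches_hand_computation(self):
        # CB (C) at origin, OG (O) at (2,0,0): centroid at 15.999*2/(12.011+15.999)
        topo = chain_topology([("SER", [("CB", "C"), ("OG", "O")], "residue")])
        frame = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        expected = 15.999 * 2.0 / (12.011 + 15.999)
        np.testing.assert_allclose(
            sidechain_center(topo.residues[0], frame), [expected, 0, 0],
            atol=1e-6)

    def test_glycine_uses_ca(self):
        topo = chain_topology([("GLY", [("N", "N"), ("CA", "C")], "residue")])
        frame = np.array([[9.0, 9, 9], [1.0, 1, 1]])
        np.testing.assert_allclose(
            sidechain_center(topo.residues[0], frame), [1.0, 1, 1])


class TestHydrophobic:
    def make(self, d):
        topo = chain_topology([
            ("LEU", [("CD1", "C")], "residue"),
            ("GLY", [("CA", "C")], "residue"),
            ("VAL", [("CG1", "C")], "residue")])
        frame = np.array([[0.0, 0, 0], [50.0, 0, 0], [d, 0, 0]])
        return topo, frame

    def test_inside_cutoff(self):
        topo, frame = self.make(4.9)
        assert hydrophobic_contacts(frame, topo) == {("A:L1", "A:V3")}

    def test_outside_cutoff(self):
        topo, frame = self.make(5.1)
        assert hydrophobic_contacts(frame, topo) == set()

    def test_boundary_inclusive(self):
        topo, frame = self.make(5.0)
        assert hydrophobic_contacts(frame, topo) == {("A:L1", "A:V3")}

    def test_random_frames_equal_bruteforce(self):
        rng = np.random.default_rng(5)
        names = ["LEU", "VAL", "ILE", "PHE", "MET", "ALA", "TRP", "PRO",
                 "GLY", "SER"]
        topo = chain_topology([(n, [("CB", "C")], "residue") for n in names])
        for _ in range(10):
            frame = rng.uniform(0, 15, size=(10, 3))
            got = hydrophobic_contacts(frame, topo, exclude_adjacent=0)
            want = set()
            hydro = [r for r in topo.residues
                     if r.name in chemistry.HYDROPHOBIC_RESIDUES]
            for i, a in enumerate(hydro):
                for b in hydro[i + 1:]:
                    if np.linalg.norm(frame[a.atom_offset]
                                      - frame[b.atom_offset]) <= 5.0:
                        want.add((a.label, b.label))
            assert got == want


class TestSaltBridge:
    def make(self, d):
        topo = chain_topology([
            ("ASP", [("CB", "C"), ("OD1", "O"), ("OD2", "O")], "residue"),
            ("GLY", [("CA", "C")], "residue"),
            ("LYS", [("NZ", "N")], "residue")])
        frame = np.zeros((5, 3))
        frame[1] = [0.0, 0, 0]     # OD1
        frame[2] = [0.0, 1, 0]     # OD2
        frame[3] = [50.0, 0, 0]    # GLY CA
        frame[4] = [d, 0, 0]       # NZ
        return topo, frame

    def test_within_cutoff(self):
        topo, frame = self.make(4.4)
        assert salt_bridges(frame, topo) == {("A:D1", "A:K3")}

    def test_outside_cutoff(self):
        topo, frame = self.make(4.6)
        assert salt_bridges(frame, topo) == set()

    def test_like_charges_excluded(self):
        topo = chain_topology([
            ("ASP", [("OD1", "O")], "residue"),
            ("GLY", [("CA", "C")], "residue"),
            ("GLU", [("OE1", "O")], "residue")])
        frame = np.array([[0.0, 0, 0], [50.0, 0, 0], [3.0, 0, 0]])
        assert salt_bridges(frame, topo) == set()


class TestHydrogenBond:
    def make(self, d_da, angle_deg):
        """SER donor with explicit HG; THR acceptor placed so the D-H...A
        angle equals ``angle_deg`` at D...A distance ``d_da``."""
        topo = chain_topology([
            ("SER", [("OG", "O"), ("HG", "H")], "residue"),
            ("GLY", [("CA", "C")], "residue"),
            ("THR", [("OG1", "O")], "residue")])
        d_pos = np.array([0.0, 0, 0])
        h_pos = np.array([1.0, 0, 0])
        theta = np.radians(180.0 - angle_deg)  # angle at H between D and A
        # place A at distance from H such that |D-A| = d_da
        # solve |h + r*(cos t, sin t, 0) - d| = d_da  with d at origin
        ct, st = np.cos(theta), np.sin(theta)
        # |(1 + r ct, r st)|^2 = d_da^2 -> r^2 + 2 r ct + 1 - d_da^2 = 0
        r = -ct + np.sqrt(ct * ct - 1 + d_da * d_da)
        a_pos = h_pos + r * np.array([ct, st, 0.0])
        frame = np.zeros((4, 3))
        frame[0], frame[1] = d_pos, h_pos
        frame[2] = [50.0, 0, 0]
        frame[3] = a_pos
        assert np.isclose(np.linalg.norm(a_pos - d_pos), d_da)
        return topo, frame

    def test_collinear_bond_included(self):
        topo, frame = self.make(3.0, 180.0)
        assert hydrogen_bonds(frame, topo) == {("A:S1", "A:T3")}

    def test_bent_bond_excluded(self):
        topo, frame = self.make(2.9, 90.0)
        assert hydrogen_bonds(frame, topo) == set()

    def test_angle_boundary_inclusive(self):
        topo, frame = self.make(3.0, 120.0)
        assert hydrogen_bonds(frame, topo) == {("A:S1", "A:T3")}

    def test_distance_only_fallback_without_hydrogen(self):
        topo = chain_topology([
            ("SER", [("OG", "O")], "residue"),
            ("GLY", [("CA", "C")], "residue"),
            ("THR", [("OG1", "O")], "residue")])
        frame = np.array([[0.0, 0, 0], [50.0, 0, 0], [3.2, 0, 0]])
        assert hydrogen_bonds(frame, topo) == {("A:S1", "A:T3")}

    def test_randomized_geometry_equals_bruteforce(self):
        rng = np.random.default_rng(8)
        topo = chain_topology([
            ("SER", [("OG", "O"), ("HG", "H")], "residue"),
            ("GLY", [("CA", "C")], "residue"),
            ("GLN", [("OE1", "O"), ("NE2", "N"), ("HE21", "H")], "residue")])
        for _ in range(30):
            frame = rng.uniform(0, 6, size=(6, 3))
            frame[1] = frame[0] + rng.normal(scale=0.3, size=3)
            frame[1] = frame[0] + (frame[1] - frame[0]) / np.linalg.norm(
                frame[1] - frame[0])  # H at 1.0 A from OG
            frame[5] = frame[4] + (frame[5] - frame[4]) / np.linalg.norm(
                frame[5] - frame[4])
            got = hydrogen_bonds(frame, topo, exclude_adjacent=0)

            def qualifies(d, h, a):
                if np.linalg.norm(d - a) > 3.5:
                    return False
                v1, v2 = d - h, a - h
                c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                return np.degrees(np.arccos(np.clip(c, -1, 1))) >= 120

            # donor OG(H) -> acceptor OE1; donor NE2(H) -> acceptor OG
            hit = (qualifies(frame[0], frame[1], frame[3])
                   or qualifies(frame[4], frame[5], frame[0]))
            assert got == ({("A:S1", "A:Q3")} if hit else set())


class TestIonCoordination:
    def make(self, d):
        topo = chain_topology([
            ("GLU", [("OE1", "O")], "residue"),
            ("CAL", [("CA", "CA")], "ion")])
        frame = np.array([[0.0, 0, 0], [d, 0, 0]])
        return topo, frame

    def test_within_cutoff(self):
        topo, frame = self.make(2.4)
        assert ion_coordination(frame, topo) == {("A:E1", "A:CAL2")}

    def test_outside_cutoff(self):
        topo, frame = self.make(3.5)
        assert ion_coordination(frame, topo) == set()

    def test_two_ions_three_glu_bruteforce(self):
        rng = np.random.default_rng(3)
        topo = chain_topology([
            ("GLU", [("OE1", "O")], "residue"),
            ("GLU", [("OE1", "O")], "residue"),
            ("GLU", [("OE1", "O")], "residue"),
            ("CAL", [("CA", "CA")], "ion"),
            ("CAL", [("CA", "CA")], "ion")])
        for _ in range(20):
            frame = rng.uniform(0, 8, size=(5, 3))
            got = ion_coordination(frame, topo)
            want = set()
            for ion in topo.residues[3:]:
                for glu in topo.residues[:3]:
                    if np.linalg.norm(frame[ion.atom_offset]
                                      - frame[glu.atom_offset]) <= 3.0:
                        a, b = sorted((ion, glu), key=lambda r: r.index)
                        want.add((a.label, b.label))
            assert got == want


class TestPersistenceTable:
    def build_ensemble(self, on_frames, total):
        topo = chain_topology([
            ("LEU", [("CD1", "C")], "residue"),
            ("GLY", [("CA", "C")], "residue"),
            ("VAL", [("CG1", "C")], "residue")])
        coords = np.zeros((total, 3, 3))
        coords[:, 1] = [50.0, 0, 0]
        for f in range(total):
            coords[f, 2] = [4.0 if f in on_frames else 20.0, 0, 0]
        return Ensemble(topo, coords)

    def test_fractional_persistence(self):
        ens = self.build_ensemble(set(range(37)), 100)
        table = persistence_table(ens, Parameters(exclude_adjacent=0))
        rec = next(r for r in table.records if r.type == "hydrophobic")
        assert rec.persistence == pytest.approx(37.0)

    def test_always_present(self):
        ens = self.build_ensemble(set(range(10)), 10)
        table = persistence_table(ens, Parameters(exclude_adjacent=0))
        assert table.records[0].persistence == 100.0

    def test_never_satisfied_pairs_omitted(self):
        ens = self.build_ensemble(set(), 10)
        table = persistence_table(ens, Parameters(exclude_adjacent=0))
        assert table.records == []

    def test_monotone_in_added_satisfying_frame(self):
        ens_a = self.build_ensemble({0, 1}, 4)
        ens_b = self.build_ensemble({0, 1, 4}, 5)
        pa = persistence_table(ens_a, Parameters(exclude_adjacent=0))
        pb = persistence_table(ens_b, Parameters(exclude_adjacent=0))
        assert pb.records[0].persistence >= pa.records[0].persistence

    def test_table_equals_per_frame_recomputation(self):
        """Vectorised reduction must equal exhaustive per-frame detection."""
        from psnkit.interactions import frame_interactions
        from psnkit.synth import ContactSpec, make_contact_ensemble
        spec = ContactSpec(((1, 3, "hydrophobic", 60.0),
                            (5, 7, "salt-bridge", 40.0),
                            (2, 9, "hydrogen-bond", 50.0)))
        ens = make_contact_ensemble(10, 50, spec, seed=21)
        params = Parameters(exclude_adjacent=0)
        table = persistence_table(ens, params)
        counts = {}
        for f in range(ens.n_frames):
            for itype, pairs in frame_interactions(ens.coords[f],
                                                   ens.topology,
                                                   params).items():
                for p in pairs:
                    counts[(*p, itype)] = counts.get((*p, itype), 0) + 1
        want = {k: 100.0 * v / ens.n_frames for k, v in counts.items()}
        got = {(r.node_i, r.node_j, r.type): r.persistence
               for r in table.records}
        assert got == pytest.approx(want)

    def test_symmetry_under_node_ordering(self):
        ens = self.build_ensemble(set(range(5)), 10)
        table = persistence_table(ens, Parameters(exclude_adjacent=0))
        for r in table.records:
            assert r.node_i < r.node_j or r.node_i.split(":")[0] <= \
                r.node_j.split(":")[0]
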