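"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the package's own code paths: shortest
paths are enumerated by exhaustive depth-first search, the global aligner is
a plain three-state dynamic program, and superposition is re-derived through
the quaternion (Horn) method.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest


# ---------------------------------------------------------------------------
# exhaustive path enumeration (oracle for the communication module)
# ---------------------------------------------------------------------------

def enumerate_shortest_paths(adj: dict, a, b) -> tuple[int | None, list[tuple]]:
    """All shortest simple paths by brute-force DFS over every simple path."""
    best: list[tuple] = []
    best_len = [None]

    def dfs(node, path):
        if best_len[0] is not None and len(path) - 1 > best_len[0]:
            return
        if node == b:
            length = len(path) - 1
            if best_len[0] is None or length < best_len[0]:
                best_len[0] = length
                best.clear()
            if length == best_len[0]:
                best.append(tuple(path))
            return
        for nxt in adj[node]:
            if nxt not in path:
                dfs(nxt, path + [nxt])

    dfs(a, [a])
    return best_len[0], sorted(best)


def oracle_sb(adj: dict, a, b, v) -> int:
    _, paths = enumerate_shortest_paths(adj, a, b)
    return sum(1 for p in paths if v in p[1:-1])


def random_connected_graph(rng: np.random.Generator, max_nodes: int = 8):
    """A random connected simple graph as an adjacency dict."""
    n = int(rng.integers(2, max_nodes + 1))
    nodes = [f"n{i}" for i in range(n)]
    adj = {u: set() for u in nodes}
    order = list(rng.permutation(n))
    for i in range(1, n):  # random spanning tree first
        u, v = nodes[order[i]], nodes[order[int(rng.integers(0, i))]]
        adj[u].add(v)
        adj[v].add(u)
    for u, v in itertools.combinations(nodes, 2):
        if v not in adj[u] and rng.random() < 0.3:
            adj[u].add(v)
            adj[v].add(u)
    return adj


# ---------------------------------------------------------------------------
# affine-gap global alignment oracle (three-state Gotoh DP, score only)
# ---------------------------------------------------------------------------

def gotoh_global_score(a: str, b: str, sub, gap_open: float,
                       gap_extend: float) -> float:
    """Optimal global affine-gap score; a length-L gap costs
    open + extend*(L-1)."""
    neg = float("-inf")
    la, lb = len(a), len(b)
    m = np.full((la + 1, lb + 1), neg)
    x = np.full((la + 1, lb + 1), neg)  # gap in b (a aligned to gap)
    y = np.full((la + 1, lb + 1), neg)  # gap in a
    m[0, 0] = 0.0
    for i in range(1, la + 1):
        x[i, 0] = -gap_open - gap_extend * (i - 1)
    for j in range(1, lb + 1):
        y[0, j] = -gap_open - gap_extend * (j - 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = sub[a[i - 1], b[j - 1]]
            m[i, j] = max(m[i - 1, j - 1], x[i - 1, j - 1],
                          y[i - 1, j - 1]) + s
            x[i, j] = max(m[i - 1, j] - gap_open, x[i - 1, j] - gap_extend,
                          y[i - 1, j] - gap_open)
            y[i, j] = max(m[i, j - 1] - gap_open, y[i, j - 1] - gap_extend,
                          x[i, j - 1] - gap_open)
    return float(max(m[la, lb], x[la, lb], y[la, lb]))


# ---------------------------------------------------------------------------
# quaternion (Horn) superposition oracle
# ---------------------------------------------------------------------------

def horn_superpose(mobile: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Optimal rigid superposition of ``mobile`` onto ``ref`` via the
    quaternion eigenvalue method; returns the transformed coordinates."""
    cm, cr = mobile.mean(axis=0), ref.mean(axis=0)
    p = mobile - cm
    q = ref - cr
    s = p.T @ q
    k = np.array([
        [s[0, 0] + s[1, 1] + s[2, 2], s[1, 2] - s[2, 1],
         s[2, 0] - s[0, 2], s[0, 1] - s[1, 0]],
        [s[1, 2] - s[2, 1], s[0, 0] - s[1, 1] - s[2, 2],
         s[0, 1] + s[1, 0], s[2, 0] + s[0, 2]],
        [s[2, 0] - s[0, 2], s[0, 1] + s[1, 0],
         -s[0, 0] + s[1, 1] - s[2, 2], s[1, 2] + s[2, 1]],
        [s[0, 1] - s[1, 0], s[2, 0] + s[0, 2],
         s[1, 2] + s[2, 1], -s[0, 0] - s[1, 1] + s[2, 2]]])
    evals, evecs = np.linalg.eigh(k)
    w, xq, yq, zq = evecs[:, np.argmax(evals)]
    rot = np.array([
        [1 - 2 * (yq * yq + zq * zq), 2 * (xq * yq - w * zq),
         2 * (xq * zq + w * yq)],
        [2 * (xq * yq + w * zq), 1 - 2 * (xq * xq + zq * zq),
         2 * (yq * zq - w * xq)],
        [2 * (xq * zq - w * yq), 2 * (yq * zq + w * xq),
         1 - 2 * (xq * xq + yq * yq)]])
    return p @ rot.T + cr


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture()
def pentapeptide_pdb(tmp_path):
    """A 3-model PDB of a 5-residue peptide plus a calcium HETATM."""
    residues = [("MET", 1), ("ALA", 2), ("LEU", 3), ("GLY", 4), ("SER", 5)]
    atoms = {"MET": ["N", "CA", "C", "O", "CB"],
             "ALA": ["N", "CA", "C", "O", "CB"],
             "LEU": ["N", "CA", "C", "O", "CB", "CD1"],
             "GLY": ["N", "CA", "C", "O"],
             "SER": ["N", "CA", "C", "O", "OG"]}
    lines = []
    rng = np.random.default_rng(0)
    for model in range(1, 4):
        lines.append(f"MODEL     {model:4d}")
        serial = 1
        for resname, resid in residues:
            for name in atoms[resname]:
                x, y, z = rng.normal(scale=5.0, size=3) + resid * 4.0
                elem = name[0]
                lines.append(
                    f"ATOM  {serial:5d}  {name:<3s} {resname:<3s} A{resid:4d}"
                    f"    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                    f"          {elem:>2s}")
                serial += 1
        lines.append(
            f"HETATM{serial:5d} CA   CAL A 101    "
            f"{1.0:8.3f}{2.0:8.3f}{3.0:8.3f}  1.00  0.00          CA")
        lines.append("ENDMDL")
    lines.append("END")
    path = tmp_path / "penta.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path
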