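"""Shortest-path communication metrics on the structure network.

Communication Robustness (CR) between two nodes is the number of distinct
shortest paths divided by their common length: many parallel routes make the
communication robust, long routes make it weak. Selective Betweenness (SB)
of a node for a pair is the number of shortest paths between the pair that
pass through that node; a pathway's cumulative SB sums SB over its
intermediate nodes, and the reported pathway(s) are those attaining the
maximal cumulative SB — all co-maximal pathways are kept, in lexicographic
node order.

The CR and SB definitions live in :func:`communication_robustness` and
:func:`selective_betweenness` only, so an alternative formula is a
one-point change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx


class PathExplosionError(RuntimeError):
    """More shortest paths than the materialisation cap allows."""


@dataclass
class CRResult:
    source: str
    target: str
    length: int | None   # shortest-path length in edges; None if disconnected
    n_paths: int | None  # number of distinct shortest paths
    cr: float | None     # n_paths / length; None iff no path exists

    @property
    def defined(self) -> bool:
        return self.cr is not None


@dataclass
class PathwayResult:
    source: str
    target: str
    paths: list[tuple[str, ...]]  # all co-maximal shortest paths
    score: int                    # the shared maximal cumulative SB
    length: int


def _check_pair(graph: nx.Graph, a: str, b: str) -> None:
    for node in (a, b):
        if node not in graph:
            raise KeyError(f"node {node!r} not in graph")
    if a == b:
        raise ValueError("source and target must differ")


def _bfs_counts(graph: nx.Graph, root: str) -> tuple[dict[str, int],
                                                     dict[str, int]]:
    """Breadth-first distances and shortest-path counts from ``root``."""
    dist = {root: 0}
    sigma = {root: 1}
    queue = [root]
    while queue:
        nxt: list[str] = []
        for u in queue:
            for v in graph[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    sigma[v] = 0
                    nxt.append(v)
                if dist[v] == dist[u] + 1:
                    sigma[v] += sigma[u]
        queue = nxt
    return dist, sigma


def shortest_path_count(graph: nx.Graph, a: str, b: str) -> tuple[int | None,
                                                                  int]:
    """(length, count) of shortest a–b paths via BFS DAG counting; length is
    ``None`` (count 0) when disconnected. Never materialises paths."""
    _check_pair(graph, a, b)
    dist, sigma = _bfs_counts(graph, a)
    if b not in dist:
        return None, 0
    return dist[b], sigma[b]


def all_shortest_paths(graph: nx.Graph, a: str, b: str,
                       max_paths: int = 100_000
                       ) -> tuple[int | None, list[tuple[str, ...]]]:
    """Every minimal-length simple path from a to b (empty when disconnected).

    Path materialisation is capped at ``max_paths``; exceeding the cap raises
    :class:`PathExplosionError` rather than exhausting memory.
    """
    length, count = shortest_path_count(graph, a, b)
    if length is None:
        return None, []
    if count > max_paths:
        raise PathExplosionError(
            f"{count} shortest paths between {a} and {b} exceed the cap "
            f"of {max_paths}")
    paths = [tuple(p) for p in nx.all_shortest_paths(graph, a, b)]
    paths.sort()
    return length, paths


def communication_robustness(graph: nx.Graph, a: str, b: str) -> CRResult:
    """CR(a, b) = (number of shortest paths) / (shortest-path length).

    Undefined (all fields ``None``-valued except the endpoints) when the two
    nodes are disconnected — no persistent route carries information.
    """
    length, count = shortest_path_count(graph, a, b)
    if length is None:
        return CRResult(a, b, None, None, None)
    return CRResult(a, b, length, count, count / length)


def selective_betweenness(graph: nx.Graph, a: str, b: str, v: str) -> int:
    """Number of shortest a–b paths passing through ``v`` (endpoints
    excluded); 0 when a and b are disconnected."""
    _check_pair(graph, a, b)
    if v in (a, b):
        raise ValueError("v must differ from both endpoints")
    if v not in graph:
        raise KeyError(f"node {v!r} not in graph")
    dist_a, sigma_a = _bfs_counts(graph, a)
    dist_b, sigma_b = _bfs_counts(graph, b)
    if b not in dist_a or v not in dist_a or v not in dist_b:
        return 0
    if dist_a[v] + dist_b[v] != dist_a[b]:
        return 0
    return sigma_a[v] * sigma_b[v]


def best_pathways(graph: nx.Graph, a: str, b: str,
                  max_paths: int = 100_000) -> PathwayResult:
    """Shortest path(s) with the highest cumulative Selective Betweenness.

    Every co-maximal pathway is reported, sorted lexicographically. Adjacent
    endpoints yield the single two-node path with score 0. Disconnected
    endpoints raise ``nx.NetworkXNoPath`` (distinct from the a = b error).
    """
    length, paths = all_shortest_paths(graph, a, b, max_paths=max_paths)
    if length is None:
        raise nx.NetworkXNoPath(f"no path between {a} and {b}")
    dist_a, sigma_a = _bfs_counts(graph, a)
    dist_b, sigma_b = _bfs_counts(graph, b)
    sb = {v: sigma_a[v] * sigma_b[v]
          for v in graph
          if v not in (a, b) and v in dist_a and v in dist_b
          and dist_a[v] + dist_b[v] == dist_a[b]}
    scored = [(sum(sb.get(v, 0) for v in p[1:-1]), p) for p in paths]
    best = max(s for s, _ in scored)
    winners = sorted(p for s, p in scored if s == best)
    return PathwayResult(a, b, winners, best, length)


def cr_table(graph: nx.Graph, sources: list[str], targets: list[str],
             top_k: int | None = None) -> list[dict]:
    """CR for every source × target pair, with a dense rank per source.

    Rows where source equals target are skipped with a notice field.
    ``top_k`` keeps only the k highest-CR defined rows per source (the
    reporting convention for interface residues). Unknown labels raise
    ``KeyError`` naming the offender.
    """
    for node in list(sources) + list(targets):
        if node not in graph:
            raise KeyError(f"node {node!r} not in graph")
    rows: list[dict] = []
    for s in sources:
        per_source: list[dict] = []
        for t in targets:
            if s == t:
                per_source.append({"source": s, "target": t, "length": None,
                                   "n_paths": None, "cr": None, "rank": None,
                                   "note": "source equals target; skipped"})
                continue
            r = communication_robustness(graph, s, t)
            per_source.append({"source": s, "target": t, "length": r.length,
                               "n_paths": r.n_paths, "cr": r.cr, "rank": None,
                               "note": "" if r.defined else "disconnected"})
        defined = sorted((row for row in per_source if row["cr"] is not None),
                         key=lambda row: -row["cr"])
        # dense rank: equal CR shares a rank
        rank, prev = 0, math.inf
        for row in defined:
            if row["cr"] < prev:
                rank += 1
                prev = row["cr"]
            row["rank"] = rank
        if top_k is not None:
            keep = {id(row) for row in defined[:top_k]}
            per_source = [row for row in per_source if id(row) in keep]
        rows.extend(per_source)
    return rows


def cr_table_to_tsv(rows: list[dict], path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\tlength\tn_paths\tCR\trank\tnote\n")
        for r in rows:
            cr = "" if r["cr"] is None else f"{r['cr']:.4f}"
            fh.write(f"{r['source']}\t{r['target']}\t"
                     f"{r['length'] if r['length'] is not None else ''}\t"
                     f"{r['n_paths'] if r['n_paths'] is not None else ''}\t"
                     f"{cr}\t{r['rank'] if r['rank'] is not None else ''}\t"
                     f"{r.get('note', '')}\n")
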