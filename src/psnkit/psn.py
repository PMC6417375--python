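"""Persistence-thresholded network construction.

The network keeps only interactions persistent enough to be structural
rather than transient. The threshold p_T is chosen by the hydrophobic
cluster-size criterion: the size of the largest connected component of the
hydrophobic-only graph is profiled on a fine persistence grid and the
inflection of its sigmoidal decay — located by a four-parameter logistic
least-squares fit — is rounded down to one decimal. All interactions at or
above p_T enter the unweighted graph; nodes with at least four connections
are hubs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.optimize import curve_fit

from .interactions import PersistenceTable


class DegenerateCurveError(ValueError):
    """Cluster curve carries no decay to locate a threshold on."""


class FitError(RuntimeError):
    """Logistic fit failed to converge."""


@dataclass
class ClusterCurve:
    """Largest hydrophobic-cluster size on a persistence grid."""

    thresholds: np.ndarray
    sizes: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.sizes = np.asarray(self.sizes, dtype=float)
        if self.thresholds.shape != self.sizes.shape:
            raise ValueError("thresholds and sizes must align")
        if np.any(self.sizes < 0):
            raise ValueError("cluster sizes must be non-negative")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("threshold\tlargest_cluster_size\n")
            for t, s in zip(self.thresholds, self.sizes):
                fh.write(f"{t:.1f}\t{s:g}\n")


@dataclass(frozen=True)
class HubRecord:
    node: str
    degree: int


@dataclass
class ThresholdFit:
    """Result of the logistic inflection fit: p_T plus diagnostics."""

    p_t: float
    p0: float
    steepness: float
    y_min: float
    y_max: float
    residual_norm: float


def cluster_curve(table: PersistenceTable, step: float = 0.1) -> ClusterCurve:
    """Largest connected-component size of the hydrophobic-only subgraph as a
    function of the persistence threshold, on a grid of ``step`` percent."""
    if not table.records:
        raise ValueError("empty persistence table")
    hydro = [(r.node_i, r.node_j, r.persistence) for r in table.records
             if r.type == "hydrophobic"]
    n_grid = int(round(100.0 / step)) + 1
    thresholds = np.round(np.arange(n_grid) * step, 10)
    sizes = np.zeros(n_grid)
    if hydro:
        # sweep from high threshold to low, adding edges as they qualify
        order = sorted(hydro, key=lambda e: -e[2])
        g: nx.Graph = nx.Graph()
        k = 0
        for gi in range(n_grid - 1, -1, -1):
            t = thresholds[gi]
            while k < len(order) and order[k][2] >= t:
                g.add_edge(order[k][0], order[k][1])
                k += 1
            sizes[gi] = max((len(c) for c in nx.connected_components(g)),
                            default=0)
    curve = ClusterCurve(thresholds, sizes)
    if np.any(np.diff(curve.sizes) > 0):
        raise AssertionError("cluster curve is not non-increasing")
    return curve


def _logistic(p, y_min, y_max, k, p0):
    return y_min + (y_max - y_min) / (1.0 + np.exp(np.clip(k * (p - p0),
                                                           -500, 500)))


def estimate_persistence_threshold(curve: ClusterCurve,
                                   rounding: str = "down") -> ThresholdFit:
    """Locate p_T at the inflection of the cluster-size decay.

    Fits y(p) = y_min + (y_max − y_min)/(1 + exp(k (p − p0))) by least
    squares, initialised from the curve quartiles, and reports p0 rounded
    down to one decimal (``rounding="nearest"`` switches to conventional
    rounding). A flat curve raises :class:`DegenerateCurveError`; a fit that
    does not converge raises :class:`FitError` with the residual norm.
    """
    t, y = curve.thresholds, curve.sizes
    y_span = float(y.max() - y.min())
    if y_span < 1e-9:
        raise DegenerateCurveError("cluster curve is flat; no decay to fit")
    mid = y.min() + 0.5 * y_span
    below = np.nonzero(y <= mid)[0]
    p0_init = float(t[below[0]]) if below.size else float(np.median(t))
    lo = y.min() + 0.25 * y_span
    hi = y.min() + 0.75 * y_span
    i_hi = np.nonzero(y <= hi)[0]
    i_lo = np.nonzero(y <= lo)[0]
    width = max(float(t[i_lo[0]] - t[i_hi[0]]) if i_hi.size and i_lo.size
                else 0.0, 1e-3)
    k_init = 4.0 / width  # logistic falls from 75% to 25% over ~2.2/k
    try:
        popt, _ = curve_fit(
            _logistic, t, y,
            p0=[float(y.min()), float(y.max()), k_init, p0_init],
            maxfev=10_000, xtol=1e-8, ftol=1e-8)
    except RuntimeError as exc:
        raise FitError(f"logistic fit did not converge: {exc}") from exc
    y_min_f, y_max_f, k_f, p0_f = (float(v) for v in popt)
    resid = float(np.linalg.norm(_logistic(t, *popt) - y))
    if not np.isfinite(resid) or resid > 0.5 * y_span * math.sqrt(len(t)):
        raise FitError(f"logistic fit rejected; residual norm {resid:.3g}")
    if rounding == "down":
        # guard against 36.8 being represented as 36.79999…
        p_t = math.floor(p0_f * 10 + 1e-6) / 10.0
    elif rounding == "nearest":
        p_t = round(p0_f, 1)
    else:
        raise ValueError(f"unknown rounding {rounding!r}")
    p_t = min(max(p_t, 0.0), 100.0)  # p_T is a persistence percentage
    return ThresholdFit(p_t=p_t, p0=p0_f, steepness=k_f, y_min=y_min_f,
                        y_max=y_max_f, residual_norm=resid)


def build_psn(table: PersistenceTable, p_t: float,
              nodes: list[str] | None = None) -> nx.Graph:
    """Unweighted network with an edge wherever any interaction type for the
    pair has persistence ≥ ``p_t``. ``nodes`` pre-populates isolated nodes so
    degrees are defined for every residue."""
    if not 0.0 <= p_t <= 100.0:
        raise ValueError("p_t must be in [0, 100]")
    g = nx.Graph(p_T=float(p_t))
    if nodes:
        g.add_nodes_from(nodes)
    best: dict[tuple[str, str], float] = {}
    for r in table.records:
        key = (r.node_i, r.node_j)
        best[key] = max(best.get(key, 0.0), r.persistence)
    for (a, b), p in best.items():
        if a != b and p >= p_t:
            g.add_edge(a, b, persistence=p)
    return g


def find_hubs(graph: nx.Graph, min_degree: int = 4) -> list[HubRecord]:
    """Nodes with degree ≥ ``min_degree``, ordered by degree descending then
    by node label."""
    hubs = [HubRecord(n, d) for n, d in graph.degree() if d >= min_degree]
    hubs.sort(key=lambda h: (-h.degree, h.node))
    return hubs


def hubs_to_tsv(hubs: list[HubRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("node\tdegree\n")
        for h in hubs:
            fh.write(f"{h.node}\t{h.degree}\n")


def annotate_hubs(graph: nx.Graph, min_degree: int = 4) -> nx.Graph:
    """Set per-node ``degree`` and ``hub`` attributes in place; returns graph."""
    for n, d in graph.degree():
        graph.nodes[n]["degree"] = int(d)
        graph.nodes[n]["hub"] = bool(d >= min_degree)
    return graph
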