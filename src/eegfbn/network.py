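"""Thresholded directed weighted graphs and their global metrics.

A functional brain network is built from a band-averaged PDC/DTF adjacency
matrix by keeping only edges whose value strictly exceeds a threshold
(default 0.3; weaker links are treated as spurious) while retaining the
weights.  Self-connections are always excluded.  Three global metrics
summarize each graph:

* mean degree D — average out-strength k_i = sum_j w_ij over nodes;
* global clustering coefficient C — average over nodes of
  C_i = 2 t_i / (kappa_i (kappa_i - 1)), with weighted triangle intensity
  t_i = 1/2 sum_{j != h} (w_ij w_ih w_jh)^(1/3) and kappa_i the number of
  distinct neighbors of i over retained edges (either direction);
  C_i = 0 when kappa_i < 2;
* characteristic path length L — mean directed shortest-path distance with
  edge distance 1/w, averaged over reachable ordered pairs (the count of
  unreachable pairs is reported alongside; a harmonic-mean "efficiency"
  variant is available for disconnected graphs).

With two connectivity methods (PDC, DTF), six bands and three metrics, one
epoch yields a 36-dimensional feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .connectivity import BandAdjacencySet

DEFAULT_TAU = 0.3

#: Metric order within each (method, band) block of the feature vector.
METRICS = ("L", "C", "D")


@dataclass
class DirectedWeightedGraph:
    """Directed graph with weights in (tau, 1], zero diagonal."""

    node_labels: list[str]
    weights: np.ndarray  # (N, N); weights[i, j] = edge i -> j
    threshold: float

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.weights))


@dataclass
class GraphFeatures:
    """Named 36-feature vector for one epoch, with disconnection counts."""

    names: list[str]
    values: np.ndarray
    unreachable: dict[str, int]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def threshold_graph(
    adj: np.ndarray,
    tau: float = DEFAULT_TAU,
    node_labels: Sequence[str] | None = None,
) -> DirectedWeightedGraph:
    """Keep entries strictly greater than ``tau``; zero the diagonal.

    Note the convention flip: adjacency entry (i, j) is the influence of
    source j on target i, so the graph edge j -> i gets weight adj[i, j].
    """
    a = np.asarray(adj, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    w = np.where(a.T > tau, a.T, 0.0)  # w[src, tgt]
    np.fill_diagonal(w, 0.0)
    labels = (
        list(node_labels)
        if node_labels is not None
        else [f"N{i + 1}" for i in range(a.shape[0])]
    )
    if len(labels) != a.shape[0]:
        raise ValueError("node_labels length does not match matrix")
    return DirectedWeightedGraph(labels, w, tau)


def _node_index(g: DirectedWeightedGraph, node: int | str) -> int:
    if isinstance(node, str):
        try:
            return g.node_labels.index(node)
        except ValueError:
            raise KeyError(
                f"unknown node {node!r}; nodes: {g.node_labels}"
            ) from None
    if not 0 <= node < g.n_nodes:
        raise KeyError(f"node index {node} out of range 0..{g.n_nodes - 1}")
    return node


def node_strength(g: DirectedWeightedGraph, node: int | str) -> float:
    """Out-strength k_i: sum of outgoing edge weights of node i."""
    return float(g.weights[_node_index(g, node)].sum())


def mean_degree(g: DirectedWeightedGraph) -> float:
    """D: average out-strength over all nodes."""
    return float(g.weights.sum() / g.n_nodes)


def clustering(g: DirectedWeightedGraph) -> tuple[np.ndarray, float]:
    """Weighted clustering: per-node C_i and global C (mean over nodes).

    Triangle intensity uses the geometric mean of the three weights on the
    directed triplet i->j, i->h, j->h, summed over ordered neighbor pairs
    with a factor 1/2; the denominator counts distinct neighbors kappa_i
    (connected to i by a retained edge in either direction).
    """
    w3 = np.cbrt(g.weights)
    # t_i = 1/2 * sum_{j,h} w3[i,j] w3[i,h] w3[j,h]; diagonal is zero so the
    # j==i, h==i and j==h terms vanish automatically.
    t = 0.5 * np.einsum("ij,jh,ih->i", w3, w3, w3)
    neighbor = (g.weights > 0) | (g.weights.T > 0)
    kappa = neighbor.sum(axis=1)
    ci = np.zeros(g.n_nodes)
    ok = kappa >= 2
    ci[ok] = 2.0 * t[ok] / (kappa[ok] * (kappa[ok] - 1.0))
    return ci, float(ci.mean())


def shortest_path_matrix(g: DirectedWeightedGraph) -> np.ndarray:
    """All-pairs directed shortest-path distances with d(u,v) = 1/w(u,v).

    Unreachable pairs are ``inf``; the diagonal is 0.
    """
    n = g.n_nodes
    src, tgt = np.nonzero(g.weights)
    dist = csr_matrix(
        (1.0 / g.weights[src, tgt], (src, tgt)), shape=(n, n)
    )
    return dijkstra(dist, directed=True)


def char_path_length(
    g: DirectedWeightedGraph,
    unreachable_policy: str = "exclude",
) -> tuple[float, int]:
    """L: mean shortest-path distance over ordered node pairs i != j.

    Returns ``(L, n_unreachable)``.  With ``unreachable_policy="exclude"``
    (default), unreachable pairs are dropped from the average and counted;
    L is NaN when no pair is reachable.  With ``"efficiency"``, L is the
    harmonic mean over all ordered pairs (unreachable pairs contribute
    zero inverse distance), which stays finite-or-inf but never NaN for
    n >= 2.
    """
    sp = shortest_path_matrix(g)
    off = ~np.eye(g.n_nodes, dtype=bool)
    d = sp[off]
    n_unreachable = int(np.sum(np.isinf(d)))
    if unreachable_policy == "exclude":
        finite = d[np.isfinite(d)]
        L = float(finite.mean()) if finite.size else float("nan")
    elif unreachable_policy == "efficiency":
        inv = np.where(np.isfinite(d), 1.0 / d, 0.0)
        mean_inv = inv.mean() if d.size else 0.0
        L = float(1.0 / mean_inv) if mean_inv > 0 else float("inf")
    else:
        raise ValueError("unreachable_policy must be 'exclude' or 'efficiency'")
    return L, n_unreachable


def graph_metrics(
    g: DirectedWeightedGraph, unreachable_policy: str = "exclude"
) -> tuple[float, float, float, int]:
    """(L, C, D, unreachable-pair count) for one graph."""
    L, n_unreach = char_path_length(g, unreachable_policy)
    _, C = clustering(g)
    D = mean_degree(g)
    return L, C, D, n_unreach


def feature_names(
    methods: Sequence[str] = ("PDC", "DTF"),
    bands: Sequence[str] = ("delta", "theta", "alpha", "beta", "gamma", "all"),
) -> list[str]:
    """Canonical feature order: method-major, then band, then L, C, D."""
    return [f"{m}_{b}_{met}" for m in methods for b in bands for met in METRICS]


def feature_vector(
    pdc_bands: BandAdjacencySet,
    dtf_bands: BandAdjacencySet,
    tau: float = DEFAULT_TAU,
    unreachable_policy: str = "exclude",
) -> GraphFeatures:
    """Assemble the per-epoch feature vector from both methods' band matrices.

    Order: PDC then DTF; within a method the band order of the adjacency
    set (delta, theta, alpha, beta, gamma, all by default); within a band
    L, C, D.
    """
    if list(pdc_bands.band_defs) != list(dtf_bands.band_defs):
        raise ValueError("PDC and DTF band definitions differ")
    if pdc_bands.channel_labels != dtf_bands.channel_labels:
        raise ValueError("PDC and DTF channel labels differ")
    names: list[str] = []
    values: list[float] = []
    unreachable: dict[str, int] = {}
    for bset in (pdc_bands, dtf_bands):
        for band, adj in bset.bands.items():
            g = threshold_graph(adj, tau, node_labels=bset.channel_labels)
            L, C, D, n_unreach = graph_metrics(g, unreachable_policy)
            prefix = f"{bset.method}_{band}"
            names += [f"{prefix}_{m}" for m in METRICS]
            values += [L, C, D]
            unreachable[prefix] = n_unreach
    return GraphFeatures(names, np.asarray(values), unreachable)


# ---------------------------------------------------------------------------
# Export

def edges_to_csv(g: DirectedWeightedGraph, path) -> None:
    """Write the retained edge list as CSV (source, target, weight)."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "target", "weight"])
        for i, j in zip(*np.nonzero(g.weights)):
            writer.writerow(
                [g.node_labels[i], g.node_labels[j], f"{g.weights[i, j]:.6f}"]
            )


def to_dot(g: DirectedWeightedGraph) -> str:
    """Graphviz DOT rendering with edge width proportional to weight."""
    lines = ["digraph fbn {"]
    for lab in g.node_labels:
        lines.append(f'  "{lab}";')
    for i, j in zip(*np.nonzero(g.weights)):
        w = g.weights[i, j]
        lines.append(
            f'  "{g.node_labels[i]}" -> "{g.node_labels[j]}"'
            f' [penwidth={1 + 4 * w:.2f}, label="{w:.2f}"];'
        )
    lines.append("}")
    return "\n".join(lines)
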