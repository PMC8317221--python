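"""Graph construction and metrics against brute-force oracles."""


import numpy as np
import pytest

from eegfbn.connectivity import BandAdjacencySet
from eegfbn.network import (
    DirectedWeightedGraph,
    char_path_length,
    clustering,
    feature_names,
    feature_vector,
    mean_degree,
    node_strength,
    shortest_path_matrix,
    threshold_graph,
)


def graph_from_weights(w: np.ndarray, tau: float = 0.0) -> DirectedWeightedGraph:
    """Build a graph directly from a source->target weight matrix."""
    w = np.asarray(w, dtype=float)
    labels = [f"N{i}" for i in range(w.shape[0])]
    return DirectedWeightedGraph(labels, w, tau)


# ---------------------------------------------------------------------------
# brute-force oracles

def brute_clustering(w: np.ndarray) -> float:
    n = w.shape[0]
    cs = []
    for i in range(n):
        t = 0.0
        for j in range(n):
            for h in range(n):
                if j == h or j == i or h == i:
                    continue
                t += (w[i, j] * w[i, h] * w[j, h]) ** (1.0 / 3.0)
        t *= 0.5
        neigh = {
            k for k in range(n) if k != i and (w[i, k] > 0 or w[k, i] > 0)
        }
        kappa = len(neigh)
        cs.append(2.0 * t / (kappa * (kappa - 1)) if kappa >= 2 else 0.0)
    return float(np.mean(cs))


def brute_shortest_paths(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest distances by enumerating every simple path."""
    n = w.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)

    def extend(node: int, target: int, visited: set, acc: float, best: list):
        if acc >= best[0]:
            return
        if node == target:
            best[0] = acc
            return
        for nxt in range(n):
            if w[node, nxt] > 0 and nxt not in visited:
                extend(nxt, target, visited | {nxt}, acc + 1.0 / w[node, nxt], best)

    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            best = [np.inf]
            extend(i, j, {i}, 0.0, best)
            dist[i, j] = best[0]
    return dist


# ---------------------------------------------------------------------------

class TestThresholdGraph:
    def test_all_below_threshold_gives_empty_graph(self):
        g = threshold_graph(np.full((4, 4), 0.2), tau=0.3)
        assert g.n_edges == 0

    def test_boundary_value_removed_strictly(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = 0.3  # exactly the threshold
        adj[1, 2] = 0.31
        g = threshold_graph(adj, tau=0.3)
        assert g.n_edges == 1
        # adjacency (i, j) means j -> i, so edge source is column 2
        assert g.weights[2, 1] == pytest.approx(0.31)

    def test_suprathreshold_weights_pass_through(self):
        adj = np.zeros((3, 3))
        adj[0, 1], adj[2, 0] = 0.9, 0.31
        g = threshold_graph(adj, tau=0.3)
        kept = sorted(g.weights[g.weights > 0])
        assert kept == pytest.approx([0.31, 0.9])

    def test_diagonal_always_zeroed(self):
        g = threshold_graph(np.full((3, 3), 0.9), tau=0.3)
        assert np.all(np.diag(g.weights) == 0)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            threshold_graph(np.zeros((2, 3)))

    @pytest.mark.parametrize("seed", range(5))
    def test_edge_count_monotone_in_threshold(self, seed, random_graph_weights):
        adj = random_graph_weights(seed)
        taus = np.linspace(0.0, 1.0, 11)
        counts = [threshold_graph(adj, t).n_edges for t in taus]
        degrees = [mean_degree(threshold_graph(adj, t)) for t in taus]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(degrees, degrees[1:]))


UNIT_TRIANGLE = np.array(
    [[0.0, 1.0, 1.0], [1.0, 0.0, 1.0], [1.0, 1.0, 0.0]]
)


class TestStrengthAndDegree:
    def test_isolated_node(self):
        g = graph_from_weights(np.zeros((3, 3)))
        assert node_strength(g, 0) == 0.0

    def test_unit_complete_triangle(self):
        g = graph_from_weights(UNIT_TRIANGLE)
        for i in range(3):
            assert node_strength(g, i) == 2.0
        assert mean_degree(g) == 2.0

    def test_star_with_half_weights(self):
        w = np.zeros((5, 5))
        w[0, 1:] = 0.5  # center -> 4 leaves
        g = graph_from_weights(w)
        assert node_strength(g, 0) == pytest.approx(2.0)
        for leaf in range(1, 5):
            assert node_strength(g, leaf) == 0.0

    def test_single_edge_mean_degree(self):
        w = np.zeros((6, 6))
        w[2, 4] = 0.7
        assert mean_degree(graph_from_weights(w)) == pytest.approx(0.7 / 6)

    def test_unknown_node_label(self):
        g = graph_from_weights(np.zeros((3, 3)))
        with pytest.raises(KeyError):
            node_strength(g, "FPZ")


class TestClustering:
    def test_unit_complete_triangle_is_fully_clustered(self):
        ci, c = clustering(graph_from_weights(UNIT_TRIANGLE))
        assert np.allclose(ci, 1.0)
        assert c == pytest.approx(1.0)

    def test_triangle_free_graph_has_zero_clustering(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 2] = w[2, 3] = 0.8  # directed path
        _, c = clustering(graph_from_weights(w))
        assert c == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_enumeration(self, seed, random_graph_weights):
        w = random_graph_weights(seed)
        _, c = clustering(graph_from_weights(w))
        assert c == pytest.approx(brute_clustering(w), abs=1e-12)


class TestPathLength:
    def test_unit_complete_graph_has_unit_paths(self):
        n = 5
        w = 1.0 - np.eye(n)
        L, unreachable = char_path_length(graph_from_weights(w))
        assert L == pytest.approx(1.0)
        assert unreachable == 0

    def test_three_node_chain(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 2] = 0.5
        L, unreachable = char_path_length(graph_from_weights(w))
        # l01 = 2, l12 = 2, l02 = 4 -> mean 8/3; reverse pairs unreachable
        assert L == pytest.approx(8.0 / 3.0)
        assert unreachable == 3

    def test_fully_disconnected_graph_is_undefined(self):
        L, unreachable = char_path_length(graph_from_weights(np.zeros((4, 4))))
        assert np.isnan(L)
        assert unreachable == 12

    def test_efficiency_policy_harmonic_mean(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 2] = 0.5
        L, _ = char_path_length(graph_from_weights(w), "efficiency")
        # inverse distances: 1/2, 1/2, 1/4 and three zeros -> mean 5/24
        assert L == pytest.approx(24.0 / 5.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_enumeration(self, seed, random_graph_weights):
        w = random_graph_weights(seed, density=0.35)
        sp = shortest_path_matrix(graph_from_weights(w))
        brute = brute_shortest_paths(w)
        both_finite = np.isfinite(sp) & np.isfinite(brute)
        assert np.array_equal(np.isfinite(sp), np.isfinite(brute))
        assert np.allclose(sp[both_finite], brute[both_finite], atol=1e-12)


class TestScaleBehavior:
    @pytest.mark.parametrize("c", [0.25, 0.5, 0.9])
    def test_uniform_weight_scaling(self, c, random_graph_weights):
        w = random_graph_weights(3)
        g, gs = graph_from_weights(w), graph_from_weights(c * w)
        assert mean_degree(gs) == pytest.approx(c * mean_degree(g))
        _, cg = clustering(g)
        _, cgs = clustering(gs)
        assert cgs == pytest.approx(c * cg)
        L, _ = char_path_length(g)
        Ls, _ = char_path_length(gs)
        assert Ls == pytest.approx(L / c)


def _band_set(method: str, matrices: dict) -> BandAdjacencySet:
    names = list(matrices)
    defs = {name: (float(i), float(i + 1)) for i, name in enumerate(names)}
    labels = [f"E{i}" for i in range(next(iter(matrices.values())).shape[0])]
    return BandAdjacencySet(method, matrices, defs, labels)


class TestFeatureVector:
    def _sets(self, rng):
        bands = ["delta", "theta", "alpha", "beta", "gamma", "all"]
        mk = lambda: {b: rng.uniform(0, 1, (8, 8)) for b in bands}
        return _band_set("PDC", mk()), _band_set("DTF", mk())

    def test_vector_has_36_named_features(self):
        rng = np.random.default_rng(0)
        p, d = self._sets(rng)
        feats = feature_vector(p, d)
        assert len(feats.values) == 36
        assert feats.names == feature_names()
        assert feats.names[0] == "PDC_delta_L"
        assert feats.names[-1] == "DTF_all_D"

    def test_all_zero_adjacency(self):
        bands = ["delta", "theta", "alpha", "beta", "gamma", "all"]
        zero = {b: np.zeros((8, 8)) for b in bands}
        feats = feature_vector(_band_set("PDC", dict(zero)), _band_set("DTF", dict(zero)))
        by_name = feats.as_dict()
        for name, v in by_name.items():
            if name.endswith("_L"):
                assert np.isnan(v)
            else:
                assert v == 0.0

    def test_node_relabeling_invariance(self):
        rng = np.random.default_rng(1)
        p, d = self._sets(rng)
        perm = rng.permutation(8)
        pp = BandAdjacencySet(
            "PDC",
            {b: m[np.ix_(perm, perm)] for b, m in p.bands.items()},
            p.band_defs,
            [p.channel_labels[i] for i in perm],
        )
        dp = BandAdjacencySet(
            "DTF",
            {b: m[np.ix_(perm, perm)] for b, m in d.bands.items()},
            d.band_defs,
            [d.channel_labels[i] for i in perm],
        )
        a = feature_vector(p, d).values
        b = feature_vector(pp, dp).values
        assert np.allclose(a, b, equal_nan=True)

    def test_band_mismatch_rejected(self):
        rng = np.random.default_rng(2)
        p, _ = self._sets(rng)
        other = _band_set("DTF", {"delta": np.zeros((8, 8))})
        with pytest.raises(ValueError, match="band"):
            feature_vector(p, other)


# ---------------------------------------------------------------------------
# property tests

from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000), tau_lo=st.floats(0.0, 0.5), delta=st.floats(0.0, 0.5))
def test_raising_threshold_never_adds_edges_or_degree(seed, tau_lo, delta):
    rng = np.random.default_rng(seed)
    adj = rng.uniform(0, 1, (6, 6))
    lo, hi = threshold_graph(adj, tau_lo), threshold_graph(adj, tau_lo + delta)
    assert hi.n_edges <= lo.n_edges
    assert mean_degree(hi) <= mean_degree(lo) + 1e-12
    # every surviving edge keeps its original weight
    kept = hi.weights > 0
    assert np.allclose(hi.weights[kept], lo.weights[kept])


@settings(derandomize=True, max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000), c=st.floats(0.05, 1.0))
def test_metric_scaling_laws_hold_for_any_factor(seed, c):
    rng = np.random.default_rng(seed)
    w = rng.uniform(0.1, 1.0, (6, 6)) * (rng.random((6, 6)) < 0.6)
    np.fill_diagonal(w, 0.0)
    g, gs = graph_from_weights(w), graph_from_weights(c * w)
    assert mean_degree(gs) == pytest.approx(c * mean_degree(g))
    _, cg = clustering(g)
    _, cgs = clustering(gs)
    assert cgs == pytest.approx(c * cg)
    L, u = char_path_length(g)
    Ls, us = char_path_length(gs)
    assert u == us
    if np.isfinite(L):
        assert Ls == pytest.approx(L / c)
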