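"""Network construction: thresholding, fixed average degree, multilayer
MST, geometric reference, and interval threshold carry-over."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import isletnet as isn
from isletnet.exceptions import ConstructionError, InputError


def sim_from_values(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"c{i:03d}" for i in range(values.shape[0])]
    return isn.SimilarityMatrix(values=values, method="correlation", cell_ids=ids)


def random_sim(n, seed, low=-0.5, high=1.0):
    rng = np.random.default_rng(seed)
    v = rng.uniform(low, high, size=(n, n))
    return sim_from_values((v + v.T) / 2)


class TestFixedThreshold:
    def test_three_cell_example(self):
        S = sim_from_values([[0, 0.9, 0.7], [0.9, 0, 0.4], [0.7, 0.4, 0]], ids=list("abc"))
        net = isn.fixed_threshold_network(S, 0.75)
        assert net.edge_set() == {frozenset(("a", "b"))}

    def test_all_below_threshold_empty(self):
        net = isn.fixed_threshold_network(random_sim(10, 0, 0.0, 0.5), 0.9)
        assert net.n_edges == 0

    def test_very_low_threshold_complete_graph(self):
        net = isn.fixed_threshold_network(random_sim(10, 0), -2.0)
        assert net.k_avg == 9

    def test_strict_inequality_excludes_ties(self):
        S = sim_from_values([[0, 0.8], [0.8, 0]])
        assert isn.fixed_threshold_network(S, 0.8).n_edges == 0

    def test_sentinel_pairs_never_connected(self):
        v = np.array([[0, np.nan], [np.nan, 0]])
        assert isn.fixed_threshold_network(sim_from_values(v), -5.0).n_edges == 0

    def test_threshold_monotonicity_edge_containment(self):
        S = random_sim(30, 2)
        prev = None
        for th in [0.9, 0.6, 0.3, 0.0, -0.3]:
            edges = isn.fixed_threshold_network(S, th).edge_set()
            if prev is not None:
                assert prev <= edges  # lower threshold only adds edges
            prev = edges


class TestFixedKavg:
    def test_target_reached_on_simulator_matrix(self, fast_similarity, islet):
        net = isn.fixed_kavg_network(fast_similarity, 8.0, tol=0.2)
        assert abs(net.k_avg - 8.0) <= 0.2
        assert net.construction["threshold_used"] is not None

    def test_target_n_minus_one_gives_complete_graph(self):
        S = random_sim(12, 3)
        net = isn.fixed_kavg_network(S, 11.0, tol=0.1)
        assert net.n_edges == 12 * 11 // 2

    def test_threshold_monotone_in_target(self):
        S = random_sim(40, 4)
        th_low = isn.fixed_kavg_network(S, 4.0).construction["threshold_used"]
        th_high = isn.fixed_kavg_network(S, 12.0).construction["threshold_used"]
        assert th_low >= th_high

    def test_unreachable_target_raises(self):
        v = np.full((6, 6), np.nan)
        v[0, 1] = v[1, 0] = 0.9
        with pytest.raises(ConstructionError, match="achievable"):
            isn.fixed_kavg_network(sim_from_values(v), 4.0)


class TestToDistance:
    def test_closed_form_values(self):
        S = sim_from_values([[0, 1.0, 0.0], [1.0, 0, -1.0], [0.0, -1.0, 0]])
        D = isn.to_distance(S)
        assert D.values[0, 1] == 0.0
        assert D.values[0, 2] == 2.0
        assert D.values[1, 2] == 4.0

    def test_sentinels_become_infinite(self):
        v = np.array([[0, np.nan], [np.nan, 0]])
        assert np.isinf(isn.to_distance(sim_from_values(v)).values[0, 1])


class TestMultilayerMST:
    def test_single_mst_edge_count(self):
        net = isn.multilayer_mst_network(random_sim(50, 5), n_layers=1)
        assert net.n_edges == 49
        assert nx.is_connected(net.graph)

    def test_single_mst_matches_networkx_oracle(self):
        # independent oracle: networkx MST on the same distances
        S = random_sim(30, 6)
        D = isn.to_distance(S)
        g = nx.Graph()
        ids = S.cell_ids
        for i in range(30):
            for j in range(i + 1, 30):
                g.add_edge(ids[i], ids[j], weight=D.values[i, j])
        want = {frozenset(e) for e in nx.minimum_spanning_tree(g).edges}
        got = isn.multilayer_mst_network(S, n_layers=1).edge_set()
        assert got == want

    def test_four_layers_on_200_nodes(self):
        net = isn.multilayer_mst_network(random_sim(200, 7), n_layers=4)
        assert net.n_edges == 4 * 199 == 796
        assert net.k_avg == pytest.approx(7.96)
        assert round(net.k_avg) == 8

    def test_layers_edge_disjoint_acyclic_spanning(self):
        S = random_sim(40, 8)
        net = isn.multilayer_mst_network(S, n_layers=3)
        layers = net.construction["layers"]
        seen = set()
        for layer in layers:
            edges = {frozenset(e) for e in layer}
            assert len(edges) == 39
            assert not (edges & seen)
            seen |= edges
            sub = nx.Graph(list(layer))
            assert nx.is_forest(sub) and nx.is_connected(sub)
        assert net.degrees().min() >= 3

    def test_monotone_transform_invariance(self):
        """sqrt(2(1-SC)) and 2(1-SC) give identical MSTs for distinct weights."""
        for seed in range(10):
            S = random_sim(25, 100 + seed)
            base = isn.multilayer_mst_network(S, n_layers=2).edge_set()
            # strictly monotone transform of the similarity scale:
            # SC' = 1 - (1 - SC)^2 / 2 maps D = 2(1-SC) to D' = (1-SC)^2 = (D/2)^2
            v2 = 1.0 - 0.5 * (1.0 - S.values) ** 2
            transformed = isn.multilayer_mst_network(sim_from_values(v2), n_layers=2).edge_set()
            assert transformed == base

    def test_disconnection_reports_completed_layers(self):
        # only a single spanning path of finite distances: layer 2 must fail
        n = 6
        v = np.full((n, n), np.nan)
        for i in range(n - 1):
            v[i, i + 1] = v[i + 1, i] = 0.9
        with pytest.raises(ConstructionError, match="1 full layer"):
            isn.multilayer_mst_network(sim_from_values(v), n_layers=2)


class TestGeometric:
    def test_unit_square_sides_only(self):
        coords = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        net = isn.geometric_network(coords, mode="distance", value=1.0)
        assert net.n_edges == 4
        lengths = isn.edge_length_distribution(net)
        assert np.allclose(lengths, 1.0)

    def test_large_threshold_complete_graph(self):
        coords = np.random.default_rng(0).uniform(0, 50, size=(8, 2))
        net = isn.geometric_network(coords, mode="distance", value=1e6)
        assert net.n_edges == 8 * 7 // 2

    def test_target_kavg_on_simulator_layout(self, islet):
        net = isn.geometric_network(
            islet.recording.coords, cell_ids=islet.recording.cell_ids,
            mode="target_kavg", value=8.0, tol=0.2,
        )
        assert abs(net.k_avg - 8.0) <= 0.2


class TestIntervalCarryover:
    def test_identical_matrices_identical_networks(self, random_similarity):
        n1, n2 = isn.interval_carryover_networks(random_similarity, random_similarity, 8.0)
        assert isn.nsi(n1, n2) == 1.0

    def test_coupling_shift_changes_density(self):
        """Raising (lowering) similarities in interval 2 raises (lowers)
        the carried-threshold network's density."""
        S1 = random_sim(40, 9, low=0.0, high=0.9)
        up = np.clip(S1.values + 0.05, None, 1.0)
        down = S1.values - 0.05
        S_up = sim_from_values(up)
        S_down = sim_from_values(down)
        n1, n2 = isn.interval_carryover_networks(S1, S_up, 8.0)
        assert n2.k_avg > n1.k_avg
        n1b, n2b = isn.interval_carryover_networks(S1, S_down, 8.0)
        assert n2b.k_avg < n1b.k_avg

    def test_cell_mismatch_rejected(self):
        S1 = random_sim(5, 0)
        S2 = isn.SimilarityMatrix(
            values=S1.values.copy(), method="correlation", cell_ids=list("vwxyz")
        )
        with pytest.raises(InputError):
            isn.interval_carryover_networks(S1, S2)


@settings(max_examples=25, derandomize=True)
@given(st.integers(0, 10_000), st.integers(5, 20))
def test_mst_invariance_under_sqrt_transform(seed, n):
    """Property: replacing D by sqrt(D) never changes the MST edge set."""
    S = random_sim(n, seed)
    base = isn.multilayer_mst_network(S, n_layers=1).edge_set()
    v2 = 1.0 - np.sqrt(np.maximum(2.0 * (1.0 - S.values), 0.0)) / 2.0
    assert isn.multilayer_mst_network(sim_from_values(v2), n_layers=1).edge_set() == base


def test_density_increases_with_coupling_strength():
    """Stronger intercellular coupling (less conduction jitter) yields
    denser fixed-threshold networks."""
    kavgs = []
    for jitter in (3.0, 1.5, 0.5):
        islet = isn.generate_islet(isn.IsletSimConfig(seed=5, wave_jitter_sd_s=jitter))
        fast = isn.bandpass_filter(islet.recording, isn.FilterSpec.named("fast"))
        S = isn.pearson_matrix(fast)
        kavgs.append(isn.fixed_threshold_network(S, 0.7).k_avg)
    assert kavgs[0] <= kavgs[1] <= kavgs[2]
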