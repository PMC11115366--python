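"""Network metrics: closed forms, brute-force oracles, small-world
behavior, hubs, and the degree-activity relation."""

import itertools

import networkx as nx
import numpy as np
import pytest

import isletnet as isn
from isletnet.metrics import nearest_neighbor_scale


def net_from_graph(g, coords=None):
    ids = [f"c{i:03d}" for i in sorted(g.nodes)]
    relabel = {n: f"c{n:03d}" for n in g.nodes}
    return isn.FunctionalNetwork(
        graph=nx.relabel_nodes(g, relabel), cell_ids=ids, coords=coords
    )


def efficiency_oracle(g):
    """Brute-force all-pairs shortest paths via Floyd-Warshall on a dense
    matrix (independent of networkx path routines)."""
    nodes = sorted(g.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for u, v in g.edges:
        d[idx[u], idx[v]] = d[idx[v], idx[u]] = 1.0
    for k in range(n):
        d = np.minimum(d, d[:, k][:, None] + d[k, :][None, :])
    iu = np.triu_indices(n, 1)
    with np.errstate(divide="ignore"):
        eff = np.where(np.isinf(d[iu]), 0.0, 1.0 / d[iu]).mean() if n > 1 else 0.0
    return eff, d


def lavg_oracle(d):
    """Average shortest path lengths of all maximum-size components (ties
    possible), from the distance matrix.  Empty list when the largest
    component is a single node."""
    finite = np.isfinite(d)
    comp_sizes = finite.sum(axis=1)
    top = comp_sizes.max()
    if top < 2:
        return []
    out = []
    seen = set()
    for row in np.flatnonzero(comp_sizes == top):
        members = tuple(np.flatnonzero(finite[row]))
        if members in seen:
            continue
        seen.add(members)
        sub = d[np.ix_(members, members)]
        iu = np.triu_indices(len(members), 1)
        out.append(sub[iu].mean())
    return out


class TestClosedForms:
    def test_complete_graph_k5(self):
        m = isn.compute_metrics(net_from_graph(nx.complete_graph(5)), sw_randomizations=0)
        assert m.k_avg == 4
        assert m.C_avg == 1
        assert m.E == 1
        assert m.S_max == 1
        assert m.L_avg == 1

    def test_two_disjoint_triangles(self):
        g = nx.Graph([(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3)])
        m = isn.compute_metrics(net_from_graph(g), sw_randomizations=0)
        assert m.S_max == 0.5
        assert m.Q == pytest.approx(0.5)  # two-triangle partition
        assert len(m.partition) == 2

    def test_path_on_three_nodes(self):
        g = nx.path_graph(3)
        m = isn.compute_metrics(net_from_graph(g), sw_randomizations=0)
        assert m.C_avg == 0
        assert m.E == pytest.approx(5 / 6)  # pair distances 1, 1, 2
        assert m.L_avg == pytest.approx(4 / 3)

    def test_degree_sum_is_twice_edges(self, fast_similarity):
        net = isn.fixed_kavg_network(fast_similarity, 8.0)
        m = isn.compute_metrics(net, sw_randomizations=0)
        assert m.degree_list.sum() == 2 * net.n_edges

    def test_empty_graph_conventions(self):
        g = nx.empty_graph(4)
        m = isn.compute_metrics(net_from_graph(g), sw_randomizations=5)
        assert m.C_avg == 0 and m.E == 0 and np.isnan(m.SW)

    def test_modularity_recomputable_from_partition(self, fast_similarity):
        net = isn.fixed_kavg_network(fast_similarity, 8.0)
        m = isn.compute_metrics(net, sw_randomizations=0)
        assert nx.community.modularity(net.graph, m.partition) == pytest.approx(m.Q)


class TestPathOracles:
    def test_atlas_graphs_up_to_six_nodes(self):
        """E and L_avg agree with the Floyd-Warshall oracle on every
        non-isomorphic graph with 2-6 nodes."""
        from networkx.generators.atlas import graph_atlas_g

        for g in graph_atlas_g():
            if g.number_of_nodes() < 2 or g.number_of_nodes() > 6:
                continue
            m = isn.compute_metrics(net_from_graph(g), sw_randomizations=0)
            e_want, d = efficiency_oracle(g)
            assert m.E == pytest.approx(e_want, abs=1e-12)
            l_want = lavg_oracle(d)
            if not l_want:
                assert np.isnan(m.L_avg)
            else:
                assert any(abs(m.L_avg - l) < 1e-12 for l in l_want)

    def test_random_graphs_up_to_twelve_nodes(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = int(rng.integers(4, 13))
            p = float(rng.uniform(0.1, 0.7))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31 - 1)))
            m = isn.compute_metrics(net_from_graph(g), sw_randomizations=0)
            e_want, d = efficiency_oracle(g)
            assert m.E == pytest.approx(e_want, abs=1e-12)
            l_want = lavg_oracle(d)
            if l_want:
                assert any(abs(m.L_avg - l) < 1e-12 for l in l_want)


class TestSmallWorld:
    def test_random_graph_sw_near_one(self):
        """An Erdos-Renyi graph is its own reference: SW ~ 1."""
        sws = []
        for seed in range(20):
            g = nx.gnm_random_graph(60, 240, seed=seed)
            m = isn.compute_metrics(net_from_graph(g), sw_randomizations=10, seed=seed)
            sws.append(m.SW)
        assert np.nanmean(sws) == pytest.approx(1.0, abs=0.2)

    def test_ring_lattice_with_shortcuts_sw_above_one(self):
        g = nx.watts_strogatz_graph(100, 8, 0.1, seed=2)
        m = isn.compute_metrics(net_from_graph(g), sw_randomizations=10, seed=0)
        assert m.SW > 1

    def test_degree_preserving_reference_flag(self):
        g = nx.watts_strogatz_graph(60, 6, 0.2, seed=1)
        m = isn.compute_metrics(net_from_graph(g), sw_randomizations=5, seed=0,
                                sw_reference="degree")
        assert np.isfinite(m.SW)


class TestEdgeLengths:
    def test_two_cells_single_edge(self):
        g = nx.Graph([(0, 1)])
        coords = np.array([[0.0, 0.0], [10.0, 0.0]])
        net = net_from_graph(g, coords=coords)
        assert isn.edge_length_distribution(net) == pytest.approx([10.0])

    def test_grid_adjacent_edge_relative_length_below_one(self):
        # 8-neighbor mean on a unit grid includes diagonals sqrt(2),
        # so an adjacent edge has relative length < 1
        xs, ys = np.meshgrid(np.arange(5.0), np.arange(5.0))
        coords = np.column_stack([xs.ravel(), ys.ravel()])
        g = nx.Graph([(0, 1)])  # one horizontal unit edge
        g.add_nodes_from(range(25))
        net = net_from_graph(g, coords=coords)
        rel = isn.edge_length_distribution(net, normalize=True)
        assert rel[0] < 1.0

    def test_geometric_edges_bounded_by_threshold(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 100, size=(40, 2))
        net = isn.geometric_network(coords, mode="distance", value=25.0)
        assert (isn.edge_length_distribution(net) <= 25.0).all()

    def test_nn_scale_fallback_below_nine_cells(self):
        coords = np.array([[0, 0], [1, 0], [0, 1]], dtype=float)
        assert nearest_neighbor_scale(coords, k=8) > 0


class TestHubs:
    def test_hub_count_ceil(self):
        g = nx.gnm_random_graph(60, 200, seed=0)
        assert len(isn.identify_hubs(net_from_graph(g), 1 / 6)) == 10

    def test_star_center_is_hub(self):
        g = nx.star_graph(11)
        hubs = isn.identify_hubs(net_from_graph(g), 1 / 6)
        assert "c000" in hubs

    def test_regular_graph_tie_break_by_cell_id(self):
        g = nx.cycle_graph(12)
        hubs = isn.identify_hubs(net_from_graph(g), 1 / 6)
        assert hubs == {"c000", "c001"}


class TestDegreeActivity:
    def test_constant_activity_gives_zero_r(self):
        g = nx.gnm_random_graph(30, 90, seed=3)
        net = net_from_graph(g)
        table, r = isn.degree_activity_relation(net, np.full(30, 0.4))
        assert r == 0.0
        assert all(row["mean_activity"] == pytest.approx(0.4) for row in table)

    def test_activity_equal_to_degree_gives_r_one(self):
        g = nx.gnm_random_graph(30, 90, seed=3)
        net = net_from_graph(g)
        _, r = isn.degree_activity_relation(net, net.degrees())
        assert r == pytest.approx(1.0)

    def test_constant_degrees_sentinel(self):
        g = nx.cycle_graph(10)
        _, r = isn.degree_activity_relation(net_from_graph(g), np.linspace(0, 1, 10))
        assert np.isnan(r)

    def test_duty_heterogeneity_induces_positive_relation(self, fast_binarized, islet):
        """Cells with higher duty cycles are better connected in
        coactivity networks built from synthetic islets."""
        S = isn.coactivity_matrix(fast_binarized)
        net = isn.fixed_kavg_network(S, 8.0, coords=islet.recording.coords)
        rat = isn.relative_active_time(fast_binarized)
        _, r = isn.degree_activity_relation(net, rat)
        assert r > 0


def test_fast_networks_more_segregated_than_slow():
    """Across seeded islets, fast-component networks show higher clustering
    and modularity and shorter relative edges than slow-component ones."""
    wins_c = wins_q = wins_len = 0
    seeds = (1, 2, 3, 4, 5)
    for seed in seeds:
        islet = isn.generate_islet(isn.IsletSimConfig(seed=seed))
        rec = islet.recording
        nf = isn.fixed_kavg_network(
            isn.pearson_matrix(isn.bandpass_filter(rec, isn.FilterSpec.named("fast"))),
            8.0, coords=rec.coords,
        )
        ns = isn.fixed_kavg_network(
            isn.pearson_matrix(isn.bandpass_filter(rec, isn.FilterSpec.named("slow"))),
            8.0, coords=rec.coords,
        )
        mf = isn.compute_metrics(nf, sw_randomizations=0)
        ms = isn.compute_metrics(ns, sw_randomizations=0)
        wins_c += mf.C_avg > ms.C_avg
        wins_q += mf.Q > ms.Q
        wins_len += (
            isn.edge_length_distribution(nf, normalize=True).mean()
            < isn.edge_length_distribution(ns, normalize=True).mean()
        )
    assert wins_c > len(seeds) / 2
    assert wins_q > len(seeds) / 2
    assert wins_len > len(seeds) / 2
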