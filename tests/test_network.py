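"""Network construction, topology identities, Zi-Pi roles, robustness."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ecoassembly.io import CommunityTable
from ecoassembly.network import (CONNECTOR, MODULE_HUB, NETWORK_HUB,
                                 PERIPHERAL, CoNetwork, build_network,
                                 detect_modules, natural_connectivity,
                                 robustness, select_top_otus, topology, zi_pi)


def make_table(mat, groups=None):
    idx = [f"s{i}" for i in range(len(mat))]
    groups = groups or ["g"] * len(mat)
    return CommunityTable(
        pd.DataFrame(mat, index=idx,
                     columns=[f"t{j:02d}" for j in range(len(mat[0]))],
                     dtype=float),
        pd.Series(dict(zip(idx, groups))))


def test_select_top_otus_is_a_superset_maximum():
    rng = np.random.default_rng(0)
    t = make_table(rng.dirichlet(np.ones(60) * 0.3, size=6))
    sub = select_top_otus(t, "g", n=20)
    assert len(sub.taxon_ids) == 20
    means = t.data.mean(axis=0)
    included_min = means[sub.taxon_ids].min()
    excluded = means.drop(sub.taxon_ids)
    assert (excluded <= included_min + 1e-15).all()


def test_select_top_otus_fewer_available_warns():
    rng = np.random.default_rng(1)
    t = make_table(rng.dirichlet(np.ones(10), size=6))
    with pytest.warns(UserWarning, match="taking all"):
        sub = select_top_otus(t, "g", n=50)
    assert len(sub.taxon_ids) == 10


def test_edges_require_both_thresholds_and_carry_sign():
    n = 8
    x = np.arange(1.0, n + 1)
    mat = np.column_stack([
        x,                   # t00
        x * 2,               # t01: rho=+1 with t00
        x[::-1],             # t02: rho=-1 with t00
        np.ones(n),          # t03: zero variance -> excluded
        np.random.default_rng(5).random(n),  # t04: noise
    ])
    t = make_table(mat)
    net = build_network(t, rho_thresh=0.8, p_thresh=0.01)
    assert "t03" in net.excluded_zero_variance
    assert net.graph.has_edge("t00", "t01")
    assert net.graph.edges["t00", "t01"]["sign"] == "+"
    assert net.graph.has_edge("t00", "t02")
    assert net.graph.edges["t00", "t02"]["sign"] == "-"
    # every retained edge satisfies both thresholds on direct re-check
    from scipy import stats

    for u, v, attrs in net.graph.edges(data=True):
        rho, p = stats.spearmanr(t.data[u], t.data[v])
        assert abs(rho) > 0.8 and p < 0.01
        assert attrs["rho"] == pytest.approx(rho, abs=1e-9)


def test_noise_yields_sparse_network():
    rng = np.random.default_rng(11)
    t = make_table(rng.random((6, 100)))
    net = build_network(t, drop_isolated=False)
    n_pairs = 100 * 99 / 2
    assert net.n_edges < 0.02 * n_pairs


def test_topology_closed_forms_triangle_and_star():
    tri = CoNetwork(nx.complete_graph(3))
    for u, v in tri.graph.edges:
        tri.graph.edges[u, v]["sign"] = "+"
    rep = topology(tri)
    assert rep.average_degree == pytest.approx(2.0)
    assert rep.density == pytest.approx(1.0)
    assert rep.clustering_coefficient == pytest.approx(1.0)
    assert rep.average_path_length == pytest.approx(1.0)
    assert rep.diameter == 1
    assert rep.n_positive == 3 and rep.n_negative == 0

    star = CoNetwork(nx.star_graph(4))  # S5: hub + 4 leaves
    rep = topology(star)
    assert rep.clustering_coefficient == pytest.approx(0.0)
    assert rep.diameter == 2
    assert rep.average_degree == pytest.approx(2 * 4 / 5)


def test_topology_identities_on_constructed_network(small_sim):
    from ecoassembly.io import to_relative

    table, *_ = small_sim
    rel = to_relative(table)
    sub = select_top_otus(rel, rel.group_labels()[0], n=60)
    net = build_network(sub, rho_thresh=0.7, p_thresh=0.05)
    if net.n_edges == 0:
        pytest.skip("fixture produced an empty network")
    rep = topology(net)
    assert rep.n_positive + rep.n_negative == rep.n_edges
    assert rep.average_degree == pytest.approx(2 * rep.n_edges / rep.n_nodes)
    assert rep.density == pytest.approx(
        2 * rep.n_edges / (rep.n_nodes * (rep.n_nodes - 1)))


def test_zi_pi_formulas_and_roles():
    # two triangles bridged by one node each
    g = nx.Graph()
    g.add_edges_from([("a1", "a2"), ("a2", "a3"), ("a1", "a3"),
                      ("b1", "b2"), ("b2", "b3"), ("b1", "b3"),
                      ("a1", "b1")])
    net = CoNetwork(g)
    modules = {"a1": 0, "a2": 0, "a3": 0, "b1": 1, "b2": 1, "b3": 1}
    df = zi_pi(net, modules)
    # a2: all links inside one module -> Pi = 0
    assert df.loc["a2", "pi"] == pytest.approx(0.0)
    # a1: 2 links in module 0, 1 in module 1 -> Pi = 1 - (2/3)^2 - (1/3)^2
    assert df.loc["a1", "pi"] == pytest.approx(1 - (2 / 3) ** 2 - (1 / 3) ** 2)
    assert set(df["role"]) <= {PERIPHERAL, MODULE_HUB, CONNECTOR, NETWORK_HUB}


def test_zi_pi_even_split_and_hub_classification():
    # node "h" with links split evenly across 2 modules -> Pi = 0.5
    g = nx.Graph()
    g.add_edges_from([("h", "m1a"), ("h", "m1b"), ("h", "m2a"), ("h", "m2b")])
    net = CoNetwork(g)
    modules = {"h": 0, "m1a": 0, "m1b": 0, "m2a": 1, "m2b": 1}
    df = zi_pi(net, modules)
    assert df.loc["h", "pi"] == pytest.approx(1 - 2 * 0.5**2)
    # m2a's single link concentrates in one module -> Pi = 0 -> peripheral
    assert df.loc["m2a", "pi"] == pytest.approx(0.0)
    assert df.loc["m2a", "role"] == PERIPHERAL


def test_natural_connectivity_closed_forms():
    k3 = nx.complete_graph(3)
    expected = np.log((np.exp(2) + 2 * np.exp(-1)) / 3)
    assert natural_connectivity(k3) == pytest.approx(expected, abs=1e-9)
    single = nx.Graph(); single.add_node("x")
    assert natural_connectivity(single) == 0.0
    # denser graph dominance at f = 0
    assert (natural_connectivity(nx.complete_graph(6))
            > natural_connectivity(nx.cycle_graph(6)))


def test_natural_connectivity_non_increasing_under_edge_removal():
    g = nx.gnp_random_graph(15, 0.4, seed=3)
    base = natural_connectivity(g)
    h = g.copy()
    edges = list(h.edges)
    prev = base
    for e in edges[:5]:
        h.remove_edge(*e)
        cur = natural_connectivity(h)
        assert cur <= prev + 1e-12
        prev = cur


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_targeted_robustness_curve_non_increasing(seed):
    g = nx.gnp_random_graph(40, 0.3, seed=seed)
    net = CoNetwork(g)
    curve = robustness(net, mode="targeted", f_max=0.8, step=0.1)
    vals = curve.connectivity
    assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))


def test_random_robustness_two_seeds_agree():
    g = nx.gnp_random_graph(40, 0.3, seed=5)
    net = CoNetwork(g)
    c1 = robustness(net, mode="random", n_reps=200, seed=1, f_max=0.4, step=0.2)
    c2 = robustness(net, mode="random", n_reps=200, seed=2, f_max=0.4, step=0.2)
    rel = np.abs(c1.connectivity - c2.connectivity) / np.abs(c1.connectivity)
    assert (rel < 0.02).all()


def test_modularity_partition_is_recorded():
    g = nx.connected_caveman_graph(3, 4)
    g = nx.relabel_nodes(g, {n: f"n{n}" for n in g.nodes})
    net = CoNetwork(g)
    detect_modules(net, seed=0)
    assert set(net.modules) == set(g.nodes)
    assert nx.get_node_attributes(net.graph, "module")
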