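"""Co-occurrence networks: construction, topology, Zi-Pi roles, robustness.

Per distance group, the 250 most abundant taxa are correlated pairwise
(Spearman); an edge is kept when |rho| > 0.8 and p < 0.01, its sign
recorded. Topology statistics follow the usual co-occurrence reporting
conventions (path length and diameter over connected pairs only). Node
roles come from the within-module degree z-score Zi and the among-module
participation coefficient Pi with thresholds 2.5 / 0.62:

    peripheral   Zi < 2.5, Pi < 0.62      module_hub   Zi > 2.5, Pi < 0.62
    connector    Zi < 2.5, Pi > 0.62      network_hub  Zi > 2.5, Pi > 0.62

Robustness is measured by natural connectivity — the log of the average
exponentiated adjacency eigenvalue — as nodes are removed at random or in
descending degree order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import CommunityTable, to_relative

logger = logging.getLogger(__name__)

PERIPHERAL = "peripheral"
MODULE_HUB = "module_hub"
CONNECTOR = "connector"
NETWORK_HUB = "network_hub"

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


@dataclass
class CoNetwork:
    """Signed undirected co-occurrence graph with per-node annotations."""

    graph: nx.Graph
    modules: dict[str, int] = field(default_factory=dict)
    excluded_zero_variance: list[str] = field(default_factory=list)
    dropped_isolated: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def select_top_otus(table: CommunityTable, group: str, n: int = 250) -> CommunityTable:
    """The ``n`` taxa with highest mean relative abundance within a group.

    Ties break lexicographically by taxon id; fewer available taxa than
    ``n`` returns them all with a warning.
    """
    rel = table if table.is_relative() else to_relative(table)
    samples = rel.samples_in_group(group)
    if len(samples) < 5:
        raise ValueError(f"group {group!r} has fewer than 5 samples; "
                         "correlations need replicates")
    sub = rel.data.loc[samples]
    means = sub.mean(axis=0)
    nonzero = means[means > 0]
    if len(nonzero) < n:
        import warnings

        warnings.warn(f"only {len(nonzero)} taxa with nonzero abundance in "
                      f"{group!r}; taking all")
        n = len(nonzero)
    # sort by (-mean, taxon id): highest first, lexicographic tie-break
    order = nonzero.sort_index().sort_values(ascending=False, kind="stable")
    keep = sorted(order.index[:n])
    return CommunityTable(sub.loc[:, keep], rel.groups.loc[samples].copy())


def _spearman_matrix(x: np.ndarray):
    """Spearman rho and two-sided p (t-approximation, average-rank ties)
    for all column pairs of an (n_samples x n_taxa) matrix."""
    ranks = stats.rankdata(x, axis=0)
    rho = np.corrcoef(ranks, rowvar=False)
    n = x.shape[0]
    rho_c = np.clip(rho, -0.9999999999, 0.9999999999)
    t = rho_c * np.sqrt((n - 2) / (1.0 - rho_c**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return rho, p


def build_network(sub_table: CommunityTable, rho_thresh: float = 0.8,
                  p_thresh: float = 0.01, bh_correct: bool = False,
                  drop_isolated: bool = True) -> CoNetwork:
    """Spearman co-occurrence network over a (already subsetted) table.

    Zero-variance taxa are excluded (logged); an edge is kept iff
    ``|rho| > rho_thresh`` and ``p < p_thresh`` (optionally BH-adjusted);
    isolated nodes are dropped by default.
    """
    if len(sub_table.sample_ids) < 5:
        raise ValueError("need >= 5 samples to estimate correlations")
    data = sub_table.data
    variances = data.var(axis=0)
    constant = sorted(variances.index[variances == 0])
    if constant:
        logger.info("excluding %d zero-variance taxa: %s", len(constant), constant)
        data = data.drop(columns=constant)
    taxa = list(data.columns)
    rho, p = _spearman_matrix(data.to_numpy())
    iu = np.triu_indices(len(taxa), k=1)
    pvals = p[iu]
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        pvals = multipletests(pvals, method="fdr_bh")[1]
    keep = (np.abs(rho[iu]) > rho_thresh) & (pvals < p_thresh)
    g = nx.Graph()
    g.add_nodes_from(taxa)
    for k in np.flatnonzero(keep):
        i, j = iu[0][k], iu[1][k]
        r = float(rho[i, j])
        g.add_edge(taxa[i], taxa[j], weight=abs(r), rho=r,
                   sign="+" if r > 0 else "-")
    dropped = []
    if drop_isolated:
        dropped = sorted(n for n, deg in g.degree() if deg == 0)
        g.remove_nodes_from(dropped)
    return CoNetwork(g, excluded_zero_variance=constant,
                     dropped_isolated=dropped)


def detect_modules(net: CoNetwork, method: str = "greedy", seed: int = 0) -> dict[str, int]:
    """Community detection for Zi-Pi; greedy modularity by default,
    Louvain by flag. The partition is stored on the network and in node
    attributes so downstream roles are reproducible."""
    if net.n_edges == 0:
        modules = {n: i for i, n in enumerate(sorted(net.graph.nodes))}
    elif method == "greedy":
        comms = nx.algorithms.community.greedy_modularity_communities(net.graph)
        modules = {n: i for i, c in enumerate(comms) for n in c}
    elif method == "louvain":
        comms = nx.algorithms.community.louvain_communities(net.graph, seed=seed)
        modules = {n: i for i, c in enumerate(comms) for n in c}
    else:
        raise ValueError(f"unknown module method {method!r}")
    net.modules = modules
    nx.set_node_attributes(net.graph, modules, "module")
    return modules


@dataclass
class TopologyReport:
    n_nodes: int
    n_edges: int
    n_positive: int
    n_negative: int
    average_degree: float
    average_path_length: float
    diameter: float
    density: float
    clustering_coefficient: float
    modularity: float

    def to_series(self) -> pd.Series:
        return pd.Series(vars(self))


def topology(net: CoNetwork, seed: int = 0) -> TopologyReport:
    """Whole-network statistics; path length and diameter are averaged /
    maximised over connected (reachable) pairs only."""
    g = net.graph
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        raise ValueError("empty network")
    signs = nx.get_edge_attributes(g, "sign")
    n_pos = sum(1 for s in signs.values() if s == "+")
    n_neg = e - n_pos
    avg_deg = 2.0 * e / n
    density = 2.0 * e / (n * (n - 1)) if n > 1 else 0.0
    # shortest paths over reachable pairs
    total, npairs, diam = 0.0, 0, 0
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        for src, lengths in nx.all_pairs_shortest_path_length(sub):
            for dst, dist in lengths.items():
                if src < dst:
                    total += dist
                    npairs += 1
                    diam = max(diam, dist)
    apl = total / npairs if npairs else float("nan")
    # mean local clustering; degree-<2 nodes contribute 0
    clustering = float(np.mean(list(nx.clustering(g).values()))) if n else 0.0
    if not net.modules:
        detect_modules(net, seed=seed)
    if e:
        comms: dict[int, set] = {}
        for node, m in net.modules.items():
            comms.setdefault(m, set()).add(node)
        modularity = nx.algorithms.community.modularity(g, comms.values())
    else:
        modularity = 0.0
    return TopologyReport(n, e, n_pos, n_neg, avg_deg, apl, diam, density,
                          clustering, modularity)


def zi_pi(net: CoNetwork, modules: dict[str, int] | None = None) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and participation coefficient (Pi)
    per node, plus the four-way role classification.

    A module with zero within-degree spread gives Zi = 0 for its nodes;
    isolated nodes get Pi = 0 by convention.
    """
    modules = modules or net.modules or detect_modules(net)
    g = net.graph
    nodes = sorted(g.nodes)
    k_within = {}
    k_by_module: dict[str, dict[int, int]] = {}
    for node in nodes:
        per_mod: dict[int, int] = {}
        for nb in g.neighbors(node):
            per_mod[modules[nb]] = per_mod.get(modules[nb], 0) + 1
        k_by_module[node] = per_mod
        k_within[node] = per_mod.get(modules[node], 0)
    # per-module mean/sd of within-degree
    stats_by_mod: dict[int, tuple[float, float]] = {}
    for m in set(modules.values()):
        vals = np.array([k_within[n] for n in nodes if modules[n] == m], dtype=float)
        stats_by_mod[m] = (vals.mean(), vals.std(ddof=0))
    rows = []
    for node in nodes:
        mu, sd = stats_by_mod[modules[node]]
        zi = (k_within[node] - mu) / sd if sd > 0 else 0.0
        k_total = g.degree(node)
        if k_total == 0:
            pi = 0.0
            logger.info("isolated node %s: Pi set to 0", node)
        else:
            pi = 1.0 - sum((km / k_total) ** 2
                           for km in k_by_module[node].values())
        if zi > ZI_THRESHOLD:
            role = NETWORK_HUB if pi > PI_THRESHOLD else MODULE_HUB
        else:
            role = CONNECTOR if pi > PI_THRESHOLD else PERIPHERAL
        rows.append({"node": node, "module": modules[node], "degree": k_total,
                     "zi": zi, "pi": pi, "role": role})
    df = pd.DataFrame(rows).set_index("node")
    nx.set_node_attributes(net.graph, df["zi"].to_dict(), "zi")
    nx.set_node_attributes(net.graph, df["pi"].to_dict(), "pi")
    nx.set_node_attributes(net.graph, df["role"].to_dict(), "role")
    return df


def natural_connectivity(graph: nx.Graph) -> float:
    """ln of the average exponentiated adjacency eigenvalue.

    A single node (eigenvalue 0) gives 0; an empty graph is undefined.
    """
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("natural connectivity undefined for an empty graph")
    if n == 1:
        return 0.0
    a = nx.to_numpy_array(graph, weight=None)
    eig = np.linalg.eigvalsh(a)
    # log-sum-exp for numerical stability
    m = eig.max()
    return float(m + np.log(np.exp(eig - m).sum()) - np.log(n))


@dataclass
class RobustnessCurve:
    fractions: np.ndarray
    connectivity: np.ndarray  # mean over reps for random mode
    mode: str
    n_reps: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fraction_removed": self.fractions,
                             "natural_connectivity": self.connectivity})


def robustness(net: CoNetwork, mode: str = "targeted", f_max: float = 0.8,
               step: float = 0.05, n_reps: int = 100, seed: int = 0) -> RobustnessCurve:
    """Natural-connectivity decay under node removal.

    ``targeted`` removes nodes in descending degree order (ties by id);
    ``random`` averages over ``n_reps`` seeded random orders. The curve is
    truncated once fewer than 2 nodes remain.
    """
    g = net.graph
    n = g.number_of_nodes()
    if n < 3:
        raise ValueError("need >= 3 nodes for a robustness curve")
    fractions = np.arange(0.0, f_max + step / 2, step)
    nodes = sorted(g.nodes)

    def curve_for(order: list[str]) -> list[float]:
        vals = []
        for f in fractions:
            k = int(np.floor(f * n))
            if n - k < 2:
                break
            h = g.copy()
            h.remove_nodes_from(order[:k])
            vals.append(natural_connectivity(h))
        return vals

    if mode == "targeted":
        order = sorted(nodes, key=lambda v: (-g.degree(v), v))
        vals = curve_for(order)
        reps = 1
    elif mode == "random":
        rng = np.random.default_rng(seed)
        all_vals = []
        for _ in range(n_reps):
            order = list(rng.permutation(nodes))
            all_vals.append(curve_for(order))
        length = min(len(v) for v in all_vals)
        vals = list(np.mean([v[:length] for v in all_vals], axis=0))
        reps = n_reps
    else:
        raise ValueError("mode must be 'random' or 'targeted'")
    m = len(vals)
    return RobustnessCurve(fractions[:m], np.asarray(vals), mode, reps)
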