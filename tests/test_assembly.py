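"""Null-model metrics: betaMNTD oracle equivalence, betaNTI/RCbray
behaviour and the five-way process classification."""

from io import StringIO

import numpy as np
import pandas as pd
import pytest

from ecoassembly.assembly import (DISPERSAL_LIMITATION,
                                  HETEROGENEOUS_SELECTION,
                                  HOMOGENEOUS_SELECTION,
                                  HOMOGENIZING_DISPERSAL, UNDOMINATED, bmntd,
                                  classify_pair, pairwise_assembly,
                                  rc_null_sample, summarize_assembly)
from ecoassembly.io import CommunityTable, PhyloTree
from skbio import TreeNode


def brute_force_bmntd(d, xi, xj, weighted=True):
    """Independent exhaustive double loop over taxa."""
    pres_i = [k for k in range(len(xi)) if xi[k] > 0]
    pres_j = [k for k in range(len(xj)) if xj[k] > 0]
    term_i = term_j = 0.0
    fi = np.array([xi[k] for k in pres_i]); fi = fi / fi.sum()
    fj = np.array([xj[k] for k in pres_j]); fj = fj / fj.sum()
    for a, k in enumerate(pres_i):
        nearest = min(d[k][m] for m in pres_j)
        term_i += (fi[a] if weighted else 1.0 / len(pres_i)) * nearest
    for b, m in enumerate(pres_j):
        nearest = min(d[m][k] for k in pres_i)
        term_j += (fj[b] if weighted else 1.0 / len(pres_j)) * nearest
    return 0.5 * (term_i + term_j)


def table_and_tree(xi, xj, newick):
    tree = PhyloTree(TreeNode.read(StringIO(newick)))
    taxa = tree.tip_names
    data = pd.DataFrame([xi, xj], index=["s1", "s2"], columns=taxa, dtype=float)
    return (CommunityTable(data, pd.Series({"s1": "a", "s2": "b"})), tree)


def test_bmntd_single_taxon_communities_hand_value():
    # patristic d(A,C) = 4 on ((A:1,B:1):1,C:2);
    t, tree = table_and_tree([1, 0, 0], [0, 0, 1], "((A:1,B:1):1,C:2);")
    assert bmntd(t, tree, ("s1", "s2")) == pytest.approx(4.0)


def test_bmntd_identical_communities_is_zero():
    t, tree = table_and_tree([0.5, 0.3, 0.2], [0.5, 0.3, 0.2],
                             "((A:1,B:1):1,C:2);")
    assert bmntd(t, tree, ("s1", "s2")) == pytest.approx(0.0)


@pytest.mark.parametrize("weighted", [True, False])
def test_bmntd_matches_brute_force_oracle(weighted):
    from ecoassembly.simulate import simulate_tree

    rng = np.random.default_rng(7)
    for rep in range(50):
        n = int(rng.integers(4, 11))
        tree = simulate_tree(n, seed=rep)
        d = tree.patristic().to_numpy()
        xi = rng.random(n) * (rng.random(n) < 0.7)
        xj = rng.random(n) * (rng.random(n) < 0.7)
        if xi.sum() == 0 or xj.sum() == 0:
            continue
        taxa = tree.tip_names
        data = pd.DataFrame([xi, xj], index=["s1", "s2"], columns=taxa)
        t = CommunityTable(data, pd.Series({"s1": "a", "s2": "b"}))
        got = bmntd(t, tree, ("s1", "s2"), weighted=weighted)
        want = brute_force_bmntd(d, xi, xj, weighted=weighted)
        assert got == pytest.approx(want, abs=1e-10)


def test_bnti_identical_communities_degenerate_null():
    t, tree = table_and_tree([0.5, 0.3, 0.2], [0.5, 0.3, 0.2],
                             "((A:1,B:1):1,C:2);")
    with pytest.warns(UserWarning, match="null sd"):
        res = pairwise_assembly(t, tree, n_null=49, seed=0, rc=False)
    assert np.isnan(res["bnti"].iloc[0])
    assert res["process"].isna().all()


def test_bnti_invariant_to_taxon_relabeling():
    """Renaming taxa consistently in table and tree leaves betaNTI unchanged."""
    from ecoassembly.simulate import SimConfig, simulate_dataset

    cfg = SimConfig(n_taxa=30, n_groups=2, reps_per_group=(2, 2), depth=500,
                    seed=13)
    tab, tree, _, _ = simulate_dataset(cfg)
    res1 = pairwise_assembly(tab, tree, n_null=99, seed=5, rc=False)
    mapping = {t: f"X{t}" for t in tab.taxon_ids}
    data2 = tab.data.rename(columns=mapping)
    tab2 = CommunityTable(data2, tab.groups)
    tree2 = PhyloTree(TreeNode.read(StringIO(tree.to_newick())))
    for tip in tree2.tree.tips():
        tip.name = mapping.get(tip.name, tip.name)
    tree2 = PhyloTree(tree2.tree)
    res2 = pairwise_assembly(tab2, tree2, n_null=99, seed=5, rc=False)
    np.testing.assert_allclose(res1["bnti"], res2["bnti"], atol=1e-9)


def test_missing_tree_tip_is_hard_error():
    t, tree = table_and_tree([1, 1, 1], [1, 1, 1], "((A:1,B:1):1,C:2);")
    extra = CommunityTable(
        t.data.assign(Z=[1.0, 1.0]), t.groups)
    with pytest.raises(Exception, match="Z"):
        pairwise_assembly(extra, tree, n_null=9, seed=0)


def test_rcbray_requires_integer_counts():
    t, tree = table_and_tree([0.5, 0.3, 0.2], [0.2, 0.3, 0.5],
                             "((A:1,B:1):1,C:2);")
    with pytest.raises(ValueError, match="integer"):
        pairwise_assembly(t, tree, n_null=9, seed=0)


def test_rcbray_disjoint_supports_approaches_one():
    """Maximal observed dissimilarity within a shared pool: the null
    almost never reaches it, so RCbray -> +1."""
    data = pd.DataFrame(
        [[40, 40, 20, 0, 0, 0], [0, 0, 0, 40, 40, 20],
         [30, 30, 20, 10, 5, 5], [10, 5, 5, 30, 30, 20]],
        index=["s1", "s2", "s3", "s4"],
        columns=list("ABCDEF"), dtype=float)
    t = CommunityTable(data, pd.Series(
        {"s1": "a", "s2": "b", "s3": "a", "s4": "b"}))
    res = pairwise_assembly(t, None, n_null=199, seed=0, phylo=False,
                            pairs=[("s1", "s2")])
    assert res["rcbray"].iloc[0] > 0.9


def test_rcbray_all_ties_is_zero():
    """A one-taxon pool makes every null draw identical to the observation."""
    data = pd.DataFrame([[10.0], [10.0]], index=["s1", "s2"], columns=["A"])
    t = CommunityTable(data, pd.Series({"s1": "a", "s2": "b"}))
    res = pairwise_assembly(t, None, n_null=99, seed=0, phylo=False)
    assert res["rcbray"].iloc[0] == pytest.approx(0.0)


def test_rc_null_sample_preserves_richness_and_total():
    rng = np.random.default_rng(0)
    occ = np.array([0.4, 0.3, 0.2, 0.05, 0.05])
    ab = np.array([0.5, 0.3, 0.1, 0.05, 0.05])
    for _ in range(20):
        s = rc_null_sample(rng, 3, 100, occ, ab)
        assert (s > 0).sum() == 3
        assert s.sum() == 100


@pytest.mark.parametrize("bn,rc,expected", [
    (2.5, 0.1, HETEROGENEOUS_SELECTION),
    (2.01, -0.99, HETEROGENEOUS_SELECTION),   # selection takes precedence
    (-2.5, 0.99, HOMOGENEOUS_SELECTION),
    (-2.01, 0.0, HOMOGENEOUS_SELECTION),
    (0.0, 0.96, DISPERSAL_LIMITATION),
    (2.0, 0.951, DISPERSAL_LIMITATION),       # |betaNTI| = 2 is stochastic
    (0.0, -0.96, HOMOGENIZING_DISPERSAL),
    (-2.0, -0.951, HOMOGENIZING_DISPERSAL),
    (-1.0, -0.3, UNDOMINATED),
    (2.0, 0.95, UNDOMINATED),                 # |RCbray| = 0.95 is undominated
    (-2.0, -0.95, UNDOMINATED),
])
def test_classification_rule_boundaries(bn, rc, expected):
    assert classify_pair(bn, rc) == expected


def test_classify_nan_propagates():
    assert np.isnan(classify_pair(float("nan"), 0.5))


def test_summarize_counts_and_percentages():
    df = pd.DataFrame({
        "sample_i": list("aabc"), "sample_j": list("bcdd"),
        "group_i": ["g1"] * 4, "group_j": ["g1"] * 4,
        "bmntd": 1.0, "bnti": [3.0, 0.0, 0.0, 0.0],
        "rcbray": [0.0, 0.99, 0.99, 0.0],
        "process": [HETEROGENEOUS_SELECTION, DISPERSAL_LIMITATION,
                    DISPERSAL_LIMITATION, UNDOMINATED],
    })
    s = summarize_assembly(df, "all")
    assert s.table.loc["all", HETEROGENEOUS_SELECTION] == pytest.approx(25.0)
    assert s.table.loc["all", DISPERSAL_LIMITATION] == pytest.approx(50.0)
    assert s.table.loc["all"].sum() == pytest.approx(100.0)
    per = summarize_assembly(df, "per-group")
    assert per.counts.loc["g1"].sum() == 4


def test_summarize_empty_scope_is_error():
    df = pd.DataFrame(columns=["sample_i", "sample_j", "group_i", "group_j",
                               "bmntd", "bnti", "rcbray", "process"])
    with pytest.raises(ValueError):
        summarize_assembly(df, "all")
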