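"""Phylogenetic and taxonomic null models of community assembly.

For every sample pair the pipeline computes

* **betaMNTD** — abundance-weighted mean distance from each taxon in one
  community to its nearest phylogenetic neighbour in the other;
* **betaNTI** — the standardised effect size of betaMNTD against a null
  that shuffles taxon labels across the tips of the phylogeny (taxa swap
  positions on the tree, abundances untouched);
* **RCbray** — the Raup-Crick position of the observed Bray-Curtis
  dissimilarity within a null that reassembles each community at its
  observed richness and read total, drawing presences in proportion to
  regional occurrence frequency and allocating reads in proportion to
  regional relative abundance.

The (betaNTI, RCbray) pair is then classified into five assembly
processes: betaNTI > 2 heterogeneous selection, betaNTI < -2 homogeneous
selection, otherwise RCbray > 0.95 dispersal limitation, RCbray < -0.95
homogenizing dispersal, else undominated.

The null randomisation pool is every taxon present anywhere in the table
(the regional pool across all distances). Null replicate permutations are
shared across pairs within one call, which is both the field convention
and what makes the all-pairs computation tractable.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CommunityTable, PhyloTree, to_relative

HETEROGENEOUS_SELECTION = "heterogeneous_selection"
HOMOGENEOUS_SELECTION = "homogeneous_selection"
DISPERSAL_LIMITATION = "dispersal_limitation"
HOMOGENIZING_DISPERSAL = "homogenizing_dispersal"
UNDOMINATED = "undominated"

PROCESSES = (HETEROGENEOUS_SELECTION, HOMOGENEOUS_SELECTION,
             DISPERSAL_LIMITATION, HOMOGENIZING_DISPERSAL, UNDOMINATED)

#: selection threshold on |betaNTI| and stochastic threshold on |RCbray|
BNTI_THRESHOLD = 2.0
RCBRAY_THRESHOLD = 0.95


def _weighted_bmntd(d_sub: np.ndarray, fi: np.ndarray, fj: np.ndarray) -> float:
    # d_sub rows = taxa of community i, cols = taxa of community j
    return 0.5 * (fi @ d_sub.min(axis=1) + fj @ d_sub.min(axis=0))


def _unweighted_bmntd(d_sub: np.ndarray) -> float:
    return 0.5 * (d_sub.min(axis=1).mean() + d_sub.min(axis=0).mean())


def bmntd(table: CommunityTable, tree: PhyloTree, pair: tuple[str, str],
          weighted: bool = True) -> float:
    """Observed betaMNTD for one sample pair, in branch-length units."""
    rel = table if table.is_relative() else to_relative(table)
    tree.require_tips(rel.taxon_ids)
    d = tree.patristic().loc[rel.taxon_ids, rel.taxon_ids].to_numpy()
    xi = rel.data.loc[pair[0]].to_numpy()
    xj = rel.data.loc[pair[1]].to_numpy()
    return _bmntd_pair(d, xi, xj, weighted)


def _bmntd_pair(d: np.ndarray, xi: np.ndarray, xj: np.ndarray,
                weighted: bool) -> float:
    ii, jj = np.flatnonzero(xi > 0), np.flatnonzero(xj > 0)
    if ii.size == 0 or jj.size == 0:
        raise ValueError("betaMNTD undefined for an empty community")
    d_sub = d[np.ix_(ii, jj)]
    if weighted:
        fi = xi[ii] / xi[ii].sum()
        fj = xj[jj] / xj[jj].sum()
        return _weighted_bmntd(d_sub, fi, fj)
    return _unweighted_bmntd(d_sub)


def bnti(table: CommunityTable, tree: PhyloTree, pair: tuple[str, str],
         n_null: int = 999, seed: int = 0, weighted: bool = True) -> float:
    """betaNTI for one pair; NaN with a warning when the null sd is zero."""
    res = pairwise_assembly(table, tree, n_null=n_null, seed=seed,
                            weighted=weighted, pairs=[pair], rc=False)
    return float(res["bnti"].iloc[0])


def rcbray(table: CommunityTable, pair: tuple[str, str],
           n_null: int = 999, seed: int = 0) -> float:
    """RCbray for one pair of count-form samples."""
    res = pairwise_assembly(table, None, n_null=n_null, seed=seed,
                            pairs=[pair], phylo=False)
    return float(res["rcbray"].iloc[0])


def classify_pair(bnti_value: float, rcbray_value: float) -> str | float:
    """Map (betaNTI, RCbray) to one of the five assembly processes."""
    if bnti_value is None or (isinstance(bnti_value, float) and math.isnan(bnti_value)):
        return float("nan")
    if bnti_value > BNTI_THRESHOLD:
        return HETEROGENEOUS_SELECTION
    if bnti_value < -BNTI_THRESHOLD:
        return HOMOGENEOUS_SELECTION
    if rcbray_value is None or (isinstance(rcbray_value, float) and math.isnan(rcbray_value)):
        return float("nan")
    if rcbray_value > RCBRAY_THRESHOLD:
        return DISPERSAL_LIMITATION
    if rcbray_value < -RCBRAY_THRESHOLD:
        return HOMOGENIZING_DISPERSAL
    return UNDOMINATED


def _bray_counts(x: np.ndarray, y: np.ndarray) -> float:
    s = float((x + y).sum())
    return float(np.abs(x - y).sum()) / s if s > 0 else 0.0


def rc_null_sample(rng, richness: int, total: int, occ_freq: np.ndarray,
                   rel_ab: np.ndarray) -> np.ndarray:
    """One probabilistically assembled community: draw ``richness`` taxa by
    occurrence frequency, seed each with one read, spread the rest
    multinomially by regional relative abundance among the drawn taxa.

    This is both the Raup-Crick null sampler and the definitional neutral
    expectation it tests against (the simulate module's neutral regime
    draws samples from this very process)."""
    n = occ_freq.size
    richness = min(richness, n)
    chosen = rng.choice(n, size=richness, replace=False, p=occ_freq)
    counts = np.zeros(n, dtype=np.int64)
    counts[chosen] = 1
    remaining = total - richness
    if remaining > 0:
        p = rel_ab[chosen]
        psum = p.sum()
        p = p / psum if psum > 0 else np.full(richness, 1.0 / richness)
        counts[chosen] += rng.multinomial(remaining, p)
    return counts


def pairwise_assembly(table: CommunityTable, tree: PhyloTree | None,
                      n_null: int = 999, seed: int = 0, weighted: bool = True,
                      pairs=None, phylo: bool = True, rc: bool = True,
                      ) -> pd.DataFrame:
    """betaMNTD / betaNTI / RCbray / process for a set of sample pairs.

    Parameters
    ----------
    table : CommunityTable
        Count-form table when ``rc`` is requested (the Raup-Crick null
        reassembles integer reads); any form for the phylogenetic metrics.
    tree : PhyloTree
        Must carry a tip for every taxon in the table (hard error otherwise).
    pairs : iterable of (sample, sample), optional
        Defaults to all unordered pairs.

    Returns a long-format frame with one row per pair.
    """
    rng = np.random.default_rng(seed)
    counts = table.counts
    if rc:
        if not np.allclose(counts, np.round(counts)):
            raise ValueError(
                "RCbray requires raw integer read counts; supply the "
                "unnormalised table")
        counts = np.round(counts).astype(np.int64)
    rel = counts / counts.sum(axis=1, keepdims=True)
    sample_index = {s: i for i, s in enumerate(table.sample_ids)}
    if pairs is None:
        pairs = list(itertools.combinations(table.sample_ids, 2))
    pairs = [tuple(p) for p in pairs]

    n_pool = len(table.taxon_ids)
    out = {
        "sample_i": [p[0] for p in pairs],
        "sample_j": [p[1] for p in pairs],
        "group_i": [str(table.groups[p[0]]) for p in pairs],
        "group_j": [str(table.groups[p[1]]) for p in pairs],
    }

    if phylo:
        if tree is None:
            raise ValueError("a phylogenetic tree is required for betaMNTD/betaNTI")
        tree.require_tips(table.taxon_ids)
        d = tree.patristic().loc[table.taxon_ids, table.taxon_ids].to_numpy()
        obs = np.array([
            _bmntd_pair(d, rel[sample_index[a]], rel[sample_index[b]], weighted)
            for a, b in pairs])
        nulls = np.empty((n_null, len(pairs)))
        for r in range(n_null):
            perm = rng.permutation(n_pool)
            d_perm = d[np.ix_(perm, perm)]
            for k, (a, b) in enumerate(pairs):
                nulls[r, k] = _bmntd_pair(
                    d_perm, rel[sample_index[a]], rel[sample_index[b]], weighted)
        mu, sd = nulls.mean(axis=0), nulls.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ses = np.where(sd > 0, (obs - mu) / sd, np.nan)
        if np.isnan(ses).any():
            import warnings

            warnings.warn("betaNTI undefined (null sd = 0) for some pairs")
        out["bmntd"] = obs
        out["bnti"] = ses
    else:
        out["bmntd"] = np.nan
        out["bnti"] = np.nan

    if rc:
        occ = (counts > 0).mean(axis=0)
        occ = occ / occ.sum()
        pool_rel = counts.sum(axis=0) / counts.sum()
        richness = (counts > 0).sum(axis=1)
        totals = counts.sum(axis=1)
        rc_vals = np.empty(len(pairs))
        for k, (a, b) in enumerate(pairs):
            ia, ib = sample_index[a], sample_index[b]
            obs_bc = _bray_counts(counts[ia], counts[ib])
            less = ties = 0
            for _ in range(n_null):
                na = rc_null_sample(rng, int(richness[ia]), int(totals[ia]),
                                    occ, pool_rel)
                nb = rc_null_sample(rng, int(richness[ib]), int(totals[ib]),
                                    occ, pool_rel)
                null_bc = _bray_counts(na, nb)
                if null_bc < obs_bc - 1e-12:
                    less += 1
                elif abs(null_bc - obs_bc) <= 1e-12:
                    ties += 1
            rc_vals[k] = 2.0 * ((less + 0.5 * ties) / n_null - 0.5)
        out["rcbray"] = rc_vals
    else:
        out["rcbray"] = np.nan

    df = pd.DataFrame(out)
    df["process"] = [classify_pair(b, r)
                     for b, r in zip(df["bnti"], df["rcbray"])]
    return df


@dataclass
class AssemblySummary:
    """Percentage of pairs assigned to each process, overall or per group."""

    table: pd.DataFrame  # rows: scope, columns: the five processes (percent)
    counts: pd.DataFrame


def summarize_assembly(results: pd.DataFrame, scope: str = "all") -> AssemblySummary:
    """Tally process percentages over all pairs or within-group pairs.

    ``scope='per-group'`` keeps only pairs whose two samples share a group
    and tallies per group; percentages in every row sum to 100.
    """
    valid = results.dropna(subset=["process"])
    if scope == "all":
        frames = {"all": valid}
    elif scope == "per-group":
        within = valid[valid["group_i"] == valid["group_j"]]
        frames = {g: sub for g, sub in within.groupby("group_i")}
    else:
        raise ValueError("scope must be 'all' or 'per-group'")
    if not frames or all(len(v) == 0 for v in frames.values()):
        raise ValueError("no classified pairs in the requested scope")
    counts = pd.DataFrame(
        {name: sub["process"].value_counts().reindex(PROCESSES, fill_value=0)
         for name, sub in frames.items()}).T
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    return AssemblySummary(pct, counts)
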