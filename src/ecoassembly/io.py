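"""Readers, writers and the shared data model.

The whole pipeline operates on three containers:

``CommunityTable``
    samples x taxa abundance matrix (reads or relative abundances) with a
    group label per sample (e.g. distance classes along a disturbance
    gradient).
``PhyloTree``
    rooted phylogeny whose tips cover the taxa; supplies patristic
    distances for the phylogenetic null models.
``EnvTable``
    samples x 9 soil covariates (TN, TP, TK, salt, SOM, SUE, SALP, SSC, pH).

Sample and taxon order is canonicalised (lexicographic) on read so every
downstream output is order-stable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

#: the nine soil covariates every EnvTable must carry, in canonical order
ENV_FACTORS = ("TN", "TP", "TK", "salt", "SOM", "SUE", "SALP", "SSC", "pH")


class ValidationError(ValueError):
    """Raised when an input table or tree violates a contract."""


@dataclass
class CommunityTable:
    """Samples x taxa abundance matrix with per-sample group labels.

    Parameters
    ----------
    data : pandas.DataFrame
        Non-negative matrix, rows = samples, columns = taxa.
    groups : pandas.Series
        Group label per sample, indexed by sample id.
    """

    data: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.data = self.data.sort_index(axis=0).sort_index(axis=1)
        self.groups = self.groups.reindex(self.data.index)
        self.validate()

    # -- contracts ---------------------------------------------------------
    def validate(self) -> None:
        arr = self.data.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValidationError("abundance matrix contains missing values")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative abundance at sample {self.data.index[i]!r}, "
                f"taxon {self.data.columns[j]!r}"
            )
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dup}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate taxon ids: {dup}")
        zero_rows = self.data.index[arr.sum(axis=1) == 0].tolist()
        if zero_rows:
            raise ValidationError(f"all-zero sample rows: {zero_rows}")
        if self.groups.isna().any():
            missing = self.groups.index[self.groups.isna()].tolist()
            raise ValidationError(f"samples missing from metadata: {missing}")

    # -- convenience -------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def group_labels(self) -> list[str]:
        """Distinct group labels in sorted order."""
        return sorted(self.groups.unique())

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def is_relative(self, tol: float = 1e-9) -> bool:
        return bool(np.allclose(self.counts.sum(axis=1), 1.0, atol=tol))

    def subset_taxa(self, taxa) -> "CommunityTable":
        sub = self.data.loc[:, list(taxa)]
        return CommunityTable(sub, self.groups.copy())

    def subset_samples(self, samples) -> "CommunityTable":
        sub = self.data.loc[list(samples)]
        return CommunityTable(sub, self.groups.loc[list(samples)])


@dataclass
class PhyloTree:
    """Rooted tree with non-negative branch lengths over taxon tips."""

    tree: TreeNode
    _patristic: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for node in self.tree.traverse(include_self=False):
            if node.length is not None and node.length < 0:
                raise ValidationError(
                    f"negative branch length {node.length} at node "
                    f"{node.name!r}"
                )

    @property
    def tip_names(self) -> list[str]:
        return sorted(t.name for t in self.tree.tips())

    def require_tips(self, taxa) -> None:
        """Raise if any requested taxon lacks a tip on the tree."""
        missing = sorted(set(taxa) - set(self.tip_names))
        if missing:
            raise ValidationError(f"taxa missing from tree: {missing}")

    def patristic(self) -> pd.DataFrame:
        """Symmetric tip-to-tip patristic distance matrix (zero diagonal)."""
        if self._patristic is None:
            dm = self.tree.tip_tip_distances()
            df = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
            order = sorted(df.index)
            self._patristic = df.loc[order, order]
        return self._patristic

    def to_newick(self) -> str:
        return str(self.tree)


@dataclass
class EnvTable:
    """Samples x soil-factor matrix with the nine canonical columns."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ENV_FACTORS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"missing soil factors: {missing}")
        extra = [c for c in self.data.columns if c not in ENV_FACTORS]
        if extra:
            raise ValidationError(f"unexpected columns: {extra}")
        self.data = self.data.loc[sorted(self.data.index), list(ENV_FACTORS)]
        if self.data.isna().any().any():
            raise ValidationError("EnvTable contains missing values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_delimited(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def read_community(path, metadata_path, taxa_as_rows: bool | None = None) -> CommunityTable:
    """Read an OTU/ASV abundance matrix plus sample metadata.

    The matrix may have taxa as rows or columns; when ``taxa_as_rows`` is
    None the orientation is auto-detected by matching the metadata's sample
    ids against rows and columns.
    """
    mat = _read_delimited(path)
    meta = _read_delimited(metadata_path)
    if "group" not in meta.columns:
        # allow a two-column sample/group file without index semantics
        meta = pd.read_csv(metadata_path,
                           sep="," if str(metadata_path).endswith(".csv") else "\t")
        if not {"sample", "group"} <= set(meta.columns):
            raise ValidationError(
                "metadata must have 'sample' and 'group' columns")
        meta = meta.set_index("sample")
    samples = set(meta.index)
    if taxa_as_rows is None:
        row_hits = len(samples & set(mat.index))
        col_hits = len(samples & set(mat.columns))
        taxa_as_rows = col_hits > row_hits
    if taxa_as_rows:
        mat = mat.T
    unmatched = sorted(set(mat.index) - samples)
    if unmatched:
        raise ValidationError(
            f"samples absent from metadata: {unmatched}")
    groups = meta.loc[mat.index, "group"].astype(str)
    return CommunityTable(mat.astype(float), groups)


def write_community(table: CommunityTable, path, metadata_path=None) -> None:
    """Write the abundance matrix (samples x taxa, TSV) and optional metadata."""
    table.data.to_csv(path, sep="\t")
    if metadata_path is not None:
        pd.DataFrame({"sample": table.sample_ids,
                      "group": table.groups.values}).to_csv(
            metadata_path, sep="\t", index=False)


def read_tree(path, require_taxa=None) -> PhyloTree:
    """Read a rooted newick tree; optionally demand tips for given taxa."""
    tree = TreeNode.read(path if hasattr(path, "read") else str(path),
                         format="newick")
    pt = PhyloTree(tree)
    if require_taxa is not None:
        pt.require_tips(require_taxa)
    return pt


def write_tree(tree: PhyloTree, path) -> None:
    tree.tree.write(str(path), format="newick")


def read_env(path) -> EnvTable:
    return EnvTable(_read_delimited(path))


def write_env(env: EnvTable, path) -> None:
    env.data.to_csv(path)


def to_relative(table: CommunityTable) -> CommunityTable:
    """Total-sum scale each sample row to relative abundances (rows sum to 1).

    Idempotent; group metadata is preserved.
    """
    totals = table.data.sum(axis=1)
    rel = table.data.div(totals, axis=0)
    return CommunityTable(rel, table.groups.copy())


def rarefy(table: CommunityTable, depth: int, seed: int = 0) -> CommunityTable:
    """Optional seeded rarefaction to a common depth (off by default
    throughout the pipeline; total-sum scaling is the working normalisation).
    """
    rng = np.random.default_rng(seed)
    counts = table.counts.astype(int)
    if (counts.sum(axis=1) < depth).any():
        raise ValidationError("a sample has fewer reads than the target depth")
    out = np.zeros_like(counts)
    for i, row in enumerate(counts):
        pool = np.repeat(np.arange(row.size), row)
        keep = rng.choice(pool, size=depth, replace=False)
        out[i] = np.bincount(keep, minlength=row.size)
    return CommunityTable(
        pd.DataFrame(out, index=table.data.index, columns=table.data.columns),
        table.groups.copy(),
    )


def write_gexf(net, path, graphml_path=None) -> None:
    """Export a co-occurrence network as GEXF (optionally also GraphML).

    Edge ``sign``/``weight`` and node ``module``/``role``/``zi``/``pi``
    attributes are preserved so the file loads directly into Gephi.
    """
    import networkx as nx

    g = net.graph if hasattr(net, "graph") else net
    if g.number_of_edges() == 0:
        warnings.warn("exporting an empty network (zero edges)")
    nx.write_gexf(g, str(path))
    if graphml_path is not None:
        nx.write_graphml(g, str(graphml_path))


def read_gexf(path):
    import networkx as nx

    return nx.read_gexf(str(path), node_type=str)


def write_pairwise(df: pd.DataFrame, path) -> None:
    """Write per-sample-pair null-model results in long format."""
    cols = ["sample_i", "sample_j", "group_i", "group_j",
            "bmntd", "bnti", "rcbray", "process"]
    df.loc[:, cols].to_csv(path, sep="\t", index=False)
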