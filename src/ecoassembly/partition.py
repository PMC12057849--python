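"""Abundant / rare taxon partitioning.

A taxon is *abundant* within a distance group when its minimum relative
abundance across that group's samples exceeds 0.1%, and *rare* when its
maximum stays below 0.01%; everything else is *intermediate*. Labels are
per group, so one taxon can be abundant near the disturbance source and
rare far from it.

The combined abundant (rare) table keeps a sample's observed value for a
taxon only when the taxon is abundant (rare) in that sample's own group and
assigns exactly 0 otherwise; columns that are zero everywhere are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CommunityTable, to_relative

ABUNDANT = "abundant"
RARE = "rare"
INTERMEDIATE = "intermediate"

#: default thresholds: 0.1% (abundant) and 0.01% (rare)
DEFAULT_ABUNDANT_THRESH = 0.001
DEFAULT_RARE_THRESH = 0.0001


@dataclass
class PartitionResult:
    """Per-group labels plus the combined abundant and rare sub-tables."""

    labels: pd.DataFrame            # groups x taxa, values in {abundant, rare, intermediate}
    abundant: CommunityTable | None
    rare: CommunityTable | None
    abundant_thresh: float
    rare_thresh: float


def classify_group(table: CommunityTable, group: str,
                   abundant_thresh: float = DEFAULT_ABUNDANT_THRESH,
                   rare_thresh: float = DEFAULT_RARE_THRESH) -> pd.Series:
    """Label every taxon abundant/rare/intermediate within one group.

    Strict inequalities on both sides: abundant iff the group minimum is
    ``> abundant_thresh``; rare iff the group maximum is ``< rare_thresh``.
    Disjoint by construction whenever ``abundant_thresh > rare_thresh``.
    """
    if abundant_thresh <= rare_thresh:
        raise ValueError("abundant_thresh must exceed rare_thresh")
    rel = table if table.is_relative() else to_relative(table)
    samples = rel.samples_in_group(group)
    if not samples:
        raise ValueError(f"no samples in group {group!r}")
    sub = rel.data.loc[samples]
    lo, hi = sub.min(axis=0), sub.max(axis=0)
    labels = pd.Series(INTERMEDIATE, index=rel.data.columns)
    labels[lo > abundant_thresh] = ABUNDANT
    labels[hi < rare_thresh] = RARE
    return labels


def build_partition(table: CommunityTable,
                    abundant_thresh: float = DEFAULT_ABUNDANT_THRESH,
                    rare_thresh: float = DEFAULT_RARE_THRESH) -> PartitionResult:
    """Classify all groups and assemble the combined abundant/rare tables."""
    rel = table if table.is_relative() else to_relative(table)
    groups = rel.group_labels()
    labels = pd.DataFrame(
        {g: classify_group(rel, g, abundant_thresh, rare_thresh) for g in groups}
    ).T  # groups x taxa

    def combined(kind: str) -> CommunityTable | None:
        data = rel.data.copy()
        for g in groups:
            mask = (labels.loc[g] == kind).to_numpy()
            rows = rel.samples_in_group(g)
            data.loc[rows, ~mask] = 0.0
        data = data.loc[:, data.sum(axis=0) > 0]
        keep = data.sum(axis=1) > 0
        if not keep.any():
            return None
        data = data.loc[keep]
        return CommunityTable(data, rel.groups.loc[data.index].copy())

    return PartitionResult(
        labels=labels,
        abundant=combined(ABUNDANT),
        rare=combined(RARE),
        abundant_thresh=abundant_thresh,
        rare_thresh=rare_thresh,
    )
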