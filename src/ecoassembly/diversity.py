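"""Alpha diversity, Bray-Curtis beta diversity, NMDS and PERMANOVA.

Conventions: Shannon in natural log, Simpson as 1 - sum(p^2); both are the
defaults of the standard community-ecology toolchain and are recorded in
the result metadata. Optional one-way ANOVA with unprotected pairwise LSD
comparisons reports group differences in the alpha indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as _skbio_permanova
from sklearn.manifold import MDS

from .io import CommunityTable, to_relative


@dataclass
class AlphaResult:
    """Per-sample alpha indices (shannon in nats, simpson as 1 - D, richness)."""

    values: pd.DataFrame  # columns: shannon, simpson, richness
    metadata: dict


@dataclass
class DistanceMatrixResult:
    sample_ids: list[str]
    matrix: pd.DataFrame  # square symmetric, zero diagonal

    def to_skbio(self) -> DistanceMatrix:
        return DistanceMatrix(self.matrix.to_numpy(), ids=self.sample_ids)


def alpha_diversity(table: CommunityTable) -> AlphaResult:
    """Shannon (-sum p ln p), Simpson (1 - sum p^2) and observed richness."""
    rel = table if table.is_relative() else to_relative(table)
    p = rel.counts
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1)
    simpson = 1.0 - (p**2).sum(axis=1)
    richness = (table.counts > 0).sum(axis=1)
    df = pd.DataFrame(
        {"shannon": shannon, "simpson": simpson, "richness": richness},
        index=rel.data.index,
    )
    return AlphaResult(df, {"shannon_base": "e", "simpson_form": "1-D"})


def bray_curtis(table: CommunityTable) -> DistanceMatrixResult:
    """Pairwise Bray-Curtis dissimilarity on relative abundances."""
    rel = table if table.is_relative() else to_relative(table)
    condensed = pdist(rel.counts, metric="braycurtis")
    mat = pd.DataFrame(squareform(condensed),
                       index=rel.data.index, columns=rel.data.index)
    return DistanceMatrixResult(list(rel.data.index), mat)


def _stress1(dist: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 between a target dissimilarity and a configuration."""
    d_hat = squareform(pdist(coords))
    iu = np.triu_indices_from(d_hat, k=1)
    obs, fit = dist[iu], d_hat[iu]
    # monotone regression of configuration distances on dissimilarity ranks
    order = np.argsort(obs, kind="stable")
    from sklearn.isotonic import IsotonicRegression

    disp = IsotonicRegression().fit_transform(obs[order], fit[order])
    num = float(((fit[order] - disp) ** 2).sum())
    den = float((fit[order] ** 2).sum())
    return np.sqrt(num / den) if den > 0 else 0.0


def nmds(dist: DistanceMatrixResult, k: int = 2, seed: int = 0,
         n_restarts: int = 20) -> tuple[pd.DataFrame, float]:
    """Non-metric MDS in ``k`` dimensions; best (lowest stress-1) of
    ``n_restarts`` random starts. Coordinates are centered; deterministic
    given the seed.
    """
    d = dist.matrix.to_numpy()
    n = d.shape[0]
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} samples for {k}-D NMDS")
    if np.allclose(d[np.triu_indices(n, 1)], d[np.triu_indices(n, 1)][0] if n > 1 else 0):
        import warnings

        warnings.warn("degenerate (all-equal) distances; returning zero-stress layout")
    best_coords, best_stress = None, np.inf
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        rs = int(rng.integers(0, 2**31 - 1))
        model = MDS(n_components=k, metric_mds=False, metric="precomputed",
                    init="random", n_init=1, random_state=rs,
                    normalized_stress=False, max_iter=300, eps=1e-9)
        coords = model.fit_transform(d)
        s = _stress1(d, coords)
        if s < best_stress:
            best_stress, best_coords = s, coords
    best_coords = best_coords - best_coords.mean(axis=0)
    cols = [f"NMDS{i + 1}" for i in range(k)]
    return pd.DataFrame(best_coords, index=dist.sample_ids, columns=cols), best_stress


def permanova(dist: DistanceMatrixResult, groups: pd.Series,
              n_perm: int = 999, seed: int = 0) -> dict:
    """Permutational MANOVA on a dissimilarity matrix.

    Pseudo-F from among/within sums of squares of the Gower-centered
    matrix; p = (1 + #{perm F >= obs F}) / (1 + n_perm).
    """
    labels = groups.loc[dist.sample_ids]
    counts = labels.value_counts()
    if (counts < 2).any() or len(counts) < 2:
        raise ValueError("PERMANOVA needs >= 2 groups with >= 2 samples each")
    res = _skbio_permanova(dist.to_skbio(), labels.to_numpy(),
                           permutations=n_perm, seed=seed)
    f = float(res["test statistic"])
    # R^2 = SS_among / SS_total from the pseudo-F identity
    a, n = len(counts), len(labels)
    r2 = 1.0 / (1.0 + (n - a) / ((a - 1) * f))
    return {"pseudo_F": f, "R2": r2, "p": float(res["p-value"]),
            "n_perm": n_perm, "n_groups": a, "n_samples": n}


def anova_lsd(alpha: AlphaResult, groups: pd.Series, index: str = "shannon",
              log1p: bool = False) -> dict:
    """One-way ANOVA plus unprotected pairwise LSD t-tests on an alpha index.

    ``log1p`` optionally transforms skewed indices before testing.
    """
    y = alpha.values[index].astype(float)
    if log1p:
        y = np.log1p(y)
    labels = groups.loc[y.index]
    by_group = {g: y[labels == g].to_numpy() for g in sorted(labels.unique())}
    f, p = stats.f_oneway(*by_group.values())
    n, a = len(y), len(by_group)
    mse = sum(((v - v.mean()) ** 2).sum() for v in by_group.values()) / (n - a)
    pairs = {}
    names = list(by_group)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            gi, gj = by_group[names[i]], by_group[names[j]]
            se = np.sqrt(mse * (1 / len(gi) + 1 / len(gj)))
            t = (gi.mean() - gj.mean()) / se
            pairs[(names[i], names[j])] = {
                "diff": float(gi.mean() - gj.mean()),
                "t": float(t),
                "p": float(2 * stats.t.sf(abs(t), df=n - a)),
            }
    return {"F": float(f), "p": float(p), "df": (a - 1, n - a), "lsd": pairs}
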