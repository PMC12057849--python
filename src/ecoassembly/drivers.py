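"""Environmental attribution of diversity and assembly.

Four analyses:

* ``lmg_importance`` — multiple regression of an alpha-diversity index on
  the nine soil factors with LMG relative-importance decomposition: each
  factor's share is its sequential R-squared increase averaged over all
  orderings, computed exactly from the full 2^9 subset-R-squared table.
  Shares are non-negative and sum to the full-model R-squared.
* ``univariate_trends`` — per-factor OLS slope / R-squared / p, the source
  of sign statements ("negatively correlated with salt").
* ``envfit_mc`` — redundancy analysis (RDA) of Hellinger-transformed
  abundances on standardised factors, then a Monte-Carlo (permutation)
  R-squared per factor against the 2-axis site-score space.
* ``bnti_env_regression`` — OLS of pairwise betaNTI on pairwise absolute
  environmental differences, with a Mantel-style permutation p (sample
  identities are permuted, because pairs sharing a sample are not
  independent).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd

from .io import CommunityTable, EnvTable, to_relative


def _ols_r2(x: np.ndarray, y: np.ndarray) -> float:
    """R-squared of OLS of y on x (with intercept)."""
    xd = np.column_stack([np.ones(len(y)), x]) if x.ndim == 2 else \
        np.column_stack([np.ones(len(y)), x[:, None]])
    beta, *_ = np.linalg.lstsq(xd, y, rcond=None)
    resid = y - xd @ beta
    tss = ((y - y.mean()) ** 2).sum()
    return float(1.0 - (resid**2).sum() / tss) if tss > 0 else 0.0


@dataclass
class ImportanceResult:
    total_r2: float
    shares: pd.Series         # per factor, sums to total_r2
    share_pct: pd.Series      # shares as % of explained variance
    univariate_sign: pd.Series


def lmg_importance(env: EnvTable, response: pd.Series) -> ImportanceResult:
    """Exact LMG decomposition of the 9-factor regression R-squared.

    Computes R-squared for all 2^p predictor subsets, then averages each
    factor's sequential contribution over orderings with the standard
    |S|!(p-|S|-1)!/p! weights. Aliased (rank-deficient) columns are
    dropped with a warning and receive share 0.
    """
    x = env.data.loc[response.index].to_numpy(dtype=float)
    y = response.to_numpy(dtype=float)
    names = list(env.data.columns)
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
    # drop aliased columns
    keep = []
    for j in range(x.shape[1]):
        trial = x[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
        else:
            import warnings

            warnings.warn(f"dropping aliased predictor {names[j]!r}")
    p = len(keep)
    r2: dict[frozenset, float] = {frozenset(): 0.0}
    for size in range(1, p + 1):
        for subset in combinations(range(p), size):
            r2[frozenset(subset)] = _ols_r2(x[:, [keep[j] for j in subset]], y)
    shares = np.zeros(len(names))
    for jpos, j in enumerate(keep):
        acc = 0.0
        others = [k for k in range(p) if k != jpos]
        for size in range(0, p):
            w = factorial(size) * factorial(p - size - 1) / factorial(p)
            for subset in combinations(others, size):
                s = frozenset(subset)
                acc += w * (r2[s | {jpos}] - r2[s])
        shares[j] = acc
    total = r2[frozenset(range(p))]
    shares_s = pd.Series(shares, index=names)
    pct = shares_s / total * 100.0 if total > 0 else shares_s * 0.0
    signs = univariate_trends(env, response)["slope"].apply(np.sign)
    return ImportanceResult(total, shares_s, pct, signs)


def univariate_trends(env: EnvTable, response: pd.Series) -> pd.DataFrame:
    """Per-factor OLS slope, R-squared and t-test p-value."""
    from scipy import stats

    y = response.to_numpy(dtype=float)
    rows = {}
    for f in env.data.columns:
        x = env.data.loc[response.index, f].to_numpy(dtype=float)
        if np.std(x) == 0:
            import warnings

            warnings.warn(f"zero-variance factor {f!r}")
            rows[f] = {"slope": np.nan, "r2": np.nan, "p": np.nan}
            continue
        res = stats.linregress(x, y)
        rows[f] = {"slope": res.slope, "r2": res.rvalue**2, "p": res.pvalue}
    return pd.DataFrame(rows).T


def _hellinger(x: np.ndarray) -> np.ndarray:
    rows = x.sum(axis=1, keepdims=True)
    return np.sqrt(x / rows)


def _stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


@dataclass
class FitResult:
    axis_variance_pct: tuple[float, float]  # % of community variance on RDA1+RDA2
    table: pd.DataFrame                     # per factor: r2, p, stars


def envfit_mc(table: CommunityTable, env: EnvTable, n_perm: int = 999,
              seed: int = 0, transform: str = "hellinger") -> FitResult:
    """RDA of the community on the soil factors plus a Monte-Carlo test.

    The community matrix is Hellinger-transformed (switchable to none /
    log1p) and column-centred; the factor matrix is standardised. Factor
    R-squared is the squared multiple correlation of the factor with the
    first two constrained-axis site scores. The permutation p refits the
    whole ordination with the factor's rows permuted inside the constraint
    matrix — permuting against fixed site scores would be anti-conservative
    because the tested factor itself helps shape the axes.
    """
    rel = table if table.is_relative() else to_relative(table)
    samples = [s for s in rel.sample_ids if s in env.data.index]
    y = rel.data.loc[samples].to_numpy(dtype=float)
    if transform == "hellinger":
        y = _hellinger(y)
    elif transform == "log1p":
        y = np.log1p(y)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    y = y - y.mean(axis=0)
    x = env.data.loc[samples].to_numpy(dtype=float)
    n, p = x.shape
    if p > n - 1:
        raise ValueError("more factors than samples - 1")
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)

    # reduce Y to an inner-product-preserving basis so refits are cheap
    uy, sy, _ = np.linalg.svd(y, full_matrices=False)
    yr = uy * sy  # n x r, yr @ yr.T == y @ y.T
    total_inertia = float((sy**2).sum())

    def rda_scores(xmat):
        q, _ = np.linalg.qr(xmat)
        fitted = q @ (q.T @ yr)
        u, svals, _ = np.linalg.svd(fitted, full_matrices=False)
        return u[:, :2] * svals[:2], svals[:2] ** 2

    scores, eig = rda_scores(x)
    axis_pct = tuple(100.0 * eig / total_inertia)

    rng = np.random.default_rng(seed)
    perms = [rng.permutation(n) for _ in range(n_perm)]
    rows = {}
    for i, f in enumerate(env.data.columns):
        obs = _ols_r2(scores, x[:, i])
        exceed = 0
        for perm in perms:
            xp = x.copy()
            xp[:, i] = x[perm, i]
            p_scores, _ = rda_scores(xp)
            if _ols_r2(p_scores, xp[:, i]) >= obs:
                exceed += 1
        pval = (1 + exceed) / (1 + n_perm)
        rows[f] = {"r2": obs, "p": pval, "stars": _stars(pval)}
    return FitResult(axis_pct, pd.DataFrame(rows).T)


def bnti_env_regression(pairwise: pd.DataFrame, env: EnvTable, factor: str,
                        n_perm: int = 999, seed: int = 0) -> dict:
    """Regress pairwise betaNTI on |env_i - env_j| for one soil factor.

    Significance by Mantel-type permutation: sample identities are permuted
    and the environmental differences recomputed, preserving the shared-
    sample dependence structure of pairs.
    """
    if factor not in env.data.columns:
        raise KeyError(f"unknown factor {factor!r}")
    df = pairwise.dropna(subset=["bnti"])
    vals = env.data[factor]
    if vals.std() == 0:
        return {"slope": np.nan, "r2": np.nan, "p": np.nan, "n_pairs": len(df)}
    diffs = np.abs(vals.loc[df["sample_i"]].to_numpy()
                   - vals.loc[df["sample_j"]].to_numpy())
    y = df["bnti"].to_numpy(dtype=float)

    from scipy import stats

    res = stats.linregress(diffs, y)
    obs_r2 = res.rvalue**2
    rng = np.random.default_rng(seed)
    samples = list(vals.index)
    idx_i = [samples.index(s) for s in df["sample_i"]]
    idx_j = [samples.index(s) for s in df["sample_j"]]
    v = vals.to_numpy(dtype=float)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(samples))
        pd_diff = np.abs(v[perm[idx_i]] - v[perm[idx_j]])
        if np.std(pd_diff) == 0:
            continue
        r = np.corrcoef(pd_diff, y)[0, 1]
        if r**2 >= obs_r2:
            exceed += 1
    return {"slope": float(res.slope), "r2": float(obs_r2),
            "p": (1 + exceed) / (1 + n_perm), "n_pairs": len(df)}
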