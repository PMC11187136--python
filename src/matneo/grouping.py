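"""Per-module dyad classification into groups A and B.

Each maternal factor module is reduced to a single binary variable per
dyad: dyads are compared by Gower's mixed-type distance (or Euclidean
Minkowski distance on standardized values when every variable in the
module is interval), clustered by ward.D agglomeration on the raw
dissimilarities, and the tree is cut into two groups. Group 'A' is the
larger cluster (ties go to the cluster containing the lexicographically
smallest dyad id); downstream tests are label-symmetric, so the
orientation is a reporting convention only.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .factors import FactorTable

__all__ = [
    "module_distance",
    "ward_d_linkage",
    "cluster_dyads",
    "DyadGrouping",
    "module_independence",
    "scaled_module_matrix",
]


def module_distance(
    ft: FactorTable, module_vars, minkowski_exponent: float = 2.0
) -> DistanceMatrix:
    """Pairwise dyad distances over the variables of one module.

    All-interval modules use the Minkowski distance (exponent 2 by
    default) on standardized values. Mixed modules use Gower's distance:
    binary contributes a 0/1 mismatch, ordinal a range-normalized
    absolute difference of level ranks, interval a range-normalized
    absolute difference; the dyad-pair distance is the mean over
    variables observed in both dyads. A pair with no co-observed
    variable gets the mean of the defined distances, with a warning.
    """
    module_vars = list(module_vars)
    if not module_vars:
        raise ValueError("module has no variables")
    sub = ft.subset(module_vars)
    enc = sub.encoded().to_numpy(dtype=float)
    n = enc.shape[0]
    all_interval = all(sub.types[v] == "interval" for v in module_vars)
    if all_interval:
        std = np.nanstd(enc, axis=0, ddof=0)
        std[std == 0] = 1.0
        z = (enc - np.nanmean(enc, axis=0)) / std
        d = np.zeros((n, n))
        for i in range(n):
            diff = np.abs(z[i] - z[i + 1 :])
            obs = np.isfinite(diff)
            # Minkowski over co-observed variables
            with np.errstate(invalid="ignore"):
                vals = np.where(obs, diff, 0.0) ** minkowski_exponent
            s = vals.sum(axis=1) ** (1.0 / minkowski_exponent)
            s[obs.sum(axis=1) == 0] = np.nan
            d[i, i + 1 :] = s
            d[i + 1 :, i] = s
    else:
        rng_ = np.nanmax(enc, axis=0) - np.nanmin(enc, axis=0)
        rng_[~np.isfinite(rng_)] = 1.0
        rng_[rng_ == 0] = 1.0
        is_binary = np.array([sub.types[v] == "binary" for v in module_vars])
        d = np.zeros((n, n))
        for i in range(n):
            diff = np.abs(enc[i] - enc[i + 1 :])
            contrib = np.where(is_binary, (diff > 0).astype(float), diff / rng_)
            obs = np.isfinite(diff)
            with np.errstate(invalid="ignore"):
                mean = np.where(obs, contrib, 0.0).sum(axis=1) / obs.sum(axis=1)
            mean[obs.sum(axis=1) == 0] = np.nan
            d[i, i + 1 :] = mean
            d[i + 1 :, i] = mean
    if np.isnan(d).any():
        fill = np.nanmean(d[np.triu_indices(n, k=1)])
        warnings.warn(
            "dyad pairs with no co-observed variables; distances imputed "
            "with the matrix mean",
            stacklevel=2,
        )
        d = np.where(np.isnan(d), fill, d)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=[str(i) for i in ft.data.index])


def ward_d_linkage(d: np.ndarray):
    """Agglomerative ward.D linkage on raw dissimilarities.

    Applies the Ward Lance-Williams update directly to the input
    dissimilarities (the classic 'ward.D' flavour, which does not square
    the input first). Returns (merges, heights) where merges is a list of
    frozensets of original indices, in merge order.
    """
    d = np.asarray(d, dtype=float).copy()
    n = d.shape[0]
    active = {i: [i] for i in range(n)}
    work = d.copy()
    np.fill_diagonal(work, np.inf)
    merges = []
    heights = []
    while len(active) > 1:
        flat = int(np.argmin(work))
        ci, cj = divmod(flat, n)
        if ci > cj:
            ci, cj = cj, ci
        h = work[ci, cj]
        members_i, members_j = active[ci], active[cj]
        merged = members_i + members_j
        ni, nj = len(members_i), len(members_j)
        # Lance-Williams ward update against every other active cluster
        for ck in active:
            if ck in (ci, cj):
                continue
            nk = len(active[ck])
            new = (
                (ni + nk) * work[ci, ck]
                + (nj + nk) * work[cj, ck]
                - nk * work[ci, cj]
            ) / (ni + nj + nk)
            work[ci, ck] = work[ck, ci] = new
        del active[cj]
        active[ci] = merged
        work[cj, :] = np.inf
        work[:, cj] = np.inf
        merges.append(frozenset(merged))
        heights.append(float(h))
    return merges, heights


def cut_to_k(merges, n: int, k: int) -> np.ndarray:
    """Cluster labels from the first n-k merges (ward tree cut)."""
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for merged in merges[: n - k]:
        members = sorted(merged)
        root = find(members[0])
        for m in members[1:]:
            parent[find(m)] = root
    roots = [find(i) for i in range(n)]
    _, labels = np.unique(roots, return_inverse=True)
    return labels


@dataclass
class DyadGrouping:
    """A/B labels per dyad for one module."""

    labels: pd.Series  # dyad id -> 'A' | 'B'
    heights: list = field(default_factory=list)
    orientation: str = "A=larger cluster; tie -> smallest dyad id"

    def counts(self) -> pd.Series:
        return self.labels.value_counts()


def cluster_dyads(dm: DistanceMatrix, k: int = 2) -> DyadGrouping:
    """ward.D clustering of dyads, cut to k=2 groups, labelled A/B."""
    n = dm.shape[0]
    if n < 2:
        raise ValueError("need at least 2 dyads to cluster")
    merges, heights = ward_d_linkage(dm.data)
    labels_num = cut_to_k(merges, n, min(k, n))
    ids = list(dm.ids)
    groups = {}
    for lab in np.unique(labels_num):
        groups[lab] = sorted(ids[i] for i in np.flatnonzero(labels_num == lab))
    # orientation: A = larger cluster; tie -> cluster with smallest dyad id
    order = sorted(groups, key=lambda lab: (-len(groups[lab]), groups[lab][0]))
    name = {}
    letters = [chr(ord("A") + i) for i in range(len(order))]
    for letter, lab in zip(letters, order):
        name[lab] = letter
    labels = pd.Series(
        {ids[i]: name[labels_num[i]] for i in range(n)}, name="group"
    ).loc[ids]
    return DyadGrouping(labels=labels, heights=heights)


def module_independence(groupings: pd.DataFrame) -> pd.DataFrame:
    """Chi-squared test on every module-pair's 2x2 A/B table, BH-adjusted.

    ``groupings`` is a dyads x modules frame of 'A'/'B' labels.
    """
    modules = list(groupings.columns)
    if len(modules) < 2:
        raise ValueError("need at least 2 modules")
    rows = []
    for ma, mb in itertools.combinations(modules, 2):
        sub = groupings[[ma, mb]].dropna()
        tab = pd.crosstab(sub[ma], sub[mb])
        if tab.shape != (2, 2):
            rows.append({"module_a": ma, "module_b": mb, "chi2": np.nan, "p": np.nan})
            continue
        chi2, p, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
        rows.append({"module_a": ma, "module_b": mb, "chi2": chi2, "p": p})
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["p_adj"] = np.nan
    if ok.any():
        out.loc[ok, "p_adj"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    out["significant"] = out["p_adj"] <= 0.05
    return out


def scaled_module_matrix(ft: FactorTable, module_vars) -> pd.DataFrame:
    """Rank-coded, z-scaled module matrix for heatmap export."""
    sub = ft.subset(list(module_vars))
    enc = sub.encoded()
    return (enc - enc.mean()) / enc.std(ddof=1).replace(0, 1.0)
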