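"""Mixed-type pairwise association testing and the maternal factor network.

Association tests dispatch on the declared variable types:

* interval/ordinal vs interval/ordinal -> Spearman rank correlation;
* binary vs interval/ordinal -> point-biserial correlation (Pearson on
  the 0/1 coding);
* binary vs binary -> chi-squared on the 2x2 table (Fisher's exact test
  when any expected cell is below 5).

p-values are Benjamini-Hochberg adjusted *within each of the three
method families separately*. Variable pairs whose adjusted p is <= alpha
become edges of an undirected, unweighted network; communities are found
by Louvain modularity maximization at a configurable resolution, with
isolated nodes pooled into a single catch-all module.
"""

from __future__ import annotations

import itertools
from math import comb, factorial

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .factors import FactorTable

__all__ = [
    "pairwise_associate",
    "build_network",
    "detect_modules",
    "betweenness",
    "write_graphml",
]

EXACT_SPEARMAN_MAX_N = 7  # full enumeration of n! rank permutations
MC_SPEARMAN_PERMS = 50_000  # seeded Monte-Carlo p for n in (7, 10)


def _spearman_stat(xr: np.ndarray, yr: np.ndarray) -> float:
    xr = xr - xr.mean()
    yr = yr - yr.mean()
    denom = np.sqrt((xr**2).sum() * (yr**2).sum())
    if denom == 0:
        return np.nan
    return float((xr * yr).sum() / denom)


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Exact (or seeded Monte-Carlo for n=8,9) two-sided permutation p."""
    n = len(x)
    xr = stats.rankdata(x)
    yr = stats.rankdata(y)
    if n <= EXACT_SPEARMAN_MAX_N:
        perms = np.array(list(itertools.permutations(range(n))))
        total = factorial(n)
    else:
        rng = np.random.default_rng(12345)
        perms = np.array([rng.permutation(n) for _ in range(MC_SPEARMAN_PERMS)])
        total = MC_SPEARMAN_PERMS
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    rhos = (xc[perms] * yc).sum(axis=1) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def _chi2_2x2(tab: np.ndarray, yates: bool):
    a, b = tab[0]
    c, d = tab[1]
    n = tab.sum()
    row = tab.sum(axis=1)
    col = tab.sum(axis=0)
    denom = row[0] * row[1] * col[0] * col[1]
    if denom == 0:
        return np.nan, np.nan
    det = abs(a * d - b * c)
    if yates:
        det = max(det - n / 2.0, 0.0)
    chi2 = n * det**2 / denom
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def pairwise_associate(
    ft: FactorTable,
    min_n: int = 10,
    yates: bool = False,
    fisher_fallback: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All pairwise associations between maternal variables.

    Observations are pairwise-complete. Pairs with fewer than ``min_n``
    complete observations, or with a zero-variance member on the complete
    cases, are skipped with a reason. Returns (results, skipped);
    ``results`` has columns var_a, var_b, method, family, statistic, p,
    p_adj, n_used with BH adjustment within each method family.
    """
    variables = ft.variables
    if len(variables) < 2:
        raise ValueError("need at least 2 variables")
    enc = ft.encoded()
    cols = {v: enc[v].to_numpy(dtype=float) for v in variables}
    types = ft.types

    rows = []
    skipped = []
    spearman_small = []  # (row_idx, x, y) needing exact p
    for va, vb in itertools.combinations(variables, 2):
        x, y = cols[va], cols[vb]
        mask = np.isfinite(x) & np.isfinite(y)
        n_used = int(mask.sum())
        if n_used < min_n:
            skipped.append({"var_a": va, "var_b": vb, "reason": "too_few_complete", "n_used": n_used})
            continue
        xm, ym = x[mask], y[mask]
        if np.ptp(xm) == 0 or np.ptp(ym) == 0:
            skipped.append({"var_a": va, "var_b": vb, "reason": "zero_variance", "n_used": n_used})
            continue
        ta, tb = types[va], types[vb]
        both_binary = ta == "binary" and tb == "binary"
        any_binary = ta == "binary" or tb == "binary"
        if both_binary:
            tab = np.empty((2, 2))
            for i in (0, 1):
                for j in (0, 1):
                    tab[i, j] = np.sum((xm == i) & (ym == j))
            expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()
            if fisher_fallback and (expected < 5).any():
                stat, p = stats.fisher_exact(tab.astype(int))
                method = "fisher_exact"
            else:
                stat, p = _chi2_2x2(tab, yates=yates)
                method = "chi_squared"
            family = "chi_squared"
        elif any_binary:
            # point-biserial = Pearson with the binary variable 0/1 coded
            r = _pearson(xm, ym)
            stat = r
            p = _t_two_sided(r, n_used)
            method = family = "point_biserial"
        else:
            xr = stats.rankdata(xm)
            yr = stats.rankdata(ym)
            rho = _spearman_stat(xr, yr)
            stat = rho
            if n_used < 10:
                p = None  # filled below by exact enumeration
                spearman_small.append((len(rows), xm, ym))
            else:
                p = _t_two_sided(rho, n_used)
            method = family = "spearman"
        rows.append(
            {
                "var_a": va,
                "var_b": vb,
                "method": method,
                "family": family,
                "statistic": stat,
                "p": p,
                "n_used": n_used,
            }
        )

    results = pd.DataFrame(rows, columns=["var_a", "var_b", "method", "family", "statistic", "p", "n_used"])
    for idx, xm, ym in spearman_small:
        results.loc[idx, "p"] = _spearman_exact_p(xm, ym, results.loc[idx, "statistic"])
    results["p"] = results["p"].astype(float).clip(upper=1.0)
    results["p_adj"] = np.nan
    for fam in results["family"].unique():
        sel = results["family"] == fam
        results.loc[sel, "p_adj"] = multipletests(results.loc[sel, "p"], method="fdr_bh")[1]
    return results, pd.DataFrame(skipped, columns=["var_a", "var_b", "reason", "n_used"])


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    return float((xc * yc).sum() / denom)


def _t_two_sided(r: float, n: int) -> float:
    r = min(max(r, -1.0), 1.0)
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


# -- Network ---------------------------------------------------------------


def build_network(assocs: pd.DataFrame, alpha: float = 0.05, nodes=None) -> nx.Graph:
    """Unweighted graph whose edges are associations with p_adj <= alpha.

    ``nodes`` optionally lists all tested variables so that variables with
    no significant partner still appear as isolated nodes.
    """
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    g.add_nodes_from(assocs["var_a"])
    g.add_nodes_from(assocs["var_b"])
    sig = assocs[assocs["p_adj"] <= alpha]
    for _, row in sig.iterrows():
        if row["var_a"] != row["var_b"]:
            g.add_edge(
                row["var_a"], row["var_b"],
                method=row["method"], statistic=row["statistic"], p_adj=row["p_adj"],
            )
    return g


def detect_modules(
    g: nx.Graph, resolution: float = 0.7, seed: int = 0, restarts: int = 10
) -> pd.Series:
    """Louvain modularity partition at the given resolution.

    The best-modularity partition over ``restarts`` seeded runs is kept
    (ties break on the earliest run), so the result is deterministic
    under ``seed`` and invariant to node input order. Isolated nodes are
    pooled into a single catch-all module carrying the highest module id.
    """
    isolated = sorted((n for n in g.nodes if g.degree(n) == 0), key=str)
    core = g.subgraph(n for n in g.nodes if g.degree(n) > 0)
    assignment: dict = {}
    n_modules = 0
    if core.number_of_nodes() > 0:
        best = None
        best_q = -np.inf
        for i in range(restarts):
            communities = nx.community.louvain_communities(
                core, resolution=resolution, seed=int(seed) + i
            )
            q = nx.community.modularity(core, communities, resolution=resolution)
            if q > best_q + 1e-12:
                best_q = q
                best = communities
        # deterministic module ids: order communities by smallest member
        best = sorted((sorted(c, key=str) for c in best), key=lambda c: str(c[0]))
        for mid, comm in enumerate(best):
            for node in comm:
                assignment[node] = mid
        n_modules = len(best)
    catch_all = n_modules
    for node in isolated:
        assignment[node] = catch_all
    s = pd.Series(assignment, name="module")
    s = s.loc[sorted(s.index, key=str)]
    s.attrs["catch_all_module"] = catch_all if isolated else None
    s.attrs["n_modules"] = n_modules
    return s


def betweenness(g: nx.Graph) -> pd.Series:
    """Unweighted shortest-path betweenness centrality, unnormalized."""
    return pd.Series(nx.betweenness_centrality(g, normalized=False), name="betweenness").sort_index()


def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, path)
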