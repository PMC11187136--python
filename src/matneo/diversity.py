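"""Alpha/beta diversity and distance-based permutation tests.

Implements Shannon/evenness/observed-taxa summaries, Bray-Curtis
distances, t-SNE summarization with mean-split grouping, and the
permutation-test battery used on ecological distance matrices:

* PERMANOVA with one or more crossed terms, overall or marginal
  (drop-one) testing via the Gower-centered inner-product matrix;
* PERMDISP (homogeneity of multivariate dispersions around the
  per-group spatial median in principal-coordinate space);
* MRPP (mean within-group dissimilarity delta with chance-corrected A);
* Kruskal-Wallis trend tests on scalar summaries.

Permutation p-values always follow the (1 + #{extreme}) / (1 + n_perm)
convention and can never be exactly zero.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from sklearn.manifold import TSNE

from .tables import CountTable, CountTableError

__all__ = [
    "alpha_diversity",
    "bray_curtis",
    "tsne_embed",
    "mean_split",
    "pcoa_coords",
    "permanova",
    "permdisp",
    "mrpp",
    "kruskal_trend",
    "PermutationTestResult",
]


# -- Alpha / beta ----------------------------------------------------------


def alpha_diversity(table: CountTable) -> pd.DataFrame:
    """Shannon index H (nats), Pielou evenness J = H/ln(S), observed taxa S.

    J is undefined (NaN) for samples with fewer than 2 observed taxa.
    Intended for rarefied tables so depths are comparable.
    """
    counts = table.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise CountTableError("zero-total sample in alpha_diversity")
    p = counts / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=0)
    observed = (counts > 0).sum(axis=0)
    evenness = np.where(observed >= 2, shannon / np.log(np.maximum(observed, 2)), np.nan)
    return pd.DataFrame(
        {"shannon": shannon, "evenness": evenness, "observed": observed},
        index=table.sample_ids,
    )


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarities between samples, computed on counts."""
    counts = table.counts.to_numpy(dtype=float).T
    if (counts.sum(axis=1) == 0).any():
        raise CountTableError("zero-total sample in bray_curtis")
    return DistanceMatrix(squareform(pdist(counts, metric="braycurtis")), ids=table.sample_ids)


def tsne_embed(dm: DistanceMatrix, seed: int = 0, perplexity: float = 30.0) -> pd.DataFrame:
    """2-D t-SNE of a precomputed distance matrix; deterministic under seed.

    The perplexity is reduced to floor((n - 2) / 3) when the requested
    value is infeasible for the sample size.
    """
    n = dm.shape[0]
    max_perp = (n - 2) // 3
    if max_perp < 1:
        raise ValueError(f"too few samples (n={n}) for a t-SNE embedding")
    eff_perp = min(perplexity, float(max_perp))
    emb = TSNE(
        n_components=2,
        metric="precomputed",
        init="random",
        perplexity=eff_perp,
        random_state=seed,
    ).fit_transform(dm.data)
    return pd.DataFrame(emb, columns=["tsne1", "tsne2"], index=list(dm.ids))


def mean_split(values) -> pd.Series:
    """Label each value 'high' (strictly above the mean) or 'low'."""
    values = pd.Series(values, dtype=float)
    if len(values) < 2:
        raise ValueError("mean_split needs at least 2 values")
    mean = values.mean()
    if values.nunique() == 1:
        warnings.warn("mean_split on a constant vector: all samples 'low'", stacklevel=2)
    return pd.Series(np.where(values > mean, "high", "low"), index=values.index)


# -- Principal coordinates -------------------------------------------------


def pcoa_coords(dm: DistanceMatrix, eig_tol: float = 1e-10):
    """Classical PCoA; axes with non-positive eigenvalues are discarded.

    Bray-Curtis is a semimetric, so negative eigenvalues can occur; they
    are dropped (no Lingoes/Cailliez correction) so that downstream
    consumers (PERMDISP, dbRDA) operate in a real Euclidean space.

    Returns (coords, eigenvalues), coords shaped (n, n_kept), each axis
    scaled so its sum of squares equals its eigenvalue.
    """
    d = np.asarray(dm.data, dtype=float)
    g = _gower_center(d)
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    keep = eigvals > eig_tol * max(eigvals.max(), 1.0)
    coords = eigvecs[:, keep] * np.sqrt(eigvals[keep])
    return coords, eigvals[keep]


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    row = a.mean(axis=0, keepdims=True)
    col = a.mean(axis=1, keepdims=True)
    return a - row - col + a.mean()


# -- Results container -----------------------------------------------------


@dataclass
class PermutationTestResult:
    """Outcome of a distance-based permutation test."""

    method: str
    statistic_name: str
    statistic: float
    p_value: float
    n_permutations: int
    seed: int | None = None
    table: pd.DataFrame | None = None  # per-term rows for PERMANOVA
    extra: dict = field(default_factory=dict)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<{self.method}: {self.statistic_name}={self.statistic:.4g}, "
            f"p={self.p_value:.4g}, n_perm={self.n_permutations}>"
        )


# -- PERMANOVA -------------------------------------------------------------


def _model_matrix(design: pd.DataFrame):
    """Full-rank model matrix with intercept; returns (X, term column slices)."""
    n = len(design)
    blocks = [np.ones((n, 1))]
    slices: dict[str, slice] = {}
    start = 1
    for term in design.columns:
        col = design[term]
        if col.nunique() < 2:
            raise ValueError(f"term {term!r} is constant")
        dummies = pd.get_dummies(col.astype("category"), drop_first=True).to_numpy(float)
        blocks.append(dummies)
        slices[term] = slice(start, start + dummies.shape[1])
        start += dummies.shape[1]
    x = np.hstack(blocks)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("singular design matrix")
    return x, slices


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x.T @ x) @ x.T


def _trace_perm(g: np.ndarray, h: np.ndarray, perms: np.ndarray, chunk: int = 128):
    """tr(G_perm @ H) for each permutation, chunked to bound memory."""
    out = np.empty(len(perms))
    for lo in range(0, len(perms), chunk):
        p = perms[lo : lo + chunk]
        gp = g[p[:, :, None], p[:, None, :]]
        out[lo : lo + chunk] = np.einsum("kij,ij->k", gp, h)
    return out


def permanova(
    dm: DistanceMatrix,
    design,
    n_perm: int | str = 999,
    seed: int = 0,
    by: str = "overall",
) -> PermutationTestResult:
    """Distance-based PERMANOVA on one or more grouping terms.

    The pseudo-F is computed from the Gower-centered inner-product matrix
    G: explained SS = tr(H G), with H the hat matrix of the design.

    ``by='overall'`` tests the whole model; ``by='margin'`` tests each
    term by the increase in residual SS when the term is dropped from the
    full design (Type-III style marginal test). Permutations shuffle the
    rows/columns of the distance matrix.

    ``n_perm='exact'`` (single-term designs only) enumerates every
    distinct assignment of the observed labels; the p-value then is the
    fraction of assignments, the observed one included, with F at least
    as large.
    """
    if isinstance(design, pd.Series):
        design = design.to_frame(name=design.name or "group")
    design = pd.DataFrame(design)
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    if len(design) != n:
        raise ValueError("design length does not match distance matrix")
    g = _gower_center(d)
    ss_total = np.trace(g)
    x_full, slices = _model_matrix(design)
    h_full = _hat(x_full)
    df_res = n - x_full.shape[1]
    ss_res = ss_total - np.trace(g @ h_full)

    if by not in ("overall", "margin"):
        raise ValueError("by must be 'overall' or 'margin'")

    if n_perm == "exact":
        return _permanova_exact(dm, design, g, ss_total, by)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(int(n_perm))])

    rows = []
    if by == "overall":
        terms = [("model", h_full, x_full.shape[1] - 1)]
    else:
        terms = []
        for term, sl in slices.items():
            cols = [j for j in range(x_full.shape[1]) if not (sl.start <= j < sl.stop)]
            h_red = _hat(x_full[:, cols])
            terms.append((term, h_red, sl.stop - sl.start))

    tr_full = _trace_perm(g, h_full, perms)
    for term, h_term, df_term in terms:
        if by == "overall":
            # G is double-centered, so the intercept explains zero SS
            ss_term = np.trace(g @ h_full)
            tr_term_perm = tr_full
        else:
            ss_term = np.trace(g @ h_full) - np.trace(g @ h_term)
            tr_term_perm = tr_full - _trace_perm(g, h_term, perms)
        f_obs = (ss_term / df_term) / (ss_res / df_res)
        ss_res_perm = ss_total - tr_full
        f_perm = (tr_term_perm / df_term) / (ss_res_perm / df_res)
        p = (1.0 + np.sum(f_perm >= f_obs)) / (1.0 + len(perms))
        rows.append(
            {
                "term": term,
                "df": df_term,
                "ss": ss_term,
                "r2": ss_term / ss_total,
                "pseudo_F": f_obs,
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows).set_index("term")
    table.loc["residual"] = [df_res, ss_res, ss_res / ss_total, np.nan, np.nan]
    table.loc["total"] = [n - 1, ss_total, 1.0, np.nan, np.nan]
    first = rows[0]
    return PermutationTestResult(
        method="permanova",
        statistic_name="pseudo-F",
        statistic=first["pseudo_F"],
        p_value=first["p_value"],
        n_permutations=len(perms),
        seed=seed,
        table=table,
        extra={"by": by},
    )


def _permanova_exact(dm, design, g, ss_total, by):
    """Exhaustive enumeration over distinct label assignments (1 term)."""
    if design.shape[1] != 1:
        raise ValueError("exact enumeration supports single-term designs only")
    labels = design.iloc[:, 0].to_numpy()
    n = len(labels)
    levels, counts = np.unique(labels, return_counts=True)
    if len(levels) != 2:
        raise ValueError("exact enumeration supports binary terms only")
    k = counts[0]
    from math import comb

    if comb(n, k) > 200_000:
        raise ValueError("too many assignments for exact enumeration")
    df_term, df_res = 1, n - 2
    f_all = []
    f_obs = None
    obs_set = frozenset(np.flatnonzero(labels == levels[0]).tolist())
    for pos in itertools.combinations(range(n), int(k)):
        lab = np.full(n, levels[1], dtype=object)
        lab[list(pos)] = levels[0]
        x, _ = _model_matrix(pd.DataFrame({"g": lab}))
        h = _hat(x)
        ss_model = np.trace(g @ h)
        f = (ss_model / df_term) / ((ss_total - ss_model) / df_res)
        f_all.append(f)
        if frozenset(pos) == obs_set:
            f_obs = f
    f_all = np.asarray(f_all)
    p = np.mean(f_all >= f_obs - 1e-12)
    return PermutationTestResult(
        method="permanova",
        statistic_name="pseudo-F",
        statistic=float(f_obs),
        p_value=float(p),
        n_permutations=len(f_all),
        seed=None,
        extra={"by": by, "exact": True},
    )


# -- PERMDISP --------------------------------------------------------------


def _spatial_median(points: np.ndarray, max_iter: int = 200, tol: float = 1e-9):
    """Weiszfeld iteration for the geometric median."""
    m = points.mean(axis=0)
    for _ in range(max_iter):
        dist = np.linalg.norm(points - m, axis=1)
        if (dist < 1e-12).any():
            # median coincides with a data point
            return points[np.argmin(dist)]
        w = 1.0 / dist
        new = (points * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(new - m) < tol:
            return new
        m = new
    return m


def _dispersion_f(coords: np.ndarray, codes: np.ndarray, n_groups: int):
    dists = np.empty(len(codes))
    for gidx in range(n_groups):
        mask = codes == gidx
        med = _spatial_median(coords[mask])
        dists[mask] = np.linalg.norm(coords[mask] - med, axis=1)
    grand = dists.mean()
    ss_between = 0.0
    ss_within = 0.0
    for gidx in range(n_groups):
        gd = dists[codes == gidx]
        ss_between += len(gd) * (gd.mean() - grand) ** 2
        ss_within += ((gd - gd.mean()) ** 2).sum()
    df_b = n_groups - 1
    df_w = len(codes) - n_groups
    tol = 1e-12 * max(dists.max() ** 2, 1e-300) * len(codes)
    if ss_within <= tol:
        return np.inf if ss_between > tol else 0.0
    return (ss_between / df_b) / (ss_within / df_w)


def permdisp(
    dm: DistanceMatrix,
    labels,
    n_perm: int = 999,
    seed: int = 0,
    center: str = "median",
) -> PermutationTestResult:
    """Homogeneity of multivariate dispersions.

    Samples are embedded by PCoA (positive-eigenvalue axes); each sample's
    distance to its group's spatial median (or centroid with
    ``center='centroid'``) feeds a one-way ANOVA F whose null
    distribution comes from permuting group labels.
    """
    labels = pd.Series(labels)
    codes, uniques = pd.factorize(labels)
    if len(uniques) < 2:
        raise ValueError("permdisp needs at least 2 groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 members")
    coords, _ = pcoa_coords(dm)
    if center == "centroid":
        f_fun = lambda c: _dispersion_f_centroid(coords, c, len(uniques))  # noqa: E731
    else:
        f_fun = lambda c: _dispersion_f(coords, c, len(uniques))  # noqa: E731
    f_obs = f_fun(codes)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        count += f_fun(rng.permutation(codes)) >= f_obs
    p = (1.0 + count) / (1.0 + n_perm)
    return PermutationTestResult(
        method="permdisp",
        statistic_name="F",
        statistic=float(f_obs),
        p_value=float(p),
        n_permutations=n_perm,
        seed=seed,
        extra={"center": center},
    )


def _dispersion_f_centroid(coords: np.ndarray, codes: np.ndarray, n_groups: int):
    dists = np.empty(len(codes))
    for gidx in range(n_groups):
        mask = codes == gidx
        cen = coords[mask].mean(axis=0)
        dists[mask] = np.linalg.norm(coords[mask] - cen, axis=1)
    grand = dists.mean()
    ss_b = ss_w = 0.0
    for gidx in range(n_groups):
        gd = dists[codes == gidx]
        ss_b += len(gd) * (gd.mean() - grand) ** 2
        ss_w += ((gd - gd.mean()) ** 2).sum()
    tol = 1e-12 * max(dists.max() ** 2, 1e-300) * len(codes)
    if ss_w <= tol:
        return np.inf if ss_b > tol else 0.0
    return (ss_b / (n_groups - 1)) / (ss_w / (len(codes) - n_groups))


# -- MRPP ------------------------------------------------------------------


def mrpp(dm: DistanceMatrix, labels, n_perm: int = 999, seed: int = 0) -> PermutationTestResult:
    """Multiple response permutation procedure.

    delta = sum_g (n_g / N) * mean within-group distance; significance from
    permuting labels (small delta = tight groups); chance-corrected
    within-group agreement A = 1 - delta / mean(delta_perm).
    """
    labels = pd.Series(labels)
    codes, uniques = pd.factorize(labels)
    if len(uniques) < 2:
        raise ValueError("mrpp needs at least 2 groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 members")
    d = np.asarray(dm.data, dtype=float)
    n = len(codes)

    def delta_of(c):
        val = 0.0
        for gidx in range(len(uniques)):
            idx = np.flatnonzero(c == gidx)
            sub = d[np.ix_(idx, idx)]
            m = sub[np.triu_indices(len(idx), k=1)].mean()
            val += (len(idx) / n) * m
        return val

    delta_obs = delta_of(codes)
    rng = np.random.default_rng(seed)
    deltas = np.array([delta_of(rng.permutation(codes)) for _ in range(n_perm)])
    p = (1.0 + np.sum(deltas <= delta_obs)) / (1.0 + n_perm)
    a = 1.0 - delta_obs / deltas.mean()
    return PermutationTestResult(
        method="mrpp",
        statistic_name="delta",
        statistic=float(delta_obs),
        p_value=float(p),
        n_permutations=n_perm,
        seed=seed,
        extra={"A": float(a)},
    )


# -- Kruskal-Wallis --------------------------------------------------------


def kruskal_trend(values, groups) -> PermutationTestResult:
    """Kruskal-Wallis H across ordered groups with tie correction and a
    chi-squared asymptotic p-value. With all values tied p = 1."""
    values = pd.Series(values, dtype=float)
    groups = pd.Series(groups)
    samples = [values[groups == g].to_numpy() for g in pd.unique(groups)]
    if len(samples) < 2:
        raise ValueError("kruskal_trend needs at least 2 groups")
    if values.nunique() == 1:
        return PermutationTestResult(
            method="kruskal_wallis", statistic_name="H", statistic=0.0,
            p_value=1.0, n_permutations=0,
        )
    h, p = stats.kruskal(*samples)
    return PermutationTestResult(
        method="kruskal_wallis",
        statistic_name="H",
        statistic=float(h),
        p_value=float(p),
        n_permutations=0,
    )
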