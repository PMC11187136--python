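"""Associating maternal module groupings with neonatal outcomes.

Three views of "outcome" are covered:

* one-dimensional microbiota summaries (Shannon, evenness, observed
  taxa, t-SNE coordinates) tested per module with two-sided Mann-Whitney
  U, BH-adjusted across modules within each summary;
* community composition, tested by marginal (drop-one) PERMANOVA over
  all module terms jointly and visualized by distance-based redundancy
  analysis (dbRDA) on principal coordinates;
* NICU admission, tested per module by 2x2 odds ratios with Wald 95%
  confidence intervals and Fisher exact p-values, optionally stratified
  by preterm status.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .diversity import pcoa_coords, permanova

__all__ = [
    "module_vs_summary",
    "marginal_permanova_modules",
    "dbrda",
    "OrdinationResult",
    "nicu_odds_ratios",
]


def module_vs_summary(groupings: pd.DataFrame, summaries: pd.DataFrame) -> pd.DataFrame:
    """Mann-Whitney battery: every module (A/B) x every scalar summary.

    Inputs are aligned on their index (dyad id); BH adjustment is applied
    across modules within each dependent summary variable. Cells where a
    group is empty after matching are recorded as skipped.
    """
    common = groupings.index.intersection(summaries.index)
    if len(common) == 0:
        raise ValueError("no dyads shared between groupings and summaries")
    g = groupings.loc[common]
    s = summaries.loc[common]
    rows = []
    for summary in s.columns:
        for module in g.columns:
            sub = pd.DataFrame({"grp": g[module], "val": s[summary]}).dropna()
            a = sub.loc[sub["grp"] == "A", "val"]
            b = sub.loc[sub["grp"] == "B", "val"]
            if len(a) == 0 or len(b) == 0:
                rows.append(
                    {"summary": summary, "module": module, "n_a": len(a),
                     "n_b": len(b), "statistic": np.nan, "p": np.nan,
                     "skipped": "empty_group"}
                )
                continue
            if a.nunique() == 1 and b.nunique() == 1 and a.iloc[0] == b.iloc[0]:
                u, p = len(a) * len(b) / 2.0, 1.0
            else:
                u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            rows.append(
                {"summary": summary, "module": module, "n_a": len(a),
                 "n_b": len(b), "statistic": float(u), "p": float(p),
                 "skipped": ""}
            )
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    for summary in out["summary"].unique():
        sel = (out["summary"] == summary) & out["p"].notna()
        if sel.any():
            out.loc[sel, "p_adj"] = multipletests(out.loc[sel, "p"], method="fdr_bh")[1]
    return out


def marginal_permanova_modules(
    dm: DistanceMatrix, groupings: pd.DataFrame, n_perm: int = 999, seed: int = 0
) -> pd.DataFrame:
    """One multi-term PERMANOVA with all modules; marginal p per module.

    Modules that are single-level (or missing) among the matched dyads
    are dropped with a note in the output.
    """
    ids = list(dm.ids)
    g = groupings.loc[[i for i in ids if i in groupings.index]]
    if len(g) != len(ids):
        raise ValueError("distance matrix contains dyads without groupings")
    g = g.loc[ids]
    kept, dropped = [], []
    for module in g.columns:
        if g[module].nunique(dropna=True) < 2 or g[module].isna().any():
            dropped.append(module)
        else:
            kept.append(module)
    if not kept:
        raise ValueError("no usable module terms")
    res = permanova(dm, g[kept], n_perm=n_perm, seed=seed, by="margin")
    table = res.table.loc[kept].reset_index().rename(columns={"term": "module"})
    for module in dropped:
        table.loc[len(table)] = {"module": module, "df": np.nan, "ss": np.nan,
                                 "r2": np.nan, "pseudo_F": np.nan, "p_value": np.nan}
    table["dropped"] = table["module"].isin(dropped)
    return table


@dataclass
class OrdinationResult:
    """dbRDA decomposition of a distance matrix under constraints."""

    constrained_eigenvalues: np.ndarray
    unconstrained_eigenvalues: np.ndarray
    site_scores: pd.DataFrame  # samples x constrained axes
    biplot_scores: pd.DataFrame  # constraint columns x constrained axes
    total_inertia: float
    constrained_inertia: float
    unconstrained_inertia: float
    rank_deficient: bool = False
    extra: dict = field(default_factory=dict)

    @property
    def constrained_fraction(self) -> float:
        return self.constrained_inertia / self.total_inertia


def dbrda(dm: DistanceMatrix, constraints: pd.DataFrame) -> OrdinationResult:
    """Distance-based redundancy analysis (capscale-style).

    The distance matrix is embedded by PCoA (positive-eigenvalue axes
    retained); site coordinates are regressed on the centered one-hot
    constraint design; the fitted variation is eigen-decomposed into
    constrained axes and the residual into unconstrained axes. Total
    inertia (sum of retained PCoA eigenvalues) splits exactly into
    constrained + unconstrained parts.
    """
    constraints = pd.DataFrame(constraints)
    ids = list(dm.ids)
    constraints = constraints.loc[ids]
    coords, eigvals = pcoa_coords(dm)
    total_inertia = float(eigvals.sum())

    # one-hot with drop-first, centered; non-numeric columns get dummies
    parts = []
    names = []
    for col in constraints.columns:
        series = constraints[col]
        if series.nunique() < 2:
            raise ValueError(f"constraint {col!r} is constant")
        if series.dtype.kind in "ifu":
            parts.append(series.to_numpy(float)[:, None])
            names.append(col)
        else:
            dummies = pd.get_dummies(series.astype("category"), drop_first=True)
            for level in dummies.columns:
                parts.append(dummies[level].to_numpy(float)[:, None])
                names.append(f"{col}{level}")
    x = np.hstack(parts)
    x = x - x.mean(axis=0)
    rank = np.linalg.matrix_rank(x)
    rank_deficient = rank < x.shape[1]

    beta, *_ = np.linalg.lstsq(x, coords, rcond=None)
    fitted = x @ beta
    resid = coords - fitted

    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    c_eig = s**2
    keep = c_eig > 1e-12 * max(total_inertia, 1.0)
    c_eig = c_eig[keep]
    site = u[:, keep] * s[keep]

    _, sr, _ = np.linalg.svd(resid, full_matrices=False)
    u_eig = sr**2
    u_eig = u_eig[u_eig > 1e-12 * max(total_inertia, 1.0)]

    axes = [f"dbRDA{i + 1}" for i in range(site.shape[1])]
    site_scores = pd.DataFrame(site, index=ids, columns=axes)
    bip = np.zeros((x.shape[1], site.shape[1]))
    for j in range(x.shape[1]):
        xc = x[:, j]
        for a in range(site.shape[1]):
            sa = site[:, a]
            denom = np.sqrt((xc**2).sum() * (sa**2).sum())
            bip[j, a] = (xc * sa).sum() / denom if denom > 0 else 0.0
    biplot_scores = pd.DataFrame(bip, index=names, columns=axes)

    return OrdinationResult(
        constrained_eigenvalues=c_eig,
        unconstrained_eigenvalues=u_eig,
        site_scores=site_scores,
        biplot_scores=biplot_scores,
        total_inertia=total_inertia,
        constrained_inertia=float((fitted**2).sum()),
        unconstrained_inertia=float((resid**2).sum()),
        rank_deficient=rank_deficient,
    )


def nicu_odds_ratios(
    groupings: pd.DataFrame,
    outcome: pd.Series,
    strata: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-module odds ratios for a binary outcome.

    The 2x2 table is (group A/B) x (outcome yes/no); OR is the
    cross-product ratio with a Wald 95% CI, exp(ln OR +/- 1.96 sqrt(sum
    1/n_ij)); p is Fisher's exact two-sided; BH across modules (within
    each stratum). Dyads with unknown outcome are excluded listwise.
    Zero cells receive the Haldane-Anscombe 0.5 correction, flagged.
    """
    outcome = pd.Series(outcome)
    frames = []
    if strata is None:
        strata_iter = [("all", pd.Series(True, index=outcome.index))]
    else:
        strata = pd.Series(strata)
        strata_iter = [("all", pd.Series(True, index=outcome.index))] + [
            (str(level), strata == level) for level in sorted(strata.dropna().unique(), key=str)
        ]
    for label, mask in strata_iter:
        rows = []
        for module in groupings.columns:
            sub = pd.DataFrame(
                {"grp": groupings[module], "out": outcome}
            ).loc[mask.reindex(groupings.index, fill_value=False)].dropna()
            a = ((sub["grp"] == "A") & (sub["out"] == 1)).sum()
            b = ((sub["grp"] == "A") & (sub["out"] == 0)).sum()
            c = ((sub["grp"] == "B") & (sub["out"] == 1)).sum()
            d = ((sub["grp"] == "B") & (sub["out"] == 0)).sum()
            rows.append({"stratum": label, "module": module, **_odds_ratio_row(a, b, c, d)})
        frame = pd.DataFrame(rows)
        ok = frame["p"].notna()
        frame["p_adj"] = np.nan
        if ok.any():
            frame.loc[ok, "p_adj"] = multipletests(frame.loc[ok, "p"], method="fdr_bh")[1]
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def _odds_ratio_row(a: int, b: int, c: int, d: int) -> dict:
    table = np.array([[a, b], [c, d]], dtype=float)
    if table.sum() == 0 or (table.sum(axis=1) == 0).any():
        return {"a": a, "b": b, "c": c, "d": d, "odds_ratio": np.nan,
                "ci_low": np.nan, "ci_high": np.nan, "p": np.nan, "corrected": False}
    corrected = (table == 0).any()
    work = table + 0.5 if corrected else table
    orat = (work[0, 0] * work[1, 1]) / (work[0, 1] * work[1, 0])
    se = np.sqrt((1.0 / work).sum())
    ci_low = float(np.exp(np.log(orat) - 1.96 * se))
    ci_high = float(np.exp(np.log(orat) + 1.96 * se))
    _, p = stats.fisher_exact(table.astype(int), alternative="two-sided")
    return {"a": a, "b": b, "c": c, "d": d, "odds_ratio": float(orat),
            "ci_low": ci_low, "ci_high": ci_high, "p": float(p),
            "corrected": bool(corrected)}
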