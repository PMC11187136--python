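"""Random-forest prediction of NICU admission from maternal variables.

The modelling chain mirrors clinical microbiome practice: ordinal
variables are dichotomized at the most balanced level boundary, binary
variables one-hot encoded, features screened by unadjusted Spearman
association with the outcome, missing values imputed by iterative
random-forest proximity averaging, and a random forest evaluated by
stratified cross-validated auROC with mean-decrease-in-Gini importances.

By default screening and imputation are refit inside each training fold
so the cross-validated auROC is leak-free; ``screen_scope='all_data'``
reproduces the simpler screen-once-on-everything ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .factors import FactorTable

__all__ = [
    "dichotomize_ordinal",
    "encode_features",
    "screen_features",
    "impute_missing",
    "fit_rf",
    "feature_corr",
    "RiskModelReport",
]


def dichotomize_ordinal(values: pd.Series, levels=None) -> pd.Series:
    """Split an ordinal variable into low/high at the most balanced cut.

    The cut point minimizes |n_high - n_low|; among ties, the cut
    placing the overall median level in the 'low' group wins. Returns a
    0/1 series (1 = high); a single-level variable raises ValueError.
    """
    values = pd.Series(values)
    observed = values.dropna()
    if levels is None:
        levels = sorted(observed.unique())
    levels = [lv for lv in levels if lv in set(observed)]
    if len(levels) < 2:
        raise ValueError("single observed level; variable should be dropped")
    counts = np.array([int((observed == lv).sum()) for lv in levels])
    total = counts.sum()
    cum = np.cumsum(counts)
    median_idx = int(np.searchsorted(cum, (total + 1) / 2.0))
    candidates = []
    for cut in range(len(levels) - 1):  # low = levels[:cut+1]
        n_low = cum[cut]
        imbalance = abs(total - 2 * n_low)
        median_in_low = 0 if median_idx <= cut else 1
        candidates.append((imbalance, median_in_low, cut))
    _, _, best = min(candidates)
    low = set(levels[: best + 1])
    out = values.map(lambda v: (0.0 if v in low else 1.0) if pd.notna(v) else np.nan)
    out.attrs["cut_after_level"] = levels[best]
    return out


def encode_features(ft: FactorTable) -> pd.DataFrame:
    """Numeric design matrix: one 0/1 indicator per binary or dichotomized
    ordinal variable, interval variables passed through. Single-level
    variables are dropped (logged in ``attrs['dropped']``)."""
    cols = {}
    dropped = []
    for var in ft.variables:
        t = ft.types[var]
        series = ft.data[var]
        if series.dropna().nunique() < 2:
            dropped.append(var)
            continue
        if t == "interval":
            cols[var] = series.astype(float)
        elif t == "binary":
            codes = ft.numeric_codes(var)
            cols[var] = pd.Series(codes, index=ft.data.index)
        else:
            codes = pd.Series(ft.numeric_codes(var), index=ft.data.index)
            cols[var] = dichotomize_ordinal(codes)
    out = pd.DataFrame(cols, index=ft.data.index)
    out.attrs["dropped"] = dropped
    return out


def screen_features(x: pd.DataFrame, y: pd.Series, alpha: float = 0.05) -> list[str]:
    """Columns whose unadjusted Spearman p-value against y is <= alpha.

    Constant columns are skipped; raises if nothing passes.
    """
    y = pd.Series(y).loc[x.index]
    selected = []
    for col in x.columns:
        sub = pd.DataFrame({"x": x[col], "y": y}).dropna()
        if sub["x"].nunique() < 2 or sub["y"].nunique() < 2 or len(sub) < 3:
            continue
        _, p = stats.spearmanr(sub["x"], sub["y"])
        if np.isfinite(p) and p <= alpha:
            selected.append(col)
    if not selected:
        raise ValueError(
            "no feature passed screening; the cohort is too small or the "
            "outcome carries no signal"
        )
    return selected


def impute_missing(
    x: pd.DataFrame,
    y: pd.Series,
    seed: int = 0,
    max_iter: int = 5,
    tol: float = 1e-6,
    max_missing: float = 0.5,
    n_trees: int = 100,
) -> pd.DataFrame:
    """Iterative random-forest proximity imputation.

    Columns start at their median (interval) or mode (binary); then a
    forest is fit on the completed matrix and every originally-missing
    entry is replaced by the proximity-weighted average (weighted vote
    for binary columns) of the observed entries of its column. Stops
    after ``max_iter`` rounds or when the largest change is below
    ``tol``. Columns missing more than ``max_missing`` are dropped
    (recorded in ``attrs['dropped']``).
    """
    x = x.copy()
    frac = x.isna().mean()
    dropped = list(frac[frac > max_missing].index)
    x = x.drop(columns=dropped)
    y = pd.Series(y).loc[x.index]
    miss = x.isna()
    binary_cols = {c for c in x.columns if set(x[c].dropna().unique()) <= {0.0, 1.0}}
    filled = x.copy()
    for c in x.columns:
        if c in binary_cols:
            mode = x[c].mode(dropna=True)
            fill = mode.iloc[0] if len(mode) else 0.0
        else:
            fill = x[c].median()
        filled[c] = x[c].fillna(fill)
    if not miss.to_numpy().any():
        filled.attrs["dropped"] = dropped
        filled.attrs["iterations"] = 0
        return filled

    for it in range(max_iter):
        rf = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed, n_jobs=1
        ).fit(filled.to_numpy(), y.to_numpy())
        leaves = rf.apply(filled.to_numpy())  # (n, trees)
        prox = _proximity(leaves)
        new = filled.copy()
        for c in x.columns:
            col_miss = miss[c].to_numpy()
            if not col_miss.any():
                continue
            obs = ~col_miss
            w = prox[np.ix_(col_miss, obs)]
            wsum = w.sum(axis=1)
            vals = filled.loc[obs, c].to_numpy()
            est = np.where(wsum > 0, (w @ vals) / np.maximum(wsum, 1e-12),
                           filled.loc[obs, c].mean())
            if c in binary_cols:
                est = (est >= 0.5).astype(float)
            new.loc[col_miss, c] = est
        change = float((new - filled).abs().to_numpy().max())
        filled = new
        if change < tol:
            break
    filled.attrs["dropped"] = dropped
    filled.attrs["iterations"] = it + 1
    return filled


def _proximity(leaves: np.ndarray) -> np.ndarray:
    """Fraction of trees in which two samples land in the same leaf."""
    n, t = leaves.shape
    prox = np.zeros((n, n))
    for j in range(t):
        col = leaves[:, j]
        same = col[:, None] == col[None, :]
        prox += same
    prox /= t
    np.fill_diagonal(prox, 0.0)  # a sample never imputes itself
    return prox


@dataclass
class RiskModelReport:
    """Cross-validated random-forest report for a binary clinical outcome."""

    auroc_cv: float
    auroc_resub: float
    auroc_per_repeat: list
    importances: pd.Series  # mean decrease in Gini, final all-data forest
    selected_features: list
    folds: int
    repeats: int
    trees: int
    seed: int
    screen_scope: str
    imputation_log: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "auroc_cv": self.auroc_cv,
            "auroc_resub": self.auroc_resub,
            "auroc_per_repeat": list(map(float, self.auroc_per_repeat)),
            "importances": self.importances.to_dict(),
            "selected_features": list(self.selected_features),
            "scheme": {
                "folds": self.folds,
                "repeats": self.repeats,
                "trees": self.trees,
                "seed": self.seed,
                "screen_scope": self.screen_scope,
            },
            "imputation_log": self.imputation_log,
        }


def fit_rf(
    x: pd.DataFrame,
    y: pd.Series,
    seed: int = 0,
    folds: int = 5,
    repeats: int = 10,
    trees: int = 500,
    screen: bool = True,
    screen_scope: str = "in_fold",
    impute: bool = True,
) -> RiskModelReport:
    """Stratified repeated k-fold random forest with Gini importances.

    The cross-validated auROC pools out-of-fold predicted probabilities
    within each repeat and averages across repeats; with the default
    ``screen_scope='in_fold'``, feature screening and imputation see
    only the training fold. Importances come from a final forest fit on
    all data (after all-data screening/imputation), alongside its
    resubstitution auROC.
    """
    y = pd.Series(y).loc[x.index].astype(int)
    if y.nunique() != 2:
        raise ValueError("outcome must be binary with both classes present")
    if y.value_counts().min() < folds:
        raise ValueError("minority class smaller than the number of folds")
    if screen_scope not in ("in_fold", "all_data"):
        raise ValueError("screen_scope must be 'in_fold' or 'all_data'")

    imputation_log: dict = {}

    def prepare(train_x, train_y, apply_x):
        feats = list(train_x.columns)
        if screen:
            try:
                feats = screen_features(train_x, train_y)
            except ValueError:
                # degenerate fold: keep the single most associated column
                feats = [_best_column(train_x, train_y)]
        tx, ax = train_x[feats], apply_x[feats]
        if impute:
            tx = impute_missing(tx, train_y, seed=seed)
            feats = list(tx.columns)
            ax = ax[feats]
            if ax.isna().to_numpy().any():
                ax = ax.fillna(tx.median())
        return tx, ax, feats

    global_feats = list(x.columns)
    if screen and screen_scope == "all_data":
        global_feats = screen_features(x, y)
        x = x[global_feats]

    aurocs = []
    rng = np.random.default_rng(seed)
    for rep in range(repeats):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rep_seed)
        prob = np.empty(len(y))
        for train_idx, test_idx in skf.split(x, y):
            tr_x, te_x = x.iloc[train_idx], x.iloc[test_idx]
            tr_y = y.iloc[train_idx]
            if screen_scope == "in_fold":
                tr_x, te_x, _ = prepare(tr_x, tr_y, te_x)
            else:
                if impute:
                    tr_x = impute_missing(tr_x, tr_y, seed=rep_seed)
                    te_x = te_x[tr_x.columns].fillna(tr_x.median())
            rf = RandomForestClassifier(
                n_estimators=trees, random_state=rep_seed, n_jobs=1
            ).fit(tr_x.to_numpy(), tr_y.to_numpy())
            prob[test_idx] = rf.predict_proba(te_x.to_numpy())[:, 1]
        aurocs.append(roc_auc_score(y, prob))

    # final all-data model for importances and resubstitution auROC
    final_x = x
    final_feats = list(final_x.columns)
    if screen and screen_scope == "in_fold":
        final_feats = screen_features(final_x, y)
        final_x = final_x[final_feats]
    if impute:
        final_x = impute_missing(final_x, y, seed=seed)
        final_feats = list(final_x.columns)
        imputation_log = {
            "dropped": final_x.attrs.get("dropped", []),
            "iterations": final_x.attrs.get("iterations", 0),
        }
    final_rf = RandomForestClassifier(
        n_estimators=trees, random_state=seed, n_jobs=1
    ).fit(final_x.to_numpy(), y.to_numpy())
    resub = roc_auc_score(y, final_rf.predict_proba(final_x.to_numpy())[:, 1])
    importances = pd.Series(
        final_rf.feature_importances_, index=final_feats, name="mean_decrease_gini"
    ).sort_values(ascending=False)

    return RiskModelReport(
        auroc_cv=float(np.mean(aurocs)),
        auroc_resub=float(resub),
        auroc_per_repeat=aurocs,
        importances=importances,
        selected_features=final_feats,
        folds=folds,
        repeats=repeats,
        trees=trees,
        seed=seed,
        screen_scope=screen_scope,
        imputation_log=imputation_log,
    )


def _best_column(x: pd.DataFrame, y: pd.Series) -> str:
    best, best_p = x.columns[0], np.inf
    for col in x.columns:
        sub = pd.DataFrame({"x": x[col], "y": y}).dropna()
        if sub["x"].nunique() < 2 or len(sub) < 3:
            continue
        _, p = stats.spearmanr(sub["x"], sub["y"])
        if np.isfinite(p) and p < best_p:
            best, best_p = col, p
    return best


def feature_corr(x: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise Spearman matrix with BH-masked significance.

    Coefficients are reported only where the BH-adjusted p (across all
    off-diagonal pairs) is <= alpha; other cells are NaN. The diagonal
    is 1.
    """
    cols = list(x.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 columns")
    k = len(cols)
    rho = np.full((k, k), np.nan)
    pvals = []
    pairs = []
    for i in range(k):
        rho[i, i] = 1.0
        for j in range(i + 1, k):
            sub = pd.DataFrame({"a": x[cols[i]], "b": x[cols[j]]}).dropna()
            if len(sub) < 3 or sub["a"].nunique() < 2 or sub["b"].nunique() < 2:
                continue
            r, p = stats.spearmanr(sub["a"], sub["b"])
            rho[i, j] = rho[j, i] = r
            pairs.append((i, j))
            pvals.append(p)
    masked = np.full((k, k), np.nan)
    np.fill_diagonal(masked, 1.0)
    if pairs:
        adj = multipletests(pvals, method="fdr_bh")[1]
        for (i, j), pa in zip(pairs, adj):
            if pa <= alpha:
                masked[i, j] = masked[j, i] = rho[i, j]
    return pd.DataFrame(masked, index=cols, columns=cols)
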