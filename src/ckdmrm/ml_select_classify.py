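"""Feature selection and binary classification of mild vs. severe disease.

Two-stage procedure over the >=70%-prevalence, imputed feature matrix:

1. *Selection.*  Proteins are ranked three ways — Mann-Whitney p-value
   (ascending), |Cohen's d| (descending), and impurity importance of a
   single decision tree whose depth limit is ramped up until its training
   ROC-AUC reaches 1.0.  The top five of each ranking are pooled, then each
   pooled protein is screened alone with a default logistic regression
   under stratified 5-fold cross-validation; the best few (default four)
   become classifier candidates.

2. *Classification.*  Every non-empty subset of the candidates is crossed
   with four algorithms (kNN, logistic regression, random forest, linear
   SVM), each grid-searched on the same folds; results carry the
   cross-validated ROC-AUC mean/SD and the pooled out-of-fold ROC curve.

By default per-fold standardization keeps preprocessing inside training
folds (fold-safe); ``paper_faithful=True`` reproduces the conventional
global-Z-score ordering instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .io_formats import AbundanceMatrix
from .stats_compare import cohens_d, mann_whitney

__all__ = [
    "FeatureRanking",
    "ClassifierSearchResult",
    "DEFAULT_GRIDS",
    "ALGORITHMS",
    "make_binary_labels",
    "rank_by_pvalue",
    "rank_by_effect_size",
    "rank_by_tree_importance",
    "pool_top_k",
    "screen_single_features",
    "exhaustive_subset_search",
    "roc_curve",
    "cv_auc",
    "nested_cv_best_feature_auc",
    "run_selection_pipeline",
]

ALGORITHMS = ("kNN", "logistic_regression", "random_forest", "linear_SVM")

#: Hyperparameter grids for the subset search (configuration, not code).
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "kNN": {"n_neighbors": [3, 5, 7, 9]},
    "logistic_regression": {"C": [0.01, 0.1, 1, 10]},
    "random_forest": {"n_estimators": [100], "max_depth": [2, 5, None]},
    "linear_SVM": {"C": [0.01, 0.1, 1, 10]},
}

MILD_GROUPS = ("MCD", "mFSGS")
SEVERE_GROUPS = ("sFSGS", "MN")


@dataclass(frozen=True)
class FeatureRanking:
    method: str  # "pvalue" | "cohens_d" | "tree_importance"
    proteins: tuple[str, ...]  # best first
    scores: tuple[float, ...]  # aligned with proteins

    def top(self, k: int) -> tuple[str, ...]:
        if len(self.proteins) < k:
            raise ValueError(
                f"ranking {self.method!r} has {len(self.proteins)} entries; need {k}"
            )
        return self.proteins[:k]


@dataclass
class ClassifierSearchResult:
    algorithm: str
    protein_subset: tuple[str, ...]
    hyperparameters: dict
    cv_auc_mean: float
    cv_auc_sd: float
    roc_points: pd.DataFrame  # fpr, tpr of the pooled out-of-fold scores


def make_binary_labels(
    groups: pd.Series,
    mild: Sequence[str] = MILD_GROUPS,
    severe: Sequence[str] = SEVERE_GROUPS,
) -> pd.Series:
    """Mild/severe labels (0/1) over patient samples; controls are excluded."""
    mask = groups.isin(list(mild) + list(severe))
    labels = groups[mask].isin(list(severe)).astype(int)
    labels.name = "severe"
    return labels


def _check_binary(y: pd.Series) -> None:
    if y.nunique() < 2:
        raise ValueError("labels contain a single class")


def _ranking_frame(X: pd.DataFrame, y: pd.Series) -> pd.DataFrame:
    mild_idx = y.index[y == 0]
    severe_idx = y.index[y == 1]
    rows = []
    for protein in X.columns:
        a = X.loc[severe_idx, protein].to_numpy()
        b = X.loc[mild_idx, protein].to_numpy()
        _, p = mann_whitney(a, b)
        d = cohens_d(a, b)
        rows.append({"protein_id": protein, "p": p, "d": d})
    return pd.DataFrame(rows).set_index("protein_id")


def rank_by_pvalue(X: pd.DataFrame, y: pd.Series) -> FeatureRanking:
    """Rank by mild-vs-severe Mann-Whitney p (ascending); ties by |d|, name."""
    _check_binary(y)
    f = _ranking_frame(X, y)
    f["absd"] = f["d"].abs()
    # stable sort after a name pre-sort: ties by |d| then protein name
    f = f.sort_index().sort_values(
        ["p", "absd"], ascending=[True, False], kind="mergesort"
    )
    return FeatureRanking("pvalue", tuple(f.index), tuple(f["p"]))


def rank_by_effect_size(X: pd.DataFrame, y: pd.Series) -> FeatureRanking:
    """Rank by |Cohen's d| (descending); ties broken by protein name."""
    _check_binary(y)
    f = _ranking_frame(X, y)
    f["absd"] = f["d"].abs()
    f = f.sort_index().sort_values("absd", ascending=False, kind="mergesort")
    return FeatureRanking("cohens_d", tuple(f.index), tuple(f["absd"]))


def rank_by_tree_importance(
    X: pd.DataFrame, y: pd.Series, max_depth_cap: int = 20, seed: int = 0
) -> tuple[FeatureRanking, int]:
    """Decision-tree importances at the first depth with training AUC 1.0.

    A single tree is fitted on all samples with the depth limit ramped
    1, 2, ... until its training ROC-AUC reaches 1.0 (or the cap, with a
    warning); impurity-based importances at that depth define the ranking.
    """
    _check_binary(y)
    xv = X.to_numpy()
    yv = y.to_numpy()
    depth_used = max_depth_cap
    tree = None
    for depth in range(1, max_depth_cap + 1):
        tree = DecisionTreeClassifier(max_depth=depth, random_state=seed).fit(xv, yv)
        auc = roc_auc_score(yv, tree.predict_proba(xv)[:, 1])
        if auc >= 1.0 - 1e-12:
            depth_used = depth
            break
    else:
        warnings.warn(
            f"training ROC-AUC did not reach 1.0 at depth cap {max_depth_cap}",
            stacklevel=2,
        )
    imp = pd.Series(tree.feature_importances_, index=X.columns)
    imp = imp.sort_index().sort_values(ascending=False, kind="mergesort")
    return (
        FeatureRanking("tree_importance", tuple(imp.index), tuple(imp)),
        depth_used,
    )


def pool_top_k(rankings: Sequence[FeatureRanking], k: int = 5) -> set[str]:
    """Union of the top-k proteins of each ranking (size in [k, len*k])."""
    pooled: set[str] = set()
    for r in rankings:
        pooled.update(r.top(k))
    return pooled


def _folds(y: pd.Series, folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified fold indices; re-stratifies (new seed) if a fold ends up
    single-class, erroring after 5 attempts."""
    yv = y.to_numpy()
    for attempt in range(5):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + attempt)
        splits = list(skf.split(np.zeros(len(yv)), yv))
        if all(
            np.unique(yv[tr]).size == 2 and np.unique(yv[te]).size == 2
            for tr, te in splits
        ):
            return splits
    raise ValueError("could not stratify folds with both classes present")


def _make_estimator(algorithm: str, params: Mapping, seed: int):
    if algorithm == "kNN":
        return KNeighborsClassifier(**params)
    if algorithm == "logistic_regression":
        return LogisticRegression(**params)
    if algorithm == "random_forest":
        return RandomForestClassifier(random_state=seed, **params)
    if algorithm == "linear_SVM":
        return SVC(kernel="linear", **params)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _scores(model, x: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(x)[:, 1]
    return model.decision_function(x)


def cv_auc(
    X: pd.DataFrame,
    y: pd.Series,
    estimator,
    splits: list[tuple[np.ndarray, np.ndarray]],
    scale_in_fold: bool = True,
) -> tuple[float, float, np.ndarray]:
    """Cross-validated ROC-AUC: per-fold mean/SD plus pooled OOF scores.

    With ``scale_in_fold`` the standardizer is fitted on training folds
    only (fold-safe); otherwise the estimator sees the matrix as-is
    (assumed globally preprocessed).
    """
    from sklearn.base import clone

    xv = X.to_numpy()
    yv = y.to_numpy()
    oof = np.empty(len(yv))
    fold_aucs = []
    for tr, te in splits:
        model = (
            make_pipeline(StandardScaler(), clone(estimator))
            if scale_in_fold
            else clone(estimator)
        )
        model.fit(xv[tr], yv[tr])
        s = _scores(model, xv[te])
        oof[te] = s
        fold_aucs.append(roc_auc_score(yv[te], s))
    return float(np.mean(fold_aucs)), float(np.std(fold_aucs)), oof


def screen_single_features(
    X: pd.DataFrame,
    y: pd.Series,
    pool: Sequence[str],
    folds: int = 5,
    seed: int = 0,
    top: int = 4,
    scale_in_fold: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-protein CV ROC-AUC with a default logistic regression.

    Each pooled protein is evaluated alone under stratified k-fold CV;
    returns the table sorted by AUC (descending, name on ties) and the top
    ``top`` proteins as the candidate set for the subset search.
    """
    _check_binary(y)
    missing = [p for p in pool if p not in X.columns]
    if missing:
        raise ValueError(f"pooled protein(s) not in matrix: {missing}")
    splits = _folds(y, folds, seed)
    rows = []
    for protein in sorted(pool):
        mean, sd, _ = cv_auc(
            X[[protein]], y, LogisticRegression(), splits, scale_in_fold
        )
        rows.append({"protein_id": protein, "cv_auc_mean": mean, "cv_auc_sd": sd})
    table = (
        pd.DataFrame(rows)
        .sort_values(["cv_auc_mean", "protein_id"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return table, table["protein_id"].head(top).tolist()


def _grid_configs(grid: Mapping[str, list]) -> list[dict]:
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in product(*(grid[k] for k in keys))]


def roc_curve(labels, scores) -> tuple[pd.DataFrame, float]:
    """ROC points by threshold sweep and the trapezoid AUC."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thresh = _sk_roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresh}), auc


def exhaustive_subset_search(
    X: pd.DataFrame,
    y: pd.Series,
    candidates: Sequence[str],
    algorithms: Sequence[str] = ALGORITHMS,
    grids: Mapping[str, Mapping[str, list]] = DEFAULT_GRIDS,
    folds: int = 5,
    seed: int = 0,
    scale_in_fold: bool = True,
) -> tuple[list[ClassifierSearchResult], dict[str, ClassifierSearchResult]]:
    """Evaluate every non-empty candidate subset x algorithm x grid point.

    All evaluations share the same stratified folds.  Per (subset,
    algorithm) the best grid configuration by mean CV AUC is kept, with its
    pooled out-of-fold ROC curve.  Results are sorted by AUC descending,
    then subset size ascending (parsimony first).
    """
    candidates = sorted(set(candidates))
    if not candidates:
        raise ValueError("candidate set is empty")
    if len(candidates) > 12:
        raise ValueError("subset search capped at 12 candidates (4095 subsets)")
    _check_binary(y)
    splits = _folds(y, folds, seed)
    results: list[ClassifierSearchResult] = []
    for size in range(1, len(candidates) + 1):
        for subset in combinations(candidates, size):
            xs = X[list(subset)]
            for algo in algorithms:
                best = None
                for params in _grid_configs(grids[algo]):
                    est = _make_estimator(algo, params, seed)
                    mean, sd, oof = cv_auc(xs, y, est, splits, scale_in_fold)
                    if best is None or mean > best[0]:
                        best = (mean, sd, oof, params)
                mean, sd, oof, params = best
                points, _ = roc_curve(y.to_numpy(), oof)
                results.append(
                    ClassifierSearchResult(
                        algorithm=algo,
                        protein_subset=subset,
                        hyperparameters=params,
                        cv_auc_mean=mean,
                        cv_auc_sd=sd,
                        roc_points=points,
                    )
                )
    results.sort(
        key=lambda r: (-r.cv_auc_mean, len(r.protein_subset), r.algorithm,
                       r.protein_subset)
    )
    best_per_algo = {}
    for r in results:
        best_per_algo.setdefault(r.algorithm, r)
    return results, best_per_algo


def nested_cv_best_feature_auc(
    X: pd.DataFrame, y: pd.Series, folds: int = 5, seed: int = 0,
    leaky: bool = False,
) -> float:
    """AUC of "pick the best single feature, then classify" — two ways.

    Fold-safe (default): inside each training fold the best feature is
    chosen by Mann-Whitney p on the training data only, the model is fitted
    there, and held-out samples are scored; the pooled out-of-fold AUC is
    returned.  ``leaky=True`` deliberately selects the feature on the full
    data first (selection outside CV) — the optimistic-bias baseline the
    fold-safe path is guarded against in tests.
    """
    _check_binary(y)
    splits = _folds(y, folds, seed)
    yv = y.to_numpy()
    if leaky:
        best = rank_by_pvalue(X, y).proteins[0]
        _, _, oof = cv_auc(X[[best]], y, LogisticRegression(), splits)
        return roc_auc_score(yv, oof)
    oof = np.empty(len(yv))
    for tr, te in splits:
        xt = X.iloc[tr]
        yt = y.iloc[tr]
        best = rank_by_pvalue(xt, yt).proteins[0]
        model = make_pipeline(StandardScaler(), LogisticRegression())
        model.fit(xt[[best]].to_numpy(), yt.to_numpy())
        oof[te] = _scores(model, X.iloc[te][[best]].to_numpy())
    return roc_auc_score(yv, oof)


@dataclass
class SelectionReport:
    rankings: dict[str, FeatureRanking]
    tree_depth_used: int
    pooled: set[str]
    screening: pd.DataFrame
    candidates: list[str]
    search_results: list[ClassifierSearchResult]
    best_per_algorithm: dict[str, ClassifierSearchResult]
    best: ClassifierSearchResult


def run_selection_pipeline(
    matrix: AbundanceMatrix,
    labels: pd.Series,
    k: int = 5,
    screen_top: int = 4,
    folds: int = 5,
    seed: int = 0,
    algorithms: Sequence[str] = ALGORITHMS,
    grids: Mapping[str, Mapping[str, list]] = DEFAULT_GRIDS,
    paper_faithful: bool = False,
) -> SelectionReport:
    """Full select -> classify path on an imputed ln-scale matrix.

    ``paper_faithful`` Z-scores the whole matrix up front (the conventional
    global ordering); the default keeps standardization inside CV training
    folds.  Deterministic under a fixed seed.
    """
    X = matrix.values.loc[labels.index]
    if paper_faithful:
        mean = X.mean()
        sd = X.std(ddof=0).replace(0.0, 1.0)
        X = (X - mean) / sd
    scale_in_fold = not paper_faithful

    r_p = rank_by_pvalue(X, labels)
    r_d = rank_by_effect_size(X, labels)
    r_t, depth = rank_by_tree_importance(X, labels, seed=seed)
    pooled = pool_top_k([r_p, r_d, r_t], k=k)
    screening, candidates = screen_single_features(
        X, labels, pooled, folds=folds, seed=seed, top=screen_top,
        scale_in_fold=scale_in_fold,
    )
    results, best_per_algo = exhaustive_subset_search(
        X, labels, candidates, algorithms=algorithms, grids=grids,
        folds=folds, seed=seed, scale_in_fold=scale_in_fold,
    )
    return SelectionReport(
        rankings={"pvalue": r_p, "cohens_d": r_d, "tree_importance": r_t},
        tree_depth_used=depth,
        pooled=pooled,
        screening=screening,
        candidates=candidates,
        search_results=results,
        best_per_algorithm=best_per_algo,
        best=results[0],
    )
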