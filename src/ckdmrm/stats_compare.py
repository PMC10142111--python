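"""Differential statistics and exploratory structure.

Group comparisons use the two-sided Mann-Whitney U test on observed
(non-imputed) values, per protein, across the study's eight contrasts
(control vs. each patient group; severe FSGS vs. the other patient groups;
mild FSGS vs. MN).  P-values are adjusted across proteins *within* each
contrast: Benjamini-Hochberg for a 10% FDR and Bonferroni-Holm for a 5%
FWER.  Cohen's d (pooled SD) quantifies effect sizes.  Exploratory
structure: Pearson correlation matrix, agglomerative clustering with
Pearson distance (1 - r, average linkage), and a PCA -> t-SNE embedding
with seven retained components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from statsmodels.stats.multitest import multipletests

from .io_formats import AbundanceMatrix

__all__ = [
    "DEFAULT_CONTRASTS",
    "ClusteringResult",
    "mann_whitney",
    "adjust_bh",
    "adjust_holm",
    "cohens_d",
    "run_contrasts",
    "pearson_matrix",
    "hierarchical_cluster",
    "embed_pca_tsne",
]

#: The eight pairwise group contrasts of the differential analysis.
DEFAULT_CONTRASTS: tuple[tuple[str, str], ...] = (
    ("control", "MCD"),
    ("control", "mFSGS"),
    ("control", "sFSGS"),
    ("control", "MN"),
    ("sFSGS", "MCD"),
    ("sFSGS", "mFSGS"),
    ("sFSGS", "MN"),
    ("mFSGS", "MN"),
)

_EXACT_MAX_N = 8  # exact enumeration feasible and preferable up to here


def mann_whitney(x, y, method: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of x, p).

    U counts pairs with x_i > y_j plus half the ties.  ``auto`` uses the
    exact null distribution when both samples are small (min n <= 8) and
    tie-free, else the tie- and continuity-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if method == "auto":
        tie_free = np.unique(np.concatenate([x, y])).size == x.size + y.size
        method = "exact" if tie_free and min(x.size, y.size) <= _EXACT_MAX_N else (
            "normal_approx"
        )
    scipy_method = {"exact": "exact", "normal_approx": "asymptotic"}[method]
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=scipy_method)
    return float(res.statistic), float(res.pvalue)


def _check_pvalues(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p))):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = _check_pvalues(p_values)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def adjust_holm(p_values) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values (input order preserved)."""
    p = _check_pvalues(p_values)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def cohens_d(x, y) -> float:
    """Standardized mean difference with the pooled (n-1) SD.

    Zero mean difference gives d = 0 even for degenerate SDs; a non-zero
    difference with zero pooled SD returns signed infinity with a warning
    (the ranking it feeds stays well defined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("cohens_d needs >= 2 values per group")
    diff = x.mean() - y.mean()
    nx, ny = x.size, y.size
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if pooled_var == 0:
        if diff == 0:
            return 0.0
        warnings.warn("zero pooled SD; Cohen's d is infinite", stacklevel=2)
        return float(np.sign(diff) * np.inf)
    return float(diff / np.sqrt(pooled_var))


def run_contrasts(
    matrix: AbundanceMatrix,
    contrasts=DEFAULT_CONTRASTS,
    alpha_raw: float = 0.01,
    fdr: float = 0.10,
    fwer: float = 0.05,
) -> pd.DataFrame:
    """Mann-Whitney tests for every protein x contrast, with adjustments.

    Tests run on observed values only (no imputation).  BH and Holm are
    applied across proteins within each contrast.  Flags: ``raw``
    (p < alpha_raw), ``fdr10`` (BH-adjusted < fdr), ``fwer5``
    (Holm-adjusted < fwer).  ``direction`` is the sign of the median
    difference (group A minus group B).
    """
    groups = matrix.groups
    known = set(groups.unique())
    rows = []
    for a, b in contrasts:
        if a not in known or b not in known:
            raise ValueError(f"contrast ({a}, {b}) names unknown group")
        ia = groups.index[groups == a]
        ib = groups.index[groups == b]
        per_contrast = []
        for protein in matrix.protein_ids:
            xa = matrix.values.loc[ia, protein].dropna().to_numpy()
            xb = matrix.values.loc[ib, protein].dropna().to_numpy()
            if xa.size == 0 or xb.size == 0:
                per_contrast.append((protein, np.nan, np.nan, 0.0))
                continue
            u, p = mann_whitney(xa, xb)
            direction = float(np.sign(np.median(xa) - np.median(xb)))
            per_contrast.append((protein, u, p, direction))
        p_raw = np.array([r[2] for r in per_contrast])
        valid = ~np.isnan(p_raw)
        p_bh = np.full_like(p_raw, np.nan)
        p_holm = np.full_like(p_raw, np.nan)
        if valid.any():
            p_bh[valid] = adjust_bh(p_raw[valid])
            p_holm[valid] = adjust_holm(p_raw[valid])
        for (protein, u, p, direction), pb, ph in zip(per_contrast, p_bh, p_holm):
            rows.append(
                {
                    "protein_id": protein,
                    "group_a": a,
                    "group_b": b,
                    "u_statistic": u,
                    "p_raw": p,
                    "p_bh": pb,
                    "p_holm": ph,
                    "direction": direction,
                    "raw": bool(p < alpha_raw) if not np.isnan(p) else False,
                    "fdr10": bool(pb < fdr) if not np.isnan(pb) else False,
                    "fwer5": bool(ph < fwer) if not np.isnan(ph) else False,
                }
            )
    return pd.DataFrame(rows)


def pearson_matrix(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Proteins x proteins Pearson correlation of a complete matrix.

    Constant columns have undefined correlations, reported as NaN.
    """
    if matrix.values.isna().any().any():
        raise ValueError("correlation matrix expects a complete matrix")
    if len(matrix.sample_ids) < 2:
        raise ValueError("need >= 2 samples")
    return matrix.values.corr(method="pearson")


@dataclass
class ClusteringResult:
    linkage: np.ndarray  # scipy linkage matrix
    labels: list[str]  # item ids in input order
    leaf_order: list[str]  # dendrogram leaves, left to right

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return rec(tree, tree.dist) + ";"


def hierarchical_cluster(
    matrix: AbundanceMatrix, axis: str = "samples", linkage_method: str = "average"
) -> ClusteringResult:
    """Agglomerative clustering with Pearson distance (1 - r).

    ``axis`` picks whether samples or proteins are clustered.  Average
    linkage (UPGMA) by default; scipy's deterministic tie-breaking gives a
    reproducible leaf order.
    """
    if matrix.values.isna().any().any():
        raise ValueError("clustering expects a complete matrix")
    if axis not in ("samples", "proteins"):
        raise ValueError("axis must be 'samples' or 'proteins'")
    data = matrix.values if axis == "samples" else matrix.values.T
    labels = list(data.index)
    if len(labels) < 2:
        raise ValueError("need >= 2 items to cluster")
    dist = pdist(data.to_numpy(), metric="correlation")  # 1 - Pearson r
    z = hierarchy.linkage(dist, method=linkage_method)
    leaves = hierarchy.dendrogram(z, no_plot=True)["leaves"]
    return ClusteringResult(
        linkage=z, labels=labels, leaf_order=[labels[i] for i in leaves]
    )


def embed_pca_tsne(
    matrix: AbundanceMatrix,
    n_components: int = 7,
    seed: int = 0,
    perplexity: float = 10.0,
) -> pd.DataFrame:
    """PCA to ``n_components`` then t-SNE to 2-D; per-sample coordinates.

    For visual QC only: beyond determinism under a fixed seed and coarse
    group separation, nothing about the embedding is assertable.
    """
    n, m = matrix.values.shape
    if n_components > min(n, m):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples, n_proteins)={min(n, m)}"
        )
    if matrix.values.isna().any().any():
        raise ValueError("embedding expects a complete matrix")
    x = PCA(n_components=n_components, random_state=seed).fit_transform(
        matrix.values.to_numpy()
    )
    coords = TSNE(
        n_components=2,
        perplexity=min(perplexity, (n - 1) / 3.0),
        random_state=seed,
        init="pca",
        learning_rate="auto",
    ).fit_transform(x)
    return pd.DataFrame(coords, index=matrix.values.index, columns=["tsne1", "tsne2"])
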