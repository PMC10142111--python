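"""Matrix preprocessing: transform, prevalence filters, imputation, scaling.

The analysis works on ln(x+1)-transformed abundances.  Protein panels are
defined by *prevalence*: a protein enters the panel if it is quantified in
at least a threshold fraction of the samples of some group (2/3 for the
descriptive panel, 70% for the classification feature set), and is a *core*
protein if it meets the threshold in every group.  Missing values — which
represent concentrations too low to quantify — are filled, for the
classification path only, by draws from a downshifted Gaussian per group:
N(mean - shift*B, (width*B)^2) with shift 0.4 and width 0.2, where B is the
group mean of the observed values (the literal published parameterization;
a Perseus-style variant scales by the observed SD instead).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import AbundanceMatrix

__all__ = [
    "PrevalencePartition",
    "ImputationParams",
    "ln1p_transform",
    "prevalence_filter",
    "venn_partition",
    "prevalence_table",
    "impute_downshifted_gaussian",
    "zscore",
    "PANEL_THRESHOLD",
    "CLASSIFICATION_THRESHOLD",
]

PANEL_THRESHOLD = 2.0 / 3.0  # descriptive panel / Venn partition
CLASSIFICATION_THRESHOLD = 0.70  # feature filter for the binary classifier

_EPS = 1e-12  # guards >= comparisons of presence fractions against float error


@dataclass
class PrevalencePartition:
    """Per-protein, per-group presence fractions and the derived panels."""

    presence: pd.DataFrame  # proteins x groups, fractions in [0, 1]
    threshold: float
    panel_proteins: set[str]  # >= threshold in at least one group
    core_proteins: set[str]  # >= threshold in every group

    @property
    def groups(self) -> list[str]:
        return list(self.presence.columns)


@dataclass(frozen=True)
class ImputationParams:
    """Downshifted-Gaussian imputation parameters.

    shift/width are fractions of the scaling basis B: the per-group
    observed mean (default, the literal published reading) or observed SD
    (``basis="group_sd"``, the Perseus convention).
    """

    shift: float = 0.4
    width: float = 0.2
    basis: str = "group_mean"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shift < 0:
            raise ValueError("shift must be >= 0")
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.basis not in ("group_mean", "group_sd"):
            raise ValueError("basis must be 'group_mean' or 'group_sd'")


def ln1p_transform(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Cell-wise x -> ln(x + 1); missing stays missing."""
    if matrix.scale_tag != "raw":
        raise ValueError(f"expected a raw-scale matrix, got {matrix.scale_tag}")
    vals = matrix.values
    if (vals < 0).any().any():
        raise ValueError("negative abundances cannot be ln(x+1)-transformed")
    return AbundanceMatrix(np.log1p(vals), scale_tag="ln1p", groups=matrix.groups.copy())


def _presence_fractions(matrix: AbundanceMatrix) -> pd.DataFrame:
    if not len(matrix.groups):
        raise ValueError("matrix has no group labels; prevalence needs groups")
    counts = matrix.values.notna().groupby(matrix.groups).sum().T
    sizes = matrix.groups.value_counts()
    return counts / sizes[counts.columns]


def prevalence_filter(
    matrix: AbundanceMatrix,
    threshold: float = PANEL_THRESHOLD,
    mode: str = "any_group",
) -> tuple[PrevalencePartition, AbundanceMatrix]:
    """Prevalence filter: keep proteins quantified in >= threshold of samples.

    ``mode="any_group"`` keeps proteins meeting the threshold in at least
    one group (the panel); ``mode="all_groups"`` keeps only core proteins
    (threshold met in every group).  Presence counts quantified cells —
    a zero value is a presence; only missing is absent.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    if mode not in ("any_group", "all_groups"):
        raise ValueError("mode must be 'any_group' or 'all_groups'")
    presence = _presence_fractions(matrix)
    meets = presence >= threshold - _EPS
    panel = set(presence.index[meets.any(axis=1)])
    core = set(presence.index[meets.all(axis=1)])
    partition = PrevalencePartition(
        presence=presence, threshold=threshold, panel_proteins=panel,
        core_proteins=core,
    )
    keep = sorted(panel if mode == "any_group" else core)
    filtered = AbundanceMatrix(
        matrix.values[keep].copy(), scale_tag=matrix.scale_tag,
        groups=matrix.groups.copy(),
    )
    return partition, filtered


def venn_partition(partition: PrevalencePartition) -> dict[frozenset, set[str]]:
    """Assign each panel protein to the exact group subset where it meets
    the threshold.  Cells are disjoint and cover the panel; the all-groups
    cell is the core."""
    meets = partition.presence >= partition.threshold - _EPS
    groups = partition.groups
    cells: dict[frozenset, set[str]] = {
        frozenset(c): set()
        for r in range(1, len(groups) + 1)
        for c in combinations(groups, r)
    }
    for protein in partition.panel_proteins:
        subset = frozenset(g for g in groups if meets.loc[protein, g])
        cells[subset].add(protein)
    return cells


def prevalence_table(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Per-protein "% present (log2 median)" strings per group.

    Percent present is printed to one decimal; the log2 of the median of
    the quantified raw values (3 significant digits) is reported only when
    presence is >= 50%, otherwise the sentinel "Nan" — low-prevalence
    medians are dominated by the censoring and are suppressed.
    """
    if matrix.scale_tag != "raw":
        raise ValueError("prevalence table expects raw-scale values")
    presence = _presence_fractions(matrix)

    def fmt_pct(f: float) -> str:
        s = f"{100 * f:.1f}"
        return s[:-2] if s.endswith(".0") else s

    rows = {}
    for protein in matrix.protein_ids:
        row = {}
        for g in presence.columns:
            frac = presence.loc[protein, g]
            in_group = matrix.groups == g
            vals = matrix.values.loc[in_group.index[in_group], protein].dropna()
            if frac >= 0.5 - _EPS and len(vals):
                med = float(np.median(vals))
                cell = f"{fmt_pct(frac)} ({np.log2(med):.3g})" if med > 0 else (
                    f"{fmt_pct(frac)} (Nan)"
                )
            else:
                cell = f"{fmt_pct(frac)} (Nan)"
            row[g] = cell
        rows[protein] = row
    return pd.DataFrame.from_dict(rows, orient="index")[list(presence.columns)]


def impute_downshifted_gaussian(
    matrix: AbundanceMatrix, params: ImputationParams = ImputationParams()
) -> AbundanceMatrix:
    """Fill missing cells with left-shifted Gaussian draws per group x protein.

    For group g, protein p with observed mean m: missing cells are drawn
    from N(m - shift*B, (width*B)^2), B = m (basis group_mean) or the
    observed SD (basis group_sd).  Groups with no observed value for a
    protein fall back to the protein's global observed statistics.
    Observed cells are never modified; fixed seed gives identical output.
    """
    if matrix.scale_tag != "ln1p":
        raise ValueError("imputation expects an ln1p-scale matrix")
    if not len(matrix.groups):
        raise ValueError("imputation is per group; matrix has no group labels")
    vals = matrix.values.copy()
    if not vals.isna().any().any():
        return AbundanceMatrix(vals, matrix.scale_tag, matrix.groups.copy())
    rng = np.random.default_rng(params.seed)
    global_mean = vals.mean()
    global_sd = vals.std(ddof=0)
    for g in sorted(matrix.groups.unique()):
        members = matrix.groups.index[matrix.groups == g]
        block = vals.loc[members]
        for protein in vals.columns:
            col = block[protein]
            n_missing = int(col.isna().sum())
            if n_missing == 0:
                continue
            obs = col.dropna()
            if len(obs):
                m = float(obs.mean())
                sd = float(obs.std(ddof=0)) if len(obs) > 1 else float(global_sd[protein])
            else:  # global fallback
                m = float(global_mean[protein])
                sd = float(global_sd[protein])
            basis = m if params.basis == "group_mean" else sd
            if not np.isfinite(basis) or params.width * basis <= 0:
                raise ValueError(
                    f"imputation width is non-positive for group {g!r}, protein "
                    f"{protein!r} (basis {basis!r}); switch basis to 'group_sd' "
                    "or floor the scaling basis"
                )
            draws = rng.normal(
                m - params.shift * basis, params.width * basis, size=n_missing
            )
            vals.loc[col.index[col.isna()], protein] = draws
    return AbundanceMatrix(vals, matrix.scale_tag, matrix.groups.copy())


def zscore(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Standardize each protein column to mean 0, population SD 1.

    Constant columns carry no information and become all zeros, with a
    warning.
    """
    vals = matrix.values
    if vals.isna().any().any():
        raise ValueError("zscore expects a complete matrix (impute first)")
    mean = vals.mean()
    sd = vals.std(ddof=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant protein column(s) set to zeros",
            stacklevel=2,
        )
    sd_safe = sd.mask(constant, 1.0)
    out = (vals - mean) / sd_safe
    out.loc[:, constant[constant].index] = 0.0
    return AbundanceMatrix(out, scale_tag="zscore", groups=matrix.groups.copy())
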