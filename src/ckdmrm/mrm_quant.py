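"""SIS-ratio quantification of MRM transition areas.

The endogenous ("light") peptide signal is normalized by a stable-isotope-
labeled standard ("heavy", SIS) spiked at known amount into every digest.
The light/heavy area ratio cancels per-injection response variation; a
1/x^2-weighted linear calibration (measured ratio vs. known concentration
ratio, the standard weighting of bioanalytical standard curves, which
equalizes *relative* error across the dynamic range) maps ratios to
concentrations.  Duplicate injections are averaged at the ratio level and
peptide concentrations roll up to protein abundances (median across
peptides; the panel is mostly one proteotypic peptide per protein).

Missing propagates as NaN throughout: a below-LOD area or a zero heavy
area yields a missing ratio, never a zero — downstream imputation assumes
missingness is left-censored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import AbundanceMatrix, TransitionMeasurement

__all__ = [
    "PeptideRatio",
    "CalibrationCurve",
    "compute_ratio",
    "fit_calibration",
    "quantify",
    "aggregate_replicates",
    "rollup_protein",
    "quantify_report",
]


@dataclass(frozen=True)
class PeptideRatio:
    """Replicate-averaged light/heavy ratio for one sample x peptide."""

    sample_id: str
    peptide_sequence: str
    ratio: float  # NaN when missing
    n_replicates_used: int
    cv_between_replicates: float  # fraction; 0.0 when only one replicate


@dataclass(frozen=True)
class CalibrationCurve:
    """Weighted linear fit of measured ratio y on known concentration ratio x."""

    peptide_sequence: str
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    weighting: str = "1/x^2"

    def invert(self, y: float) -> float:
        """Back-calculate the concentration ratio for a measured ratio."""
        if self.slope == 0:
            raise ValueError("calibration slope is zero; curve not invertible")
        return (y - self.intercept) / self.slope


def compute_ratio(
    light_area: float,
    heavy_area: float,
    *,
    light_below_lod: bool = False,
    heavy_below_lod: bool = False,
) -> float:
    """Light/heavy area ratio; NaN when undefined.

    A true-zero light area is a valid ratio of 0.0; a zero or below-LOD
    heavy area makes the ratio missing (the standard failed, nothing can be
    said about the analyte).
    """
    if light_below_lod or heavy_below_lod:
        return np.nan
    if np.isnan(light_area) or np.isnan(heavy_area):
        return np.nan
    if light_area < 0 or heavy_area < 0:
        raise ValueError(
            f"areas must be non-negative, got light={light_area}, heavy={heavy_area}"
        )
    if heavy_area == 0:
        return np.nan
    return light_area / heavy_area


def fit_calibration(
    points: Sequence[tuple[float, float]],
    peptide_sequence: str = "",
    weighting: str = "1/x^2",
) -> CalibrationCurve:
    """Fit y = a*x + b by weighted least squares with weights 1/x^2.

    ``points`` are (known concentration ratio x, measured area ratio y).
    Solved by the closed-form weighted normal equations; the reported R^2
    is the weighted coefficient of determination.
    """
    if weighting != "1/x^2":
        raise ValueError("only 1/x^2 weighting is supported")
    pts = [(float(x), float(y)) for x, y in points]
    if len(pts) < 2:
        raise ValueError("calibration needs >= 2 points")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.any(x <= 0):
        raise ValueError("all calibration levels must be > 0 (1/x^2 weight undefined)")
    if np.unique(x).size < 2:
        raise ValueError("singular design: all calibration levels identical")
    w = 1.0 / (x * x)
    sw = w.sum()
    sx = (w * x).sum()
    sy = (w * y).sum()
    sxx = (w * x * x).sum()
    sxy = (w * x * y).sum()
    denom = sw * sxx - sx * sx
    a = (sw * sxy - sx * sy) / denom
    b = (sy - a * sx) / sw
    resid = y - (a * x + b)
    ybar_w = sy / sw
    ss_tot = (w * (y - ybar_w) ** 2).sum()
    ss_res = (w * resid**2).sum()
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CalibrationCurve(
        peptide_sequence=peptide_sequence,
        slope=float(a),
        intercept=float(b),
        r_squared=float(r2),
        n_points=len(pts),
    )


def quantify(
    ratio: float, curve: CalibrationCurve, sis_concentration: float
) -> float:
    """Concentration = curve^{-1}(ratio) * SIS amount; fmol per sample.

    Negative back-calculated concentrations (ratio below the curve's zero
    crossing, i.e. under the calibrated range) are clamped to missing with
    a warning rather than reported as impossible negative amounts.
    """
    if curve.slope == 0:
        raise ValueError("calibration slope is zero")
    if np.isnan(ratio):
        return np.nan
    conc = curve.invert(ratio) * sis_concentration
    if conc < 0:
        warnings.warn(
            f"back-calculated concentration {conc:.3g} < 0 for "
            f"{curve.peptide_sequence or 'peptide'}; reported as missing",
            stacklevel=2,
        )
        return np.nan
    return conc


def aggregate_replicates(
    sample_id: str,
    peptide_sequence: str,
    replicate_ratios: Iterable[float],
) -> PeptideRatio:
    """Average replicate ratios; record how many survived and their CV.

    Missing replicates (NaN) are dropped; an empty set yields a missing
    ratio.  CV is the between-replicate coefficient of variation
    (population SD / mean), 0.0 by convention for a single replicate.
    """
    vals = np.array([r for r in replicate_ratios if not np.isnan(r)])
    if vals.size == 0:
        return PeptideRatio(sample_id, peptide_sequence, np.nan, 0, np.nan)
    mean = float(vals.mean())
    if vals.size == 1:
        cv = 0.0
    else:
        sd = float(vals.std(ddof=0))  # population SD: CV of the n injections made
        cv = sd / mean if mean != 0 else np.nan
    return PeptideRatio(sample_id, peptide_sequence, mean, int(vals.size), cv)


def rollup_protein(peptide_concentrations: Iterable[float]) -> float:
    """Protein abundance from its peptides: pass-through or median.

    Single-peptide proteins pass through; multi-peptide proteins take the
    median across peptides.  All-missing yields missing.
    """
    vals = np.array([c for c in peptide_concentrations if not np.isnan(c)])
    if vals.size == 0:
        return np.nan
    return float(np.median(vals))


def quantify_report(
    measurements: Iterable[TransitionMeasurement],
    sis_concentrations: Mapping[str, float] | float,
    curves: Mapping[str, CalibrationCurve] | None = None,
    group_of: Mapping[str, str] | None = None,
) -> AbundanceMatrix:
    """Full quantification pipeline: transition report -> abundance matrix.

    Per (sample, peptide, replicate) the light/heavy ratio is computed;
    replicates are averaged; the ratio is converted to a concentration via
    the peptide's calibration curve when one is supplied, otherwise by
    simple SIS normalization (ratio x SIS amount, an identity curve);
    peptides roll up to proteins by median.

    ``sis_concentrations`` is fmol spiked per sample, either one number for
    the whole (balanced) mixture or a per-peptide map.
    """
    by_cell: dict[tuple[str, str, str, int], dict[str, TransitionMeasurement]] = {}
    peptide_protein: dict[str, str] = {}
    for m in measurements:
        peptide_protein.setdefault(m.peptide_sequence, m.protein_id)
        key = (m.sample_id, m.protein_id, m.peptide_sequence, m.replicate)
        by_cell.setdefault(key, {})[m.label] = m

    # replicate ratios per (sample, protein, peptide)
    rep_ratios: dict[tuple[str, str, str], list[float]] = {}
    for (sample, protein, peptide, _rep), pair in sorted(by_cell.items()):
        light = pair.get("light")
        heavy = pair.get("heavy")
        if light is None or heavy is None:
            ratio = np.nan
        else:
            ratio = compute_ratio(
                light.area if not light.below_lod else np.nan,
                heavy.area if not heavy.below_lod else np.nan,
                light_below_lod=light.below_lod,
                heavy_below_lod=heavy.below_lod,
            )
        rep_ratios.setdefault((sample, protein, peptide), []).append(ratio)

    def sis_for(peptide: str) -> float:
        if isinstance(sis_concentrations, Mapping):
            return float(sis_concentrations[peptide])
        return float(sis_concentrations)

    # peptide concentrations per sample
    conc: dict[str, dict[str, list[float]]] = {}
    samples_seen: list[str] = []
    for (sample, protein, peptide), ratios in sorted(rep_ratios.items()):
        agg = aggregate_replicates(sample, peptide, ratios)
        if curves is not None and peptide in curves:
            c = quantify(agg.ratio, curves[peptide], sis_for(peptide))
        else:
            c = agg.ratio * sis_for(peptide) if not np.isnan(agg.ratio) else np.nan
        if sample not in conc:
            conc[sample] = {}
            samples_seen.append(sample)
        conc[sample].setdefault(protein, []).append(c)

    proteins = sorted({p for s in conc.values() for p in s})
    data = {
        s: {p: rollup_protein(conc[s].get(p, [np.nan])) for p in proteins}
        for s in samples_seen
    }
    values = pd.DataFrame.from_dict(data, orient="index").loc[samples_seen, proteins]
    groups = (
        pd.Series({s: group_of[s] for s in samples_seen if s in group_of})
        if group_of
        else pd.Series(dtype=object)
    )
    return AbundanceMatrix(values=values, scale_tag="raw", groups=groups)
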