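"""Synthetic cohort generator for the CKD urine-proteomics pipeline.

Emulates the statistical structure the analysis assumes, at desk scale and
with known ground truth: a five-group cohort (healthy controls plus MCD,
mild/severe FSGS and MN patients) measured over a ~177-protein MRM panel,
with

* ln-scale Gaussian protein abundances with per-protein baselines and
  planted group effects (the discriminative "markers"),
* left-censored, abundance-dependent missingness via a logistic detection
  curve (low abundance -> likely missing), the mechanism the downshifted-
  Gaussian imputation downstream targets,
* duplicate injections with multiplicative technical noise for the
  transition-report path, and
* clinical covariates (eGFR, 24-h proteinuria, steroid resistance) drawn
  from log-normal distributions centered on the study groups' published
  medians, constrained so FSGS severity labels agree with the severity
  index by construction.

All randomness flows from the design's single integer seed through
independent numpy generator streams; two calls with the same design are
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .io_formats import AbundanceMatrix, ClinicalRecord, TransitionMeasurement
from .severity_index import severity_score

__all__ = [
    "PlantedMarker",
    "CohortDesign",
    "SyntheticTruth",
    "generate_cohort",
    "generate_transition_report",
    "generate_calibration_standards",
    "DEFAULT_GROUP_SIZES",
    "CLINICAL_PRIORS",
]

#: Study cohort sizes: 23 healthy controls and 46 patients.
DEFAULT_GROUP_SIZES: dict[str, int] = {
    "control": 23,
    "MCD": 8,
    "mFSGS": 11,
    "sFSGS": 15,
    "MN": 12,
}

#: Per-group clinical priors: median eGFR (mL/min/1.73 m^2), median 24-h
#: proteinuria (g), steroid-resistance rate (None = not determined).
#: Patient medians follow the study's cohort table; controls have normal
#: kidney function and no meaningful proteinuria.
CLINICAL_PRIORS: dict[str, tuple[float, float, float | None]] = {
    "control": (105.0, 0.1, None),
    "MCD": (93.0, 3.24, 0.0),
    "mFSGS": (96.9, 2.3, 0.30),
    "sFSGS": (42.0, 5.0, 0.846),
    "MN": (77.3, 3.25, None),  # steroid response not determined for MN
}

_EGFR_LN_SD = 0.30  # log-normal spread around the group median
_PROTEINURIA_LN_SD = 0.40


@dataclass(frozen=True)
class PlantedMarker:
    """A protein with known group effects (ln-units added to the baseline)."""

    protein_index: int
    effects: Mapping[str, float]


def _default_markers() -> tuple[PlantedMarker, ...]:
    # Three severity markers: elevated in all glomerulopathies, strongly in
    # the severe groups, mirroring the behavior of the study's top panel
    # proteins.  With base_sd = 0.6 the mild-vs-severe Cohen's d is >= 2.
    return (
        PlantedMarker(5, {"MCD": 0.05, "mFSGS": 0.05, "sFSGS": 1.35, "MN": 1.30}),
        PlantedMarker(23, {"sFSGS": 1.35, "MN": 1.30}),
        PlantedMarker(41, {"MCD": 0.10, "mFSGS": 0.10, "sFSGS": 1.40, "MN": 1.35}),
    )


@dataclass(frozen=True)
class CohortDesign:
    """Full parameterization of one synthetic cohort.

    Abundances are ln-scale Gaussian: protein p in group g is
    N(mu_p + delta_{p,g}, base_sd^2), mu_p drawn once per cohort from
    ``base_mean_range``.  A cell is observed with probability
    logistic((x - detection_midpoint) * detection_slope).
    """

    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    n_proteins: int = 177
    planted_markers: Sequence[PlantedMarker] = field(default_factory=_default_markers)
    base_mean_range: tuple[float, float] = (0.0, 6.0)  # ln-units
    base_sd: float = 0.6  # ln-units, within-group
    marker_base_mean: float = 5.2  # planted markers sit high enough to be detected
    detection_midpoint: float = 4.05  # ln-units at 50% detection
    detection_slope: float = 2.5  # per ln-unit
    cv_technical: float = 0.05  # duplicate-injection CV
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if n <= 0:
                raise ValueError(f"group {g!r} has non-positive size {n}")
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be > 0")
        if not (0 <= self.cv_technical < 1):
            raise ValueError("cv_technical must be in [0, 1)")
        if self.detection_slope <= 0:
            raise ValueError("detection_slope must be > 0 (detection increasing)")
        for m in self.planted_markers:
            if not (0 <= m.protein_index < self.n_proteins):
                raise ValueError(
                    f"planted marker index {m.protein_index} outside protein panel"
                )
            unknown = set(m.effects) - set(self.group_sizes)
            if unknown:
                raise ValueError(f"planted marker effects on unknown group(s) {unknown}")


@dataclass
class SyntheticTruth:
    """Ground truth for parameter-recovery tests."""

    true_abundances: pd.DataFrame  # samples x proteins, ln-scale, complete
    observed_mask: pd.DataFrame  # True where the cohort matrix has a value
    marker_ids: list[str]
    clinical: pd.DataFrame  # egfr, proteinuria, steroid_resistant, severity_class


def _rng(design: CohortDesign, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=design.seed, spawn_key=(stream,))
    )


def _protein_ids(n: int) -> list[str]:
    return [f"P{i:03d}" for i in range(n)]


def _sample_ids(group_sizes: Mapping[str, int]) -> list[tuple[str, str]]:
    out = []
    for g, n in group_sizes.items():
        out.extend((f"{g}_{i + 1:02d}", g) for i in range(n))
    return out


def _draw_clinical(
    group: str, rng: np.random.Generator
) -> tuple[float, float, bool | None, str | None]:
    """One clinical draw; FSGS groups are rejection-sampled so the severity
    index reproduces the group label (truth labels are consistent by
    construction)."""
    egfr_med, pu_med, resist_rate = CLINICAL_PRIORS[group]
    want = group if group in ("mFSGS", "sFSGS") else None
    for _ in range(10_000):
        egfr = float(egfr_med * np.exp(rng.normal(0.0, _EGFR_LN_SD)))
        pu = float(pu_med * np.exp(rng.normal(0.0, _PROTEINURIA_LN_SD)))
        resistant: bool | None
        if resist_rate is None:
            resistant = None
        else:
            resistant = bool(rng.random() < resist_rate)
        if want is None:
            return egfr, pu, resistant, None
        cls = severity_score(egfr, pu, resistant).classification
        if cls == want:
            return egfr, pu, resistant, cls
    raise RuntimeError(
        f"could not draw severity-consistent covariates for group {group}"
    )


def generate_cohort(
    design: CohortDesign,
) -> tuple[AbundanceMatrix, list[ClinicalRecord], SyntheticTruth]:
    """Generate one cohort: raw abundance matrix with missingness, clinical
    records, and the complete ground truth.

    The returned matrix is on the raw concentration scale (expm1 of the
    ln-scale truth) so the standard ln(x+1) transform recovers the
    generative scale exactly; missing cells are NaN.
    """
    rng_base = _rng(design, 0)
    rng_abund = _rng(design, 1)
    rng_miss = _rng(design, 2)
    rng_clin = _rng(design, 3)

    proteins = _protein_ids(design.n_proteins)
    samples = _sample_ids(design.group_sizes)
    sample_ids = [s for s, _ in samples]
    groups = pd.Series({s: g for s, g in samples})

    lo, hi = design.base_mean_range
    mu = rng_base.uniform(lo, hi, size=design.n_proteins)
    for m in design.planted_markers:
        mu[m.protein_index] = design.marker_base_mean

    delta = np.zeros((len(samples), design.n_proteins))
    for m in design.planted_markers:
        for j, (_, g) in enumerate(samples):
            delta[j, m.protein_index] = m.effects.get(g, 0.0)

    x = rng_abund.normal(mu[None, :] + delta, design.base_sd)
    x = np.maximum(x, 0.0)  # concentrations cannot be negative on the raw scale

    p_detect = expit((x - design.detection_midpoint) * design.detection_slope)
    observed = rng_miss.random(x.shape) < p_detect

    truth_df = pd.DataFrame(x, index=sample_ids, columns=proteins)
    mask_df = pd.DataFrame(observed, index=sample_ids, columns=proteins)
    raw = np.expm1(x)
    raw[~observed] = np.nan
    matrix = AbundanceMatrix(
        values=pd.DataFrame(raw, index=sample_ids, columns=proteins),
        scale_tag="raw",
        groups=groups,
    )

    records: list[ClinicalRecord] = []
    clin_rows = []
    for s, g in samples:
        egfr, pu, resistant, severity = _draw_clinical(g, rng_clin)
        records.append(
            ClinicalRecord(
                sample_id=s, group=g, egfr=egfr, proteinuria=pu,
                steroid_resistant=resistant,
            )
        )
        clin_rows.append(
            {
                "sample_id": s,
                "group": g,
                "egfr": egfr,
                "proteinuria": pu,
                "steroid_resistant": resistant,
                "severity_class": severity,
            }
        )
    clinical = pd.DataFrame(clin_rows).set_index("sample_id")

    truth = SyntheticTruth(
        true_abundances=truth_df,
        observed_mask=mask_df,
        marker_ids=[proteins[m.protein_index] for m in design.planted_markers],
        clinical=clinical,
    )
    return matrix, records, truth


_AA = "ACDEFGHIKLMNPQRSTVWY"


def surrogate_peptide(protein_index: int, length: int = 8) -> str:
    """Deterministic proteotypic-peptide stand-in for protein ``i``.

    Encodes the index in the amino-acid alphabet with a fixed terminal K
    (tryptic-looking), so peptide<->protein mapping is one-to-one and needs
    no random state.
    """
    digits = []
    i = protein_index
    for _ in range(length - 1):
        digits.append(_AA[i % len(_AA)])
        i //= len(_AA)
    return "".join(reversed(digits)) + "K"


def generate_transition_report(
    truth: SyntheticTruth,
    sis_concentration: float,
    response_factor: float,
    design: CohortDesign,
    n_replicates: int = 2,
) -> list[TransitionMeasurement]:
    """Synthesize a transition-level light/heavy report from the truth.

    One surrogate peptide per protein.  Both traces of an injection share a
    common injection-level noise factor (which the light/heavy ratio
    cancels) plus independent per-trace multiplicative noise of CV
    ``cv_technical``, leaving the ratio with a residual CV of about
    sqrt(2) x cv_technical.  Cells censored in the cohort matrix appear as
    below-LOD light traces.
    """
    if sis_concentration <= 0:
        raise ValueError("sis_concentration must be > 0")
    if response_factor <= 0:
        raise ValueError("response_factor must be > 0")
    rng = _rng(design, 4)
    cv = design.cv_technical
    sigma = np.sqrt(np.log1p(cv * cv)) if cv > 0 else 0.0

    proteins = list(truth.true_abundances.columns)
    peptides = {p: surrogate_peptide(i) for i, p in enumerate(proteins)}
    out: list[TransitionMeasurement] = []
    for s in truth.true_abundances.index:
        for p in proteins:
            conc = float(np.expm1(truth.true_abundances.loc[s, p]))
            detected = bool(truth.observed_mask.loc[s, p])
            for rep in range(1, n_replicates + 1):
                inj = float(np.exp(rng.normal(0.0, sigma))) if sigma else 1.0
                eps_l = float(np.exp(rng.normal(0.0, sigma))) if sigma else 1.0
                eps_h = float(np.exp(rng.normal(0.0, sigma))) if sigma else 1.0
                heavy = sis_concentration * response_factor * inj * eps_h
                light = conc * response_factor * inj * eps_l
                out.append(
                    TransitionMeasurement(
                        sample_id=s, replicate=rep, protein_id=p,
                        peptide_sequence=peptides[p], label="heavy", area=heavy,
                    )
                )
                out.append(
                    TransitionMeasurement(
                        sample_id=s, replicate=rep, protein_id=p,
                        peptide_sequence=peptides[p], label="light",
                        area=light if detected else np.nan,
                        below_lod=not detected,
                    )
                )
    return out


def generate_calibration_standards(
    levels: Sequence[float],
    noise_cv: float,
    seed: int,
    n_replicates: int = 1,
) -> list[tuple[float, float]]:
    """Calibration points (true concentration ratio, measured ratio).

    Measured ratio = true ratio x (1 + N(0, noise_cv)) per level and
    replicate; an ideal assay (slope 1, intercept 0) plus relative noise.
    """
    if len(set(levels)) < 2:
        raise ValueError("need >= 2 distinct calibration levels")
    if any(x <= 0 for x in levels):
        raise ValueError("calibration levels must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(5,)))
    points = []
    for x in levels:
        for _ in range(n_replicates):
            y = x * (1.0 + rng.normal(0.0, noise_cv)) if noise_cv > 0 else float(x)
            points.append((float(x), float(y)))
    return points
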