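"""FSGS severity index: eGFR + proteinuria + steroid-resistance scoring.

FSGS patients are split into mild (mFSGS) and severe (sFSGS) subgroups by a
three-part clinical score: points for reduced kidney function (eGFR,
CKD-EPI), for the severity of 24-h proteinuria, and one point for steroid
resistance of the nephrotic syndrome.  A total < 3 classifies mFSGS;
>= 3 classifies sFSGS.

The published bin edges are ambiguous at their boundaries (adjacent rows
overlap at the printed edges); this module resolves every bin as half-open,
closed on the left, with renal function considered "saved" at eGFR >= 60.
All boundary choices live in the two bin tables below.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

from .io_formats import ClinicalRecord, FSGS_UNRESOLVED

__all__ = [
    "SeverityScore",
    "UnscorableError",
    "severity_score",
    "classify_fsgs_cohort",
    "EGFR_BINS",
    "PROTEINURIA_BINS",
    "SEVERE_THRESHOLD",
]

# (lower bound inclusive, points); scanned top-down, first match wins.
# eGFR in mL/min/1.73 m^2.
EGFR_BINS: tuple[tuple[float, int], ...] = (
    (60.0, 0),  # renal function saved
    (45.0, 1),
    (35.0, 2),
    (float("-inf"), 3),
)

# Proteinuria in g/24 h; half-point steps kept exact as Fractions.
PROTEINURIA_BINS: tuple[tuple[float, Fraction], ...] = (
    (7.0, Fraction(3)),
    (6.0, Fraction(5, 2)),
    (5.0, Fraction(2)),
    (4.0, Fraction(3, 2)),
    (3.0, Fraction(1)),
    (2.0, Fraction(1, 2)),
    (float("-inf"), Fraction(0)),
)

SEVERE_THRESHOLD = 3  # total >= 3 -> sFSGS


class UnscorableError(ValueError):
    """The severity index cannot be computed (e.g. steroid status unknown)."""


@dataclass(frozen=True)
class SeverityScore:
    egfr_points: int
    proteinuria_points: Fraction
    steroid_points: int
    total: Fraction
    classification: str  # "mFSGS" or "sFSGS"


def severity_score(
    egfr: float, proteinuria: float, steroid_resistant: bool | None
) -> SeverityScore:
    """Score one patient; raises :class:`UnscorableError` on unknown steroid status."""
    if egfr <= 0:
        raise ValueError(f"egfr must be > 0, got {egfr}")
    if proteinuria < 0:
        raise ValueError(f"proteinuria must be >= 0, got {proteinuria}")
    if steroid_resistant is None:
        raise UnscorableError("steroid-resistance status unknown; cannot score")
    egfr_pts = next(p for lo, p in EGFR_BINS if egfr >= lo)
    pu_pts = next(p for lo, p in PROTEINURIA_BINS if proteinuria >= lo)
    steroid_pts = 1 if steroid_resistant else 0
    total = Fraction(egfr_pts) + pu_pts + Fraction(steroid_pts)
    cls = "sFSGS" if total >= SEVERE_THRESHOLD else "mFSGS"
    return SeverityScore(egfr_pts, pu_pts, steroid_pts, total, cls)


def classify_fsgs_cohort(
    records: Iterable[ClinicalRecord],
) -> tuple[list[ClinicalRecord], dict[str, int], list[str]]:
    """Relabel FSGS-unresolved records as mFSGS/sFSGS via the severity index.

    Returns (relabeled records, subgroup counts, unscorable sample ids).
    Non-FSGS records pass through unchanged; records whose covariates do
    not allow scoring are excluded from relabeling with a warning.
    """
    out: list[ClinicalRecord] = []
    counts = {"mFSGS": 0, "sFSGS": 0}
    unscored: list[str] = []
    for r in records:
        if r.group != FSGS_UNRESOLVED:
            out.append(r)
            continue
        try:
            score = severity_score(r.egfr, r.proteinuria, r.steroid_resistant)
        except UnscorableError:
            unscored.append(r.sample_id)
            continue
        counts[score.classification] += 1
        out.append(
            ClinicalRecord(
                sample_id=r.sample_id,
                group=score.classification,
                egfr=r.egfr,
                proteinuria=r.proteinuria,
                steroid_resistant=r.steroid_resistant,
                sex=r.sex,
                age=r.age,
            )
        )
    if unscored:
        warnings.warn(
            f"{len(unscored)} FSGS record(s) could not be scored and were "
            f"excluded: {unscored[:5]}",
            stacklevel=2,
        )
    return out, counts, unscored
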