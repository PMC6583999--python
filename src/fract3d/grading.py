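"""Reduction grading: Matta's criteria and CT-based three-tier criteria.

Matta's radiograph-based grading bins the largest residual gap or step-off:
anatomical (0-1 mm), imperfect (2-3 mm), poor (> 3 mm).  The printed integer
bins leave real values in (1, 2) undefined, so each bin is closed at its
upper bound (<= 1 / <= 3 / > 3) to make the grading total on the
non-negative reals without moving any printed boundary.

The CT-based three-tier criteria grade three parameters separately and
average them:

* gap:            perfect <= 2 mm,   good <= 5 mm,   moderate > 5 mm
* step-off:       perfect <= 1 mm,   good <= 3 mm,   moderate > 3 mm
* total gap area: perfect <= 100 mm^2, good <= 200 mm^2, moderate > 200 mm^2

The final grade is the category nearest the mean of the ordinal scores
(perfect=1, good=2, moderate=3); ties round toward the worse grade
(conservative clinical reporting).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

log = logging.getLogger(__name__)

MATTA_CATEGORIES = ("anatomical", "imperfect", "poor")
CT3_CATEGORIES = ("perfect", "good", "moderate")

#: upper bounds of the first two bins, per parameter
_CT3_BINS = {"gap": (2.0, 5.0), "step_off": (1.0, 3.0), "total_gap_area": (100.0, 200.0)}


def _check_nonneg(value: float, name: str) -> float:
    value = float(value)
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be a non-negative finite number, got {value}")
    return value


def matta_grade(residual_mm: float) -> str:
    """Matta category for a residual displacement (largest gap or step-off)."""
    r = _check_nonneg(residual_mm, "residual displacement")
    if r <= 1.0:
        return "anatomical"
    if r <= 3.0:
        return "imperfect"
    return "poor"


def _ct3_bin(value: float, bins) -> str:
    if value <= bins[0]:
        return "perfect"
    if value <= bins[1]:
        return "good"
    return "moderate"


@dataclass
class CT3Grade:
    gap: str
    step_off: str
    total_gap_area: str
    final: str

    def as_dict(self) -> dict:
        return {"gap": self.gap, "step_off": self.step_off,
                "total_gap_area": self.total_gap_area, "final": self.final}


def grade_3dct(gap_mm: float, step_mm: float, area_mm2: float) -> CT3Grade:
    """Grade the three CT parameters and average them into a final category."""
    cats = {
        "gap": _ct3_bin(_check_nonneg(gap_mm, "gap"), _CT3_BINS["gap"]),
        "step_off": _ct3_bin(_check_nonneg(step_mm, "step-off"), _CT3_BINS["step_off"]),
        "total_gap_area": _ct3_bin(
            _check_nonneg(area_mm2, "total gap area"), _CT3_BINS["total_gap_area"]
        ),
    }
    mean_score = float(np.mean([CT3_CATEGORIES.index(c) + 1 for c in cats.values()]))
    # nearest category; exact .5 ties go to the worse grade
    final = CT3_CATEGORIES[int(np.floor(mean_score + 0.5)) - 1]
    return CT3Grade(final=final, **cats)


def residual_pct(pre_value: float, post_value: float) -> Optional[float]:
    """Residual displacement as a percentage of the initial displacement.

    ``100 * post / pre``: 0 % is an anatomical reduction, 100 % means no
    reduction at all, and > 100 % means the displacement increased.  If the
    fracture was already anatomic preoperatively (pre == 0) the percentage
    is undefined and ``None`` is returned.
    """
    pre_value = _check_nonneg(pre_value, "preoperative value")
    post_value = _check_nonneg(post_value, "postoperative value")
    if pre_value == 0:
        log.warning("preoperative displacement is zero; residual percentage undefined")
        return None
    return 100.0 * post_value / pre_value


def overall_reduction(percentages) -> float:
    """Arithmetic mean of per-parameter residual percentages."""
    pct = [p for p in percentages if p is not None]
    if not pct:
        raise ValueError("need at least one defined percentage")
    return float(np.mean([_check_nonneg(p, "percentage") for p in pct]))


@dataclass
class GradingResult:
    """All grading outputs for one postoperative assessment."""

    matta_gap: str
    matta_step_off: str
    matta_overall: str                 # on the largest residual gap or step-off
    criteria_3dct: CT3Grade
    residual_pct: dict = field(default_factory=dict)
    overall_reduction_pct: Optional[float] = None

    def as_dict(self) -> dict:
        return {
            "matta_gap": self.matta_gap,
            "matta_step_off": self.matta_step_off,
            "matta_overall": self.matta_overall,
            "criteria_3dct": self.criteria_3dct.as_dict(),
            "residual_pct": self.residual_pct,
            "overall_reduction_pct": self.overall_reduction_pct,
        }


def grade_reduction(
    post_max_gap: float,
    post_max_step: float,
    post_area: float,
    pre_means: Optional[dict] = None,
    post_means: Optional[dict] = None,
) -> GradingResult:
    """Full grading block from postoperative maxima (+ optional pre/post means).

    ``pre_means`` / ``post_means`` carry ``mean_gap``, ``mean_step_off`` and
    ``total_gap_area`` used for the residual percentages (the percentage is
    computed on the average displacement, while grading uses maxima).
    """
    pct: dict = {}
    overall = None
    if pre_means and post_means:
        for key in ("mean_gap", "mean_step_off", "total_gap_area"):
            if key in pre_means and key in post_means:
                pct[key] = residual_pct(pre_means[key], post_means[key])
        if pct:
            defined = [v for v in pct.values() if v is not None]
            overall = float(np.mean(defined)) if defined else None
    return GradingResult(
        matta_gap=matta_grade(post_max_gap),
        matta_step_off=matta_grade(post_max_step),
        matta_overall=matta_grade(max(post_max_gap, post_max_step)),
        criteria_3dct=grade_3dct(post_max_gap, post_max_step, post_area),
        residual_pct=pct,
        overall_reduction_pct=overall,
    )
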