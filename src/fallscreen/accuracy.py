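"""Predictive-accuracy metrics and ROC sweeps over functional-test cutoffs.

Metrics are computed from the population-standardized confusion fractions,
renormalized over the determinate subset.  Ratios with a zero denominator
are reported as ``None`` ("undefined") rather than coerced to a number, so
degenerate cohorts remain visible in reports.

A ROC sweep reruns the full screen -> standardize -> metrics chain for each
cutoff of one functional test.  The grid is augmented with infinite-cutoff
sentinels whose classifications are the two extreme assignments -- every
assessed person normal, or every assessed person abnormal.  Those extreme
classifications depend only on the flowchart routing, not on which test is
used, so the endpoint operating points coincide across TUG, SPPB and gait
speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .cohort import Cohort, CohortError, ReferenceWeights
from .screening import TESTS, ScreeningConfig, screen_cohort
from .standardize import StandardizedConfusion, standardized_confusion

__all__ = [
    "AccuracyMetrics",
    "RocPoint",
    "RocCurve",
    "accuracy_metrics",
    "roc_sweep",
    "DEFAULT_CUTOFF_GRIDS",
]

#: the named operating points reported in tabular output
DEFAULT_CUTOFF_GRIDS = {
    "tug": (12.0, 13.5, 15.0),
    "sppb": (9.0, 11.0),
    "gait_speed": (0.8, 1.0),
}


@dataclass(frozen=True)
class AccuracyMetrics:
    """Se/Sp/PPV/NPV/Acc on the determinate-renormalized confusion.

    ``None`` marks an undefined ratio (zero denominator).
    """

    se: float | None
    sp: float | None
    ppv: float | None
    npv: float | None
    acc: float | None

    def as_dict(self) -> dict:
        return {"se": self.se, "sp": self.sp, "ppv": self.ppv, "npv": self.npv, "acc": self.acc}


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def accuracy_metrics(confusion: StandardizedConfusion) -> AccuracyMetrics:
    """Sensitivity, specificity, predictive values and accuracy."""
    d = confusion.determinate
    if d <= 0:
        raise CohortError("no determinate confusion mass; metrics undefined")
    tp, fp, fn, tn = confusion.tp, confusion.fp, confusion.fn, confusion.tn
    return AccuracyMetrics(
        se=_ratio(tp, tp + fn),
        sp=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        acc=(tp + tn) / d,
    )


@dataclass(frozen=True)
class RocPoint:
    cutoff: float
    se: float | None
    sp: float | None


@dataclass(frozen=True)
class RocCurve:
    """Operating points of one functional test across cutoffs.

    ``all_normal`` / ``all_abnormal`` are the extreme assignments (the
    infinite-cutoff sentinels); they are also present in ``points``.
    """

    test: str
    points: tuple[RocPoint, ...]
    all_normal: RocPoint
    all_abnormal: RocPoint
    outcome_def: str


def roc_sweep(
    cohort: Cohort,
    weights: ReferenceWeights,
    test: str = "tug",
    cutoffs: Sequence[float] | None = None,
    outcome_def: Literal["ge1", "ge2"] = "ge1",
    dense: bool = False,
) -> RocCurve:
    """Sweep the screening cutoff of one test and collect (Se, Sp) points.

    ``cutoffs=None`` uses the named default grid; ``dense=True`` instead
    uses every distinct observed value of the test in the cohort.  The
    grid is always augmented with the two infinite sentinels.
    """
    col, direction, _ = TESTS[test]
    if cutoffs is None:
        if dense:
            vals = cohort.df[col].dropna().unique()
            cutoffs = sorted(float(v) for v in vals)
        else:
            cutoffs = DEFAULT_CUTOFF_GRIDS[test]
    cutoffs = list(cutoffs)
    if not cutoffs:
        raise CohortError("cutoff grid is empty")
    grid = sorted(set(cutoffs) | {-math.inf, math.inf})

    points = []
    by_cutoff = {}
    for c in grid:
        config = ScreeningConfig(test=test, cutoff=c, abnormal_direction=direction)
        conf = standardized_confusion(screen_cohort(cohort, config), weights, outcome_def)
        m = accuracy_metrics(conf)
        pt = RocPoint(c, m.se, m.sp)
        points.append(pt)
        by_cutoff[c] = pt

    # under greater_than, +inf forces "normal" and -inf "abnormal"; mirrored for less_than
    normal_at = math.inf if direction == "greater_than" else -math.inf
    return RocCurve(
        test=test,
        points=tuple(points),
        all_normal=by_cutoff[normal_at],
        all_abnormal=by_cutoff[-normal_at],
        outcome_def=outcome_def,
    )
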