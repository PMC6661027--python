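"""The AGS/BGS fall-risk screening flowchart as a configurable classifier.

The screening asks every older adult about falls in the previous year and
about difficulty walking across a small room (annotation B of the
guidelines).  Recurrent fallers (two or more prior falls, annotation D)
are stratified as high risk immediately and referred to multifactorial
assessment (annotation C).  Single fallers and persons reporting walking
difficulty undergo a gait/balance evaluation (annotation E) with one
functional test -- TUG (abnormal above the cutoff, default 13.5 s), SPPB
or gait speed (abnormal below their cutoffs); an abnormal result means
high risk, a normal one low risk.  Everyone else is low risk.  The
acute-fall presentation branch of the guidelines is not modelled.

Abnormality is a strict inequality, so an infinite cutoff forces the
evaluation's result regardless of the measured value: under the
greater-than convention a cutoff of +inf makes every assessed person
normal and -inf makes everyone abnormal (mirrored for less-than).  These
forced assignments are the extreme points of the ROC sweeps and are
decidable even when the test value is missing.

Required data that are missing make the risk class *indeterminate* under
the default policy; the alternative policy excludes such persons from
summary denominators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, CohortError, ParticipantRecord

__all__ = [
    "TESTS",
    "ScreeningConfig",
    "ScreeningOutcome",
    "ScreeningSummary",
    "CohortScreeningResult",
    "classify_participant",
    "screen_cohort",
    "write_outcomes",
    "read_outcomes",
]

#: functional test name -> (cohort column, default abnormal direction, default cutoff)
TESTS = {
    "tug": ("tug_s", "greater_than", 13.5),
    "sppb": ("sppb", "less_than", 9.0),
    "gait_speed": ("gait_speed_mps", "less_than", 0.8),
}

RISK_CLASSES = ("high", "low", "indeterminate")


@dataclass(frozen=True)
class ScreeningConfig:
    """Choice of gait/balance test, abnormality cutoff, and missing-data policy."""

    test: Literal["tug", "sppb", "gait_speed"] = "tug"
    cutoff: float = 13.5
    abnormal_direction: Literal["greater_than", "less_than"] | None = None
    missing_policy: Literal["indeterminate", "exclude"] = "indeterminate"

    def __post_init__(self) -> None:
        if self.test not in TESTS:
            raise ValueError(f"test must be one of {tuple(TESTS)}, got {self.test!r}")
        if self.abnormal_direction is None:
            object.__setattr__(self, "abnormal_direction", TESTS[self.test][1])
        if self.abnormal_direction not in ("greater_than", "less_than"):
            raise ValueError(f"bad abnormal_direction {self.abnormal_direction!r}")
        if self.missing_policy not in ("indeterminate", "exclude"):
            raise ValueError(f"bad missing_policy {self.missing_policy!r}")
        if math.isnan(self.cutoff):
            raise ValueError("cutoff must not be NaN")

    @classmethod
    def for_test(cls, test: str, cutoff: float | None = None, **kw) -> "ScreeningConfig":
        """Config with the test's conventional direction and default cutoff."""
        _, direction, default_cutoff = TESTS[test]
        return cls(test=test, cutoff=default_cutoff if cutoff is None else cutoff,
                   abnormal_direction=direction, **kw)

    def is_abnormal(self, value: float) -> bool | None:
        """Strict-inequality abnormality; None when undecidable (missing value).

        Infinite cutoffs decide the comparison for *any* real value, so
        they resolve even without a measurement.
        """
        gt = self.abnormal_direction == "greater_than"
        if math.isinf(self.cutoff):
            # value > +inf is false, value > -inf is true (dually for <)
            forced_abnormal = (self.cutoff < 0) if gt else (self.cutoff > 0)
            return forced_abnormal
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return None
        return value > self.cutoff if gt else value < self.cutoff


@dataclass(frozen=True)
class ScreeningOutcome:
    """Risk class plus the flowchart path for one participant.

    ``path`` lists the guideline annotations traversed: B (screening
    questions), D (recurrent-faller gate), E (gait/balance evaluation),
    C (referral to multifactorial assessment).  ``assessed`` is true iff
    the gait/balance evaluation was required (E in path).
    """

    risk_class: Literal["high", "low", "indeterminate"]
    assessed: bool
    path: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.assessed != ("E" in self.path):
            raise ValueError("assessed must hold exactly when E is in the path")


def classify_participant(record: ParticipantRecord, config: ScreeningConfig | None = None) -> ScreeningOutcome:
    """Run one person through the screening flowchart (scalar reference path).

    Deterministic and total on valid records; see the module docstring for
    the decision rules and the missing-data semantics.
    """
    config = config or ScreeningConfig()
    pf = record.prior_falls
    if pf is None:
        return ScreeningOutcome("indeterminate", False, ("B",))
    if pf == "2+":
        return ScreeningOutcome("high", False, ("B", "D", "C"))
    if pf == "0":
        wd = record.walking_difficulty
        if wd is None:
            return ScreeningOutcome("indeterminate", False, ("B",))
        if not wd:
            return ScreeningOutcome("low", False, ("B",))
    # single faller, or no falls but reported difficulty -> evaluate gait/balance
    value = getattr(record, {"tug": "tug", "sppb": "sppb", "gait_speed": "gait_speed"}[config.test])
    abnormal = config.is_abnormal(value if value is None else float(value))
    if abnormal is None:
        return ScreeningOutcome("indeterminate", True, ("B", "E"))
    if abnormal:
        return ScreeningOutcome("high", True, ("B", "E", "C"))
    return ScreeningOutcome("low", True, ("B", "E"))


@dataclass(frozen=True)
class ScreeningSummary:
    """Cohort-level crude fractions of the screening result.

    Under the ``indeterminate`` policy the three risk fractions are over
    all records and sum to one; under ``exclude`` they are over the
    determinate subset (high + low = 1) and ``frac_indeterminate`` is 0
    by construction, with the excluded count reported separately.
    """

    n: int
    n_high: int
    n_low: int
    n_indeterminate: int
    n_assessed: int
    frac_high: float
    frac_low: float
    frac_indeterminate: float
    frac_assessed: float
    missing_policy: str


class CohortScreeningResult:
    """Vectorized screening result: per-record class codes plus the summary."""

    def __init__(self, cohort: Cohort, config: ScreeningConfig,
                 risk_class: np.ndarray, assessed: np.ndarray):
        self.cohort = cohort
        self.config = config
        self.risk_class = risk_class  # object array of "high"/"low"/"indeterminate"
        self.assessed = assessed      # bool array

    @property
    def outcomes(self) -> list[ScreeningOutcome]:
        out = []
        two_plus = (self.cohort.df["prior_falls"] == "2+").to_numpy()
        for rc, ass, tp in zip(self.risk_class, self.assessed, two_plus):
            if tp:
                path = ("B", "D", "C")
            elif ass:
                path = ("B", "E", "C") if rc == "high" else ("B", "E")
            else:
                path = ("B",)
            out.append(ScreeningOutcome(rc, bool(ass), path))
        return out

    @property
    def summary(self) -> ScreeningSummary:
        n = len(self.risk_class)
        n_high = int((self.risk_class == "high").sum())
        n_low = int((self.risk_class == "low").sum())
        n_ind = n - n_high - n_low
        n_assessed = int(self.assessed.sum())
        if self.config.missing_policy == "exclude":
            denom = n_high + n_low
            if denom == 0:
                raise CohortError("no determinate records to summarize")
            return ScreeningSummary(n, n_high, n_low, n_ind, n_assessed,
                                    n_high / denom, n_low / denom, 0.0,
                                    n_assessed / denom, "exclude")
        return ScreeningSummary(n, n_high, n_low, n_ind, n_assessed,
                                n_high / n, n_low / n, n_ind / n,
                                n_assessed / n, "indeterminate")


def screen_cohort(cohort: Cohort, config: ScreeningConfig | None = None) -> CohortScreeningResult:
    """Screen every participant; vectorized over the cohort table."""
    if len(cohort) == 0:
        raise CohortError("cannot screen an empty cohort")
    config = config or ScreeningConfig()
    df = cohort.df
    n = len(df)

    pf = df["prior_falls"]
    pf_missing = pf.isna().to_numpy()
    two_plus = (pf == "2+").to_numpy()
    one = (pf == "1").to_numpy()
    zero = (pf == "0").to_numpy()

    wd = df["walking_difficulty"].to_numpy()
    wd_missing = np.isnan(wd)

    col = TESTS[config.test][0]
    value = df[col].to_numpy(dtype=float)
    gt = config.abnormal_direction == "greater_than"
    if math.isinf(config.cutoff):
        forced = (config.cutoff < 0) if gt else (config.cutoff > 0)
        abnormal = np.full(n, forced)
        test_undecided = np.zeros(n, dtype=bool)
    else:
        abnormal = (value > config.cutoff) if gt else (value < config.cutoff)
        test_undecided = np.isnan(value)
        abnormal = np.where(test_undecided, False, abnormal)

    assessed = one | (zero & ~wd_missing & (wd == 1.0))
    risk = np.full(n, "indeterminate", dtype=object)
    risk[two_plus] = "high"
    risk[zero & ~wd_missing & (wd == 0.0)] = "low"
    risk[assessed & ~test_undecided & abnormal] = "high"
    risk[assessed & ~test_undecided & ~abnormal] = "low"
    # pf missing, or zero falls with unknown difficulty, or assessed with
    # missing test value, stay indeterminate
    return CohortScreeningResult(cohort, config, risk, assessed)


def write_outcomes(result: CohortScreeningResult, path) -> None:
    """Per-record outcomes CSV: id, risk_class, assessed, path."""
    rows = [
        {"id": rid, "risk_class": o.risk_class, "assessed": int(o.assessed), "path": "".join(o.path)}
        for rid, o in zip(result.cohort.df["id"], result.outcomes)
    ]
    pd.DataFrame(rows, columns=["id", "risk_class", "assessed", "path"]).to_csv(path, index=False)


def read_outcomes(path) -> pd.DataFrame:
    """Read an outcomes CSV back; validates risk classes and path/assessed coherence."""
    df = pd.read_csv(path, dtype={"id": str, "risk_class": str, "assessed": int, "path": str})
    bad = ~df["risk_class"].isin(RISK_CLASSES)
    if bad.any():
        raise CohortError(f"bad risk_class {df.loc[bad, 'risk_class'].iloc[0]!r} in {path}")
    if ((df["assessed"] == 1) != df["path"].str.contains("E")).any():
        raise CohortError(f"assessed flag inconsistent with path in {path}")
    return df
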