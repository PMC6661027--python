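"""Direct age-sex standardization of per-person indicators.

Crude cohort fractions reflect the cohort's own age-sex composition; to
report what a screening result would look like in a reference population
(here: the national population of older adults), each stratum-specific
rate is weighted by the reference population's stratum share.  Strata
with no cohort members are dropped and the remaining weights
renormalized, with a logged notice, so reported fractions always sum to
one over the classes of a partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .cohort import Cohort, CohortError, ReferenceWeights
from .screening import CohortScreeningResult

logger = logging.getLogger(__name__)

__all__ = [
    "StandardizedFraction",
    "StandardizedConfusion",
    "standardize",
    "standardized_confusion",
    "OUTCOME_DEFINITIONS",
]

#: outcome definition -> minimum prospective fall count making a "faller"
OUTCOME_DEFINITIONS = {"ge1": 1, "ge2": 2}


@dataclass(frozen=True)
class StandardizedFraction:
    """A directly standardized population fraction with its audit trail."""

    value: float
    per_stratum: tuple[tuple[str, float, int], ...]  # (label, stratum fraction, stratum n)
    dropped_strata: tuple[str, ...]

    def __float__(self) -> float:
        return self.value


def _stratum_layout(cohort: Cohort, weights: ReferenceWeights):
    """Assign records to strata; return (indices, kept strata, renormalized weights)."""
    df = cohort.df
    idx = weights.stratum_indices(df["age"].to_numpy(), df["sex"].to_numpy())
    counts = np.bincount(idx, minlength=len(weights))
    occupied = counts > 0
    if not occupied.any():
        raise CohortError("all strata are empty")
    w = weights.weights.copy()
    dropped = tuple(s.label for s, occ in zip(weights.strata, occupied) if not occ and s.weight > 0)
    if dropped:
        logger.info("dropping empty strata %s and renormalizing weights", dropped)
    w[~occupied] = 0.0
    total = w.sum()
    if total <= 0:
        raise CohortError("reference weight mass falls entirely on empty strata")
    return idx, counts, occupied, w / total, dropped


def standardize(indicator: Sequence[float], cohort: Cohort, weights: ReferenceWeights) -> StandardizedFraction:
    """Directly standardize a per-record indicator in [0, 1].

    The standardized value is the weighted mean of within-stratum means,
    using the reference weights renormalized over non-empty strata.
    """
    ind = np.asarray(indicator, dtype=float)
    if len(ind) != len(cohort):
        raise CohortError(f"indicator length {len(ind)} != cohort size {len(cohort)}")
    if np.isnan(ind).any() or (ind < 0).any() or (ind > 1).any():
        raise CohortError("indicator values must be in [0, 1] with no missing entries")
    idx, counts, occupied, w, dropped = _stratum_layout(cohort, weights)
    sums = np.bincount(idx, weights=ind, minlength=len(weights))
    frac = np.divide(sums, counts, out=np.zeros_like(sums), where=occupied)
    value = float(np.dot(w, frac))
    audit = tuple(
        (s.label, float(frac[i]), int(counts[i]))
        for i, s in enumerate(weights.strata)
        if occupied[i]
    )
    return StandardizedFraction(value, audit, dropped)


@dataclass(frozen=True)
class StandardizedConfusion:
    """Population-standardized confusion fractions for one outcome definition.

    ``tp`` is the standardized fraction of the population that is screened
    high risk *and* falls (per ``outcome_def``), and so on; persons with an
    indeterminate risk class or a missing prospective outcome form the
    separate ``indeterminate`` fraction.  The five fractions partition the
    population and sum to one.
    """

    tp: float
    fp: float
    fn: float
    tn: float
    indeterminate: float = 0.0
    outcome_def: str = "ge1"
    per_stratum: tuple = ()
    dropped_strata: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for nm in ("tp", "fp", "fn", "tn", "indeterminate"):
            v = getattr(self, nm)
            if not 0 <= v <= 1:
                raise ValueError(f"{nm} must be in [0, 1], got {v}")

    @property
    def prevalence(self) -> float:
        """Standardized fraction of the population falling at least once
        (or twice under ``ge2``): TP + FN, classifier-independent."""
        return self.tp + self.fn

    @property
    def determinate(self) -> float:
        return self.tp + self.fp + self.fn + self.tn


def standardized_confusion(
    result: CohortScreeningResult,
    weights: ReferenceWeights,
    outcome_def: Literal["ge1", "ge2"] = "ge1",
) -> StandardizedConfusion:
    """Standardize the screening-vs-outcome cross-classification.

    Each record lands in exactly one of TP/FP/FN/TN/indeterminate; the
    within-stratum fractions of the five classes are weighted by the
    (renormalized) reference weights, so the five standardized fractions
    sum to one by construction.
    """
    if outcome_def not in OUTCOME_DEFINITIONS:
        raise ValueError(f"outcome_def must be one of {tuple(OUTCOME_DEFINITIONS)}")
    cohort = result.cohort
    falls = cohort.df["prospective_falls"].to_numpy(dtype=float)
    faller = falls >= OUTCOME_DEFINITIONS[outcome_def]
    risk = result.risk_class
    determinate = (risk != "indeterminate") & ~np.isnan(falls)
    if not determinate.any():
        raise CohortError("no records with both a determinate risk class and an observed outcome")

    high = risk == "high"
    classes = {
        "tp": determinate & high & faller,
        "fp": determinate & high & ~faller,
        "fn": determinate & ~high & faller,
        "tn": determinate & ~high & ~faller,
        "ind": ~determinate,
    }
    idx, counts, occupied, w, dropped = _stratum_layout(cohort, weights)
    values = {}
    audit = {}
    for nm, mask in classes.items():
        sums = np.bincount(idx, weights=mask.astype(float), minlength=len(counts))
        frac = np.divide(sums, counts, out=np.zeros_like(sums), where=occupied)
        values[nm] = float(np.dot(w, frac))
        audit[nm] = frac
    total = sum(values.values())
    assert abs(total - 1.0) <= 1e-9, f"confusion fractions sum to {total}, not 1"
    per_stratum = tuple(
        (s.label, int(counts[i]), {nm: float(audit[nm][i]) for nm in classes})
        for i, s in enumerate(weights.strata)
        if occupied[i]
    )
    return StandardizedConfusion(
        tp=values["tp"],
        fp=values["fp"],
        fn=values["fn"],
        tn=values["tn"],
        indeterminate=values["ind"],
        outcome_def=outcome_def,
        per_stratum=per_stratum,
        dropped_strata=dropped,
    )
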