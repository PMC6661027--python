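"""Nonparametric bootstrap confidence intervals for cohort statistics.

Participants are resampled with replacement and the statistic recomputed
per replicate; intervals are percentile intervals.  When an interval for
the intervention relative risk is supplied, each replicate additionally
draws RR from a log-normal matched to that 95% interval, propagating the
intervention-effect uncertainty into impact quantities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

from .cohort import Cohort, CohortError

logger = logging.getLogger(__name__)

__all__ = ["IntervalEstimate", "bootstrap_ci", "rr_lognormal"]

DEFAULT_N_BOOT = 2000


@dataclass(frozen=True)
class IntervalEstimate:
    """Point estimate with a percentile bootstrap interval."""

    point: float
    lo: float
    hi: float
    level: float = 0.95
    n_boot: int = DEFAULT_N_BOOT
    seed: int = 0
    n_dropped: int = 0  # replicates where the statistic was undefined

    def as_dict(self) -> dict:
        return {"point": self.point, "lo": self.lo, "hi": self.hi, "level": self.level}


def rr_lognormal(rr: float, rr_interval: tuple[float, float], level: float = 0.95):
    """Log-normal RR sampler matched to a central interval around ``rr``.

    The log-sd is chosen so that ``rr_interval`` is the central ``level``
    interval of LogNormal(log rr, sd).
    """
    lo, hi = rr_interval
    if not 0 < lo < hi:
        raise ValueError("rr_interval must satisfy 0 < lo < hi")
    z = stats.norm.ppf(0.5 + level / 2)
    sigma = (math.log(hi) - math.log(lo)) / (2 * z)
    mu = math.log(rr)

    def draw(rng: np.random.Generator) -> float:
        return float(np.exp(mu + sigma * rng.standard_normal()))

    return draw


def bootstrap_ci(
    statistic: Callable,
    cohort: Cohort,
    n_boot: int = DEFAULT_N_BOOT,
    level: float = 0.95,
    seed: int = 0,
    rr: float | None = None,
    rr_interval: tuple[float, float] | None = None,
) -> IntervalEstimate | dict[str, IntervalEstimate]:
    """Percentile bootstrap interval(s) for ``statistic`` over the cohort.

    ``statistic(cohort)`` may return a float or a dict of floats (several
    statistics share the same resamples); with ``rr_interval`` set it is
    called as ``statistic(cohort, rr=...)`` and the point estimate uses
    the central ``rr``.  Replicates where the statistic is undefined
    (``None``/NaN, or an exception from a degenerate resample) are dropped
    with a logged count; more than 20% dropped is an error.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if len(cohort) == 0:
        raise CohortError("cannot bootstrap an empty cohort")
    rng = np.random.default_rng(seed)
    draw_rr = None
    if rr_interval is not None:
        draw_rr = rr_lognormal(rr if rr is not None else sum(rr_interval) / 2, rr_interval, level)

    def evaluate(c: Cohort, r: float | None):
        if draw_rr is None:
            return statistic(c)
        return statistic(c, rr=r)

    point = evaluate(cohort, rr)
    scalar = not isinstance(point, dict)
    keys = ("__value__",) if scalar else tuple(point)
    reps = {k: [] for k in keys}
    dropped = 0
    n = len(cohort)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        r = draw_rr(rng) if draw_rr is not None else None
        try:
            val = evaluate(cohort.take(idx), r)
        except (CohortError, ValueError, ZeroDivisionError):
            val = None
        if scalar:
            val = {"__value__": val}
        elif val is None:
            val = {k: None for k in keys}
        if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in val.values()):
            dropped += 1
            continue
        for k in keys:
            reps[k].append(float(val[k]))

    if dropped:
        logger.info("dropped %d/%d bootstrap replicates with undefined statistic", dropped, n_boot)
    if dropped > 0.2 * n_boot:
        raise CohortError(
            f"statistic undefined on {dropped}/{n_boot} replicates; "
            "the cohort is too small or too degenerate for a stable interval"
        )

    alpha = (1 - level) / 2

    def interval(k: str, pt: float) -> IntervalEstimate:
        arr = np.asarray(reps[k])
        lo, hi = np.quantile(arr, [alpha, 1 - alpha])
        return IntervalEstimate(float(pt), float(lo), float(hi), level, n_boot, seed, dropped)

    if scalar:
        return interval("__value__", point)
    return {k: interval(k, point[k]) for k in keys}
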