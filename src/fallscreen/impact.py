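"""Scenario impact model for a population fall-prevention service.

Two population measures summarize a prevention policy: Co, the fraction
of the older population referred to the costly multifactorial fall-risk
assessment and tailored intervention (size/cost of the service), and F,
the fraction of the population experiencing at least one fall in the
following 12 months (clinical effectiveness).  The intervention reduces
an individual's probability of falling by a relative risk RR (default
0.78, meta-analytic estimate), assumed equal across risk strata.

With the standardized confusion fractions TP/FP/FN/TN of the screening
classifier, the four policies compare as:

==================================  ===========  =============================
policy                              Co           F
==================================  ===========  =============================
screening (intervene on high risk)  TP + FP      RR*TP + FN
intervention on none                0            TP + FN
intervention on everyone            1            RR*(TP + FN)
random coverage c (risk-blind)      c            (TP + FN)*(1 - c + c*RR)
==================================  ===========  =============================

The code evaluates these formulas directly; derived identities (e.g. that
the parity coverage equals the sensitivity) are verified in tests, not
assumed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from scipy.optimize import brentq

from .standardize import StandardizedConfusion

__all__ = [
    "ImpactEstimate",
    "impact_scenario",
    "parity_coverage",
    "delta_fallers_vs_random",
    "relative_reduction",
    "SCENARIOS",
]

SCENARIOS = ("screening", "none", "everyone", "random")

#: relative risk of falling under the multifactorial intervention (95% CI 0.64-0.94)
DEFAULT_RR = 0.78
DEFAULT_RR_INTERVAL = (0.64, 0.94)


@dataclass(frozen=True)
class ImpactEstimate:
    """(Co, F) for one prevention scenario at a given relative risk."""

    scenario: str
    co: float
    f: float
    rr: float
    coverage: float | None = None  # only for the random scenario


def impact_scenario(
    confusion: StandardizedConfusion,
    rr: float = DEFAULT_RR,
    scenario: Literal["screening", "none", "everyone", "random"] = "screening",
    coverage: float | None = None,
) -> ImpactEstimate:
    """Coverage and faller fraction of one policy (table in module docstring)."""
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}, got {scenario!r}")
    if not rr > 0:
        raise ValueError("rr must be > 0")
    if scenario != "random" and coverage is not None:
        raise ValueError("coverage applies only to the random scenario")
    tp, fp, fn = confusion.tp, confusion.fp, confusion.fn
    prev = tp + fn
    if scenario == "screening":
        return ImpactEstimate("screening", tp + fp, rr * tp + fn, rr)
    if scenario == "none":
        return ImpactEstimate("none", 0.0, prev, rr)
    if scenario == "everyone":
        return ImpactEstimate("everyone", 1.0, rr * prev, rr)
    if coverage is None or not 0 <= coverage <= 1:
        raise ValueError("random scenario needs coverage in [0, 1]")
    return ImpactEstimate("random", coverage, prev * (1 - coverage + coverage * rr), rr, coverage)


def parity_coverage(confusion: StandardizedConfusion, rr: float = DEFAULT_RR) -> float:
    """Random-policy coverage at which F matches the screening policy's F.

    Solved numerically (root bracketing on [0, 1] to 1e-12) from the two
    scenario formulas; no closed form is assumed.
    """
    if not 0 < rr < 1:
        raise ValueError("parity coverage needs rr in (0, 1); at rr = 1 every coverage ties")
    if confusion.tp <= 0:
        raise ValueError("parity coverage undefined without true positives")
    f_screen = impact_scenario(confusion, rr, "screening").f

    def gap(c: float) -> float:
        return impact_scenario(confusion, rr, "random", coverage=c).f - f_screen

    return float(brentq(gap, 0.0, 1.0, xtol=1e-13, rtol=8.9e-16))


def delta_fallers_vs_random(confusion: StandardizedConfusion, rr: float = DEFAULT_RR) -> float:
    """Extra faller reduction of screening vs a risk-blind policy of equal coverage.

    F_random(Co_screening) - F_screening: how many more of the population
    (as a fraction) would fall if the same coverage were spent regardless
    of risk.
    """
    screen = impact_scenario(confusion, rr, "screening")
    rand = impact_scenario(confusion, rr, "random", coverage=screen.co)
    return rand.f - screen.f


def relative_reduction(confusion: StandardizedConfusion, rr: float = DEFAULT_RR) -> float:
    """Relative reduction in fallers of screening vs intervention-on-none."""
    f_none = impact_scenario(confusion, rr, "none").f
    if f_none <= 0:
        raise ValueError("relative reduction undefined at zero prevalence")
    f_screen = impact_scenario(confusion, rr, "screening").f
    return 1.0 - f_screen / f_none
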