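"""Synthetic cohort generator with a single latent-frailty factor.

The generator emulates the structure of a community-dwelling 65+ cohort of
the kind used to evaluate fall-risk screening (the InCHIANTI follow-up
survey is the template): marginal distributions of age, sex, prior falls
(0/1/2+), self-reported walking difficulty, TUG, SPPB, gait speed and the
prospective 12-month fall count, with item-level missingness.

All cross-variable dependence flows through one standard-normal latent
frailty variable, coupled to age.  Categorical and binary variables are
produced by thresholding Gaussian-copula latents, and the functional tests
share their loading inside the total variance, so every marginal matches
its nominal parameter exactly (before rounding/clipping) no matter how
strong the couplings are.  Prospective falls are Poisson with a log-rate
linear in frailty; :func:`calibrate_fall_mixture` solves the resulting
Poisson-lognormal mixture for the (baseline rate, loading) pair that
reproduces a target 0/1/2+ fall distribution.
"""

from __future__ import annotations

import dataclasses
import functools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize, stats

from .cohort import DEFAULT_BANDS, Cohort, ReferenceWeights, Stratum

__all__ = [
    "GeneratorParams",
    "default_params",
    "calibrate_fall_mixture",
    "fall_count_pmf",
    "generate_cohort",
    "generate_reference_weights",
]

MISSING_VARIABLES = ("prior_falls", "walking_difficulty", "tug", "sppb", "gait_speed", "prospective_falls")

#: sample (crude) descriptive statistics of the template cohort (n = 438)
_CRUDE = {
    "age_mean": 82.4,
    "age_sd": 6.5,
    "prob_female": 0.607,
    "prior_falls_probs": (0.731, 0.169, 0.100),
    "prob_walking_difficulty": 0.228,
    "tug_mean": 12.2,
    "tug_sd": 5.5,
    "sppb_mean": 8.1,
    "sppb_sd": 3.6,
    "speed_mean": 1.08,
    "speed_sd": 0.30,
    "prospective_falls_probs": (0.801, 0.121, 0.078),
    "missing_probs": {
        "prior_falls": 7 / 438,
        "walking_difficulty": 0.0,
        "tug": 164 / 438,
        "sppb": 124 / 438,
        "gait_speed": 171 / 438,
        "prospective_falls": 0.0,
    },
}

#: age-sex structure of the standard (reference) population of older adults
_REFERENCE_POPULATION = {"age_mean": 75.9, "age_sd": 7.6, "prob_female": 0.568}


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the synthetic cohort generator.

    Loadings are correlations in [-1, 1] between the latent frailty factor
    and each variable's Gaussian latent; the sign convention is that
    positive frailty means worse function (TUG loading positive, SPPB and
    gait-speed loadings negative).  ``frailty_loading_falls`` acts on the
    log of the Poisson fall rate and is unbounded.
    """

    n: int = 1000
    seed: int = 0
    age_mean: float = _CRUDE["age_mean"]
    age_sd: float = _CRUDE["age_sd"]
    prob_female: float = _CRUDE["prob_female"]
    prior_falls_probs: tuple[float, float, float] = _CRUDE["prior_falls_probs"]
    prob_walking_difficulty: float = _CRUDE["prob_walking_difficulty"]
    tug_mean: float = _CRUDE["tug_mean"]
    tug_sd: float = _CRUDE["tug_sd"]
    sppb_mean: float = _CRUDE["sppb_mean"]
    sppb_sd: float = _CRUDE["sppb_sd"]
    speed_mean: float = _CRUDE["speed_mean"]
    speed_sd: float = _CRUDE["speed_sd"]
    age_frailty_coupling: float = 0.4
    frailty_loading_prior_falls: float = 0.5
    frailty_loading_difficulty: float = 0.5
    frailty_loading_tests: tuple[float, float, float] = (0.55, -0.6, -0.6)  # (tug, sppb, speed)
    frailty_loading_falls: float = 1.8066823966459329
    baseline_fall_rate: float = 0.09122938806064124
    missing_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(_CRUDE["missing_probs"])
    )
    name: str = "custom"

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for nm in ("age_sd", "tug_sd", "sppb_sd", "speed_sd"):
            if not getattr(self, nm) > 0:
                raise ValueError(f"{nm} must be > 0")
        probs = dict(
            prob_female=self.prob_female,
            prob_walking_difficulty=self.prob_walking_difficulty,
        )
        for nm, p in probs.items():
            if not 0 <= p <= 1:
                raise ValueError(f"{nm} must be in [0, 1]")
        pf = self.prior_falls_probs
        if len(pf) != 3 or any(p < 0 or p > 1 for p in pf) or abs(sum(pf) - 1) > 1e-9:
            raise ValueError("prior_falls_probs must be three probabilities summing to 1")
        for rho in (
            self.age_frailty_coupling,
            self.frailty_loading_prior_falls,
            self.frailty_loading_difficulty,
            *self.frailty_loading_tests,
        ):
            if not -1 <= rho <= 1:
                raise ValueError("copula loadings must lie in [-1, 1]")
        if not self.baseline_fall_rate > 0:
            raise ValueError("baseline_fall_rate must be > 0")
        unknown = set(self.missing_probs) - set(MISSING_VARIABLES)
        if unknown:
            raise ValueError(f"unknown missing_probs keys: {sorted(unknown)}")
        for nm, p in self.missing_probs.items():
            if not 0 <= p <= 1:
                raise ValueError(f"missing prob for {nm} must be in [0, 1]")

    # flat key-value serialization used by config files and the CLI
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["prior_falls_probs"] = list(self.prior_falls_probs)
        d["frailty_loading_tests"] = list(self.frailty_loading_tests)
        d["missing_probs"] = dict(self.missing_probs)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorParams":
        kw = dict(d)
        if "prior_falls_probs" in kw:
            kw["prior_falls_probs"] = tuple(kw["prior_falls_probs"])
        if "frailty_loading_tests" in kw:
            kw["frailty_loading_tests"] = tuple(kw["frailty_loading_tests"])
        return cls(**kw)


def fall_count_pmf(baseline_rate: float, loading: float, k: int, order: int = 80) -> float:
    """P(falls = k) under the Poisson-lognormal frailty mixture.

    Computed by Gauss-Hermite quadrature over the standard-normal frailty.
    """
    x, w = hermegauss(order)
    w = w / w.sum()
    lam = baseline_rate * np.exp(loading * x)
    return float(np.sum(w * stats.poisson.pmf(k, lam)))


@functools.lru_cache(maxsize=32)
def calibrate_fall_mixture(p0: float, p1: float) -> tuple[float, float]:
    """Solve for (baseline_fall_rate, frailty_loading_falls) matching a target
    fall-count distribution with P(0) = ``p0`` and P(1) = ``p1``.

    The two-parameter mixture is exactly identified by the two constraints;
    P(2+) = 1 - p0 - p1 then follows.
    """
    if not (0 < p0 < 1 and 0 < p1 < 1 and p0 + p1 < 1):
        raise ValueError("need 0 < p0, p1 and p0 + p1 < 1")

    def eqs(x):
        lam0, b = math.exp(x[0]), x[1]
        return [fall_count_pmf(lam0, b, 0) - p0, fall_count_pmf(lam0, b, 1) - p1]

    sol = optimize.root(eqs, [math.log(0.25), 0.8], tol=1e-12)
    if not sol.success:
        raise RuntimeError(f"fall-mixture calibration failed: {sol.message}")
    return math.exp(sol.x[0]), float(sol.x[1])


# ---------------------------------------------------------------------
# delivered-marginal calibration
#
# Truncation (age >= 65), flooring (TUG, gait speed) and rounding/clipping
# (SPPB in [0, 12]) would otherwise bias the delivered moments away from
# the nominal mean/sd; the latent location and scale are solved so the
# *delivered* marginal has exactly the nominal moments.


def _solve_two_moments(name: str, moments, mean: float, sd: float) -> tuple[float, float]:
    def eqs(x):
        mu, sig = x[0], math.exp(x[1])
        m1, m2 = moments(mu, sig)
        return [m1 - mean, math.sqrt(max(m2 - m1 * m1, 1e-12)) - sd]

    sol = optimize.root(eqs, [mean, math.log(sd)], tol=1e-12)
    if not sol.success:
        raise ValueError(f"cannot calibrate {name} to mean {mean}, sd {sd}: {sol.message}")
    return float(sol.x[0]), float(math.exp(sol.x[1]))


@functools.lru_cache(maxsize=128)
def _truncnorm_latent_params(mean: float, sd: float, lower: float) -> tuple[float, float]:
    """Latent (loc, scale) whose normal truncated below at ``lower`` has the given moments."""

    def moments(mu, sig):
        a = (lower - mu) / sig
        d = stats.truncnorm(a, np.inf, loc=mu, scale=sig)
        m1 = d.mean()
        return m1, d.var() + m1 * m1

    return _solve_two_moments("truncated age", moments, mean, sd)


@functools.lru_cache(maxsize=128)
def _floored_latent_params(mean: float, sd: float, floor: float) -> tuple[float, float]:
    """Latent (loc, scale) such that max(N(loc, scale), floor) has the given moments."""

    def moments(mu, sig):
        a = (floor - mu) / sig
        cdf, pdf = stats.norm.cdf(a), stats.norm.pdf(a)
        m1 = floor * cdf + mu * (1 - cdf) + sig * pdf
        m2 = floor**2 * cdf + (mu**2 + sig**2) * (1 - cdf) + (mu + floor) * sig * pdf
        return m1, m2

    return _solve_two_moments("floored test score", moments, mean, sd)


@functools.lru_cache(maxsize=128)
def _discrete_latent_params(mean: float, sd: float, lo: int = 0, hi: int = 12) -> tuple[float, float]:
    """Latent (loc, scale) such that clip(round(N(loc, scale)), lo, hi) has the given moments."""
    ks = np.arange(lo, hi + 1)

    def moments(mu, sig):
        upper = np.where(ks == hi, np.inf, ks + 0.5)
        lower_edges = np.where(ks == lo, -np.inf, ks - 0.5)
        pmf = stats.norm.cdf(upper, mu, sig) - stats.norm.cdf(lower_edges, mu, sig)
        return float(np.sum(pmf * ks)), float(np.sum(pmf * ks**2))

    return _solve_two_moments("discrete test score", moments, mean, sd)


@functools.lru_cache(maxsize=1)
def _default_fall_params() -> tuple[float, float]:
    p0, p1, _ = _CRUDE["prospective_falls_probs"]
    return calibrate_fall_mixture(p0, p1)


def default_params(n: int = 1000, seed: int = 0, **overrides) -> GeneratorParams:
    """The named default calibration: crude marginals of the template cohort.

    Fall-mixture parameters are solved (and cached) so the implied
    prospective 0/1/2+ fall distribution is (80.1%, 12.1%, 7.8%).
    """
    lam0, b = _default_fall_params()
    params = GeneratorParams(
        n=n,
        seed=seed,
        baseline_fall_rate=lam0,
        frailty_loading_falls=b,
        name="crude-marginals-v1",
    )
    if overrides:
        params = dataclasses.replace(params, **overrides)
    params.validate()
    return params


def _mix(rng: np.random.Generator, frailty: np.ndarray, rho: float) -> np.ndarray:
    """A standard-normal latent with correlation ``rho`` to frailty."""
    return rho * frailty + math.sqrt(1 - rho * rho) * rng.standard_normal(len(frailty))


def generate_cohort(params: GeneratorParams) -> Cohort:
    """Draw a synthetic cohort; bit-reproducible from ``params.seed``.

    Age is an inverse-CDF draw from a normal truncated below at 65, sharing
    its uniform with the frailty factor so the age-frailty coupling leaves
    both marginals exact.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n

    u_age = rng.uniform(size=n)
    age_loc, age_scale = _truncnorm_latent_params(params.age_mean, params.age_sd, 65.0)
    a65 = (65.0 - age_loc) / age_scale
    age = stats.truncnorm.ppf(u_age, a65, np.inf, loc=age_loc, scale=age_scale)
    z_age = stats.norm.ppf(u_age)
    frailty = _mix(rng, z_age, params.age_frailty_coupling)

    sex = np.where(rng.uniform(size=n) < params.prob_female, "female", "male").astype(object)

    p0, p1, _ = params.prior_falls_probs
    z_pf = _mix(rng, frailty, params.frailty_loading_prior_falls)
    pf = np.full(n, "2+", dtype=object)
    pf[z_pf < stats.norm.ppf(p0 + p1)] = "1"
    pf[z_pf < stats.norm.ppf(p0)] = "0"

    z_wd = _mix(rng, frailty, params.frailty_loading_difficulty)
    wd = (z_wd > stats.norm.ppf(1 - params.prob_walking_difficulty)).astype(float)

    rho_t, rho_s, rho_v = params.frailty_loading_tests
    tug_loc, tug_scale = _floored_latent_params(params.tug_mean, params.tug_sd, 0.1)
    tug = np.maximum(tug_loc + tug_scale * _mix(rng, frailty, rho_t), 0.1)  # physical floor; keeps tug > 0
    sppb_loc, sppb_scale = _discrete_latent_params(params.sppb_mean, params.sppb_sd, 0, 12)
    sppb = np.clip(np.round(sppb_loc + sppb_scale * _mix(rng, frailty, rho_s)), 0, 12)
    spd_loc, spd_scale = _floored_latent_params(params.speed_mean, params.speed_sd, 0.0)
    speed = np.maximum(spd_loc + spd_scale * _mix(rng, frailty, rho_v), 0.0)

    rate = params.baseline_fall_rate * np.exp(params.frailty_loading_falls * frailty)
    falls = rng.poisson(rate).astype(float)

    df_cols = {
        "id": [f"s{i}" for i in range(n)],
        "age": age,
        "sex": sex,
        "prior_falls": pf,
        "walking_difficulty": wd,
        "tug_s": tug,
        "sppb": sppb,
        "gait_speed_mps": speed,
        "prospective_falls": falls,
    }
    import pandas as pd

    df = pd.DataFrame(df_cols)

    miss = {**{v: 0.0 for v in MISSING_VARIABLES}, **params.missing_probs}
    col_of = {
        "prior_falls": "prior_falls",
        "walking_difficulty": "walking_difficulty",
        "tug": "tug_s",
        "sppb": "sppb",
        "gait_speed": "gait_speed_mps",
        "prospective_falls": "prospective_falls",
    }
    for var in MISSING_VARIABLES:
        p = miss[var]
        if p <= 0:
            continue
        drop = rng.uniform(size=n) < p
        col = col_of[var]
        if col == "prior_falls":
            df.loc[drop, col] = None
        else:
            df.loc[drop, col] = np.nan

    return Cohort(df, provenance=f"synthetic(seed={params.seed}, n={n}, {params.name})")


def generate_reference_weights(
    age_mean: float = _REFERENCE_POPULATION["age_mean"],
    age_sd: float = _REFERENCE_POPULATION["age_sd"],
    prob_female: float = _REFERENCE_POPULATION["prob_female"],
    bands: Sequence[tuple[float, float]] = DEFAULT_BANDS,
) -> ReferenceWeights:
    """Reference weights from a truncated-Gaussian age pyramid and a sex split.

    Each stratum's weight is proportional to the truncated-normal
    probability mass of its age band times the sex probability; the
    defaults describe the standard population of older adults used for
    the age-sex standardized results.
    """
    bands = sorted(tuple(b) for b in bands)
    if bands[0][0] > 65 or not math.isinf(bands[-1][1]):
        raise ValueError("bands must cover [65, inf)")
    a65 = (65.0 - age_mean) / age_sd
    strata = []
    for lo, hi in bands:
        mass = stats.truncnorm.cdf(hi, a65, np.inf, loc=age_mean, scale=age_sd) - stats.truncnorm.cdf(
            lo, a65, np.inf, loc=age_mean, scale=age_sd
        )
        for sex, psex in (("female", prob_female), ("male", 1 - prob_female)):
            strata.append(Stratum(lo, hi if not math.isinf(hi) else math.inf, sex, mass * psex))
    return ReferenceWeights(strata)
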