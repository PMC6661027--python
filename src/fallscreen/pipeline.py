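"""End-to-end orchestration: simulate/load -> screen -> standardize -> impact.

A single :class:`RunConfig` describes one reproducible analysis: where the
cohort and reference weights come from (files or the synthetic generator),
which functional test and cutoff the screening uses, the outcome
definitions, the intervention relative risk, and the bootstrap settings.
:func:`run_pipeline` produces a report bundle -- a plain dict of numbers
with provenance metadata (seed, config hash) -- and :func:`render_report`
serializes it deterministically, so identical configs yield byte-identical
reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import accuracy as acc_mod
from . import impact as impact_mod
from .bootstrap import bootstrap_ci
from .cohort import (
    Cohort,
    ReferenceWeights,
    read_cohort,
    read_reference_weights,
    write_cohort,
    write_reference_weights,
)
from .screening import ScreeningConfig, screen_cohort, write_outcomes
from .standardize import standardize, standardized_confusion
from .synth import GeneratorParams, default_params, generate_reference_weights

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "render_report"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """One reproducible end-to-end analysis."""

    cohort_path: str | None = None
    generator: GeneratorParams | None = None
    weights_path: str | None = None
    weights_generator: Mapping[str, float] | None = None
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    outcome_defs: tuple[str, ...] = ("ge1", "ge2")
    rr: float = impact_mod.DEFAULT_RR
    rr_interval: tuple[float, float] | None = None
    ci: bool = False
    n_boot: int = 2000
    level: float = 0.95
    seed: int = 0
    roc_dense: bool = False
    outdir: str | None = None

    def __post_init__(self) -> None:
        if (self.cohort_path is None) == (self.generator is None):
            raise ValueError("specify exactly one of cohort_path or generator")
        if self.weights_path is not None and self.weights_generator is not None:
            raise ValueError("specify at most one of weights_path or weights_generator")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat key-value config file; keyword overrides win."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        kw: dict = {}
        for key in ("cohort_path", "weights_path", "rr", "ci", "n_boot", "level",
                    "seed", "roc_dense", "outdir"):
            if key in raw:
                kw[key] = raw.pop(key)
        if "generator" in raw:
            g = raw.pop("generator")
            kw["generator"] = GeneratorParams.from_dict(g) if g is not None else None
        if "weights_generator" in raw:
            kw["weights_generator"] = raw.pop("weights_generator")
        if "outcome_defs" in raw:
            kw["outcome_defs"] = tuple(raw.pop("outcome_defs"))
        if "rr_interval" in raw:
            ri = raw.pop("rr_interval")
            kw["rr_interval"] = tuple(ri) if ri is not None else None
        screen_kw = {}
        for key in ("test", "cutoff", "abnormal_direction", "missing_policy"):
            if f"screening_{key}" in raw:
                screen_kw[key] = raw.pop(f"screening_{key}")
        if screen_kw:
            kw["screening"] = (ScreeningConfig.for_test(screen_kw.pop("test"), **screen_kw)
                               if "test" in screen_kw else ScreeningConfig(**screen_kw))
        if raw:
            raise ValueError(f"unknown config keys: {sorted(raw)}")
        return cls(**kw)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"] = self.generator.to_dict() if self.generator else None
        d["screening"] = dataclasses.asdict(self.screening)
        d["weights_generator"] = dict(self.weights_generator) if self.weights_generator else None
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_jsonable(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as e:
                raise PipelineError(f"stage {name!r}: {e}") from e
        return wrapper
    return deco


@_stage("inputs")
def _load_inputs(config: RunConfig) -> tuple[Cohort, ReferenceWeights]:
    if config.cohort_path:
        cohort = read_cohort(config.cohort_path)
    else:
        from .synth import generate_cohort

        cohort = generate_cohort(config.generator)
    if config.weights_path:
        weights = read_reference_weights(config.weights_path)
    else:
        weights = generate_reference_weights(**(config.weights_generator or {}))
    return cohort, weights


def _branch_fractions(cohort: Cohort, weights: ReferenceWeights, screening: ScreeningConfig) -> dict:
    result = screen_cohort(cohort, screening)
    risk = result.risk_class
    out = {}
    for name, mask in (
        ("high", risk == "high"),
        ("low", risk == "low"),
        ("indeterminate", risk == "indeterminate"),
        ("assessed", result.assessed),
    ):
        sf = standardize(mask.astype(float), cohort, weights)
        out[name] = {"value": sf.value, "source": f"standardize({name})"}
    s = result.summary
    out["crude"] = {
        "high": s.frac_high, "low": s.frac_low,
        "indeterminate": s.frac_indeterminate, "assessed": s.frac_assessed,
        "n": s.n, "source": "screen_cohort.summary",
    }
    return out


def _impact_table(confusion, rr: float, coverage: float | None = None) -> dict:
    out = {}
    for scenario in ("none", "everyone", "screening"):
        est = impact_mod.impact_scenario(confusion, rr, scenario)
        out[scenario] = {"co": est.co, "f": est.f}
    co_screen = out["screening"]["co"]
    rand = impact_mod.impact_scenario(confusion, rr, "random",
                                      coverage=coverage if coverage is not None else co_screen)
    out["random"] = {"co": rand.co, "f": rand.f}
    out["rr"] = rr
    try:
        out["parity_coverage"] = impact_mod.parity_coverage(confusion, rr)
        out["extra_coverage_for_parity"] = out["parity_coverage"] - co_screen
    except ValueError:
        out["parity_coverage"] = None
        out["extra_coverage_for_parity"] = None
    out["delta_fallers_vs_random"] = impact_mod.delta_fallers_vs_random(confusion, rr)
    out["relative_reduction"] = impact_mod.relative_reduction(confusion, rr)
    out["source"] = "impact_scenario/parity_coverage/delta_fallers_vs_random/relative_reduction"
    return out


def _ci_statistics(screening: ScreeningConfig, weights: ReferenceWeights, rr_default: float):
    """One multi-statistic closure so all intervals share the resamples."""

    def stat(cohort: Cohort, rr: float | None = None) -> dict:
        r = rr_default if rr is None else rr
        result = screen_cohort(cohort, screening)
        risk = result.risk_class
        vals = {}
        for name, mask in (("high", risk == "high"), ("low", risk == "low"),
                           ("indeterminate", risk == "indeterminate"),
                           ("assessed", result.assessed)):
            vals[name] = standardize(mask.astype(float), cohort, weights).value
        conf = standardized_confusion(result, weights, "ge1")
        vals["prevalence"] = conf.prevalence
        vals["f_screening"] = impact_mod.impact_scenario(conf, r, "screening").f
        vals["f_none"] = impact_mod.impact_scenario(conf, r, "none").f
        vals["delta_fallers_vs_random"] = impact_mod.delta_fallers_vs_random(conf, r)
        try:
            vals["parity_coverage"] = impact_mod.parity_coverage(conf, r)
        except ValueError:
            vals["parity_coverage"] = None
        vals["relative_reduction"] = impact_mod.relative_reduction(conf, r)
        return vals

    return stat


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and return the report bundle."""
    cohort, weights = _load_inputs(config)

    screen_stage = _stage("screening")(_branch_fractions)
    branch = screen_stage(cohort, weights, config.screening)

    @_stage("accuracy")
    def acc_stage() -> dict:
        out = {}
        for test, grid in acc_mod.DEFAULT_CUTOFF_GRIDS.items():
            for outcome_def in config.outcome_defs:
                curve = acc_mod.roc_sweep(cohort, weights, test, grid, outcome_def)
                for pt in curve.points:
                    key = f"{test}@{pt.cutoff:g}:{outcome_def}"
                    conf = standardized_confusion(
                        screen_cohort(cohort, acc_mod.ScreeningConfig(
                            test=test, cutoff=pt.cutoff,
                            abnormal_direction=acc_mod.TESTS[test][1])),
                        weights, outcome_def)
                    m = acc_mod.accuracy_metrics(conf)
                    out[key] = {**m.as_dict(), "source": "accuracy_metrics"}
        return out

    @_stage("roc")
    def roc_stage() -> dict:
        out = {}
        for test in acc_mod.DEFAULT_CUTOFF_GRIDS:
            curve = acc_mod.roc_sweep(cohort, weights, test, None, "ge1", dense=config.roc_dense)
            out[test] = [{"cutoff": p.cutoff, "se": p.se, "sp": p.sp} for p in curve.points]
        return out

    @_stage("impact")
    def impact_stage() -> dict:
        result = screen_cohort(cohort, config.screening)
        conf = standardized_confusion(result, weights, "ge1")
        table = _impact_table(conf, config.rr)
        table["confusion"] = {
            "tp": conf.tp, "fp": conf.fp, "fn": conf.fn, "tn": conf.tn,
            "indeterminate": conf.indeterminate, "source": "standardized_confusion",
        }
        return table

    bundle = {
        "meta": {
            "seed": config.seed,
            "config_hash": config.config_hash,
            "config": config.to_jsonable(),
            "cohort_n": len(cohort),
            "cohort_provenance": cohort.provenance,
        },
        "branch_fractions": branch,
        "accuracy": acc_stage(),
        "roc": roc_stage(),
        "impact": impact_stage(),
    }

    if config.ci:
        @_stage("uncertainty")
        def ci_stage() -> dict:
            stat = _ci_statistics(config.screening, weights, config.rr)
            intervals = bootstrap_ci(
                stat, cohort, n_boot=config.n_boot, level=config.level,
                seed=config.seed, rr=config.rr, rr_interval=config.rr_interval,
            )
            return {k: v.as_dict() for k, v in intervals.items()}

        bundle["ci"] = ci_stage()

    if config.outdir:
        _write_bundle(bundle, cohort, weights, config)
    return bundle


@_stage("report")
def _write_bundle(bundle: dict, cohort: Cohort, weights: ReferenceWeights, config: RunConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    text, blob = render_report(bundle)
    (outdir / "report.json").write_text(blob)
    (outdir / "report.txt").write_text(text)
    if config.generator is not None:
        write_cohort(cohort, outdir / "cohort.csv")
    if config.weights_path is None:
        write_reference_weights(weights, outdir / "weights.csv")
    result = screen_cohort(cohort, config.screening)
    write_outcomes(result, outdir / "outcomes.csv")
    for test, points in bundle["roc"].items():
        import pandas as pd

        pd.DataFrame(points).assign(test=test).to_csv(outdir / f"roc_{test}.csv", index=False)
    logger.info("report bundle written to %s (config %s)", outdir, config.config_hash)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def render_report(bundle: dict) -> tuple[str, str]:
    """Render (human-readable text, canonical JSON) for a bundle.

    The JSON is sorted and fully precise, so re-running an identical
    config reproduces it byte for byte.
    """
    blob = json.dumps(_jsonable(bundle), sort_keys=True, indent=2) + "\n"

    lines = ["fall-risk screening analysis", "=" * 29, ""]
    meta = bundle["meta"]
    lines.append(f"cohort: {meta['cohort_provenance']} (n = {meta['cohort_n']})")
    lines.append(f"seed {meta['seed']}, config {meta['config_hash']}")
    lines.append("")
    bf = bundle["branch_fractions"]
    lines.append("standardized screening fractions:")
    for k in ("high", "low", "indeterminate", "assessed"):
        lines.append(f"  {k:14s} {bf[k]['value']:.4f}")
    imp = bundle["impact"]
    lines.append("")
    lines.append(f"impact (RR = {imp['rr']}):")
    for scenario in ("none", "everyone", "screening", "random"):
        row = imp[scenario]
        lines.append(f"  {scenario:10s} Co = {row['co']:.4f}  F = {row['f']:.4f}")
    if imp["parity_coverage"] is not None:
        lines.append(f"  parity coverage      {imp['parity_coverage']:.4f}")
        lines.append(f"  extra cov for parity {imp['extra_coverage_for_parity']:.4f}")
    lines.append(f"  delta fallers vs random {imp['delta_fallers_vs_random']:.5f}")
    lines.append(f"  relative reduction      {imp['relative_reduction']:.4f}")
    if "ci" in bundle:
        lines.append("")
        lines.append(f"95% bootstrap intervals:")
        for k, v in sorted(bundle["ci"].items()):
            lines.append(f"  {k:24s} {v['point']:.4f} ({v['lo']:.4f}-{v['hi']:.4f})")
    return "\n".join(lines) + "\n", blob
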