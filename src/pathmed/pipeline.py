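"""End-to-end orchestration: simulate -> select PRS -> fit -> bootstrap ->
sensitivity -> threshold scan -> confounder screen -> report.

Each stage writes machine-readable output (delimited text or JSON) into
the run directory and the manifest records parameters, per-stage seeds
and outcomes.  A single master seed expands into per-stage seeds through
numpy's SeedSequence spawning, so stages are reproducible independently.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import GeneratorConfig, default_imagen_config, default_ucc_config
from .generate import generate_cohort, inject_missingness
from .io import ColumnMap, read_cohort, summarize, write_cohort
from .mediation import ParallelMediation, PathModelSpec
from .prs import LassoThresholdSelector
from .scan import scan_percentiles, upscale_sample
from .screen import screen
from .sensitivity import acme_curve

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "DEFAULT_STAGES"]

DEFAULT_STAGES = (
    "simulate",
    "summarize",
    "select_prs",
    "fit",
    "sensitivity",
    "threshold_scan",
    "screen",
    "report",
)


@dataclass
class RunConfig:
    out_dir: str
    cohort_file: str | None = None          # read a cohort instead of simulating
    generator: str = "ucc"                  # "ucc" | "imagen" when simulating
    stages: tuple[str, ...] = DEFAULT_STAGES
    seed: int = 0
    n_boot: int = 5000
    scan_n_boot: int = 1000
    scan_step_percent: float = 5.0
    scan_factor: int = 10
    exposure: str | None = None             # default: PRS column chosen by select_prs
    mediators: tuple[str, ...] = ("ctq_total", "cannabis_case")
    outcome: str = "cape_total"
    covariates: tuple[str, ...] = ()
    missing_rule: str = "complete_ml"
    apply_missingness: bool = False
    sensitivity_mediator: str = "ctq_total"
    rho_grid: tuple[float, ...] = tuple(np.round(np.linspace(-0.9, 0.9, 37), 3))
    screen_candidates: tuple[str, ...] = ("pc1", "pc2", "pc3", "age", "gender")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        for key in ("stages", "mediators", "covariates", "rho_grid", "screen_candidates"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def _stage_seeds(master: int, stages: tuple[str, ...]) -> dict[str, int]:
    """One child seed per stage, spawned from the master SeedSequence."""
    ss = np.random.SeedSequence(master)
    children = ss.spawn(len(stages))
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(stages, children)
    }


def _generator_config(name: str) -> GeneratorConfig:
    if name == "ucc":
        return default_ucc_config()
    if name == "imagen":
        return default_imagen_config()
    raise ValueError(f"unknown generator {name!r} (expected 'ucc' or 'imagen')")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order.

    Returns the manifest (also written as ``manifest.json``).  A stage
    failure halts downstream stages; partial outputs are preserved and
    the manifest carries the failure marker.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, DEFAULT_STAGES)
    manifest: dict = {
        "package_version": __version__,
        "master_seed": config.seed,
        "stage_seeds": {},
        "parameters": {
            "n_boot": config.n_boot,
            "scan_n_boot": config.scan_n_boot,
            "scan_step_percent": config.scan_step_percent,
            "scan_factor": config.scan_factor,
            "missing_rule": config.missing_rule,
            "mediators": list(config.mediators),
            "outcome": config.outcome,
            "covariates": list(config.covariates),
        },
        "stages": {},
        "failed": None,
    }

    state: dict = {}
    try:
        for stage in DEFAULT_STAGES:
            if stage not in config.stages:
                continue
            runner = _STAGE_RUNNERS[stage]
            if stage in ("simulate", "select_prs", "fit", "threshold_scan"):
                manifest["stage_seeds"][stage] = seeds[stage]
            runner(config, state, out, seeds[stage], manifest)
            manifest["stages"][stage] = "ok"
    except Exception as exc:  # halt downstream, keep partial outputs
        logger.exception("stage failed")
        manifest["failed"] = {"stage": stage, "error": str(exc)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


# ----------------------------------------------------------------------
# stage implementations
# ----------------------------------------------------------------------

def _stage_simulate(config, state, out, seed, manifest):
    if config.cohort_file:
        table = read_cohort(config.cohort_file)
        state["generator"] = None
    else:
        gen = _generator_config(config.generator)
        table = generate_cohort(gen, seed=seed)
        if config.apply_missingness:
            table = inject_missingness(table, gen, seed=seed + 1)
        state["generator"] = gen
        write_cohort(table, out / "cohort.csv")
        (out / "generator_config.json").write_text(
            json.dumps(
                {
                    "cohort": config.generator,
                    "n": gen.n_individuals,
                    "seed": seed,
                    "prs_sd": gen.prs_sd,
                    "paths": {f"{s}->{t}": v for (s, t), v in gen.path_coefficients.items()},
                },
                indent=2,
            )
        )
    state["table"] = table


def _stage_summarize(config, state, out, seed, manifest):
    summary = summarize(state["table"])
    summary.to_csv(out / "summary.csv")
    state["summary"] = summary


def _stage_select_prs(config, state, out, seed, manifest):
    sel = LassoThresholdSelector(outcome=config.outcome, random_state=seed)
    sel.fit(state["table"])
    sel.result_.to_frame().to_csv(out / "prs_selection.csv", index=False)
    state["exposure"] = config.exposure or sel.chosen_
    manifest.setdefault("results", {})["chosen_prs"] = sel.chosen_
    manifest["results"]["chosen_prs_r2"] = sel.chosen_r2_


def _exposure(config, state):
    return config.exposure or state.get("exposure", "prs_pt_0.5")


def _stage_fit(config, state, out, seed, manifest):
    est = ParallelMediation(
        exposure=_exposure(config, state),
        mediators=config.mediators,
        outcome=config.outcome,
        covariates=config.covariates,
        missing=config.missing_rule,
        n_boot=config.n_boot,
        random_state=seed,
    )
    est.fit(state["table"])
    state["mediation"] = est
    frame = est.effects_.to_frame()
    frame.to_csv(out / "effects.csv", index=False)
    manifest.setdefault("results", {})["effects"] = {
        row["quantity"]: row["estimate"] for _, row in frame.iterrows()
    }


def _stage_sensitivity(config, state, out, seed, manifest):
    curve = acme_curve(
        state["mediation"].model_,
        config.sensitivity_mediator,
        rho_grid=np.asarray(config.rho_grid),
    )
    frame = curve.to_frame()
    frame.to_csv(out / "sensitivity.csv", index=False)
    manifest.setdefault("results", {})["rho_zero"] = curve.rho_zero
    manifest["results"]["r2_at_zero"] = curve.r2_at_zero


def _stage_threshold_scan(config, state, out, seed, manifest):
    fit = state["mediation"].model_
    big = upscale_sample(fit, factor=config.scan_factor, seed=seed)
    scan = scan_percentiles(
        big,
        fit.spec,
        step_percent=config.scan_step_percent,
        n_boot=config.scan_n_boot,
        seed=seed + 1,
        mediator=config.sensitivity_mediator,
    )
    scan.to_frame().to_csv(out / "threshold_scan.csv", index=False)
    manifest.setdefault("results", {})["threshold_percentile"] = scan.threshold_percentile


def _stage_screen(config, state, out, seed, manifest):
    report = screen(
        state["table"],
        outcome=config.outcome,
        exposure=_exposure(config, state),
        candidates=list(config.screen_candidates),
    )
    report.step1.to_csv(out / "screen_step1.csv", index=False)
    report.step2.to_csv(out / "screen_step2.csv", index=False)
    manifest.setdefault("results", {})["confounders"] = report.confounders


def _stage_report(config, state, out, seed, manifest):
    """Human-readable summary; every number also exists in a CSV/JSON."""
    lines = ["Parallel multiple-mediator path model", "=" * 40]
    est = state.get("mediation")
    if est is not None:
        frame = est.effects_.to_frame()
        for _, row in frame.iterrows():
            ci = ""
            if row["ci_lower"] == row["ci_lower"]:
                ci = f" (95% CI {row['ci_lower']:.3f}; {row['ci_upper']:.3f})"
            prop = ""
            if row["proportion_mediated_pct"] == row["proportion_mediated_pct"]:
                prop = f"  [{row['proportion_mediated_pct']:.1f}% mediated]"
            lines.append(f"{row['quantity']:<28}{row['estimate']:.3f}{ci}{prop}")
    results = manifest.get("results", {})
    if "rho_zero" in results and results["rho_zero"] is not None:
        lines.append(
            f"sensitivity rho_zero        {results['rho_zero']:.3f}"
            f"  (R^2 = {results['r2_at_zero']:.3f})"
        )
    if results.get("threshold_percentile") is not None:
        lines.append(
            f"mediation threshold         {results['threshold_percentile']:.0f}th percentile"
        )
    (out / "report.txt").write_text("\n".join(lines) + "\n")


_STAGE_RUNNERS = {
    "simulate": _stage_simulate,
    "summarize": _stage_summarize,
    "select_prs": _stage_select_prs,
    "fit": _stage_fit,
    "sensitivity": _stage_sensitivity,
    "threshold_scan": _stage_threshold_scan,
    "screen": _stage_screen,
    "report": _stage_report,
}
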