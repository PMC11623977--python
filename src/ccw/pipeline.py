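"""End-to-end orchestration: config parsing, the full run, artifact bundle.

The run config is the machine-readable emulation protocol: input tables,
time grid, eligibility criteria, the treatment strategies being compared,
the weight model, and the estimands.  ``run_pipeline`` executes

    read -> eligibility -> clone -> censor -> expand -> weight -> diagnose
         -> estimate -> bootstrap

and writes the complete artifact bundle (person-time tables, survival
curves, estimates, balance and weight reports, flow report, manifest, log).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .clone_censor import (
    attrition_counts,
    censor_clones,
    expand_person_time,
    make_clones,
)
from .cohort import CohortBundle, apply_eligibility, read_cohort
from .diagnostics import weight_summary, weighted_smd
from .estimation import bootstrap_ci, contrast, per_interval_risk_check, weighted_km
from .trial_spec import (
    ComponentRule,
    ExcusalRule,
    StrategySpec,
    TimeGrid,
    validate_strategy,
)
from .weights import (
    WeightModelSpec,
    combine_classic_weights,
    compute_ipcw,
    compute_iptw,
    fit_classic_model,
    fit_uncensored_model,
)

__all__ = ["RunConfig", "run_pipeline", "estimate_once", "parse_strategies", "PipelineError"]

logger = logging.getLogger("ccw")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")


def parse_strategies(items: list[dict]) -> list[StrategySpec]:
    out = []
    for item in items:
        comps = tuple(
            ComponentRule(
                component=c["component"],
                mode=c.get("mode", "require"),
                window=tuple(c.get("window", (0, 0))),
                anchor=c.get("anchor", "time-zero"),
                trigger=c.get("trigger"),
                lift_on_trigger=c.get("lift_on_trigger"),
            )
            for c in item["components"]
        )
        excusals = tuple(
            ExcusalRule(condition=e["condition"] if isinstance(e, dict) else e)
            for e in item.get("excusals", ())
        )
        out.append(
            StrategySpec(
                id=item["id"],
                kind=item.get("kind", "initiation"),
                components=comps,
                excusals=excusals,
            )
        )
    return out


def parse_weight_spec(block: dict | None) -> WeightModelSpec:
    block = block or {}
    return WeightModelSpec(
        implementation=block.get("implementation", "ipcw"),
        denominator_covariates=tuple(block.get("denominator", ())),
        numerator_covariates=tuple(block.get("numerator", ())),
        stabilized=bool(block.get("stabilized", False)),
        estimator=block.get("estimator"),
        time_form=block.get("time_form", "default"),
        truncation_percentile=block.get("truncation_percentile"),
    )


@dataclass
class RunConfig:
    patients: str
    grid: TimeGrid
    strategies: list[StrategySpec]
    treatments: str | None = None
    covariates: str | None = None
    eligibility: list[dict] = field(default_factory=list)
    weights: WeightModelSpec = field(default_factory=WeightModelSpec)
    classic_weights: bool = False
    estimands: list[str] = field(default_factory=lambda: ["survival_difference"])
    horizon: float | None = None
    arms: tuple[str, str] | None = None
    bootstrap_B: int = 0
    seed: int = 0
    output: str = "ccw_output"
    raw: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path | None = None) -> "RunConfig":
        def _resolve(p):
            if p is None:
                return None
            p = Path(p)
            if base_dir is not None and not p.is_absolute():
                p = base_dir / p
            return str(p)

        inputs = raw.get("inputs", {})
        grid_block = raw.get("grid", {})
        grid = TimeGrid(
            horizon=int(grid_block.get("horizon", 365)),
            interval_length=int(grid_block.get("interval_length", 1)),
            unit=grid_block.get("unit", "day"),
        )
        est = raw.get("estimation", {})
        boot = est.get("bootstrap", {}) or {}
        arms = est.get("arms")
        return cls(
            patients=_resolve(inputs.get("patients")),
            treatments=_resolve(inputs.get("treatments")),
            covariates=_resolve(inputs.get("covariates")),
            grid=grid,
            eligibility=raw.get("eligibility", []) or [],
            strategies=parse_strategies(raw.get("strategies", [])),
            weights=parse_weight_spec(raw.get("weights")),
            classic_weights=bool((raw.get("weights") or {}).get("classic", False)),
            estimands=list(est.get("estimands", ["survival_difference"])),
            horizon=est.get("horizon"),
            arms=tuple(arms) if arms else None,
            bootstrap_B=int(boot.get("B", 0)),
            seed=int(boot.get("seed", 0)),
            output=_resolve(raw.get("output", "ccw_output")),
            raw=raw,
        )

    def validate(self) -> None:
        if not self.strategies or len(self.strategies) < 2:
            raise PipelineError("config", "need at least two strategies")
        ids = [s.id for s in self.strategies]
        if self.arms:
            missing = [a for a in self.arms if a not in ids]
            if missing:
                raise PipelineError(
                    "config", f"estimand names undefined strategy id(s): {missing}"
                )
        for e in self.estimands:
            if e not in ("risk_difference", "survival_difference", "rmst_difference"):
                raise PipelineError("config", f"unknown estimand {e!r}")


def compute_weighted_table(
    bundle: CohortBundle,
    strategies: list[StrategySpec],
    weight_spec: WeightModelSpec | None,
    classic: bool = False,
):
    """Clone, censor, expand and weight; returns (table, clones, models)."""
    spec = weight_spec or WeightModelSpec(
        implementation="ipcw",
        denominator_covariates=tuple(bundle.baseline_covariate_names),
    )
    clones = censor_clones(make_clones(bundle, strategies), bundle, strategies)
    table = expand_person_time(clones, bundle, strategies=strategies)
    models: dict = {}
    if spec.implementation == "iptw":
        table, info = compute_iptw(bundle, table, spec, strategies, bundle.grid)
        models["iptw"] = info
    else:
        numerators = None
        for s in strategies:
            models[s.id] = fit_uncensored_model(table, spec, s.id, bundle.grid)
        if spec.is_stabilized:
            numerators = {
                s.id: fit_uncensored_model(
                    table, spec, s.id, bundle.grid, numerator=True
                )
                for s in strategies
            }
        table = compute_ipcw(table, {k: v for k, v in models.items()}, spec, numerators)
    if classic:
        classic_models = {
            s.id: fit_classic_model(table, spec, s.id, bundle.grid)
            for s in strategies
        }
        table = combine_classic_weights(table, classic_models)
    if spec.truncation_percentile is not None:
        from .weights import truncate_weights

        table, n_trunc = truncate_weights(table, spec.truncation_percentile)
        models["_n_truncated"] = n_trunc
    return table, clones, models


def estimate_once(
    bundle: CohortBundle,
    strategies: list[StrategySpec],
    weight_spec: WeightModelSpec | None,
    estimand: str,
    horizon: float,
    arms: tuple[str, str] | None = None,
    classic: bool = False,
) -> float:
    """Point estimate of one contrast by the full row-level pipeline."""
    table, _, _ = compute_weighted_table(bundle, strategies, weight_spec, classic)
    arms = arms or (strategies[0].id, strategies[1].id)
    curves = {a: weighted_km(table, a) for a in arms}
    return contrast(curves, estimand, horizon, arms).point


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full emulation and write the artifact bundle.

    Returns a manifest dict (also written as ``manifest.json``).  Any stage
    failure raises :class:`PipelineError` carrying the stage name after
    writing a partial manifest.
    """
    out = Path(config.output)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.txt"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    manifest: dict = {
        "config_hash": hashlib.sha256(
            json.dumps(config.raw, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": config.seed,
        "artifacts": [],
        "stages": [],
    }

    def _stage(name):
        logger.info("stage %s", name)
        manifest["stages"].append(name)

    def _write_manifest():
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    def _artifact(path: Path):
        manifest["artifacts"].append(path.name)

    t0 = time.time()
    try:
        _stage("config")
        config.validate()

        _stage("read")
        bundle = read_cohort(
            config.patients, config.grid, config.treatments, config.covariates
        )
        logger.info("read %d patients, %d treatment events, %d covariate records",
                    bundle.n_patients, len(bundle.treatments), len(bundle.covariates))
        screened = bundle.n_patients

        _stage("eligibility")
        bundle, exclusion_log = apply_eligibility(bundle, config.eligibility)
        logger.info("eligible %d (excluded %s)", bundle.n_patients, exclusion_log)

        _stage("clone_censor")
        known = bundle.component_names | {
            r.component for s in config.strategies for r in s.components
        }
        for s in config.strategies:
            validate_strategy(s, known)
        table, clones, models = compute_weighted_table(
            bundle, config.strategies, config.weights, config.classic_weights
        )
        flow = attrition_counts(clones, exclusion_log, screened, bundle)
        flow.to_json(out / "flow_report.json")
        _artifact(out / "flow_report.json")
        (out / "flow_report.txt").write_text(flow.to_text())
        _artifact(out / "flow_report.txt")

        clone_table = expand_person_time(clones, bundle, strategies=config.strategies)
        clone_table.to_csv(out / "clone_person_time.csv", index=False)
        _artifact(out / "clone_person_time.csv")
        table.to_csv(out / "weighted_person_time.csv", index=False)
        _artifact(out / "weighted_person_time.csv")

        _stage("diagnostics")
        with open(out / "weight_summary.json", "w") as fh:
            json.dump(weight_summary(table), fh, indent=2)
        _artifact(out / "weight_summary.json")
        covs = bundle.baseline_covariate_names
        arms = config.arms or (config.strategies[0].id, config.strategies[1].id)
        if covs:
            ref = max(
                (r.window[1] for s in config.strategies for r in s.components),
                default=0,
            )
            try:
                report = weighted_smd(table, ref, covs, arms=arms)
                report.to_csv(out / "balance_report.csv")
                _artifact(out / "balance_report.csv")
            except ValueError as err:
                logger.warning("balance report skipped: %s", err)
        for line in per_interval_risk_check(table):
            logger.warning("%s", line)

        _stage("estimate")
        horizon = config.horizon if config.horizon is not None else config.grid.horizon
        curves = {a: weighted_km(table, a) for a in arms}
        pd.concat([c.to_frame() for c in curves.values()]).to_csv(
            out / "survival_curves.csv", index=False
        )
        _artifact(out / "survival_curves.csv")
        estimates = []
        for estimand in config.estimands:
            if config.bootstrap_B >= 2:
                est = bootstrap_ci(
                    bundle,
                    config.strategies,
                    estimand,
                    horizon,
                    weight_spec=config.weights,
                    B=config.bootstrap_B,
                    seed=config.seed,
                    arms=arms,
                )
            else:
                est = contrast(curves, estimand, horizon, arms)
            estimates.append(est.to_dict())
            logger.info("%s at %s: %.6f", estimand, horizon, est.point)
        with open(out / "estimates.json", "w") as fh:
            json.dump(estimates, fh, indent=2)
        _artifact(out / "estimates.json")

        manifest["elapsed_seconds"] = round(time.time() - t0, 3)
        _write_manifest()
        logger.info("done in %.1fs", manifest["elapsed_seconds"])
        return manifest
    except PipelineError:
        _write_manifest()
        raise
    except Exception as err:  # noqa: BLE001 - annotate with the failing stage
        _write_manifest()
        stage = manifest["stages"][-1] if manifest["stages"] else "unknown"
        raise PipelineError(stage, str(err)) from err
    finally:
        logger.removeHandler(handler)
        handler.close()
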