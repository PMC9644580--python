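"""End-to-end orchestration: simulate -> estimate -> run -> psa -> report.

Each stage is callable on its own with file handoffs (the CLI exposes them
as subcommands); :func:`run_pipeline` chains them and writes a JSON
manifest with the stage seeds, a configuration hash and the package
version, so every emitted number is reproducible from the manifest alone.
All randomness flows from one top-level seed expanded per stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cea import (
    ceac,
    ce_plane,
    evaluate_strategies,
    incremental_summary,
    population_scale,
    run_psa,
)
from .config import ModelConfig, load_default_config
from .engine import evaluate_model
from .estimation import estimate_transition_matrix, summarize_costs
from .reporting import summarize_cohort
from .synthetic import MEDICATION_GROUPS, generate_baseline, generate_billing, generate_histories

__all__ = ["AnalysisConfig", "StageError", "run_pipeline"]

log = logging.getLogger("cadcea")

_STAGES = ("simulate", "estimate", "run", "psa", "report")


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class AnalysisConfig:
    """Settings for one full analysis run."""

    model_path: str | Path | None = None  # None -> shipped default model
    out_dir: str | Path = "results"
    seed: int = 0
    n_draws: int = 1000
    base_strategy: str = "current_practice"
    wtp_grid: tuple[float, ...] = tuple(float(x) for x in range(0, 160_001, 10_000))
    patients_per_year: float = 6000.0
    use_estimated_transitions: bool = True
    sample_transitions: bool = False
    verbosity: int = logging.INFO
    engine_overrides: dict = field(default_factory=dict)

    def load_model(self) -> ModelConfig:
        if self.model_path is None:
            cfg = load_default_config()
        else:
            path = Path(self.model_path)
            if not path.exists():
                raise StageError("config", f"model file not found: {path}")
            cfg = ModelConfig.from_yaml(path)
        if self.engine_overrides:
            import dataclasses as _dc

            cfg.engine = _dc.replace(cfg.engine, **self.engine_overrides)
        return cfg

    def stage_seeds(self) -> dict[str, int]:
        rng = np.random.default_rng(self.seed)
        return {s: int(rng.integers(0, 2**31)) for s in _STAGES}

    def digest(self) -> str:
        doc = {
            "model_path": str(self.model_path),
            "seed": self.seed,
            "n_draws": self.n_draws,
            "base_strategy": self.base_strategy,
            "wtp_grid": list(self.wtp_grid),
            "patients_per_year": self.patients_per_year,
            "use_estimated_transitions": self.use_estimated_transitions,
            "sample_transitions": self.sample_transitions,
            "engine_overrides": self.engine_overrides,
        }
        return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()


def _csv(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, index=False, float_format="%.10g")
    return path.name


def stage_simulate(cfg: ModelConfig, out: Path, seed: int) -> dict:
    truth = cfg.ground_truth(seed=seed)
    histories = generate_histories(truth)
    billing = generate_billing(histories, truth)
    arm_sizes = {
        arm: int(round(w * truth.n_patients))
        for arm, w in cfg.synthetic.get("start_distribution", {}).items()
    }
    baseline = generate_baseline(arm_sizes, seed=seed + 1)
    return {
        "histories": _csv(histories, out / "histories.csv"),
        "billing": _csv(billing, out / "billing.csv"),
        "baseline": _csv(baseline, out / "baseline.csv"),
    }


def stage_estimate(cfg: ModelConfig, out: Path) -> tuple[ModelConfig, dict]:
    histories = pd.read_csv(out / "histories.csv")
    billing = pd.read_csv(out / "billing.csv")
    death = next(d["name"] for d in cfg.state_defs if d.get("absorbing"))
    estimates = estimate_transition_matrix(
        histories, cfg.state_names, absorbing=death
    )
    fitted = cfg.with_transitions(estimates)
    cost_summary = pd.DataFrame(
        [
            {"group": g, **dict(zip(("mean", "sd"), summarize_costs(billing, g)))}
            for g in MEDICATION_GROUPS
            if (billing["group"] == g).any()
        ]
    )
    doc = fitted.parameter_document()
    with open(out / "parameters.json", "w") as fh:
        json.dump(doc, fh, indent=1)
    outputs = {
        "parameters": "parameters.json",
        "cost_summary": _csv(cost_summary, out / "cost_summary.csv"),
    }
    return fitted, outputs


def stage_run(cfg: ModelConfig, out: Path) -> dict:
    outputs = {}
    totals = []
    for arm, model in cfg.build_models().items():
        cost, qaly, trace = evaluate_model(model, cfg.engine)
        occ = trace.occupancy
        tidy = pd.DataFrame(
            {
                "cycle": np.repeat(np.arange(occ.shape[0]), occ.shape[1]),
                "state": np.tile(trace.state_names, occ.shape[0]),
                "count": occ.ravel(),
            }
        )
        outputs[f"trace_{arm}"] = _csv(tidy, out / f"trace_{arm}.csv")
        totals.append({"arm": arm, "cost": cost, "qaly": qaly})
    outputs["arm_totals"] = _csv(pd.DataFrame(totals), out / "arm_totals.csv")
    strat = evaluate_strategies(cfg)
    outputs["strategy_totals"] = _csv(strat, out / "strategy_totals.csv")
    return outputs


def stage_psa(cfg: ModelConfig, out: Path, seed: int, n_draws: int, sample_transitions: bool):
    psa = run_psa(
        cfg,
        n_draws=n_draws,
        seed=seed,
        sample_transitions=sample_transitions,
    )
    return psa, {"psa_draws": _csv(psa.draws, out / "psa_draws.csv")}


def stage_report(cfg: ModelConfig, analysis: AnalysisConfig, psa, out: Path) -> dict:
    outputs = {}
    base = analysis.base_strategy
    wtp = cfg.engine.wtp_threshold
    rows = []
    for name in cfg.strategies:
        # the base policy compares against itself: an all-zero row anchors
        # the table the way the CE plane puts current practice at the origin
        ce = incremental_summary(psa, name, base, wtp)
        annual_cost, annual_qaly, annual_value = population_scale(
            ce, analysis.patients_per_year
        )
        rows.append(
            {
                "strategy": name,
                "base": base,
                "delta_cost": ce.delta_cost,
                "delta_cost_lo": ce.delta_cost_ui[0],
                "delta_cost_hi": ce.delta_cost_ui[1],
                "delta_qaly": ce.delta_qaly,
                "delta_qaly_lo": ce.delta_qaly_ui[0],
                "delta_qaly_hi": ce.delta_qaly_ui[1],
                "nmb": ce.nmb,
                "nmb_lo": ce.nmb_ui[0],
                "nmb_hi": ce.nmb_ui[1],
                "p_cost_saving": ce.p_cost_saving,
                "p_qaly_gain": ce.p_qaly_gain,
                "p_cost_effective": ce.p_cost_effective,
                "annual_cost_change": annual_cost,
                "annual_qaly_change": annual_qaly,
                "annual_qaly_value": annual_value,
            }
        )
        if name != base:
            curve = ceac(psa, name, base, analysis.wtp_grid)
            outputs[f"ceac_{name}"] = _csv(curve, out / f"ceac_{name}.csv")
            plane = ce_plane(psa, name, base)
            outputs[f"ce_plane_{name}"] = _csv(plane, out / f"ce_plane_{name}.csv")
    outputs["strategy_comparison"] = _csv(
        pd.DataFrame(rows), out / "strategy_comparison.csv"
    )
    baseline = pd.read_csv(out / "baseline.csv")
    outputs["cohort_summary"] = _csv(
        summarize_cohort(baseline), out / "cohort_summary.csv"
    )
    return outputs


def run_pipeline(analysis: AnalysisConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    out = Path(analysis.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=analysis.verbosity)
    seeds = analysis.stage_seeds()
    manifest: dict = {
        "version": __version__,
        "seed": analysis.seed,
        "stage_seeds": seeds,
        "config_sha256": analysis.digest(),
        "outputs": {},
        "completed_stages": [],
    }

    def _finish(stage: str, outputs: dict) -> None:
        manifest["outputs"].update(outputs)
        manifest["completed_stages"].append(stage)
        log.info("stage %s done: %s", stage, sorted(outputs))

    try:
        cfg = analysis.load_model()
    except StageError:
        _write_manifest(manifest, out)
        raise
    try:
        log.info("simulate: seed=%d", seeds["simulate"])
        _finish("simulate", stage_simulate(cfg, out, seeds["simulate"]))

        fitted, outputs = stage_estimate(cfg, out)
        _finish("estimate", outputs)
        run_cfg = fitted if analysis.use_estimated_transitions else cfg

        _finish("run", stage_run(run_cfg, out))

        psa, outputs = stage_psa(
            run_cfg, out, seeds["psa"], analysis.n_draws, analysis.sample_transitions
        )
        _finish("psa", outputs)

        _finish("report", stage_report(run_cfg, analysis, psa, out))
    except StageError:
        _write_manifest(manifest, out)
        raise
    except Exception as exc:  # annotate with the failed stage
        failed = _STAGES[len(manifest["completed_stages"])]
        _write_manifest(manifest, out)
        raise StageError(failed, str(exc)) from exc
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    manifest["partial"] = len(manifest["completed_stages"]) < len(_STAGES)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
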