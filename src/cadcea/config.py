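"""Model configuration: structure, parameters, strategies, ground truth.

The model structure (states, allowed transitions per arm, starting arms,
policy mixes) is data, not code: it ships as a YAML document so users can
adapt the topology to their own reading of the clinical pathways.  This
module loads and validates that document, assembles per-arm
:class:`~cadcea.engine.Model` objects, and derives the synthetic-data
ground truth from the same description.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .engine import EngineConfig, Model, StateDefinition
from .estimation import DistributionSpec, TransitionEstimate
from .synthetic import GroundTruth

__all__ = ["ModelConfig", "build_model", "load_default_config"]

_ROW_TOL = 1e-9


def _spec_from_dict(d: dict) -> DistributionSpec:
    kind = d["kind"]
    if kind == "dirichlet":
        return DistributionSpec(kind=kind, counts=tuple(d["counts"]))
    if kind == "fixed":
        return DistributionSpec(kind=kind, mean=float(d["mean"]))
    return DistributionSpec(kind=kind, mean=float(d["mean"]), sd=float(d["sd"]))


@dataclass
class ModelConfig:
    """Parsed model configuration (structure + parameters + strategies)."""

    state_defs: list[dict]
    parameters: dict[str, DistributionSpec]
    allowed: dict[str, list[str]]
    probabilities: dict[str, dict[str, float]]
    arms: dict[str, str]  # arm name -> start state
    strategies: dict[str, dict[str, float]]
    synthetic: dict = field(default_factory=dict)
    engine: EngineConfig = field(default_factory=EngineConfig)
    dirichlet_counts: dict[str, dict[str, float]] = field(default_factory=dict)

    # -- construction ----------------------------------------------------

    @classmethod
    def from_dict(cls, doc: dict) -> "ModelConfig":
        params = {k: _spec_from_dict(v) for k, v in doc.get("parameters", {}).items()}
        trans = doc.get("transitions", {})
        engine_kwargs = doc.get("engine", {})
        return cls(
            state_defs=list(doc["states"]),
            parameters=params,
            allowed={k: list(v) for k, v in trans.get("allowed", {}).items()},
            probabilities={
                k: dict(v) for k, v in trans.get("probabilities", {}).items()
            },
            arms={k: v["start_state"] for k, v in doc.get("arms", {}).items()},
            strategies={k: dict(v) for k, v in doc.get("strategies", {}).items()},
            synthetic=dict(doc.get("synthetic", {})),
            engine=EngineConfig(**engine_kwargs),
            dirichlet_counts={
                k: dict(v) for k, v in trans.get("dirichlet_counts", {}).items()
            },
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    # -- resolution ------------------------------------------------------

    @property
    def state_names(self) -> list[str]:
        return [d["name"] for d in self.state_defs]

    def _resolve(self, value, draws: dict[str, float] | None, where: str) -> float:
        """A numeric field is either a literal or the name of a parameter."""
        if value is None:
            return 0.0
        if isinstance(value, str):
            if value not in self.parameters:
                raise ValueError(f"missing parameter {value!r} needed by {where}")
            if draws is not None and value in draws:
                return float(draws[value])
            spec = self.parameters[value]
            if spec.kind == "dirichlet":
                raise ValueError(f"{where}: dirichlet spec cannot supply a scalar")
            return float(spec.mean)
        return float(value)

    def resolve_states(self, draws: dict[str, float] | None = None) -> tuple[StateDefinition, ...]:
        out = []
        for d in self.state_defs:
            name = d["name"]
            out.append(
                StateDefinition(
                    name=name,
                    per_cycle_cost=self._resolve(d.get("per_cycle_cost"), draws, name),
                    entry_cost=self._resolve(d.get("entry_cost"), draws, name),
                    utility=self._resolve(d.get("utility"), draws, name),
                    absorbing=bool(d.get("absorbing", False)),
                )
            )
        return tuple(out)

    def transition_matrix(
        self, rows: dict[str, dict[str, float]] | None = None
    ) -> np.ndarray:
        """Assemble the row-stochastic matrix; disallowed pairs stay 0."""
        names = self.state_names
        index = {s: i for i, s in enumerate(names)}
        probs = rows if rows is not None else self.probabilities
        m = np.zeros((len(names), len(names)))
        for d in self.state_defs:
            if d.get("absorbing"):
                m[index[d["name"]], index[d["name"]]] = 1.0
        for frm, row in probs.items():
            if frm not in index:
                raise ValueError(f"transition from unknown state {frm!r}")
            allowed = set(self.allowed.get(frm, names))
            for to, p in row.items():
                if to not in index:
                    raise ValueError(f"transition {frm!r}->{to!r}: unknown state")
                if to not in allowed:
                    raise ValueError(
                        f"transition {frm!r}->{to!r} not in the arm's diagram"
                    )
                m[index[frm], index[to]] = float(p)
        bad = np.abs(m.sum(axis=1) - 1.0) > _ROW_TOL
        if bad.any():
            culprits = [names[i] for i in np.flatnonzero(bad)]
            raise ValueError(f"row sums differ from 1 for states {culprits}")
        return m

    def build_models(
        self,
        draws: dict[str, float] | None = None,
        transition_rows: dict[str, dict[str, float]] | None = None,
    ) -> dict[str, Model]:
        """One validated :class:`Model` per starting arm."""
        states = self.resolve_states(draws)
        matrix = self.transition_matrix(transition_rows)
        return {
            arm: Model(arm=arm, states=states, matrix=matrix, start_state=start)
            for arm, start in self.arms.items()
        }

    def with_transitions(
        self, estimates: dict[str, TransitionEstimate]
    ) -> "ModelConfig":
        """A copy whose probabilities (and Dirichlet counts) come from estimates."""
        probs: dict[str, dict[str, float]] = {}
        counts: dict[str, dict[str, float]] = {}
        for frm, est in estimates.items():
            probs[frm] = {
                t: p for t, p in zip(est.to_states, est.probabilities) if p > 0
            }
            counts[frm] = {t: c for t, c in zip(est.to_states, est.counts) if c > 0}
        return dataclasses.replace(
            self, probabilities=probs, dirichlet_counts=counts
        )

    # -- synthetic ground truth ------------------------------------------

    def ground_truth(self, seed: int = 0, **overrides) -> GroundTruth:
        """Ground truth for the record generator, from this configuration."""
        syn = dict(self.synthetic)
        syn.update(overrides)
        names = self.state_names
        start = np.zeros(len(names))
        for arm, w in syn.get("start_distribution", {}).items():
            start[names.index(self.arms.get(arm, arm))] = w
        cost_params = {}
        for grp, pname in syn.get("medication_groups", {}).items():
            spec = self.parameters[pname]
            cost_params[grp] = (spec.mean, spec.sd)
        proc_costs = {}
        for st, pname in syn.get("procedure_cost_states", {}).items():
            spec = self.parameters[pname]
            proc_costs[st] = (spec.mean, spec.sd)
        return GroundTruth(
            states=tuple(names),
            transition_matrix=self.transition_matrix(),
            start_distribution=start,
            cost_params=cost_params,
            procedure_costs=proc_costs,
            procedure_states=tuple(syn.get("procedure_cost_states", {})),
            stent_states=tuple(syn.get("stent_states", ())),
            bypass_states=tuple(syn.get("bypass_states", ())),
            n_patients=int(syn.get("n_patients", 10_000)),
            n_cycles=int(syn.get("n_cycles", 20)),
            administrative_censoring=bool(syn.get("administrative_censoring", False)),
            seed=seed,
        )

    # -- serialization ---------------------------------------------------

    def parameter_document(self) -> dict:
        """JSON/YAML-ready dump of states, transition rows and distributions."""
        rows = []
        for frm, row in self.probabilities.items():
            tos = list(row)
            rows.append(
                {
                    "from": frm,
                    "to": tos,
                    "probabilities": [row[t] for t in tos],
                    "counts": [
                        self.dirichlet_counts.get(frm, {}).get(t, None) for t in tos
                    ],
                }
            )
        dists = {}
        for name, spec in self.parameters.items():
            d = {"kind": spec.kind}
            if spec.kind == "dirichlet":
                d["counts"] = list(spec.counts)
            else:
                d["mean"] = spec.mean
                if spec.sd is not None:
                    d["sd"] = spec.sd
            dists[name] = d
        return {"states": self.state_names, "rows": rows, "distributions": dists}


def build_model(config: ModelConfig, arm: str) -> Model:
    """Build one arm's validated model at the parameter means."""
    models = config.build_models()
    if arm not in models:
        raise ValueError(f"unknown arm {arm!r}; have {sorted(models)}")
    return models[arm]


def load_default_config() -> ModelConfig:
    """The shipped default model (nine states, three arms, five policies)."""
    ref = resources.files("cadcea.data").joinpath("default_model.yaml")
    with ref.open() as fh:
        return ModelConfig.from_dict(yaml.safe_load(fh))
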