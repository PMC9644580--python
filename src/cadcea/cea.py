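"""Strategy comparison: PSA, incremental statistics, NMB, CEAC, scaling.

Strategies are mixes of starting arms (e.g. current practice = 81.9% OMT,
13.5% PCI, 4.6% CABG).  Probabilistic sensitivity analysis samples every
cost and utility distribution once per draw and evaluates all strategies
under the same draw (common random numbers), so between-strategy contrasts
reflect parameter uncertainty, not sampling noise.  Net monetary benefit
at willingness-to-pay lambda is NMB = lambda * dQALY - dCost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ModelConfig
from .engine import EngineConfig, evaluate_model

__all__ = [
    "StrategyMix",
    "PSAResult",
    "CEResult",
    "evaluate_mix",
    "evaluate_strategies",
    "run_psa",
    "incremental_summary",
    "ceac",
    "ce_plane",
    "population_scale",
]

_W_TOL = 1e-12


@dataclass(frozen=True)
class StrategyMix:
    """A policy: nonnegative starting-arm weights summing to 1."""

    name: str
    weights: dict[str, float]

    def __post_init__(self) -> None:
        w = np.array(list(self.weights.values()), dtype=float)
        if (w < 0).any():
            raise ValueError(f"strategy {self.name!r}: weights must be >= 0")
        if abs(w.sum() - 1.0) > _W_TOL:
            raise ValueError(
                f"strategy {self.name!r}: weights sum to {w.sum()}, not 1"
            )


def evaluate_mix(
    mix: StrategyMix, arm_results: dict[str, tuple[float, float]]
) -> tuple[float, float]:
    """Weighted average of per-arm (cost, QALY) results under one draw."""
    missing = set(mix.weights) - set(arm_results)
    if missing:
        raise ValueError(f"strategy {mix.name!r}: no results for arms {sorted(missing)}")
    cost = sum(w * arm_results[a][0] for a, w in mix.weights.items())
    qaly = sum(w * arm_results[a][1] for a, w in mix.weights.items())
    return float(cost), float(qaly)


def _strategy_mixes(config: ModelConfig) -> list[StrategyMix]:
    return [StrategyMix(name, dict(w)) for name, w in config.strategies.items()]


def evaluate_strategies(
    config: ModelConfig, engine: EngineConfig | None = None
) -> pd.DataFrame:
    """Deterministic (parameter-mean) cost and QALYs per strategy."""
    engine = engine or config.engine
    models = config.build_models()
    arm_results = {
        arm: evaluate_model(model, engine)[:2] for arm, model in models.items()
    }
    rows = []
    for mix in _strategy_mixes(config):
        cost, qaly = evaluate_mix(mix, arm_results)
        rows.append({"strategy": mix.name, "cost": cost, "qaly": qaly})
    return pd.DataFrame(rows)


@dataclass
class PSAResult:
    """Per-draw, per-strategy totals from probabilistic sensitivity analysis."""

    draws: pd.DataFrame  # columns: draw, strategy, cost, qaly
    n_draws: int
    seed: int

    def totals(self, strategy: str) -> pd.DataFrame:
        sub = self.draws[self.draws["strategy"] == strategy]
        if len(sub) == 0:
            raise ValueError(f"strategy {strategy!r} not in PSA result")
        return sub.sort_values("draw").reset_index(drop=True)


def run_psa(
    config: ModelConfig,
    engine: EngineConfig | None = None,
    n_draws: int = 1000,
    seed: int = 0,
    sample_transitions: bool = False,
) -> PSAResult:
    """Sample parameters ``n_draws`` times and evaluate every strategy.

    Each draw samples all cost and utility distributions once; transition
    rows are additionally drawn from their Dirichlet count evidence when
    ``sample_transitions`` is set and counts are available (the default
    varies costs and utilities only).  All strategies share the draw.
    """
    engine = engine or config.engine
    rng = np.random.default_rng(seed)
    mixes = _strategy_mixes(config)
    sampled_names = [
        n for n, s in config.parameters.items() if s.kind in ("gamma", "beta", "fixed")
    ]
    records = []
    for d in range(n_draws):
        draw_values = {n: config.parameters[n].sample(rng) for n in sampled_names}
        rows = None
        if sample_transitions and config.dirichlet_counts:
            rows = {}
            for frm, cnts in config.dirichlet_counts.items():
                tos = list(cnts)
                alpha = np.array([cnts[t] for t in tos], dtype=float)
                p = rng.dirichlet(alpha)
                rows[frm] = dict(zip(tos, p))
            # rows without count evidence keep their point estimates
            for frm, row in config.probabilities.items():
                rows.setdefault(frm, dict(row))
        models = config.build_models(draws=draw_values, transition_rows=rows)
        arm_results = {
            arm: evaluate_model(model, engine)[:2] for arm, model in models.items()
        }
        for mix in mixes:
            cost, qaly = evaluate_mix(mix, arm_results)
            records.append(
                {"draw": d, "strategy": mix.name, "cost": cost, "qaly": qaly}
            )
    return PSAResult(draws=pd.DataFrame(records), n_draws=n_draws, seed=seed)


@dataclass
class CEResult:
    """Incremental comparison of one strategy against a base policy."""

    strategy: str
    base: str
    wtp: float
    delta_cost: float
    delta_qaly: float
    nmb: float
    delta_cost_ui: tuple[float, float]
    delta_qaly_ui: tuple[float, float]
    nmb_ui: tuple[float, float]
    p_cost_saving: float
    p_qaly_gain: float
    p_cost_effective: float


def _deltas(psa: PSAResult, strategy: str, base: str) -> tuple[np.ndarray, np.ndarray]:
    s = psa.totals(strategy)
    b = psa.totals(base)
    return (
        s["cost"].to_numpy() - b["cost"].to_numpy(),
        s["qaly"].to_numpy() - b["qaly"].to_numpy(),
    )


def incremental_summary(
    psa: PSAResult, strategy: str, base: str, wtp: float
) -> CEResult:
    """Per-draw deltas vs the base policy with 95% percentile intervals.

    Probabilities use strict inequalities: a tie (delta exactly 0, as in a
    self-comparison) counts as neither cost-saving nor effective.
    """
    dc, dq = _deltas(psa, strategy, base)
    nmb = wtp * dq - dc
    lo, hi = 2.5, 97.5

    def ui(x: np.ndarray) -> tuple[float, float]:
        return float(np.percentile(x, lo)), float(np.percentile(x, hi))

    return CEResult(
        strategy=strategy,
        base=base,
        wtp=wtp,
        delta_cost=float(dc.mean()),
        delta_qaly=float(dq.mean()),
        nmb=float(nmb.mean()),
        delta_cost_ui=ui(dc),
        delta_qaly_ui=ui(dq),
        nmb_ui=ui(nmb),
        p_cost_saving=float((dc < 0).mean()),
        p_qaly_gain=float((dq > 0).mean()),
        p_cost_effective=float((nmb > 0).mean()),
    )


def ceac(
    psa: PSAResult, strategy: str, base: str, wtp_grid
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve: P(NMB > 0) per threshold."""
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("wtp_grid must be non-empty")
    if (grid < 0).any() or (np.diff(grid) < 0).any():
        raise ValueError("wtp_grid must be nonnegative and increasing")
    dc, dq = _deltas(psa, strategy, base)
    prob = [(lam * dq - dc > 0).mean() for lam in grid]
    return pd.DataFrame({"wtp": grid, "p_cost_effective": prob})


def ce_plane(psa: PSAResult, strategy: str, base: str) -> pd.DataFrame:
    """Per-draw (delta QALY, delta cost) pairs for plotting."""
    dc, dq = _deltas(psa, strategy, base)
    return pd.DataFrame(
        {"draw": np.arange(dc.size), "delta_qaly": dq, "delta_cost": dc}
    )


def population_scale(
    ce: CEResult, patients_per_year: float, wtp: float | None = None
) -> tuple[float, float, float]:
    """Scale per-patient increments to an annual treated population.

    Returns (annual cost change, annual QALY change, annual monetary value
    of the QALY change at the willingness-to-pay threshold).
    """
    if patients_per_year < 0:
        raise ValueError("patients_per_year must be >= 0")
    wtp = ce.wtp if wtp is None else wtp
    annual_cost = ce.delta_cost * patients_per_year
    annual_qaly = ce.delta_qaly * patients_per_year
    return annual_cost, annual_qaly, annual_qaly * wtp
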