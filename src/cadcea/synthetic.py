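"""Synthetic patient records with known ground truth.

Generates line-level state histories (patient_id, cycle, state) by
simulating a Markov chain under a known row-stochastic transition matrix,
plus per-period billing records with Gamma-distributed medication costs
for the three medical-therapy cost groups (never intervened, after a
stent, after a bypass).  Every downstream stage — transition estimation,
cost summarisation, the cohort engine — is testable against this truth
without access to any clinical repository.

Records end at absorption: the death observation is emitted once, at the
cycle the patient enters it, and nothing afterwards, mirroring a billing
system that stops at death.  An optional administrative censoring time
(uniform over the observation window) produces unequal follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GroundTruth",
    "generate_histories",
    "generate_billing",
    "generate_baseline",
    "MEDICATION_GROUPS",
    "PROCEDURE_GROUP",
]

#: the three OMT medication cost groups
MEDICATION_GROUPS = ("no-intervention", "post-stent", "post-bypass")
#: billing category for one-time procedure costs
PROCEDURE_GROUP = "procedure"

_TOL = 1e-12


@dataclass(frozen=True)
class GroundTruth:
    """The data-generating process for a synthetic cohort.

    ``transition_matrix`` is per 6-month cycle over ``states``; exactly one
    state must be absorbing (its row a unit vector on itself) and is taken
    as death.  ``cost_params`` maps each medication group to a
    (mean, sd) pair of the 6-month cost; ``procedure_costs`` optionally
    maps procedure states to (mean, sd) of their one-time cost.
    """

    states: tuple[str, ...]
    transition_matrix: np.ndarray
    start_distribution: np.ndarray
    cost_params: dict = field(default_factory=dict)
    procedure_costs: dict = field(default_factory=dict)
    procedure_states: tuple[str, ...] = ()
    bypass_states: tuple[str, ...] = ()
    stent_states: tuple[str, ...] = ()
    n_patients: int = 10_000
    n_cycles: int = 20
    administrative_censoring: bool = False
    seed: int = 0
    death_state: str | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.transition_matrix, dtype=float)
        start = np.asarray(self.start_distribution, dtype=float)
        object.__setattr__(self, "transition_matrix", m)
        object.__setattr__(self, "start_distribution", start)
        k = len(self.states)
        if m.shape != (k, k):
            raise ValueError("transition_matrix shape must match states")
        if (m < 0).any() or (m > 1).any():
            raise ValueError("probabilities must lie in [0, 1]")
        bad = np.abs(m.sum(axis=1) - 1.0) > _TOL
        if bad.any():
            names = [self.states[i] for i in np.flatnonzero(bad)]
            raise ValueError(f"non-stochastic transition rows: {names}")
        if start.shape != (k,) or (start < 0).any() or abs(start.sum() - 1) > _TOL:
            raise ValueError("start_distribution must be a probability vector")
        absorbing = [
            i
            for i in range(k)
            if m[i, i] == 1.0 and np.all(np.delete(m[i], i) == 0.0)
        ]
        if self.death_state is not None:
            # explicit designation, for chains with other self-loop rows
            # (e.g. the identity chain used as a degenerate test case)
            di = self.states.index(self.death_state)
            if di not in absorbing:
                raise ValueError(
                    f"death state {self.death_state!r} is not absorbing"
                )
        elif len(absorbing) == 1:
            di = absorbing[0]
        else:
            raise ValueError(
                "exactly one state must be absorbing (death); name death_state "
                "explicitly when other rows are unit self-loops"
            )
        object.__setattr__(self, "_death_index", di)
        object.__setattr__(self, "death_state", self.states[di])
        for grp in self.cost_params:
            mean, sd = self.cost_params[grp]
            if mean <= 0 or sd <= 0:
                raise ValueError(f"cost group {grp!r} requires mean > 0 and SD > 0")
        if self.n_patients < 0 or self.n_cycles < 1:
            raise ValueError("need n_patients >= 0 and n_cycles >= 1")


def _simulate_states(truth: GroundTruth, rng: np.random.Generator) -> np.ndarray:
    """(n_patients, n_cycles+1) int state-index paths of the Markov chain."""
    n, c = truth.n_patients, truth.n_cycles
    k = len(truth.states)
    cum = np.cumsum(truth.transition_matrix, axis=1)
    cum[:, -1] = 1.0  # guard against round-off
    paths = np.empty((n, c + 1), dtype=np.int64)
    start_cum = np.cumsum(truth.start_distribution)
    start_cum[-1] = 1.0
    paths[:, 0] = np.searchsorted(start_cum, rng.random(n), side="right")
    for t in range(1, c + 1):
        u = rng.random(n)
        cur = paths[:, t - 1]
        # row-wise inverse-CDF draw: compare u against each state's cum row
        nxt = (u[:, None] > cum[cur]).sum(axis=1)
        paths[:, t] = nxt
    return paths


def generate_histories(truth: GroundTruth) -> pd.DataFrame:
    """Line-level state histories drawn from the ground-truth chain.

    Returns a tidy frame with columns ``patient_id, cycle, state``, one row
    per observed patient-cycle.  Observations stop at (and include) entry
    into the absorbing state; with ``administrative_censoring`` each
    patient is additionally truncated at a uniform random cycle in
    [1, n_cycles].  The same seed always yields the same frame.
    """
    rng = np.random.default_rng(truth.seed)
    n, c = truth.n_patients, truth.n_cycles
    if n == 0:
        return pd.DataFrame(columns=["patient_id", "cycle", "state"])
    paths = _simulate_states(truth, rng)
    di = truth._death_index

    dead = paths == di
    # first cycle at which the patient is dead (n_cycles+1 if never)
    first_dead = np.where(dead.any(axis=1), dead.argmax(axis=1), c + 1)
    last_obs = np.minimum(first_dead, c)
    if truth.administrative_censoring:
        censor = rng.integers(1, c + 1, size=n)
        last_obs = np.minimum(last_obs, censor)

    lengths = last_obs + 1
    pid = np.repeat(np.arange(n), lengths)
    cycle = np.concatenate([np.arange(L) for L in lengths])
    state_idx = paths[pid, cycle]
    return pd.DataFrame(
        {
            "patient_id": np.char.add("P", np.char.zfill(pid.astype(str), 6)),
            "cycle": cycle,
            "state": np.asarray(truth.states, dtype=object)[state_idx],
        }
    )


def generate_billing(
    histories: pd.DataFrame, truth: GroundTruth, seed: int | None = None
) -> pd.DataFrame:
    """Per-period billing records for the generated histories.

    Each patient-period in a non-absorbing, non-procedure state yields one
    medication record whose amount is Gamma-distributed with the group's
    mean/SD; the group follows the patient's procedure history (bypass
    overrides stent).  Each entry into a procedure state yields one record
    of the distinct ``procedure`` category, so billing-derived and
    config-derived costing can be cross-checked.
    """
    for grp, (mean, sd) in truth.cost_params.items():
        if sd <= 0:
            raise ValueError(f"cost group {grp!r} requires SD > 0")
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    if len(histories) == 0:
        return pd.DataFrame(columns=["patient_id", "period", "group", "amount"])

    df = histories.sort_values(["patient_id", "cycle"], kind="stable").copy()
    is_stent = df["state"].isin(truth.stent_states)
    is_bypass = df["state"].isin(truth.bypass_states)
    # cumulative procedure exposure per patient up to and including this row
    df["_stent"] = is_stent.groupby(df["patient_id"], observed=True).cummax()
    df["_bypass"] = is_bypass.groupby(df["patient_id"], observed=True).cummax()

    records = []
    med_mask = (
        ~df["state"].isin(truth.procedure_states)
        & (df["state"] != truth.death_state)
    )
    med = df[med_mask]
    group = np.where(
        med["_bypass"], "post-bypass", np.where(med["_stent"], "post-stent", "no-intervention")
    )
    for g in MEDICATION_GROUPS:
        sel = group == g
        if not sel.any():
            continue
        mean, sd = truth.cost_params[g]
        shape, scale = (mean / sd) ** 2, sd**2 / mean
        amounts = rng.gamma(shape, scale, size=int(sel.sum()))
        records.append(
            pd.DataFrame(
                {
                    "patient_id": med.loc[sel, "patient_id"].to_numpy(),
                    "period": med.loc[sel, "cycle"].to_numpy(),
                    "group": g,
                    "amount": amounts,
                }
            )
        )

    proc = df[df["state"].isin(truth.procedure_states)]
    if len(proc) > 0 and truth.procedure_costs:
        for state, (mean, sd) in truth.procedure_costs.items():
            sel = proc["state"] == state
            if not sel.any():
                continue
            shape, scale = (mean / sd) ** 2, sd**2 / mean
            amounts = rng.gamma(shape, scale, size=int(sel.sum()))
            records.append(
                pd.DataFrame(
                    {
                        "patient_id": proc.loc[sel, "patient_id"].to_numpy(),
                        "period": proc.loc[sel, "cycle"].to_numpy(),
                        "group": PROCEDURE_GROUP,
                        "amount": amounts,
                    }
                )
            )

    if not records:
        return pd.DataFrame(columns=["patient_id", "period", "group", "amount"])
    out = pd.concat(records, ignore_index=True)
    return out.sort_values(["patient_id", "period", "group"], kind="stable").reset_index(
        drop=True
    )


# Table-2-style marginals: per-arm mean age (SD ~11y) and male fraction.
_BASELINE_DEFAULTS = {
    "OMT": {"age_mean": 62.96, "age_sd": 11.0, "male_frac": 0.69},
    "PCI": {"age_mean": 58.85, "age_sd": 11.0, "male_frac": 0.83},
    "CABG": {"age_mean": 60.84, "age_sd": 11.0, "male_frac": 0.83},
}


def generate_baseline(
    arm_sizes: dict[str, int], seed: int = 0, params: dict | None = None
) -> pd.DataFrame:
    """Simple baseline-characteristics table (age, sex) per starting arm.

    Ages are normal per arm and sex is Bernoulli; this emulates only the
    marginal structure of a baseline table, not any covariate joint
    distribution.
    """
    params = params or _BASELINE_DEFAULTS
    rng = np.random.default_rng(seed)
    frames = []
    for arm, n in arm_sizes.items():
        p = params[arm]
        frames.append(
            pd.DataFrame(
                {
                    "arm": arm,
                    "age": rng.normal(p["age_mean"], p["age_sd"], size=n),
                    "sex": np.where(rng.random(n) < p["male_frac"], "male", "female"),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
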