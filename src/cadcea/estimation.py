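"""Parameter estimation for the decision model.

Turns line-level patient state histories and billing records into the
quantities the Markov engine consumes: per-row transition probabilities
with Dirichlet count evidence, probabilities rescaled between horizons
under a constant-hazard assumption, and mean/SD-parameterised gamma and
beta sampling distributions for costs and health utilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DistributionSpec",
    "TransitionEstimate",
    "gamma_from_mean_sd",
    "beta_from_mean_sd",
    "beta_moments_from_shapes",
    "rescale_probability",
    "transition_pairs",
    "estimate_transition_row",
    "estimate_transition_matrix",
    "summarize_costs",
]

_KINDS = ("gamma", "beta", "dirichlet", "fixed")


@dataclass(frozen=True)
class DistributionSpec:
    """A sampling distribution in mean/SD (or count) parameterisation.

    Gamma and beta laws are stored by their first two moments; the shape
    parameters are derived by the method of moments and never stored as
    primary data.  ``dirichlet`` rows are stored as nonnegative counts;
    ``fixed`` is a point mass at ``mean``.
    """

    kind: str
    mean: float | None = None
    sd: float | None = None
    counts: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "gamma":
            if self.mean is None or self.sd is None or self.mean <= 0 or self.sd <= 0:
                raise ValueError("gamma requires mean > 0 and sd > 0")
        elif self.kind == "beta":
            if self.mean is None or self.sd is None:
                raise ValueError("beta requires mean and sd")
            if not 0.0 < self.mean < 1.0:
                raise ValueError(f"beta mean must lie in (0, 1), got {self.mean}")
            if self.sd <= 0 or self.sd**2 >= self.mean * (1.0 - self.mean):
                raise ValueError(
                    "no beta law exists: need 0 < sd^2 < mean*(1-mean), "
                    f"got mean={self.mean}, sd={self.sd}"
                )
        elif self.kind == "dirichlet":
            if self.counts is None or len(self.counts) < 2:
                raise ValueError("dirichlet requires at least 2 counts")
            arr = np.asarray(self.counts, dtype=float)
            if (arr < 0).any() or arr.sum() <= 0:
                raise ValueError("dirichlet counts must be >= 0 with positive sum")
        elif self.kind == "fixed":
            if self.mean is None:
                raise ValueError("fixed requires a mean (the point value)")

    # -- derived shape parameters (method of moments) --------------------

    @property
    def gamma_shape(self) -> float:
        if self.kind != "gamma":
            raise AttributeError("gamma_shape defined for gamma specs only")
        return (self.mean / self.sd) ** 2

    @property
    def gamma_scale(self) -> float:
        if self.kind != "gamma":
            raise AttributeError("gamma_scale defined for gamma specs only")
        return self.sd**2 / self.mean

    @property
    def beta_a(self) -> float:
        a, _ = self._beta_shapes()
        return a

    @property
    def beta_b(self) -> float:
        _, b = self._beta_shapes()
        return b

    def _beta_shapes(self) -> tuple[float, float]:
        if self.kind != "beta":
            raise AttributeError("beta shapes defined for beta specs only")
        m, v = self.mean, self.sd**2
        k = m * (1.0 - m) / v - 1.0
        return m * k, (1.0 - m) * k

    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Draw from the law; support is respected by construction."""
        if self.kind == "gamma":
            return rng.gamma(self.gamma_shape, self.gamma_scale, size=size)
        if self.kind == "beta":
            a, b = self._beta_shapes()
            return rng.beta(a, b, size=size)
        if self.kind == "dirichlet":
            alpha = np.asarray(self.counts, dtype=float)
            # zero cells are structural: keep them exactly zero in every draw
            pos = alpha > 0
            out_shape = (size or 1, alpha.size)
            out = np.zeros(out_shape)
            out[:, pos] = rng.dirichlet(alpha[pos], size=size or 1)
            return out if size is not None else out[0]
        # fixed
        if size is None:
            return self.mean
        return np.full(size, self.mean, dtype=float)


def gamma_from_mean_sd(mean: float, sd: float) -> DistributionSpec:
    """Gamma law with exactly the given mean and SD.

    Method of moments: shape = (mean/sd)^2, scale = sd^2/mean.
    """
    if mean <= 0 or sd <= 0:
        raise ValueError(f"gamma requires mean > 0 and sd > 0, got {mean}, {sd}")
    return DistributionSpec(kind="gamma", mean=float(mean), sd=float(sd))


def beta_from_mean_sd(mean: float, sd: float) -> DistributionSpec:
    """Beta law with the given mean and SD (a = m*k, b = (1-m)*k, k = m(1-m)/sd^2 - 1)."""
    return DistributionSpec(kind="beta", mean=float(mean), sd=float(sd))


def beta_moments_from_shapes(a: float, b: float) -> tuple[float, float]:
    """Invert (a, b) shape parameters to (mean, sd)."""
    if a <= 0 or b <= 0:
        raise ValueError("beta shapes must be positive")
    mean = a / (a + b)
    var = a * b / ((a + b) ** 2 * (a + b + 1.0))
    return mean, float(np.sqrt(var))


def rescale_probability(
    p_source: float, horizon_source: float, horizon_target: float
) -> float:
    """Convert a probability between time horizons via cumulative incidence.

    Under a constant hazard, an event probability ``p`` over horizon ``T``
    becomes ``1 - (1 - p)**(t/T)`` over horizon ``t``.  ``p = 1`` maps to 1
    for any positive target horizon (limiting behaviour, not an error).
    """
    if not 0.0 <= p_source <= 1.0:
        raise ValueError(f"p_source must lie in [0, 1], got {p_source}")
    if horizon_source <= 0 or horizon_target <= 0:
        raise ValueError("horizons must be positive and in the same time unit")
    if p_source == 1.0:
        return 1.0
    return 1.0 - (1.0 - p_source) ** (horizon_target / horizon_source)


@dataclass(frozen=True)
class TransitionEstimate:
    """Maximum-likelihood transition row with Dirichlet count evidence."""

    from_state: str
    to_states: tuple[str, ...]
    counts: tuple[float, ...]
    probabilities: tuple[float, ...] = field(init=False)
    pseudo_count: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=float) + self.pseudo_count
        total = arr.sum()
        if total <= 0:
            raise ValueError(
                f"state {self.from_state!r} has no observed successor pairs"
            )
        object.__setattr__(self, "probabilities", tuple(arr / total))

    @property
    def dirichlet(self) -> DistributionSpec:
        arr = tuple(c + self.pseudo_count for c in self.counts)
        return DistributionSpec(kind="dirichlet", counts=arr)


def transition_pairs(histories: pd.DataFrame) -> pd.DataFrame:
    """Consecutive (state, next_state) observation pairs, pooled over patients.

    Pairs are formed only where cycle ``c+1`` immediately follows cycle ``c``
    for the same patient, so censored follow-up contributes no spurious pairs.
    """
    df = histories.sort_values(["patient_id", "cycle"], kind="stable")
    nxt_state = df["state"].shift(-1)
    nxt_cycle = df["cycle"].shift(-1)
    nxt_pid = df["patient_id"].shift(-1)
    ok = (nxt_pid == df["patient_id"]) & (nxt_cycle == df["cycle"] + 1)
    out = pd.DataFrame(
        {
            "cycle": df.loc[ok, "cycle"].to_numpy(),
            "state": df.loc[ok, "state"].to_numpy(),
            "next_state": nxt_state[ok].to_numpy(),
        }
    )
    return out


def estimate_transition_row(
    histories: pd.DataFrame,
    from_state: str,
    state_list: list[str] | tuple[str, ...],
    pseudo_count: float = 0.0,
) -> TransitionEstimate:
    """Estimate one transition row as observed proportions.

    Counts tally, over all patients and cycles, the pairs (cycle ``c`` in
    ``from_state``, cycle ``c+1`` in each successor); probabilities are the
    maximum-likelihood proportions counts / total.
    """
    observed = set(histories["state"].unique())
    pairs = transition_pairs(histories)
    rows = pairs[pairs["state"] == from_state]
    if len(rows) == 0:
        if from_state not in observed:
            raise ValueError(f"state {from_state!r} absent from the histories")
        raise ValueError(
            f"state {from_state!r} observed only at final cycles: "
            "no successor pairs to tally"
        )
    tally = rows["next_state"].value_counts()
    unknown = set(tally.index) - set(state_list)
    if unknown:
        raise ValueError(f"successor states {sorted(unknown)} not in state list")
    counts = tuple(float(tally.get(s, 0)) for s in state_list)
    return TransitionEstimate(
        from_state=from_state,
        to_states=tuple(state_list),
        counts=counts,
        pseudo_count=pseudo_count,
    )


def estimate_transition_matrix(
    histories: pd.DataFrame,
    state_list: list[str] | tuple[str, ...],
    absorbing: str | None = None,
    pseudo_count: float = 0.0,
    by_cycle: bool = False,
):
    """Estimate all transition rows, pooled over cycles (time-homogeneous).

    The absorbing state, if named, gets a unit row on itself.  With
    ``by_cycle=True`` a dict cycle -> row-estimate-dict is returned instead
    (stratified estimator; off by default to match the pooled design).
    """
    if by_cycle:
        pairs = transition_pairs(histories)
        out: dict[int, dict[str, TransitionEstimate]] = {}
        for cyc, grp in pairs.groupby("cycle"):
            rows = {}
            for s in state_list:
                if s == absorbing:
                    continue
                sub = grp[grp["state"] == s]
                if len(sub) == 0:
                    continue
                tally = sub["next_state"].value_counts()
                rows[s] = TransitionEstimate(
                    from_state=s,
                    to_states=tuple(state_list),
                    counts=tuple(float(tally.get(t, 0)) for t in state_list),
                    pseudo_count=pseudo_count,
                )
            out[int(cyc)] = rows
        return out

    estimates: dict[str, TransitionEstimate] = {}
    for s in state_list:
        if s == absorbing:
            continue
        estimates[s] = estimate_transition_row(
            histories, s, state_list, pseudo_count=pseudo_count
        )
    return estimates


def summarize_costs(billing: pd.DataFrame, group: str) -> tuple[float, float]:
    """Sample mean and SD of per-patient-period amounts in one cost group.

    SD uses the n-1 denominator; a single record yields SD 0 by convention.
    An empty group is an error, never a NaN.
    """
    amounts = billing.loc[billing["group"] == group, "amount"].to_numpy(dtype=float)
    if amounts.size == 0:
        raise ValueError(f"no billing records for group {group!r}")
    mean = float(amounts.mean())
    sd = 0.0 if amounts.size == 1 else float(amounts.std(ddof=1))
    return mean, sd
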