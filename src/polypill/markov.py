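"""Discrete-time Markov cohort engine.

Provides state-space and model containers, cohort-trace propagation, and
discounted accumulation of per-state and per-transition rewards. Transition
matrices may be constant or cycle-indexed (one matrix per cycle) to support
age-dependent hazards over long horizons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "StateSpace",
    "MarkovModel",
    "CohortTrace",
    "ModelValidationError",
    "run_trace",
    "discounted_totals",
]

#: absolute tolerance for row-stochasticity checks
ROW_SUM_TOL = 1e-9
#: deviations below this are treated as floating-point dust and renormalized
ROW_SUM_RENORM = 1e-12


class ModelValidationError(ValueError):
    """Raised when a model or trace violates a structural invariant."""


@dataclass(frozen=True)
class StateSpace:
    """Ordered health-state labels with a designated absorbing subset."""

    names: tuple[str, ...]
    absorbing: frozenset[str] = frozenset()

    def __init__(self, names: Sequence[str], absorbing: Sequence[str] = ()):
        object.__setattr__(self, "names", tuple(names))
        object.__setattr__(self, "absorbing", frozenset(absorbing))
        if len(set(self.names)) != len(self.names):
            raise ModelValidationError("state names must be unique")
        unknown = self.absorbing - set(self.names)
        if unknown:
            raise ModelValidationError(f"absorbing states not in state list: {sorted(unknown)}")
        if not self.absorbing:
            raise ModelValidationError("at least one absorbing state is required")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    @property
    def absorbing_indices(self) -> tuple[int, ...]:
        return tuple(i for i, n in enumerate(self.names) if n in self.absorbing)


def _as_matrix_sequence(transition: np.ndarray, n_cycles: int) -> np.ndarray:
    """Broadcast a constant matrix to shape (n_cycles, S, S); pass 3-D through."""
    t = np.asarray(transition, dtype=float)
    if t.ndim == 2:
        return np.broadcast_to(t, (n_cycles, *t.shape))
    if t.ndim == 3:
        if t.shape[0] < n_cycles:
            raise ModelValidationError(
                f"transition sequence has {t.shape[0]} matrices but the model runs "
                f"{n_cycles} cycles"
            )
        return t[:n_cycles]
    raise ModelValidationError("transition must be a 2-D matrix or a 3-D sequence of matrices")


@dataclass
class MarkovModel:
    """A cohort model: states, transitions, rewards, discounting and horizon.

    Parameters
    ----------
    states : StateSpace
    transition : array
        Either a single row-stochastic ``(S, S)`` matrix or a cycle-indexed
        ``(T, S, S)`` stack (row ``t`` applies to the step from cycle ``t`` to
        ``t + 1``).
    initial_distribution : array
        Probability vector over states at cycle 0.
    n_cycles : int
        Number of annual cycles to run.
    costs, utilities : array
        Per-state annual rewards (USD/year and QALY-weight respectively).
    discount_rate : float
        Annual discount fraction applied to both reward streams by default.
    transition_costs : mapping, optional
        One-time costs keyed by ``(from_state, to_state)`` label pairs,
        credited whenever the corresponding transition occurs.
    cycle_length : float
        Cycle duration in years (fixed at 1 in all shipped analyses).
    """

    states: StateSpace
    transition: np.ndarray
    initial_distribution: np.ndarray
    n_cycles: int
    costs: np.ndarray
    utilities: np.ndarray
    discount_rate: float = 0.0
    transition_costs: Mapping[tuple[str, str], float] | None = None
    cycle_length: float = 1.0
    utility_discount_rate: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ModelValidationError("n_cycles must be >= 1")
        self.initial_distribution = np.asarray(self.initial_distribution, dtype=float)
        self.costs = np.asarray(self.costs, dtype=float)
        self.utilities = np.asarray(self.utilities, dtype=float)
        s = len(self.states)
        for name, arr in (
            ("initial_distribution", self.initial_distribution),
            ("costs", self.costs),
            ("utilities", self.utilities),
        ):
            if arr.shape != (s,):
                raise ModelValidationError(f"{name} must have one entry per state ({s})")
        if abs(self.initial_distribution.sum() - 1.0) > ROW_SUM_TOL:
            raise ModelValidationError("initial_distribution must sum to 1")
        if np.any(self.initial_distribution < 0):
            raise ModelValidationError("initial_distribution entries must be >= 0")
        if np.any(self.costs < 0):
            raise ModelValidationError("per-state costs must be >= 0")
        if np.any((self.utilities < 0) | (self.utilities > 1)):
            raise ModelValidationError("utilities must lie in [0, 1]")
        if self.discount_rate < 0:
            raise ModelValidationError("discount_rate must be >= 0")
        self.transition = self._validate_transition(self.transition)

    def _validate_transition(self, transition: np.ndarray) -> np.ndarray:
        mats = np.array(_as_matrix_sequence(transition, self.n_cycles), dtype=float)
        if np.any((mats < 0) | (mats > 1)):
            raise ModelValidationError("transition probabilities must lie in [0, 1]")
        row_sums = mats.sum(axis=2)
        dev = np.abs(row_sums - 1.0)
        bad = np.argwhere(dev > ROW_SUM_TOL)
        if bad.size:
            t, i = bad[0]
            raise ModelValidationError(
                f"transition row for state '{self.states.names[i]}' at cycle {t} "
                f"sums to {row_sums[t, i]!r}, not 1"
            )
        # renormalize floating-point dust only
        dusty = (dev > 0) & (dev <= ROW_SUM_RENORM)
        if np.any(dusty):
            mats = mats / row_sums[:, :, None]
        for i in self.states.absorbing_indices:
            expected = np.zeros(len(self.states))
            expected[i] = 1.0
            if not np.allclose(mats[:, i, :], expected, atol=ROW_SUM_TOL):
                raise ModelValidationError(
                    f"absorbing state '{self.states.names[i]}' must transition only to itself"
                )
        return mats

    def transition_at(self, cycle: int) -> np.ndarray:
        return self.transition[cycle]


@dataclass
class CohortTrace:
    """State-occupancy fractions; row ``t`` is the distribution at cycle start ``t``."""

    states: StateSpace
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if self.occupancy.ndim != 2 or self.occupancy.shape[1] != len(self.states):
            raise ModelValidationError("occupancy must be (n_cycles + 1) x n_states")
        if np.any(np.abs(self.occupancy.sum(axis=1) - 1.0) > ROW_SUM_TOL):
            raise ModelValidationError("every occupancy row must sum to 1")

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def occupancy_of(self, state: str) -> np.ndarray:
        return self.occupancy[:, self.states.index(state)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.occupancy,
            columns=list(self.states.names),
            index=pd.RangeIndex(self.occupancy.shape[0], name="cycle"),
        )


def run_trace(model: MarkovModel) -> CohortTrace:
    """Propagate the cohort distribution through every cycle.

    Returns a trace with ``n_cycles + 1`` rows; row 0 is the initial
    distribution and row ``t + 1`` equals row ``t`` times the cycle-``t``
    transition matrix.
    """
    s = len(model.states)
    occ = np.empty((model.n_cycles + 1, s))
    occ[0] = model.initial_distribution
    for t in range(model.n_cycles):
        occ[t + 1] = occ[t] @ model.transition_at(t)
    return CohortTrace(model.states, occ)


def _transition_cost_matrix(
    states: StateSpace, transition_costs: Mapping[tuple[str, str], float] | None
) -> np.ndarray | None:
    if not transition_costs:
        return None
    s = len(states)
    mat = np.zeros((s, s))
    for (src, dst), cost in transition_costs.items():
        if cost < 0:
            raise ModelValidationError("one-time transition costs must be >= 0")
        mat[states.index(src), states.index(dst)] = cost
    return mat


def discounted_totals(
    trace: CohortTrace,
    costs: np.ndarray,
    utilities: np.ndarray,
    discount_rate: float,
    *,
    one_time_costs: Mapping[tuple[str, str], float] | None = None,
    transition: np.ndarray | None = None,
    utility_discount_rate: float | None = None,
    half_cycle_correction: bool = False,
) -> tuple[float, float]:
    """Discounted (total cost, total QALY) over the trace horizon.

    Rewards for cycle ``t`` are credited to the distribution occupied at the
    start of cycle ``t`` and discounted by ``(1 + r) ** -t``; with
    ``half_cycle_correction`` the average of the cycle-start and cycle-end
    distributions is used instead. One-time transition costs require the
    ``transition`` matrix (or stack) that generated the trace.
    """
    costs = np.asarray(costs, dtype=float)
    utilities = np.asarray(utilities, dtype=float)
    if np.any(costs < 0):
        raise ModelValidationError("per-state costs must be >= 0")
    if np.any((utilities < 0) | (utilities > 1)):
        raise ModelValidationError("utilities must lie in [0, 1]")
    if discount_rate < 0:
        raise ModelValidationError("discount_rate must be >= 0")
    r_u = discount_rate if utility_discount_rate is None else utility_discount_rate

    n = trace.n_cycles
    occ = trace.occupancy
    state_weights = occ[:-1]
    if half_cycle_correction:
        state_weights = 0.5 * (occ[:-1] + occ[1:])

    t = np.arange(n)
    disc_c = (1.0 + discount_rate) ** -t
    disc_u = (1.0 + r_u) ** -t

    total_cost = float(disc_c @ (state_weights @ costs))
    total_qaly = float(disc_u @ (state_weights @ utilities))

    tc_mat = _transition_cost_matrix(trace.states, one_time_costs)
    if tc_mat is not None:
        if transition is None:
            raise ModelValidationError(
                "one_time_costs requires the transition matrix used to build the trace"
            )
        mats = _as_matrix_sequence(transition, n)
        # expected event cost in cycle t: occ[t] . (P_t * C) . 1
        event_cost = np.einsum("ti,tij,ij->t", occ[:-1], mats, tc_mat)
        total_cost += float(disc_c @ event_cost)
    return total_cost, total_qaly


def totals_for_model(model: MarkovModel, trace: CohortTrace | None = None) -> tuple[float, float]:
    """Convenience wrapper: run (or reuse) the trace and accumulate rewards."""
    if trace is None:
        trace = run_trace(model)
    return discounted_totals(
        trace,
        model.costs,
        model.utilities,
        model.discount_rate,
        one_time_costs=model.transition_costs,
        transition=model.transition,
        utility_discount_rate=model.utility_discount_rate,
    )
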