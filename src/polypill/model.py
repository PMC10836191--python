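"""Three-arm treatment model: standard care vs fixed-dose vs variable-dose polypill.

Health states: on treatment without prior side effects, on treatment having
continued after side effects, off treatment (discontinued for side effects or
non/low adherence), post-MI, and dead. Structural rules: discontinuation
happens only through side effects or non-adherence; a single off-treatment MI
probability applies regardless of why treatment stopped; post-MI patients are
fully adherent; every state is exposed to age-indexed background mortality;
MI events split into fatal and non-fatal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .cea import CeaResult, StrategyOutcome, rank_strategies
from .markov import MarkovModel, ModelValidationError, StateSpace, run_trace, totals_for_model

__all__ = [
    "ArmParameters",
    "SharedParameters",
    "STATE_NAMES",
    "STANDARD_CARE",
    "FDC",
    "VD",
    "gompertz_mortality",
    "GompertzMortality",
    "combine_competing_risks",
    "build_arm_model",
    "arm_outcome",
    "run_three_arm_base_case",
    "arm_from_dict",
    "shared_from_dict",
    "load_analysis",
    "analysis_to_dict",
    "set_parameter",
    "make_evaluator",
]

ON_TX_NO_SE = "OnTx-NoSE"
ON_TX_POST_SE = "OnTx-PostSE"
OFF_TX = "OffTx"
POST_MI = "Post-MI"
DEAD = "Dead"
STATE_NAMES = (ON_TX_NO_SE, ON_TX_POST_SE, OFF_TX, POST_MI, DEAD)

STANDARD_CARE = "standard-care"
FDC = "FDC"
VD = "VD"
ARM_NAMES = (STANDARD_CARE, FDC, VD)


def _check_prob(value: float, name: str) -> float:
    if not 0.0 <= value <= 1.0:
        raise ModelValidationError(f"{name} must lie in [0, 1], got {value}")
    return float(value)


def _check_nonneg(value: float, name: str) -> float:
    if value < 0:
        raise ModelValidationError(f"{name} must be >= 0, got {value}")
    return float(value)


@dataclass
class ArmParameters:
    """Per-arm annual probabilities and costs."""

    name: str
    p_side_effect: float
    p_discontinue_given_side_effect: float
    p_nonadherence: float
    p_mi_on_treatment_no_se: float
    p_mi_on_treatment_after_se: float
    p_mi_off_treatment: float
    monthly_drug_cost: float
    side_effect_cost: float = 0.0
    side_effect_disutility: float = 0.0

    def __post_init__(self) -> None:
        for f in (
            "p_side_effect",
            "p_discontinue_given_side_effect",
            "p_nonadherence",
            "p_mi_on_treatment_no_se",
            "p_mi_on_treatment_after_se",
            "p_mi_off_treatment",
            "side_effect_disutility",
        ):
            setattr(self, f, _check_prob(getattr(self, f), f"{self.name}.{f}"))
        for f in ("monthly_drug_cost", "side_effect_cost"):
            setattr(self, f, _check_nonneg(getattr(self, f), f"{self.name}.{f}"))


@dataclass(frozen=True)
class GompertzMortality:
    """Parametric annual mortality q(age) = min(1, a * exp(b * age))."""

    a: float = 5e-5
    b: float = 0.085

    def __call__(self, age: float) -> float:
        return min(1.0, self.a * math.exp(self.b * age))


def gompertz_mortality(a: float = 5e-5, b: float = 0.085) -> GompertzMortality:
    """Parametric stand-in for an age-indexed annual mortality table."""
    return GompertzMortality(a, b)


@dataclass
class SharedParameters:
    """Arm-independent clinical, cost and preference inputs."""

    start_age: float = 60.0
    p_mi_fatal: float = 0.0
    p_death_post_mi: float = 0.0
    background_mortality: Callable[[float], float] | Mapping[int, float] = field(
        default_factory=gompertz_mortality
    )
    mi_event_cost: float = 0.0
    post_mi_annual_cost: float = 0.0
    post_mi_treatment_cost: float = 0.0  # USD/month
    utilities: Mapping[str, float] = field(
        default_factory=lambda: {"on_treatment": 1.0, "off_treatment": 1.0, "post_mi": 1.0}
    )
    discount_rate: float = 0.03
    wtp: float = 100_000.0

    def __post_init__(self) -> None:
        _check_prob(self.p_mi_fatal, "p_mi_fatal")
        _check_prob(self.p_death_post_mi, "p_death_post_mi")
        for f in ("mi_event_cost", "post_mi_annual_cost", "post_mi_treatment_cost"):
            _check_nonneg(getattr(self, f), f)
        for key, u in self.utilities.items():
            _check_prob(u, f"utilities[{key}]")
        if self.discount_rate < 0:
            raise ModelValidationError("discount_rate must be >= 0")
        if self.wtp < 0:
            raise ModelValidationError("wtp must be >= 0")

    def mortality_at(self, age: float) -> float:
        q = self.background_mortality
        if callable(q):
            return _check_prob(q(age), f"background_mortality({age})")
        try:
            return _check_prob(q[int(round(age))], f"background_mortality[{age}]")
        except KeyError:
            raise ModelValidationError(
                f"background mortality table does not cover age {age}"
            ) from None

    def default_horizon(self, max_age: float = 100.0) -> int:
        return max(1, int(round(max_age - self.start_age)))


def combine_competing_risks(probabilities: Sequence[float]) -> tuple[float, list[float]]:
    """Compose independent annual exit probabilities into one stochastic row.

    Each probability ``p`` is converted to a constant rate ``-ln(1 - p)``;
    the probability of leaving the state within the cycle, ``1 - exp(-sum)``,
    is allocated proportionally to the rates. Returns ``(stay, exits)`` with
    ``stay + sum(exits) == 1``.
    """
    probs = [float(p) for p in probabilities]
    for p in probs:
        _check_prob(p, "competing risk probability")
    if not probs:
        return 1.0, []
    certain = [i for i, p in enumerate(probs) if p == 1.0]
    if certain:
        others = [p for i, p in enumerate(probs) if i not in certain and p > 0]
        if others or len(certain) > 1:
            warnings.warn(
                "a certain (p=1) event absorbs all exit probability; "
                "competing risks were ignored",
                stacklevel=2,
            )
        exits = [0.0] * len(probs)
        exits[certain[0]] = 1.0
        return 0.0, exits
    rates = [-math.log1p(-p) for p in probs]
    total = sum(rates)
    if total == 0.0:
        return 1.0, [0.0] * len(probs)
    p_exit = -math.expm1(-total)
    exits = [p_exit * r / total for r in rates]
    return 1.0 - p_exit, exits


def _row(
    states: StateSpace, stay: str, allocations: Mapping[str, float]
) -> np.ndarray:
    row = np.zeros(len(states))
    for dst, p in allocations.items():
        row[states.index(dst)] += p
    row[states.index(stay)] += 1.0 - row.sum()
    return row


def build_arm_model(
    arm: ArmParameters,
    shared: SharedParameters,
    n_cycles: int | None = None,
    *,
    split_off_treatment: bool = False,
    mi_tunnel: bool = False,
) -> MarkovModel:
    """Assemble one arm's cycle-indexed Markov model.

    ``split_off_treatment`` tracks side-effect discontinuers and non-adherers
    as separate states (both carry the same off-treatment MI probability);
    ``mi_tunnel`` routes non-fatal MIs through an explicit 1-year event state
    carrying the acute cost as a state reward instead of a transition reward.
    """
    if n_cycles is None:
        n_cycles = shared.default_horizon()
    if n_cycles < 1:
        raise ModelValidationError("n_cycles must be >= 1")

    names = [ON_TX_NO_SE, ON_TX_POST_SE]
    if split_off_treatment:
        names += ["OffTx-SE", "OffTx-NA"]
    else:
        names += [OFF_TX]
    if mi_tunnel:
        names += ["MI-Event"]
    names += [POST_MI, DEAD]
    states = StateSpace(names, absorbing=[DEAD])
    s = len(states)

    u_on = shared.utilities.get("on_treatment", 1.0)
    u_off = shared.utilities.get("off_treatment", u_on)
    u_post_mi = shared.utilities.get("post_mi", u_on)
    u_post_se = min(max(u_on - arm.side_effect_disutility, 0.0), 1.0)

    annual_drug = 12.0 * arm.monthly_drug_cost
    post_mi_cost = shared.post_mi_annual_cost + 12.0 * shared.post_mi_treatment_cost

    costs = np.zeros(s)
    utilities = np.zeros(s)
    for i, name in enumerate(names):
        if name == ON_TX_NO_SE:
            costs[i], utilities[i] = annual_drug, u_on
        elif name == ON_TX_POST_SE:
            costs[i], utilities[i] = annual_drug + arm.side_effect_cost, u_post_se
        elif name.startswith("OffTx"):
            costs[i], utilities[i] = 0.0, u_off
        elif name == "MI-Event":
            costs[i], utilities[i] = shared.mi_event_cost + post_mi_cost, u_post_mi
        elif name == POST_MI:
            costs[i], utilities[i] = post_mi_cost, u_post_mi
        else:  # Dead
            costs[i], utilities[i] = 0.0, 0.0

    mi_destination = "MI-Event" if mi_tunnel else POST_MI
    fatal = shared.p_mi_fatal

    def mi_split(p_mi_alloc: float) -> dict[str, float]:
        return {mi_destination: p_mi_alloc * (1.0 - fatal), DEAD: p_mi_alloc * fatal}

    mats = np.zeros((n_cycles, s, s))
    for t in range(n_cycles):
        q_bg = shared.mortality_at(shared.start_age + t)

        # on treatment, no side effects yet
        stay, (e_se, e_na, e_mi, e_d) = combine_competing_risks(
            [arm.p_side_effect, arm.p_nonadherence, arm.p_mi_on_treatment_no_se, q_bg]
        )
        off_se = "OffTx-SE" if split_off_treatment else OFF_TX
        off_na = "OffTx-NA" if split_off_treatment else OFF_TX
        alloc: dict[str, float] = {}

        def add(dst: str, p: float, alloc: dict[str, float] = alloc) -> None:
            alloc[dst] = alloc.get(dst, 0.0) + p

        add(ON_TX_POST_SE, e_se * (1.0 - arm.p_discontinue_given_side_effect))
        add(off_se, e_se * arm.p_discontinue_given_side_effect)
        add(off_na, e_na)
        add(DEAD, e_d)
        for dst, p in mi_split(e_mi).items():
            add(dst, p)
        mats[t, states.index(ON_TX_NO_SE)] = _row(states, ON_TX_NO_SE, alloc)

        # on treatment, continued after side effects: recurrent side effects can
        # still trigger discontinuation; non-discontinuing recurrences stay put
        stay, (e_se, e_na, e_mi, e_d) = combine_competing_risks(
            [arm.p_side_effect, arm.p_nonadherence, arm.p_mi_on_treatment_after_se, q_bg]
        )
        alloc = {DEAD: e_d}
        add(off_se, e_se * arm.p_discontinue_given_side_effect, alloc)
        add(off_na, e_na, alloc)
        for dst, p in mi_split(e_mi).items():
            add(dst, p, alloc)
        mats[t, states.index(ON_TX_POST_SE)] = _row(states, ON_TX_POST_SE, alloc)

        # off treatment (one MI probability regardless of discontinuation reason)
        stay, (e_mi, e_d) = combine_competing_risks([arm.p_mi_off_treatment, q_bg])
        for src in ([off_se, off_na] if split_off_treatment else [OFF_TX]):
            alloc = {DEAD: e_d}
            for dst, p in mi_split(e_mi).items():
                add(dst, p, alloc)
            mats[t, states.index(src)] = _row(states, src, alloc)

        # post-MI (fully adherent; background + excess mortality only)
        _, (e_excess, e_d) = combine_competing_risks([shared.p_death_post_mi, q_bg])
        post_mi_row = _row(states, POST_MI, {DEAD: e_excess + e_d})
        mats[t, states.index(POST_MI)] = post_mi_row
        if mi_tunnel:
            alloc = {DEAD: e_excess + e_d}
            row = np.zeros(s)
            row[states.index(DEAD)] = alloc[DEAD]
            row[states.index(POST_MI)] = 1.0 - alloc[DEAD]
            mats[t, states.index("MI-Event")] = row

        mats[t, states.index(DEAD), states.index(DEAD)] = 1.0

        row_sums = mats[t].sum(axis=1)
        bad = np.argwhere(np.abs(row_sums - 1.0) > 1e-9)
        if bad.size:
            i = int(bad[0][0])
            raise ModelValidationError(
                f"arm '{arm.name}': transitions out of state '{names[i]}' at cycle {t} "
                f"sum to {row_sums[i]}"
            )

    initial = np.zeros(s)
    initial[states.index(ON_TX_NO_SE)] = 1.0

    transition_costs = None
    if not mi_tunnel and shared.mi_event_cost > 0:
        sources = [ON_TX_NO_SE, ON_TX_POST_SE] + (
            ["OffTx-SE", "OffTx-NA"] if split_off_treatment else [OFF_TX]
        )
        transition_costs = {(src, POST_MI): shared.mi_event_cost for src in sources}

    return MarkovModel(
        states=states,
        transition=mats,
        initial_distribution=initial,
        n_cycles=n_cycles,
        costs=costs,
        utilities=utilities,
        discount_rate=shared.discount_rate,
        transition_costs=transition_costs,
    )


def arm_outcome(
    arm: ArmParameters, shared: SharedParameters, n_cycles: int | None = None
) -> StrategyOutcome:
    model = build_arm_model(arm, shared, n_cycles)
    cost, qaly = totals_for_model(model)
    return StrategyOutcome(arm.name, cost, qaly)


def run_three_arm_base_case(
    arms: Sequence[ArmParameters],
    shared: SharedParameters,
    n_cycles: int | None = None,
) -> CeaResult:
    """Build, run and rank the standard-care / FDC / VD comparison."""
    names = sorted(a.name for a in arms)
    if names != sorted(ARM_NAMES):
        raise ModelValidationError(
            f"expected exactly the arms {ARM_NAMES}, got {tuple(names)}"
        )
    outcomes = [arm_outcome(a, shared, n_cycles) for a in arms]
    return rank_strategies(outcomes)


# ---------------------------------------------------------------------------
# config schema (one document per analysis: shared block + three arm blocks)

_ARM_FIELDS = (
    "p_side_effect",
    "p_discontinue_given_side_effect",
    "p_nonadherence",
    "p_mi_on_treatment_no_se",
    "p_mi_on_treatment_after_se",
    "p_mi_off_treatment",
    "monthly_drug_cost",
    "side_effect_cost",
    "side_effect_disutility",
)


def arm_from_dict(name: str, cfg: Mapping) -> ArmParameters:
    kwargs = {f: float(cfg[f]) for f in _ARM_FIELDS if f in cfg}
    missing = [f for f in _ARM_FIELDS[:7] if f not in cfg]
    if missing:
        raise ModelValidationError(f"arm '{name}' missing fields: {missing}")
    return ArmParameters(name=name, **kwargs)


def shared_from_dict(cfg: Mapping) -> SharedParameters:
    mortality = cfg.get("background_mortality")
    if mortality is None:
        bg = gompertz_mortality()
    elif isinstance(mortality, Mapping) and "gompertz" in mortality:
        g = mortality["gompertz"]
        bg = gompertz_mortality(float(g.get("a", 5e-5)), float(g.get("b", 0.085)))
    elif isinstance(mortality, Mapping):
        bg = {int(age): float(q) for age, q in mortality.items()}
    else:
        raise ModelValidationError("background_mortality must be a table or gompertz block")
    return SharedParameters(
        start_age=float(cfg.get("start_age", 60)),
        p_mi_fatal=float(cfg.get("p_mi_fatal", 0.0)),
        p_death_post_mi=float(cfg.get("p_death_post_mi", 0.0)),
        background_mortality=bg,
        mi_event_cost=float(cfg.get("mi_event_cost", 0.0)),
        post_mi_annual_cost=float(cfg.get("post_mi_annual_cost", 0.0)),
        post_mi_treatment_cost=float(cfg.get("post_mi_treatment_cost", 0.0)),
        utilities=dict(cfg["utilities"])
        if cfg.get("utilities")
        else {"on_treatment": 1.0, "off_treatment": 1.0, "post_mi": 1.0},
        discount_rate=float(cfg.get("discount_rate", 0.03)),
        wtp=float(cfg.get("wtp", 100_000)),
    )


def load_analysis(path) -> tuple[SharedParameters, list[ArmParameters]]:
    """Read a full analysis config: shared parameters plus the three arms."""
    from .io import load_config

    cfg = load_config(path)
    shared = shared_from_dict(cfg.get("shared", {}))
    arms = [arm_from_dict(name, block) for name, block in cfg.get("arms", {}).items()]
    return shared, arms


def analysis_to_dict(shared: SharedParameters, arms: Sequence[ArmParameters]) -> dict:
    """Serialize an analysis (inverse of :func:`load_analysis`'s schema)."""
    bg = shared.background_mortality
    if isinstance(bg, GompertzMortality):
        mortality: dict = {"gompertz": {"a": bg.a, "b": bg.b}}
    elif isinstance(bg, Mapping):
        mortality = {int(age): float(q) for age, q in bg.items()}
    else:
        raise ModelValidationError(
            "only Gompertz or tabulated background mortality can be serialized"
        )
    return {
        "shared": {
            "start_age": shared.start_age,
            "p_mi_fatal": shared.p_mi_fatal,
            "p_death_post_mi": shared.p_death_post_mi,
            "background_mortality": mortality,
            "mi_event_cost": shared.mi_event_cost,
            "post_mi_annual_cost": shared.post_mi_annual_cost,
            "post_mi_treatment_cost": shared.post_mi_treatment_cost,
            "utilities": dict(shared.utilities),
            "discount_rate": shared.discount_rate,
            "wtp": shared.wtp,
        },
        "arms": {
            arm.name: {f: getattr(arm, f) for f in _ARM_FIELDS} for arm in arms
        },
    }


def set_parameter(
    shared: SharedParameters,
    arms: Sequence[ArmParameters],
    name: str,
    value: float,
) -> tuple[SharedParameters, list[ArmParameters]]:
    """Return a copy of the analysis with one named parameter replaced.

    ``name`` is ``"shared.<field>"`` for arm-independent scalars or
    ``"<arm>.<field>"`` (e.g. ``"VD.monthly_drug_cost"``) for arm fields.
    """
    import dataclasses

    scope, _, attr = name.partition(".")
    if not attr:
        raise KeyError(f"parameter '{name}' must be qualified as 'scope.field'")
    if scope == "shared":
        if not hasattr(shared, attr) or attr in ("background_mortality", "utilities"):
            raise KeyError(f"unknown or non-scalar shared parameter '{attr}'")
        return dataclasses.replace(shared, **{attr: value}), list(arms)
    new_arms = []
    hit = False
    for arm in arms:
        if arm.name == scope:
            if attr not in _ARM_FIELDS:
                raise KeyError(f"unknown arm parameter '{attr}'")
            arm = dataclasses.replace(arm, **{attr: value})
            hit = True
        new_arms.append(arm)
    if not hit:
        raise KeyError(f"no arm named '{scope}'")
    return shared, new_arms


def make_evaluator(
    shared: SharedParameters,
    arms: Sequence[ArmParameters],
    parameter: str,
    n_cycles: int | None = None,
) -> Callable[[float], list[StrategyOutcome]]:
    """Factory for one-way sweeps: value -> outcomes of every arm."""

    def evaluate(value: float) -> list[StrategyOutcome]:
        s, a = set_parameter(shared, arms, parameter, value)
        return [arm_outcome(arm, s, n_cycles) for arm in a]

    return evaluate
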