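"""Cost-effectiveness analytics: ICERs, dominance, frontier, sensitivity.

Strategies are compared on discounted (cost, effect) pairs. Strictly
dominated strategies (another strategy is at least as effective for no more
cost, strictly better on one axis) are flagged first; extended dominance then
iteratively removes frontier points whose incremental ratio exceeds that of
the next more-effective alternative, leaving a frontier with strictly
increasing costs, effects and ICERs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "StrategyOutcome",
    "CeaResult",
    "SensitivityResult",
    "EqualEffect",
    "icer",
    "rank_strategies",
    "cost_effective_choice",
    "one_way_sensitivity",
    "tornado_table",
]

ON_FRONTIER = "on-frontier"
DOMINATED = "dominated"
EXTENDED_DOMINATED = "extended-dominated"
EQUIVALENT = "equivalent"


class EqualEffect(ValueError):
    """Signalled when an ICER is requested between equally effective strategies."""


@dataclass(frozen=True)
class StrategyOutcome:
    """Discounted totals for one treatment strategy."""

    name: str
    cost: float
    effect: float

    def __post_init__(self) -> None:
        if self.cost < 0:
            raise ValueError(f"strategy '{self.name}': cost must be >= 0")
        if self.effect < 0:
            raise ValueError(f"strategy '{self.name}': effect must be >= 0")


def icer(reference: StrategyOutcome, comparator: StrategyOutcome) -> float:
    """Incremental cost-effectiveness ratio of ``reference`` vs ``comparator``.

    Positive when the reference is both more costly and more effective;
    negative ratios indicate dominance one way or the other (a cheaper,
    more effective reference yields a negative ratio and is dominant).

    Raises
    ------
    EqualEffect
        If the two strategies have exactly the same effect.
    """
    d_effect = reference.effect - comparator.effect
    if d_effect == 0.0:
        raise EqualEffect(
            f"'{reference.name}' and '{comparator.name}' have equal effect; no ICER defined"
        )
    return (reference.cost - comparator.cost) / d_effect


@dataclass
class CeaResult:
    """Ranked strategies with dominance flags and frontier ICERs.

    ``outcomes`` is sorted by increasing effect (then cost). ``status`` maps
    each strategy to on-frontier / dominated / extended-dominated (frontier
    strategies tied on both axes are flagged equivalent). ``icers`` maps each
    frontier strategy to its ICER versus the previous frontier strategy; the
    least effective frontier strategy has no comparator and maps to ``None``.
    """

    outcomes: list[StrategyOutcome]
    status: dict[str, str]
    icers: dict[str, float | None] = field(default_factory=dict)

    @property
    def frontier(self) -> list[StrategyOutcome]:
        return [o for o in self.outcomes if self.status[o.name] in (ON_FRONTIER, EQUIVALENT)]

    def to_records(self) -> list[dict]:
        return [
            {
                "strategy": o.name,
                "cost": o.cost,
                "effect": o.effect,
                "status": self.status[o.name],
                "icer": self.icers.get(o.name),
            }
            for o in self.outcomes
        ]


def rank_strategies(outcomes: Sequence[StrategyOutcome]) -> CeaResult:
    """Flag dominance and compute frontier ICERs for >= 2 strategies."""
    if len(outcomes) < 2:
        raise ValueError("need at least 2 strategies to rank")
    names = [o.name for o in outcomes]
    if len(set(names)) != len(names):
        raise ValueError("duplicate strategy names")

    ranked = sorted(outcomes, key=lambda o: (o.effect, o.cost))
    status: dict[str, str] = {}

    # strict dominance (ties on both axes are equivalent, not dominated)
    for o in ranked:
        dominated = any(
            other.cost <= o.cost
            and other.effect >= o.effect
            and (other.cost < o.cost or other.effect > o.effect)
            for other in ranked
            if other.name != o.name
        )
        status[o.name] = DOMINATED if dominated else ON_FRONTIER

    # extended dominance: drop interior points with non-increasing ICERs
    def candidates() -> list[StrategyOutcome]:
        return [o for o in ranked if status[o.name] == ON_FRONTIER]

    # collapse exact (cost, effect) ties to one representative for the sweep
    def unique_frontier(cands: list[StrategyOutcome]) -> list[StrategyOutcome]:
        seen: dict[tuple[float, float], StrategyOutcome] = {}
        for o in cands:
            seen.setdefault((o.cost, o.effect), o)
        return list(seen.values())

    changed = True
    while changed:
        changed = False
        front = unique_frontier(candidates())
        for a, b, c in zip(front, front[1:], front[2:]):
            if icer(b, a) >= icer(c, b):
                for o in candidates():
                    if (o.cost, o.effect) == (b.cost, b.effect):
                        status[o.name] = EXTENDED_DOMINATED
                changed = True
                break

    # flag equivalents and assign frontier ICERs
    front = candidates()
    groups: dict[tuple[float, float], list[StrategyOutcome]] = {}
    for o in front:
        groups.setdefault((o.cost, o.effect), []).append(o)
    for group in groups.values():
        if len(group) > 1:
            for o in group:
                status[o.name] = EQUIVALENT

    icers: dict[str, float | None] = {}
    unique = unique_frontier(front)
    prev: StrategyOutcome | None = None
    for o in unique:
        value = None if prev is None else icer(o, prev)
        for member in groups[(o.cost, o.effect)]:
            icers[member.name] = value
        prev = o
    return CeaResult(outcomes=ranked, status=status, icers=icers)


def cost_effective_choice(result: CeaResult, wtp: float) -> str:
    """Most effective frontier strategy whose frontier ICER is <= ``wtp``.

    The least effective frontier strategy always qualifies (it has no
    incremental comparator); if the frontier is somehow empty the least
    costly strategy is returned.
    """
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    best: StrategyOutcome | None = None
    for o in result.frontier:
        ratio = result.icers.get(o.name)
        if ratio is None or ratio <= wtp:
            if best is None or o.effect > best.effect:
                best = o
    if best is None:  # unreachable with a valid CeaResult; defensive fallback
        best = min(result.outcomes, key=lambda o: o.cost)
    return best.name


@dataclass
class SensitivityResult:
    """One-way sweep of a parameter with an optional cost-effectiveness flip point."""

    parameter: str
    grid: np.ndarray
    icer_curve: np.ndarray
    threshold: float | None
    target: str
    wtp: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({self.parameter: self.grid, "icer": self.icer_curve})


def _target_icer(result: CeaResult, target: str) -> float:
    if result.status.get(target) in (ON_FRONTIER, EQUIVALENT):
        value = result.icers.get(target)
        return math.nan if value is None else value
    return math.nan


def one_way_sensitivity(
    evaluate: Callable[[float], Sequence[StrategyOutcome]],
    parameter: str,
    low: float,
    high: float,
    *,
    wtp: float,
    target: str,
    n_grid: int = 41,
    tol_fraction: float = 1e-6,
) -> SensitivityResult:
    """Sweep one parameter, tracking the target strategy's frontier ICER.

    ``evaluate(value)`` must rebuild and solve every strategy with the named
    parameter set to ``value`` and all others at base case. The threshold is
    the parameter value where "``target`` is the cost-effective choice at
    ``wtp``" flips, located by bisection to ``tol_fraction`` of the range;
    absent when the predicate is constant across the grid.
    """
    if not low < high:
        raise ValueError("low must be < high")
    grid = np.linspace(low, high, n_grid)

    def predicate(value: float) -> bool:
        return cost_effective_choice(rank_strategies(evaluate(value)), wtp) == target

    icer_curve = np.empty(n_grid)
    flags = np.empty(n_grid, dtype=bool)
    for k, value in enumerate(grid):
        result = rank_strategies(evaluate(value))
        icer_curve[k] = _target_icer(result, target)
        flags[k] = cost_effective_choice(result, wtp) == target

    threshold: float | None = None
    for k in range(n_grid - 1):
        if flags[k] != flags[k + 1]:
            threshold = _bisect_flip(
                predicate, grid[k], grid[k + 1], flags[k], tol_fraction * (high - low)
            )
            break
    return SensitivityResult(parameter, grid, icer_curve, threshold, target, wtp)


def _bisect_flip(
    predicate: Callable[[float], bool], lo: float, hi: float, lo_flag: bool, tol: float
) -> float:
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if predicate(mid) == lo_flag:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def tornado_table(
    evaluate_named: Callable[[str, float], Sequence[StrategyOutcome]],
    ranges: dict[str, tuple[float, float]],
    *,
    target: str,
):
    """ICER of the target comparison at each parameter's low and high bound."""
    import pandas as pd

    rows = []
    for name, (low, high) in ranges.items():
        icer_low = _target_icer(rank_strategies(evaluate_named(name, low)), target)
        icer_high = _target_icer(rank_strategies(evaluate_named(name, high)), target)
        rows.append(
            {"parameter": name, "low": low, "high": high, "icer_low": icer_low, "icer_high": icer_high}
        )
    return pd.DataFrame(rows)
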