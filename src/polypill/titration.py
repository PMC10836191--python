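"""Dose titration: compose modular tablet units into exact per-drug doses.

Doses are handled as exact rationals (``fractions.Fraction``), never floats,
so 2.5 mg steps compose without equality traps. The per-drug solver is a
bounded change-making dynamic program minimizing the number of units, with
deterministic tie-breaks: fewer distinct strengths first, then prefer larger
strengths (multiset compared in descending order).

Capacity rules for the assembled polypill: interlocking dome/dimple units
(design 1) fit up to 5 in an AA capsule or 8 in a 000 capsule; annular disks
stacked on a dissolvable rod (design 2) fit up to 10.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ModularUnit",
    "PolypillConfig",
    "InfeasibleDoseError",
    "CapacityError",
    "CAPACITY",
    "as_dose",
    "solve_drug_dose",
    "assemble_polypill",
    "taper_schedule",
    "load_catalogue",
]

#: maximum unit counts per (design, container)
CAPACITY: dict[tuple[int, str], int] = {(1, "AA"): 5, (1, "000"): 8, (2, "rod"): 10}
#: container preference order per design (smallest first)
_CONTAINERS: dict[int, tuple[str, ...]] = {1: ("AA", "000"), 2: ("rod",)}


class InfeasibleDoseError(ValueError):
    """No exact combination of unit strengths reaches the target dose."""

    def __init__(self, target: Fraction, below: Fraction | None, above: Fraction | None):
        self.target, self.below, self.above = target, below, above
        parts = [f"target dose {float(target)} mg is not an exact combination"]
        if below is not None:
            parts.append(f"nearest achievable below: {float(below)} mg")
        if above is not None:
            parts.append(f"nearest achievable above: {float(above)} mg")
        super().__init__("; ".join(parts))


class CapacityError(ValueError):
    """Assembled unit count exceeds the design's container capacity."""

    def __init__(self, design: int, total: int, limit: int):
        self.design, self.total, self.limit = design, total, limit
        super().__init__(
            f"design {design} polypill holds at most {limit} units, needs {total}"
        )


def as_dose(value) -> Fraction:
    """Coerce a dose to an exact rational (floats go through their repr)."""
    if isinstance(value, Fraction):
        return value
    if isinstance(value, int):
        return Fraction(value)
    if isinstance(value, float):
        return Fraction(str(value))
    return Fraction(value)


@dataclass(frozen=True)
class ModularUnit:
    """One single-drug modular tablet."""

    drug: str
    strength: Fraction
    design: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "strength", as_dose(self.strength))
        if self.strength <= 0:
            raise ValueError(f"{self.drug}: strength must be > 0")
        if self.design not in (1, 2):
            raise ValueError(f"{self.drug}: design must be 1 or 2")


@dataclass
class PolypillConfig:
    """A feasible assembly: per-drug unit counts, design and container."""

    counts: dict[str, dict[Fraction, int]]
    design: int
    container: str
    total_units: int

    def dose_of(self, drug: str) -> Fraction:
        return sum(
            (s * n for s, n in self.counts.get(drug, {}).items()), start=Fraction(0)
        )

    def to_jsonable(self) -> dict:
        return {
            "design": self.design,
            "container": self.container,
            "total_units": self.total_units,
            "units": {
                drug: {str(float(s)): n for s, n in sorted(strengths.items(), reverse=True)}
                for drug, strengths in self.counts.items()
            },
        }


def _tie_break_key(counts: Mapping[Fraction, int]) -> tuple:
    """Sort key: (units, distinct strengths, descending-strength multiset preference)."""
    total = sum(counts.values())
    distinct = sum(1 for n in counts.values() if n > 0)
    multiset = []
    for s in sorted((s for s, n in counts.items() if n > 0), reverse=True):
        multiset.extend([-s] * counts[s])  # smaller key = larger strengths earlier
    return (total, distinct, tuple(multiset))


def solve_drug_dose(
    target, strengths: Sequence
) -> dict[Fraction, int]:
    """Exact minimal-unit combination of ``strengths`` summing to ``target``.

    Returns a strength -> count map (zero counts omitted); a zero target
    yields an empty map. Raises :class:`InfeasibleDoseError` with the nearest
    achievable doses below and above when no exact combination exists.
    """
    target = as_dose(target)
    if target < 0:
        raise ValueError("target dose must be >= 0")
    strengths = sorted({as_dose(s) for s in strengths}, reverse=True)
    if not strengths:
        raise ValueError("strengths must be non-empty")
    if any(s <= 0 for s in strengths):
        raise ValueError("strengths must be positive")
    if target == 0:
        return {}

    # scale everything to integers
    denom = 1
    for s in strengths + [target]:
        denom = denom * s.denominator // _gcd(denom, s.denominator)
    units = [int(s * denom) for s in strengths]
    goal = int(target * denom)
    limit = goal + max(units)

    # best[v] = optimal counts tuple reaching value v, by tie-break key
    best: list[tuple[int, ...] | None] = [None] * (limit + 1)
    best[0] = (0,) * len(units)
    for v in range(1, limit + 1):
        candidates = []
        for k, u in enumerate(units):
            if v >= u and best[v - u] is not None:
                counts = list(best[v - u])
                counts[k] += 1
                candidates.append(tuple(counts))
        if candidates:
            best[v] = min(
                candidates,
                key=lambda c: _tie_break_key({strengths[k]: c[k] for k in range(len(c))}),
            )

    if best[goal] is not None:
        return {strengths[k]: n for k, n in enumerate(best[goal]) if n > 0}

    below = next(
        (Fraction(v, denom) for v in range(goal - 1, -1, -1) if best[v] is not None), None
    )
    if below == 0:
        below = None
    above = next(
        (Fraction(v, denom) for v in range(goal + 1, limit + 1) if best[v] is not None),
        None,
    )
    raise InfeasibleDoseError(target, below, above)


def _gcd(a: int, b: int) -> int:
    while b:
        a, b = b, a % b
    return a


def check_capacity(design: int, total_units: int, container: str | None = None) -> str:
    """Smallest admissible container, or raise :class:`CapacityError`.

    With ``container`` given, that specific container's limit is enforced.
    """
    if design not in _CONTAINERS:
        raise ValueError("design must be 1 or 2")
    if container is not None:
        limit = CAPACITY[(design, container)]
        if total_units > limit:
            raise CapacityError(design, total_units, limit)
        return container
    for cont in _CONTAINERS[design]:
        if total_units <= CAPACITY[(design, cont)]:
            return cont
    raise CapacityError(
        design, total_units, max(CAPACITY[(design, c)] for c in _CONTAINERS[design])
    )


def assemble_polypill(
    targets: Mapping[str, object],
    catalogue: Iterable[ModularUnit],
    design: int,
    *,
    container: str | None = None,
) -> PolypillConfig:
    """Solve each drug's dose independently and pick the smallest container."""
    catalogue = list(catalogue)
    counts: dict[str, dict[Fraction, int]] = {}
    for drug, target in targets.items():
        strengths = [u.strength for u in catalogue if u.drug == drug and u.design == design]
        if not strengths:
            raise KeyError(f"drug '{drug}' not in catalogue for design {design}")
        counts[drug] = solve_drug_dose(target, strengths)
    total = sum(n for per_drug in counts.values() for n in per_drug.values())
    chosen = check_capacity(design, total, container)
    return PolypillConfig(counts=counts, design=design, container=chosen, total_units=total)


def taper_schedule(
    dose_sequence: Sequence, strengths: Sequence, design: int, *, drug: str = "drug"
) -> list[PolypillConfig]:
    """One config per taper period; warns (not errors) on dose increases."""
    doses = [as_dose(d) for d in dose_sequence]
    if any(d < 0 for d in doses):
        raise ValueError("taper doses must be >= 0")
    if any(b > a for a, b in zip(doses, doses[1:])):
        warnings.warn("taper sequence is not non-increasing", stacklevel=2)
    configs = []
    for period, dose in enumerate(doses):
        try:
            counts = solve_drug_dose(dose, strengths)
        except InfeasibleDoseError as exc:
            raise ValueError(
                f"taper period {period} (dose {float(dose)} mg) is infeasible: {exc}"
            ) from exc
        total = sum(counts.values())
        container = check_capacity(design, total) if total else _CONTAINERS[design][0]
        configs.append(
            PolypillConfig(
                counts={drug: counts}, design=design, container=container, total_units=total
            )
        )
    return configs


def load_catalogue(path: str | Path) -> list[ModularUnit]:
    """Read a unit catalogue CSV with columns drug, strength_mg, design."""
    units = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            units.append(
                ModularUnit(
                    drug=row["drug"].strip(),
                    strength=as_dose(row["strength_mg"].strip()),
                    design=int(row["design"]),
                )
            )
    return units
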