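"""Pharmacopeial quality-control calculators for tablet batches.

Implements the pass/fail computations for content uniformity (acceptance
value), weight variation, friability, disintegration, dissolution against a
per-drug Q criterion, and descriptive hardness statistics. Boundary
conventions: weight deviation <= 7.5% passes, friability <= 1.0% passes,
disintegration <= 900 s passes, dissolution mean >= Q passes, and the
acceptance value must be strictly < 15.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import mean, stdev
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "UniformityConstants",
    "DissolutionCriterion",
    "TabletBatch",
    "DISSOLUTION_CRITERIA",
    "acceptance_value",
    "weight_variation",
    "friability_loss",
    "disintegration_pass",
    "dissolution_pass",
    "hardness_summary",
    "evaluate_batch",
]


@dataclass(frozen=True)
class UniformityConstants:
    """Content-uniformity constants for a sample of 10 units."""

    k: float = 2.4
    m_low: float = 98.5
    m_high: float = 101.5
    av_limit: float = 15.0


@dataclass(frozen=True)
class DissolutionCriterion:
    """Not-less-than ``q`` percent dissolved at ``time_min`` minutes."""

    drug: str
    q: float
    time_min: float

    def __post_init__(self) -> None:
        if not 0 < self.q <= 100:
            raise ValueError("Q must lie in (0, 100]")
        if self.time_min <= 0:
            raise ValueError("criterion time must be > 0")


#: Monograph dissolution criteria (Q % / minutes). Two rows were printed for
#: 50 mg isoniazid with different limits; the second (NLT 75% in 45 min) is
#: presumed to describe ethambutol and is kept under both keys so callers
#: must name the drug explicitly.
DISSOLUTION_CRITERIA: dict[str, DissolutionCriterion] = {
    c.drug: c
    for c in [
        DissolutionCriterion("rosuvastatin", 75, 30),
        DissolutionCriterion("lisinopril", 80, 30),
        DissolutionCriterion("hydrochlorothiazide", 60, 60),
        DissolutionCriterion("acetylsalicylic_acid", 80, 30),
        DissolutionCriterion("isoniazid", 80, 45),
        DissolutionCriterion("isoniazid_alt", 75, 45),  # flagged duplicate row
        DissolutionCriterion("ethambutol", 75, 45),
        DissolutionCriterion("rifampicin", 75, 45),
        DissolutionCriterion("pyrazinamide", 75, 45),
        DissolutionCriterion("prednisone", 80, 30),
    ]
}


@dataclass
class TabletBatch:
    """Per-unit measurements for one formulation batch."""

    label_claim: float  # mg
    target_weight: float  # mg
    weights: Sequence[float] = ()  # mg, n=20
    contents: Sequence[float] = ()  # % of label claim, n=10
    disintegration_times: Sequence[float] = ()  # s, n=6
    friability: tuple[float, float, bool] | None = None  # (initial g, final g, breakage)
    dissolution: Mapping[int, Sequence[tuple[float, float]]] = field(default_factory=dict)
    hardness: Sequence[float] = ()  # kp

    def __post_init__(self) -> None:
        for name in ("weights", "contents", "disintegration_times", "hardness"):
            vals = getattr(self, name)
            if any(v <= 0 for v in vals):
                raise ValueError(f"{name} must all be positive")
        for vessel, profile in self.dissolution.items():
            for _, pct in profile:
                if not 0 <= pct <= 110:
                    raise ValueError(f"vessel {vessel}: % dissolved must lie in [0, 110]")


def acceptance_value(
    contents: Sequence[float], constants: UniformityConstants | None = None
) -> tuple[float, bool]:
    """Content-uniformity acceptance value |M - mean| + k*s and its pass flag.

    The reference value M equals the sample mean clipped to
    [98.5, 101.5] % of label claim; s is the sample standard deviation
    (n - 1 denominator). Pass requires AV strictly below 15.0. The default
    k = 2.4 applies to n = 10 only; other sample sizes must supply an
    explicit :class:`UniformityConstants` with the appropriate k.
    """
    n = len(contents)
    if constants is None:
        if n != 10:
            raise ValueError("acceptance value requires n=10 unless k is supplied explicitly")
        constants = UniformityConstants()
    if n < 2:
        raise ValueError("need at least 2 content measurements")
    x_bar = mean(contents)
    s = stdev(contents)
    m = min(max(x_bar, constants.m_low), constants.m_high)
    av = abs(m - x_bar) + constants.k * s
    return av, av < constants.av_limit


def weight_variation(
    weights: Sequence[float], limit_pct: float | None = None
) -> tuple[float, bool]:
    """Maximum percent deviation from the batch mean weight and its pass flag.

    Without an explicit ``limit_pct`` the 7.5 % limit applies and the mean
    weight must fall in the 130-324 mg band that limit covers. Strict
    reading: every unit must be within the limit (inclusive).
    """
    if len(weights) != 20:
        raise ValueError("weight variation requires n=20 tablets")
    w = np.asarray(weights, dtype=float)
    mean_w = w.mean()
    if limit_pct is None:
        if not 130.0 <= mean_w <= 324.0:
            raise ValueError(
                f"mean weight {mean_w:.1f} mg outside [130, 324]; supply limit_pct"
            )
        limit_pct = 7.5
    max_dev = float(np.abs(w - mean_w).max() / mean_w * 100.0)
    return max_dev, max_dev <= limit_pct


def weight_variation_usp_classic(
    weights: Sequence[float], limit_pct: float = 7.5
) -> tuple[float, bool]:
    """Classic two-tier reading: <=2 units may exceed the limit, none twice it."""
    if len(weights) != 20:
        raise ValueError("weight variation requires n=20 tablets")
    w = np.asarray(weights, dtype=float)
    dev = np.abs(w - w.mean()) / w.mean() * 100.0
    n_beyond = int((dev > limit_pct).sum())
    n_double = int((dev > 2 * limit_pct).sum())
    return float(dev.max()), n_beyond <= 2 and n_double == 0


def friability_loss(
    initial_g: float, final_g: float, breakage: bool = False
) -> tuple[float, bool]:
    """Percent mass loss after tumbling; any breakage fails outright."""
    if initial_g <= 0 or final_g <= 0:
        raise ValueError("masses must be positive")
    if final_g > initial_g:
        raise ValueError("final mass exceeds initial mass: measurement error")
    loss = (initial_g - final_g) / initial_g * 100.0
    # inclusive 1% limit; absolute float tolerance so e.g. 6.500 -> 6.435 g
    # (exactly 1.00%) is not failed by representation error
    return loss, (loss <= 1.0 + 1e-9) and not breakage


def disintegration_pass(times_s: Sequence[float]) -> bool:
    """All six units must disintegrate within 15 minutes (900 s)."""
    if len(times_s) != 6:
        raise ValueError("disintegration requires n=6 units")
    return max(times_s) <= 900.0


def _pct_at(profile: Sequence[tuple[float, float]], t: float) -> float:
    pts = sorted(profile)
    times = [p[0] for p in pts]
    for when, pct in pts:
        if when == t:
            return pct
    if not times or t < times[0] or t > times[-1]:
        raise ValueError(f"criterion time {t} min outside sampled range {times[:1]}..{times[-1:]}")
    return float(np.interp(t, times, [p[1] for p in pts]))


def dissolution_pass(
    profiles: Mapping[int, Sequence[tuple[float, float]]] | Sequence[Sequence[tuple[float, float]]],
    criterion: DissolutionCriterion,
) -> tuple[float, bool]:
    """Batch mean % dissolved at the criterion time versus the Q limit.

    The per-vessel value is the exact sample point when one exists at the
    criterion time, otherwise linear interpolation between the bracketing
    observations. Pass iff the mean is >= Q.
    """
    vessels = list(profiles.values()) if isinstance(profiles, Mapping) else list(profiles)
    if not vessels:
        raise ValueError("need at least one dissolution vessel")
    values = [_pct_at(v, criterion.time_min) for v in vessels]
    batch_mean = float(np.mean(values))
    return batch_mean, batch_mean >= criterion.q


def hardness_summary(forces_kp: Sequence[float]) -> tuple[float, float]:
    """Mean and sample standard deviation of crushing forces (no limit exists)."""
    if len(forces_kp) < 2:
        raise ValueError("hardness summary requires at least 2 measurements")
    return mean(forces_kp), stdev(forces_kp)


def evaluate_batch(
    batch: TabletBatch,
    criterion: DissolutionCriterion | None = None,
) -> dict:
    """Run every applicable QC computation and collect a report dict."""
    report: dict[str, dict] = {}
    if batch.contents:
        av, ok = acceptance_value(list(batch.contents))
        report["content_uniformity"] = {"av": av, "pass": ok}
    if batch.weights:
        dev, ok = weight_variation(list(batch.weights))
        report["weight_variation"] = {"max_deviation_pct": dev, "pass": ok}
    if batch.friability is not None:
        loss, ok = friability_loss(*batch.friability)
        report["friability"] = {"loss_pct": loss, "pass": ok}
    if batch.disintegration_times:
        report["disintegration"] = {
            "max_time_s": max(batch.disintegration_times),
            "pass": disintegration_pass(list(batch.disintegration_times)),
        }
    if batch.dissolution and criterion is not None:
        mean_pct, ok = dissolution_pass(batch.dissolution, criterion)
        report["dissolution"] = {
            "mean_pct": mean_pct,
            "q": criterion.q,
            "time_min": criterion.time_min,
            "pass": ok,
        }
    if len(batch.hardness) >= 2:
        m, s = hardness_summary(list(batch.hardness))
        report["hardness"] = {"mean_kp": m, "sd_kp": s}
    report["overall_pass"] = all(
        section.get("pass", True) for section in report.values() if isinstance(section, dict)
    )
    return report
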