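"""Seeded generators for model inputs and a micro-simulation oracle.

Everything here is a stand-in for inputs the analyses normally take from
external tables: cohort-model parameter sets with the structural orderings
of the three treatment arms, tablet-batch measurement sets, and an
individual-level Monte-Carlo simulator used to cross-check the cohort
engine. One :class:`numpy.random.SeedSequence` is spawned into named
substreams (one per output block) so adding a field never perturbs earlier
draws; identical specs always reproduce identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .markov import MarkovModel
from .model import ArmParameters, SharedParameters, FDC, STANDARD_CARE, VD, gompertz_mortality

__all__ = [
    "GeneratorSpec",
    "BatchSpec",
    "MicroSimResult",
    "gen_cea_params",
    "simulate_individuals",
    "gen_tablet_batch",
    "DEFAULT_RANGES",
]

# Stand-in sampling ranges (not literature estimates). Chosen to straddle the
# decision-relevant region: side-effect probabilities up to ~0.75, variable-dose
# monthly cost up to $150, annual on-treatment MI probabilities spanning
# 0.011-0.014, so threshold searches have a crossing to find.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "p_side_effect": (0.05, 0.75),
    "p_discontinue_given_side_effect": (0.10, 0.50),
    "p_nonadherence": (0.05, 0.45),
    "p_mi_on_treatment_no_se": (0.005, 0.016),
    "p_mi_on_treatment_after_se": (0.006, 0.020),
    "p_mi_off_treatment": (0.015, 0.040),
    "monthly_drug_cost_standard": (2.0, 15.0),
    "monthly_drug_cost_fdc": (10.0, 60.0),
    "monthly_drug_cost_vd": (20.0, 150.0),
    "side_effect_cost": (0.0, 500.0),
    "side_effect_disutility": (0.0, 0.15),
    "p_mi_fatal": (0.10, 0.40),
    "p_death_post_mi": (0.02, 0.08),
    "mi_event_cost": (20_000.0, 60_000.0),
    "post_mi_annual_cost": (1_000.0, 5_000.0),
    "post_mi_treatment_cost": (10.0, 100.0),
    "u_on_treatment": (0.85, 0.95),
    "u_off_treatment": (0.80, 0.95),
    "u_post_mi": (0.60, 0.80),
}


@dataclass(frozen=True)
class BatchSpec:
    """Moments for one synthetic tablet batch."""

    label_claim: float = 5.0  # mg
    target_weight: float = 137.0  # mg
    weight_cv_pct: float = 2.0
    content_mean_pct: float = 100.0
    content_cv_pct: float = 2.0
    disintegration_mean_s: float = 120.0
    disintegration_cv_pct: float = 20.0
    dissolution_fmax: float = 95.0  # plateau, % released
    dissolution_scale_min: float = 10.0  # Weibull scale, minutes
    dissolution_shape: float = 1.2
    dissolution_noise_pct: float = 1.0
    friability_loss_pct: float = 0.4
    hardness_mean_kp: float = 4.0
    hardness_cv_pct: float = 8.0

    def __post_init__(self) -> None:
        for name in (
            "weight_cv_pct",
            "content_cv_pct",
            "disintegration_cv_pct",
            "dissolution_noise_pct",
            "hardness_cv_pct",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.dissolution_fmax <= 110:
            raise ValueError("dissolution_fmax must lie in [0, 110]")
        if self.dissolution_scale_min <= 0 or self.dissolution_shape <= 0:
            raise ValueError("Weibull scale and shape must be > 0")


@dataclass(frozen=True)
class GeneratorSpec:
    """Seed plus sampling ranges and batch moments for all generators."""

    seed: int = 0
    oracle_cohort_size: int = 100_000
    ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )
    batch: BatchSpec = field(default_factory=BatchSpec)

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_RANGES)
        for key, (low, high) in dict(self.ranges).items():
            if key not in DEFAULT_RANGES:
                raise ValueError(f"unknown parameter range '{key}'")
            if not low <= high:
                raise ValueError(f"range for '{key}' has low > high")
            merged[key] = (float(low), float(high))
        for key in ("p_side_effect", "p_nonadherence", "p_mi_fatal"):
            lo, hi = merged[key]
            if not (0 <= lo and hi <= 1):
                raise ValueError(f"range for '{key}' outside [0, 1]")
        object.__setattr__(self, "ranges", merged)
        if self.oracle_cohort_size < 1:
            raise ValueError("oracle_cohort_size must be >= 1")


def _substreams(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def gen_cea_params(spec: GeneratorSpec) -> tuple[SharedParameters, list[ArmParameters]]:
    """Draw a full, valid three-arm parameter set.

    Structural orderings enforced on every draw: standard care has the lowest
    drug cost and the highest non-adherence; the variable-dose arm's
    side-effect probability never exceeds the fixed-dose arm's; the two
    polypill arms share on-treatment MI probabilities.
    """
    streams = _substreams(spec.seed, ("shared", "arms"))
    rng_shared, rng_arms = streams["shared"], streams["arms"]
    r = spec.ranges

    def u(rng: np.random.Generator, key: str) -> float:
        low, high = r[key]
        return float(rng.uniform(low, high))

    u_on = u(rng_shared, "u_on_treatment")
    shared = SharedParameters(
        start_age=60.0,
        p_mi_fatal=u(rng_shared, "p_mi_fatal"),
        p_death_post_mi=u(rng_shared, "p_death_post_mi"),
        background_mortality=gompertz_mortality(),
        mi_event_cost=u(rng_shared, "mi_event_cost"),
        post_mi_annual_cost=u(rng_shared, "post_mi_annual_cost"),
        post_mi_treatment_cost=u(rng_shared, "post_mi_treatment_cost"),
        utilities={
            "on_treatment": u_on,
            "off_treatment": min(u(rng_shared, "u_off_treatment"), u_on),
            "post_mi": u(rng_shared, "u_post_mi"),
        },
        discount_rate=0.03,
        wtp=100_000.0,
    )

    nonadherence = sorted(rng_arms.uniform(*r["p_nonadherence"], size=3))
    p_se_fdc = u(rng_arms, "p_side_effect")
    p_se_vd = p_se_fdc * float(rng_arms.uniform(0.3, 1.0))
    p_se_std = u(rng_arms, "p_side_effect")
    p_disc = u(rng_arms, "p_discontinue_given_side_effect")
    p_mi_no_se = u(rng_arms, "p_mi_on_treatment_no_se")
    p_mi_after_se = max(u(rng_arms, "p_mi_on_treatment_after_se"), p_mi_no_se)
    p_mi_off = max(u(rng_arms, "p_mi_off_treatment"), p_mi_after_se)
    se_cost = u(rng_arms, "side_effect_cost")
    se_disutility = u(rng_arms, "side_effect_disutility")

    cost_std = u(rng_arms, "monthly_drug_cost_standard")
    cost_fdc = max(u(rng_arms, "monthly_drug_cost_fdc"), cost_std)
    cost_vd = max(u(rng_arms, "monthly_drug_cost_vd"), cost_fdc)

    def arm(name: str, p_se: float, p_na: float, cost: float) -> ArmParameters:
        return ArmParameters(
            name=name,
            p_side_effect=p_se,
            p_discontinue_given_side_effect=p_disc,
            p_nonadherence=p_na,
            p_mi_on_treatment_no_se=p_mi_no_se,
            p_mi_on_treatment_after_se=p_mi_after_se,
            p_mi_off_treatment=p_mi_off,
            monthly_drug_cost=cost,
            side_effect_cost=se_cost,
            side_effect_disutility=se_disutility,
        )

    arms = [
        arm(STANDARD_CARE, p_se_std, nonadherence[2], cost_std),
        arm(FDC, p_se_fdc, min(nonadherence[0], nonadherence[1]), cost_fdc),
        arm(VD, p_se_vd, min(nonadherence[0], nonadherence[1]), cost_vd),
    ]
    return shared, arms


@dataclass
class MicroSimResult:
    """Empirical trace and per-individual discounted reward summaries."""

    occupancy: np.ndarray  # (n_cycles + 1, n_states) fractions
    mean_cost: float
    mean_qaly: float
    se_cost: float
    se_qaly: float
    n: int

    def occupancy_se(self) -> np.ndarray:
        p = self.occupancy
        return np.sqrt(p * (1.0 - p) / self.n)


def simulate_individuals(model: MarkovModel, n: int, seed: int) -> MicroSimResult:
    """Simulate ``n`` independent trajectories by categorical sampling.

    Rewards mirror the cohort engine's default convention: per-state rewards
    are credited to the state occupied at cycle start and discounted by
    ``(1 + r) ** -t``; one-time transition costs are credited in the cycle
    the transition occurs.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    s = len(model.states)
    start = int(np.argmax(model.initial_distribution))
    if not np.isclose(model.initial_distribution[start], 1.0):
        states = rng.choice(s, size=n, p=model.initial_distribution)
    else:
        states = np.full(n, start, dtype=np.int64)

    tc_mat = np.zeros((s, s))
    for (src, dst), cost in (model.transition_costs or {}).items():
        tc_mat[model.states.index(src), model.states.index(dst)] = cost

    r_c = model.discount_rate
    r_u = r_c if model.utility_discount_rate is None else model.utility_discount_rate

    counts = np.zeros((model.n_cycles + 1, s))
    cost_tot = np.zeros(n)
    qaly_tot = np.zeros(n)
    counts[0] = np.bincount(states, minlength=s)
    for t in range(model.n_cycles):
        disc_c = (1.0 + r_c) ** -t
        disc_u = (1.0 + r_u) ** -t
        cost_tot += disc_c * model.costs[states]
        qaly_tot += disc_u * model.utilities[states]
        cum = np.cumsum(model.transition_at(t), axis=1)
        draws = rng.random(n)
        nxt = (draws[:, None] > cum[states]).sum(axis=1)
        cost_tot += disc_c * tc_mat[states, nxt]
        states = nxt
        counts[t + 1] = np.bincount(states, minlength=s)

    return MicroSimResult(
        occupancy=counts / n,
        mean_cost=float(cost_tot.mean()),
        mean_qaly=float(qaly_tot.mean()),
        se_cost=float(cost_tot.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        se_qaly=float(qaly_tot.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        n=n,
    )


DISSOLUTION_TIMES = (5.0, 10.0, 15.0, 20.0, 30.0, 45.0, 60.0)


def gen_tablet_batch(spec: GeneratorSpec):
    """Draw one synthetic batch of QC measurements.

    Weights, contents and disintegration times are normal draws (truncated
    positive) at the spec's moments; dissolution follows a Weibull release
    curve ``F(t) = F_max * (1 - exp(-(t/scale)^shape))`` with additive
    observation noise, sampled at fixed time points in four vessels. All
    coefficients of variation at zero yield exactly the nominal values.
    """
    from .qc import TabletBatch

    b = spec.batch
    streams = _substreams(
        spec.seed, ("weights", "contents", "disintegration", "dissolution", "hardness")
    )

    def normal(rng, mean: float, cv_pct: float, size: int) -> np.ndarray:
        if cv_pct == 0.0:
            return np.full(size, mean)
        draws = rng.normal(mean, mean * cv_pct / 100.0, size=size)
        return np.clip(draws, mean * 1e-3, None)  # truncate positive

    weights = normal(streams["weights"], b.target_weight, b.weight_cv_pct, 20)
    contents = normal(streams["contents"], b.content_mean_pct, b.content_cv_pct, 10)
    disintegration = normal(
        streams["disintegration"], b.disintegration_mean_s, b.disintegration_cv_pct, 6
    )
    hardness = normal(streams["hardness"], b.hardness_mean_kp, b.hardness_cv_pct, 10)

    rng_d = streams["dissolution"]
    t = np.asarray(DISSOLUTION_TIMES)
    curve = b.dissolution_fmax * (1.0 - np.exp(-((t / b.dissolution_scale_min) ** b.dissolution_shape)))
    dissolution = {}
    for vessel in range(1, 5):
        noise = (
            rng_d.normal(0.0, b.dissolution_noise_pct, size=t.size)
            if b.dissolution_noise_pct > 0
            else np.zeros(t.size)
        )
        observed = np.clip(curve + noise, 0.0, 110.0)
        dissolution[vessel] = list(zip(t.tolist(), observed.tolist()))

    initial = 6.5
    final = initial * (1.0 - b.friability_loss_pct / 100.0)
    return TabletBatch(
        label_claim=b.label_claim,
        target_weight=b.target_weight,
        weights=weights.tolist(),
        contents=contents.tolist(),
        disintegration_times=disintegration.tolist(),
        friability=(initial, final, False),
        dissolution=dissolution,
        hardness=hardness.tolist(),
    )


def with_seed(spec: GeneratorSpec, seed: int) -> GeneratorSpec:
    return replace(spec, seed=seed)
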