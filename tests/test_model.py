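import math

import numpy as np
import pytest

from polypill.cea import EQUIVALENT, cost_effective_choice
from polypill.markov import ModelValidationError, run_trace, totals_for_model
from polypill.model import (
    ARM_NAMES,
    FDC,
    STANDARD_CARE,
    VD,
    ArmParameters,
    SharedParameters,
    analysis_to_dict,
    arm_outcome,
    build_arm_model,
    combine_competing_risks,
    gompertz_mortality,
    load_analysis,
    make_evaluator,
    run_three_arm_base_case,
    set_parameter,
)


def make_arm(name="VD", **over):
    base = dict(
        p_side_effect=0.2,
        p_discontinue_given_side_effect=0.3,
        p_nonadherence=0.1,
        p_mi_on_treatment_no_se=0.011,
        p_mi_on_treatment_after_se=0.014,
        p_mi_off_treatment=0.025,
        monthly_drug_cost=50.0,
        side_effect_cost=200.0,
        side_effect_disutility=0.05,
    )
    base.update(over)
    return ArmParameters(name=name, **base)


def make_shared(**over):
    base = dict(
        start_age=60.0,
        p_mi_fatal=0.25,
        p_death_post_mi=0.05,
        background_mortality=gompertz_mortality(),
        mi_event_cost=40_000.0,
        post_mi_annual_cost=2_000.0,
        post_mi_treatment_cost=30.0,
        utilities={"on_treatment": 0.9, "off_treatment": 0.88, "post_mi": 0.7},
        discount_rate=0.03,
        wtp=100_000.0,
    )
    base.update(over)
    return SharedParameters(**base)


class TestCombineCompetingRisks:
    def test_single_risk_unchanged(self):
        stay, exits = combine_competing_risks([0.3])
        assert exits[0] == pytest.approx(0.3, abs=1e-15)
        assert stay == pytest.approx(0.7, abs=1e-15)

    def test_two_half_risks(self):
        # rates ln2 each; exit = 1 - e^{-ln4} = 0.75, split equally
        stay, exits = combine_competing_risks([0.5, 0.5])
        assert stay == pytest.approx(0.25, abs=1e-12)
        assert exits == pytest.approx([0.375, 0.375], abs=1e-12)

    def test_all_zero(self):
        stay, exits = combine_competing_risks([0.0, 0.0, 0.0])
        assert stay == 1.0
        assert exits == [0.0, 0.0, 0.0]

    def test_certain_event_takes_all_with_warning(self):
        with pytest.warns(UserWarning, match="certain"):
            stay, exits = combine_competing_risks([1.0, 0.4])
        assert stay == 0.0
        assert exits == [1.0, 0.0]

    def test_sums_to_one(self, rng):
        for _ in range(100):
            probs = rng.uniform(0, 0.99, size=rng.integers(1, 5))
            stay, exits = combine_competing_risks(list(probs))
            assert stay + sum(exits) == pytest.approx(1.0, abs=1e-12)
            assert all(e >= 0 for e in exits)

    def test_out_of_range_rejected(self):
        with pytest.raises(ModelValidationError):
            combine_competing_risks([1.2])


class TestBuildArmModel:
    def test_no_side_effects_state_unreachable(self):
        arm = make_arm(p_side_effect=0.0)
        model = build_arm_model(arm, make_shared(), n_cycles=20)
        trace = run_trace(model)
        assert np.all(trace.occupancy_of("OnTx-PostSE") == 0.0)

    def test_all_zero_probabilities_cohort_stays_put(self):
        arm = make_arm(
            p_side_effect=0.0,
            p_nonadherence=0.0,
            p_mi_on_treatment_no_se=0.0,
            p_mi_on_treatment_after_se=0.0,
            p_mi_off_treatment=0.0,
        )
        shared = make_shared(
            p_death_post_mi=0.0, background_mortality=lambda age: 0.0
        )
        trace = run_trace(build_arm_model(arm, shared, n_cycles=15))
        assert np.all(trace.occupancy_of("OnTx-NoSE") == 1.0)

    def test_state_lumping_equivalence_for_off_treatment(self):
        # identical off-treatment MI risk for both discontinuation reasons makes
        # the split-state variant trace-equivalent after lumping
        arm, shared = make_arm(), make_shared()
        lumped = run_trace(build_arm_model(arm, shared, n_cycles=30))
        split_model = build_arm_model(arm, shared, n_cycles=30, split_off_treatment=True)
        split = run_trace(split_model)
        off_lumped = lumped.occupancy_of("OffTx")
        off_split = split.occupancy_of("OffTx-SE") + split.occupancy_of("OffTx-NA")
        np.testing.assert_allclose(off_split, off_lumped, atol=1e-12)
        for state in ("OnTx-NoSE", "OnTx-PostSE", "Post-MI", "Dead"):
            np.testing.assert_allclose(
                split.occupancy_of(state), lumped.occupancy_of(state), atol=1e-12
            )
        # and so are the totals
        np.testing.assert_allclose(
            totals_for_model(split_model),
            totals_for_model(build_arm_model(arm, shared, n_cycles=30)),
            rtol=1e-12,
        )

    def test_on_treatment_states_lumpable_when_se_is_free(self):
        # no side-effect cost/disutility and equal on-treatment MI risks: the
        # two on-treatment states merge into one in a hand-built reduced model
        arm = make_arm(
            side_effect_cost=0.0,
            side_effect_disutility=0.0,
            p_mi_on_treatment_after_se=0.011,
        )
        shared = make_shared()
        full_model = build_arm_model(arm, shared, n_cycles=25)
        full_cost, full_qaly = totals_for_model(full_model)

        from polypill.markov import MarkovModel, StateSpace

        states = StateSpace(["OnTx", "OffTx", "Post-MI", "Dead"], absorbing=["Dead"])
        mats = np.zeros((25, 4, 4))
        for t in range(25):
            q = shared.mortality_at(60 + t)
            _, (e_se, e_na, e_mi, e_d) = combine_competing_risks(
                [arm.p_side_effect, arm.p_nonadherence, 0.011, q]
            )
            # side-effect exits that do not discontinue return to OnTx
            to_off = e_se * arm.p_discontinue_given_side_effect + e_na
            mats[t, 0] = [
                1 - to_off - e_mi - e_d,
                to_off,
                e_mi * (1 - shared.p_mi_fatal),
                e_mi * shared.p_mi_fatal + e_d,
            ]
            _, (e_mi, e_d) = combine_competing_risks([arm.p_mi_off_treatment, q])
            mats[t, 1] = [0, 1 - e_mi - e_d, e_mi * (1 - shared.p_mi_fatal), e_mi * shared.p_mi_fatal + e_d]
            _, (e_x, e_d) = combine_competing_risks([shared.p_death_post_mi, q])
            mats[t, 2] = [0, 0, 1 - e_x - e_d, e_x + e_d]
            mats[t, 3] = [0, 0, 0, 1]
        reduced = MarkovModel(
            states=states,
            transition=mats,
            initial_distribution=np.array([1.0, 0, 0, 0]),
            n_cycles=25,
            costs=np.array([600.0, 0.0, 2360.0, 0.0]),
            utilities=np.array([0.9, 0.88, 0.7, 0.0]),
            discount_rate=0.03,
            transition_costs={("OnTx", "Post-MI"): 40_000.0, ("OffTx", "Post-MI"): 40_000.0},
        )
        red_cost, red_qaly = totals_for_model(reduced)
        assert full_cost == pytest.approx(red_cost, abs=1e-9 * red_cost)
        assert full_qaly == pytest.approx(red_qaly, abs=1e-9)

    def test_wait_until_wholly_dead(self):
        import warnings

        with warnings.catch_warnings():
            # Gompertz mortality saturates at q=1 beyond ~age 117
            warnings.simplefilter("ignore", UserWarning)
            trace = run_trace(build_arm_model(make_arm(), make_shared(), n_cycles=80))
        assert trace.occupancy_of("Dead")[-1] > 0.999

    def test_mi_tunnel_variant_runs_and_roughly_matches(self):
        arm, shared = make_arm(), make_shared()
        plain = totals_for_model(build_arm_model(arm, shared, n_cycles=40))
        tunnel = totals_for_model(build_arm_model(arm, shared, n_cycles=40, mi_tunnel=True))
        # same order of magnitude; tunnel discounts acute costs one cycle later
        assert tunnel[0] == pytest.approx(plain[0], rel=0.1)
        assert tunnel[1] == pytest.approx(plain[1], rel=0.05)

    def test_default_horizon_runs_to_age_100(self):
        shared = make_shared()
        model = build_arm_model(make_arm(), shared)
        assert model.n_cycles == 40

    def test_mi_probability_monotonicity(self):
        shared = make_shared()
        qalys, incidences = [], []
        for p in np.linspace(0.0, 0.10, 11):
            arm = make_arm(p_mi_on_treatment_no_se=p, p_mi_on_treatment_after_se=max(p, 0.014))
            model = build_arm_model(arm, shared, n_cycles=40)
            trace = run_trace(model)
            _, qaly = totals_for_model(model, trace)
            qalys.append(qaly)
            # cumulative non-fatal MI incidence: inflow into Post-MI
            post_mi = trace.occupancy_of("Post-MI")
            dead_in = trace.occupancy_of("Dead")
            incidences.append(post_mi.sum() + dead_in[-1])
        assert all(a >= b - 1e-12 for a, b in zip(qalys, qalys[1:]))

    def test_row_probabilities_validated(self):
        # probabilities combined via competing risks always yield stochastic rows
        arm = make_arm(p_side_effect=0.99, p_nonadherence=0.99, p_mi_on_treatment_no_se=0.9)
        model = build_arm_model(arm, make_shared(), n_cycles=10)
        assert np.allclose(model.transition.sum(axis=2), 1.0, atol=1e-9)


class TestThreeArmBaseCase:
    def test_identical_arms_tie(self):
        shared = make_shared()
        arms = [make_arm(name=n) for n in ARM_NAMES]
        result = run_three_arm_base_case(arms, shared, n_cycles=30)
        assert all(s == EQUIVALENT for s in result.status.values())
        assert all(v is None for v in result.icers.values())

    def test_zero_drug_cost_identical_clinical_ties(self):
        shared = make_shared()
        arms = [make_arm(name=n, monthly_drug_cost=0.0) for n in ARM_NAMES]
        result = run_three_arm_base_case(arms, shared, n_cycles=30)
        costs = {o.cost for o in result.outcomes}
        effects = {o.effect for o in result.outcomes}
        assert len(costs) == 1 and len(effects) == 1

    def test_vd_better_mi_but_pricier_gets_finite_icer(self):
        shared = make_shared()
        std = make_arm(STANDARD_CARE, monthly_drug_cost=5.0, p_nonadherence=0.4)
        fdc = make_arm(FDC, monthly_drug_cost=30.0)
        vd = make_arm(
            VD,
            monthly_drug_cost=60.0,
            p_mi_on_treatment_no_se=0.008,
            p_mi_on_treatment_after_se=0.010,
            p_side_effect=0.1,
        )
        result = run_three_arm_base_case([std, fdc, vd], shared)
        assert result.status[VD] == "on-frontier"
        ratio = result.icers[VD]
        assert ratio is not None and 0 < ratio < math.inf

    def test_wrong_arm_set_rejected(self):
        with pytest.raises(ModelValidationError, match="arms"):
            run_three_arm_base_case([make_arm("A"), make_arm("B"), make_arm("C")], make_shared())


class TestParameterPlumbing:
    def test_set_parameter_arm_and_shared(self):
        shared, arms = make_shared(), [make_arm(name=n) for n in ARM_NAMES]
        s2, a2 = set_parameter(shared, arms, "VD.monthly_drug_cost", 120.0)
        assert next(a for a in a2 if a.name == VD).monthly_drug_cost == 120.0
        assert next(a for a in a2 if a.name == FDC).monthly_drug_cost == 50.0
        s3, _ = set_parameter(shared, arms, "shared.mi_event_cost", 1.0)
        assert s3.mi_event_cost == 1.0
        assert shared.mi_event_cost == 40_000.0

    def test_set_parameter_unknown_rejected(self):
        shared, arms = make_shared(), [make_arm(name=n) for n in ARM_NAMES]
        with pytest.raises(KeyError):
            set_parameter(shared, arms, "VD.bogus", 1.0)
        with pytest.raises(KeyError):
            set_parameter(shared, arms, "nosucharm.monthly_drug_cost", 1.0)
        with pytest.raises(KeyError):
            set_parameter(shared, arms, "unqualified", 1.0)

    def test_make_evaluator_reacts_to_parameter(self):
        shared, arms = make_shared(), [make_arm(name=n) for n in ARM_NAMES]
        evaluate = make_evaluator(shared, arms, "VD.monthly_drug_cost", n_cycles=20)
        lo = {o.name: o.cost for o in evaluate(10.0)}
        hi = {o.name: o.cost for o in evaluate(100.0)}
        assert hi[VD] > lo[VD]
        assert hi[FDC] == lo[FDC]

    def test_config_round_trip(self, tmp_path):
        import yaml

        shared, arms = make_shared(), [make_arm(name=n) for n in ARM_NAMES]
        doc = analysis_to_dict(shared, arms)
        path = tmp_path / "analysis.yaml"
        path.write_text(yaml.safe_dump(doc))
        shared2, arms2 = load_analysis(path)
        vd2 = next(a for a in arms2 if a.name == VD)
        vd = next(a for a in arms if a.name == VD)
        assert arm_outcome(vd2, shared2, 20) == arm_outcome(vd, shared, 20)
        assert shared2.wtp == shared.wtp

    def test_tabulated_mortality(self):
        table = {age: 0.01 for age in range(60, 101)}
        shared = make_shared(background_mortality=table)
        model = build_arm_model(make_arm(), shared, n_cycles=10)
        assert model.n_cycles == 10
        shared_short = make_shared(background_mortality={60: 0.01})
        with pytest.raises(ModelValidationError, match="cover"):
            build_arm_model(make_arm(), shared_short, n_cycles=10)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ModelValidationError):
            make_arm(p_side_effect=1.5)
        with pytest.raises(ModelValidationError):
            make_shared(p_mi_fatal=-0.1)


def test_wtp_choice_on_constructed_frontier():
    shared = make_shared()
    std = make_arm(STANDARD_CARE, monthly_drug_cost=5.0, p_nonadherence=0.45, p_side_effect=0.3)
    fdc = make_arm(FDC, monthly_drug_cost=30.0)
    vd = make_arm(
        VD, monthly_drug_cost=60.0, p_side_effect=0.1, p_mi_on_treatment_no_se=0.008
    )
    result = run_three_arm_base_case([std, fdc, vd], shared)
    choice = cost_effective_choice(result, shared.wtp)
    assert choice in (FDC, VD)
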