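import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rtebench import (
    AdequacyRule,
    CareType,
    DEAInstance,
    FuzzySet,
    assess_all,
    compile_knowledge_base,
    default_knowledge_base,
    derive_variables,
    transform_record,
    transform_value,
)
from rtebench.adequacy import (
    COMPETENCE_FLOOR,
    INPUT_INVERSION_FLOOR,
    OUTPUT_SCALE,
    PASS_THROUGH,
)
from rtebench.scenarios import build_scenarios

from conftest import make_record

BUDGET_RULE = AdequacyRule(
    care_type=CareType.FLOATING_OUTREACH,
    variable="budget_per_place",
    role="input",
    adequate_range=(5000.0, 6000.0),
    direction="higher_better",
    penalty_factor=2.0,
)

KB_YAML = """
provenance: expert-panel example
pass_through: [places]
rules:
  - care_type: floating_outreach
    variable: budget_per_place
    role: input
    adequate_range: [5000, 6000]
    direction: higher_better
    penalty_factor: 2
"""


class TestCompileKnowledgeBase:
    def test_rule_retrievable_by_key(self):
        kb = compile_knowledge_base(KB_YAML)
        rule = kb.resolve(CareType.FLOATING_OUTREACH, "budget_per_place")
        assert rule.adequate_range == (5000.0, 6000.0)
        assert rule.penalty_factor == 2.0
        assert kb.resolve(CareType.FLOATING_OUTREACH, "places") == PASS_THROUGH

    def test_empty_config_warns(self):
        with pytest.warns(UserWarning, match="pass through"):
            kb = compile_knowledge_base("{}")
        assert not kb.rules

    def test_duplicate_rule_rejected(self):
        dup = KB_YAML + KB_YAML.split("rules:")[1]
        with pytest.raises(ValueError, match="duplicate"):
            compile_knowledge_base(dup)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError, match="lo >= hi"):
            AdequacyRule(
                care_type="supported_housing", variable="places", role="input",
                adequate_range=(5, 5),
            )

    def test_unresolvable_variable_is_error(self):
        kb = compile_knowledge_base(KB_YAML)
        with pytest.raises(KeyError, match="no adequacy rule"):
            kb.resolve(CareType.FLOATING_OUTREACH, "staff_per_user")


class TestDefaultKnowledgeBase:
    def test_range_is_interquartile(self, sh_cohort, sh_kb):
        rule = sh_kb.resolve(CareType.SUPPORTED_HOUSING, "budget_per_place")
        vals = [derive_variables(r).budget_per_place for r in sh_cohort]
        lo, hi = np.percentile(vals, [25, 75])
        assert rule.adequate_range == pytest.approx((lo, hi))

    def test_stay_band_contains_two_years(self, sh_kb):
        rule = sh_kb.resolve(CareType.SUPPORTED_HOUSING, "length_of_stay")
        assert rule.direction == "target_band"
        lo, hi = rule.adequate_range
        assert lo <= 2.0 <= hi

    def test_provenance_is_data_derived(self, sh_kb):
        assert sh_kb.provenance == "data-derived stand-in"
        assert all(r.penalty_factor == 2.0 for r in sh_kb.rules.values())

    def test_too_few_records_rejected(self, sh_cohort):
        with pytest.raises(ValueError, match="at least 5"):
            default_knowledge_base(sh_cohort[:3])


class TestTransformValue:
    def test_upper_bound_is_best_for_higher_better(self):
        assert transform_value(BUDGET_RULE, 6000.0) == pytest.approx(1.0)

    def test_midpoint_maps_to_three_quarters(self):
        assert transform_value(BUDGET_RULE, 5500.0) == pytest.approx(0.75)

    def test_lower_bound_maps_to_half(self):
        assert transform_value(BUDGET_RULE, 5000.0) == pytest.approx(0.5)

    def test_double_penalty_at_range_exit(self):
        just_below = transform_value(BUDGET_RULE, 5000.0 - 1e-9)
        assert just_below == pytest.approx(0.25, abs=1e-6)
        # the discontinuity at the boundary is exactly the penalty factor
        assert transform_value(BUDGET_RULE, 5000.0) / just_below == \
            pytest.approx(2.0, abs=1e-6)

    def test_penalised_side_stays_below_in_range(self):
        outside = [transform_value(BUDGET_RULE, x) for x in (0, 2500, 4999, 6001, 10000)]
        assert max(outside) <= 0.5

    @given(st.floats(min_value=5000, max_value=6000))
    @settings(max_examples=50, deadline=None)
    def test_monotone_inside_range(self, x):
        c = transform_value(BUDGET_RULE, x)
        assert transform_value(BUDGET_RULE, min(x + 10, 6000.0)) >= c

    @given(st.floats(min_value=0, max_value=4999))
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing_away_below_range(self, x):
        nearer = transform_value(BUDGET_RULE, x + 0.5)
        farther = transform_value(BUDGET_RULE, x)
        assert farther <= nearer
        if nearer > COMPETENCE_FLOOR:
            assert farther < nearer

    def test_lower_better_orientation(self):
        rule = AdequacyRule(
            care_type="supported_housing", variable="staff_per_user", role="input",
            adequate_range=(0.2, 0.8), direction="lower_better",
        )
        assert transform_value(rule, 0.2) == pytest.approx(1.0)
        assert transform_value(rule, 0.8) == pytest.approx(0.5)

    def test_target_band_peaks_at_centre(self):
        rule = AdequacyRule(
            care_type="supported_housing", variable="length_of_stay", role="output",
            adequate_range=(1.0, 2.0), direction="target_band",
        )
        assert transform_value(rule, 1.5) == pytest.approx(1.0)
        assert transform_value(rule, 1.0) == pytest.approx(0.5)
        assert transform_value(rule, 2.0) == pytest.approx(0.5)
        assert transform_value(rule, 8.0) < transform_value(rule, 3.0) < 0.5


class TestProductSumGravity:
    SETS = (
        FuzzySet("low", (0.0, 0.0, 1.5), 0.3),
        FuzzySet("adequate", (1.0, 1.5, 2.0), 1.0),
        FuzzySet("high", (1.5, 3.0, 3.0), 0.4),
    )
    RULE = AdequacyRule(
        care_type="supported_housing", variable="length_of_stay", role="output",
        adequate_range=(1.0, 2.0), transform_kind="product_sum_gravity",
        fuzzy_sets=SETS,
    )

    def test_band_centre_returns_its_consequent(self):
        # only the "adequate" set is active at its peak
        assert self.RULE.fuzzy_sets[1].membership(1.5) == 1.0
        assert self.RULE.fuzzy_sets[0].membership(1.5) == 0.0
        assert transform_value(self.RULE, 1.5) == pytest.approx(1.0)

    @given(st.floats(min_value=0.0, max_value=3.0))
    @settings(max_examples=60, deadline=None)
    def test_defuzzified_within_consequent_hull(self, x):
        c = transform_value(self.RULE, x)
        cons = [s.consequent for s in self.SETS]
        assert min(cons) / self.RULE.penalty_factor <= c <= max(cons) + 1e-12

    def test_blend_is_gravity_weighted(self):
        # at x = 1.25, "low" and "adequate" are both half-active
        mu_low = self.SETS[0].membership(1.25)
        mu_ad = self.SETS[1].membership(1.25)
        expected = (mu_low * 0.3 + mu_ad * 1.0) / (mu_low + mu_ad)
        assert transform_value(self.RULE, 1.25) == pytest.approx(expected)


class TestTransformRecord:
    def test_best_competence_maps_to_extremes(self, sh_cohort, sh_kb):
        scenario = build_scenarios(CareType.SUPPORTED_HOUSING)[0]
        rule = sh_kb.resolve(CareType.SUPPORTED_HOUSING, "budget_per_place")
        rec = sh_cohort[0]
        x, y = transform_record(sh_kb, derive_variables(rec), scenario)
        assert (x > 0).all() and (y >= 0).all()
        assert x.min() >= 1.0  # inputs are 1/c with c <= 1

    def test_identical_services_identical_vectors(self, sh_kb):
        scenario = build_scenarios(CareType.SUPPORTED_HOUSING)[1]
        a = make_record(service_id="a")
        b = make_record(service_id="b")
        xa, ya = transform_record(sh_kb, derive_variables(a), scenario)
        xb, yb = transform_record(sh_kb, derive_variables(b), scenario)
        np.testing.assert_array_equal(xa, xb)
        np.testing.assert_array_equal(ya, yb)

    def test_improving_competence_weakly_improves_theta(self, sh_kb):
        """End-to-end orientation: a service whose movers rate rises toward
        the adequate range can only gain (never lose) efficiency."""
        scenario = build_scenarios(CareType.SUPPORTED_HOUSING)[0]
        base = [make_record(service_id=f"s{k}", movers_2yr=k, places=20 + k,
                            occupied_places=15) for k in range(4)]
        worse = make_record(service_id="t", movers_2yr=0)
        better = make_record(service_id="t", movers_2yr=6)
        thetas = []
        for probe in (worse, better):
            X, Y = zip(*[
                transform_record(sh_kb, derive_variables(r), scenario)
                for r in base + [probe]
            ])
            res = assess_all(DEAInstance(X=np.array(X), Y=np.array(Y)))
            thetas.append(res.theta[-1])
        assert thetas[1] >= thetas[0] - 1e-9
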