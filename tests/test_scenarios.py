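import itertools

import numpy as np
import pandas as pd
import pytest

from rtebench import (
    CareType,
    DEAInstance,
    MCConfig,
    RTEDistribution,
    assess_all,
    build_scenarios,
    classify_impact,
    compare_to_baseline,
    derive_variables,
    run_study,
    transform_record,
    wilcoxon_signed_rank,
)
from rtebench.scenarios import BASELINE_INPUTS, BASELINE_OUTPUTS

from conftest import make_record


class TestBuildScenarios:
    @pytest.mark.parametrize("care_type,expected", [
        (CareType.RESIDENTIAL_MOVE_ON, 8),
        (CareType.RESIDENTIAL_NON_MOVE_ON, 8),
        (CareType.SUPPORTED_HOUSING, 8),
        (CareType.FLOATING_OUTREACH, 7),
    ])
    def test_scenario_counts(self, care_type, expected):
        assert len(build_scenarios(care_type)) == expected

    def test_baseline_variable_membership(self):
        base = build_scenarios(CareType.SUPPORTED_HOUSING)[0]
        assert base.is_baseline
        assert set(base.inputs) == {"places", "staff_per_user", "budget_per_place"}
        assert set(base.outputs) == {
            "length_of_stay", "occupancy_pct", "movers_per_place"
        }

    def test_each_quality_scenario_adds_one_domain(self):
        for ct in CareType:
            scenarios = build_scenarios(ct)
            domains = [s.quality_domain for s in scenarios[1:]]
            assert len(set(domains)) == len(domains)  # each domain once
            for s in scenarios[1:]:
                assert s.inputs == BASELINE_INPUTS
                assert len(s.outputs) == 4
                assert s.outputs[:3] == BASELINE_OUTPUTS

    def test_second_scenario_domain_per_care_type(self):
        assert build_scenarios(CareType.RESIDENTIAL_MOVE_ON)[1].quality_domain == \
            "living_environment"
        assert build_scenarios(CareType.FLOATING_OUTREACH)[1].quality_domain == \
            "therapeutic_environment"

    def test_floating_outreach_never_sees_living_environment(self):
        domains = {s.quality_domain for s in build_scenarios(CareType.FLOATING_OUTREACH)}
        assert "living_environment" not in domains


class TestRunStudy:
    def test_identical_cohort_deterministically_efficient(self, sh_kb):
        """Symmetry: with no perturbation, identical services all score
        exactly 1 in every scenario (each supports the others at equality)."""
        records = [make_record(service_id=f"s{k}") for k in range(4)]
        for sc in build_scenarios(CareType.SUPPORTED_HOUSING):
            X, Y = zip(*[
                transform_record(sh_kb, derive_variables(r), sc) for r in records
            ])
            theta = assess_all(DEAInstance(X=np.array(X), Y=np.array(Y))).theta
            np.testing.assert_allclose(theta, 1.0, atol=1e-9)

    def test_identical_cohort_mc_means_near_one(self, sh_kb):
        records = [make_record(service_id=f"s{k}") for k in range(4)]
        scenarios = build_scenarios(CareType.SUPPORTED_HOUSING)[:2]
        matrix, _ = run_study(records, sh_kb, scenarios, MCConfig(seed=1, n_max=40))
        assert (matrix.to_numpy() >= 0.98).all()

    def test_global_average_is_column_mean(self, sh_cohort, sh_kb):
        scenarios = build_scenarios(CareType.SUPPORTED_HOUSING)[:2]
        matrix, _ = run_study(sh_cohort[:6], sh_kb, scenarios,
                              MCConfig(seed=3, n_max=40))
        services = matrix.drop(index="global_average")
        np.testing.assert_allclose(
            matrix.loc["global_average"].to_numpy(),
            services.mean(axis=0).to_numpy(),
        )

    def test_global_average_invariant_to_service_order(self, sh_cohort, sh_kb):
        scenarios = build_scenarios(CareType.SUPPORTED_HOUSING)[:1]
        cfg = MCConfig(seed=9, n_max=30)
        a, _ = run_study(sh_cohort[:5], sh_kb, scenarios, cfg)
        b, _ = run_study(list(reversed(sh_cohort[:5])), sh_kb, scenarios, cfg)
        assert a.loc["global_average", "scenario_1"] == pytest.approx(
            b.loc["global_average", "scenario_1"], abs=1e-12
        )

    def test_mixed_care_types_rejected(self, sh_kb):
        records = [
            make_record(service_id="a"),
            make_record(service_id="b", care_type=CareType.FLOATING_OUTREACH,
                        occupied_places=18),
        ]
        with pytest.raises(ValueError, match="one care type"):
            run_study(records, sh_kb, build_scenarios(CareType.SUPPORTED_HOUSING))

    def test_zero_quality_column_leaves_deterministic_theta_unchanged(self, sh_kb):
        """A constant-zero output column is inactive in the envelopment LP,
        so the quality scenario's deterministic scores equal the baseline."""
        records = [
            make_record(service_id=f"s{k}", places=10 + 4 * k, occupied_places=8,
                        movers_2yr=k,
                        quirc={d: 0.0 for d in make_record().quirc})
            for k in range(5)
        ]
        base, scen = build_scenarios(CareType.SUPPORTED_HOUSING)[:2]
        thetas = {}
        for sc in (base, scen):
            X, Y = zip(*[
                transform_record(sh_kb, derive_variables(r), sc) for r in records
            ])
            thetas[sc.id] = assess_all(DEAInstance(X=np.array(X), Y=np.array(Y))).theta
        np.testing.assert_allclose(thetas[1], thetas[2], atol=1e-9)


def exact_signed_rank_p(diff):
    """Independent oracle: enumerate all 2^n sign assignments of the ranked
    absolute differences and count |W - E[W]| at least as extreme."""
    diff = np.asarray(diff, dtype=float)
    diff = diff[diff != 0]
    n = diff.size
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(diff))
    w_obs = ranks[diff > 0].sum()
    mu = ranks.sum() / 2
    count = 0
    total = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = ranks[np.array(signs, dtype=bool)].sum()
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestWilcoxon:
    def test_all_equal_positive_differences(self):
        base = np.zeros(10)
        scen = np.full(10, 0.1)
        _, p = wilcoxon_signed_rank(base, scen)
        assert p == pytest.approx(2 * 0.5**10)

    def test_all_tied_pairs_report_no_difference(self):
        stat, p = wilcoxon_signed_rank(np.ones(8), np.ones(8))
        assert p == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_exact_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 11))
        base = rng.uniform(0.3, 0.9, n)
        scen = base + rng.normal(0.02, 0.05, n)
        _, p = wilcoxon_signed_rank(base, scen)
        assert p == pytest.approx(exact_signed_rank_p(scen - base), abs=1e-10)


class TestCompareAndClassify:
    def _matrix(self, base, scen):
        idx = [f"s{k}" for k in range(len(base))] + ["global_average"]
        return pd.DataFrame(
            {
                "scenario_1": list(base) + [np.mean(base)],
                "scenario_2": list(scen) + [np.mean(scen)],
            },
            index=pd.Index(idx, name="service_id"),
        )

    def test_identical_scenario_is_neutral(self):
        base = np.linspace(0.4, 0.9, 8)
        imp = compare_to_baseline(self._matrix(base, base), 2)
        assert imp.p_value == 1.0
        assert imp.global_class == "neutral"
        assert set(imp.per_service_class.values()) == {"neutral"}

    def test_large_uniform_shift_is_positive(self):
        base = np.linspace(0.3, 0.6, 10)
        imp = compare_to_baseline(self._matrix(base, base + 0.2), 2)
        assert imp.global_class == "positive"
        assert imp.p_value < 0.01
        assert imp.class_percentages["positive"] == 100.0

    def test_requires_six_services(self):
        base = np.linspace(0.3, 0.6, 4)
        with pytest.raises(ValueError, match="at least 6"):
            compare_to_baseline(self._matrix(base, base), 2)

    def test_class_percentages_partition(self):
        base = np.linspace(0.3, 0.8, 12)
        rng = np.random.default_rng(0)
        scen = np.clip(base + rng.normal(0.05, 0.1, 12), 0.05, 1.0)
        imp = compare_to_baseline(self._matrix(base, scen), 2)
        assert sum(imp.class_percentages.values()) == pytest.approx(100.0)

    def _dist(self, mean, sd, n=50, seed=0, scenario_id=1):
        rng = np.random.default_rng(seed)
        s = np.clip(rng.normal(mean, sd, n), 1e-6, 1.0)
        return RTEDistribution("s", scenario_id, s, True)

    def test_zero_difference_neutral(self):
        d = self._dist(0.6, 0.01)
        assert classify_impact(d, d) == "neutral"

    def test_disjoint_shift_positive(self):
        a = self._dist(0.4, 0.005, seed=1)
        b = self._dist(0.8, 0.005, seed=2, scenario_id=2)
        assert classify_impact(a, b) == "positive"
        assert classify_impact(b, a) == "negative"

    def test_half_delta_shift_neutral(self):
        a = self._dist(0.6, 0.005, seed=3)
        b = self._dist(0.625, 0.005, seed=4, scenario_id=2)
        assert classify_impact(a, b, delta=0.05) == "neutral"
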