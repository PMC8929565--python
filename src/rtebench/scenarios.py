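"""Scenario definitions, study orchestration and quality-impact comparison.

A *scenario* is a named selection of DEA inputs and outputs. Scenario 1
(the baseline) uses only technical variables — inputs: places, staff per
user, budget per place; outputs: length of stay, occupancy %, movers per
place. Each further scenario adds exactly one quality-of-care domain
(scaled by service size) as a fourth output, so the quality protocol is
two-step: assess technical efficiency first, then measure how each quality
domain shifts it. Residential and supported-housing services have 8
scenarios; floating outreach has 7 (no living-environment domain).

Scenario score distributions are compared against the baseline with a
two-sided Wilcoxon signed-rank test paired at the service level, and each
service is classified as a positive / neutral / negative responder to a
quality domain by a documented mean-difference + significance rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .adequacy import KnowledgeBase
from .montecarlo import MCConfig, RTEDistribution, run_simulation
from .records import CareType, ServiceRecord, quirc_domains_for

__all__ = [
    "Scenario",
    "ImpactAssessment",
    "build_scenarios",
    "run_study",
    "compare_to_baseline",
    "classify_impact",
    "wilcoxon_signed_rank",
]

BASELINE_INPUTS = ("places", "staff_per_user", "budget_per_place")
BASELINE_OUTPUTS = ("length_of_stay", "occupancy_pct", "movers_per_place")

# Order in which quality domains extend the baseline, per care type.
_DOMAIN_ORDER = (
    "living_environment",
    "therapeutic_environment",
    "self_management_autonomy",
    "social_interface",
    "human_rights",
    "treatments_and_interventions",
    "recovery_based_practice",
)


@dataclass(frozen=True)
class Scenario:
    """One input/output variable selection for the efficiency assessment."""

    id: int
    label: str
    care_type: CareType
    inputs: tuple[str, ...]
    outputs: tuple[str, ...]

    @property
    def quality_domain(self) -> str | None:
        for o in self.outputs:
            if o.startswith("quality_"):
                return o.removeprefix("quality_")
        return None

    @property
    def is_baseline(self) -> bool:
        return self.quality_domain is None


def build_scenarios(care_type: CareType | str) -> list[Scenario]:
    """Baseline plus one scenario per applicable quality domain.

    8 scenarios for residential (both orientations) and supported housing,
    7 for floating outreach.
    """
    ct = CareType(care_type)
    applicable = set(quirc_domains_for(ct))
    scenarios = [
        Scenario(
            id=1,
            label="baseline (technical variables only)",
            care_type=ct,
            inputs=BASELINE_INPUTS,
            outputs=BASELINE_OUTPUTS,
        )
    ]
    next_id = 2
    for domain in _DOMAIN_ORDER:
        if domain not in applicable:
            continue
        scenarios.append(
            Scenario(
                id=next_id,
                label=f"baseline + {domain.replace('_', ' ')}",
                care_type=ct,
                inputs=BASELINE_INPUTS,
                outputs=BASELINE_OUTPUTS + (f"quality_{domain}",),
            )
        )
        next_id += 1
    return scenarios


def run_study(
    records: Sequence[ServiceRecord],
    kb: KnowledgeBase,
    scenarios: Sequence[Scenario],
    mc_config: MCConfig | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, int], RTEDistribution]]:
    """Run the Monte Carlo assessment for every scenario.

    Returns ``(matrix, distributions)``: the matrix has one row per service
    and one ``scenario_<id>`` column of mean scores, plus a trailing
    ``global_average`` row (the unweighted mean of service means); the dict
    keeps the full per-(service, scenario) score distributions for the
    statistical comparison. The baseline scenario is always run first.
    """
    cfg = mc_config or MCConfig()
    records = list(records)
    care_types = {r.care_type for r in records}
    if len(care_types) != 1:
        raise ValueError("run_study assesses one care type at a time")
    (ct,) = care_types
    for sc in scenarios:
        if sc.care_type is not ct:
            raise ValueError(
                f"scenario {sc.id} targets {sc.care_type.value}, records are {ct.value}"
            )
    ordered = sorted(scenarios, key=lambda s: (not s.is_baseline, s.id))

    distributions: dict[tuple[str, int], RTEDistribution] = {}
    columns: dict[str, list[float]] = {}
    ids = [r.service_id for r in records]
    for k, sc in enumerate(ordered):
        # independent, reproducible stream per scenario
        sub_cfg = MCConfig(
            variation=cfg.variation, n_max=cfg.n_max, stop_rel_se=cfg.stop_rel_se,
            seed=int(np.random.SeedSequence([cfg.seed, sc.id]).generate_state(1)[0] % (2**31)),
            min_sims=cfg.min_sims, batch=cfg.batch, max_retries=cfg.max_retries,
        )
        dists = run_simulation(records, sc, kb, sub_cfg)
        for sid, d in dists.items():
            distributions[(sid, sc.id)] = d
        columns[f"scenario_{sc.id}"] = [dists[sid].mean for sid in ids]

    matrix = pd.DataFrame(columns, index=pd.Index(ids, name="service_id"))
    matrix = matrix[[f"scenario_{s.id}" for s in sorted(scenarios, key=lambda s: s.id)]]
    matrix.loc["global_average"] = matrix.mean(axis=0)
    return matrix, distributions


def wilcoxon_signed_rank(
    baseline: np.ndarray, scenario: np.ndarray
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (Wilcoxon's original procedure); the null
    distribution is exact for n <= 25 remaining pairs and a tie-corrected
    normal approximation beyond. All pairs tied returns (0, 1): no evidence
    of any difference.
    """
    diff = np.asarray(scenario, dtype=float) - np.asarray(baseline, dtype=float)
    diff = diff[diff != 0.0]
    if diff.size == 0:
        return 0.0, 1.0
    method = "exact" if diff.size <= 25 else "approx"
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(diff, zero_method="wilcox", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class ImpactAssessment:
    """Scenario-vs-baseline comparison for one care type."""

    scenario_id: int
    statistic: float
    p_value: float
    mean_difference: float
    global_class: str
    per_service_class: Mapping[str, str]

    @property
    def class_percentages(self) -> dict[str, float]:
        counts = {"negative": 0, "neutral": 0, "positive": 0}
        for c in self.per_service_class.values():
            counts[c] += 1
        total = max(len(self.per_service_class), 1)
        return {k: 100.0 * v / total for k, v in counts.items()}


def compare_to_baseline(
    matrix: pd.DataFrame,
    scenario_id: int,
    distributions: Mapping[tuple[str, int], RTEDistribution] | None = None,
    *,
    baseline_id: int = 1,
    delta: float = 0.05,
    alpha: float = 0.05,
) -> ImpactAssessment:
    """Compare one quality scenario against the technical baseline.

    The test pairs per-service mean scores (one pair per service). The
    global class applies the same delta/significance rule to the global
    mean difference; per-service classes come from
    :func:`classify_impact` when the full distributions are supplied,
    otherwise from the mean difference alone.
    """
    b_col, s_col = f"scenario_{baseline_id}", f"scenario_{scenario_id}"
    for col in (b_col, s_col):
        if col not in matrix.columns:
            raise ValueError(f"column {col!r} missing from result matrix")
    services = [i for i in matrix.index if i != "global_average"]
    if len(services) < 6:
        raise ValueError("need at least 6 services for a meaningful paired test")
    base = matrix.loc[services, b_col].to_numpy()
    scen = matrix.loc[services, s_col].to_numpy()
    statistic, p = wilcoxon_signed_rank(base, scen)
    mean_diff = float(np.mean(scen - base))

    per_service: dict[str, str] = {}
    for sid, d in zip(services, scen - base):
        if distributions is not None:
            per_service[sid] = classify_impact(
                distributions[(sid, baseline_id)],
                distributions[(sid, scenario_id)],
                delta=delta,
                alpha=alpha,
            )
        else:
            per_service[sid] = (
                "positive" if d > delta else "negative" if d < -delta else "neutral"
            )

    if p < alpha and abs(mean_diff) > delta:
        global_class = "positive" if mean_diff > 0 else "negative"
    else:
        global_class = "neutral"
    return ImpactAssessment(
        scenario_id=scenario_id,
        statistic=statistic,
        p_value=p,
        mean_difference=mean_diff,
        global_class=global_class,
        per_service_class=per_service,
    )


def classify_impact(
    baseline: RTEDistribution,
    scenario: RTEDistribution,
    *,
    delta: float = 0.05,
    alpha: float = 0.05,
) -> str:
    """Classify one service's response to a quality domain.

    positive : mean difference > delta AND the two score samples differ
        significantly (two-sided Mann-Whitney at ``alpha``);
    negative : symmetric with mean difference < -delta;
    neutral  : everything else.
    """
    d = scenario.mean - baseline.mean
    if abs(d) <= delta:
        return "neutral"
    a, b = baseline.samples, scenario.samples
    if np.all(a == a[0]) and np.all(b == b[0]):
        # degenerate (zero-variance) samples: decide on the means alone
        significant = a[0] != b[0]
    else:
        significant = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue < alpha
    if not significant:
        return "neutral"
    return "positive" if d > 0 else "negative"
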