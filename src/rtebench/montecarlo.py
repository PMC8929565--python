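"""Monte Carlo uncertainty propagation for efficiency scores.

Real service data are imprecise (budgets shift, occupancy fluctuates), so
a single deterministic DEA run over-interprets the dataset. The engine
treats every raw variable as a symmetric triangular distribution centred
on its observed value with ±5% support, redraws the whole dataset each
iteration, re-derives rates, re-interprets them through the knowledge
base, re-solves DEA, and accumulates a distribution of efficiency scores
per service. Sampling stops once the relative standard error of every
service's mean score falls below 2.5% (checked from a minimum of 30
simulations, in batches of 10) or at the 500-simulation cap.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .adequacy import KnowledgeBase, transform_record
from .dea import DEAInstance, efficiency_scores
from .records import NUMERIC_FIELDS, ServiceRecord, derive_variables

__all__ = ["MCConfig", "RTEDistribution", "perturb", "run_simulation", "aggregate"]


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo engine settings.

    variation : half-width of the triangular perturbation as a fraction of
        the observed value (0.05 = ±5%).
    n_max : simulation cap (500 mirrors the published run count).
    stop_rel_se : stop when sd/(mean*sqrt(n)) <= this for every service.
    min_sims : minimum simulations before convergence is checked.
    batch : simulations between convergence checks.
    """

    variation: float = 0.05
    n_max: int = 500
    stop_rel_se: float = 0.025
    seed: int = 0
    min_sims: int = 30
    batch: int = 10
    max_retries: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.variation < 1.0:
            raise ValueError("variation must be in (0, 1)")
        if not self.n_max >= self.min_sims >= 2:
            raise ValueError("need n_max >= min_sims >= 2")
        if self.seed < 0:
            raise ValueError("seed must be nonnegative")


@dataclass(frozen=True)
class RTEDistribution:
    """Monte Carlo sample of efficiency scores for one (service, scenario)."""

    service_id: str
    scenario_id: int
    samples: np.ndarray
    converged: bool

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", s)
        if s.size and ((s <= 0).any() or (s > 1 + 1e-9).any()):
            raise ValueError("efficiency samples must lie in (0, 1]")

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def mean(self) -> float:
        return float(self.samples.mean())

    @property
    def sd(self) -> float:
        return float(self.samples.std(ddof=1)) if self.n > 1 else 0.0

    @property
    def rel_se(self) -> float:
        """Relative standard error of the mean: sd / (mean * sqrt(n))."""
        return self.sd / (self.mean * np.sqrt(self.n)) if self.n else np.inf


def perturb(
    values: np.ndarray, variation: float, rng: np.random.Generator
) -> np.ndarray:
    """Symmetric triangular perturbation: each value v is replaced by a draw
    with mode v on [v(1-variation), v(1+variation)]. Zeros stay zero (the
    support is multiplicative and collapses)."""
    if not 0.0 < variation < 1.0:
        raise ValueError("variation must be in (0, 1)")
    v = np.asarray(values, dtype=float)
    if not np.isfinite(v).all() or (v < 0).any():
        raise ValueError("values must be finite and nonnegative")
    factors = rng.triangular(1.0 - variation, 1.0, 1.0 + variation, size=v.shape)
    return v * factors


def _perturb_record(
    record: ServiceRecord, variation: float, rng: np.random.Generator
) -> ServiceRecord:
    """Perturb every raw numeric variable of a record (quality scores
    included). Rates are derived *after* perturbation so they inherit
    coherent noise; integer fields are perturbed continuously because only
    the derived rates enter DEA."""
    raw = np.array([getattr(record, f) for f in NUMERIC_FIELDS])
    pert = perturb(raw, variation, rng)
    updates = dict(zip(NUMERIC_FIELDS, pert))
    qkeys = sorted(record.quirc)
    qvals = perturb(np.array([record.quirc[k] for k in qkeys]), variation, rng)
    updates["quirc"] = {k: float(min(v, 100.0)) for k, v in zip(qkeys, qvals)}
    # keep the occupancy invariant under independent noise
    updates["occupied_places"] = float(
        min(updates["occupied_places"], updates["places"])
    )
    return replace(record, **{k: (v if k == "quirc" else float(v)) for k, v in updates.items()})


def run_simulation(
    records: Sequence[ServiceRecord],
    scenario,
    kb: KnowledgeBase,
    mc_config: MCConfig | None = None,
) -> dict[str, RTEDistribution]:
    """Monte Carlo efficiency assessment of one scenario.

    Each iteration draws a perturbed copy of every record, derives rates,
    interprets them through the knowledge base, and solves the
    input-oriented VRS DEA; the per-service scores are accumulated until
    the stopping rule fires. Fully reproducible under ``mc_config.seed``.
    """
    cfg = mc_config or MCConfig()
    records = list(records)
    if len(records) < 2:
        raise ValueError("need at least 2 services for a relative assessment")
    ids = [r.service_id for r in records]
    # one stream per (seed, iteration, service identity): results do not
    # depend on the order services are listed in
    digests = [zlib.crc32(sid.encode()) for sid in ids]
    samples: list[list[float]] = [[] for _ in records]

    n = 0
    converged = False
    while n < cfg.n_max:
        theta = _one_iteration(records, scenario, kb, cfg, n, digests)
        for k, t in enumerate(theta):
            samples[k].append(t)
        n += 1
        if n >= cfg.min_sims and n % cfg.batch == 0:
            if _all_converged(samples, cfg.stop_rel_se):
                converged = True
                break
    if not converged:
        converged = _all_converged(samples, cfg.stop_rel_se)

    return {
        sid: RTEDistribution(
            service_id=sid,
            scenario_id=getattr(scenario, "id", 0),
            samples=np.array(s),
            converged=converged,
        )
        for sid, s in zip(ids, samples)
    }


def _one_iteration(records, scenario, kb, cfg, iteration, digests) -> np.ndarray:
    last_err: Exception | None = None
    for attempt in range(cfg.max_retries + 1):
        try:
            perturbed = [
                _perturb_record(
                    r, cfg.variation,
                    np.random.default_rng(
                        np.random.SeedSequence([cfg.seed, iteration, attempt, dig])
                    ),
                )
                for r, dig in zip(records, digests)
            ]
            X, Y = [], []
            for r in perturbed:
                xi, yi = transform_record(kb, derive_variables(r), scenario)
                X.append(xi)
                Y.append(yi)
            inst = DEAInstance(X=np.array(X), Y=np.array(Y),
                               labels=tuple(r.service_id for r in records))
            return efficiency_scores(inst)
        except (RuntimeError, ValueError) as exc:  # solver hiccup: redraw
            last_err = exc
    raise RuntimeError(
        f"DEA failed for {cfg.max_retries + 1} consecutive redraws: {last_err}"
    )


def _all_converged(samples: list[list[float]], stop_rel_se: float) -> bool:
    for s in samples:
        arr = np.asarray(s)
        mean = arr.mean()
        sd = arr.std(ddof=1)
        if sd / (mean * np.sqrt(arr.size)) > stop_rel_se:
            return False
    return True


def aggregate(distribution: RTEDistribution) -> dict[str, float]:
    """Summary row for one score distribution: mean, sd, relative SE,
    2.5/50/97.5% quantiles and the convergence flag."""
    if distribution.n < 1:
        raise ValueError("empty sample")
    s = distribution.samples
    q = np.percentile(s, [2.5, 50, 97.5])
    return {
        "service_id": distribution.service_id,
        "scenario_id": distribution.scenario_id,
        "n": distribution.n,
        "mean": distribution.mean,
        "sd": distribution.sd,
        "rel_se": distribution.rel_se,
        "q2.5": float(q[0]),
        "q50": float(q[1]),
        "q97.5": float(q[2]),
        "converged": distribution.converged,
    }
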