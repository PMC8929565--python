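"""Synthetic service cohorts and known-efficiency frontier fixtures.

Two generators live here:

* :func:`generate_services` draws service cohorts whose per-care-type
  means, standard deviations and ranges match the published descriptive
  statistics of the QuEST national sample of supported accommodation
  services (:func:`quest_presets`), so every pipeline stage can be
  exercised without the restricted study dataset;
* :func:`generate_frontier_cohort` constructs DEA instances with *known*
  true efficiencies: frontier DMUs are placed on a monotone concave VRS
  frontier and inefficient DMUs are frontier points with all inputs
  inflated by ``1/theta``, so input-oriented VRS DEA must recover exactly
  ``theta`` — the package's parameter-recovery anchor.

Each variable is drawn from a normal distribution truncated at the
published (min, max) — the four statistics the sample description prints
are exactly a truncated normal's natural parameters. Occupied places are
generated jointly with places (an occupancy fraction times places) so the
``occupied <= places`` invariant holds by construction. Variables are
independent across fields by default; an optional Gaussian-copula rank
correlation couples places with budget and occupancy for added realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import stats

from .records import CareType, ServiceRecord, quirc_domains_for

__all__ = [
    "VariableSpec",
    "SyntheticSpec",
    "FrontierCohortSpec",
    "quest_presets",
    "generate_services",
    "generate_frontier_cohort",
]


@dataclass(frozen=True)
class VariableSpec:
    """Truncated-normal parameters for one variable: mean/sd of the parent
    normal are set to the published sample mean/sd; support is [min, max]."""

    mean: float
    sd: float
    min: float
    max: float
    integer: bool = False

    def __post_init__(self) -> None:
        if self.min > self.max:
            raise ValueError(f"unsatisfiable spec: min {self.min} > max {self.max}")
        if not (self.min <= self.mean <= self.max):
            raise ValueError(
                f"spec mean {self.mean} outside [{self.min}, {self.max}]"
            )
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.sd == 0 or self.min == self.max:
            vals = np.full(n, self.mean)
        else:
            # moment-matched parent parameters: plugging the published
            # (mean, sd) straight into loc/scale would shift the *truncated*
            # moments whenever the bounds are asymmetric around the mean
            mu, sigma = _matched_truncnorm_params(
                self.mean, self.sd, self.min, self.max
            )
            a = (self.min - mu) / sigma
            b = (self.max - mu) / sigma
            vals = stats.truncnorm.rvs(
                a, b, loc=mu, scale=sigma, size=n, random_state=rng
            )
        if self.integer:
            vals = np.clip(np.rint(vals), self.min, self.max)
        return vals


@lru_cache(maxsize=512)
def _matched_truncnorm_params(
    mean: float, sd: float, lo: float, hi: float
) -> tuple[float, float]:
    """Parent (mu, sigma) whose [lo, hi]-truncated normal has the target
    mean and sd (least-squares moment matching; falls back to the naive
    parameters if the target moments are unattainable on the support)."""

    def residual(p):
        mu, s = p
        a, b = (lo - mu) / s, (hi - mu) / s
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=s, moments="mv")
        return [float(m) - mean, float(np.sqrt(v)) - sd]

    try:
        from scipy.optimize import least_squares

        res = least_squares(
            residual, x0=[mean, sd],
            bounds=([lo - 10 * (hi - lo), 1e-9 * (hi - lo)],
                    [hi + 10 * (hi - lo), 100 * (hi - lo)]),
        )
        # always accept the optimum: the naive parameters are the starting
        # point, so the fit can only improve on them; for heavily skewed
        # variables whose published (mean, sd) no truncated normal on [lo, hi]
        # attains exactly, this is the closest member of the family
        if res.success:
            return float(res.x[0]), float(res.x[1])
    except Exception:  # pragma: no cover - solver pathologies only
        pass
    return mean, sd


@dataclass(frozen=True)
class SyntheticSpec:
    """Per-care-type distributional parameters for a synthetic cohort.

    ``variables[care_type][name]`` are :class:`VariableSpec`;
    ``quality[care_type][domain]`` are (mean, sd) of 0-100 truncated
    normals; ``occupancy_fraction[care_type]`` is the (mean, sd) of the
    occupied/places fraction, truncated to [0, 1].
    """

    variables: Mapping[str, Mapping[str, VariableSpec]]
    quality: Mapping[str, Mapping[str, tuple[float, float]]]
    occupancy_fraction: Mapping[str, tuple[float, float]]
    correlate: bool = False

    def for_care_type(self, care_type: CareType | str) -> Mapping[str, VariableSpec]:
        ct = CareType(care_type).value
        if ct not in self.variables:
            raise ValueError(f"spec does not cover care type {ct!r}")
        return self.variables[ct]

    def to_yaml(self) -> str:
        doc = {
            "variables": {
                ct: {
                    name: {
                        "mean": vs.mean, "sd": vs.sd, "min": vs.min,
                        "max": vs.max, "integer": vs.integer,
                    }
                    for name, vs in per_ct.items()
                }
                for ct, per_ct in self.variables.items()
            },
            "quality": {
                ct: {d: list(ms) for d, ms in per_ct.items()}
                for ct, per_ct in self.quality.items()
            },
            "occupancy_fraction": {
                ct: list(ms) for ct, ms in self.occupancy_fraction.items()
            },
            "correlate": self.correlate,
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SyntheticSpec":
        doc = yaml.safe_load(text)
        return cls(
            variables={
                ct: {
                    name: VariableSpec(
                        mean=v["mean"], sd=v["sd"], min=v["min"], max=v["max"],
                        integer=bool(v.get("integer", False)),
                    )
                    for name, v in per_ct.items()
                }
                for ct, per_ct in doc["variables"].items()
            },
            quality={
                ct: {d: tuple(ms) for d, ms in per_ct.items()}
                for ct, per_ct in doc["quality"].items()
            },
            occupancy_fraction={
                ct: tuple(ms) for ct, ms in doc["occupancy_fraction"].items()
            },
            correlate=bool(doc.get("correlate", False)),
        )


# Published sample statistics (mean, sd, min, max) per care type for the
# variables entering the efficiency assessment. Staff is full-time-equivalent
# professionals per service user; budget is the total annual budget in GBP.
# The published floating-outreach occupied-places maximum (6) contradicts its
# own mean of 28.89 and is almost certainly a typo; occupancy is therefore
# generated as a fraction of places (see module docstring) and its ceiling is
# the places maximum.
_QUEST_STATS: dict[str, dict[str, tuple[float, float, float, float, bool]]] = {
    "residential_non_move_on": {
        "places": (21.26, 7.12, 9, 40, True),
        "staff_fte_per_user": (0.66, 0.31, 0.34, 1.66, False),
        "annual_budget": (500_623.10, 167_559.51, 211_897.40, 941_766.23, False),
        "length_of_stay": (10.0, 5.42, 4, 20, False),
        "occupied_places": (19.68, 7.46, 8, 37, True),
        "movers_2yr": (0.58, 0.69, 0, 2, True),
    },
    "residential_move_on": {
        "places": (15.67, 7.52, 7, 27, True),
        "staff_fte_per_user": (0.83, 0.56, 0.46, 2.25, False),
        "annual_budget": (386_467.36, 285_133.49, 265_535.16, 1_024_207.06, False),
        "length_of_stay": (3.13, 1.55, 2, 6, False),
        "occupied_places": (11.56, 5.41, 7, 23, True),
        "movers_2yr": (6.22, 3.46, 2, 12, True),
    },
    "supported_housing": {
        "places": (10.99, 5.11, 3, 28, True),
        "staff_fte_per_user": (0.45, 0.27, 0.10, 1.61, False),
        "annual_budget": (334_635.12, 155_682.08, 91_363.00, 852_721.33, False),
        "length_of_stay": (3.24, 2.97, 1, 20, False),
        "occupied_places": (10.27, 5.15, 1, 28, True),
        "movers_2yr": (5.63, 6.84, 0, 40, True),
    },
    "floating_outreach": {
        "places": (29.97, 22.90, 5, 80, True),
        "staff_fte_per_user": (0.17, 0.17, 0.03, 0.97, False),
        "annual_budget": (171_950.08, 131_354.68, 28_685.67, 458_970.67, False),
        "length_of_stay": (2.83, 2.16, 1, 9, False),
        "occupied_places": (28.89, 23.02, 4, 80, True),  # max 6 in print: typo
        "movers_2yr": (13.0, 16.49, 0, 75, True),
    },
}

#: Study sample sizes per care type (services with complete quality data).
QUEST_SAMPLE_SIZES: dict[str, int] = {
    "residential_move_on": 9,
    "residential_non_move_on": 13,
    "supported_housing": 34,
    "floating_outreach": 30,
}

# Quality domain score distribution (mean, sd) on the 0-100 scale. The
# source sample reports no per-domain statistics; mid-60s means with
# moderate spread reflect the published finding that supported housing
# scored highest and floating outreach lowest on quality of care.
_QUALITY_MEANS = {
    "residential_non_move_on": (58.0, 14.0),
    "residential_move_on": (60.0, 14.0),
    "supported_housing": (65.0, 12.0),
    "floating_outreach": (55.0, 13.0),
}


def quest_presets() -> SyntheticSpec:
    """Built-in :class:`SyntheticSpec` matching the published per-care-type
    (mean, sd, min, max) of every assessment variable."""
    variables = {
        ct: {
            name: VariableSpec(mean=m, sd=s, min=lo, max=hi, integer=integer)
            for name, (m, s, lo, hi, integer) in per_ct.items()
        }
        for ct, per_ct in _QUEST_STATS.items()
    }
    quality = {
        ct: {d: _QUALITY_MEANS[ct] for d in quirc_domains_for(ct)}
        for ct in _QUEST_STATS
    }
    occupancy_fraction = {}
    for ct, per_ct in _QUEST_STATS.items():
        occ = per_ct["occupied_places"]
        pl = per_ct["places"]
        mean_frac = min(occ[0] / pl[0], 1.0)
        sd_frac = 0.1
        occupancy_fraction[ct] = (mean_frac, sd_frac)
    return SyntheticSpec(
        variables=variables,
        quality=quality,
        occupancy_fraction=occupancy_fraction,
    )


def generate_services(
    care_type: CareType | str,
    n: int,
    spec: SyntheticSpec | None = None,
    seed: int | None = None,
) -> list[ServiceRecord]:
    """Draw ``n`` synthetic service records of one care type.

    Every variable respects its spec bounds with probability 1 (truncated
    sampling, integer fields rounded then re-clipped); occupied places are
    an occupancy fraction times places, so ``occupied <= places`` always
    holds. Deterministic under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ct = CareType(care_type)
    spec = spec or quest_presets()
    rng = np.random.default_rng(seed)
    vars_ct = spec.for_care_type(ct)

    places = vars_ct["places"].draw(n, rng)
    staff = vars_ct["staff_fte_per_user"].draw(n, rng)
    budget = vars_ct["annual_budget"].draw(n, rng)
    stay = vars_ct["length_of_stay"].draw(n, rng)
    movers = vars_ct["movers_2yr"].draw(n, rng)

    if spec.correlate:
        # couple budget and staff with places through a shared rank order
        order = np.argsort(np.argsort(places))
        budget = np.sort(budget)[order]
        staff = np.sort(staff)[order]

    f_mean, f_sd = spec.occupancy_fraction[ct.value]
    a = (0.0 - f_mean) / f_sd
    b = (1.0 - f_mean) / f_sd
    frac = stats.truncnorm.rvs(a, b, loc=f_mean, scale=f_sd, size=n, random_state=rng)
    occ_spec = vars_ct["occupied_places"]
    occupied = np.minimum(np.rint(frac * places), places)
    occupied = np.maximum(occupied, min(occ_spec.min, places.min()))
    occupied = np.minimum(occupied, places)

    domains = quirc_domains_for(ct)
    qdraws = {}
    for d in domains:
        qm, qs = spec.quality[ct.value][d]
        qa, qb = (0.0 - qm) / qs, (100.0 - qm) / qs
        qdraws[d] = stats.truncnorm.rvs(
            qa, qb, loc=qm, scale=qs, size=n, random_state=rng
        )

    records = []
    for k in range(n):
        records.append(
            ServiceRecord(
                service_id=f"{ct.value}_{k:03d}",
                care_type=ct,
                places=float(places[k]),
                staff_fte_per_user=float(staff[k]),
                annual_budget=float(budget[k]),
                length_of_stay=float(stay[k]),
                occupied_places=float(occupied[k]),
                movers_2yr=float(movers[k]),
                quirc={d: float(qdraws[d][k]) for d in domains},
            )
        )
    return records


@dataclass(frozen=True)
class FrontierCohortSpec:
    """Specification of a known-truth DEA recovery fixture."""

    n_frontier: int = 5
    true_theta: tuple[float, ...] = (0.3, 0.5, 0.7, 0.9)
    n_inputs: int = 1
    n_outputs: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frontier < 2:
            raise ValueError("need at least 2 frontier DMUs")
        for t in self.true_theta:
            if not 0.0 < t <= 1.0:
                raise ValueError(f"true theta must be in (0, 1], got {t}")


def generate_frontier_cohort(
    spec: FrontierCohortSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Construct ``(X, Y, true_theta)`` with known input-oriented VRS scores.

    Frontier DMUs sit on a strictly convex increasing input-requirement
    curve ``x(y)`` (equivalently a concave production frontier), so each is
    the unique cheapest way to reach its output level and is efficient.
    Each inefficient DMU copies a frontier point and divides all inputs by
    its true theta; radial contraction by exactly theta returns it to the
    frontier, so DEA on the pooled cohort must score it theta (to solver
    tolerance). Multi-input cohorts scale a strictly positive input-mix
    vector per DMU; multi-output cohorts spread the output level over
    components.
    """
    rng = np.random.default_rng(spec.seed)
    nf = spec.n_frontier
    y_levels = np.linspace(1.0, 2.0 + nf, nf)
    x_levels = 1.0 + 0.15 * y_levels**2  # convex increasing input requirement

    mix_in = rng.uniform(0.8, 1.2, spec.n_inputs)
    mix_in /= mix_in.mean()
    mix_out = rng.uniform(0.8, 1.2, spec.n_outputs)
    mix_out /= mix_out.mean()

    Xf = np.outer(x_levels, mix_in)
    Yf = np.outer(y_levels, mix_out)

    # anchor inefficient DMUs to interior frontier points: a DMU anchored at
    # the extreme output level can exit the spanned output range under small
    # perturbations and flip to self-referent efficiency
    lo_a, hi_a = (1, nf - 1) if nf > 2 else (0, nf)
    anchors = rng.integers(lo_a, hi_a, size=len(spec.true_theta))
    Xi = np.array([Xf[a] / t for a, t in zip(anchors, spec.true_theta)])
    Yi = np.array([Yf[a] for a in anchors])

    X = np.vstack([Xf, Xi]) if len(spec.true_theta) else Xf
    Y = np.vstack([Yf, Yi]) if len(spec.true_theta) else Yf
    truth = np.concatenate([np.ones(nf), np.asarray(spec.true_theta, dtype=float)])
    return X, Y, truth
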