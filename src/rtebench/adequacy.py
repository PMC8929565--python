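"""Fuzzy inference engine: expert interpretation of variable values.

DEA is operationally blind — a budget of £5,500 per place is just a number
to the LP. Before efficiency is assessed, each variable value is
*interpreted* against an expert knowledge base: every rule carries an
adequacy range ``[lo, hi]`` (values inside are considered appropriate for
that care type), a direction, and a penalty multiplier applied when the
value falls outside the range.

The interpretation produces a *competence* score on a common (0, 1] scale:

* inside the range, a linear monotone map onto [0.5, 1] oriented by the
  rule's direction (``target_band`` maps distance from the band centre);
* outside, the competence of the nearest bound is divided by the penalty
  factor (default 2) and decays further with normalised distance from the
  range, so out-of-range values always score at or below in-range ones;
* alternatively, a ``product_sum_gravity`` rule defuzzifies labelled
  membership functions by their activation-weighted centre of gravity.

Competences are then made DEA-ready: outputs keep "larger = better"
(competence times a fixed scale constant); inputs are inverted
(reciprocal of competence, floored) so that "smaller = better" holds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .records import CareType, DerivedVariables, quirc_domains_for

__all__ = [
    "FuzzySet",
    "AdequacyRule",
    "KnowledgeBase",
    "PASS_THROUGH",
    "compile_knowledge_base",
    "default_knowledge_base",
    "transform_value",
    "transform_record",
]

#: Marker for variables analysed raw (no interpretation).
PASS_THROUGH = "pass_through"

#: Competence floor: interpreted values never reach exactly zero, keeping
#: DEA data strictly positive no matter how far outside the range.
COMPETENCE_FLOOR = 1e-3

#: Floor on competence before input inversion (bounds DEA inputs above).
INPUT_INVERSION_FLOOR = 0.05

#: Fixed scale constant for DEA outputs (competence * scale).
OUTPUT_SCALE = 100.0


@dataclass(frozen=True)
class FuzzySet:
    """A labelled membership function with a consequent competence level.

    ``breakpoints`` parameterise a triangular (3 points) or trapezoidal
    (4 points) membership function; ``consequent`` is the competence the
    rule asserts when the set is fully activated.
    """

    label: str
    breakpoints: tuple[float, ...]
    consequent: float

    def __post_init__(self) -> None:
        bp = tuple(float(b) for b in self.breakpoints)
        object.__setattr__(self, "breakpoints", bp)
        if len(bp) not in (3, 4):
            raise ValueError(f"fuzzy set {self.label!r}: need 3 or 4 breakpoints")
        if list(bp) != sorted(bp):
            raise ValueError(f"fuzzy set {self.label!r}: breakpoints must be sorted")
        if not 0.0 < self.consequent <= 1.0:
            raise ValueError(f"fuzzy set {self.label!r}: consequent must be in (0, 1]")

    def membership(self, x: float) -> float:
        bp = self.breakpoints
        if len(bp) == 3:
            a, b, c = bp
            if x <= a or x >= c:
                # degenerate shoulders (a == b or b == c) are full at the peak
                if x == b:
                    return 1.0
                return 0.0
            if x <= b:
                return 1.0 if a == b else (x - a) / (b - a)
            return 1.0 if b == c else (c - x) / (c - b)
        a, b, c, d = bp
        if x < a or x > d:
            return 0.0
        if x < b:
            return (x - a) / (b - a) if a != b else 1.0
        if x <= c:
            return 1.0
        return (d - x) / (d - c) if c != d else 1.0


@dataclass(frozen=True)
class AdequacyRule:
    """Expert interpretation of one variable for one care type."""

    care_type: CareType
    variable: str
    role: str  # "input" | "output"
    adequate_range: tuple[float, float]
    direction: str = "higher_better"  # | "lower_better" | "target_band"
    penalty_factor: float = 2.0
    transform_kind: str = "linear_monotone"  # | "product_sum_gravity"
    fuzzy_sets: tuple[FuzzySet, ...] = ()
    penalty_slope: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "care_type", CareType(self.care_type))
        lo, hi = (float(v) for v in self.adequate_range)
        object.__setattr__(self, "adequate_range", (lo, hi))
        if lo >= hi:
            raise ValueError(
                f"rule ({self.care_type.value}, {self.variable}): lo >= hi"
            )
        if self.role not in ("input", "output"):
            raise ValueError(f"rule role must be 'input' or 'output', got {self.role!r}")
        if self.direction not in ("higher_better", "lower_better", "target_band"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.penalty_factor < 1.0:
            raise ValueError("penalty_factor must be >= 1")
        if self.transform_kind not in ("linear_monotone", "product_sum_gravity"):
            raise ValueError(f"unknown transform_kind {self.transform_kind!r}")
        if self.transform_kind == "product_sum_gravity" and not self.fuzzy_sets:
            raise ValueError("product_sum_gravity rules need fuzzy sets")

    @property
    def key(self) -> tuple[CareType, str]:
        return (self.care_type, self.variable)


@dataclass(frozen=True)
class KnowledgeBase:
    """Immutable set of adequacy rules keyed by (care_type, variable).

    ``provenance`` records where the ranges come from — in practice either
    an expert consensus panel or the data-derived stand-in built by
    :func:`default_knowledge_base`.
    """

    rules: Mapping[tuple[CareType, str], AdequacyRule]
    pass_through: frozenset[str] = frozenset()
    provenance: str = "unspecified"

    def resolve(self, care_type: CareType, variable: str) -> AdequacyRule | str:
        rule = self.rules.get((CareType(care_type), variable))
        if rule is not None:
            return rule
        if variable in self.pass_through or variable.startswith("quality_"):
            # scaled quality scores are already on an interpreted 0-100*places
            # scale; by default they pass through unless a rule says otherwise
            return PASS_THROUGH
        raise KeyError(
            f"no adequacy rule or pass-through marker for "
            f"({CareType(care_type).value}, {variable})"
        )


def compile_knowledge_base(config: str | dict) -> KnowledgeBase:
    """Build a :class:`KnowledgeBase` from a YAML string/path or parsed dict.

    Schema::

        provenance: expert-panel 2014
        pass_through: [places]
        rules:
          - care_type: floating_outreach
            variable: budget_per_place
            role: input
            adequate_range: [5000, 6000]
            direction: higher_better
            penalty_factor: 2
            transform_kind: linear_monotone
    """
    if isinstance(config, dict):
        data = config
    else:
        text = config
        try:
            import os
            if os.path.exists(str(config)):
                with open(config) as fh:
                    text = fh.read()
        except (OSError, ValueError):
            pass
        data = yaml.safe_load(text) or {}
    rules: dict[tuple[CareType, str], AdequacyRule] = {}
    for raw in data.get("rules", []) or []:
        fs = tuple(
            FuzzySet(s["label"], tuple(s["breakpoints"]), float(s["consequent"]))
            for s in raw.get("fuzzy_sets", []) or []
        )
        rule = AdequacyRule(
            care_type=raw["care_type"],
            variable=raw["variable"],
            role=raw["role"],
            adequate_range=tuple(raw["adequate_range"]),
            direction=raw.get("direction", "higher_better"),
            penalty_factor=float(raw.get("penalty_factor", 2.0)),
            transform_kind=raw.get("transform_kind", "linear_monotone"),
            fuzzy_sets=fs,
            penalty_slope=float(raw.get("penalty_slope", 1.0)),
        )
        if rule.key in rules:
            raise ValueError(
                f"duplicate rule for ({rule.care_type.value}, {rule.variable})"
            )
        rules[rule.key] = rule
    if not rules:
        warnings.warn(
            "empty knowledge base: all variables will pass through uninterpreted",
            stacklevel=2,
        )
    return KnowledgeBase(
        rules=rules,
        pass_through=frozenset(data.get("pass_through", []) or []),
        provenance=str(data.get("provenance", "unspecified")),
    )


# Direction conventions for the data-derived stand-in knowledge base.
# Inputs follow the published example (inside the adequate range, a greater
# value corresponds to better competence); length of stay is a target band
# for time-limited care types, where staying much beyond the expected two
# years signals a blocked pathway, and passes through where placements are
# not time-limited.
_DEFAULT_DIRECTIONS = {
    "budget_per_place": ("input", "higher_better"),
    "places": ("input", "higher_better"),
    "staff_per_user": ("input", "higher_better"),
    "occupancy_pct": ("output", "higher_better"),
    "movers_per_place": ("output", "higher_better"),
    "length_of_stay": ("output", "target_band"),
}

_TIME_LIMITED = frozenset(
    {CareType.SUPPORTED_HOUSING, CareType.FLOATING_OUTREACH, CareType.RESIDENTIAL_MOVE_ON}
)

#: Expected tenancy band (years) for time-limited care types.
DEFAULT_STAY_BAND = (1.0, 2.0)


def default_knowledge_base(records: Sequence, *, min_records: int = 5) -> KnowledgeBase:
    """Data-derived stand-in knowledge base.

    The expert consensus ranges behind the original analysis are not
    published, so this builds a documented substitute: per (care_type,
    variable), the adequate range is the empirical interquartile range of
    the derived variable, the direction follows a fixed table
    (``movers_per_place`` higher-is-better, ``length_of_stay`` a target
    band around the expected two-year tenancy for time-limited types), and
    the penalty factor is 2. Provenance is marked ``data-derived stand-in``.
    """
    from .records import derive_variables

    by_type: dict[CareType, list] = {}
    for r in records:
        by_type.setdefault(r.care_type, []).append(r)
    rules: dict[tuple[CareType, str], AdequacyRule] = {}
    for ct, group in by_type.items():
        if len(group) < min_records:
            raise ValueError(
                f"need at least {min_records} records per care type to derive "
                f"a knowledge base; {ct.value} has {len(group)}"
            )
        derived = [derive_variables(r).as_dict() for r in group]
        for var, (role, direction) in _DEFAULT_DIRECTIONS.items():
            if var == "length_of_stay":
                if ct not in _TIME_LIMITED:
                    continue  # pass-through: placements not time-limited
                lo, hi = DEFAULT_STAY_BAND
            else:
                vals = np.array([d[var] for d in derived], dtype=float)
                lo, hi = np.percentile(vals, [25, 75])
                if hi - lo < 1e-9:  # degenerate spread: widen symmetrically
                    pad = max(abs(lo) * 0.1, 1e-6)
                    lo, hi = lo - pad, hi + pad
            rules[(ct, var)] = AdequacyRule(
                care_type=ct,
                variable=var,
                role=role,
                adequate_range=(float(lo), float(hi)),
                direction=direction,
                penalty_factor=2.0,
            )
    return KnowledgeBase(
        rules=rules,
        pass_through=frozenset({"length_of_stay"}),
        provenance="data-derived stand-in",
    )


def transform_value(rule: AdequacyRule, x: float) -> float:
    """Interpret a variable value: map it to a competence in (0, 1].

    Inside ``[lo, hi]``, a linear monotone map onto [0.5, 1] oriented by
    the rule's direction (for ``target_band``, competence peaks at the band
    centre and falls to 0.5 at the edges). Outside, the nearest bound's
    competence is divided by ``penalty_factor`` and decays hyperbolically
    with the distance from the range (normalised by the range width), so
    the transform is monotone away from the range and bounded below by
    :data:`COMPETENCE_FLOOR`.
    """
    if not np.isfinite(x) or x < 0:
        raise ValueError(f"variable value must be finite and nonnegative, got {x}")
    if rule.transform_kind == "product_sum_gravity":
        return _product_sum_gravity(rule, x)
    lo, hi = rule.adequate_range
    if lo <= x <= hi:
        return _in_range_competence(rule, x)
    bound = lo if x < lo else hi
    c_bound = _in_range_competence(rule, bound)
    dist = (lo - x if x < lo else x - hi) / (hi - lo)
    c = (c_bound / rule.penalty_factor) / (1.0 + rule.penalty_slope * dist)
    return max(c, COMPETENCE_FLOOR)


def _in_range_competence(rule: AdequacyRule, x: float) -> float:
    lo, hi = rule.adequate_range
    t = (x - lo) / (hi - lo)
    if rule.direction == "higher_better":
        return 0.5 + 0.5 * t
    if rule.direction == "lower_better":
        return 1.0 - 0.5 * t
    centre = 0.5 * (lo + hi)
    half = 0.5 * (hi - lo)
    return 1.0 - 0.5 * abs(x - centre) / half


def _product_sum_gravity(rule: AdequacyRule, x: float) -> float:
    """Centre-of-gravity defuzzification of product-activated consequents.

    Each labelled set's activation is its membership at ``x`` (with a single
    antecedent the product reduces to the membership itself); activations
    are sum-aggregated and the competence is the activation-weighted mean of
    the consequent levels.
    """
    acts = np.array([s.membership(x) for s in rule.fuzzy_sets])
    cons = np.array([s.consequent for s in rule.fuzzy_sets])
    total = acts.sum()
    if total <= 0.0:
        # outside every set's support: treat like an out-of-range value,
        # penalising the nearest set's consequent
        lo = min(s.breakpoints[0] for s in rule.fuzzy_sets)
        hi = max(s.breakpoints[-1] for s in rule.fuzzy_sets)
        edge = lo if x < lo else hi
        nearest = min(rule.fuzzy_sets, key=lambda s: min(abs(x - b) for b in s.breakpoints))
        dist = abs(x - edge) / max(hi - lo, 1e-12)
        c = (nearest.consequent / rule.penalty_factor) / (1.0 + rule.penalty_slope * dist)
        return max(c, COMPETENCE_FLOOR)
    return float(acts @ cons / total)


def transform_record(
    kb: KnowledgeBase,
    derived: DerivedVariables,
    scenario,
) -> tuple[np.ndarray, np.ndarray]:
    """Interpret a service's derived variables for one scenario.

    Returns DEA-ready ``(inputs, outputs)`` vectors: outputs are competences
    scaled by :data:`OUTPUT_SCALE` (larger = better), inputs are inverted
    competences ``1 / max(c, floor)`` (smaller = better), and pass-through
    variables enter raw. All input entries are strictly positive.
    """
    values = derived.as_dict()
    inputs = []
    for name in scenario.inputs:
        x = values[name]
        resolved = _resolve(kb, scenario.care_type, name)
        if resolved is PASS_THROUGH or resolved == PASS_THROUGH:
            v = float(x)
        else:
            c = transform_value(resolved, x)
            v = 1.0 / max(c, INPUT_INVERSION_FLOOR)
        if v <= 0:
            raise ValueError(f"nonpositive DEA input for {name!r}: {v}")
        inputs.append(v)
    outputs = []
    for name in scenario.outputs:
        x = values[name]
        resolved = _resolve(kb, scenario.care_type, name)
        if resolved is PASS_THROUGH or resolved == PASS_THROUGH:
            v = float(x)
        else:
            v = OUTPUT_SCALE * transform_value(resolved, x)
        if v < 0:
            raise ValueError(f"negative DEA output for {name!r}: {v}")
        outputs.append(v)
    return np.asarray(inputs), np.asarray(outputs)


def _resolve(kb: KnowledgeBase, care_type: CareType, variable: str):
    return kb.resolve(care_type, variable)
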