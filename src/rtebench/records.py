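"""Service data model, derived rate variables, tabular IO and imputation.

A *service record* holds the raw resources, outcomes and quality-of-care
scores of one supported accommodation service. DEA never sees these raw
fields directly: they are first converted into per-place / per-user rates
(:func:`derive_variables`) so that services of very different sizes become
comparable, and quality-domain scores are rescaled by service size
(``score * places / 100``) so that a given quality level "counts" more in a
larger service.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CareType",
    "QUIRC_DOMAINS",
    "quirc_domains_for",
    "ServiceRecord",
    "DerivedVariables",
    "derive_variables",
    "load_services",
    "save_services",
    "records_to_frame",
    "impute_missing",
]


class CareType(str, Enum):
    """The three main types of supported accommodation, with residential care
    split into move-on oriented and non-move-on oriented subgroups."""

    RESIDENTIAL_MOVE_ON = "residential_move_on"
    RESIDENTIAL_NON_MOVE_ON = "residential_non_move_on"
    SUPPORTED_HOUSING = "supported_housing"
    FLOATING_OUTREACH = "floating_outreach"


#: QuIRC-SA quality-of-care domains, each scored 0-100 by the service manager.
QUIRC_DOMAINS: tuple[str, ...] = (
    "living_environment",
    "therapeutic_environment",
    "treatments_and_interventions",
    "self_management_autonomy",
    "social_interface",
    "human_rights",
    "recovery_based_practice",
)


def quirc_domains_for(care_type: CareType | str) -> tuple[str, ...]:
    """Domains applicable to a care type.

    Floating outreach users live in their own tenancies, so the instrument
    has no "living environment" domain for that type (6 domains, not 7).
    """
    if CareType(care_type) is CareType.FLOATING_OUTREACH:
        return tuple(d for d in QUIRC_DOMAINS if d != "living_environment")
    return QUIRC_DOMAINS


# Raw numeric fields that may carry missing values / be perturbed.
NUMERIC_FIELDS: tuple[str, ...] = (
    "places",
    "staff_fte_per_user",
    "annual_budget",
    "length_of_stay",
    "occupied_places",
    "movers_2yr",
)


@dataclass(frozen=True)
class ServiceRecord:
    """One service's raw resources, outcomes and quality scores.

    Parameters
    ----------
    service_id
        Opaque identifier (anonymised in published datasets).
    care_type
        One of the four :class:`CareType` values.
    places
        Number of available beds/places (> 0).
    staff_fte_per_user
        Full-time-equivalent professionals *per service user*.
    annual_budget
        Total annual budget, GBP/year.
    length_of_stay
        Average length of stay in years.
    occupied_places
        Currently occupied places (<= places).
    movers_2yr
        Users moved to more independent accommodation over the last 2 years.
    quirc
        Mapping domain name -> score in [0, 100]; 7 domains (6 for
        floating outreach, which has no living-environment domain).
    outlier_flag
        Expert annotation; flagged services are retained but can be
        excluded at load time.
    """

    service_id: str
    care_type: CareType
    places: float
    staff_fte_per_user: float
    annual_budget: float
    length_of_stay: float
    occupied_places: float
    movers_2yr: float
    quirc: Mapping[str, float] = field(default_factory=dict)
    outlier_flag: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "care_type", CareType(self.care_type))
        object.__setattr__(self, "quirc", dict(self.quirc))
        self._validate()

    def _validate(self) -> None:
        for name in NUMERIC_FIELDS:
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                continue  # missing allowed until imputation
            if v < 0:
                raise ValueError(
                    f"service {self.service_id!r}: field {name!r} is negative ({v})"
                )
        if not _is_missing(self.places) and self.places <= 0:
            raise ValueError(f"service {self.service_id!r}: places must be positive")
        if not _is_missing(self.places) and not _is_missing(self.occupied_places):
            if self.occupied_places > self.places:
                raise ValueError(
                    f"service {self.service_id!r}: occupied_places "
                    f"({self.occupied_places}) exceeds places ({self.places})"
                )
        expected = set(quirc_domains_for(self.care_type))
        got = set(self.quirc)
        missing_domains = expected - got
        extra = got - expected
        if extra:
            raise ValueError(
                f"service {self.service_id!r}: unexpected quality domains {sorted(extra)}"
            )
        if missing_domains:
            # domains must be present as keys (values may be NaN pre-imputation)
            raise ValueError(
                f"service {self.service_id!r}: missing quality domains {sorted(missing_domains)}"
            )
        for d, s in self.quirc.items():
            if not _is_missing(s) and not (0.0 <= s <= 100.0):
                raise ValueError(
                    f"service {self.service_id!r}: quality score {d}={s} outside [0, 100]"
                )

    def has_missing(self) -> bool:
        return any(_is_missing(getattr(self, f)) for f in NUMERIC_FIELDS) or any(
            _is_missing(v) for v in self.quirc.values()
        )


def _is_missing(v: object) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


@dataclass(frozen=True)
class DerivedVariables:
    """Size-adjusted rate variables entering the efficiency analysis.

    ``quality_scaled[d] = quirc[d] * places / 100`` — a score of 90 means
    something different in a 10-place and a 100-place service, so quality
    outputs carry the service size.
    """

    budget_per_place: float
    places: float
    staff_per_user: float
    length_of_stay: float
    occupancy_pct: float
    movers_per_place: float
    quality_scaled: Mapping[str, float]

    def as_dict(self) -> dict[str, float]:
        d = {
            "budget_per_place": self.budget_per_place,
            "places": self.places,
            "staff_per_user": self.staff_per_user,
            "length_of_stay": self.length_of_stay,
            "occupancy_pct": self.occupancy_pct,
            "movers_per_place": self.movers_per_place,
        }
        for k, v in self.quality_scaled.items():
            d[f"quality_{k}"] = v
        return d


def derive_variables(record: ServiceRecord) -> DerivedVariables:
    """Compute DEA-ready rates from a raw record.

    Raises
    ------
    ValueError
        If ``places`` is zero/missing (all rates are per place).
    """
    if _is_missing(record.places) or record.places <= 0:
        raise ValueError(f"service {record.service_id!r}: places must be positive")
    occupied = min(record.occupied_places, record.places)
    return DerivedVariables(
        budget_per_place=record.annual_budget / record.places,
        places=float(record.places),
        staff_per_user=float(record.staff_fte_per_user),
        length_of_stay=float(record.length_of_stay),
        occupancy_pct=100.0 * occupied / record.places,
        movers_per_place=record.movers_2yr / record.places,
        quality_scaled={d: s * record.places / 100.0 for d, s in record.quirc.items()},
    )


# ---------------------------------------------------------------------------
# Tabular IO
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("service_id", "care_type") + NUMERIC_FIELDS
_QUIRC_PREFIX = "quirc_"


def records_to_frame(records: Sequence[ServiceRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict[str, object] = {
            "service_id": r.service_id,
            "care_type": r.care_type.value,
            **{f: getattr(r, f) for f in NUMERIC_FIELDS},
            "outlier_flag": r.outlier_flag,
        }
        for d, s in r.quirc.items():
            row[_QUIRC_PREFIX + d] = s
        rows.append(row)
    return pd.DataFrame(rows)


def save_services(records: Sequence[ServiceRecord], path) -> None:
    """Write a record set as CSV (round-trips losslessly with load_services)."""
    # %.17g round-trips float64 exactly
    records_to_frame(records).to_csv(path, index=False, float_format="%.17g")


def load_services(
    path,
    care_type_filter: CareType | str | None = None,
    *,
    exclude_outliers: bool = False,
    cap_occupancy: bool = False,
) -> list[ServiceRecord]:
    """Load service records from a delimited table.

    Parameters
    ----------
    path
        CSV file with one row per service; required columns are
        ``service_id, care_type, places, staff_fte_per_user, annual_budget,
        length_of_stay, occupied_places, movers_2yr`` plus ``quirc_<domain>``
        columns for the applicable quality domains. ``outlier_flag`` is
        optional (defaults to False).
    care_type_filter
        If given, only records of that care type are returned.
    exclude_outliers
        Drop rows whose ``outlier_flag`` is set (the outlier decision itself
        is an expert annotation carried in the file, never auto-detected).
    cap_occupancy
        If True, rows with ``occupied_places > places`` are capped to
        ``places`` with a warning instead of raising.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    records: list[ServiceRecord] = []
    for idx, row in df.iterrows():
        care_type = CareType(str(row["care_type"]))
        domains = quirc_domains_for(care_type)
        quirc = {}
        for d in domains:
            col = _QUIRC_PREFIX + d
            if col not in df.columns:
                raise ValueError(f"{path}: missing quality column {col!r} (row {idx})")
            quirc[d] = float(row[col])
        occupied = float(row["occupied_places"])
        places = float(row["places"])
        if cap_occupancy and not math.isnan(occupied) and not math.isnan(places):
            if occupied > places:
                warnings.warn(
                    f"row {idx} (service {row['service_id']!r}): occupied_places "
                    f"{occupied} capped to places {places}",
                    stacklevel=2,
                )
                occupied = places
        try:
            rec = ServiceRecord(
                service_id=str(row["service_id"]),
                care_type=care_type,
                places=places,
                staff_fte_per_user=float(row["staff_fte_per_user"]),
                annual_budget=float(row["annual_budget"]),
                length_of_stay=float(row["length_of_stay"]),
                occupied_places=occupied,
                movers_2yr=float(row["movers_2yr"]),
                quirc=quirc,
                outlier_flag=bool(row.get("outlier_flag", False)),
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {idx}: {exc}") from exc
        if care_type_filter is not None and rec.care_type is not CareType(care_type_filter):
            continue
        if exclude_outliers and rec.outlier_flag:
            continue
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Missing-value imputation
# ---------------------------------------------------------------------------

def impute_missing(records: Sequence[ServiceRecord], seed: int) -> list[ServiceRecord]:
    """Impute missing numeric values by Monte Carlo draws from the empirical
    distribution of the same field within the same care type.

    Each missing cell is replaced by a uniform draw over the observed values
    of that (care_type, field) pair, so imputed values always lie inside the
    observed support. Observed values are never altered; the result is
    deterministic under a fixed seed.

    Raises
    ------
    ValueError
        If a field has fewer than 3 observed values within a care type, or
        is entirely missing within a care type that needs it.
    """
    rng = np.random.default_rng(seed)
    by_type: dict[CareType, list[ServiceRecord]] = {}
    for r in records:
        by_type.setdefault(r.care_type, []).append(r)

    pools: dict[tuple[CareType, str], np.ndarray] = {}
    for ct, group in by_type.items():
        fields = list(NUMERIC_FIELDS) + [
            f"quirc:{d}" for d in quirc_domains_for(ct)
        ]
        for f in fields:
            vals = [_cell(r, f) for r in group]
            observed = np.array([v for v in vals if not _is_missing(v)], dtype=float)
            if any(_is_missing(v) for v in vals):
                if observed.size == 0:
                    raise ValueError(
                        f"cannot impute {f!r} for {ct.value}: entirely missing"
                    )
                if observed.size < 3:
                    raise ValueError(
                        f"cannot impute {f!r} for {ct.value}: fewer than 3 observed values"
                    )
            pools[(ct, f)] = observed

    out: list[ServiceRecord] = []
    for r in records:
        updates: dict[str, object] = {}
        for f in NUMERIC_FIELDS:
            if _is_missing(getattr(r, f)):
                pool = pools[(r.care_type, f)]
                updates[f] = float(rng.choice(pool))
        new_quirc = dict(r.quirc)
        changed_q = False
        for d in quirc_domains_for(r.care_type):
            if _is_missing(new_quirc.get(d)):
                pool = pools[(r.care_type, f"quirc:{d}")]
                new_quirc[d] = float(rng.choice(pool))
                changed_q = True
        if changed_q:
            updates["quirc"] = new_quirc
        out.append(replace(r, **updates) if updates else r)
    return out


def _cell(r: ServiceRecord, f: str) -> float:
    if f.startswith("quirc:"):
        return r.quirc.get(f.split(":", 1)[1], float("nan"))
    return getattr(r, f)
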