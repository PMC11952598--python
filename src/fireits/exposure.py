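"""Exposure classification, enrollment handling, ICD-10 grouping, aggregation.

Census-tract-like areal units are assigned to three exposure strata by
minimum distance to wildfire perimeters: ``high`` (< 20 km from any
perimeter), ``moderate`` (>= 20 km but inside the focal county), and
``minimal`` (>= 20 km, outside the focal county). Visit records carry a
single primary ICD-10 code which maps to all-cause plus at most one of four
specific cause categories:

    cardiovascular    I00-I99
    injury            S00-T88
    neuropsychiatric  F01-F99
    respiratory       J00-J99

Membership is decided on the code's letter + first two digits; anything
after the three-character stem is ignored.
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from datetime import date

import pandas as pd

from .synthetic import CAUSES, MODALITIES, ArealUnit, FirePerimeter

__all__ = [
    "STRATA",
    "ExposureAssignment",
    "EnrollmentSpell",
    "VisitRecord",
    "CategorizationError",
    "AggregationError",
    "merge_enrollment_spells",
    "classify_exposure",
    "categorize_visit",
    "aggregate_daily_counts",
]

STRATA: tuple[str, ...] = ("high", "moderate", "minimal")


class CategorizationError(ValueError):
    """Malformed ICD-10 code."""


class AggregationError(ValueError):
    """Visit records reference units without an exposure assignment."""


@dataclass(frozen=True)
class ExposureAssignment:
    unit_id: str
    distance_km: float
    county: str
    in_focal_county: bool
    stratum: str


@dataclass(frozen=True)
class EnrollmentSpell:
    member_id: str
    start: date
    end: date

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"spell for {self.member_id}: start {self.start} > end {self.end}")


@dataclass(frozen=True)
class VisitRecord:
    member_id: str
    date: date
    modality: str
    icd10: str
    unit_id: str


# ---------------------------------------------------------------------------
# enrollment
# ---------------------------------------------------------------------------


def merge_enrollment_spells(
    spells: Sequence[EnrollmentSpell], max_gap_days: int = 30
) -> list[EnrollmentSpell]:
    """Coalesce one member's spells whose gaps are at most ``max_gap_days``.

    The gap between consecutive spells is the count of uncovered days
    strictly between them (overlapping or abutting spells have gap <= 0).
    Output spells are chronologically sorted and pairwise separated by more
    than ``max_gap_days`` uncovered days. Idempotent.
    """
    if not spells:
        return []
    members = {s.member_id for s in spells}
    if len(members) != 1:
        raise ValueError(f"spells must belong to one member, got {sorted(members)}")
    ordered = sorted(spells, key=lambda s: (s.start, s.end))
    merged = [ordered[0]]
    for nxt in ordered[1:]:
        cur = merged[-1]
        gap = (nxt.start - cur.end).days - 1
        if gap <= max_gap_days:
            if nxt.end > cur.end:
                merged[-1] = EnrollmentSpell(cur.member_id, cur.start, nxt.end)
        else:
            merged.append(nxt)
    return merged


# ---------------------------------------------------------------------------
# exposure classification
# ---------------------------------------------------------------------------


def classify_exposure(
    units: Sequence[ArealUnit],
    perimeters: Sequence[FirePerimeter],
    threshold_km: float = 20.0,
    focal_county: str = "Los Angeles",
    mode: str = "boundary",
) -> list[ExposureAssignment]:
    """Assign every areal unit to exactly one exposure stratum.

    Distance is the minimum boundary-to-boundary distance (in km) between the
    unit polygon and any perimeter polygon — zero when they intersect.
    ``mode="centroid"`` measures from the unit centroid instead. Strata follow
    the strict-inequality convention: distance < threshold is ``high``;
    distance >= threshold is ``moderate`` inside the focal county and
    ``minimal`` outside it. Geometries must share one planar projected
    coordinate system in metres.
    """
    if not perimeters:
        raise ValueError("at least one fire perimeter is required")
    if mode not in ("boundary", "centroid"):
        raise ValueError(f"unknown distance mode {mode!r}")
    if threshold_km <= 0:
        raise ValueError("threshold_km must be > 0")

    out: list[ExposureAssignment] = []
    for unit in units:
        geom = unit.geometry.centroid if mode == "centroid" else unit.geometry
        if geom.is_empty:
            raise ValueError(f"unit {unit.unit_id} has an empty geometry")
        d_km = min(geom.distance(p.geometry) for p in perimeters) / 1000.0
        in_focal = unit.county == focal_county
        if d_km < threshold_km:
            stratum = "high"
        elif in_focal:
            stratum = "moderate"
        else:
            stratum = "minimal"
        out.append(
            ExposureAssignment(
                unit_id=unit.unit_id,
                distance_km=d_km,
                county=unit.county,
                in_focal_county=in_focal,
                stratum=stratum,
            )
        )
    return out


# ---------------------------------------------------------------------------
# ICD-10 categorization
# ---------------------------------------------------------------------------

_ICD_RE = re.compile(r"^([A-Z])([0-9]{2})[0-9A-Z]?(?:\.[0-9A-Z]{1,4})?$")


def categorize_visit(icd10: str) -> frozenset[str]:
    """Map one ICD-10 code to ``{"all_cause"}`` plus at most one specific category.

    Membership is decided by the letter and the two-digit numeric stem:
    I00-I99 cardiovascular, S00-T88 injury, F01-F99 neuropsychiatric,
    J00-J99 respiratory. F00 and T89-T99 stems fall outside their ranges and
    are all-cause only, as is any other valid code (e.g. U07.1).
    """
    m = _ICD_RE.match(icd10.strip().upper() if isinstance(icd10, str) else "")
    if m is None:
        raise CategorizationError(f"malformed ICD-10 code: {icd10!r}")
    letter, nn = m.group(1), int(m.group(2))
    cats = {"all_cause"}
    if letter == "I":
        cats.add("cardiovascular")
    elif letter == "S" or (letter == "T" and nn <= 88):
        cats.add("injury")
    elif letter == "F" and nn >= 1:
        cats.add("neuropsychiatric")
    elif letter == "J":
        cats.add("respiratory")
    return frozenset(cats)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def aggregate_daily_counts(
    records: Iterable[VisitRecord],
    assignments: Sequence[ExposureAssignment],
    calendar: Sequence,
    modalities: Sequence[str] = MODALITIES,
    causes: Sequence[str] = CAUSES,
) -> pd.DataFrame:
    """Aggregate visit records into the complete daily cube with explicit zeros.

    Every record's unit must have an exposure assignment; each record counts
    once toward all-cause and once toward its specific category (if any).
    Returns a tidy frame over the full calendar x stratum x modality x cause
    product, so downstream series have one row per date even when no visits
    occurred.
    """
    stratum_of = {a.unit_id: a.stratum for a in assignments}
    strata = sorted({a.stratum for a in assignments}, key=STRATA.index)
    if not strata:
        raise AggregationError("no exposure assignments supplied")
    calendar = pd.DatetimeIndex(calendar)

    tallies: dict[tuple, int] = {}
    for rec in records:
        if rec.unit_id not in stratum_of:
            raise AggregationError(f"visit record references unassigned unit {rec.unit_id!r}")
        if rec.modality not in modalities:
            raise AggregationError(f"unknown modality {rec.modality!r}")
        stratum = stratum_of[rec.unit_id]
        for cause in categorize_visit(rec.icd10):
            if cause not in causes:
                continue
            key = (pd.Timestamp(rec.date), stratum, rec.modality, cause)
            tallies[key] = tallies.get(key, 0) + 1

    index = pd.MultiIndex.from_product(
        [calendar, strata, list(modalities), list(causes)],
        names=["date", "stratum", "modality", "cause"],
    )
    counts = pd.Series(0, index=index, dtype=int, name="count")
    for key, n in tallies.items():
        if key[0] not in calendar:
            continue  # visits outside the study calendar are dropped
        counts.loc[key] = n
    return counts.reset_index()
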