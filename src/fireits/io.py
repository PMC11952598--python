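"""Plain-text I/O: tidy CSVs for counts and covariates, GeoJSON for geometries.

Column schemas
--------------
visits:      date, stratum, modality, cause, count
covariates:  date, tmax, tmin, rhmax, rhmin, wind, srad, ww_flu, ww_rsv, ww_sarscov2
assignments: unit_id, distance_km, county, in_focal_county, stratum
records:     member_id, date, modality, icd10, unit_id
spells:      member_id, start, end
GeoJSON features carry ``unit_id``/``county`` (tracts) or ``fire_id``
(perimeters) properties; coordinates are planar projected metres.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping, shape

from .exposure import EnrollmentSpell, ExposureAssignment, VisitRecord
from .synthetic import ArealUnit, FirePerimeter

__all__ = [
    "write_visits_csv",
    "read_visits_csv",
    "write_covariates_csv",
    "read_covariates_csv",
    "write_units_geojson",
    "read_units_geojson",
    "write_fires_geojson",
    "read_fires_geojson",
    "write_assignments_csv",
    "read_assignments_csv",
    "read_records_csv",
    "read_spells_csv",
]


def write_visits_csv(visits: pd.DataFrame, path: str | Path) -> None:
    out = visits.copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_visits_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"stratum": str, "modality": str, "cause": str})
    df["date"] = pd.to_datetime(df["date"])
    return df


def write_covariates_csv(covariates: pd.DataFrame, path: str | Path) -> None:
    out = covariates.copy()
    out.insert(0, "date", pd.DatetimeIndex(out.index).strftime("%Y-%m-%d"))
    out.to_csv(path, index=False)


def read_covariates_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df.index = pd.to_datetime(df.pop("date"))
    return df


def write_units_geojson(units: list[ArealUnit], path: str | Path) -> None:
    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"unit_id": u.unit_id, "county": u.county},
                "geometry": mapping(u.geometry),
            }
            for u in units
        ],
    }
    Path(path).write_text(json.dumps(fc))


def read_units_geojson(path: str | Path) -> list[ArealUnit]:
    fc = json.loads(Path(path).read_text())
    return [
        ArealUnit(
            unit_id=str(f["properties"]["unit_id"]),
            geometry=shape(f["geometry"]),
            county=str(f["properties"].get("county", "")),
        )
        for f in fc["features"]
    ]


def write_fires_geojson(fires: list[FirePerimeter], path: str | Path) -> None:
    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"fire_id": f.fire_id},
                "geometry": mapping(f.geometry),
            }
            for f in fires
        ],
    }
    Path(path).write_text(json.dumps(fc))


def read_fires_geojson(path: str | Path) -> list[FirePerimeter]:
    fc = json.loads(Path(path).read_text())
    return [
        FirePerimeter(fire_id=str(f["properties"].get("fire_id", i)), geometry=shape(f["geometry"]))
        for i, f in enumerate(fc["features"])
    ]


def write_assignments_csv(assignments: list[ExposureAssignment], path: str | Path) -> None:
    pd.DataFrame(
        {
            "unit_id": [a.unit_id for a in assignments],
            "distance_km": [a.distance_km for a in assignments],
            "county": [a.county for a in assignments],
            "in_focal_county": [a.in_focal_county for a in assignments],
            "stratum": [a.stratum for a in assignments],
        }
    ).to_csv(path, index=False)


def read_assignments_csv(path: str | Path) -> list[ExposureAssignment]:
    df = pd.read_csv(path)
    return [
        ExposureAssignment(
            unit_id=str(r.unit_id),
            distance_km=float(r.distance_km),
            county=str(r.county),
            in_focal_county=bool(r.in_focal_county),
            stratum=str(r.stratum),
        )
        for r in df.itertuples()
    ]


def read_records_csv(path: str | Path) -> list[VisitRecord]:
    df = pd.read_csv(path, dtype=str)
    return [
        VisitRecord(
            member_id=r.member_id,
            date=pd.Timestamp(r.date).date(),
            modality=r.modality,
            icd10=r.icd10,
            unit_id=r.unit_id,
        )
        for r in df.itertuples()
    ]


def read_spells_csv(path: str | Path) -> list[EnrollmentSpell]:
    df = pd.read_csv(path, dtype=str)
    return [
        EnrollmentSpell(
            member_id=r.member_id,
            start=pd.Timestamp(r.start).date(),
            end=pd.Timestamp(r.end).date(),
        )
        for r in df.itertuples()
    ]
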