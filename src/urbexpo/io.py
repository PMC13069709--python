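"""GeoJSON / CSV / YAML input-output.

GeoJSON coordinates in this package are planar meters (a synthetic
projected frame), not longitude/latitude; every FeatureCollection written
here carries a top-level ``"coordinate_system": "planar_meters"`` note
recording that dialect.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import pandas as pd
from shapely import wkt as shapely_wkt
from shapely.geometry import Polygon, mapping, shape

from .geoexposure import InvalidGeometryError, Parcel, Residence
from .synthetic_city import AdminMap

__all__ = [
    "write_parcels_geojson", "read_parcels_geojson",
    "read_parcels_csv_wkt", "write_parcels_csv_wkt",
    "write_admin_geojson", "read_admin_geojson",
    "write_residences_csv", "read_residences_csv",
]

_PLANAR_NOTE = "planar_meters"
KNOWN_CLASSES = {"transport_facility", "industrial", "business2_white",
                 "residential", "park", "other"}


def _feature_collection(features: list[dict]) -> dict:
    return {"type": "FeatureCollection",
            "coordinate_system": _PLANAR_NOTE,
            "note": "coordinates are planar Cartesian meters, not lon/lat",
            "features": features}


def write_parcels_geojson(parcels: Sequence[Parcel], path: str | Path) -> None:
    feats = [{"type": "Feature",
              "properties": {"id": p.parcel_id,
                             "land_use_class": p.land_use_class},
              "geometry": mapping(p.polygon)} for p in parcels]
    Path(path).write_text(json.dumps(_feature_collection(feats)))


def _coerce_class(props: dict, fid: object) -> str:
    cls = props.get("land_use_class")
    if cls is None:
        warnings.warn(f"feature {fid!r} missing land_use_class; "
                      "bucketed as 'other'", stacklevel=3)
        return "other"
    if cls not in KNOWN_CLASSES:
        warnings.warn(f"feature {fid!r}: unknown land_use_class {cls!r}; "
                      "bucketed as 'other'", stacklevel=3)
        return "other"
    return cls


def read_parcels_geojson(path: str | Path) -> list[Parcel]:
    doc = json.loads(Path(path).read_text())
    parcels = []
    for i, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties") or {}
        fid = props.get("id", i)
        try:
            geom = shape(feat["geometry"])
        except Exception as exc:
            raise InvalidGeometryError(
                f"feature {fid!r}: malformed geometry ({exc})") from exc
        if not isinstance(geom, Polygon) or not geom.is_valid:
            raise InvalidGeometryError(f"feature {fid!r}: not a simple polygon")
        parcels.append(Parcel(str(fid), _coerce_class(props, fid), geom))
    return parcels


def write_parcels_csv_wkt(parcels: Sequence[Parcel], path: str | Path) -> None:
    pd.DataFrame({
        "id": [p.parcel_id for p in parcels],
        "land_use_class": [p.land_use_class for p in parcels],
        "wkt": [p.polygon.wkt for p in parcels],
    }).to_csv(path, index=False)


def read_parcels_csv_wkt(path: str | Path) -> list[Parcel]:
    df = pd.read_csv(path)
    parcels = []
    for _, row in df.iterrows():
        try:
            geom = shapely_wkt.loads(row["wkt"])
        except Exception as exc:
            raise InvalidGeometryError(
                f"feature {row['id']!r}: malformed WKT ({exc})") from exc
        cls = _coerce_class({"land_use_class": row.get("land_use_class")},
                            row["id"])
        parcels.append(Parcel(str(row["id"]), cls, geom))
    return parcels


def write_admin_geojson(admin: AdminMap, path: str | Path) -> None:
    feats = []
    for pa_id, poly in admin.planning_areas:
        feats.append({"type": "Feature",
                      "properties": {"level": "planning_area",
                                     "area_id": pa_id},
                      "geometry": mapping(poly)})
    for sz_id, pa_id, poly in admin.subzones:
        feats.append({"type": "Feature",
                      "properties": {"level": "subzone", "subzone_id": sz_id,
                                     "area_id": pa_id},
                      "geometry": mapping(poly)})
    doc = _feature_collection(feats)
    doc["extent"] = list(admin.extent)
    Path(path).write_text(json.dumps(doc))


def read_admin_geojson(path: str | Path) -> AdminMap:
    doc = json.loads(Path(path).read_text())
    pas, szs = [], []
    for feat in doc["features"]:
        props = feat["properties"]
        poly = shape(feat["geometry"])
        if props["level"] == "planning_area":
            pas.append((props["area_id"], poly))
        else:
            szs.append((props["subzone_id"], props["area_id"], poly))
    return AdminMap(tuple(pas), tuple(szs), tuple(doc["extent"]))


def write_residences_csv(residences: Sequence[Residence],
                         path: str | Path) -> None:
    pd.DataFrame({
        "postcode_id": [r.postcode_id for r in residences],
        "x_m": [r.point[0] for r in residences],
        "y_m": [r.point[1] for r in residences],
        "subzone_id": [r.subzone_id for r in residences],
        "planning_area_id": [r.planning_area_id for r in residences],
    }).to_csv(path, index=False)


def read_residences_csv(path: str | Path) -> list[Residence]:
    df = pd.read_csv(path)
    return [Residence(str(r.postcode_id), (float(r.x_m), float(r.y_m)),
                      str(r.subzone_id), str(r.planning_area_id))
            for r in df.itertuples()]
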