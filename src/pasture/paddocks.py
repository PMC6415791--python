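"""Paddock polygons: container, validation, GeoJSON I/O."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

SPECIES = ("fescue", "ryegrass")


@dataclass
class Paddock:
    paddock_id: str
    geometry: BaseGeometry
    species: str = "fescue"

    @property
    def area_ha(self) -> float:
        return self.geometry.area / 10_000.0


@dataclass
class PaddockMap:
    """Validated collection of paddock polygons in a shared projected CRS."""

    paddocks: list[Paddock]
    crs: str = "LOCAL_METRIC"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.paddocks:
            raise ValueError("PaddockMap needs at least one paddock")
        ids = [p.paddock_id for p in self.paddocks]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate paddock ids")
        for p in self.paddocks:
            if p.geometry.is_empty or not p.geometry.is_valid:
                raise ValueError(f"paddock {p.paddock_id}: empty or invalid polygon")
            if p.species not in SPECIES:
                raise ValueError(f"paddock {p.paddock_id}: unknown species {p.species!r}")

    def __iter__(self):
        return iter(self.paddocks)

    def __len__(self):
        return len(self.paddocks)

    def __getitem__(self, paddock_id: str) -> Paddock:
        for p in self.paddocks:
            if p.paddock_id == paddock_id:
                return p
        raise KeyError(paddock_id)

    @property
    def total_area_ha(self) -> float:
        return sum(p.area_ha for p in self.paddocks)


def write_geojson(path, pmap: PaddockMap) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {
                "paddock_id": p.paddock_id,
                "species": p.species,
                "area_ha": round(p.area_ha, 6),
            },
            "geometry": mapping(p.geometry),
        }
        for p in pmap
    ]
    doc = {"type": "FeatureCollection", "crs_label": pmap.crs, "features": features}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_geojson(path) -> PaddockMap:
    with open(path) as fh:
        doc = json.load(fh)
    paddocks = [
        Paddock(
            paddock_id=str(f["properties"]["paddock_id"]),
            geometry=shape(f["geometry"]),
            species=f["properties"].get("species", "fescue"),
        )
        for f in doc["features"]
    ]
    return PaddockMap(paddocks=paddocks, crs=doc.get("crs_label", "LOCAL_METRIC"))
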