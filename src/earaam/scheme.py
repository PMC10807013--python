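"""Canonical 91-point landmark scheme, region atlas and acupoint registry.

The landmark indexing is frozen in the shipped ``data/scheme.json``: the outer
helix rim is traced clockwise from the upper attachment (indices 0-35), inner
structures follow (inner helix edge 36-55, antihelix ridge 56-67, concha rim
68-75, tragus 76-79, antitragus 80-81), and the nine earlobe contour points
come last (82-90).  All geometry code reads indices from the scheme; nothing
downstream hard-codes them.

Coordinates throughout the package are 0-based pixels, x rightward and
y downward from the top-left image corner.
"""

from __future__ import annotations

import difflib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

#: The nine auricular regions, in the standard naming and order.
REGION_NAMES = (
    "helix",
    "antihelix",
    "cymba conchae",
    "cavum conchae",
    "fossae helicis",
    "fossae triangularis auriculae",
    "tragus",
    "antitragus",
    "earlobe",
)

#: Sub-area counts per region.  The two conchae carry 18 sub-areas combined.
SUBAREA_COUNTS = {
    "helix": 12,
    "antihelix": 13,
    "cymba conchae": 6,
    "cavum conchae": 12,
    "fossae helicis": 6,
    "fossae triangularis auriculae": 5,
    "tragus": 4,
    "antitragus": 4,
    "earlobe": 9,
}

POINT_COUNT = 91


class SchemeError(ValueError):
    """A scheme/atlas/acupoint file violates its schema or an invariant."""


@dataclass(frozen=True)
class LandmarkScheme:
    """Canonical indexing of the 91 ear landmarks.

    Attributes
    ----------
    point_count : int
        Number of landmarks (91; shape vectors have dimension 182).
    labels : tuple of str
        One anatomical label per index.
    earlobe_contour_indices : tuple of int
        The nine ordered indices tracing the raw earlobe contour
        (the input points of the earlobe reconstruction).
    group_map : dict
        Region name -> sorted tuple of landmark indices.
    """

    point_count: int
    labels: tuple
    earlobe_contour_indices: tuple
    group_map: dict

    def validate(self) -> "LandmarkScheme":
        if self.point_count != POINT_COUNT:
            raise SchemeError(f"point_count must be {POINT_COUNT}, got {self.point_count}")
        if len(self.labels) != self.point_count:
            raise SchemeError(
                f"labels: expected {self.point_count} entries, got {len(self.labels)}"
            )
        eci = self.earlobe_contour_indices
        if len(eci) != 9:
            raise SchemeError(f"earlobe_contour_indices: expected 9 entries, got {len(eci)}")
        if len(set(eci)) != 9:
            raise SchemeError("earlobe_contour_indices: indices must be distinct")
        if any(not (0 <= i < self.point_count) for i in eci):
            raise SchemeError("earlobe_contour_indices: index out of range")
        covered = set()
        for name, idxs in self.group_map.items():
            if any(not (0 <= i < self.point_count) for i in idxs):
                raise SchemeError(f"group_map[{name!r}]: index out of range")
            covered.update(idxs)
        missing = set(range(self.point_count)) - covered
        if missing:
            raise SchemeError(f"group_map: indices not covered by any group: {sorted(missing)}")
        return self

    def to_dict(self) -> dict:
        return {
            "point_count": self.point_count,
            "labels": list(self.labels),
            "earlobe_contour_indices": list(self.earlobe_contour_indices),
            "group_map": {k: list(v) for k, v in self.group_map.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkScheme":
        try:
            scheme = cls(
                point_count=int(d["point_count"]),
                labels=tuple(d["labels"]),
                earlobe_contour_indices=tuple(int(i) for i in d["earlobe_contour_indices"]),
                group_map={str(k): tuple(int(i) for i in v) for k, v in d["group_map"].items()},
            )
        except (KeyError, TypeError) as exc:
            raise SchemeError(f"scheme file missing or malformed field: {exc}") from exc
        return scheme.validate()


@dataclass(frozen=True)
class RegionAtlas:
    """Polygonal atlas of the nine auricular regions.

    ``regions`` maps each region name to an ordered list of polygon vertices;
    a vertex is either a landmark index (int) or a derived-point token such as
    ``"P1"``...``"P9"`` (the reconstructed earlobe reference points).
    ``subareas`` lists the named sub-areas of each region; the counts follow
    the national auricular standard's enumeration.
    """

    regions: dict
    subareas: dict

    def validate(self) -> "RegionAtlas":
        names = tuple(self.regions)
        if set(names) != set(REGION_NAMES):
            raise SchemeError(
                f"regions: expected exactly {sorted(REGION_NAMES)}, got {sorted(names)}"
            )
        for name, verts in self.regions.items():
            if len(verts) < 3:
                raise SchemeError(f"regions[{name!r}]: polygon needs >= 3 vertices")
            for v in verts:
                if isinstance(v, str):
                    if not (v.startswith("P") and v[1:].isdigit() and 1 <= int(v[1:]) <= 9):
                        raise SchemeError(f"regions[{name!r}]: bad derived-point token {v!r}")
                elif not (0 <= int(v) < POINT_COUNT):
                    raise SchemeError(f"regions[{name!r}]: landmark index {v} out of range")
        for name, subs in self.subareas.items():
            want = SUBAREA_COUNTS.get(name)
            if want is None:
                raise SchemeError(f"subareas: unknown region {name!r}")
            if len(subs) != want:
                raise SchemeError(
                    f"subareas[{name!r}]: expected {want} sub-areas, got {len(subs)}"
                )
        combined = len(self.subareas["cymba conchae"]) + len(self.subareas["cavum conchae"])
        if combined != 18:
            raise SchemeError(f"conchae sub-areas must total 18 combined, got {combined}")
        return self

    def to_dict(self) -> dict:
        return {"regions": {k: list(v) for k, v in self.regions.items()},
                "subareas": {k: list(v) for k, v in self.subareas.items()}}

    @classmethod
    def from_dict(cls, d: dict) -> "RegionAtlas":
        try:
            atlas = cls(
                regions={str(k): list(v) for k, v in d["regions"].items()},
                subareas={str(k): list(v) for k, v in d["subareas"].items()},
            )
        except (KeyError, TypeError) as exc:
            raise SchemeError(f"atlas file missing or malformed field: {exc}") from exc
        return atlas.validate()


@dataclass(frozen=True)
class AcupointEntry:
    """One named acupoint, anchored inside a host region.

    ``kind`` is ``"area"`` (highlighted as a filled polygon) or ``"point"``
    (a single marked pixel).  The anchor gives the host region and a relative
    position: ``rel`` is an (u, v) fraction of the host polygon's bounding box,
    ``subarea`` (earlobe only) names one of the nine lobe sub-areas instead.
    ``rel_size`` scales an area acupoint's footprint relative to the host.
    """

    name: str
    kind: str
    region: str
    rel: tuple = None
    subarea: int = None
    rel_size: float = 0.25

    def validate(self) -> "AcupointEntry":
        if self.kind not in ("area", "point"):
            raise SchemeError(f"acupoint {self.name!r}: kind must be 'area' or 'point'")
        if self.region not in REGION_NAMES:
            raise SchemeError(f"acupoint {self.name!r}: unknown region {self.region!r}")
        if (self.rel is None) == (self.subarea is None):
            raise SchemeError(
                f"acupoint {self.name!r}: exactly one of rel / subarea must be given"
            )
        if self.rel is not None:
            u, v = self.rel
            if not (0.0 < u < 1.0 and 0.0 < v < 1.0):
                raise SchemeError(f"acupoint {self.name!r}: rel must lie strictly in (0,1)^2")
        if self.subarea is not None and not (1 <= int(self.subarea) <= 9):
            raise SchemeError(f"acupoint {self.name!r}: subarea must be 1..9")
        return self


class AcupointRegistry:
    """Name -> :class:`AcupointEntry` registry with fuzzy miss reporting."""

    def __init__(self, entries):
        self.entries = {}
        for e in entries:
            if e.name in self.entries:
                raise SchemeError(f"duplicate acupoint name {e.name!r}")
            self.entries[e.name] = e.validate()

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.values())

    def get(self, name: str) -> AcupointEntry:
        try:
            return self.entries[name]
        except KeyError:
            near = difflib.get_close_matches(name, self.entries, n=3, cutoff=0.4)
            hint = f"; did you mean {near}?" if near else ""
            raise KeyError(f"unknown acupoint {name!r}{hint}") from None

    def to_dict(self) -> dict:
        out = []
        for e in self.entries.values():
            d = {"name": e.name, "kind": e.kind, "region": e.region, "rel_size": e.rel_size}
            if e.rel is not None:
                d["rel"] = list(e.rel)
            if e.subarea is not None:
                d["subarea"] = int(e.subarea)
            out.append(d)
        return {"acupoints": out}

    @classmethod
    def from_dict(cls, d: dict) -> "AcupointRegistry":
        try:
            entries = [
                AcupointEntry(
                    name=str(a["name"]),
                    kind=str(a["kind"]),
                    region=str(a["region"]),
                    rel=tuple(a["rel"]) if "rel" in a else None,
                    subarea=int(a["subarea"]) if "subarea" in a else None,
                    rel_size=float(a.get("rel_size", 0.25)),
                )
                for a in d["acupoints"]
            ]
        except (KeyError, TypeError) as exc:
            raise SchemeError(f"acupoint file missing or malformed field: {exc}") from exc
        return cls(entries)


def _read_json(path) -> dict:
    try:
        with open(path) as fh:
            return json.load(fh)
    except json.JSONDecodeError as exc:
        raise SchemeError(f"{path}: not valid JSON: {exc}") from exc


def _default_path(name: str) -> Path:
    return Path(str(resources.files("earaam").joinpath("data", name)))


def load_scheme(path=None) -> LandmarkScheme:
    """Load and validate a landmark scheme (the shipped default if *path* is None)."""
    return LandmarkScheme.from_dict(_read_json(path or _default_path("scheme.json")))


def load_atlas(path=None) -> RegionAtlas:
    """Load and validate a region atlas (the shipped default if *path* is None)."""
    return RegionAtlas.from_dict(_read_json(path or _default_path("atlas.json")))


def load_acupoints(path=None) -> AcupointRegistry:
    """Load and validate the acupoint registry (shipped default if *path* is None)."""
    return AcupointRegistry.from_dict(_read_json(path or _default_path("acupoints.json")))


def lookup_acupoint(name, atlas, landmarks, registry=None, scheme=None):
    """Resolve a named acupoint to highlight geometry in image coordinates.

    Returns ``("area", polygon)`` with an (m, 2) vertex array, or
    ``("point", (x, y))``.  Positions are resolved relative to the host
    region's polygon as built from the given fitted landmarks.
    """
    from earaam import geometry  # deferred: geometry depends on this module

    registry = registry if registry is not None else load_acupoints()
    scheme = scheme if scheme is not None else load_scheme()
    entry = registry.get(name)
    polys = geometry.build_region_polygons(landmarks, scheme, atlas)
    host = np.asarray(polys[entry.region], dtype=float)

    if entry.subarea is not None:
        if entry.region != "earlobe":
            raise SchemeError(f"acupoint {entry.name!r}: subarea anchors require the earlobe")
        recon = geometry.reconstruct_earlobe(
            geometry.densify_earlobe(landmarks[list(scheme.earlobe_contour_indices)])
        )
        sub = geometry.divide_earlobe_nine(recon)[int(entry.subarea) - 1]
        anchor = np.asarray(sub, dtype=float).mean(axis=0)
        if entry.kind == "area":
            return "area", np.asarray(sub, dtype=float)
        return "point", tuple(anchor)

    lo, hi = host.min(axis=0), host.max(axis=0)
    anchor = lo + np.asarray(entry.rel, dtype=float) * (hi - lo)
    if entry.kind == "point":
        return "point", tuple(anchor)

    import shapely.geometry as sgeom

    region_poly = sgeom.Polygon(host)
    if not region_poly.is_valid:
        region_poly = region_poly.buffer(0)
    radius = entry.rel_size * np.sqrt(max(region_poly.area, 1.0))
    disk = sgeom.Point(*anchor).buffer(radius, quad_segs=16)
    patch = disk.intersection(region_poly)
    if patch.is_empty:
        patch = disk  # anchor outside an irregular host polygon: show the disk
    if patch.geom_type == "MultiPolygon":
        patch = max(patch.geoms, key=lambda g: g.area)
    return "area", np.asarray(patch.exterior.coords, dtype=float)
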