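"""Range inference: convex hulls of occurrences clipped to occupied classes.

A first-pass range estimate for a taxon is the convex hull of its
collection localities.  The hull over-covers, so it is trimmed: the
environmental-class raster is downsampled to 20 km blocks, the class under
every occurrence point is extracted, and the parts of the hull lying in
classes with zero occurrences are removed.  The clipped range is generally
a multipart polygon.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import MultiPolygon, Polygon, box
from shapely.ops import unary_union

from .projection import AFRICA_ALBERS, AlbersEqualArea
from .raster import ClassRaster, extract_classes

__all__ = [
    "RangePolygon",
    "DegenerateHullError",
    "convex_hull",
    "clip_by_occupied_classes",
    "infer_ranges",
]


class DegenerateHullError(ValueError):
    """Fewer than 3 points, or all points collinear: no 2-D hull exists."""


@dataclass
class RangePolygon:
    """Inferred range of a taxon: raw hull, clipped hull, occupied classes."""

    taxon: str
    hull: Polygon
    clipped: MultiPolygon
    occupied_classes: frozenset[int]
    n_points: int

    @property
    def hull_area(self) -> float:
        return self.hull.area

    @property
    def clipped_area(self) -> float:
        return self.clipped.area

    def to_geojson(
        self, path: str | Path, projection: AlbersEqualArea = AFRICA_ALBERS, densify_m: float = 50_000.0
    ) -> None:
        """Write hull and clipped range as WGS84 GeoJSON features."""

        def unproject(geom):
            geom = geom.segmentize(densify_m)

            def ring(coords):
                arr = np.asarray(coords)
                lat, lon = projection.inverse(arr[:, 0], arr[:, 1])
                return [[float(lo), float(la)] for lo, la in zip(lon, lat)]

            if geom.geom_type == "Polygon":
                polys = [geom]
            else:
                polys = list(geom.geoms)
            return {
                "type": "MultiPolygon",
                "coordinates": [
                    [ring(p.exterior.coords)] + [ring(i.coords) for i in p.interiors]
                    for p in polys
                ],
            }

        features = [
            {
                "type": "Feature",
                "geometry": unproject(self.hull),
                "properties": {"taxon": self.taxon, "layer": "hull", "n_points": self.n_points},
            },
            {
                "type": "Feature",
                "geometry": unproject(self.clipped),
                "properties": {
                    "taxon": self.taxon,
                    "layer": "clipped",
                    "occupied_classes": sorted(self.occupied_classes),
                },
            },
        ]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)


def convex_hull(points: np.ndarray) -> Polygon:
    """Minimum bounding convex polygon of a projected point set.

    Vertices are returned counter-clockwise starting from the lowest-y
    (then lowest-x) vertex.  Degenerate input (fewer than 3 points, or all
    collinear) raises :class:`DegenerateHullError`.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise DegenerateHullError(f"need at least 3 points, got {len(pts)}")
    from shapely import MultiPoint

    geom = MultiPoint(pts).convex_hull
    if geom.geom_type != "Polygon":
        raise DegenerateHullError("all points collinear: hull is degenerate")
    coords = np.asarray(geom.exterior.coords)[:-1]  # drop closing vertex
    # orient counter-clockwise (positive shoelace area)
    area2 = np.sum(coords[:, 0] * np.roll(coords[:, 1], -1) - np.roll(coords[:, 0], -1) * coords[:, 1])
    if area2 < 0:
        coords = coords[::-1]
    start = np.lexsort((coords[:, 0], coords[:, 1]))[0]
    coords = np.roll(coords, -start, axis=0)
    return Polygon(coords)


def clip_by_occupied_classes(
    hull: Polygon, raster: ClassRaster, points: np.ndarray, taxon: str = ""
) -> RangePolygon:
    """Remove hull area lying in environmental classes with no occurrences.

    ``occupied_classes`` is the set of raster classes under the occurrence
    points (nodata excluded); the clipped range is the intersection of the
    hull with the union of all cells of those classes.  Exact cell-polygon
    geometry is used, not a rasterised approximation.
    """
    pts = np.asarray(points, dtype=float)
    classes = extract_classes(raster, pts)
    occupied = frozenset(int(c) for c in classes if c != raster.nodata)
    if not occupied:
        raise ValueError("no occurrence falls in a valid raster class")
    # restrict the cell scan to the hull's bounding box
    xmin, ymin, xmax, ymax = hull.bounds
    x0, y0 = raster.origin_xy
    ny, nx = raster.grid.shape
    ix_lo = max(int(np.floor((xmin - x0) / raster.cell_m)), 0)
    ix_hi = min(int(np.floor((xmax - x0) / raster.cell_m)), nx - 1)
    iy_lo = max(int(np.floor((ymin - y0) / raster.cell_m)), 0)
    iy_hi = min(int(np.floor((ymax - y0) / raster.cell_m)), ny - 1)
    sub = raster.grid[iy_lo : iy_hi + 1, ix_lo : ix_hi + 1]
    occ_mask = np.isin(sub, sorted(occupied))
    # merge runs of occupied cells within each row into single rectangles
    boxes = []
    for dy in range(occ_mask.shape[0]):
        row = occ_mask[dy]
        edges = np.flatnonzero(np.diff(np.concatenate([[0], row.view(np.int8), [0]])))
        for start, stop in zip(edges[::2], edges[1::2]):
            x_lo, y_lo, *_ = raster.cell_box(iy_lo + dy, ix_lo + int(start))
            *_, x_hi, y_hi = raster.cell_box(iy_lo + dy, ix_lo + int(stop) - 1)
            boxes.append(box(x_lo, y_lo, x_hi, y_hi))
    clipped = hull.intersection(unary_union(boxes)) if boxes else Polygon()
    if clipped.geom_type == "Polygon":
        clipped = MultiPolygon([clipped]) if not clipped.is_empty else MultiPolygon()
    elif clipped.geom_type == "GeometryCollection":
        clipped = MultiPolygon([g for g in clipped.geoms if g.geom_type == "Polygon"])
    return RangePolygon(
        taxon=taxon, hull=hull, clipped=clipped, occupied_classes=occupied, n_points=len(pts)
    )


def infer_ranges(
    rs,
    pp,
    raster: ClassRaster,
    group_by: str = "morph_group",
    block_m: Optional[float] = 20_000.0,
) -> tuple[list[RangePolygon], list[str]]:
    """One clipped range polygon per taxon label with >= 3 non-collinear sites.

    ``group_by`` is ``"morph_group"`` or ``"subspecies"``.  The raster is
    block-downsampled to ``block_m`` first (pass ``None`` to skip).  Returns
    the polygons and the labels skipped as degenerate or unlabelled.
    """
    from .raster import block_downsample

    if group_by not in {"morph_group", "subspecies"}:
        raise ValueError("group_by must be 'morph_group' or 'subspecies'")
    if block_m is not None and block_m > raster.cell_m:
        raster = block_downsample(raster, block_m)
    labels: dict[str, list[int]] = {}
    for row, idx in enumerate(pp.source_index):
        label = getattr(rs[int(idx)], group_by)
        if label:
            labels.setdefault(label, []).append(row)
    polygons: list[RangePolygon] = []
    skipped: list[str] = []
    for label in sorted(labels):
        pts = pp.xy[labels[label]]
        try:
            hull = convex_hull(pts)
        except DegenerateHullError:
            warnings.warn(f"taxon {label!r}: degenerate hull ({len(pts)} points); skipped", stacklevel=2)
            skipped.append(label)
            continue
        polygons.append(clip_by_occupied_classes(hull, raster, pts, taxon=label))
    return polygons, skipped
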