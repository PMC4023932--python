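"""Equal-area projection for Africa and distance-band spatial weights.

Coordinates are projected from WGS84 into an Albers equal-area conic plane
before any distance-based analysis, so that Euclidean distances and areas in
metres are meaningful across the continent.  The conventional Africa
configuration is the default: central meridian 25°E, standard parallels
20°N and 23°S, latitude of origin 0°, no false easting/northing.  The
projection is computed on the authalic sphere (R = 6 371 007.181 m), which
makes it exactly area-preserving for spherical geometry.

Spatial weights are binary distance bands: j is a neighbour of i iff
0 < d(i, j) <= band (closed band, planar Euclidean distance), optionally
including self-neighbourhood (w_ii = 1) as required by the Gi* statistic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

__all__ = [
    "AlbersEqualArea",
    "AFRICA_ALBERS",
    "ProjectedPoints",
    "SpatialWeights",
    "project",
    "build_weights",
]

AUTHALIC_RADIUS_M = 6_371_007.181


@dataclass(frozen=True)
class AlbersEqualArea:
    """Albers equal-area conic projection on the authalic sphere.

    Parameters are degrees.  Forward maps (lat, lon) -> (x, y) metres;
    ``inverse`` undoes it.  Latitudes of exactly ±90° are rejected (the
    projection is singular at the poles for this configuration).
    """

    central_meridian: float = 25.0
    standard_parallel_1: float = 20.0
    standard_parallel_2: float = -23.0
    latitude_of_origin: float = 0.0
    radius_m: float = AUTHALIC_RADIUS_M

    @property
    def crs_tag(self) -> str:
        return (
            f"albers_sphere:lon0={self.central_meridian},"
            f"sp1={self.standard_parallel_1},sp2={self.standard_parallel_2},"
            f"lat0={self.latitude_of_origin},R={self.radius_m}"
        )

    def _constants(self) -> tuple[float, float, float]:
        p1 = math.radians(self.standard_parallel_1)
        p2 = math.radians(self.standard_parallel_2)
        n = 0.5 * (math.sin(p1) + math.sin(p2))
        if n == 0.0:
            raise ValueError("standard parallels must not be symmetric about the equator")
        c = math.cos(p1) ** 2 + 2.0 * n * math.sin(p1)
        rho0 = self.radius_m * math.sqrt(c - 2.0 * n * math.sin(math.radians(self.latitude_of_origin))) / n
        return n, c, rho0

    def forward(self, lat, lon):
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        if np.any(np.abs(lat) >= 90.0) or np.any(np.abs(lon) > 180.0):
            raise ValueError("latitude must be in (-90, 90), longitude in [-180, 180]")
        n, c, rho0 = self._constants()
        phi = np.radians(lat)
        theta = n * np.radians(((lon - self.central_meridian + 180.0) % 360.0) - 180.0)
        rho = self.radius_m * np.sqrt(c - 2.0 * n * np.sin(phi)) / n
        x = rho * np.sin(theta)
        y = rho0 - rho * np.cos(theta)
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        n, c, rho0 = self._constants()
        rho = np.hypot(x, rho0 - y) * math.copysign(1.0, n)
        theta = np.arctan2(np.sign(n) * x, np.sign(n) * (rho0 - y))
        sin_phi = (c - (rho * n / self.radius_m) ** 2) / (2.0 * n)
        lat = np.degrees(np.arcsin(np.clip(sin_phi, -1.0, 1.0)))
        lon = self.central_meridian + np.degrees(theta / n)
        lon = ((lon + 180.0) % 360.0) - 180.0
        return lat, lon


AFRICA_ALBERS = AlbersEqualArea()


@dataclass
class ProjectedPoints:
    """Point set in the projected plane, with a handle back to its source rows."""

    xy: np.ndarray  # (n, 2) metres
    crs_tag: str
    source_index: np.ndarray  # (n,) indices into the originating record set

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        self.source_index = np.asarray(self.source_index, dtype=int)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must be (n, 2)")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("projected coordinates must be finite")
        if len(self.source_index) != len(self.xy):
            raise ValueError("source_index length mismatch")

    def __len__(self) -> int:
        return len(self.xy)

    def to_geojson(self, path: str | Path, projection: AlbersEqualArea = AFRICA_ALBERS) -> None:
        """Write the points as a WGS84 GeoJSON FeatureCollection."""
        lat, lon = projection.inverse(self.xy[:, 0], self.xy[:, 1])
        features = [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(lo), float(la)]},
                "properties": {"source_index": int(i)},
            }
            for lo, la, i in zip(lon, lat, self.source_index)
        ]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)


def project(
    lat,
    lon,
    projection: AlbersEqualArea = AFRICA_ALBERS,
    source_index=None,
) -> ProjectedPoints:
    """Project WGS84 coordinates into the equal-area plane."""
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    x, y = projection.forward(lat, lon)
    if source_index is None:
        source_index = np.arange(len(x))
    return ProjectedPoints(
        xy=np.column_stack([x, y]), crs_tag=projection.crs_tag, source_index=source_index
    )


@dataclass
class SpatialWeights:
    """Binary distance-band neighbour structure over projected points.

    ``matrix`` is a symmetric sparse 0/1 matrix; with ``include_self`` the
    diagonal is 1 (the Gi* convention), without it the diagonal is 0 (the
    Moran's I convention).
    """

    n: int
    band_m: float
    include_self: bool
    matrix: sparse.csr_matrix = field(repr=False)

    def neighbours(self, i: int) -> np.ndarray:
        return self.matrix.indices[self.matrix.indptr[i] : self.matrix.indptr[i + 1]]

    @property
    def cardinalities(self) -> np.ndarray:
        return np.diff(self.matrix.indptr)

    @property
    def total_weight(self) -> float:
        return float(self.matrix.sum())


def build_weights(pp: ProjectedPoints | np.ndarray, band_m: float, include_self: bool = False) -> SpatialWeights:
    """Build closed distance-band binary weights (d <= band) in the plane.

    Coincident points (d = 0, distinct indices) are neighbours; a point is
    never its own neighbour unless ``include_self``.
    """
    xy = pp.xy if isinstance(pp, ProjectedPoints) else np.asarray(pp, dtype=float)
    n = len(xy)
    if n < 2:
        raise ValueError("need at least two points to build weights")
    if not band_m > 0:
        raise ValueError("band_m must be positive")
    tree = cKDTree(xy)
    pairs = tree.query_pairs(band_m, output_type="ndarray")  # d <= band, i < j
    rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
    cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
    data = np.ones(len(rows))
    mat = sparse.coo_matrix((data, (rows, cols)), shape=(n, n))
    if include_self:
        mat = mat + sparse.identity(n, format="coo")
    return SpatialWeights(n=n, band_m=float(band_m), include_self=include_self, matrix=mat.tocsr())
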