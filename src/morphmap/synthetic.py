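"""Synthetic specimen sets and class rasters with known planted structure.

The generator emulates the statistical features the spatial analyses rely
on, so every stage can be tested against a known truth without any
external data:

* collection localities of strongly varying density — uniform background
  points plus disc-shaped clusters of over-collecting, with several
  specimens multinomially assigned to each cluster site (collectors
  revisit productive localities, so per-site counts vary);
* per-region morph compositions, with imperfect-mimic morphs concentrated
  in a designated "transitional" region: each specimen whose drawn morph is
  imperfect targets the inside of the transitional polygon with probability
  1 − ε (outside with probability ε) and is relocated only if it is on the
  wrong side, so the planted inside-probability is exactly 1 − ε while the
  clustered point pattern is disturbed as little as possible;
* a class-structured environmental raster in which occurrences occupy only
  a subset of classes, so hull clipping has something to remove.

All randomness flows from one seeded :class:`numpy.random.Generator`
threaded through every stage; the same seed reproduces the same records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Point, Polygon, box
from shapely.ops import unary_union

from .projection import AFRICA_ALBERS, AlbersEqualArea
from .raster import ClassRaster
from .records import RecordSet, SpecimenRecord
from .registry import MorphRegistry, default_registry

__all__ = [
    "Cluster",
    "Region",
    "SyntheticConfig",
    "generate_records",
    "generate_raster",
    "generate_csr",
    "reference_scenario",
    "overlay_scenario",
]


@dataclass(frozen=True)
class Cluster:
    centre_xy: tuple[float, float]
    radius_m: float
    n_points: int


@dataclass(frozen=True)
class Region:
    polygon: Polygon
    subspecies: str
    morph_freqs: dict[str, float]  # morph drawn for each female in the region


@dataclass
class SyntheticConfig:
    seed: int
    extent: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax metres
    n_background: int
    clusters: list[Cluster] = field(default_factory=list)
    regions: list[Region] = field(default_factory=list)
    transitional: list[int] = field(default_factory=list)  # region indices
    imperfect_leak: float = 0.1
    raster_classes: list[tuple[Polygon, int]] = field(default_factory=list)
    cell_m: float = 10_000.0
    female_fraction: float = 0.464
    geocode_error_max_km: float = 60.0
    cluster_site_fraction: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.imperfect_leak <= 1.0:
            raise ValueError("imperfect_leak must be in [0, 1]")
        for c in self.clusters:
            if c.n_points < 0:
                raise ValueError("cluster n_points must be >= 0")
        for r in self.regions:
            total = sum(r.morph_freqs.values())
            if r.morph_freqs and abs(total - 1.0) > 1e-9:
                raise ValueError(f"region {r.subspecies!r}: morph frequencies sum to {total}")

    @property
    def transitional_polygon(self):
        if not self.transitional:
            return None
        return unary_union([self.regions[i].polygon for i in self.transitional])


def _uniform_in_extent(rng: np.random.Generator, extent, n: int) -> np.ndarray:
    xmin, ymin, xmax, ymax = extent
    return np.column_stack(
        [rng.uniform(xmin, xmax, n), rng.uniform(ymin, ymax, n)]
    )


def _uniform_in_polygon(rng: np.random.Generator, poly, max_tries: int = 10_000) -> tuple[float, float]:
    xmin, ymin, xmax, ymax = poly.bounds
    for _ in range(max_tries):
        x = rng.uniform(xmin, xmax)
        y = rng.uniform(ymin, ymax)
        if poly.covers(Point(x, y)):
            return (x, y)
    raise RuntimeError("rejection sampling failed: polygon area too small?")


def _uniform_outside_polygon(rng: np.random.Generator, extent, poly, max_tries: int = 10_000) -> tuple[float, float]:
    xmin, ymin, xmax, ymax = extent
    for _ in range(max_tries):
        x = rng.uniform(xmin, xmax)
        y = rng.uniform(ymin, ymax)
        if not poly.covers(Point(x, y)):
            return (x, y)
    raise RuntimeError("rejection sampling failed: polygon nearly fills the extent")


def generate_csr(n: int, extent, seed_or_rng) -> np.ndarray:
    """Complete spatial randomness: n uniform independent points in extent."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    return _uniform_in_extent(rng, extent, n)


def _cluster_points(rng: np.random.Generator, cfg: SyntheticConfig, cluster: Cluster) -> np.ndarray:
    """Specimen coordinates for one cluster: few unique sites, many visits."""
    n = cluster.n_points
    if n == 0:
        return np.empty((0, 2))
    n_sites = max(3, int(round(n * cfg.cluster_site_fraction)))
    n_sites = min(n_sites, n)
    xmin, ymin, xmax, ymax = cfg.extent
    sites = np.empty((n_sites, 2))
    cx, cy = cluster.centre_xy
    for i in range(n_sites):
        while True:  # rejection: keep sites inside the study extent
            r = cluster.radius_m * np.sqrt(rng.uniform())
            a = rng.uniform(0, 2 * np.pi)
            x, y = cx + r * np.cos(a), cy + r * np.sin(a)
            if xmin <= x <= xmax and ymin <= y <= ymax:
                sites[i] = (x, y)
                break
    assignment = rng.integers(0, n_sites, size=n)
    return sites[assignment]


def generate_records(
    cfg: SyntheticConfig,
    registry: MorphRegistry | None = None,
    projection: AlbersEqualArea = AFRICA_ALBERS,
) -> RecordSet:
    """Draw a reproducible synthetic specimen record set.

    Background specimens are CSR on the extent; cluster specimens are
    multinomially spread over uniform sites within each disc.  Sex is
    female with ``female_fraction``; females draw a morph from their
    region's frequency table, males carry none.  Imperfect morphs are
    relocated into/out of the transitional polygon per ``imperfect_leak``.
    Geocode errors are uniform on [0, ``geocode_error_max_km``] so the
    40 km curation filter has bite.  Coordinates are stored as WGS84
    lat/lon via the inverse projection.
    """
    registry = registry or default_registry()
    rng = np.random.default_rng(cfg.seed)
    chunks = [_cluster_points(rng, cfg, c) for c in cfg.clusters]
    chunks.append(_uniform_in_extent(rng, cfg.extent, cfg.n_background))
    xy = np.vstack(chunks) if chunks else np.empty((0, 2))
    trans_poly = cfg.transitional_polygon

    def region_at(x: float, y: float) -> Optional[Region]:
        p = Point(x, y)
        for reg in cfg.regions:
            if reg.polygon.covers(p):
                return reg
        return None

    records: list[SpecimenRecord] = []
    n_unlabelled = 0
    for i in range(len(xy)):
        x, y = float(xy[i, 0]), float(xy[i, 1])
        region = region_at(x, y)
        sex = "female" if rng.uniform() < cfg.female_fraction else "male"
        morph = ""
        if sex == "female" and region is not None and region.morph_freqs:
            morphs = list(region.morph_freqs)
            probs = np.array([region.morph_freqs[m] for m in morphs])
            morph = morphs[rng.choice(len(morphs), p=probs / probs.sum())]
        if morph and registry.is_imperfect(morph) and trans_poly is not None:
            # place inside the transitional polygon with prob 1 - leak,
            # moving the point only when its current side disagrees
            target_inside = rng.uniform() < 1.0 - cfg.imperfect_leak
            inside_now = trans_poly.covers(Point(x, y))
            if target_inside and not inside_now:
                x, y = _uniform_in_polygon(rng, trans_poly)
            elif not target_inside and inside_now:
                x, y = _uniform_outside_polygon(rng, cfg.extent, trans_poly)
            region = region_at(x, y)
        if region is None:
            n_unlabelled += 1
        lat, lon = projection.inverse(x, y)
        records.append(
            SpecimenRecord(
                voucher_id=f"SYN{i + 1:06d}",
                sex=sex,
                morph=morph,
                morph_group=registry.group_of(morph) if morph else "",
                subspecies=region.subspecies if region is not None else "",
                country=region.subspecies if region is not None else "",
                locality=f"synthetic site ({x / 1000:.1f} km, {y / 1000:.1f} km)",
                latitude=float(lat),
                longitude=float(lon),
                geocode_error_km=float(rng.uniform(0.0, cfg.geocode_error_max_km)),
            )
        )
    if n_unlabelled:
        warnings.warn(
            f"{n_unlabelled} point(s) fall outside every region polygon and carry empty labels",
            stacklevel=2,
        )
    return RecordSet(records, provenance=f"synthetic(seed={cfg.seed})")


def generate_raster(cfg: SyntheticConfig) -> ClassRaster:
    """Class raster on the extent: each cell takes the class of the first
    listed polygon covering its centre, nodata elsewhere."""
    import shapely

    xmin, ymin, xmax, ymax = cfg.extent
    nx = int(np.ceil((xmax - xmin) / cfg.cell_m))
    ny = int(np.ceil((ymax - ymin) / cfg.cell_m))
    cx = xmin + (np.arange(nx) + 0.5) * cfg.cell_m
    cy = ymin + (np.arange(ny) + 0.5) * cfg.cell_m
    gx, gy = np.meshgrid(cx, cy)
    centres = shapely.points(np.column_stack([gx.ravel(), gy.ravel()]))
    grid = np.full(nx * ny, -9999, dtype=int)
    for poly, class_id in reversed(cfg.raster_classes):  # first-listed wins
        grid[shapely.covers(poly, centres)] = class_id
    return ClassRaster(origin_xy=(xmin, ymin), cell_m=cfg.cell_m, grid=grid.reshape(ny, nx), nodata=-9999)


# ---------------------------------------------------------------------------
# Shipped scenarios


def reference_scenario(seed: int = 20140516) -> SyntheticConfig:
    """The documented reference scenario driving the end-to-end checks.

    A 7000 x 7000 km study window (continental scale): three dense,
    widely separated collecting clusters (radius 150 km, so planted
    clustering scale = 300 km diameter) inside the transitional belt —
    echoing the heavy historical collecting around Lake Victoria — over a
    thin uniform background; five faunal regions (a Western and an Eastern
    mainland region, a two-part transitional belt, and an island block)
    with distinct morph compositions; imperfect-morph leakage ε = 0.1; and
    a five-class environmental raster aligned with the faunal regions, so
    each taxon's hull is clipped to the classes it actually occupies.
    """
    xmin, xmax = -3.5e6, 3.5e6
    ymin, ymax = -3.5e6, 3.5e6
    extent = (xmin, ymin, xmax, ymax)
    island = box(2.2e6, -3.5e6, 3.5e6, -2.2e6)
    west = box(xmin, ymin, 0.2e6, ymax)
    meseres = box(0.2e6, -2.0e6, 0.7e6, 2.0e6)
    polytrophus = box(0.7e6, -2.0e6, 1.1e6, 2.0e6)
    east = (
        box(1.1e6, ymin, xmax, ymax)
        .difference(island)
        .union(box(0.2e6, ymin, 1.1e6, -2.0e6))
        .union(box(0.2e6, 2.0e6, 1.1e6, ymax))
    )
    regions = [
        Region(island, "meriones", {"meriones": 1.0}),
        Region(
            west,
            "dardanus",
            {
                "hippocoon": 0.25,
                "dionysos": 0.15,
                "planemoides": 0.15,
                "trophonius": 0.15,
                "cenea": 0.10,
                "niobe": 0.10,
                "natalica": 0.10,
            },
        ),
        Region(
            meseres,
            "meseres",
            {
                "hippocoonides": 0.20,
                "cenea": 0.15,
                "meseres": 0.15,
                "salaami": 0.10,
                "planemoides": 0.10,
                "trimeni": 0.08,
                "lamborni": 0.07,
                "mixtoides": 0.05,
                "intermediate": 0.10,
            },
        ),
        Region(
            polytrophus,
            "polytrophus",
            {
                "hippocoonides": 0.20,
                "cenea": 0.15,
                "meseres": 0.10,
                "poultoni": 0.10,
                "planemoides": 0.05,
                "trimeni": 0.10,
                "swynnertoni": 0.05,
                "carpenteri": 0.05,
                "lamborni": 0.05,
                "intermediate": 0.15,
            },
        ),
        Region(
            east,
            "tibullus",
            {
                "cenea": 0.25,
                "trophonius": 0.20,
                "hippocoonides": 0.25,
                "salaami": 0.10,
                "natalica": 0.10,
                "poultoni": 0.08,
                "trimeni": 0.02,
            },
        ),
    ]
    south = box(xmin, ymin, 2.2e6, -3.0e6)
    raster_classes = [
        (island, 4),
        (south, 5),
        (box(xmin, ymin, 0.2e6, ymax), 1),
        (box(0.2e6, -2.0e6, 1.1e6, 2.0e6), 2),
        (east, 3),
    ]
    clusters = [
        Cluster((0.45e6, 1.50e6), 150_000.0, 400),
        Cluster((0.85e6, -0.10e6), 150_000.0, 350),
        Cluster((0.40e6, -1.60e6), 150_000.0, 300),
    ]
    return SyntheticConfig(
        seed=seed,
        extent=extent,
        n_background=3500,
        clusters=clusters,
        regions=regions,
        transitional=[2, 3],
        imperfect_leak=0.1,
        raster_classes=raster_classes,
        cell_m=10_000.0,
    )


def overlay_scenario(seed: int, n_records: int = 500, leak: float = 0.1) -> SyntheticConfig:
    """A minimal scenario for the overlay-recovery check: every female draws
    an imperfect morph, so ~all records test the planted inside-fraction."""
    extent = (-1.5e6, -1.0e6, 1.5e6, 1.0e6)
    trans = box(-0.4e6, -0.4e6, 0.4e6, 0.4e6)
    outside = box(*extent).difference(trans)
    freqs = {"intermediate": 0.3, "trimeni": 0.25, "lamborni": 0.25, "mixtoides": 0.2}
    regions = [
        Region(trans, "meseres", dict(freqs)),
        Region(outside, "tibullus", dict(freqs)),
    ]
    return SyntheticConfig(
        seed=seed,
        extent=extent,
        n_background=n_records,
        clusters=[],
        regions=regions,
        transitional=[0],
        imperfect_leak=leak,
        raster_classes=[(box(*extent), 1)],
        cell_m=100_000.0,
        female_fraction=1.0,
    )
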