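"""Adaptive-a local convex hull (LoCoH) utilization distributions, isopleth
core areas, overlap decomposition and spatial gregariousness indices.

The LoCoH estimator builds, around every sighting, the convex hull of the
point and its nearest neighbours; in *adaptive* mode the neighbour set of a
point grows outward until the cumulative distance from the point to its
neighbours would exceed a user-supplied bound ``a`` (metres).  Sorting the
hulls densest-first and accumulating their union until a target fraction of
sightings is covered yields an isopleth; the 60% isopleth is used throughout
as the *core area* — the region where an individual concentrates activity.

Two summary indices quantify how much individual core areas coincide:

* group spatial gregariousness  gSGI  = (sum_{i>=2} i * O_i) / (K * A)
* individual spatial gregariousness  iSGI_x = (sum_{i>=2} i * O_ix) / (K * A_x)

where ``A`` is the union area of all ``K`` core areas, ``O_i`` the area
covered by *exactly* ``i`` of them, and for the individual form the overlaps
``O_ix`` are clipped to the focal individual's own core area ``A_x`` with the
focal's own core counted in the multiplicity.  Both range from 0 (pairwise
disjoint) to 1 (all core areas identical).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import MultiPoint, Point, Polygon, MultiPolygon
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from fisofus.errors import ConfigurationError, EstimationError, InsufficientDataError

M2_PER_HA = 1e4

__all__ = [
    "Hull", "Isopleth", "CoreArea", "OverlapDecomposition",
    "build_hulls_adaptive", "isopleth_from_hulls", "core_area",
    "a_selection_diagnostics", "overlap_decomposition",
    "group_spatial_gregariousness", "individual_spatial_gregariousness",
    "isgi_by_sex", "core_area_to_geojson",
]


@dataclass
class Hull:
    """Local convex hull around one parent point."""

    parent_index: int
    parent: tuple[float, float]
    neighbor_indices: np.ndarray
    polygon: BaseGeometry
    enclosed_count: int
    degenerate: bool = False

    @property
    def area(self) -> float:
        return self.polygon.area


@dataclass
class Isopleth:
    """Region accumulated from the densest hulls until ``level`` of the
    points are covered."""

    level: float
    region: BaseGeometry
    area_ha: float
    points_covered: int
    total_points: int


@dataclass
class CoreArea:
    """Seasonal core area of one individual (the 0.60 isopleth by default)."""

    individual_id: str
    season: str
    isopleth: Isopleth
    n_points: int
    a_value: float

    @property
    def region(self) -> BaseGeometry:
        return self.isopleth.region

    @property
    def area_ha(self) -> float:
        return self.isopleth.area_ha


@dataclass
class OverlapDecomposition:
    """Union area ``A`` split by overlap multiplicity.

    ``per_multiplicity[i]`` (1-based, in hectares) is the area covered by
    exactly ``i`` of the ``K`` input regions; the entries sum to ``A``.
    """

    union_area_ha: float
    per_multiplicity: dict[int, float]
    k: int
    pieces: list[tuple[BaseGeometry, int]] = field(default_factory=list, repr=False)

    @property
    def max_multiplicity(self) -> int:
        pos = [i for i, a in self.per_multiplicity.items() if a > 0]
        return max(pos) if pos else 0


# ---------------------------------------------------------------------------
# hull construction

def build_hulls_adaptive(points: np.ndarray, a: float,
                         jitter: float = 0.0, seed: int | None = None) -> list[Hull]:
    """Build one adaptive local convex hull per point.

    For each parent point the other points are ranked by distance; neighbours
    are included in increasing order while the running sum of distances stays
    ``<= a``.  Collinear or duplicate neighbour sets give zero-area polygons
    flagged ``degenerate`` (still usable: they cover their own point).

    Parameters
    ----------
    points : (n, 2) array of projected coordinates in metres (n >= 3 distinct).
    a : cumulative-distance bound in metres.
    jitter : if > 0, duplicate coordinates are displaced uniformly by at most
        this amount (metres) before hull construction, seeded by ``seed``.
        Keeps repeated scan locations from collapsing the geometry.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ConfigurationError("points must be an (n, 2) array")
    if a <= 0:
        raise ConfigurationError("a must be positive")
    if len(pts) < 3:
        raise InsufficientDataError("need at least 3 points for LoCoH")
    if jitter > 0:
        pts = _jitter_duplicates(pts, jitter, seed)

    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])
    n = len(pts)
    hulls: list[Hull] = []
    point_geoms = shapely.points(pts)
    for i in range(n):
        order = np.argsort(dist[i], kind="stable")
        order = order[order != i]
        csum = np.cumsum(dist[i][order])
        neighbors = order[csum <= a]
        members = np.concatenate(([i], neighbors))
        geom = MultiPoint(pts[members]).convex_hull
        degenerate = geom.area == 0.0
        if isinstance(geom, Point) or degenerate:
            poly = geom
            enclosed = int(np.sum(shapely.intersects(geom, point_geoms))) \
                if not isinstance(geom, Point) else int(np.sum((pts == pts[i]).all(axis=1)))
        else:
            poly = geom
            enclosed = int(np.sum(shapely.covers(poly, point_geoms)))
        hulls.append(Hull(i, (pts[i, 0], pts[i, 1]), neighbors, poly,
                          max(enclosed, 1), degenerate))
    if all(h.degenerate for h in hulls):
        warnings.warn("all hulls degenerate (collinear or duplicated points)")
    return hulls


def _jitter_duplicates(pts: np.ndarray, amount: float, seed: int | None) -> np.ndarray:
    """Displace repeated coordinates by <= ``amount`` metres (seeded)."""
    rng = np.random.default_rng(seed)
    out = pts.copy()
    _, first = np.unique(out, axis=0, return_index=True)
    dup_mask = np.ones(len(out), dtype=bool)
    dup_mask[first] = False
    ndup = int(dup_mask.sum())
    if ndup:
        out[dup_mask] += rng.uniform(-amount, amount, size=(ndup, 2))
    return out


def isopleth_from_hulls(hulls: list[Hull], level: float,
                        total_points: int | None = None,
                        points: np.ndarray | None = None) -> Isopleth:
    """Accumulate hulls densest-first into the ``level`` isopleth.

    Hulls are sorted by enclosed point count (descending), ties broken by
    smaller area then parent index, and unioned until the covered fraction of
    parent points reaches ``level``.  Boundary points count as covered.
    """
    if not (0.0 < level <= 1.0):
        raise ConfigurationError("level must be in (0, 1]")
    live = [h for h in hulls if not h.degenerate]
    if not live:
        raise EstimationError("all hulls degenerate; cannot form an isopleth")
    if points is None:
        points = np.array([h.parent for h in hulls])
    total = total_points if total_points is not None else len(points)
    point_geoms = shapely.points(np.asarray(points, dtype=float))

    order = sorted(live, key=lambda h: (-h.enclosed_count, h.area, h.parent_index))
    covered = np.zeros(len(point_geoms), dtype=bool)
    parts: list[BaseGeometry] = []
    needed = level * total
    n_cov = 0
    for h in order:
        parts.append(h.polygon)
        newly = ~covered
        if newly.any():
            hit = shapely.covers(h.polygon, point_geoms[newly])
            covered[np.flatnonzero(newly)[hit]] = True
        n_cov = int(covered.sum())
        if n_cov >= needed - 1e-9:
            break
    region = unary_union(parts)
    return Isopleth(level, region, region.area / M2_PER_HA, n_cov, total)


def core_area(t, ind: str, season: str, a: float, level: float = 0.60,
              min_points: int = 10, jitter: float = 0.01,
              jitter_seed: int = 0) -> CoreArea:
    """Seasonal core area for one individual from its own scan locations.

    The same ``a`` should be used for every individual and season of an
    analysis run.  Duplicate coordinates are jittered by up to ``jitter``
    metres (default 1 cm, seeded) so repeated scan locations do not collapse
    hulls; pass ``jitter=0`` to disable.
    """
    df = t.df
    if "season" not in df.columns:
        raise ConfigurationError("seasons not assigned; call with_seasons first")
    sub = df[(df["individual_id"] == ind) & (df["season"] == season)]
    if len(sub) < min_points:
        raise InsufficientDataError(
            f"{ind} has {len(sub)} sightings in {season}; floor is {min_points}")
    pts = sub[["x", "y"]].to_numpy(dtype=float)
    hulls = build_hulls_adaptive(pts, a, jitter=jitter, seed=jitter_seed)
    iso = isopleth_from_hulls(hulls, level, points=pts)
    return CoreArea(ind, season, iso, len(pts), a)


def a_selection_diagnostics(points: np.ndarray, candidates: list[float],
                            barriers: list[BaseGeometry] | None = None,
                            level: float = 0.60) -> list[dict]:
    """Diagnostics to guide the choice of the adaptive bound ``a``.

    Returns one row per candidate with the patch count and total area of the
    ``level`` isopleth, plus the area intersecting known barrier polygons
    (areas the animals demonstrably do not use, e.g. a lake).  In practice
    ``a`` is chosen as a compromise between few separate patches and minimal
    barrier intrusion; no choice is made automatically.
    """
    if not candidates:
        raise ConfigurationError("candidates must be non-empty")
    barrier_union = unary_union(barriers) if barriers else None
    rows = []
    pts = np.asarray(points, dtype=float)
    for a in candidates:
        hulls = build_hulls_adaptive(pts, a)
        try:
            iso = isopleth_from_hulls(hulls, level, points=pts)
        except EstimationError:
            rows.append({"a": a, "patch_count": 0, "total_area_ha": 0.0,
                         "barrier_intersection_ha": 0.0})
            continue
        region = iso.region
        patches = len(region.geoms) if isinstance(region, MultiPolygon) else 1
        inter = region.intersection(barrier_union).area / M2_PER_HA \
            if barrier_union is not None else 0.0
        rows.append({"a": a, "patch_count": patches,
                     "total_area_ha": iso.area_ha,
                     "barrier_intersection_ha": inter})
    return rows


# ---------------------------------------------------------------------------
# overlap decomposition and gregariousness

def _decompose(regions: list[BaseGeometry]) -> list[tuple[BaseGeometry, int]]:
    """Split the union of ``regions`` into pieces of constant multiplicity.

    Incremental overlay: each new region intersects every existing piece
    (raising its count) and contributes its remainder at count 1.
    """
    pieces: list[tuple[BaseGeometry, int]] = []
    union_so_far: BaseGeometry | None = None
    for reg in regions:
        new_pieces: list[tuple[BaseGeometry, int]] = []
        for geom, count in pieces:
            inter = geom.intersection(reg)
            rest = geom.difference(reg)
            if inter.area > 0:
                new_pieces.append((inter, count + 1))
            if rest.area > 0:
                new_pieces.append((rest, count))
        fresh = reg if union_so_far is None else reg.difference(union_so_far)
        if fresh.area > 0:
            new_pieces.append((fresh, 1))
        union_so_far = reg if union_so_far is None else unary_union([union_so_far, reg])
        pieces = new_pieces
    return pieces


def overlap_decomposition(core_areas: list) -> OverlapDecomposition:
    """Exact per-multiplicity decomposition of a set of core areas.

    Accepts :class:`CoreArea` objects (same season required) or raw shapely
    geometries.  ``O_i`` is the area covered by *exactly* ``i`` inputs.
    """
    regions = _as_regions(core_areas)
    if len(regions) < 2:
        raise ConfigurationError("need at least 2 core areas")
    seasons = {ca.season for ca in core_areas if isinstance(ca, CoreArea)}
    if len(seasons) > 1:
        raise ConfigurationError(f"mixed seasons in decomposition: {sorted(seasons)}")
    pieces = _decompose(regions)
    per: dict[int, float] = {i: 0.0 for i in range(1, len(regions) + 1)}
    for geom, count in pieces:
        per[count] += geom.area / M2_PER_HA
    union_area = sum(per.values())
    return OverlapDecomposition(union_area, per, len(regions), pieces)


def _as_regions(objs) -> list[BaseGeometry]:
    return [o.region if isinstance(o, CoreArea) else o for o in objs]


def group_spatial_gregariousness(d: OverlapDecomposition) -> float:
    """gSGI = (sum_{i>=2} i*O_i) / (K*A): 1 for K identical core areas, 0
    when all are pairwise disjoint."""
    if d.union_area_ha <= 0:
        raise EstimationError("union area is zero; gSGI undefined")
    num = sum(i * o for i, o in d.per_multiplicity.items() if i >= 2)
    return num / (d.k * d.union_area_ha)


def individual_spatial_gregariousness(x, others: list) -> float:
    """iSGI for focal core area ``x`` against ``others``.

    Overlap multiplicities are measured inside ``A_x`` only and count the
    focal's own core area, so the index reaches 1 when every core area
    coincides with ``A_x`` and 0 when ``x`` is disjoint from all others.
    """
    x_region = x.region if isinstance(x, CoreArea) else x
    regions = _as_regions(others)
    ax = x_region.area / M2_PER_HA
    if ax <= 0:
        raise EstimationError("focal core area has zero area; iSGI undefined")
    k = len(regions) + 1
    pieces = _decompose([x_region] + regions)
    num = 0.0
    for geom, count in pieces:
        if count >= 2:
            clipped = geom.intersection(x_region)
            num += count * clipped.area / M2_PER_HA
    return num / (k * ax)


def isgi_by_sex(core_areas: list[CoreArea], roster) -> dict[str, float | None]:
    """Per-individual iSGI restricted to same-sex core areas.

    Individuals whose sex class has a single member get ``None`` (the index
    is undefined without at least one same-sex partner).
    """
    sexes = roster.sexes if hasattr(roster, "sexes") else dict(roster)
    out: dict[str, float | None] = {}
    for ca in core_areas:
        sex = sexes.get(ca.individual_id, "unknown")
        same = [o for o in core_areas
                if o.individual_id != ca.individual_id
                and sexes.get(o.individual_id) == sex]
        out[ca.individual_id] = (individual_spatial_gregariousness(ca, same)
                                 if same else None)
    return out


# ---------------------------------------------------------------------------
# export

def core_area_to_geojson(cas: list[CoreArea]) -> dict:
    """GeoJSON FeatureCollection of core-area polygons with metadata
    properties (individual, season, isopleth level, a value, area in ha)."""
    from shapely.geometry import mapping

    feats = []
    for ca in cas:
        feats.append({
            "type": "Feature",
            "geometry": mapping(ca.region),
            "properties": {
                "individual_id": ca.individual_id,
                "season": ca.season,
                "level": ca.isopleth.level,
                "a_value": ca.a_value,
                "area_ha": ca.area_ha,
                "n_points": ca.n_points,
            },
        })
    return {"type": "FeatureCollection", "features": feats}
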