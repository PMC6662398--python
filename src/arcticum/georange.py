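"""Range-polygon construction and pairwise contact (sympatry) analysis.

A taxon's geographic range is operationalised as the convex hull of its
collection points in an equal-area projected plane; taxa known from fewer
than three locations (or only collinear ones) instead get a 5-km buffer
around their point or segment, a distance well inside known black-fly
dispersal.  Two taxa are in *contact* when their range polygons intersect
(shared interior or touching boundary); sympatry of a cytotype is contact
with at least one full sibling species.

Projection: an Albers equal-area conic on the authalic sphere with standard
parallels 20N and 60N and central meridian 96W -- a conventional equal-area
choice for North America.  Equal-area is essential because polygon areas in
km2 are read straight off the projected plane.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LineString, MultiPoint, Point, Polygon, mapping
from shapely.geometry.base import BaseGeometry

from .records import Accuracy, Rank, Site, TaxonCatalog

#: Authalic (equal-area) sphere radius in metres for the WGS84 ellipsoid.
AUTHALIC_RADIUS_M = 6_371_007.181


@dataclass(frozen=True)
class AlbersEqualArea:
    """Spherical Albers equal-area conic projection (forward and inverse).

    Defaults are the conventional North-American parametrisation: standard
    parallels 20N / 60N, latitude of origin 40N, central meridian 96W.
    Coordinates are in metres.
    """

    std_parallel_1: float = 20.0
    std_parallel_2: float = 60.0
    lat_origin: float = 40.0
    lon_origin: float = -96.0
    false_easting: float = 0.0
    false_northing: float = 0.0
    radius: float = AUTHALIC_RADIUS_M

    def _constants(self) -> tuple[float, float, float]:
        phi1 = math.radians(self.std_parallel_1)
        phi2 = math.radians(self.std_parallel_2)
        n = 0.5 * (math.sin(phi1) + math.sin(phi2))
        c = math.cos(phi1) ** 2 + 2.0 * n * math.sin(phi1)
        rho0 = self.radius * math.sqrt(c - 2.0 * n * math.sin(math.radians(self.lat_origin))) / n
        return n, c, rho0

    def forward(self, lon, lat):
        """Project lon/lat (degrees) to x/y (metres). Vectorised."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        if np.any(np.abs(lat) > 90.0) or np.any(np.abs(lon) > 180.0):
            raise ValueError("coordinates outside valid lon/lat range")
        n, c, rho0 = self._constants()
        rho = self.radius * np.sqrt(c - 2.0 * n * np.sin(np.radians(lat))) / n
        theta = n * np.radians(lon - self.lon_origin)
        x = rho * np.sin(theta) + self.false_easting
        y = rho0 - rho * np.cos(theta) + self.false_northing
        return x, y

    def inverse(self, x, y):
        """Unproject x/y (metres) back to lon/lat (degrees). Vectorised."""
        x = np.asarray(x, dtype=float) - self.false_easting
        y = np.asarray(y, dtype=float) - self.false_northing
        n, c, rho0 = self._constants()
        rho = np.hypot(x, rho0 - y)
        theta = np.arctan2(x, rho0 - y)
        sin_phi = (c - (rho * n / self.radius) ** 2) / (2.0 * n)
        lat = np.degrees(np.arcsin(np.clip(sin_phi, -1.0, 1.0)))
        lon = self.lon_origin + np.degrees(theta / n)
        return lon, lat


def project_points(
    sites: Sequence[Site],
    projection: Optional[AlbersEqualArea] = None,
    exclude_county_centroids: bool = False,
) -> np.ndarray:
    """Forward-project site coordinates; returns an (n, 2) array of metres.

    County-centroid sites participate by default (their ~100-km error is
    small against continental ranges); ``exclude_county_centroids`` drops
    them.
    """
    proj = projection or AlbersEqualArea()
    kept = [
        s
        for s in sites
        if not (exclude_county_centroids and s.accuracy is Accuracy.COUNTY_CENTROID)
    ]
    if not kept:
        return np.empty((0, 2))
    x, y = proj.forward([s.lon for s in kept], [s.lat for s in kept])
    return np.column_stack([x, y])


class RangeMethod(str, Enum):
    CONVEX_HULL = "convex_hull"
    BUFFER_5KM = "buffer_5km"


#: Buffer radius applied to under-sampled taxa, metres (5 km).
BUFFER_RADIUS_M = 5_000.0


@dataclass
class RangePolygon:
    taxon: str
    rank: Rank
    method: RangeMethod
    polygon: Polygon
    n_locations: int

    @property
    def area_km2(self) -> float:
        return self.polygon.area / 1e6


def _collinear(points: np.ndarray) -> bool:
    hull = MultiPoint([tuple(p) for p in points]).convex_hull
    return not isinstance(hull, Polygon)


def build_range_polygon(
    taxon: str,
    points: np.ndarray,
    rank: Rank = Rank.CYTOTYPE,
    buffer_radius_m: float = BUFFER_RADIUS_M,
    mask: Optional[BaseGeometry] = None,
) -> RangePolygon:
    """Construct a taxon's range polygon from projected collection points.

    Three or more non-collinear points yield a convex hull; one point a
    buffer disc; two points (or any collinear set) a buffered segment.  An
    optional mask polygon (e.g. a coastline) clips the result.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(points)
    if n == 0:
        raise ValueError(f"taxon {taxon!r}: no locations")
    if n == 1:
        geom = Point(points[0]).buffer(buffer_radius_m, quad_segs=256)
        method = RangeMethod.BUFFER_5KM
    elif n == 2 or _collinear(points):
        # Degenerate hulls (zero area) would make contact counting vacuous;
        # buffer the extremal segment instead.
        mp = MultiPoint([tuple(p) for p in points])
        hull = mp.convex_hull  # Point or LineString
        geom = hull.buffer(buffer_radius_m, quad_segs=256)
        method = RangeMethod.BUFFER_5KM
    else:
        geom = MultiPoint([tuple(p) for p in points]).convex_hull
        method = RangeMethod.CONVEX_HULL
    if mask is not None:
        geom = geom.intersection(mask)
    return RangePolygon(
        taxon=taxon, rank=rank, method=method, polygon=geom, n_locations=n
    )


@dataclass
class ContactMatrix:
    """Symmetric boolean contact relation over taxa, with rank metadata."""

    taxa: list[str]
    ranks: list[Rank]
    matrix: np.ndarray  # boolean, symmetric, diagonal False

    def contact(self, a: str, b: str) -> bool:
        i, j = self.taxa.index(a), self.taxa.index(b)
        return bool(self.matrix[i, j])

    def contact_counts(self) -> pd.DataFrame:
        """Per-taxon contact counts split by partner rank (diagonal excluded)."""
        sib = np.array([r is Rank.SIBLING for r in self.ranks])
        rows = []
        for i, (taxon, rank) in enumerate(zip(self.taxa, self.ranks)):
            row = self.matrix[i]
            rows.append(
                {
                    "taxon": taxon,
                    "rank": rank.value,
                    "contacts_siblings": int(row[sib].sum()),
                    "contacts_cytotypes": int(row[~sib].sum()),
                }
            )
        return pd.DataFrame(rows)


def pairwise_contact_matrix(ranges: Sequence[RangePolygon]) -> ContactMatrix:
    """All-pairs polygon intersection tests (boundary touching counts)."""
    if len(ranges) < 2:
        raise ValueError("need at least two ranges")
    n = len(ranges)
    matrix = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            hit = ranges[i].polygon.intersects(ranges[j].polygon)
            matrix[i, j] = matrix[j, i] = hit
    return ContactMatrix(
        taxa=[r.taxon for r in ranges],
        ranks=[r.rank for r in ranges],
        matrix=matrix,
    )


@dataclass
class SympatryCensus:
    n_cytotypes_with_sibling_contact: int
    n_cytotypes_total: int
    group_means: pd.DataFrame  # index: grouping; columns: mean, se, n

    @property
    def sympatry_fraction(self) -> float:
        if self.n_cytotypes_total == 0:
            return float("nan")
        return self.n_cytotypes_with_sibling_contact / self.n_cytotypes_total


def _group_stats(counts: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SE of contact counts for the four rank-pair groupings."""
    rows = []
    for grouping, rank, col in (
        ("sibling_vs_sibling", "sibling", "contacts_siblings"),
        ("sibling_vs_cytotype", "sibling", "contacts_cytotypes"),
        ("cytotype_vs_sibling", "cytotype", "contacts_siblings"),
        ("cytotype_vs_cytotype", "cytotype", "contacts_cytotypes"),
    ):
        vals = counts.loc[counts["rank"] == rank, col].to_numpy(dtype=float)
        n = len(vals)
        mean = float(vals.mean()) if n else float("nan")
        se = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
        rows.append({"grouping": grouping, "mean": mean, "se": se, "n": n})
    return pd.DataFrame(rows).set_index("grouping")


def sympatry_census_from_counts(counts: pd.DataFrame) -> SympatryCensus:
    """Sympatry census from a per-taxon contact-count table.

    ``counts`` needs columns ``taxon, rank, contacts_siblings,
    contacts_cytotypes`` (e.g. the published range summary or
    :meth:`ContactMatrix.contact_counts`).
    """
    cyt = counts[counts["rank"] == "cytotype"]
    return SympatryCensus(
        n_cytotypes_with_sibling_contact=int((cyt["contacts_siblings"] > 0).sum()),
        n_cytotypes_total=len(cyt),
        group_means=_group_stats(counts),
    )


def sympatry_census(
    matrix: ContactMatrix, catalog: Optional[TaxonCatalog] = None
) -> SympatryCensus:
    """Sympatry census from a computed contact matrix.

    When a catalog is supplied its ranks override the matrix's (the two must
    cover the same taxa).
    """
    counts = matrix.contact_counts()
    if catalog is not None:
        missing = set(counts["taxon"]) - set(catalog.names())
        if missing:
            raise ValueError(f"taxa absent from catalog: {sorted(missing)}")
        counts["rank"] = [catalog.rank_of(t).value for t in counts["taxon"]]
        # ranks changed: recompute partner-rank splits from the matrix
        sib = np.array([catalog.rank_of(t) is Rank.SIBLING for t in matrix.taxa])
        counts["contacts_siblings"] = matrix.matrix[:, sib].sum(axis=1)
        counts["contacts_cytotypes"] = matrix.matrix[:, ~sib].sum(axis=1)
    return sympatry_census_from_counts(counts)


def ranges_to_geojson(
    ranges: Sequence[RangePolygon],
    projection: Optional[AlbersEqualArea] = None,
) -> dict:
    """Export ranges as a GeoJSON FeatureCollection in WGS84 lon/lat."""
    proj = projection or AlbersEqualArea()

    def unproject(geom: BaseGeometry) -> dict:
        gj = mapping(geom)

        def conv(coords):
            if coords and isinstance(coords[0], (int, float)):
                lon, lat = proj.inverse(coords[0], coords[1])
                return [float(lon), float(lat)]
            return [conv(list(c)) for c in coords]

        gj = dict(gj)
        gj["coordinates"] = conv([list(c) for c in gj["coordinates"]] if gj["type"] != "Point" else list(gj["coordinates"]))
        return gj

    features = [
        {
            "type": "Feature",
            "geometry": unproject(r.polygon),
            "properties": {
                "taxon": r.taxon,
                "rank": r.rank.value,
                "method": r.method.value,
                "area_km2": r.area_km2,
                "n_locations": r.n_locations,
            },
        }
        for r in ranges
    ]
    return {"type": "FeatureCollection", "features": features}


def write_geojson(obj: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1)
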