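"""Discrete global grids and presence-only aggregation.

Occurrence points (folklore records and real-animal records alike) are
reduced to *presence cells* of a discrete global grid system (DGGS): a
category is either present in a cell or it is not, and per-cell record
counts are deliberately discarded so that wildly uneven sampling effort
cannot leak into any downstream statistic.

Three grid backends are provided:

``fibonacci`` (default)
    A spherical-Voronoi DGGS whose generators are a Fibonacci lattice on
    the unit sphere with exactly ``120 * 7**r + 2`` generators at
    resolution ``r`` — the cell cardinalities of an aperture-7 hexagonal
    hierarchy (122, 842, 5882, ... cells at r = 0, 1, 2, ...). Cells are
    the Voronoi regions of the generators; almost all are hexagon-like.
    Point-to-cell lookup is nearest-generator via a KD-tree on unit
    vectors, which makes the partition property exact by construction.

``h3``
    A thin adapter over the ``h3`` (h3-py) library when it is installed.
    Optional; nothing else in the package imports it.

``latlon``
    A plain equal-angle latitude/longitude grid. Cheap, non-hexagonal,
    useful for debugging; its cell counts do not follow the aperture-7
    cardinalities.
"""

from __future__ import annotations

import math
from abc import ABC, abstractmethod
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, FrozenSet, Iterable, List, Mapping, Set, Tuple

import numpy as np
from scipy.spatial import cKDTree

EARTH_RADIUS_KM = 6371.0
MAX_RESOLUTION = 4

__all__ = [
    "EARTH_RADIUS_KM",
    "MAX_RESOLUTION",
    "GeoPoint",
    "CellId",
    "Role",
    "OccurrenceRecord",
    "PresenceMap",
    "GridBackend",
    "FibonacciVoronoiGrid",
    "EqualAngleGrid",
    "H3Grid",
    "get_backend",
    "point_to_cell",
    "enumerate_cells",
    "cell_centroid",
    "haversine_km",
    "haversine_matrix_km",
    "build_presence",
    "write_presence_tsv",
]


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


@dataclass(frozen=True)
class GeoPoint:
    """A point on the globe in decimal degrees.

    Latitude must lie in [-90, 90]; longitude is normalised on
    construction to the half-open interval [-180, 180) (a longitude of
    exactly 180 becomes -180, so every meridian has one representation).
    """

    lat: float
    lon: float

    def __post_init__(self) -> None:
        lat, lon = float(self.lat), float(self.lon)
        if not math.isfinite(lat) or not (-90.0 <= lat <= 90.0):
            raise ValidationError(f"lat must be in [-90, 90], got {self.lat!r}")
        if not math.isfinite(lon):
            raise ValidationError(f"lon must be finite, got {self.lon!r}")
        lon = ((lon + 180.0) % 360.0) - 180.0
        object.__setattr__(self, "lat", lat)
        object.__setattr__(self, "lon", lon)

    def unit_vector(self) -> np.ndarray:
        phi = math.radians(self.lat)
        lam = math.radians(self.lon)
        return np.array(
            [math.cos(phi) * math.cos(lam), math.cos(phi) * math.sin(lam), math.sin(phi)]
        )


@dataclass(frozen=True)
class CellId:
    """One cell of a DGGS at a stated resolution. Equality is string equality."""

    id: str
    resolution: int

    def __post_init__(self) -> None:
        if self.resolution < 0:
            raise ValidationError(f"resolution must be >= 0, got {self.resolution}")
        if not self.id:
            raise ValidationError("cell id must be non-empty")


class Role(str, Enum):
    REAL = "real"
    TRICKSTER = "trickster"


@dataclass(frozen=True)
class OccurrenceRecord:
    """A single georeferenced record of a category in a role.

    ``category`` names the animal (e.g. ``"raccoon"``); ``role`` says
    whether the record is a real-animal observation or a folklore
    (trickster) record at the place where the story was collected.
    """

    category: str
    role: Role
    point: GeoPoint
    source: str = ""

    def __post_init__(self) -> None:
        if not self.category:
            raise ValidationError("category must be non-empty")
        if not isinstance(self.role, Role):
            raise ValidationError(f"role must be a Role, got {self.role!r}")


# ---------------------------------------------------------------------------
# Grid backends
# ---------------------------------------------------------------------------


class GridBackend(ABC):
    """Interface every grid backend implements."""

    name: str = "abstract"

    @abstractmethod
    def point_to_cell(self, p: GeoPoint, resolution: int) -> CellId: ...

    @abstractmethod
    def cell_centroid(self, c: CellId) -> GeoPoint: ...

    @abstractmethod
    def enumerate_cells(self, resolution: int) -> Set[CellId]: ...

    def _check_resolution(self, resolution: int) -> None:
        if not (0 <= resolution <= MAX_RESOLUTION):
            raise ValidationError(
                f"resolution must be in [0, {MAX_RESOLUTION}], got {resolution}"
            )


class FibonacciVoronoiGrid(GridBackend):
    """Spherical-Voronoi DGGS on a Fibonacci lattice.

    Resolution ``r`` uses ``N = 120 * 7**r + 2`` generators placed by the
    golden-angle spiral, giving near-uniform cell areas. A cell is the
    set of points closer (chordally, equivalently great-circle) to its
    generator than to any other; the generator is the published cell
    centroid, so ``point_to_cell(cell_centroid(c)) == c`` exactly.
    """

    name = "fibonacci"

    _GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))

    def __init__(self) -> None:
        self._cache: Dict[int, Tuple[np.ndarray, np.ndarray, cKDTree]] = {}

    @staticmethod
    def n_cells(resolution: int) -> int:
        return 120 * 7**resolution + 2

    def _lattice(self, resolution: int):
        if resolution not in self._cache:
            n = self.n_cells(resolution)
            i = np.arange(n, dtype=np.float64)
            z = 1.0 - 2.0 * (i + 0.5) / n
            lon = np.degrees((i * self._GOLDEN_ANGLE) % (2.0 * math.pi))
            lon = ((lon + 180.0) % 360.0) - 180.0
            lat = np.degrees(np.arcsin(np.clip(z, -1.0, 1.0)))
            phi = np.radians(lat)
            lam = np.radians(lon)
            xyz = np.column_stack(
                [np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)]
            )
            self._cache[resolution] = (lat, lon, cKDTree(xyz))
        return self._cache[resolution]

    def _make_id(self, resolution: int, index: int) -> CellId:
        return CellId(f"FV{resolution}-{index}", resolution)

    def _parse_index(self, c: CellId) -> int:
        prefix = f"FV{c.resolution}-"
        if not c.id.startswith(prefix):
            raise ValidationError(f"not a {self.name} cell id: {c.id!r}")
        try:
            index = int(c.id[len(prefix):])
        except ValueError:
            raise ValidationError(f"malformed cell id: {c.id!r}") from None
        if not (0 <= index < self.n_cells(c.resolution)):
            raise ValidationError(f"cell index out of range: {c.id!r}")
        return index

    def point_to_cell(self, p: GeoPoint, resolution: int) -> CellId:
        self._check_resolution(resolution)
        _, _, tree = self._lattice(resolution)
        _, idx = tree.query(p.unit_vector())
        return self._make_id(resolution, int(idx))

    def points_to_cells(self, lats: np.ndarray, lons: np.ndarray, resolution: int) -> List[CellId]:
        """Vectorised lookup for many points at once."""
        self._check_resolution(resolution)
        _, _, tree = self._lattice(resolution)
        phi = np.radians(np.asarray(lats, dtype=float))
        lam = np.radians(np.asarray(lons, dtype=float))
        xyz = np.column_stack(
            [np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)]
        )
        _, idx = tree.query(xyz)
        return [self._make_id(resolution, int(i)) for i in idx]

    def cell_centroid(self, c: CellId) -> GeoPoint:
        index = self._parse_index(c)
        lat, lon, _ = self._lattice(c.resolution)
        return GeoPoint(float(lat[index]), float(lon[index]))

    def enumerate_cells(self, resolution: int) -> Set[CellId]:
        self._check_resolution(resolution)
        return {self._make_id(resolution, i) for i in range(self.n_cells(resolution))}


class EqualAngleGrid(GridBackend):
    """Equal-angle lat/lon grid: resolution r has cells of 45/2**r degrees."""

    name = "latlon"

    def _cell_deg(self, resolution: int) -> float:
        return 45.0 / (2**resolution)

    def point_to_cell(self, p: GeoPoint, resolution: int) -> CellId:
        self._check_resolution(resolution)
        d = self._cell_deg(resolution)
        row = min(int((p.lat + 90.0) // d), int(round(180.0 / d)) - 1)
        col = int((p.lon + 180.0) // d) % int(round(360.0 / d))
        return CellId(f"EA{resolution}-{row}-{col}", resolution)

    def cell_centroid(self, c: CellId) -> GeoPoint:
        try:
            prefix, row, col = c.id.split("-")
            if prefix != f"EA{c.resolution}":
                raise ValueError
            row, col = int(row), int(col)
        except ValueError:
            raise ValidationError(f"not a {self.name} cell id: {c.id!r}") from None
        d = self._cell_deg(c.resolution)
        return GeoPoint(-90.0 + (row + 0.5) * d, -180.0 + (col + 0.5) * d)

    def enumerate_cells(self, resolution: int) -> Set[CellId]:
        self._check_resolution(resolution)
        d = self._cell_deg(resolution)
        n_rows = int(round(180.0 / d))
        n_cols = int(round(360.0 / d))
        return {
            CellId(f"EA{resolution}-{r}-{c}", resolution)
            for r in range(n_rows)
            for c in range(n_cols)
        }


class H3Grid(GridBackend):
    """Adapter over h3-py (any of the v3/v4 APIs). Import is deferred."""

    name = "h3"

    def __init__(self) -> None:
        import h3  # noqa: optional dependency

        self._h3 = h3
        v4 = hasattr(h3, "latlng_to_cell")
        self._to_cell = h3.latlng_to_cell if v4 else h3.geo_to_h3
        self._to_latlng = h3.cell_to_latlng if v4 else h3.h3_to_geo
        self._res0 = h3.get_res0_cells if v4 else h3.get_res0_indexes
        self._children = h3.cell_to_children if v4 else h3.h3_to_children

    def point_to_cell(self, p: GeoPoint, resolution: int) -> CellId:
        self._check_resolution(resolution)
        return CellId(str(self._to_cell(p.lat, p.lon, resolution)), resolution)

    def cell_centroid(self, c: CellId) -> GeoPoint:
        lat, lon = self._to_latlng(c.id)
        return GeoPoint(float(lat), float(lon))

    def enumerate_cells(self, resolution: int) -> Set[CellId]:
        self._check_resolution(resolution)
        out: Set[CellId] = set()
        for base in self._res0():
            if resolution == 0:
                out.add(CellId(str(base), 0))
            else:
                out.update(CellId(str(h), resolution) for h in self._children(base, resolution))
        return out


_BACKENDS: Dict[str, GridBackend] = {}


def get_backend(name: str = "fibonacci") -> GridBackend:
    """Return the (cached) grid backend with the given name."""
    if name not in _BACKENDS:
        if name == "fibonacci":
            _BACKENDS[name] = FibonacciVoronoiGrid()
        elif name == "latlon":
            _BACKENDS[name] = EqualAngleGrid()
        elif name == "h3":
            _BACKENDS[name] = H3Grid()
        else:
            raise ValidationError(f"unknown grid backend: {name!r}")
    return _BACKENDS[name]


# Module-level conveniences bound to a chosen backend -----------------------


def point_to_cell(p: GeoPoint, resolution: int, backend: str | GridBackend = "fibonacci") -> CellId:
    b = backend if isinstance(backend, GridBackend) else get_backend(backend)
    return b.point_to_cell(p, resolution)


def enumerate_cells(resolution: int, backend: str | GridBackend = "fibonacci") -> Set[CellId]:
    b = backend if isinstance(backend, GridBackend) else get_backend(backend)
    return b.enumerate_cells(resolution)


def cell_centroid(c: CellId, backend: str | GridBackend = "fibonacci") -> GeoPoint:
    b = backend if isinstance(backend, GridBackend) else get_backend(backend)
    return b.cell_centroid(c)


# ---------------------------------------------------------------------------
# Great-circle distances
# ---------------------------------------------------------------------------


def haversine_km(a: GeoPoint, b: GeoPoint, radius_km: float = EARTH_RADIUS_KM) -> float:
    """Great-circle distance between two points on a sphere of ``radius_km``."""
    phi1, phi2 = math.radians(a.lat), math.radians(b.lat)
    dphi = phi2 - phi1
    dlam = math.radians(b.lon - a.lon)
    h = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * radius_km * math.asin(min(1.0, math.sqrt(h)))


def haversine_matrix_km(
    lats: np.ndarray, lons: np.ndarray, radius_km: float = EARTH_RADIUS_KM
) -> np.ndarray:
    """Full pairwise great-circle distance matrix for arrays of degrees."""
    phi = np.radians(np.asarray(lats, dtype=float))[:, None]
    lam = np.radians(np.asarray(lons, dtype=float))[:, None]
    dphi = phi - phi.T
    dlam = lam - lam.T
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi) * np.cos(phi.T) * np.sin(dlam / 2.0) ** 2
    return 2.0 * radius_km * np.arcsin(np.minimum(1.0, np.sqrt(h)))


# ---------------------------------------------------------------------------
# Presence maps
# ---------------------------------------------------------------------------


@dataclass
class PresenceMap:
    """Presence-only cell sets per (category, role), at one resolution.

    Per-cell record counts are kept in ``record_counts`` for logging and
    diagnostics only; no statistic in this package reads them.
    """

    resolution: int
    cells: Dict[Tuple[str, Role], FrozenSet[CellId]] = field(default_factory=dict)
    record_counts: Dict[Tuple[str, Role], Counter] = field(default_factory=dict)

    def get(self, category: str, role: Role) -> FrozenSet[CellId]:
        return self.cells.get((category, role), frozenset())

    def categories(self, role: Role | None = None) -> List[str]:
        cats = {k[0] for k in self.cells if role is None or k[1] == role}
        return sorted(cats)

    def __len__(self) -> int:
        return len(self.cells)


def build_presence(
    records: Iterable[OccurrenceRecord],
    resolution: int,
    backend: str | GridBackend = "fibonacci",
) -> PresenceMap:
    """Reduce records to presence-only cell sets.

    Record multiplicity within a cell is discarded; the output is
    invariant under record order and duplication. An empty record list
    yields an empty map.
    """
    b = backend if isinstance(backend, GridBackend) else get_backend(backend)
    sets: Dict[Tuple[str, Role], Set[CellId]] = {}
    counts: Dict[Tuple[str, Role], Counter] = {}
    for rec in records:
        cell = b.point_to_cell(rec.point, resolution)
        key = (rec.category, rec.role)
        sets.setdefault(key, set()).add(cell)
        counts.setdefault(key, Counter())[cell] += 1
    return PresenceMap(
        resolution=resolution,
        cells={k: frozenset(v) for k, v in sets.items()},
        record_counts=counts,
    )


def write_presence_tsv(presence: PresenceMap, path) -> None:
    """Export a presence map as TSV (category, role, cell_id, resolution)."""
    import pandas as pd

    rows = [
        {"category": cat, "role": role.value, "cell_id": c.id, "resolution": presence.resolution}
        for (cat, role), cells in sorted(presence.cells.items())
        for c in sorted(cells, key=lambda x: x.id)
    ]
    pd.DataFrame(rows, columns=["category", "role", "cell_id", "resolution"]).to_csv(
        path, sep="\t", index=False
    )
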