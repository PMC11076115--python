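"""Cell climate assignment and Whittaker biome classification.

Each grid cell receives a (mean annual temperature, annual precipitation)
pair looked up at its centroid on a gridded climate surface. Cells whose
centroid has no climate (ocean) fall back to the mean of the surface
values at the real-animal occurrence coordinates inside the cell — the
rationale being that wherever a real animal was recorded there is land,
so those coordinates sample the cell's terrestrial climate. Cells where
neither route yields both variables are MISSING and are excluded from
biome statistics (but not from the distance-based analyses, which need
no climate).

Classification follows Whittaker's biome scheme: nine named classes in
(MAT degC, annual precipitation cm/yr) space plus an OUTLIER class for
climates outside every named polygon. The packaged polygon file
``data/whittaker_polygons_synthetic.csv`` is a synthetic, stylized
digitization of the classic diagram made for this package (nine simple
polygons tiling -15..30 degC x 0..450 cm); swap in any digitization with
the same schema via :func:`load_biome_polygons`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .gridding import (
    CellId,
    GeoPoint,
    GridBackend,
    OccurrenceRecord,
    PresenceMap,
    Role,
    ValidationError,
    get_backend,
)

OUTLIER = "OUTLIER"

#: The nine named classes, in classification priority order (boundary ties go
#: to the earlier class). OUTLIER is implicit as the tenth label.
BIOME_PRIORITY: Tuple[str, ...] = (
    "tundra",
    "boreal forest",
    "temperate seasonal forest",
    "temperate rain forest",
    "tropical rain forest",
    "tropical seasonal forest/savanna",
    "subtropical desert",
    "temperate grassland/desert",
    "woodland/shrubland",
)

ALL_BIOME_LABELS: Tuple[str, ...] = BIOME_PRIORITY + (OUTLIER,)


@dataclass(frozen=True)
class ClimatePair:
    """Annual mean temperature (degC) and annual precipitation (mm/yr)."""

    mat: float
    map_mm: float

    def __post_init__(self) -> None:
        if not (-60.0 <= self.mat <= 60.0) or not math.isfinite(self.mat):
            raise ValidationError(f"mat must be in [-60, 60] degC, got {self.mat!r}")
        if not (self.map_mm >= 0.0) or not math.isfinite(self.map_mm):
            raise ValidationError(f"map_mm must be >= 0, got {self.map_mm!r}")


@dataclass
class BiomePolygonSet:
    """Named-class polygons in (MAT degC, precipitation cm/yr) space."""

    polygons: Dict[str, Polygon]
    priority: Tuple[str, ...] = BIOME_PRIORITY

    def __post_init__(self) -> None:
        if sorted(self.priority) != sorted(self.polygons):
            raise ValidationError("priority order must be a permutation of the polygon classes")
        for name, poly in self.polygons.items():
            if not poly.is_valid:
                raise ValidationError(f"polygon for {name!r} is not simple/valid")


def load_biome_polygons(path=None) -> BiomePolygonSet:
    """Load a polygon set from CSV (``biome, vertex_index, mat_c, precip_cm``).

    With no path, loads the packaged synthetic digitization.
    """
    if path is None:
        ref = resources.files("tricksterbiogeo.data") / "whittaker_polygons_synthetic.csv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    polys: Dict[str, Polygon] = {}
    for name, grp in df.groupby("biome", sort=False):
        grp = grp.sort_values("vertex_index")
        polys[str(name)] = Polygon(zip(grp["mat_c"], grp["precip_cm"]))
    return BiomePolygonSet(polygons=polys)


# ---------------------------------------------------------------------------
# Climate surface
# ---------------------------------------------------------------------------


@dataclass
class ClimateSurface:
    """A rectilinear lon/lat grid of MAT (degC) and precipitation (mm/yr).

    ``mat`` and ``map_mm`` are 2-D arrays indexed [lat, lon]; NaN marks
    nodata (ocean). Lookup is nearest-node; points farther than one cell
    outside the domain are nodata.
    """

    lats: np.ndarray
    lons: np.ndarray
    mat: np.ndarray
    map_mm: np.ndarray

    def __post_init__(self) -> None:
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        if self.mat.shape != (len(self.lats), len(self.lons)):
            raise ValidationError("mat array shape must be (n_lats, n_lons)")
        if self.map_mm.shape != self.mat.shape:
            raise ValidationError("map_mm array shape must match mat")

    def _nearest_index(self, lat: float, lon: float) -> Optional[Tuple[int, int]]:
        i = int(np.argmin(np.abs(self.lats - lat)))
        j = int(np.argmin(np.abs(self.lons - lon)))
        step_lat = np.max(np.abs(np.diff(self.lats))) if len(self.lats) > 1 else 180.0
        step_lon = np.max(np.abs(np.diff(self.lons))) if len(self.lons) > 1 else 360.0
        if abs(self.lats[i] - lat) > step_lat or abs(self.lons[j] - lon) > step_lon:
            return None
        return i, j

    def value_at(self, p: GeoPoint) -> Optional[ClimatePair]:
        """Nearest-node climate at a point, or None where nodata."""
        idx = self._nearest_index(p.lat, p.lon)
        if idx is None:
            return None
        mat = float(self.mat[idx])
        mm = float(self.map_mm[idx])
        if math.isnan(mat) or math.isnan(mm):
            return None
        return ClimatePair(mat, max(0.0, mm))

    def to_dataframe(self) -> pd.DataFrame:
        jj, ii = np.meshgrid(np.arange(len(self.lons)), np.arange(len(self.lats)))
        return pd.DataFrame(
            {
                "lon": self.lons[jj.ravel()],
                "lat": self.lats[ii.ravel()],
                "mat": self.mat.ravel(),
                "map_mm": self.map_mm.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, nodata: Optional[float] = None) -> "ClimateSurface":
        for col in ("lon", "lat", "mat", "map_mm"):
            if col not in df.columns:
                raise ValidationError(f"climate surface table is missing column: {col}")
        df = df.copy()
        if nodata is not None:
            df.loc[df["mat"] == nodata, "mat"] = np.nan
            df.loc[df["map_mm"] == nodata, "map_mm"] = np.nan
        lats = np.sort(df["lat"].unique())
        lons = np.sort(df["lon"].unique())
        mat = df.pivot_table(index="lat", columns="lon", values="mat", dropna=False)
        mm = df.pivot_table(index="lat", columns="lon", values="map_mm", dropna=False)
        mat = mat.reindex(index=lats, columns=lons)
        mm = mm.reindex(index=lats, columns=lons)
        return cls(lats=lats, lons=lons, mat=mat.to_numpy(), map_mm=mm.to_numpy())

    @classmethod
    def from_csv(cls, path, nodata: Optional[float] = None) -> "ClimateSurface":
        return cls.from_dataframe(pd.read_csv(path), nodata=nodata)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def assign_cell_climate(
    c: CellId,
    surface: ClimateSurface,
    fallback_points: Sequence[GeoPoint] = (),
    backend: str | GridBackend = "fibonacci",
) -> Tuple[Optional[ClimatePair], str]:
    """Climate at a cell's centroid, with occurrence-coordinate fallback.

    Returns ``(pair, source)`` with source one of ``centroid``,
    ``fallback`` or ``missing``. Fallback averages the surface values at
    the given points (real-animal coordinates inside the cell) that have
    data for both variables.
    """
    b = backend if isinstance(backend, GridBackend) else get_backend(backend)
    centroid_value = surface.value_at(b.cell_centroid(c))
    if centroid_value is not None:
        return centroid_value, "centroid"
    values = [v for p in fallback_points if (v := surface.value_at(p)) is not None]
    if values:
        return (
            ClimatePair(
                float(np.mean([v.mat for v in values])),
                float(np.mean([v.map_mm for v in values])),
            ),
            "fallback",
        )
    return None, "missing"


def build_cell_climate(
    cells: Iterable[CellId],
    surface: ClimateSurface,
    fallback_records: Sequence[OccurrenceRecord] = (),
    backend: str | GridBackend = "fibonacci",
) -> Dict[CellId, Tuple[Optional[ClimatePair], str]]:
    """Assign climate to many cells, routing each cell's inside-cell
    real-animal coordinates into the fallback."""
    b = backend if isinstance(backend, GridBackend) else get_backend(backend)
    by_cell: Dict[CellId, List[GeoPoint]] = {}
    cells = list(cells)
    resolution = cells[0].resolution if cells else 0
    for rec in fallback_records:
        by_cell.setdefault(b.point_to_cell(rec.point, resolution), []).append(rec.point)
    return {
        c: assign_cell_climate(c, surface, by_cell.get(c, ()), backend=b) for c in cells
    }


def classify_biome(cp: ClimatePair, polygons: Optional[BiomePolygonSet] = None) -> str:
    """Whittaker class of a climate pair; OUTLIER if no polygon contains it.

    Precipitation is converted mm/yr -> cm/yr before the polygon test
    (the diagram's axis is cm). Boundary points count as inside; overlaps
    resolve by the set's priority order, so classification is total and
    deterministic.
    """
    polygons = polygons if polygons is not None else _default_polygons()
    pt = Point(cp.mat, cp.map_mm / 10.0)
    for name in polygons.priority:
        if polygons.polygons[name].covers(pt):
            return name
    return OUTLIER


_POLYGON_CACHE: List[BiomePolygonSet] = []


def _default_polygons() -> BiomePolygonSet:
    if not _POLYGON_CACHE:
        _POLYGON_CACHE.append(load_biome_polygons())
    return _POLYGON_CACHE[0]


def biome_counts(
    cells: Iterable[CellId],
    climate: Mapping[CellId, Optional[ClimatePair]],
    polygons: Optional[BiomePolygonSet] = None,
) -> Tuple[Dict[str, int], int]:
    """Count cells per biome label; returns (counts over the 10 labels,
    number of MISSING cells excluded)."""
    counts = {label: 0 for label in ALL_BIOME_LABELS}
    n_missing = 0
    for c in cells:
        cp = climate.get(c)
        if isinstance(cp, tuple):  # accept build_cell_climate output directly
            cp = cp[0]
        if cp is None:
            n_missing += 1
            continue
        counts[classify_biome(cp, polygons)] += 1
    return counts, n_missing


def background_cells(presence: PresenceMap) -> Set[CellId]:
    """The terrestrial background: union of all REAL-role presence cells.

    This is the support of every null model in the analysis; it is
    undefined (an error) when no real-animal presence exists.
    """
    union: Set[CellId] = set()
    for (cat, role), cells in presence.cells.items():
        if role == Role.REAL:
            union |= cells
    if not union:
        raise ValidationError("background undefined: presence map has no REAL cells")
    return union


def write_climate_tsv(
    climate: Mapping[CellId, Tuple[Optional[ClimatePair], str]],
    path,
    polygons: Optional[BiomePolygonSet] = None,
) -> None:
    """Export per-cell climate and biome as TSV."""
    rows = []
    for c in sorted(climate, key=lambda x: x.id):
        cp, source = climate[c]
        rows.append(
            {
                "cell_id": c.id,
                "mat": "" if cp is None else cp.mat,
                "map_mm": "" if cp is None else cp.map_mm,
                "biome": "" if cp is None else classify_biome(cp, polygons),
                "climate_source": source,
            }
        )
    pd.DataFrame(rows, columns=["cell_id", "mat", "map_mm", "biome", "climate_source"]).to_csv(
        path, sep="\t", index=False
    )
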