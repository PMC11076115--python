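"""Synthetic world generator with machine-readable ground truth.

Emulates the statistical structure of the real inputs — presence-only
occurrence points with spatially uneven sampling intensity, species
confined to climate niches on a smooth climate surface with oceans, and
folklore ("trickster") records tied to species ranges — without any
external data. Three trickster scenarios span the hypotheses the
analysis discriminates:

``SUBSET_RANDOM``
    Trickster cells are a uniform random subset of the real animal's
    cells: the permutation test's null is true by construction, and the
    conditional probability P(real | trickster) is exactly 1.

``SUBSET_CLUSTERED``
    Trickster cells are a spatially contiguous clump inside the real
    range (a seed cell plus its nearest range cells), emulating cultural
    transmission between neighbouring societies: conditional probability
    1 and genuine spatial clustering.

``DECOUPLED``
    Trickster cells are a uniform sample of *all* grid cells, ignoring
    the species range: folklore transmitted freely across ecological
    conditions. The conditional probability then has hypergeometric
    expectation |real cells| / |all cells|.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .climate_biome import ClimateSurface
from .gridding import (
    CellId,
    GeoPoint,
    GridBackend,
    OccurrenceRecord,
    Role,
    ValidationError,
    get_backend,
    haversine_matrix_km,
)
from .spatial_permutation import category_rng


class Scenario(str, Enum):
    SUBSET_RANDOM = "subset_random"
    SUBSET_CLUSTERED = "subset_clustered"
    DECOUPLED = "decoupled"


@dataclass(frozen=True)
class SpeciesSpec:
    """A synthetic species: a climate niche plus a sampling regime."""

    category: str
    mat_range: Tuple[float, float]  # degC
    precip_range: Tuple[float, float]  # mm/yr
    n_points: int = 600
    sampling_bias: float = 2.0  # weight ~ (1 + d/500km)^-bias toward a hotspot

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValidationError("n_points must be >= 1")
        if self.mat_range[0] > self.mat_range[1] or self.precip_range[0] > self.precip_range[1]:
            raise ValidationError(f"niche ranges must be ordered for {self.category!r}")


@dataclass(frozen=True)
class TricksterSpec:
    category: str
    scenario: Scenario
    n_cells: int = 10
    cluster_spread_km: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValidationError("n_cells must be >= 2")
        if self.scenario == Scenario.SUBSET_CLUSTERED and not self.cluster_spread_km:
            raise ValidationError("SUBSET_CLUSTERED requires cluster_spread_km")


#: Latitudinal precipitation bands: (|lat| low, |lat| high, mean mm/yr, sd mm/yr).
DEFAULT_PRECIP_BANDS: Tuple[Tuple[float, float, float, float], ...] = (
    (0.0, 10.0, 2600.0, 500.0),
    (10.0, 30.0, 700.0, 250.0),
    (30.0, 55.0, 1000.0, 250.0),
    (55.0, 90.0, 400.0, 150.0),
)


@dataclass
class SyntheticWorldConfig:
    seed: int = 0
    surface_cell_deg: float = 2.0
    equator_temp: float = 30.0
    temp_gradient: float = 0.6  # degC lost per degree of latitude
    temp_noise_sd: float = 1.0
    precip_bands: Tuple[Tuple[float, float, float, float], ...] = DEFAULT_PRECIP_BANDS
    ocean_fraction: float = 0.3
    resolution: int = 1
    backend: str = "fibonacci"
    species: Tuple[SpeciesSpec, ...] = ()
    trickster_scenarios: Tuple[TricksterSpec, ...] = ()

    def __post_init__(self) -> None:
        if any(b[3] < 0 for b in self.precip_bands) or self.temp_noise_sd < 0:
            raise ValidationError("all noise sds must be >= 0")
        if not (0.0 <= self.ocean_fraction < 1.0):
            raise ValidationError("ocean_fraction must be in [0, 1)")


@dataclass
class SyntheticCategoryTruth:
    category: str
    scenario: Scenario
    real_cells: Set[CellId]
    trickster_cells: Set[CellId]
    expected_outcome: str


@dataclass
class SyntheticWorld:
    config: SyntheticWorldConfig
    surface: ClimateSurface
    records: List[OccurrenceRecord]
    truth: Dict[str, SyntheticCategoryTruth]


# ---------------------------------------------------------------------------
# Surface
# ---------------------------------------------------------------------------


def _band_params(abs_lat: np.ndarray, bands) -> Tuple[np.ndarray, np.ndarray]:
    mean = np.zeros_like(abs_lat)
    sd = np.zeros_like(abs_lat)
    for lo, hi, m, s in bands:
        mask = (abs_lat >= lo) & (abs_lat <= hi) & (mean == 0)
        mean[mask] = m
        sd[mask] = s
    return mean, sd


def generate_surface(config: SyntheticWorldConfig) -> ClimateSurface:
    """Deterministic synthetic climate surface.

    MAT declines linearly from the equator value with Gaussian noise;
    precipitation is drawn per latitudinal band; a configurable fraction
    of nodes becomes nodata (ocean) in contiguous circular blobs.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xC11A]))
    d = config.surface_cell_deg
    lats = np.arange(-90.0 + d / 2.0, 90.0, d)
    lons = np.arange(-180.0 + d / 2.0, 180.0, d)
    lat_grid = np.repeat(lats[:, None], len(lons), axis=1)

    mat = (
        config.equator_temp
        - config.temp_gradient * np.abs(lat_grid)
        + rng.normal(0.0, config.temp_noise_sd, size=lat_grid.shape)
    )
    mat = np.clip(mat, -59.0, 59.0)

    band_mean, band_sd = _band_params(np.abs(lat_grid), config.precip_bands)
    precip = np.clip(rng.normal(band_mean, np.maximum(band_sd, 1e-12)), 0.0, None)

    # ocean: add circular blobs until the nodata fraction is reached
    n_nodes = mat.size
    ocean = np.zeros(mat.shape, dtype=bool)
    lon_grid = np.repeat(lons[None, :], len(lats), axis=0)
    attempts = 0
    while ocean.mean() < config.ocean_fraction and attempts < 500:
        attempts += 1
        c_lat = rng.uniform(-70.0, 70.0)
        c_lon = rng.uniform(-180.0, 180.0)
        radius = rng.uniform(800.0, 3000.0)
        phi1 = np.radians(lat_grid)
        phi2 = np.radians(c_lat)
        dlam = np.radians(lon_grid - c_lon)
        h = (
            np.sin((phi2 - phi1) / 2.0) ** 2
            + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
        )
        dist = 2.0 * 6371.0 * np.arcsin(np.minimum(1.0, np.sqrt(h)))
        ocean |= dist <= radius
    mat[ocean] = np.nan
    precip[ocean] = np.nan
    return ClimateSurface(lats=lats, lons=lons, mat=mat, map_mm=precip)


# ---------------------------------------------------------------------------
# Species occurrences
# ---------------------------------------------------------------------------


def generate_species(
    config: SyntheticWorldConfig, surface: ClimateSurface, spec: SpeciesSpec
) -> Tuple[List[OccurrenceRecord], Set[CellId]]:
    """Presence-only points inside the species' climate niche.

    Surface nodes whose climate falls in the niche are the habitable
    set; points are sampled from it with intensity decaying from a
    random hotspot (GBIF-style unevenness: ``sampling_bias`` is the decay
    exponent) and jittered within their node so every point's
    nearest-node climate stays inside the declared niche. Returns the
    records plus the ground-truth grid presence cells.
    """
    rng = category_rng(config.seed, "species:" + spec.category)
    backend = get_backend(config.backend)

    ii, jj = np.where(
        (surface.mat >= spec.mat_range[0])
        & (surface.mat <= spec.mat_range[1])
        & (surface.map_mm >= spec.precip_range[0])
        & (surface.map_mm <= spec.precip_range[1])
    )
    if len(ii) == 0:
        raise ValidationError(f"species {spec.category!r} has an empty niche on this surface")

    node_lats = surface.lats[ii]
    node_lons = surface.lons[jj]
    hot = int(rng.integers(len(ii)))
    phi = np.radians(node_lats)
    lam = np.radians(node_lons)
    h = (
        np.sin((phi - phi[hot]) / 2.0) ** 2
        + np.cos(phi) * np.cos(phi[hot]) * np.sin((lam - lam[hot]) / 2.0) ** 2
    )
    d_hot = 2.0 * 6371.0 * np.arcsin(np.minimum(1.0, np.sqrt(h)))
    weights = (1.0 + d_hot / 500.0) ** (-float(spec.sampling_bias))
    weights /= weights.sum()

    # one rng triple per point (node choice + 2 jitters) so a larger
    # n_points extends the point sequence instead of reshuffling it:
    # presence sets are monotone in n_points by construction
    cumw = np.cumsum(weights)
    jitter = 0.49 * config.surface_cell_deg
    records: List[OccurrenceRecord] = []
    for _ in range(spec.n_points):
        u = rng.random(3)
        k = min(int(np.searchsorted(cumw, u[0] * cumw[-1], side="right")), len(cumw) - 1)
        la = float(np.clip(node_lats[k] + (2.0 * u[1] - 1.0) * jitter, -90.0, 90.0))
        lo = float(node_lons[k] + (2.0 * u[2] - 1.0) * jitter)
        records.append(
            OccurrenceRecord(
                category=spec.category, role=Role.REAL, point=GeoPoint(la, lo), source="synthetic"
            )
        )
    truth = {backend.point_to_cell(r.point, config.resolution) for r in records}
    return records, truth


# ---------------------------------------------------------------------------
# Trickster records
# ---------------------------------------------------------------------------


def generate_tricksters(
    spec: TricksterSpec,
    real_cells: Set[CellId],
    all_cells: Set[CellId],
    seed: int,
    backend: str | GridBackend = "fibonacci",
) -> Tuple[List[OccurrenceRecord], SyntheticCategoryTruth]:
    """Trickster records for one scenario; one point per chosen cell centroid."""
    b = backend if isinstance(backend, GridBackend) else get_backend(backend)
    rng = category_rng(seed, "trickster:" + spec.category)
    if spec.scenario in (Scenario.SUBSET_RANDOM, Scenario.SUBSET_CLUSTERED):
        if spec.n_cells > len(real_cells):
            raise ValidationError(
                f"{spec.category!r}: n_cells={spec.n_cells} exceeds |real cells|={len(real_cells)}"
            )
    real_sorted = sorted(real_cells, key=lambda c: c.id)

    if spec.scenario == Scenario.SUBSET_RANDOM:
        idx = rng.choice(len(real_sorted), size=spec.n_cells, replace=False)
        chosen = {real_sorted[i] for i in idx}
        expected = "constrained by real presence; not clustered beyond the null"
    elif spec.scenario == Scenario.SUBSET_CLUSTERED:
        lats = np.array([b.cell_centroid(c).lat for c in real_sorted])
        lons = np.array([b.cell_centroid(c).lon for c in real_sorted])
        dmat = haversine_matrix_km(lats, lons)
        order = rng.permutation(len(real_sorted))
        chosen = None
        for seed_idx in order:  # try seed cells until one has enough neighbours in range
            near = np.where(dmat[seed_idx] <= spec.cluster_spread_km)[0]
            if len(near) >= spec.n_cells:
                near = near[np.argsort(dmat[seed_idx][near], kind="stable")]
                chosen = {real_sorted[i] for i in near[: spec.n_cells]}
                break
        if chosen is None:
            raise ValidationError(
                f"{spec.category!r}: no seed cell has {spec.n_cells} real cells within "
                f"{spec.cluster_spread_km} km"
            )
        expected = "constrained by real presence; spatially clustered"
    elif spec.scenario == Scenario.DECOUPLED:
        all_sorted = sorted(all_cells, key=lambda c: c.id)
        if spec.n_cells > len(all_sorted):
            raise ValidationError(f"{spec.category!r}: n_cells exceeds the global grid size")
        idx = rng.choice(len(all_sorted), size=spec.n_cells, replace=False)
        chosen = {all_sorted[i] for i in idx}
        expected = "not constrained by real presence"
    else:  # pragma: no cover
        raise ValidationError(f"unknown scenario: {spec.scenario}")

    records = [
        OccurrenceRecord(
            category=spec.category, role=Role.TRICKSTER, point=b.cell_centroid(c), source="synthetic"
        )
        for c in sorted(chosen, key=lambda c: c.id)
    ]
    truth = SyntheticCategoryTruth(
        category=spec.category,
        scenario=spec.scenario,
        real_cells=set(real_cells),
        trickster_cells=chosen,
        expected_outcome=expected,
    )
    return records, truth


# ---------------------------------------------------------------------------
# Whole worlds
# ---------------------------------------------------------------------------

_NICHES = {
    "tropical": ((20.0, 32.0), (600.0, 4500.0)),
    "subtropical": ((12.0, 28.0), (300.0, 2200.0)),
    "temperate": ((2.0, 18.0), (400.0, 2000.0)),
    "boreal": ((-12.0, 8.0), (200.0, 1500.0)),
    "wide": ((-15.0, 32.0), (200.0, 4500.0)),
}

#: The default world: 16 categories (the analysis's canonical category
#: count), spread over climate niches and split across the three
#: trickster scenarios.
_DEFAULT_CATEGORIES: Tuple[Tuple[str, str, Scenario], ...] = (
    ("anteater", "tropical", Scenario.SUBSET_RANDOM),
    ("badger", "temperate", Scenario.SUBSET_RANDOM),
    ("ground squirrel", "boreal", Scenario.DECOUPLED),
    ("hawk", "wide", Scenario.SUBSET_RANDOM),
    ("mink", "temperate", Scenario.SUBSET_RANDOM),
    ("mouse", "temperate", Scenario.DECOUPLED),
    ("opossum", "tropical", Scenario.SUBSET_CLUSTERED),
    ("owl", "wide", Scenario.DECOUPLED),
    ("porcupine", "subtropical", Scenario.SUBSET_CLUSTERED),
    ("rabbit/hare", "temperate", Scenario.SUBSET_CLUSTERED),
    ("raccoon", "subtropical", Scenario.DECOUPLED),
    ("rat", "subtropical", Scenario.SUBSET_RANDOM),
    ("raven/crow", "boreal", Scenario.SUBSET_CLUSTERED),
    ("skunk", "temperate", Scenario.DECOUPLED),
    ("spider", "tropical", Scenario.SUBSET_CLUSTERED),
    ("wren", "boreal", Scenario.SUBSET_CLUSTERED),
)


def default_config(seed: int = 0, resolution: int = 1) -> SyntheticWorldConfig:
    """The frozen default study conditions: 16 mixed-scenario categories."""
    species = tuple(
        SpeciesSpec(category=cat, mat_range=_NICHES[n][0], precip_range=_NICHES[n][1])
        for cat, n, _ in _DEFAULT_CATEGORIES
    )
    tricksters = tuple(
        TricksterSpec(
            category=cat,
            scenario=sc,
            n_cells=12,
            cluster_spread_km=3000.0 if sc == Scenario.SUBSET_CLUSTERED else None,
        )
        for cat, _, sc in _DEFAULT_CATEGORIES
    )
    return SyntheticWorldConfig(
        seed=seed, resolution=resolution, species=species, trickster_scenarios=tricksters
    )


def generate_world(config: SyntheticWorldConfig) -> SyntheticWorld:
    """Generate surface, species records and trickster records with truth."""
    surface = generate_surface(config)
    backend = get_backend(config.backend)
    all_cells = backend.enumerate_cells(config.resolution)
    records: List[OccurrenceRecord] = []
    real_by_cat: Dict[str, Set[CellId]] = {}
    for spec in config.species:
        recs, cells = generate_species(config, surface, spec)
        records.extend(recs)
        real_by_cat[spec.category] = cells
    truth: Dict[str, SyntheticCategoryTruth] = {}
    for tspec in config.trickster_scenarios:
        if tspec.category not in real_by_cat:
            raise ValidationError(f"trickster spec {tspec.category!r} has no species spec")
        recs, t = generate_tricksters(
            tspec, real_by_cat[tspec.category], all_cells, config.seed, backend=backend
        )
        records.extend(recs)
        truth[tspec.category] = t
    return SyntheticWorld(config=config, surface=surface, records=records, truth=truth)


def write_world(world: SyntheticWorld, out_dir) -> Dict[str, str]:
    """Write occurrences CSV, climate surface CSV and ground-truth JSON."""
    import os

    import pandas as pd

    os.makedirs(out_dir, exist_ok=True)
    occ_path = os.path.join(out_dir, "occurrences.csv")
    surf_path = os.path.join(out_dir, "climate_surface.csv")
    truth_path = os.path.join(out_dir, "ground_truth.json")
    pd.DataFrame(
        {
            "category": [r.category for r in world.records],
            "role": [r.role.value for r in world.records],
            "decimalLatitude": [r.point.lat for r in world.records],
            "decimalLongitude": [r.point.lon for r in world.records],
            "source": [r.source for r in world.records],
        }
    ).to_csv(occ_path, index=False)
    world.surface.to_csv(surf_path)
    payload = {
        cat: {
            "scenario": t.scenario.value,
            "expected_outcome": t.expected_outcome,
            "real_cells": sorted(c.id for c in t.real_cells),
            "trickster_cells": sorted(c.id for c in t.trickster_cells),
            "resolution": world.config.resolution,
        }
        for cat, t in sorted(world.truth.items())
    }
    with open(truth_path, "w") as fh:
        json.dump(payload, fh, indent=1)
    return {"occurrences": occ_path, "surface": surf_path, "ground_truth": truth_path}
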