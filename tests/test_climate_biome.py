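import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tricksterbiogeo.climate_biome import (
    ALL_BIOME_LABELS,
    BIOME_PRIORITY,
    OUTLIER,
    ClimatePair,
    ClimateSurface,
    assign_cell_climate,
    background_cells,
    biome_counts,
    build_cell_climate,
    classify_biome,
    load_biome_polygons,
)
from tricksterbiogeo.gridding import (
    CellId,
    GeoPoint,
    OccurrenceRecord,
    PresenceMap,
    Role,
    ValidationError,
    get_backend,
)


def _uniform_surface(mat=15.0, mm=900.0, nodata_mask=None, d=10.0):
    lats = np.arange(-90 + d / 2, 90, d)
    lons = np.arange(-180 + d / 2, 180, d)
    m = np.full((len(lats), len(lons)), mat)
    p = np.full((len(lats), len(lons)), mm)
    if nodata_mask is not None:
        m[nodata_mask] = np.nan
        p[nodata_mask] = np.nan
    return ClimateSurface(lats=lats, lons=lons, mat=m, map_mm=p)


class TestClimatePair:
    def test_range_enforced(self):
        with pytest.raises(ValidationError):
            ClimatePair(80.0, 100.0)
        with pytest.raises(ValidationError):
            ClimatePair(10.0, -1.0)


class TestAssignCellClimate:
    def test_centroid_value_returned_unchanged(self):
        surface = _uniform_surface(mat=7.0, mm=650.0)
        cell = get_backend("fibonacci").point_to_cell(GeoPoint(20, 30), 1)
        pair, source = assign_cell_climate(cell, surface)
        assert source == "centroid"
        assert (pair.mat, pair.map_mm) == (7.0, 650.0)

    def test_fallback_is_arithmetic_mean_of_points_with_data(self):
        # all-ocean surface except two nodes holding (10, 500) and (14, 700)
        surface = _uniform_surface(nodata_mask=np.s_[:, :])
        b = get_backend("fibonacci")
        cell = b.point_to_cell(GeoPoint(0, 0), 1)
        i = np.argmin(np.abs(surface.lats - 2.0))
        j1 = np.argmin(np.abs(surface.lons - 2.0))
        j2 = np.argmin(np.abs(surface.lons + 2.0))
        surface.mat[i, j1], surface.map_mm[i, j1] = 10.0, 500.0
        surface.mat[i, j2], surface.map_mm[i, j2] = 14.0, 700.0
        pair, source = assign_cell_climate(
            cell, surface, fallback_points=[GeoPoint(2, 2), GeoPoint(2, -2), GeoPoint(2, 30)]
        )
        assert source == "fallback"
        assert (pair.mat, pair.map_mm) == (12.0, 600.0)

    def test_missing_when_no_route_has_data(self):
        surface = _uniform_surface(nodata_mask=np.s_[:, :])
        cell = get_backend("fibonacci").point_to_cell(GeoPoint(0, 0), 1)
        pair, source = assign_cell_climate(cell, surface, [GeoPoint(1, 1)])
        assert pair is None and source == "missing"

    def test_build_cell_climate_routes_fallback_records_per_cell(self):
        surface = _uniform_surface(nodata_mask=np.s_[:, :], d=1.0)
        b = get_backend("fibonacci")
        cell = b.point_to_cell(GeoPoint(5, 5), 1)
        cen = b.cell_centroid(cell)
        # give data to a node ~1 degree east of the centroid: inside the cell
        # (cells at this resolution span several degrees) but not the
        # centroid's own nearest node, so only the fallback route can see it
        i = np.argmin(np.abs(surface.lats - cen.lat))
        j = np.argmin(np.abs(surface.lons - (cen.lon + 1.2)))
        surface.mat[i, j], surface.map_mm[i, j] = 20.0, 1000.0
        record_point = GeoPoint(float(surface.lats[i]), float(surface.lons[j]))
        assert b.point_to_cell(record_point, 1) == cell
        other = b.point_to_cell(GeoPoint(-60, -120), 1)
        recs = [OccurrenceRecord("fox", Role.REAL, record_point)]
        out = build_cell_climate([cell, other], surface, recs)
        assert out[cell] == (ClimatePair(20.0, 1000.0), "fallback")
        assert out[other] == (None, "missing")


class TestClassifyBiome:
    @pytest.mark.parametrize(
        "mat,mm,expected",
        [
            (25.0, 3500.0, "tropical rain forest"),
            (-12.0, 200.0, "tundra"),
            (40.0, 9000.0, OUTLIER),
            (25.0, 1500.0, "tropical seasonal forest/savanna"),
            (12.0, 1200.0, "temperate seasonal forest"),
            (0.0, 1000.0, "boreal forest"),
            (25.0, 300.0, "subtropical desert"),
            (10.0, 150.0, "temperate grassland/desert"),
            (10.0, 400.0, "woodland/shrubland"),
        ],
    )
    def test_reference_classifications(self, mat, mm, expected):
        assert classify_biome(ClimatePair(mat, mm)) == expected

    def test_boundary_point_classified_not_outlier(self):
        polygons = load_biome_polygons()
        # a vertex of the tundra polygon lies on its boundary
        x, y = polygons.polygons["tundra"].exterior.coords[0]
        assert classify_biome(ClimatePair(x, y * 10.0)) != OUTLIER

    @given(
        mat=st.floats(min_value=-60, max_value=60, allow_nan=False),
        mm=st.floats(min_value=0, max_value=10000, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_total_and_deterministic(self, mat, mm):
        cp = ClimatePair(mat, mm)
        label = classify_biome(cp)
        assert label in ALL_BIOME_LABELS
        assert classify_biome(cp) == label

    def test_exactly_ten_labels(self):
        assert len(ALL_BIOME_LABELS) == 10
        assert len(BIOME_PRIORITY) == 9 and OUTLIER not in BIOME_PRIORITY


class TestBiomeCounts:
    def test_empty_cell_set(self):
        counts, n_missing = biome_counts([], {})
        assert sum(counts.values()) == 0 and n_missing == 0

    def test_single_label_counted(self):
        cells = [CellId(f"FV1-{i}", 1) for i in range(3)]
        climate = {c: ClimatePair(25.0, 3500.0) for c in cells}
        counts, _ = biome_counts(cells, climate)
        assert counts["tropical rain forest"] == 3
        assert sum(counts.values()) == 3

    def test_sum_equals_non_missing(self):
        cells = [CellId(f"FV1-{i}", 1) for i in range(5)]
        climate = {cells[0]: None, cells[1]: None}
        climate.update({c: ClimatePair(0.0, 1000.0) for c in cells[2:]})
        counts, n_missing = biome_counts(cells, climate)
        assert sum(counts.values()) == 3 and n_missing == 2

    def test_agrees_with_per_cell_classification(self, world):
        surface = world.surface
        b = get_backend("fibonacci")
        cells = sorted(world.truth["badger"].real_cells, key=lambda c: c.id)
        climate = build_cell_climate(cells, surface)
        pairs = {c: v[0] for c, v in climate.items()}
        counts, n_missing = biome_counts(cells, pairs)
        expected = {}
        for c in cells:
            cp = pairs[c]
            if cp is None:
                continue
            label = classify_biome(cp)
            expected[label] = expected.get(label, 0) + 1
        assert {k: v for k, v in counts.items() if v} == expected
        assert sum(counts.values()) + n_missing == len(cells)


class TestBackgroundCells:
    def _presence(self, mapping):
        return PresenceMap(
            resolution=1,
            cells={
                (cat, role): frozenset(CellId(f"FV1-{i}", 1) for i in ids)
                for (cat, role), ids in mapping.items()
            },
        )

    def test_union_of_disjoint_sets(self):
        p = self._presence({("a", Role.REAL): {1, 2, 3}, ("b", Role.REAL): {4, 5, 6, 7}})
        assert len(background_cells(p)) == 7

    def test_overlapping_sets(self):
        p = self._presence({("a", Role.REAL): {1, 2}, ("b", Role.REAL): {2, 3}})
        assert {c.id for c in background_cells(p)} == {"FV1-1", "FV1-2", "FV1-3"}

    def test_trickster_cells_excluded(self):
        p = self._presence({("a", Role.REAL): {1}, ("a", Role.TRICKSTER): {2, 3}})
        assert len(background_cells(p)) == 1

    def test_monotone_in_categories(self):
        small = self._presence({("a", Role.REAL): {1, 2}})
        big = self._presence({("a", Role.REAL): {1, 2}, ("b", Role.REAL): {9}})
        assert background_cells(small) <= background_cells(big)

    def test_error_without_real_presence(self):
        with pytest.raises(ValidationError, match="REAL"):
            background_cells(self._presence({("a", Role.TRICKSTER): {1, 2}}))


class TestClimateSurfaceIO:
    def test_csv_round_trip_preserves_values_and_nodata(self, tmp_path):
        mask = np.zeros((18, 36), dtype=bool)
        mask[0, 0] = True
        surface = _uniform_surface(mat=3.5, mm=420.0, nodata_mask=mask)
        path = tmp_path / "surface.csv"
        surface.to_csv(path)
        loaded = ClimateSurface.from_csv(path)
        assert np.array_equal(loaded.mat, surface.mat, equal_nan=True)
        assert np.array_equal(loaded.map_mm, surface.map_mm, equal_nan=True)

    def test_nodata_marker_translated(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame(
            {"lon": [0.0, 1.0], "lat": [0.0, 0.0], "mat": [-999.0, 5.0], "map_mm": [-999.0, 100.0]}
        )
        surface = ClimateSurface.from_dataframe(df, nodata=-999.0)
        assert np.isnan(surface.mat[0, 0]) and surface.mat[0, 1] == 5.0
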