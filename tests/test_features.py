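"""GIS buffer features: land-use areas, traffic, population, table assembly."""

import numpy as np
import pandas as pd
import pytest
from shapely.affinity import translate
from shapely.geometry import LineString, Polygon, box

from transferlur import features as ft


def _segments(midpoints):
    """Horizontal 50 m segments whose midpoints are the given (x, y)."""
    return pd.DataFrame({
        "segment_id": [f"S{i}" for i in range(len(midpoints))],
        "geometry": [LineString([(x - 25, y), (x + 25, y)])
                     for x, y in midpoints],
    })


def _landuse(geoms, cls):
    return pd.DataFrame({"geometry": geoms, "class": [cls] * len(geoms)})


class TestBufferArea:
    def test_full_containment_is_circle_area(self):
        segs = _segments([(0, 0)])
        poly = box(-1000, -1000, 1000, 1000)
        out = ft.buffer_area_features(segs, _landuse([poly], "industry"),
                                      buffers_m=(100,))
        assert out.loc["S0", "industry_100"] == pytest.approx(
            np.pi * 100**2, rel=3e-4)

    def test_absent_class_is_zero(self):
        segs = _segments([(0, 0)])
        out = ft.buffer_area_features(segs, _landuse([box(0, 0, 1, 1)], "port"),
                                      buffers_m=(100,))
        assert out.loc["S0", "industry_100"] == 0.0
        assert (out.filter(like="natural_") == 0.0).all().all()

    def test_half_plane_is_half_circle(self):
        # polygon covering y >= 0 through the midpoint: half the buffer disc
        segs = _segments([(0, 0)])
        half = box(-10000, 0, 10000, 10000)
        out = ft.buffer_area_features(segs, _landuse([half], "water"),
                                      buffers_m=(300,))
        assert out.loc["S0", "water_300"] == pytest.approx(
            np.pi * 300**2 / 2, rel=1e-3)

    def test_unknown_class_rejected(self):
        segs = _segments([(0, 0)])
        with pytest.raises(ValueError, match="harbour"):
            ft.buffer_area_features(segs, _landuse([box(0, 0, 1, 1)], "harbour"))

    def test_monotone_in_radius(self):
        segs = _segments([(0, 0), (200, 150)])
        polys = _landuse([box(-50, -50, 400, 60), box(100, 100, 250, 300)],
                         "residential")
        out = ft.buffer_area_features(segs, polys, buffers_m=(100, 300, 500))
        for sid in out.index:
            vals = [out.loc[sid, f"residential_{r}"] for r in (100, 300, 500)]
            assert vals == sorted(vals)


class TestTraffic:
    def _roads(self, rows):
        return pd.DataFrame(rows, columns=["geometry", "intensity",
                                           "hd_intensity", "major"])

    def test_nearest_road_intensity(self):
        segs = _segments([(0, 0)])
        roads = self._roads([(LineString([(-500, 0), (500, 0)]),
                              5000.0, 400.0, True)])
        out = ft.traffic_features(segs, roads, buffers_m=(100,))
        assert out.loc["S0", "traffic_nearest"] == 5000.0
        assert out.loc["S0", "traffic_nearest_major"] == 5000.0
        assert out.loc["S0", "hd_traffic_nearest"] == 400.0

    def test_chord_length_through_buffer_center(self):
        # a 1000 m straight road through the buffer centre: chord = 2r
        segs = _segments([(0, 0)])
        roads = self._roads([(LineString([(0, -500), (0, 500)]),
                              3000.0, 100.0, False)])
        out = ft.traffic_features(segs, roads, buffers_m=(100,))
        assert out.loc["S0", "roadlength_100"] == pytest.approx(200.0, rel=1e-4)
        assert out.loc["S0", "traffic_100"] == pytest.approx(
            3000.0 * 200.0, rel=1e-4)
        assert out.loc["S0", "roadlength_major_100"] == 0.0

    def test_empty_buffer_is_zero(self):
        segs = _segments([(0, 0)])
        roads = self._roads([(LineString([(5000, 0), (6000, 0)]),
                              3000.0, 100.0, False)])
        out = ft.traffic_features(segs, roads, buffers_m=(100,))
        assert out.loc["S0", "roadlength_100"] == 0.0
        assert out.loc["S0", "traffic_100"] == 0.0

    def test_no_major_roads_warns_and_zeroes(self, caplog):
        segs = _segments([(0, 0)])
        roads = self._roads([(LineString([(-10, 0), (10, 0)]),
                              1000.0, 50.0, False)])
        with caplog.at_level("WARNING", logger="transferlur.features"):
            out = ft.traffic_features(segs, roads, buffers_m=(100,))
        assert "no major roads" in caplog.text
        assert out.loc["S0", "traffic_nearest_major"] == 0.0


class TestPopulation:
    def test_uniform_density_times_disc_area(self):
        segs = _segments([(0, 0)])
        cell = box(-2000, -2000, 2000, 2000)  # 16 km2, 16000 people => 1000/km2
        pop = pd.DataFrame({"geometry": [cell], "population": [16000.0]})
        out = ft.population_features(segs, pop, buffers_m=(500,))
        density = 16000.0 / cell.area
        assert out.loc["S0", "population_500"] == pytest.approx(
            density * np.pi * 500**2, rel=3e-4)

    def test_zero_population(self):
        segs = _segments([(0, 0)])
        pop = pd.DataFrame({"geometry": [box(-100, -100, 100, 100)],
                            "population": [0.0]})
        out = ft.population_features(segs, pop, buffers_m=(100,))
        assert out.loc["S0", "population_100"] == 0.0

    def test_straddling_two_cells_area_weighted(self):
        segs = _segments([(0, 0)])
        left, right = box(-1000, -1000, 0, 1000), box(0, -1000, 1000, 1000)
        pop = pd.DataFrame({"geometry": [left, right],
                            "population": [4000.0, 8000.0]})
        out = ft.population_features(segs, pop, buffers_m=(200,))
        half_disc = np.pi * 200**2 / 2
        oracle = (4000.0 * half_disc / left.area
                  + 8000.0 * half_disc / right.area)
        assert out.loc["S0", "population_200"] == pytest.approx(oracle, rel=3e-4)


class TestBuildTable:
    def _layers(self):
        landuse = pd.DataFrame({
            "geometry": [box(-200, -200, 200, 200), box(100, 100, 600, 600)],
            "class": ["residential", "industry"]})
        roads = pd.DataFrame({
            "geometry": [LineString([(-400, 10), (400, 10)]),
                         LineString([(0, -400), (0, 400)])],
            "intensity": [8000.0, 2000.0], "hd_intensity": [600.0, 100.0],
            "major": [True, False]})
        pop = pd.DataFrame({"geometry": [box(-500, -500, 500, 500)],
                            "population": [10000.0]})
        return landuse, roads, pop

    def test_identical_columns_across_cities_and_roundtrip(self, tmp_path):
        landuse, roads, pop = self._layers()
        t1 = ft.build_feature_table(_segments([(0, 0), (100, 50)]),
                                    landuse, roads, pop,
                                    area_buffers=(100, 300),
                                    traffic_buffers=(50, 100))
        t2 = ft.build_feature_table(_segments([(30, -20)]),
                                    landuse, roads, pop,
                                    area_buffers=(100, 300),
                                    traffic_buffers=(50, 100))
        assert list(t1.columns) == list(t2.columns)
        ft.check_identical_columns({"a": t1, "b": t2})
        with pytest.raises(ValueError, match="differ"):
            ft.check_identical_columns({"a": t1, "b": t2.iloc[:, :-1]})
        ft.write_feature_table(t1, tmp_path / "f.csv", tmp_path / "f.json")
        back = ft.read_feature_table(tmp_path / "f.csv")
        pd.testing.assert_frame_equal(t1, back)  # lossless round-trip

    def test_row_order_keyed_by_segment_id(self):
        landuse, roads, pop = self._layers()
        segs = _segments([(0, 0), (100, 50), (-50, -50)])
        shuffled = segs.iloc[[2, 0, 1]].reset_index(drop=True)
        t1 = ft.build_feature_table(segs, landuse, roads, pop,
                                    area_buffers=(100,), traffic_buffers=(50,))
        t2 = ft.build_feature_table(shuffled, landuse, roads, pop,
                                    area_buffers=(100,), traffic_buffers=(50,))
        pd.testing.assert_frame_equal(t1, t2)

    def test_translation_invariance(self):
        landuse, roads, pop = self._layers()
        segs = _segments([(0, 0), (150, -100)])
        t1 = ft.build_feature_table(segs, landuse, roads, pop,
                                    area_buffers=(100, 300),
                                    traffic_buffers=(50, 100))
        dx, dy = 5000.0, -3000.0
        move = lambda df: df.assign(
            geometry=[translate(g, dx, dy) for g in df["geometry"]])
        t2 = ft.build_feature_table(move(segs), move(landuse), move(roads),
                                    move(pop), area_buffers=(100, 300),
                                    traffic_buffers=(50, 100))
        pd.testing.assert_frame_equal(t1, t2, rtol=1e-9, atol=1e-6)

    def test_schema_sidecar(self, tmp_path):
        landuse, roads, pop = self._layers()
        t = ft.build_feature_table(_segments([(0, 0)]), landuse, roads, pop,
                                   area_buffers=(100,), traffic_buffers=(50,))
        schema = ft.column_schema(t)
        by_col = {s["column"]: s for s in schema}
        assert by_col["industry_100"] == {"column": "industry_100",
                                          "group": "land_use",
                                          "base": "industry", "buffer_m": 100}
        assert by_col["traffic_nearest"]["group"] == "traffic"
        assert by_col["population_100"]["group"] == "population"
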