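"""Built-environment buffer indicators: counting, clipping, land-use mix,
retail floor-area ratio, and the assembled per-patient vector."""

import math

import numpy as np
import pandas as pd
import pytest

from carepath.builtenv import (
    area_in_radius,
    assemble_features,
    count_points_in_radius,
    length_in_radius,
    lum_index,
    retfar,
    vkt_in_radius,
)


def _pt(x, y):
    return {"type": "Feature", "geometry": {"type": "Point", "coordinates": [x, y]}, "properties": {}}


def _line(coords, **props):
    return {"type": "Feature", "geometry": {"type": "LineString", "coordinates": coords}, "properties": props}


def _rect(x, y, w, h, **props):
    return {
        "type": "Feature",
        "geometry": {"type": "Polygon", "coordinates": [[[x, y], [x + w, y], [x + w, y + h], [x, y + h], [x, y]]]},
        "properties": props,
    }


def _fc(feats):
    return {"type": "FeatureCollection", "features": feats}


class TestPointCount:
    def test_empty_layer_counts_zero(self):
        assert count_points_in_radius(_fc([]), (0, 0), 500) == 0

    def test_boundary_point_counted(self):
        assert count_points_in_radius(_fc([_pt(500.0, 0.0)]), (0, 0), 500) == 1

    def test_random_points_match_brute_force(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-1000, 1000, (500, 2))
        layer = _fc([_pt(x, y) for x, y in pts])
        got = count_points_in_radius(layer, (100.0, -50.0), 400.0)
        want = sum(1 for x, y in pts if math.hypot(x - 100.0, y + 50.0) <= 400.0)
        assert got == want


class TestLength:
    def test_diameter_chord(self):
        line = _fc([_line([[-1000, 0], [1000, 0]])])
        assert length_in_radius(line, (0, 0), 500) == pytest.approx(1000, rel=1e-4)

    def test_line_outside_zero(self):
        assert length_in_radius(_fc([_line([[2000, 2000], [3000, 2000]])]), (0, 0), 500) == 0.0

    def test_random_segments_match_sampling_oracle(self):
        rng = np.random.default_rng(1)
        center, r = (0.0, 0.0), 300.0
        for _ in range(20):
            p0 = rng.uniform(-600, 600, 2)
            p1 = rng.uniform(-600, 600, 2)
            seg_len = float(np.hypot(*(p1 - p0)))
            # dense point-sampling numeric integration of the inside fraction
            ts = np.linspace(0, 1, 40001)
            pts = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
            inside = np.hypot(pts[:, 0], pts[:, 1]) <= r
            want = seg_len * inside.mean()
            got = length_in_radius(_fc([_line([list(p0), list(p1)])]), center, r)
            assert got == pytest.approx(want, abs=max(0.001 * seg_len, 0.05))


class TestArea:
    def test_square_fully_inside_keeps_area(self):
        assert area_in_radius(_fc([_rect(-50, -50, 100, 100)]), (0, 0), 500) == pytest.approx(10_000)

    def test_covering_polygon_gives_disc_area(self):
        big = _fc([_rect(-2000, -2000, 4000, 4000)])
        got = area_in_radius(big, (0, 0), 500)
        assert got == pytest.approx(math.pi * 500**2, rel=1e-3)  # 128-gon approximation

    def test_self_intersecting_polygon_rejected(self):
        bow = {
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [[[0, 0], [100, 100], [100, 0], [0, 100], [0, 0]]]},
            "properties": {},
        }
        with pytest.raises(ValueError):
            area_in_radius(_fc([bow]), (0, 0), 500)

    def test_random_rectangles_match_monte_carlo(self):
        # disjoint rectangles on a coarse grid so summed clip areas equal the
        # union's area, which the Monte-Carlo oracle estimates
        rng = np.random.default_rng(2)
        r = 400.0
        cells = rng.choice(16, size=6, replace=False)
        rects = []
        for cidx in cells:
            gx, gy = (cidx % 4) * 250 - 500.0, (cidx // 4) * 250 - 500.0
            rects.append(_rect(gx + 10, gy + 10, float(rng.uniform(50, 230)), float(rng.uniform(50, 230))))
        got = area_in_radius(_fc(rects), (0, 0), r)

        n = 200_000
        xy = rng.uniform(-r, r, (n, 2))
        in_disc = np.hypot(xy[:, 0], xy[:, 1]) <= r
        hits = np.zeros(n, dtype=bool)
        for f in rects:
            ring = np.asarray(f["geometry"]["coordinates"][0])
            x0, y0 = ring.min(axis=0)
            x1, y1 = ring.max(axis=0)
            hits |= (xy[:, 0] >= x0) & (xy[:, 0] <= x1) & (xy[:, 1] >= y0) & (xy[:, 1] <= y1)
        frac = np.mean(hits & in_disc)
        est = frac * (2 * r) ** 2
        se = (2 * r) ** 2 * np.sqrt(frac * (1 - frac) / n)
        assert abs(got - est) < 3 * se


class TestVKT:
    def test_direct_product(self):
        link = _fc([_line([[-250, 0], [250, 0]], vol_light=1000.0, vol_heavy=0.0)])
        assert vkt_in_radius(link, (0, 0), 500, "light") == pytest.approx(500.0)

    def test_zero_volume_network(self):
        link = _fc([_line([[-250, 0], [250, 0]], vol_light=0.0, vol_heavy=0.0)])
        assert vkt_in_radius(link, (0, 0), 500, "heavy") == 0.0

    def test_negative_volume_rejected(self):
        link = _fc([_line([[0, 0], [10, 0]], vol_light=-5.0)])
        with pytest.raises(ValueError):
            vkt_in_radius(link, (0, 0), 500, "light")

    def test_random_network_matches_per_link_oracle(self):
        rng = np.random.default_rng(3)
        feats = [
            _line([list(rng.uniform(-800, 800, 2)), list(rng.uniform(-800, 800, 2))],
                  vol_light=float(rng.uniform(0, 2e4)), vol_heavy=float(rng.uniform(0, 2e3)))
            for _ in range(15)
        ]
        for cls in ("light", "heavy"):
            got = vkt_in_radius(_fc(feats), (0, 0), 500, cls)
            want = sum(
                f["properties"][f"vol_{cls}"] * length_in_radius(_fc([f]), (0, 0), 500) / 1000.0
                for f in feats
            )
            assert got == pytest.approx(want, rel=1e-12)


class TestLUM:
    def test_homogeneous_buffer_scores_zero(self):
        parcels = _fc([_rect(-100, -100, 200, 200, landuse_class="residential")])
        assert lum_index(parcels, (0, 0), 500, taxonomy=["residential", "retail"]) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_mix_scores_one(self):
        parcels = _fc(
            [
                _rect(-100, 0, 100, 100, landuse_class="residential"),
                _rect(0, 0, 100, 100, landuse_class="retail"),
            ]
        )
        assert lum_index(parcels, (0, 0), 500, taxonomy=["residential", "retail"]) == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_entropy_example(self):
        parcels = _fc(
            [
                _rect(-150, 0, 150, 100, landuse_class="residential"),  # 15000 m2 = 75%
                _rect(0, 0, 50, 100, landuse_class="retail"),  # 5000 m2 = 25%
            ]
        )
        want = -(0.75 * math.log(0.75) + 0.25 * math.log(0.25)) / math.log(2)
        got = lum_index(parcels, (0, 0), 500, taxonomy=["residential", "retail"])
        assert got == pytest.approx(want, abs=1e-12)
        assert round(want, 4) == 0.8113

    def test_empty_buffer_is_missing(self):
        assert math.isnan(lum_index(_fc([]), (0, 0), 500))

    def test_single_class_taxonomy_rejected(self):
        with pytest.raises(ValueError):
            lum_index(_fc([]), (0, 0), 500, taxonomy=["residential"])

    def test_invariant_to_class_relabeling(self):
        parcels = _fc(
            [
                _rect(-100, 0, 100, 100, landuse_class="residential"),
                _rect(0, 0, 60, 100, landuse_class="retail"),
            ]
        )
        swapped = _fc(
            [
                _rect(-100, 0, 100, 100, landuse_class="retail"),
                _rect(0, 0, 60, 100, landuse_class="residential"),
            ]
        )
        tax = ["residential", "retail", "other"]
        assert lum_index(parcels, (0, 0), 500, taxonomy=tax) == pytest.approx(
            lum_index(swapped, (0, 0), 500, taxonomy=tax), abs=1e-12
        )


class TestRetFAR:
    def test_single_parcel_ratio(self):
        parcels = _fc([_rect(-25, -25, 50, 50, landuse_class="retail", floor_area_m2=5000.0, parcel_area_m2=2500.0)])
        assert retfar(parcels, (0, 0), 250) == pytest.approx(2.0)

    def test_no_retail_in_buffer_is_zero(self):
        parcels = _fc([_rect(-25, -25, 50, 50, landuse_class="residential")])
        assert retfar(parcels, (0, 0), 250) == 0.0

    def test_negative_floor_area_rejected(self):
        parcels = _fc([_rect(-25, -25, 50, 50, landuse_class="retail", floor_area_m2=-1.0)])
        with pytest.raises(ValueError):
            retfar(parcels, (0, 0), 250)

    def test_random_parcels_match_direct_sum_oracle(self):
        rng = np.random.default_rng(4)
        feats = []
        for _ in range(12):
            cls = rng.choice(["retail", "residential"])
            feats.append(
                _rect(float(rng.uniform(-400, 300)), float(rng.uniform(-400, 300)),
                      float(rng.uniform(30, 200)), float(rng.uniform(30, 200)),
                      landuse_class=str(cls), floor_area_m2=float(rng.uniform(100, 5000)))
            )
        got = retfar(_fc(feats), (0, 0), 250)
        from shapely.geometry import Point, shape

        disc = Point(0, 0).buffer(250, quad_segs=32)
        floor = land = 0.0
        for f in feats:
            if f["properties"]["landuse_class"] != "retail":
                continue
            clipped = shape(f["geometry"]).intersection(disc).area
            if clipped > 0:
                floor += f["properties"]["floor_area_m2"]
                land += clipped
        assert got == pytest.approx(floor / land if land else 0.0, rel=1e-12)


class TestInvariants:
    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        shift = np.array([12345.6, -789.0])
        pts = rng.uniform(-600, 600, (50, 2))
        layer0 = _fc([_pt(x, y) for x, y in pts])
        layer1 = _fc([_pt(x + shift[0], y + shift[1]) for x, y in pts])
        c0, c1 = (0.0, 0.0), tuple(shift)
        assert count_points_in_radius(layer0, c0, 500) == count_points_in_radius(layer1, c1, 500)
        rect0 = _fc([_rect(-100, -100, 300, 200, landuse_class="retail", floor_area_m2=100.0)])
        rect1 = _fc([_rect(-100 + shift[0], -100 + shift[1], 300, 200, landuse_class="retail", floor_area_m2=100.0)])
        a0 = area_in_radius(rect0, c0, 500)
        a1 = area_in_radius(rect1, c1, 500)
        assert a1 == pytest.approx(a0, rel=1e-9)

    def test_monotone_in_radius(self):
        rng = np.random.default_rng(6)
        pts = _fc([_pt(*rng.uniform(-900, 900, 2)) for _ in range(80)])
        lines = _fc([_line([list(rng.uniform(-900, 900, 2)), list(rng.uniform(-900, 900, 2))],
                           vol_light=100.0, vol_heavy=10.0) for _ in range(10)])
        polys = _fc([_rect(float(rng.uniform(-900, 600)), float(rng.uniform(-900, 600)), 200, 150)
                     for _ in range(6)])
        radii = [100, 250, 500, 800]
        for fn in (
            lambda r: count_points_in_radius(pts, (0, 0), r),
            lambda r: length_in_radius(lines, (0, 0), r),
            lambda r: area_in_radius(polys, (0, 0), r),
            lambda r: vkt_in_radius(lines, (0, 0), r, "light"),
        ):
            vals = [fn(r) for r in radii]
            assert all(b >= a - 1e-9 for a, b in zip(vals, vals[1:]))

    def test_large_radius_converges_to_layer_totals(self):
        rng = np.random.default_rng(7)
        lines = _fc([_line([list(rng.uniform(-500, 500, 2)), list(rng.uniform(-500, 500, 2))]) for _ in range(5)])
        from shapely.geometry import shape

        total = sum(shape(f["geometry"]).length for f in lines["features"])
        assert length_in_radius(lines, (0, 0), 1e5) == pytest.approx(total, rel=1e-9)


class TestAssemble:
    def _region(self):
        layers = {
            "bus_stops": _fc([_pt(100, 100), _pt(2000, 2000)]),
            "subway_stations": _fc([]),
            "intersections": _fc([_pt(150, 100)]),
            "bike_paths": _fc([_line([[0, 120], [300, 120]])]),
            "green_spaces": _fc([_rect(50, 50, 100, 100)]),
            "sidewalks": _fc([]),
            "traffic": _fc([_line([[0, 80], [400, 80]], vol_light=1000.0, vol_heavy=100.0)]),
            "parcels": _fc([_rect(0, 0, 300, 300, landuse_class="retail", floor_area_m2=900.0)]),
        }
        tracts = pd.DataFrame(
            {"tract_id": ["T0", "T1"], "pm25": [9.0, 10.0], "o3": [46.0, 47.0], "gini": [0.4, 0.5],
             "college_pct": [30.0, 40.0], "poverty": [2.0, 1.0], "uninsured_pct": [8.0, 9.0],
             "low_food_access": [0, 1]}
        )
        return layers, tracts

    def test_empty_region_all_zero_and_lum_missing(self):
        layers = {k: _fc([]) for k in ("bus_stops", "subway_stations", "intersections", "bike_paths",
                                       "green_spaces", "sidewalks", "traffic", "parcels")}
        _, tracts = self._region()
        patients = pd.DataFrame({"patient_id": ["a"], "home_x": [100.0], "home_y": [100.0], "tract_id": ["T0"]})
        out = assemble_features(patients, layers, tracts)
        row = out.iloc[0]
        assert row["bus_stops_500"] == 0 and row["bike_len_500"] == 0 and row["vkt_light_500"] == 0
        assert np.isnan(row["lum_500"])
        assert row["pm25"] == 9.0

    def test_identical_coordinates_identical_vectors(self):
        layers, tracts = self._region()
        patients = pd.DataFrame(
            {"patient_id": ["a", "b"], "home_x": [120.0, 120.0], "home_y": [110.0, 110.0], "tract_id": ["T0", "T0"]}
        )
        out = assemble_features(patients, layers, tracts).drop(columns=["patient_id"])
        assert out.iloc[0].equals(out.iloc[1])

    def test_unknown_tract_rejected_with_patient_listed(self):
        layers, tracts = self._region()
        patients = pd.DataFrame({"patient_id": ["zz"], "home_x": [0.0], "home_y": [0.0], "tract_id": ["NOPE"]})
        with pytest.raises(ValueError, match="zz"):
            assemble_features(patients, layers, tracts)

    def test_vector_matches_indicator_by_indicator_oracle(self):
        layers, tracts = self._region()
        patients = pd.DataFrame({"patient_id": ["a"], "home_x": [100.0], "home_y": [100.0], "tract_id": ["T1"]})
        out = assemble_features(patients, layers, tracts).iloc[0]
        c = (100.0, 100.0)
        assert out["bus_stops_500"] == count_points_in_radius(layers["bus_stops"], c, 500)
        assert out["bike_len_500"] == pytest.approx(length_in_radius(layers["bike_paths"], c, 500))
        assert out["green_area_500"] == pytest.approx(area_in_radius(layers["green_spaces"], c, 500))
        assert out["vkt_heavy_500"] == pytest.approx(vkt_in_radius(layers["traffic"], c, 500, "heavy"))
        assert out["lum_500"] == pytest.approx(lum_index(layers["parcels"], c, 500))
        assert out["retfar_250"] == pytest.approx(retfar(layers["parcels"], c, 250))
        assert out["gini"] == 0.5
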