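"""Region geometry: plume polygons, crossings, perimeter-density ratios."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from octoplume import regions as R
from octoplume import synthetic as syn


def track_from_points(points, frame_rate=10.0):
    p = np.asarray(points, float)
    return pd.DataFrame(
        {
            "frame": np.arange(len(p)),
            "time_s": np.arange(len(p)) / frame_rate,
            "center_x_cm": p[:, 0],
            "center_y_cm": p[:, 1],
        }
    )


def winding_number_inside(point, vertices):
    """Independent point-in-polygon oracle via summed subtended angles."""
    v = np.asarray(vertices, float) - np.asarray(point, float)
    ang = np.arctan2(v[:, 1], v[:, 0])
    d = np.diff(np.concatenate([ang, ang[:1]]))
    d = (d + np.pi) % (2 * np.pi) - np.pi
    return abs(d.sum()) > np.pi


class TestVarianceProjection:
    def test_static_video_zero(self):
        stack = np.tile(np.arange(12.0).reshape(3, 4), (5, 1, 1))
        assert np.allclose(R.variance_projection(stack), 0.0)

    def test_alternating_pixel_quarter(self):
        stack = np.zeros((10, 2, 2))
        stack[::2, 0, 0] = 1.0
        assert R.variance_projection(stack)[0, 0] == pytest.approx(0.25)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            R.variance_projection(np.zeros((1, 4, 4)))


class TestThresholdToPolygon:
    def test_rectangle_mask_recovered(self):
        img = np.zeros((60, 80))
        img[20:40, 10:50] = 1.0
        poly = R.threshold_to_polygon(img, px_per_cm=2.0, source_cm=(15.0, 15.0), percentile=50)
        got = Polygon(poly.vertices)
        want = Polygon([(5, 10), (24.5, 10), (24.5, 19.5), (5, 19.5)])
        overlap = got.intersection(want).area / got.union(want).area
        assert overlap > 0.9

    def test_larger_component_kept(self):
        img = np.zeros((50, 50))
        img[5:10, 5:10] = 1.0  # small blob
        img[20:45, 20:45] = 1.0  # big blob containing the source
        poly = R.threshold_to_polygon(img, px_per_cm=1.0, source_cm=(30.0, 30.0), percentile=50)
        assert Polygon(poly.vertices).area > 300

    def test_area_monotone_in_percentile(self):
        scene = syn.SyntheticScene(px_per_cm=2.0, rng_seed=0)
        stack = syn.simulate_plume_video(scene, (150.0, 58.0), 120, seed=5)
        var = R.variance_projection(stack)
        a99 = Polygon(
            R.threshold_to_polygon(var, 2.0, (150.0, 58.0), percentile=99).vertices
        ).area
        a95 = Polygon(
            R.threshold_to_polygon(var, 2.0, (150.0, 58.0), percentile=95).vertices
        ).area
        assert a95 >= a99

    def test_mask_contains_source_and_widens_downstream(self):
        scene = syn.SyntheticScene(px_per_cm=2.0, rng_seed=0)
        stack = syn.simulate_plume_video(scene, (150.0, 58.0), 150, seed=5)
        var = R.variance_projection(stack)
        poly = R.threshold_to_polygon(var, 2.0, (150.0, 58.0), percentile=98)
        assert R.point_in_polygon((150.0, 58.0), poly)
        from shapely.geometry import LineString

        w_near = poly.shapely.intersection(LineString([(146, 0), (146, 116)])).length
        w_far = poly.shapely.intersection(LineString([(128, 0), (128, 116)])).length
        assert w_far > w_near


class TestPointInPolygon:
    def test_centroid_and_outside(self):
        poly = R.PlumePolygon(
            vertices=[(0, 0), (10, 0), (10, 6), (0, 6)], source=(5.0, 3.0)
        )
        assert R.point_in_polygon((5, 3), poly)
        assert not R.point_in_polygon((20, 3), poly)
        assert R.point_in_polygon((0, 0), poly)  # boundary counts as inside

    def test_matches_winding_number_oracle(self):
        rng = np.random.default_rng(42)
        verts = [(0, 0), (8, -2), (12, 4), (9, 9), (3, 11), (-2, 5)]
        poly = R.PlumePolygon(vertices=verts, source=(5.0, 4.0))
        pts = rng.uniform(-5, 15, size=(1000, 2))
        for p in pts:
            assert R.point_in_polygon(p, poly) == winding_number_inside(p, verts)


class TestFirstCrossing:
    def test_straight_track_exact_circle_entry(self):
        circle = R.TargetCircle(center=(5.0, 0.0), radius=1.0)
        track = track_from_points([(x, 0.0) for x in np.linspace(0, 10, 101)])
        events = R.first_crossing(track, circle, "target_circle", 10.0)
        assert len(events) == 1
        assert events[0].point[0] == pytest.approx(4.0, abs=1e-6)
        assert events[0].point[1] == pytest.approx(0.0, abs=1e-6)
        # crossing point satisfies the circle equation to 1e-6 cm
        d = np.hypot(events[0].point[0] - 5.0, events[0].point[1])
        assert d == pytest.approx(1.0, abs=1e-6)

    def test_track_starting_inside_flagged(self):
        circle = R.TargetCircle(center=(0.0, 0.0), radius=5.0)
        track = track_from_points([(0, 0), (1, 0), (2, 0)])
        events = R.first_crossing(track, circle, "target_circle", 10.0)
        assert len(events) == 1 and events[0].started_inside
        assert events[0].frame == 0

    def test_reset_rule_separates_approaches(self):
        circle = R.TargetCircle(center=(0.0, 0.0), radius=2.0)
        inside, outside = (0.0, 0.0), (10.0, 0.0)
        pts = (
            [outside] * 5 + [inside] * 5
            + [outside] * 600  # 60 s outside at 10 Hz
            + [inside] * 5
        )
        events = R.first_crossing(track_from_points(pts), circle, "c", 10.0, reset_s=30.0)
        assert len(events) == 2
        # a short excursion below the reset time does not arm a new approach
        pts2 = [outside] * 5 + [inside] * 5 + [outside] * 20 + [inside] * 5
        events2 = R.first_crossing(track_from_points(pts2), circle, "c", 10.0, reset_s=30.0)
        assert len(events2) == 1

    def test_never_entering_gives_no_events(self):
        circle = R.TargetCircle(center=(50.0, 50.0), radius=1.0)
        track = track_from_points([(0, 0), (1, 0)])
        assert R.first_crossing(track, circle, "c", 10.0) == []


class TestClassifyApproach:
    def setup_method(self):
        self.rect = R.StationRectangle(center=(140.0, 58.0), square_size=24.0, bait_index=1)
        self.rs = R.RegionSet(
            station_rect=self.rect,
            target_circle=R.TargetCircle(center=(150.0, 58.0)),
            plume=R.PlumePolygon(
                vertices=[(100, 50), (160, 50), (160, 66), (100, 66)], source=(150.0, 58.0)
            ),
        )

    def test_downstream_edge_is_against_flow(self):
        # flow (-1, 0): entering through the low-x edge means moving upstream
        ev = R.CrossingEvent(frame=3, point=(128.0, 58.0), region_id="station_rect")
        assert R.classify_approach(ev, self.rs) == "against_flow:bait"

    def test_upstream_edge_is_with_flow_control(self):
        ev = R.CrossingEvent(frame=3, point=(152.0, 30.0), region_id="station_rect")
        assert R.classify_approach(ev, self.rs) == "with_flow:control"

    def test_corner_owned_by_ccw_segment(self):
        # the rectangle's low-x/low-y corner: on the CCW walk the side edge
        # ends there coming from the against-flow edge, which owns it
        x0, y0, _, _ = self.rect.bounds
        ev = R.CrossingEvent(frame=0, point=(x0, y0), region_id="station_rect")
        label = R.classify_approach(ev, self.rs)
        assert label == "against_flow:control"

    def test_circle_crossing_by_plume_membership(self):
        ev_in = R.CrossingEvent(frame=0, point=(140.0, 58.0), region_id="target_circle")
        ev_out = R.CrossingEvent(frame=0, point=(150.0, 44.5), region_id="target_circle")
        assert R.classify_approach(ev_in, self.rs) == "inside_plume"
        assert R.classify_approach(ev_out, self.rs) == "outside_plume"

    def test_surge_cast_tracks_enter_against_flow(self, scene):
        labels = []
        for seed in range(8):
            truth = syn.simulate_motion(
                "surge_cast",
                duration_s=60.0,
                seed=seed,
                scene=scene,
                params={"start_cm": (80.0, 58.0), "wall_margin_cm": 10.0},
            )
            track = track_from_points(truth.true_center_cm)
            for ev in R.first_crossing(track, self.rect, "station_rect", 10.0):
                labels.append(R.classify_approach(ev, self.rs))
        against = sum(lab.startswith("against_flow") for lab in labels)
        assert labels and against / len(labels) > 0.5


class TestExpectedRatios:
    def setup_method(self):
        self.rs = R.RegionSet(
            station_rect=R.StationRectangle(center=(140.0, 58.0), square_size=24.0, bait_index=0)
        )

    def test_long_edge_share_is_three_eighths(self):
        ratios = R.expected_ratios(self.rs, "side_partition")
        assert ratios["against_flow"] == pytest.approx(0.375)
        assert ratios["with_flow"] == pytest.approx(0.375)
        assert ratios["side"] == pytest.approx(0.25)
        assert sum(ratios.values()) == pytest.approx(1.0)

    def test_bait_conditional_share_is_one_third(self):
        ratios = R.expected_ratios(self.rs, "stations_given_against_flow")
        assert ratios["bait"] == pytest.approx(1.0 / 3.0)
        assert sum(ratios.values()) == pytest.approx(1.0)

    def test_half_plane_plume_covers_half_circle(self):
        rs = R.RegionSet(
            target_circle=R.TargetCircle(center=(0.0, 0.0), radius=10.0),
            plume=R.PlumePolygon(
                vertices=[(0, -50), (50, -50), (50, 50), (0, 50)], source=(25.0, 0.0)
            ),
        )
        ratios = R.expected_ratios(rs, "plume_arc")
        assert ratios["inside_plume"] == pytest.approx(0.5, abs=1e-3)

    def test_segment_lengths_sum_to_external_perimeter(self):
        rect = self.rs.station_rect
        total = sum(seg.length for seg in rect.external_segments())
        assert total == pytest.approx(8 * rect.square_size)


class TestOccupancy:
    def test_wall_hugging_track(self):
        track = track_from_points([(5.0, 50.0)] * 20)
        rs = R.RegionSet()
        out = R.occupancy_stats(track, rs, active=np.ones(20, bool))
        assert out["wall_fraction"] == 1.0

    def test_uniform_points_match_area_fraction(self):
        rng = np.random.default_rng(0)
        L, W, band = 185.0, 116.0, 15.0
        pts = rng.uniform((0, 0), (L, W), size=(20000, 2))
        track = track_from_points(pts)
        out = R.occupancy_stats(track, R.RegionSet(), active=np.ones(len(pts), bool))
        inner = (L - 2 * band) * (W - 2 * band)
        expected = 1.0 - inner / (L * W)
        assert out["wall_fraction"] == pytest.approx(expected, abs=0.02)

    def test_hourly_profile_localized(self):
        n = 7200  # 2 hours at 1 Hz equivalent spacing of 1 s
        track = track_from_points([(90.0, 58.0)] * n, frame_rate=1.0)
        active = np.zeros(n, bool)
        active[:3600] = True  # active only in the first hour
        out = R.occupancy_stats(track, R.RegionSet(), active=active, start_hour=20.0)
        assert out["hourly_activity"][20] == 1.0
        assert out["hourly_activity"][21] == 0.0

    def test_no_active_frames_raises(self):
        track = track_from_points([(5.0, 5.0)] * 3)
        with pytest.raises(ValueError):
            R.occupancy_stats(track, R.RegionSet(), active=np.zeros(3, bool))


class TestPlumePolygonValidation:
    def test_self_intersection_rejected(self):
        with pytest.raises(ValueError):
            R.PlumePolygon(vertices=[(0, 0), (10, 10), (10, 0), (0, 10)], source=(5, 5))

    def test_source_outside_rejected(self):
        with pytest.raises(ValueError, match="source"):
            R.PlumePolygon(vertices=[(0, 0), (10, 0), (10, 10), (0, 10)], source=(50, 50))
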