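"""Side-view LiDAR chain: decoding, pose, downsampling, ground removal,
clustering and the three plant-location methods."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rowoptics import lidar
from rowoptics.lidar import (
    GroundModel,
    GroundPlane,
    LidarConfig,
    PointCloud,
    Pose,
    Scan,
    ScanSet,
    apply_pose,
    cluster_plants,
    delimit_seedbed,
    extract_aerial,
    grid_downsample,
    initial_k,
    locate_centre,
    locate_lowest,
    locate_stem_intersection,
    normalize_heights,
    polar_to_cartesian,
    run_lidar_pipeline,
)

CFG = LidarConfig(theoretical_spacing=290.0, rng_seed=0)

FLAT_GROUND = GroundModel(
    (GroundPlane(-1e6, 1e6, np.array([0.0, 0.0, 1.0]), 0.0, 0.0, 0.0),)
)


def make_cluster(points, config=CFG, ground=FLAT_GROUND):
    return lidar._build_cluster(np.asarray(points, float), config, ground)


class TestPolarToCartesian:
    def test_near_range_gate(self):
        scan = Scan([0.0, 10.0], [40.0, 1000.0], 0.0)
        cloud = polar_to_cartesian(scan, CFG)
        assert len(cloud) == 1

    def test_axis_case(self):
        scan = Scan([0.0], [1000.0], 0.0)
        cloud = polar_to_cartesian(scan, CFG)
        assert cloud.points[0] == pytest.approx([0.0, 1000.0, 0.0])

    def test_full_scan_against_trig_oracle(self, rng):
        angles = np.arange(-135.0, 135.0, 0.5)
        ranges = rng.uniform(60, 5000, size=angles.size)
        cloud = polar_to_cartesian(Scan(angles, ranges, 0.0), CFG)
        for (x, y, z), a, r in zip(cloud.points, angles, ranges):
            assert x == 0.0
            assert y == pytest.approx(r * math.cos(math.radians(a)))
            assert z == pytest.approx(r * math.sin(math.radians(a)))


class TestApplyPose:
    def test_identity(self, rng):
        cloud = PointCloud(rng.normal(size=(20, 3)) * 100)
        out = apply_pose(cloud, Pose(0, 0, 0, 0))
        assert out.points == pytest.approx(cloud.points)

    def test_lateral_mount_hand_computed(self):
        out = apply_pose(PointCloud([[100.0, 200.0, 300.0]]), Pose(0, -180, 0, 1000))
        assert out.points[0] == pytest.approx([900.0, 200.0, -300.0], abs=1e-9)

    def test_pure_translation(self, rng):
        cloud = PointCloud(rng.normal(size=(10, 3)) * 100)
        out = apply_pose(cloud, Pose(0, 0, 0, 250.0))
        assert out.points - cloud.points == pytest.approx(
            np.tile([250.0, 0.0, 0.0], (10, 1))
        )

    @given(
        st.floats(-360, 360),
        st.floats(-360, 360),
        st.floats(-360, 360),
    )
    def test_rotation_is_isometry(self, roll, pitch, yaw):
        rng = np.random.default_rng(99)
        pts = rng.normal(size=(8, 3)) * 500
        out = apply_pose(PointCloud(pts), Pose(roll, pitch, yaw, 0.0)).points
        d_in = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        d_out = np.linalg.norm(out[:, None] - out[None], axis=-1)
        assert d_out == pytest.approx(d_in, rel=1e-9, abs=1e-9)


class TestCloudOps:
    def test_normalize_heights(self):
        cloud = PointCloud([[0, 0, 5.0], [1, 1, 10.0]])
        out = normalize_heights(cloud)
        assert list(out.z) == [0.0, 5.0]
        again = normalize_heights(out)
        assert again.points == pytest.approx(out.points)

    def test_normalize_random_min_exactly_zero(self, rng):
        out = normalize_heights(PointCloud(rng.normal(size=(50, 3)) * 100))
        assert out.z.min() == 0.0

    def test_delimit_identity_and_empty(self, rng):
        cloud = PointCloud(rng.uniform(-100, 100, size=(30, 3)))
        assert len(delimit_seedbed(cloud, (-1e6, 1e6), (-1e6, 1e6))) == 30
        assert len(delimit_seedbed(cloud, (500, 600), None)) == 0
        with pytest.raises(ValueError):
            delimit_seedbed(cloud, (10, -10), None)

    def test_delimit_equals_predicate_oracle(self, rng):
        pts = rng.uniform(-100, 100, size=(200, 3))
        out = delimit_seedbed(PointCloud(pts), (-50, 25), (0, 80))
        mask = (pts[:, 0] >= -50) & (pts[:, 0] <= 25) & (pts[:, 1] >= 0) & (pts[:, 1] <= 80)
        assert out.points == pytest.approx(pts[mask])

    def test_grid_merges_box_mates_to_centroid(self):
        cloud = PointCloud([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0]])
        out = grid_downsample(cloud, CFG)
        assert len(out) == 1
        assert out.points[0] == pytest.approx([0.5, 0.5, 0.5])

    def test_grid_keeps_sparse_cloud(self, rng):
        pts = rng.permutation(np.arange(20))[:, None] * np.array([[10.0, 10.0, 10.0]])
        out = grid_downsample(PointCloud(pts), CFG)
        assert len(out) == 20

    def test_grid_equals_hash_grid_oracle(self, rng):
        pts = rng.uniform(0, 30, size=(300, 3))
        out = grid_downsample(PointCloud(pts), CFG)
        origin = pts.min(axis=0)
        boxes = {}
        for p in pts:
            key = tuple(np.floor((p - origin) / CFG.grid_step).astype(int))
            boxes.setdefault(key, []).append(p)
        expect = sorted(tuple(np.mean(v, axis=0)) for v in boxes.values())
        got = sorted(map(tuple, out.points))
        assert len(out) <= len(pts)
        assert np.array(got) == pytest.approx(np.array(expect))


class TestExtractAerial:
    def make_ground(self, rng, sigma=0.0, n=2000, tilt=0.0):
        x = rng.uniform(0, 800, n)
        y = rng.uniform(0, 500, n)
        z = tilt * x + rng.normal(0, sigma, n) if sigma else tilt * x
        return np.column_stack([x, y, z])

    def test_blob_separated_exactly_from_flat_plane(self, rng):
        ground = self.make_ground(rng, sigma=2.0)
        blob = rng.normal([400, 250, 200], 15, size=(150, 3))
        cloud = PointCloud(np.vstack([ground, blob]))
        aerial, model = extract_aerial(cloud, CFG, rng)
        assert len(aerial) == 150
        assert aerial.z.min() > 100
        assert len(model.planes) >= 1

    def test_pure_plane_leaves_nothing(self, rng):
        aerial, _ = extract_aerial(PointCloud(self.make_ground(rng, sigma=1.0)), CFG, rng)
        assert len(aerial) == 0

    def test_ground_recall_with_moderate_noise(self, rng):
        ground = self.make_ground(rng, sigma=10.0)
        blob = rng.normal([400, 250, 250], 10, size=(100, 3))
        aerial, _ = extract_aerial(PointCloud(np.vstack([ground, blob])), CFG, rng)
        # every blob point survives; at most 1% of ground leaks through
        assert len(aerial) >= 100
        assert len(aerial) - 100 <= 0.01 * len(ground)

    def test_steep_plane_rejected_by_angular_constraint(self, rng):
        tilted = self.make_ground(rng, tilt=math.tan(math.radians(10.0)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aerial, model = extract_aerial(PointCloud(tilted), CFG, rng)
        assert len(aerial) == len(tilted)  # nothing removed
        assert len(model.planes) == 0

    def test_sparse_interval_passes_through(self, rng):
        cloud = PointCloud([[0.0, 0.0, 0.0], [10.0, 5.0, 3.0]])
        with pytest.warns(UserWarning):
            aerial, _ = extract_aerial(cloud, CFG, rng)
        assert len(aerial) == 2


class TestInitialK:
    @pytest.mark.parametrize(
        "travelled,spacing,expected",
        [(10000.0, 290.0, 70), (240.0, 240.0, 4), (100.0, 240.0, 2)],
    )
    def test_examples(self, travelled, spacing, expected):
        assert initial_k(travelled, spacing) == expected

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            initial_k(0.0, 240.0)


class TestClusterPlants:
    def blob(self, rng, centre, n=60, sigma=8.0):
        return rng.normal(centre, sigma, size=(n, 3))

    def test_two_blobs_recovered_from_inflated_k(self, rng):
        pts = np.vstack(
            [self.blob(rng, [500, 0, 100]), self.blob(rng, [1000, 0, 100])]
        )
        clusters = cluster_plants(PointCloud(pts), CFG, k0=6)
        assert len(clusters) == 2
        assert abs(clusters[0].centre_x - 500) < 15
        assert abs(clusters[1].centre_x - 1000) < 15

    def test_single_blob(self, rng):
        clusters = cluster_plants(PointCloud(self.blob(rng, [700, 0, 80])), CFG, k0=4)
        assert len(clusters) == 1

    def test_small_cluster_excluded(self, rng):
        pts = np.vstack(
            [self.blob(rng, [500, 0, 100]), self.blob(rng, [1200, 0, 100], n=4, sigma=1.0)]
        )
        clusters = cluster_plants(PointCloud(pts), CFG, k0=2)
        assert len(clusters) == 1
        assert all(len(c.points) >= CFG.min_cluster_size for c in clusters)

    def test_reduction_postcondition_no_close_centroids(self, rng):
        centres = [[i * 120.0, 0, 100] for i in range(6)]  # closer than 0.2 * 290? no: 120 > 58
        pts = np.vstack([self.blob(rng, c, n=40) for c in centres])
        clusters = cluster_plants(PointCloud(pts), CFG, k0=12)
        xs = np.sort([c.centre_x for c in clusters])
        assert np.diff(xs).min() >= CFG.min_distance_between_plants


class TestLocators:
    def test_centre_of_symmetric_blob(self):
        pts = [[990.0, 0, 100], [1010.0, 0, 100], [1000.0, 0, 90], [1000.0, 0, 110], [1000.0, 0, 100]]
        c = make_cluster(pts)
        assert locate_centre(c) == pytest.approx(1000.0)

    def test_centre_is_mean_oracle(self, rng):
        pts = rng.normal([800, 0, 120], 20, size=(50, 3))
        assert locate_centre(make_cluster(pts)) == pytest.approx(pts[:, 0].mean())

    def test_lowest_point_and_tie_break(self):
        pts = [[1000.0, 0, 50.0], [995.0, 0, 10.0], [1005.0, 0, 60.0], [990.0, 0, 80.0], [985.0, 0, 70.0]]
        assert locate_lowest(make_cluster(pts)) == pytest.approx(995.0)
        tied = pts + [[980.0, 0, 10.0]]
        assert locate_lowest(make_cluster(tied)) == pytest.approx(980.0)

    def test_lowest_equals_argmin_oracle(self, rng):
        pts = rng.normal([800, 0, 120], 20, size=(50, 3))
        c = make_cluster(pts)
        assert locate_lowest(c) == pytest.approx(pts[np.argmin(pts[:, 2]), 0])

    def test_vertical_stem_intersects_at_its_column(self):
        z = np.arange(20, 220, 5.0)
        stem = np.column_stack([np.full_like(z, 1000.0), np.zeros_like(z), z])
        c = make_cluster(stem)
        x = locate_stem_intersection(c, FLAT_GROUND, CFG)
        assert abs(x - 1000.0) <= CFG.grid_step

    def test_leaning_plant_intersection_finds_base_centre_finds_canopy(self, rng):
        lean, height = 50.0, 120.0
        z = np.arange(0, height, 2.0)
        stem_x = 1000.0 + lean * z / height
        stem = np.column_stack([stem_x, np.zeros_like(z), z])
        canopy_c = np.array([1000.0 + 0.6 * lean, 0.0, 180.0])
        canopy = rng.normal(canopy_c, [25.0, 5.0, 15.0], size=(250, 3))
        member = np.vstack([stem, canopy])
        c = make_cluster(member)
        x_inter = locate_stem_intersection(c, FLAT_GROUND, CFG)
        x_centre = locate_centre(c)
        assert abs(x_inter - 1000.0) < 8.0  # base of the stem
        assert abs(x_centre - member[:, 0].mean()) < 1e-9  # canopy-weighted
        assert x_centre - x_inter > 0.3 * lean  # difference reflects the lean

    def test_stick_cylinder_methods_agree(self, rng):
        # a lateral scan hits a thin stick near its axis: x-scatter well
        # under the stick diameter
        z = np.repeat(np.arange(30, 280, 6.0), 2)
        x = 1000.0 + rng.uniform(-1.5, 1.5, z.size)
        c = make_cluster(np.column_stack([x, np.zeros_like(z), z]))
        locs = [locate_centre(c), locate_lowest(c), locate_stem_intersection(c, FLAT_GROUND, CFG)]
        assert max(locs) - min(locs) <= 2 * CFG.grid_step

    def test_stem_parallel_to_ground_falls_back_to_lowest(self):
        # points on the line z = 0.5 x - 450, same slope as the ground line
        pts = [[1000.0, 0, 50.0], [1002.0, 0, 51.0], [1004.0, 0, 52.0], [1006.0, 0, 53.0], [1008.0, 0, 54.0]]
        sloped_ground = GroundModel(
            (GroundPlane(-1e6, 1e6, np.array([0.0, 0.0, 1.0]), 0.0, 0.5, 0.0),)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            c = make_cluster(pts, ground=sloped_ground)
        with pytest.warns(UserWarning):
            x = locate_stem_intersection(c, sloped_ground, CFG)
        assert x == pytest.approx(locate_lowest(c))


class TestPipeline:
    def test_empty_scans(self):
        result = run_lidar_pipeline(ScanSet(()), CFG)
        assert all(len(v) == 0 for v in result.estimates.values())

    def test_deterministic_given_seed(self, stick_row_run):
        cfg, truth, scans, lc, result = stick_row_run
        again = run_lidar_pipeline(
            scans,
            lc,
            y_bounds=(cfg.row_offset - cfg.bed_halfwidth, cfg.row_offset + cfg.bed_halfwidth),
        )
        for method in result.estimates:
            a = [e.location for e in result.estimates[method]]
            b = [e.location for e in again.estimates[method]]
            assert a == pytest.approx(b)

    def test_estimates_sorted_and_counts_logged(self, stick_row_run):
        _, truth, _, lc, result = stick_row_run
        for ests in result.estimates.values():
            locs = [e.location for e in ests]
            assert locs == sorted(locs)
        d = result.diagnostics
        assert d["decoded_points"] >= d["seedbed_points"] >= d["gridded_points"] >= d["aerial_points"]

    def test_cluster_centroids_respect_min_distance(self, stick_row_run):
        _, _, _, lc, result = stick_row_run
        xs = np.sort([c.centre_x for c in result.clusters])
        assert np.diff(xs).min() >= lc.min_distance_between_plants
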