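"""Side-view LiDAR processing chain for in-row plant localization.

A 2-D laser scanner rides on the platform with its scan plane perpendicular
to the travel direction, slicing the crop row laterally while a ground-wheel
encoder provides the along-track coordinate.  The chain is:

1. polar -> Cartesian decoding of each scan in a horizontal-reference
   sensor frame, with a near-range gate;
2. a rigid pose transform (roll/pitch/yaw as row-vector matrix products)
   plus the encoder translation on x, mapping every point into the platform
   frame (x = travel, z = up), followed by height normalisation;
3. optional manual seedbed delimitation and box-grid downsampling;
4. ground removal by per-interval MSAC plane fitting constrained to
   near-vertical normals, leaving the aerial (plant) points;
5. k-means clustering of the aerial points with an automatic
   cluster-count reduction until no two cluster centres sit closer
   along-track than a fifth of the nominal plant spacing;
6. three per-cluster location estimates: centre of the cluster, lowest
   point, and the intersection of a fitted stem line with the local ground
   line.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .row_model import PlantEstimate

__all__ = [
    "Scan",
    "ScanSet",
    "Pose",
    "PointCloud",
    "GroundModel",
    "LidarConfig",
    "PlantCluster",
    "PipelineResult",
    "polar_to_cartesian",
    "apply_pose",
    "normalize_heights",
    "delimit_seedbed",
    "grid_downsample",
    "extract_aerial",
    "initial_k",
    "cluster_plants",
    "locate_centre",
    "locate_lowest",
    "locate_stem_intersection",
    "run_lidar_pipeline",
]


@dataclass(frozen=True)
class Scan:
    """One LiDAR revolution: beam angles (deg), ranges (mm), encoder value."""

    angles_deg: np.ndarray
    ranges_mm: np.ndarray
    encoder_mm: float
    timestamp_ms: float = 0.0

    def __post_init__(self) -> None:
        a = np.asarray(self.angles_deg, dtype=float)
        r = np.asarray(self.ranges_mm, dtype=float)
        object.__setattr__(self, "angles_deg", a)
        object.__setattr__(self, "ranges_mm", r)
        if a.shape != r.shape or a.ndim != 1:
            raise ValueError("angles and ranges must be 1-D and matching")
        if a.size > 1 and not np.all(np.diff(a) > 0):
            raise ValueError("angles must be strictly increasing within a scan")
        if np.any(r < 0):
            raise ValueError("ranges must be >= 0")


@dataclass(frozen=True)
class ScanSet:
    """Encoder-ordered sequence of scans."""

    scans: tuple[Scan, ...]

    def __post_init__(self) -> None:
        scans = tuple(self.scans)
        object.__setattr__(self, "scans", scans)
        enc = [s.encoder_mm for s in scans]
        if any(b < a for a, b in zip(enc, enc[1:])):
            raise ValueError("encoder values must be non-decreasing across scans")

    def __len__(self) -> int:
        return len(self.scans)

    def __iter__(self):
        return iter(self.scans)

    @property
    def travelled_mm(self) -> float:
        if not self.scans:
            return 0.0
        return self.scans[-1].encoder_mm - self.scans[0].encoder_mm

    @classmethod
    def from_csv(cls, path) -> "ScanSet":
        df = pd.read_csv(path)
        scans = []
        for sid, grp in df.groupby("scan_id", sort=True):
            grp = grp.sort_values("angle_deg")
            scans.append(
                Scan(
                    grp["angle_deg"].to_numpy(),
                    grp["range_mm"].to_numpy(),
                    float(grp["encoder_mm"].iloc[0]),
                    float(grp["timestamp_ms"].iloc[0]),
                )
            )
        scans.sort(key=lambda s: s.encoder_mm)
        return cls(tuple(scans))

    def to_csv(self, path) -> None:
        frames = []
        for i, s in enumerate(self.scans):
            frames.append(
                pd.DataFrame(
                    {
                        "scan_id": i,
                        "timestamp_ms": s.timestamp_ms,
                        "encoder_mm": s.encoder_mm,
                        "angle_deg": s.angles_deg,
                        "range_mm": s.ranges_mm,
                    }
                )
            )
        out = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(
                columns=["scan_id", "timestamp_ms", "encoder_mm", "angle_deg", "range_mm"]
            )
        )
        out.to_csv(path, index=False)


@dataclass(frozen=True)
class Pose:
    """Sensor orientation (deg) and along-track translation (mm).

    The platform mounts the scanner laterally, which corresponds to
    roll 0, pitch −180, yaw 0 and an x translation equal to the encoder
    value at scan time.
    """

    roll_deg: float = 0.0
    pitch_deg: float = -180.0
    yaw_deg: float = 0.0
    x_translation_mm: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.roll_deg, self.pitch_deg, self.yaw_deg):
            if not -360.0 <= v <= 360.0:
                raise ValueError("pose angles must be within [-360, 360] degrees")

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous transform for row-vector points ``v @ M``."""
        phi, theta, psi = (
            math.radians(self.roll_deg),
            math.radians(self.pitch_deg),
            math.radians(self.yaw_deg),
        )
        rx = np.array(
            [
                [1, 0, 0, 0],
                [0, math.cos(phi), math.sin(phi), 0],
                [0, -math.sin(phi), math.cos(phi), 0],
                [0, 0, 0, 1],
            ]
        )
        ry = np.array(
            [
                [math.cos(theta), 0, -math.sin(theta), 0],
                [0, 1, 0, 0],
                [math.sin(theta), 0, math.cos(theta), 0],
                [0, 0, 0, 1],
            ]
        )
        rz = np.array(
            [
                [math.cos(psi), math.sin(psi), 0, 0],
                [-math.sin(psi), math.cos(psi), 0, 0],
                [0, 0, 1, 0],
                [0, 0, 0, 1],
            ]
        )
        t = np.eye(4)
        t[3, 0] = self.x_translation_mm
        return rx @ ry @ rz @ t


@dataclass(frozen=True)
class PointCloud:
    """3-D points (mm) in the platform frame, optionally tagged by scan."""

    points: np.ndarray
    scan_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "points", pts)
        if not np.isfinite(pts).all():
            raise ValueError("points must be finite")
        if self.scan_id is not None:
            sid = np.asarray(self.scan_id)
            if sid.shape[0] != pts.shape[0]:
                raise ValueError("scan_id length mismatch")
            object.__setattr__(self, "scan_id", sid)

    def __len__(self) -> int:
        return int(self.points.shape[0])

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.points[:, 2]

    def select(self, mask: np.ndarray) -> "PointCloud":
        return PointCloud(
            self.points[mask],
            None if self.scan_id is None else self.scan_id[mask],
        )

    @classmethod
    def concatenate(cls, clouds: Sequence["PointCloud"]) -> "PointCloud":
        clouds = [c for c in clouds if len(c)]
        if not clouds:
            return cls(np.empty((0, 3)))
        pts = np.vstack([c.points for c in clouds])
        if all(c.scan_id is not None for c in clouds):
            sid = np.concatenate([c.scan_id for c in clouds])
        else:
            sid = None
        return cls(pts, sid)


@dataclass(frozen=True)
class GroundPlane:
    """One fitted ground plane over an along-track interval."""

    x_lo: float
    x_hi: float
    normal: np.ndarray  # unit, z >= 0
    offset: float  # plane: normal . p = offset
    line_a: float  # ground line z = a x + b in the row's x-z projection
    line_b: float


@dataclass(frozen=True)
class GroundModel:
    """Per-interval ground planes and their x-z ground lines."""

    planes: tuple[GroundPlane, ...]

    def line_at(self, x: float) -> tuple[float, float]:
        """Ground line (a, b) for the interval containing x (nearest otherwise)."""
        if not self.planes:
            raise ValueError("ground model is empty")
        for p in self.planes:
            if p.x_lo <= x <= p.x_hi:
                return p.line_a, p.line_b
        p = min(self.planes, key=lambda p: min(abs(x - p.x_lo), abs(x - p.x_hi)))
        return p.line_a, p.line_b


@dataclass(frozen=True)
class LidarConfig:
    """All thresholds of the LiDAR chain, in mm and degrees.

    Defaults follow the field calibration: 50-mm near-range gate, 3-mm box
    grid, 80-mm plane-evaluation intervals, 40-mm MSAC inlier threshold with
    normals within 5 deg of vertical, minimum cluster size 5 and 4-mm
    histogram bins for the stem line.  ``min_distance_between_plants`` is
    fixed at a fifth of the nominal spacing.
    """

    theoretical_spacing: float
    min_range: float = 50.0
    grid_step: float = 3.0
    eval_interval: float = 80.0
    msac_threshold: float = 40.0
    reference_vector: tuple[float, float, float] = (0.0, 0.0, 1.0)
    max_angular_distance: float = 5.0
    min_cluster_size: int = 5
    histogram_jump: float = 4.0
    msac_iterations: int = 500
    kmeans_replicates: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "theoretical_spacing",
            "min_range",
            "grid_step",
            "eval_interval",
            "msac_threshold",
            "max_angular_distance",
            "histogram_jump",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.min_cluster_size < 1 or self.msac_iterations < 1:
            raise ValueError("min_cluster_size and msac_iterations must be >= 1")

    @property
    def min_distance_between_plants(self) -> float:
        return 0.2 * self.theoretical_spacing


@dataclass(frozen=True)
class PlantCluster:
    """One plant's aerial points and its three location estimates."""

    points: np.ndarray
    centroid: np.ndarray
    lowest_point: np.ndarray
    centre_x: float
    lowest_x: float
    stem_intersection_x: float
    stem_line: tuple[float, float] | None  # (slope, intercept) of z = c1 x + c0
    stem_fallback: bool  # intersection fell back to the lowest point


@dataclass
class PipelineResult:
    """Output of the full LiDAR chain."""

    estimates: dict[str, list[PlantEstimate]]
    clusters: list[PlantCluster]
    ground: GroundModel
    diagnostics: dict[str, int] = field(default_factory=dict)


def polar_to_cartesian(scan: Scan, config: LidarConfig) -> PointCloud:
    """Decode one scan into the horizontal-reference sensor frame.

    Beams live in the sensor's scan plane (x' = 0): angle 0 points along
    +y', positive angles rotate toward +z'.  Returns shorter than the
    near-range gate (sensor-window reflections, dust) are dropped.
    """
    keep = scan.ranges_mm > config.min_range
    r = scan.ranges_mm[keep]
    a = np.radians(scan.angles_deg[keep])
    pts = np.column_stack([np.zeros_like(r), r * np.cos(a), r * np.sin(a)])
    return PointCloud(pts)


def apply_pose(cloud: PointCloud, pose: Pose) -> PointCloud:
    """Rigid map into the platform frame: ``[x y z 1] @ Rx @ Ry @ Rz @ T``."""
    if len(cloud) == 0:
        return cloud
    hom = np.hstack([cloud.points, np.ones((len(cloud), 1))])
    out = hom @ pose.matrix()
    return PointCloud(out[:, :3], cloud.scan_id)


def normalize_heights(cloud: PointCloud) -> PointCloud:
    """Shift z so the lowest point sits at exactly 0."""
    if len(cloud) == 0:
        return cloud
    pts = cloud.points.copy()
    pts[:, 2] -= pts[:, 2].min()
    return PointCloud(pts, cloud.scan_id)


def delimit_seedbed(
    cloud: PointCloud,
    x_bounds: tuple[float, float] | None = None,
    y_bounds: tuple[float, float] | None = None,
) -> PointCloud:
    """Manual axis-aligned crop to the points above one seedbed."""
    mask = np.ones(len(cloud), dtype=bool)
    for bounds, axis in ((x_bounds, 0), (y_bounds, 1)):
        if bounds is None:
            continue
        lo, hi = bounds
        if lo > hi:
            raise ValueError("bounds must be ordered (lo <= hi)")
        mask &= (cloud.points[:, axis] >= lo) & (cloud.points[:, axis] <= hi)
    return cloud.select(mask)


def grid_downsample(cloud: PointCloud, config: LidarConfig) -> PointCloud:
    """Box-grid filter: points in the same cubic box merge to their centroid.

    Boxes are ``grid_step``-sized cubes anchored at the cloud's minimum
    corner.
    """
    if len(cloud) == 0:
        return cloud
    origin = cloud.points.min(axis=0)
    idx = np.floor((cloud.points - origin) / config.grid_step).astype(np.int64)
    _, inverse, counts = np.unique(
        idx, axis=0, return_inverse=True, return_counts=True
    )
    sums = np.zeros((counts.size, 3))
    np.add.at(sums, inverse, cloud.points)
    return PointCloud(sums / counts[:, None])


def _fit_plane_msac(
    pts: np.ndarray, config: LidarConfig, rng: np.random.Generator
) -> tuple[np.ndarray, float] | None:
    """MSAC plane fit constrained to near-vertical normals.

    Hypotheses come from random 3-point samples; the score is the truncated
    squared distance sum (cap at threshold^2).  Candidates whose normal is
    farther than ``max_angular_distance`` degrees from the reference vector
    are discarded before scoring.  Returns (unit normal, offset) or None if
    no admissible hypothesis was found.
    """
    n = pts.shape[0]
    iters = config.msac_iterations
    samples = rng.integers(0, n, size=(iters, 3))
    p0 = pts[samples[:, 0]]
    normals = np.cross(pts[samples[:, 1]] - p0, pts[samples[:, 2]] - p0)
    norms = np.linalg.norm(normals, axis=1)
    ok = norms > 1e-9
    normals[ok] /= norms[ok, None]
    # orient upward, then apply the angular constraint
    flip = normals[:, 2] < 0
    normals[flip] *= -1
    ref = np.asarray(config.reference_vector, dtype=float)
    ref /= np.linalg.norm(ref)
    cos_max = math.cos(math.radians(config.max_angular_distance))
    ok &= normals @ ref >= cos_max
    if not ok.any():
        return None
    normals, p0 = normals[ok], p0[ok]
    offsets = np.einsum("ij,ij->i", normals, p0)
    dist = np.abs(pts @ normals.T - offsets)  # (n_pts, n_hyp)
    tau2 = config.msac_threshold**2
    cost = np.minimum(dist**2, tau2).sum(axis=0)
    best = int(np.argmin(cost))
    normal, offset = normals[best], float(offsets[best])

    # least-squares refinement on the inliers, kept only if it still
    # satisfies the angular constraint
    inl = np.abs(pts @ normal - offset) <= config.msac_threshold
    if inl.sum() >= 3:
        centre = pts[inl].mean(axis=0)
        _, _, vt = np.linalg.svd(pts[inl] - centre, full_matrices=False)
        cand = vt[2]
        if cand[2] < 0:
            cand = -cand
        if cand @ ref >= cos_max:
            normal, offset = cand, float(cand @ centre)
    return normal, offset


def extract_aerial(
    cloud: PointCloud, config: LidarConfig, rng: np.random.Generator | None = None
) -> tuple[PointCloud, GroundModel]:
    """Remove the seedbed surface, returning aerial points + ground model.

    The cloud is cut into ``eval_interval`` slabs along x; in each slab an
    MSAC plane constrained to within ``max_angular_distance`` degrees of
    vertical is fitted and its inliers (distance <= threshold) are removed
    as ground.  Slabs with fewer than 3 points, or where no admissible
    plane exists, pass through unchanged.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    if len(cloud) == 0:
        return cloud, GroundModel(())
    x = cloud.x
    x_lo, x_hi = float(x.min()), float(x.max())
    # the last interval absorbs the trailing remainder: a sliver narrower
    # than the evaluation interval would hold points from a single scan
    # plane, for which no near-vertical ground plane exists
    n_iv = max(1, int((x_hi - x_lo) // config.eval_interval))
    aerial_masks = np.ones(len(cloud), dtype=bool)
    planes: list[GroundPlane] = []
    for i in range(n_iv):
        lo = x_lo + i * config.eval_interval
        hi = lo + config.eval_interval if i < n_iv - 1 else x_hi + 1e-9
        sel = (x >= lo) & (x < hi)
        pts = cloud.points[sel]
        if pts.shape[0] < 3:
            if pts.shape[0]:
                warnings.warn(
                    f"interval [{lo:.0f}, {hi:.0f}) mm has <3 points; passing through as aerial"
                )
            continue
        fit = _fit_plane_msac(pts, config, rng)
        if fit is None:
            warnings.warn(
                f"no admissible ground plane in interval [{lo:.0f}, {hi:.0f}) mm"
            )
            continue
        normal, offset = fit
        dist = np.abs(pts @ normal - offset)
        ground = dist <= config.msac_threshold
        idx = np.nonzero(sel)[0]
        aerial_masks[idx[ground]] = False
        y0 = float(np.median(pts[ground][:, 1])) if ground.any() else 0.0
        nz = normal[2] if abs(normal[2]) > 1e-12 else 1e-12
        planes.append(
            GroundPlane(
                x_lo=lo,
                x_hi=hi,
                normal=normal,
                offset=offset,
                line_a=-normal[0] / nz,
                line_b=(offset - normal[1] * y0) / nz,
            )
        )
    return cloud.select(aerial_masks), GroundModel(tuple(planes))


def initial_k(travelled_mm: float, theoretical_mm: float) -> int:
    """Starting cluster count: ``floor(travelled/spacing + 1) * 2``."""
    if travelled_mm <= 0 or theoretical_mm <= 0:
        raise ValueError("travelled_mm and theoretical_mm must be > 0")
    return int(math.floor(travelled_mm / theoretical_mm + 1.0) * 2)


def _kmeans(
    points: np.ndarray, k: int, config: LidarConfig, init=None
) -> tuple[np.ndarray, np.ndarray]:
    """One k-means fit; k-means++ replicates or a warm-start init."""
    km = KMeans(
        n_clusters=k,
        init="k-means++" if init is None else init,
        n_init=config.kmeans_replicates if init is None else 1,
        random_state=config.rng_seed % (2**32),
    )
    labels = km.fit_predict(points)
    return labels, km.cluster_centers_


def cluster_plants(
    aerial: PointCloud,
    config: LidarConfig,
    k0: int,
    ground: GroundModel | None = None,
) -> list[PlantCluster]:
    """Partition aerial points into plants by reduced k-means.

    Starting from ``k0`` clusters (k-means++ seeding, best of
    ``kmeans_replicates`` runs), the squared-Euclidean k-means is repeated
    with one fewer cluster for as long as any two cluster centres are
    closer along-track than ``min_distance_between_plants``.  Each
    reduction step warm-starts from the previous iteration's centroids
    with the offending pair fused into their weighted mean, so an
    over-segmented solution collapses onto the same plants rather than
    being re-seeded from scratch.  Clusters with fewer than
    ``min_cluster_size`` members are then discarded.
    """
    if len(aerial) == 0 or k0 < 1:
        warnings.warn("no aerial points or k reduced to 0; no clusters")
        return []
    pts = aerial.points
    k = min(k0, pts.shape[0])
    labels = None
    init = None
    while k >= 1:
        labels, centres = _kmeans(pts, k, config, init=init)
        uniq, counts = np.unique(labels, return_counts=True)
        centres = centres[uniq]
        order = np.argsort(centres[:, 0])
        centres, counts = centres[order], counts[order]
        gaps = np.diff(centres[:, 0])
        if gaps.size == 0 or gaps.min() >= config.min_distance_between_plants:
            break
        # fuse the closest along-track pair into its weighted mean and
        # warm-start the (k-1)-means from the surviving centroids
        i = int(np.argmin(gaps))
        w = counts[i : i + 2].astype(float)
        fused = (centres[i : i + 2] * w[:, None]).sum(axis=0) / w.sum()
        init = np.vstack([centres[:i], fused[None, :], centres[i + 2 :]])
        k = init.shape[0]
    if k < 1 or labels is None:
        warnings.warn("cluster count reduced to 0")
        return []

    clusters: list[PlantCluster] = []
    for i in np.unique(labels):
        member = pts[labels == i]
        if member.shape[0] < config.min_cluster_size:
            continue
        clusters.append(_build_cluster(member, config, ground))
    clusters.sort(key=lambda c: c.centre_x)
    return clusters


def _build_cluster(
    member: np.ndarray, config: LidarConfig, ground: GroundModel | None
) -> PlantCluster:
    centroid = member.mean(axis=0)
    low_idx = np.lexsort((member[:, 0], member[:, 2]))[0]  # min z, ties -> min x
    lowest = member[low_idx]
    inter_x, stem_line, fallback = _stem_intersection(member, config, ground)
    return PlantCluster(
        points=member,
        centroid=centroid,
        lowest_point=lowest,
        centre_x=float(centroid[0]),
        lowest_x=float(lowest[0]),
        stem_intersection_x=inter_x,
        stem_line=stem_line,
        stem_fallback=fallback,
    )


def locate_centre(cluster: PlantCluster) -> float:
    """Along-track location of the cluster centroid."""
    return cluster.centre_x


def locate_lowest(cluster: PlantCluster) -> float:
    """Along-track location of the cluster's lowest point."""
    return cluster.lowest_x


def locate_stem_intersection(
    cluster: PlantCluster,
    ground: GroundModel,
    config: LidarConfig,
) -> float:
    """Stem line / ground line intersection (recomputed from members)."""
    x, _, fb = _stem_intersection(cluster.points, config, ground)
    return x


def _stem_intersection(
    member: np.ndarray, config: LidarConfig, ground: GroundModel | None
) -> tuple[float, tuple[float, float] | None, bool]:
    """Fit the stem line and intersect it with the local ground line.

    Member x values are histogrammed with ``histogram_jump`` bins; the
    maximal-count bin (adjacent ties merged) gives the x window, and only
    points in the bottom half of the cluster's z range survive.  An ordinary
    least-squares line (z on x) through the survivors is the stem line;
    near-vertical point sets (x spread < 1 mm) use x = median(x) directly.
    Falls back to the lowest point when fewer than 2 points survive, when
    the stem line is (near) parallel to the ground line, or when the
    intersection lands implausibly far (> half the nominal spacing) from
    the cluster.
    """
    xs, zs = member[:, 0], member[:, 2]
    low_idx = np.lexsort((xs, zs))[0]
    fallback_x = float(xs[low_idx])

    nbins = max(1, int(math.ceil((xs.max() - xs.min()) / config.histogram_jump)))
    counts, edges = np.histogram(xs, bins=nbins)
    best = int(np.argmax(counts))
    lo_bin = hi_bin = best
    while lo_bin > 0 and counts[lo_bin - 1] == counts[best]:
        lo_bin -= 1
    while hi_bin < nbins - 1 and counts[hi_bin + 1] == counts[best]:
        hi_bin += 1
    x_lo, x_hi = edges[lo_bin], edges[hi_bin + 1]

    z_mid = zs.min() + 0.5 * (zs.max() - zs.min())
    keep = (xs >= x_lo) & (xs <= x_hi + 1e-12) & (zs <= z_mid)
    if keep.sum() < 2:
        warnings.warn("stem fit: <2 surviving points; falling back to lowest point")
        return fallback_x, None, True
    sx, sz = xs[keep], zs[keep]

    # near-vertical point sets: no usable leverage for an OLS line of z on
    # x.  Detected either by negligible x spread or by the absence of x-z
    # correlation (a vertical column's x scatter is measurement noise).
    if sx.max() - sx.min() < 1.0 or sz.max() - sz.min() < 1e-9:
        return float(np.median(sx)), None, False
    r = float(np.corrcoef(sx, sz)[0, 1])
    if not np.isfinite(r) or abs(r) < 0.3:
        return float(np.median(sx)), None, False

    c1, c0 = np.polyfit(sx, sz, 1)
    if ground is None or not ground.planes:
        a, b = 0.0, 0.0
    else:
        a, b = ground.line_at(float(np.median(sx)))
    if abs(c1 - a) < 1e-9:
        warnings.warn("stem line parallel to ground line; falling back to lowest point")
        return fallback_x, (float(c1), float(c0)), True
    x_star = (b - c0) / (c1 - a)
    if abs(x_star - float(np.median(sx))) > 0.5 * config.theoretical_spacing:
        warnings.warn("stem/ground intersection implausibly far; falling back to lowest point")
        return fallback_x, (float(c1), float(c0)), True
    return float(x_star), (float(c1), float(c0)), False


def run_lidar_pipeline(
    scans: ScanSet,
    config: LidarConfig,
    rng: np.random.Generator | None = None,
    pose: Pose | None = None,
    x_bounds: tuple[float, float] | None = None,
    y_bounds: tuple[float, float] | None = None,
) -> PipelineResult:
    """Full chain from raw scans to the three plant-location estimate lists."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    diagnostics: dict[str, int] = {}
    clouds = []
    for scan in scans:
        local = polar_to_cartesian(scan, config)
        p = pose if pose is not None else Pose(0.0, -180.0, 0.0, scan.encoder_mm)
        clouds.append(apply_pose(local, p))
    cloud = PointCloud.concatenate(clouds)
    diagnostics["decoded_points"] = len(cloud)
    if len(cloud) == 0:
        return PipelineResult(
            {m: [] for m in ("cluster_centre", "lowest_point", "stem_ground_intersection")},
            [],
            GroundModel(()),
            diagnostics,
        )
    cloud = normalize_heights(cloud)
    cloud = delimit_seedbed(cloud, x_bounds, y_bounds)
    diagnostics["seedbed_points"] = len(cloud)
    cloud = grid_downsample(cloud, config)
    diagnostics["gridded_points"] = len(cloud)
    aerial, ground = extract_aerial(cloud, config, rng)
    diagnostics["aerial_points"] = len(aerial)

    estimates: dict[str, list[PlantEstimate]] = {
        "cluster_centre": [],
        "lowest_point": [],
        "stem_ground_intersection": [],
    }
    clusters: list[PlantCluster] = []
    if len(aerial):
        k0 = initial_k(max(scans.travelled_mm, 1.0), config.theoretical_spacing)
        clusters = cluster_plants(aerial, config, k0, ground)
        for i, c in enumerate(clusters):
            ref = f"cluster-{i}"
            estimates["cluster_centre"].append(
                PlantEstimate(max(c.centre_x, 0.0), "cluster_centre", ref)
            )
            estimates["lowest_point"].append(
                PlantEstimate(max(c.lowest_x, 0.0), "lowest_point", ref)
            )
            estimates["stem_ground_intersection"].append(
                PlantEstimate(max(c.stem_intersection_x, 0.0), "stem_ground_intersection", ref)
            )
    for lst in estimates.values():
        lst.sort(key=lambda e: e.location)
    diagnostics["clusters"] = len(clusters)
    return PipelineResult(estimates, clusters, ground, diagnostics)
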