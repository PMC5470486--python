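"""Synthetic rows, sensor logs, scans and frames for testing the pipelines.

The generators emulate the geometry the field platforms produced: a raised
seedbed carrying a row of ~30-cm-spaced tomato plants (vertical or slightly
leaning stem plus an ellipsoidal foliage shell) or wooden calibration
sticks, scanned laterally by a 50-Hz, 0.5-degree LiDAR advancing at
~0.36 m/s, with a ground-wheel encoder (~1 mm per pulse) as the along-track
reference, an infrared beam crossing the row at stem height, and a
sideways camera firing every second.

Everything is analytic ray-tracing against simple primitives (planes,
cylinders, ellipsoid shells); no rendering engine, no radiometry.  All
generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .image_validation import FrameMeta
from .lightbeam import BeamLog
from .lidar import Scan, ScanSet
from .row_model import RowTruth

__all__ = [
    "SimConfig",
    "gen_row_truth",
    "gen_beam_log",
    "gen_lidar_scans",
    "gen_frames",
    "render_frame",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated row.

    Lengths in mm, rates in Hz, speeds in mm/s.  Defaults reproduce the
    field setting: 30-cm nominal spacing placed intentionally non-uniformly,
    19.5-cm plants with 10-mm stems, 0.36 m/s platform speed, 50-Hz scans at
    0.5 degrees, 0.98 mm per encoder pulse (1.18 on the lab conveyor).
    """

    n_plants: int = 20
    plant_kind: str = "tomato"  # "tomato" | "stick"
    nominal_spacing: float = 300.0
    spacing_jitter_std: float = 15.0
    start_mm: float = 500.0
    stem_height: float = 195.0
    stem_diameter: float = 10.0
    stem_lean_mm: float = 0.0  # x offset of the stem top w.r.t. its base
    foliage_radius: float = 60.0
    foliage_center_frac: float = 0.75  # canopy centre height / stem height
    foliage_density: float = 0.5  # probability a beam hitting the shell returns
    platform_speed: float = 360.0
    scan_rate: float = 50.0
    angular_resolution: float = 0.5
    angle_min_deg: float = 2.0
    angle_max_deg: float = 80.0
    pulse_relation: float = 0.98
    point_noise_std: float = 5.0
    beam_height: float = 40.0  # light-beam height above the bed
    missing_plant_prob: float = 0.0
    weed_prob: float = 0.0
    weed_width: float = 1.5
    # platform / bed geometry
    sensor_height: float = 400.0  # sensor above the bed top at x = 0
    row_offset: float = 600.0  # lateral distance sensor -> row axis
    bed_halfwidth: float = 350.0
    bed_tilt: float = 0.0  # dz of the bed top per mm of x
    shoulder_width: float = 100.0
    shoulder_drop: float = 150.0
    # camera model
    mm_per_px: float = 0.5
    frame_width_px: int = 1920
    frame_interval_s: float = 1.0
    frame_noise_px: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.plant_kind not in ("tomato", "stick"):
            raise ValueError("plant_kind must be 'tomato' or 'stick'")
        for name in (
            "nominal_spacing",
            "stem_height",
            "stem_diameter",
            "platform_speed",
            "scan_rate",
            "angular_resolution",
            "pulse_relation",
            "mm_per_px",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("missing_plant_prob", "weed_prob", "foliage_density"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @classmethod
    def lab_beam(cls, **overrides) -> "SimConfig":
        """Laboratory conveyor: 11 artificial plants, 100-mm spacing."""
        base = dict(
            n_plants=11,
            nominal_spacing=100.0,
            spacing_jitter_std=2.0,
            stem_height=130.0,
            pulse_relation=1.18,
            platform_speed=375.0,  # 1.35 km/h conveyor
            point_noise_std=0.0,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def stick_row(cls, **overrides) -> "SimConfig":
        """Field calibration row: 19 wooden sticks at 240-mm spacing."""
        base = dict(
            n_plants=19,
            plant_kind="stick",
            nominal_spacing=240.0,
            spacing_jitter_std=10.0,
            stem_height=300.0,
            point_noise_std=5.0,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def tomato_row(cls, **overrides) -> "SimConfig":
        """Field tomato row: 290-mm nominal spacing, jittered by 30 mm."""
        base = dict(
            n_plants=20,
            nominal_spacing=290.0,
            spacing_jitter_std=30.0,
            point_noise_std=5.0,
        )
        base.update(overrides)
        return cls(**base)

    def bed_top_z(self, x) -> np.ndarray:
        """Bed-top height (platform frame, sensor at z = 0)."""
        return -self.sensor_height + self.bed_tilt * np.asarray(x, dtype=float)

    def row_end_mm(self, truth: RowTruth) -> float:
        last = truth.positions[-1] if len(truth) else self.start_mm
        return float(last + max(self.start_mm, 100.0))


def gen_row_truth(config: SimConfig, rng: np.random.Generator | None = None) -> RowTruth:
    """Draw ground-truth stem positions: cumulative jittered spacings."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    if config.n_plants < 1:
        return RowTruth(np.empty(0))
    steps = config.nominal_spacing + rng.normal(
        0.0, config.spacing_jitter_std, size=config.n_plants
    )
    steps = np.maximum(steps, 1.0)
    positions = config.start_mm + np.cumsum(steps)
    keep = rng.random(config.n_plants) >= config.missing_plant_prob
    positions = positions[keep]
    labels = tuple(str(i + 1) for i in range(positions.size))
    return RowTruth(positions, labels)


def _stem_axis_x(config: SimConfig, base_x: np.ndarray, z_above_bed) -> np.ndarray:
    """x of the (possibly leaning) stem axis at a given height above the bed."""
    frac = np.clip(np.asarray(z_above_bed, dtype=float) / config.stem_height, 0.0, 1.0)
    return np.asarray(base_x, dtype=float) + config.stem_lean_mm * frac


def gen_beam_log(
    truth: RowTruth, config: SimConfig, rng: np.random.Generator | None = None
) -> BeamLog:
    """Simulate the light-beam state at every encoder pulse.

    The beam crosses the row at ``beam_height`` above the bed; it reads 1
    whenever it intersects a stem cylinder at that height, plus optional
    short spurious blips (weeds/leaves) narrower than the detection filter.

    The receiver latches: the blocked state is asserted from the encoder
    count active when the leading edge cuts the beam until the count after
    the trailing edge clears it, so a blocked run overhangs the true
    obstacle by up to one pulse on each side.  A stem of diameter ``d``
    therefore yields an interval of length in ``(d, d + 2 * pulse_relation)``
    — the same one-pulse-per-edge overestimate seen in bench calibrations.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 1)
    end = config.row_end_mm(truth)
    n_pulses = int(math.ceil(end / config.pulse_relation)) + 1
    pulses = np.arange(n_pulses)
    dist = pulses * config.pulse_relation
    state = np.zeros(n_pulses, dtype=np.int8)
    latch = config.pulse_relation  # one-pulse edge latching (see docstring)
    radius = config.stem_diameter / 2.0
    for x0 in truth.positions:
        axis = _stem_axis_x(config, x0, config.beam_height)
        state[np.abs(dist - axis) < radius + latch] = 1
    # spurious blips between plants
    for left, right in zip(truth.positions[:-1], truth.positions[1:]):
        if rng.random() < config.weed_prob:
            centre = rng.uniform(left + 30.0, right - 30.0)
            state[np.abs(dist - centre) < config.weed_width / 2.0 + latch] = 1
    dt_ms = 1000.0 * config.pulse_relation / config.platform_speed
    return BeamLog(pulses, state, timestamp_ms=pulses * dt_ms)


def _ray_bed(config: SimConfig, enc: float, sin_a: np.ndarray, cos_a: np.ndarray) -> np.ndarray:
    """Range to the seedbed (top, shoulders, or base ground); inf if missed.

    Rays run from the sensor origin along (0, cos a, -sin a) in the platform
    frame; the bed is a raised trapezoidal prism, uniform along x apart from
    an optional linear tilt of its top.
    """
    zb = float(config.bed_top_z(enc))
    y_in_lo = config.row_offset - config.bed_halfwidth
    y_in_hi = config.row_offset + config.bed_halfwidth
    t = np.full_like(sin_a, np.inf)

    with np.errstate(divide="ignore", invalid="ignore"):
        # flat top
        t_top = -zb / sin_a
        y_top = t_top * cos_a
        ok = (sin_a > 0) & (y_top >= y_in_lo) & (y_top <= y_in_hi)
        t = np.where(ok & (t_top < t), t_top, t)
        # shoulders: z(y) = zb - drop * (inner_y - y) / width (near side)
        for inner, sign in ((y_in_lo, 1.0), (y_in_hi, -1.0)):
            outer = inner - sign * config.shoulder_width
            slope = sign * config.shoulder_drop / config.shoulder_width
            # surface z = zb - drop + slope*(y - outer)  [near side, sign=+1]
            denom = -sin_a - slope * cos_a
            t_sh = (zb - config.shoulder_drop + slope * (0.0 - outer)) / denom
            y_sh = t_sh * cos_a
            lo, hi = min(inner, outer), max(inner, outer)
            ok = (t_sh > 0) & (y_sh >= lo) & (y_sh <= hi)
            t = np.where(ok & (t_sh < t), t_sh, t)
        # base ground beyond the shoulders
        z_base = zb - config.shoulder_drop
        t_base = -z_base / sin_a
        y_base = t_base * cos_a
        out_lo = y_in_lo - config.shoulder_width
        out_hi = y_in_hi + config.shoulder_width
        ok = (sin_a > 0) & ((y_base < out_lo) | (y_base > out_hi)) & (t_base > 0)
        t = np.where(ok & (t_base < t), t_base, t)
    return t


def _ray_stem(
    config: SimConfig, enc: float, x0: float, sin_a: np.ndarray, cos_a: np.ndarray
) -> np.ndarray:
    """Range to one stem cylinder; inf where missed."""
    zb = float(config.bed_top_z(enc))
    h = config.stem_height
    radius = config.stem_diameter / 2.0
    lean = config.stem_lean_mm
    if abs(lean) < 1e-9:
        z_lo, z_hi = 0.0, h
        dx = enc - x0
    else:
        # height window where |enc - axis(z)| <= radius
        lo = (enc - x0 - radius) * h / lean
        hi = (enc - x0 + radius) * h / lean
        z_lo, z_hi = max(0.0, min(lo, hi)), min(h, max(lo, hi))
        if z_hi <= z_lo:
            return np.full_like(sin_a, np.inf)
        dx = enc - float(_stem_axis_x(config, x0, 0.5 * (z_lo + z_hi)))
    if abs(dx) > radius:
        return np.full_like(sin_a, np.inf)
    w = math.sqrt(radius**2 - dx**2)
    with np.errstate(divide="ignore"):
        t = (config.row_offset - w) / cos_a
    z = -t * sin_a - zb  # height above bed at the hit
    ok = (cos_a > 0) & (z >= z_lo) & (z <= z_hi)
    return np.where(ok, t, np.inf)


def _ray_foliage(
    config: SimConfig,
    enc: float,
    x0: float,
    sin_a: np.ndarray,
    cos_a: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Range to a plant's ellipsoidal foliage shell (porous); inf if missed."""
    zb = float(config.bed_top_z(enc))
    a = b = c = config.foliage_radius
    zc = zb + config.foliage_center_frac * config.stem_height
    xc = x0 + config.stem_lean_mm * config.foliage_center_frac
    yc = config.row_offset
    u0 = (enc - xc) / a
    if abs(u0) >= 1.0:
        return np.full_like(sin_a, np.inf)
    qa = (cos_a / b) ** 2 + (sin_a / c) ** 2
    qb = -2.0 * (cos_a * yc / b**2 + sin_a * (-zc) / c**2)
    qc = (yc / b) ** 2 + (zc / c) ** 2 + u0**2 - 1.0
    disc = qb**2 - 4.0 * qa * qc
    with np.errstate(invalid="ignore"):
        t = (-qb - np.sqrt(disc)) / (2.0 * qa)
    hit = (disc > 0) & (t > 0)
    hit &= rng.random(sin_a.shape) < config.foliage_density
    return np.where(hit, t, np.inf)


def gen_lidar_scans(
    truth: RowTruth, config: SimConfig, rng: np.random.Generator | None = None
) -> ScanSet:
    """Ray-trace the side-view LiDAR over the whole row.

    The sensor advances at ``platform_speed`` emitting ``scan_rate`` scans
    per second; each beam returns the range of its nearest intersection
    with the seedbed prism, a stem cylinder or a foliage shell, plus
    Gaussian range noise.  Beams with no intersection report range 0 (no
    return), which the pipeline's near-range gate removes.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 2)
    end = config.row_end_mm(truth)
    step = config.platform_speed / config.scan_rate
    n_scans = int(math.ceil(end / step)) + 1
    angles = np.arange(
        config.angle_min_deg, config.angle_max_deg + 1e-9, config.angular_resolution
    )
    rad = np.radians(angles)
    sin_a, cos_a = np.sin(rad), np.cos(rad)
    radius = config.stem_diameter / 2.0
    reach = max(radius, abs(config.stem_lean_mm) + radius, config.foliage_radius)

    scans = []
    for j in range(n_scans):
        enc = j * step
        t = _ray_bed(config, enc, sin_a, cos_a)
        near = truth.positions[np.abs(truth.positions - enc) <= reach + 1.0]
        for x0 in near:
            t = np.minimum(t, _ray_stem(config, enc, x0, sin_a, cos_a))
            if config.plant_kind == "tomato":
                t = np.minimum(t, _ray_foliage(config, enc, x0, sin_a, cos_a, rng))
        ranges = np.where(np.isfinite(t), t, 0.0)
        if config.point_noise_std > 0:
            noise = rng.normal(0.0, config.point_noise_std, size=ranges.shape)
            ranges = np.where(ranges > 0, np.maximum(ranges + noise, 0.0), 0.0)
        scans.append(
            Scan(
                angles_deg=angles,
                ranges_mm=ranges,
                encoder_mm=enc,
                timestamp_ms=1000.0 * j / config.scan_rate,
            )
        )
    return ScanSet(tuple(scans))


def gen_frames(
    truth: RowTruth, config: SimConfig, rng: np.random.Generator | None = None
) -> list[FrameMeta]:
    """Pinhole side-view camera: one metadata row per visible stem per frame.

    Frames fire every ``frame_interval_s`` of travel; the encoder value maps
    to the image centre column and each stem within the field of view
    contributes its exact signed pixel offset (plus optional pixel noise).
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 3)
    end = config.row_end_mm(truth)
    step = config.platform_speed * config.frame_interval_s
    n_frames = int(math.ceil(end / step)) + 1
    half_width_mm = config.frame_width_px / 2.0 * config.mm_per_px
    frames = []
    for j in range(n_frames):
        enc = j * step
        emitted = False
        for x0 in truth.positions:
            offset_mm = x0 - enc
            if abs(offset_mm) > half_width_mm * 0.98:
                continue
            offset_px = offset_mm / config.mm_per_px
            if config.frame_noise_px > 0:
                offset_px += rng.normal(0.0, config.frame_noise_px)
            frames.append(
                FrameMeta(
                    frame_id=j,
                    timestamp_ms=1000.0 * j * config.frame_interval_s,
                    encoder_mm=enc,
                    stem_offset_px=float(
                        np.clip(offset_px, -config.frame_width_px / 2, config.frame_width_px / 2)
                    ),
                    frame_width_px=config.frame_width_px,
                )
            )
            emitted = True
        if not emitted:
            frames.append(
                FrameMeta(
                    frame_id=j,
                    timestamp_ms=1000.0 * j * config.frame_interval_s,
                    encoder_mm=enc,
                    stem_offset_px=None,
                    frame_width_px=config.frame_width_px,
                )
            )
    return frames


def render_frame(
    truth: RowTruth,
    config: SimConfig,
    encoder_mm: float,
    *,
    shape: tuple[int, int] = (240, 320),
) -> np.ndarray:
    """Render a small green-on-brown RGB frame centred at ``encoder_mm``.

    Purely geometric: brown soil, a green stem rectangle and (for tomatoes)
    a green foliage disc per visible plant.  Scaled so the rendered width
    spans the camera's field of view.
    """
    h, w = shape
    mmpp = config.frame_width_px * config.mm_per_px / w  # mm per rendered pixel
    img = np.zeros((h, w, 3), dtype=np.uint8)
    img[..., 0], img[..., 1], img[..., 2] = 120, 85, 50  # soil
    ground_row = int(h * 0.85)
    cols = (np.arange(w) - w / 2) * mmpp + encoder_mm
    rows_mm = (ground_row - np.arange(h)) * mmpp  # height above bed per row
    for x0 in truth.positions:
        if abs(x0 - encoder_mm) > w / 2 * mmpp + config.foliage_radius:
            continue
        # stem
        stem_cols = np.abs(cols - x0) <= max(config.stem_diameter / 2, mmpp)
        stem_rows = (rows_mm >= 0) & (rows_mm <= config.stem_height)
        img[np.ix_(stem_rows, stem_cols)] = (40, 160, 40)
        if config.plant_kind == "tomato":
            zc = config.foliage_center_frac * config.stem_height
            xc = x0 + config.stem_lean_mm * config.foliage_center_frac
            dy = (rows_mm[:, None] - zc) ** 2
            dx = (cols[None, :] - xc) ** 2
            disc = dx + dy <= config.foliage_radius**2
            img[disc] = (50, 180, 50)
    return img
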