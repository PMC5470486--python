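"""Light-beam + wheel-encoder stem detection.

A single infrared emitter/receiver pair is mounted across the crop row a few
centimetres above the soil.  Whenever the beam is blocked the receiver emits
a logic 1, which the data logger samples together with the cumulative pulse
count of a ground-wheel encoder.  Multiplying pulse counts by the encoder
calibration constant (mm per pulse) turns the binary stream into a function
of along-track distance; maximal blocked runs become detection intervals,
very short runs (leaves, weeds, clods) are filtered out, and nearby
detections are merged into plant records whose location is the detection
midpoint.

Detection intervals double as stem-diameter estimates: the along-track
length of the blocked run is the chord the stem cuts out of the beam, so a
10-mm stem yields a ~10-mm interval plus one quantisation step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BeamConfig",
    "BeamLog",
    "DetectionInterval",
    "PlantRecord",
    "pulses_to_mm",
    "extract_intervals",
    "filter_short",
    "merge_to_plants",
    "estimate_diameter",
    "detect_plants",
]


@dataclass(frozen=True)
class BeamConfig:
    """Parameters of the beam-detection algorithm.

    Parameters
    ----------
    pulse_distance_relation
        Encoder calibration, mm of travel per pulse (1.18 on the lab
        conveyor, 0.98 for the field ground wheel).
    theoretical_plant_distance
        Nominal in-row plant spacing, mm (100 lab, 380 field).
    detection_filter
        Minimum along-track length (mm) a blocked run must cover to count
        as a detection; shorter blips are discarded.  Default 4 mm.
    spacing_tolerance
        Fractional tolerance on the nominal spacing.  A candidate closer
        than ``theoretical * (1 - tolerance)`` to the previous potential
        plant is treated as another interruption of the same plant and
        merged; the derived ``expected_plant_distance`` is
        ``theoretical * (1 + tolerance)`` and flags suspiciously long gaps.
    """

    pulse_distance_relation: float
    theoretical_plant_distance: float
    detection_filter: float = 4.0
    spacing_tolerance: float = 0.2

    def __post_init__(self) -> None:
        for name in ("pulse_distance_relation", "theoretical_plant_distance", "detection_filter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.spacing_tolerance < 1:
            raise ValueError("spacing_tolerance must be in (0, 1)")

    @property
    def expected_plant_distance(self) -> float:
        """Nominal spacing plus the tolerance (upper gate), mm."""
        return self.theoretical_plant_distance * (1.0 + self.spacing_tolerance)

    @property
    def new_plant_distance(self) -> float:
        """Minimum distance at which a candidate is a new plant, mm."""
        return self.theoretical_plant_distance * (1.0 - self.spacing_tolerance)


@dataclass(frozen=True)
class BeamLog:
    """Time-ordered samples of (cumulative encoder pulses, beam state)."""

    pulse_count: np.ndarray
    state: np.ndarray
    timestamp_ms: np.ndarray | None = None

    def __post_init__(self) -> None:
        pulses = np.asarray(self.pulse_count, dtype=float)
        state = np.asarray(self.state, dtype=np.int8)
        object.__setattr__(self, "pulse_count", pulses)
        object.__setattr__(self, "state", state)
        if pulses.shape != state.shape or pulses.ndim != 1:
            raise ValueError("pulse_count and state must be 1-D and same length")
        if np.any(np.diff(pulses) < 0):
            raise ValueError("pulse_count must be non-decreasing (reverse travel unsupported)")
        if not np.isin(state, (0, 1)).all():
            raise ValueError("state must be 0/1")
        if self.timestamp_ms is not None:
            ts = np.asarray(self.timestamp_ms, dtype=float)
            if ts.shape != pulses.shape:
                raise ValueError("timestamp_ms length mismatch")
            object.__setattr__(self, "timestamp_ms", ts)

    def __len__(self) -> int:
        return int(self.pulse_count.size)

    @classmethod
    def from_csv(cls, path) -> "BeamLog":
        df = pd.read_csv(path)
        return cls(
            df["pulse_count"].to_numpy(),
            df["beam_state"].to_numpy(),
            df["timestamp_ms"].to_numpy() if "timestamp_ms" in df else None,
        )

    def to_csv(self, path) -> None:
        ts = self.timestamp_ms
        if ts is None:
            ts = np.zeros(len(self))
        pd.DataFrame(
            {
                "timestamp_ms": ts,
                "pulse_count": self.pulse_count,
                "beam_state": self.state.astype(int),
            }
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class DetectionInterval:
    """One maximal blocked run, in along-track mm."""

    start_mm: float
    end_mm: float
    midpoint_mm: float

    def __post_init__(self) -> None:
        if self.end_mm < self.start_mm:
            raise ValueError("end_mm must be >= start_mm")
        if not self.start_mm <= self.midpoint_mm <= self.end_mm:
            raise ValueError("midpoint must lie inside the interval")

    @property
    def length_mm(self) -> float:
        return self.end_mm - self.start_mm


@dataclass
class PlantRecord:
    """A detected plant: contributing intervals and chosen location."""

    index: int
    intervals: list[DetectionInterval]
    location_mm: float
    distance_from_previous_mm: float = field(default=float("nan"))

    @property
    def n_intervals(self) -> int:
        return len(self.intervals)


def pulses_to_mm(pulse_count, config: BeamConfig):
    """Convert cumulative encoder pulses to along-track distance in mm."""
    pulses = np.asarray(pulse_count, dtype=float)
    if np.any(pulses < 0):
        raise ValueError("pulse_count must be >= 0")
    out = pulses * config.pulse_distance_relation
    return float(out) if np.isscalar(pulse_count) else out


def extract_intervals(log: BeamLog, config: BeamConfig) -> list[DetectionInterval]:
    """Turn maximal runs of blocked-beam samples into detection intervals.

    The interval midpoint is the mean of all sample distances inside the
    run (not ``(start + end) / 2``); the two differ when the stream is not
    sampled uniformly in distance.
    """
    if len(log) == 0:
        return []
    dist = pulses_to_mm(log.pulse_count, config)
    state = log.state
    # run boundaries of state==1
    padded = np.concatenate(([0], state, [0]))
    edges = np.diff(padded)
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0]  # exclusive
    return [
        DetectionInterval(
            start_mm=float(dist[i]),
            end_mm=float(dist[j - 1]),
            midpoint_mm=float(dist[i:j].mean()),
        )
        for i, j in zip(starts, ends)
    ]


def filter_short(
    intervals: Sequence[DetectionInterval], config: BeamConfig
) -> list[DetectionInterval]:
    """Drop detections shorter than ``detection_filter`` mm along track."""
    return [iv for iv in intervals if iv.length_mm >= config.detection_filter]


def merge_to_plants(
    intervals: Sequence[DetectionInterval], config: BeamConfig
) -> list[PlantRecord]:
    """Group surviving detections into plant records.

    The first detection seeds plant 1.  Each subsequent candidate is
    compared against the previous potential plant's location: farther than
    ``new_plant_distance`` starts a new plant; closer candidates are merged
    into it, and the merged plant's location is re-chosen as the contributing
    interval midpoint closest to the theoretical midpoint (previous plant's
    location plus the nominal spacing; for plant 1, its seeding midpoint
    plus the nominal spacing).
    """
    ivs = sorted(intervals, key=lambda iv: iv.start_mm)
    plants: list[PlantRecord] = []
    seed_mid = float("nan")  # first interval midpoint of the current plant
    for iv in ivs:
        if not plants:
            plants.append(PlantRecord(1, [iv], iv.midpoint_mm))
            seed_mid = iv.midpoint_mm
            continue
        cur = plants[-1]
        if iv.midpoint_mm - cur.location_mm > config.new_plant_distance:
            plants.append(PlantRecord(cur.index + 1, [iv], iv.midpoint_mm))
            seed_mid = iv.midpoint_mm
        else:
            cur.intervals.append(iv)
            anchor = plants[-2].location_mm if len(plants) >= 2 else seed_mid
            target = anchor + config.theoretical_plant_distance
            cur.location_mm = min(
                (i.midpoint_mm for i in cur.intervals),
                key=lambda m: abs(m - target),
            )
    for prev, cur in zip(plants, plants[1:]):
        cur.distance_from_previous_mm = cur.location_mm - prev.location_mm
    return plants


def estimate_diameter(interval: DetectionInterval) -> float:
    """Stem diameter estimate: the along-track length of the blocked run."""
    return interval.length_mm


def detect_plants(log: BeamLog, config: BeamConfig) -> list[PlantRecord]:
    """Full chain: intervals -> short-run filter -> plant merging."""
    return merge_to_plants(filter_short(extract_intervals(log, config), config), config)


def plants_to_frame(plants: Sequence[PlantRecord]) -> pd.DataFrame:
    """Plant records as the standard output table."""
    return pd.DataFrame(
        {
            "plant_id": [p.index for p in plants],
            "location_mm": [p.location_mm for p in plants],
            "distance_from_previous_mm": [p.distance_from_previous_mm for p in plants],
            "n_intervals": [p.n_intervals for p in plants],
        }
    )
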