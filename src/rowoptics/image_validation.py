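"""Image + odometry stem localization used to validate the LiDAR estimates.

A sideways-looking RGB camera fires at fixed 1-s intervals while the
encoder value at each exposure is logged; the encoder value corresponds to
the image centre.  Segmenting the plant in each frame gives a signed pixel
offset of the stem from the centre column, and registering consecutive
frames against the encoder distance between them yields a motion relation
in mm per pixel, so each frame produces

    stem location = encoder value + offset_px * mm_per_pixel

with positive offsets on the side of larger along-track distance.  A plant
seen in several frames contributes the mean of its per-frame locations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure, morphology
from skimage.registration import phase_cross_correlation

from .row_model import PlantEstimate

__all__ = [
    "FrameMeta",
    "StemObservation",
    "MotionRelation",
    "RegistrationError",
    "segment_plant",
    "motion_relation",
    "estimate_shift",
    "stem_location",
    "locate_plants_from_frames",
]


@dataclass(frozen=True)
class FrameMeta:
    """Metadata of one frame: capture odometry and stem observation."""

    frame_id: int
    timestamp_ms: float
    encoder_mm: float
    stem_offset_px: float | None = None
    frame_width_px: int = 1920

    def __post_init__(self) -> None:
        if self.stem_offset_px is not None and abs(self.stem_offset_px) > self.frame_width_px / 2:
            raise ValueError("stem offset outside the frame")


@dataclass(frozen=True)
class StemObservation:
    """Signed pixel offset of a stem from the image centre column.

    Positive offsets lie toward larger along-track distance (``left of
    centre'' on the reference rig; mirrored rigs must negate).
    """

    offset_px: float
    frame_id: int = 0


@dataclass(frozen=True)
class MotionRelation:
    """Forward-speed scale for a frame pair, mm of travel per pixel."""

    mm_per_pixel: float

    def __post_init__(self) -> None:
        if self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be > 0 for forward motion")


class RegistrationError(RuntimeError):
    """Raised when two frames cannot be registered (no overlap/structure)."""


def segment_plant(
    image: np.ndarray,
    *,
    green_margin: float = 10.0,
    erosion_radius: int = 2,
) -> tuple[np.ndarray, float]:
    """Segment the plant by green dominance and locate its stem column.

    A pixel is plant when its green channel exceeds both red and blue by
    ``green_margin``.  Erosion followed by morphological reconstruction
    removes specks smaller than the erosion structuring element while
    restoring the shape of what survives.  Returns the binary mask and the
    stem column: the median x of the bottom 20% of rows of the largest
    connected component.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError("expected an RGB image (H, W, 3)")
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    mask = (g >= r + green_margin) & (g >= b + green_margin)
    if erosion_radius > 0:
        seed = morphology.erosion(mask, morphology.disk(erosion_radius))
        mask = morphology.reconstruction(seed, mask, method="dilation").astype(bool)
    if not mask.any():
        raise ValueError("no plant pixels found")
    labels = measure.label(mask)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    comp = labels == largest
    rows = np.nonzero(comp.any(axis=1))[0]
    bottom = rows[int(np.ceil(0.8 * rows.size)):]
    if bottom.size == 0:
        bottom = rows[-1:]
    cols = np.nonzero(comp[bottom].any(axis=0))[0]
    return mask, float(np.median(cols))


def motion_relation(pixel_shift: float, encoder_delta: float) -> MotionRelation:
    """mm-per-pixel scale from an inter-frame pixel shift + encoder delta."""
    if pixel_shift == 0:
        raise ValueError("zero pixel shift: no apparent motion between frames")
    return MotionRelation(abs(encoder_delta) / abs(pixel_shift))


def estimate_shift(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    *,
    min_correlation: float = 0.2,
) -> float:
    """Signed horizontal displacement (px) of frame_b relative to frame_a.

    Default implementation is whole-image translational registration by
    phase correlation; any keypoint-based estimator with the same contract
    (a signed pixel shift) can be substituted.  Raises
    :class:`RegistrationError` when the aligned overlap correlates poorly
    (structureless or non-overlapping frames).
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.ndim == 3:
        a = a.mean(axis=2)
    if b.ndim == 3:
        b = b.mean(axis=2)
    # phase_cross_correlation reports the shift registering b onto a; the
    # displacement of b's content is its negation (verified on constructed
    # pairs)
    shift, _, _ = phase_cross_correlation(a, b)
    shift_px = -float(shift[1])
    dx = int(round(shift_px))
    # verify: correlation of the aligned overlap
    if dx >= 0:
        ov_a, ov_b = a[:, : a.shape[1] - dx], b[:, dx:]
    else:
        ov_a, ov_b = a[:, -dx:], b[:, : b.shape[1] + dx]
    if min(ov_a.size, ov_b.size) == 0:
        raise RegistrationError("no overlap at estimated shift")
    va, vb = ov_a.std(), ov_b.std()
    if va == 0 or vb == 0:
        if np.allclose(ov_a, ov_b):
            return shift_px
        raise RegistrationError("structureless frames")
    corr = float(np.corrcoef(ov_a.ravel(), ov_b.ravel())[0, 1])
    if corr < min_correlation:
        raise RegistrationError(f"registration unreliable (corr={corr:.2f})")
    return shift_px


def stem_location(
    encoder_mm: float, observation: StemObservation, relation: MotionRelation
) -> float:
    """Per-frame stem location: encoder value ± pixel offset × mm/px."""
    return encoder_mm + observation.offset_px * relation.mm_per_pixel


def locate_plants_from_frames(
    frames: list[FrameMeta],
    relation: MotionRelation,
    theoretical_spacing: float,
) -> tuple[list[PlantEstimate], list[float]]:
    """Average per-frame stem locations into one estimate per plant.

    Per-frame locations are computed for every frame carrying a stem
    observation, sorted, and split into plants wherever the gap exceeds
    half the nominal spacing (the same radius that defines a false
    positive).  Returns the per-plant mean locations and the per-plant
    sample standard deviations.
    """
    locs = sorted(
        stem_location(f.encoder_mm, StemObservation(f.stem_offset_px, f.frame_id), relation)
        for f in frames
        if f.stem_offset_px is not None
    )
    if not locs:
        return [], []
    groups: list[list[float]] = [[locs[0]]]
    for loc in locs[1:]:
        if loc - groups[-1][-1] > theoretical_spacing / 2.0:
            groups.append([loc])
        else:
            groups[-1].append(loc)
    estimates, stds = [], []
    for i, grp in enumerate(groups):
        arr = np.asarray(grp)
        estimates.append(
            PlantEstimate(max(float(arr.mean()), 0.0), "image", f"frames-{i}")
        )
        stds.append(float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0)
    return estimates, stds


def relation_from_metadata(frames: list[FrameMeta]) -> MotionRelation:
    """Estimate the mm-per-pixel scale from stem tracks in the metadata.

    A stem fixed in the field drifts across consecutive frames by
    ``encoder_delta / mm_per_pixel`` pixels, identically for every plant, so
    the scale is recovered as the median of ``encoder_delta / pixel_drift``
    over all positive-drift observation pairs in consecutive frames.
    """
    by_frame: dict[int, list[FrameMeta]] = {}
    for f in frames:
        if f.stem_offset_px is not None:
            by_frame.setdefault(f.frame_id, []).append(f)
    ids = sorted(by_frame)
    candidates = []
    for a, b in zip(ids, ids[1:]):
        delta_enc = by_frame[b][0].encoder_mm - by_frame[a][0].encoder_mm
        if delta_enc <= 0:
            continue
        for fa in by_frame[a]:
            for fb in by_frame[b]:
                drift = fa.stem_offset_px - fb.stem_offset_px
                if drift > 0:
                    candidates.append(delta_enc / drift)
    if not candidates:
        raise ValueError("cannot estimate motion relation: no stem drift between frames")
    return MotionRelation(float(np.median(candidates)))


def frames_from_csv(path) -> list[FrameMeta]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        off = row.get("stem_offset_px")
        out.append(
            FrameMeta(
                int(row["frame_id"]),
                float(row["timestamp_ms"]),
                float(row["encoder_mm"]),
                None if pd.isna(off) else float(off),
            )
        )
    return out


def frames_to_csv(frames: list[FrameMeta], path) -> None:
    pd.DataFrame(
        {
            "frame_id": [f.frame_id for f in frames],
            "timestamp_ms": [f.timestamp_ms for f in frames],
            "encoder_mm": [f.encoder_mm for f in frames],
            "stem_offset_px": [f.stem_offset_px for f in frames],
        }
    ).to_csv(path, index=False)
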