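"""Shared domain types, ground truth and detection-quality metrics.

Every localization method in this package ultimately produces a list of
along-track plant positions in millimetres.  This module holds the ground
truth container, the matching rule that decides which estimates count as
correct detections (an estimate is a false positive when it lies more than
half the nominal plant spacing from every true plant centre), and the
summary statistics reported for field trials: a detection-accuracy
percentage and the mean/standard deviation of signed location errors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "RowTruth",
    "PlantEstimate",
    "MatchReport",
    "ErrorSummary",
    "METHODS",
    "detection_accuracy",
    "detection_error",
    "match_detections",
    "spacing_series",
    "summarize_error",
]

#: Recognised provenance tags for a plant-location estimate.
METHODS = frozenset(
    {"beam", "cluster_centre", "lowest_point", "stem_ground_intersection", "image"}
)


@dataclass(frozen=True)
class RowTruth:
    """Ground-truth along-track stem locations of one crop row.

    Parameters
    ----------
    positions
        Along-track stem locations in mm, strictly increasing, all >= 0.
    labels
        Optional per-plant identifiers (same length as ``positions``).
    """

    positions: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if pos.ndim != 1:
            raise ValueError("positions must be a 1-D sequence")
        if pos.size and pos[0] < 0:
            raise ValueError("positions must be non-negative")
        if pos.size > 1 and not np.all(np.diff(pos) > 0):
            raise ValueError("positions must be strictly increasing")
        if self.labels is not None:
            labels = tuple(str(x) for x in self.labels)
            if len(labels) != pos.size:
                raise ValueError("labels length must match positions")
            object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return int(self.positions.size)

    @classmethod
    def from_csv(cls, path) -> "RowTruth":
        df = pd.read_csv(path)
        df = df.sort_values("position_mm")
        return cls(df["position_mm"].to_numpy(float), tuple(df["id"].astype(str)))

    def to_csv(self, path) -> None:
        labels = self.labels or tuple(str(i + 1) for i in range(len(self)))
        pd.DataFrame({"id": labels, "position_mm": self.positions}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class PlantEstimate:
    """One estimated plant location with its method of origin."""

    location: float
    method: str
    source_ref: str = ""

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {sorted(METHODS)}")
        if self.location < 0:
            raise ValueError("location must be >= 0")


@dataclass(frozen=True)
class MatchReport:
    """Outcome of matching estimates to true plant positions."""

    n_correct: int
    n_false_positive: int
    n_false_negative: int
    #: (truth index, estimate index, absolute error mm) per matched pair
    pairs: tuple[tuple[int, int, float], ...] = field(default_factory=tuple)

    @property
    def percent_detected(self) -> float:
        """Share of real plants with a matched detection, in percent."""
        n_real = self.n_correct + self.n_false_negative
        if n_real == 0:
            raise ValueError("no real plants in report")
        return 100.0 * self.n_correct / n_real

    def to_dict(self) -> dict:
        return {
            "n_correct": self.n_correct,
            "n_false_positive": self.n_false_positive,
            "n_false_negative": self.n_false_negative,
            "pairs": [list(p) for p in self.pairs],
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


@dataclass(frozen=True)
class ErrorSummary:
    """Mean and standard deviation (mm) of signed location errors."""

    mean_mm: float
    std_mm: float
    n: int

    def to_dict(self) -> dict:
        return {"mean_mm": self.mean_mm, "std_mm": self.std_mm, "n": self.n}

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def detection_accuracy(n_real: int, n_detected: int, *, rounded: bool = False) -> float:
    """Detection-accuracy percentage from plant counts.

    Defined as ``100 * min(n_real, n_detected) / max(n_real, n_detected)`` so
    that both over-counting (false positives) and under-counting (missed
    plants) reduce the score symmetrically.  ``rounded=True`` returns the
    nearest integer, the convention used in trial reports.
    """
    if n_real <= 0:
        raise ValueError("n_real must be > 0")
    if n_detected < 0:
        raise ValueError("n_detected must be >= 0")
    if n_detected == 0:
        value = 0.0
    else:
        value = 100.0 * min(n_real, n_detected) / max(n_real, n_detected)
    return float(round(value)) if rounded else value


def detection_error(n_real: int, n_detected: int, *, rounded: bool = True) -> float:
    """Complementary error percentage, ``100 - accuracy``."""
    err = 100.0 - detection_accuracy(n_real, n_detected)
    return float(round(err)) if rounded else err


def match_detections(
    estimates: Sequence[PlantEstimate] | Sequence[float],
    truth: RowTruth,
    spacing: float,
) -> MatchReport:
    """Match estimates to true plants under the half-spacing rule.

    An estimate may be paired with a truth position only when their absolute
    distance is at most ``spacing / 2``.  Among all one-to-one pairings the
    matching maximises the number of matched pairs and, among those, minimises
    the total absolute error (solved as a rectangular assignment problem).
    Unmatched estimates are false positives; unmatched truths false negatives.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    est = np.asarray(
        [e.location if isinstance(e, PlantEstimate) else float(e) for e in estimates],
        dtype=float,
    )
    tru = truth.positions
    n_t, n_e = tru.size, est.size
    if n_t == 0 or n_e == 0:
        return MatchReport(0, n_e, n_t, ())

    radius = spacing / 2.0
    err = np.abs(tru[:, None] - est[None, :])
    feasible = err <= radius
    # One infeasible assignment must cost more than every feasible matching
    # combined, so the solver maximises feasible cardinality first.
    big = (radius + 1.0) * (n_t + n_e + 1.0)
    cost = np.where(feasible, err, big)
    rows, cols = linear_sum_assignment(cost)
    pairs = tuple(
        (int(i), int(j), float(err[i, j]))
        for i, j in zip(rows, cols)
        if feasible[i, j]
    )
    n_correct = len(pairs)
    return MatchReport(n_correct, n_e - n_correct, n_t - n_correct, pairs)


def spacing_series(positions: Sequence[float]) -> np.ndarray:
    """Consecutive along-track differences of a sorted position list."""
    pos = np.asarray(positions, dtype=float)
    if pos.size < 2:
        return np.empty(0)
    return np.diff(pos)


def summarize_error(
    estimates: Sequence[PlantEstimate] | Sequence[float],
    truth: RowTruth,
    spacing: float,
) -> ErrorSummary:
    """Signed-error summary (estimate − truth, mm) over matched pairs.

    Positive errors mean the estimate lies beyond the true plant in the
    travel direction.  The standard deviation uses the sample (n − 1)
    convention; a single matched pair reports std 0.
    """
    report = match_detections(estimates, truth, spacing)
    if report.n_correct == 0:
        raise ValueError("no matched pairs; cannot summarise errors")
    est = np.asarray(
        [e.location if isinstance(e, PlantEstimate) else float(e) for e in estimates],
        dtype=float,
    )
    errors = np.array([est[j] - truth.positions[i] for i, j, _ in report.pairs])
    std = float(np.std(errors, ddof=1)) if errors.size > 1 else 0.0
    return ErrorSummary(float(np.mean(errors)), std, int(errors.size))
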