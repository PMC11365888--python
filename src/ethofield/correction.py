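"""Kinematic post-hoc revision of movement labels.

Labels from pose-based classification occasionally disagree with the
animal's actual kinematics; a slow, long "sniffing" episode is
behaviorally a pause.  Each :class:`CorrectionRule` relabels bouts of a
source movement whose mean horizontal back speed is *strictly below*
``max_speed_mm_s`` and whose duration is *strictly above*
``min_duration_s``.  The shipped default is the single published rule:
sniffing slower than 15 mm/s lasting more than 3 s becomes pausing.
Boundary cases (exactly 15 mm/s, exactly 3 s) are not corrected.

Speeds are computed on the back trajectory after a centered moving-average
smoothing (default window 0.33 s) to suppress keypoint jitter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .ontology import (
    MOVEMENTS,
    Bout,
    Ethogram,
    Trajectory,
    bouts_of,
)

__all__ = [
    "CorrectionRule",
    "DEFAULT_RULES",
    "smooth_positions",
    "bout_speed",
    "apply_corrections",
]

DEFAULT_SMOOTH_WINDOW_S = 0.33


@dataclass(frozen=True)
class CorrectionRule:
    """Relabel ``source`` bouts slower than ``max_speed`` and longer than ``min_duration``."""

    source: str
    max_speed_mm_s: float
    min_duration_s: float
    target: str

    def __post_init__(self) -> None:
        for name in (self.source, self.target):
            if name not in MOVEMENTS:
                raise ValueError(f"unknown movement in rule: {name!r}")
        if self.source == self.target:
            raise ValueError("rule source and target must differ")
        if self.max_speed_mm_s <= 0 or self.min_duration_s <= 0:
            raise ValueError("rule thresholds must be > 0")


#: The published rule: slow, long sniffing is revised to pausing.
DEFAULT_RULES: tuple[CorrectionRule, ...] = (
    CorrectionRule("sniffing", 15.0, 3.0, "pausing"),
)


def smooth_positions(
    points: np.ndarray, window_s: float, frame_rate: float
) -> np.ndarray:
    """Centered moving average of (n, 2) positions; window 0 disables."""
    if window_s <= 0:
        return np.asarray(points, dtype=float)
    w = int(round(window_s * frame_rate))
    if w % 2 == 0:
        w += 1
    if w <= 1:
        return np.asarray(points, dtype=float)
    return uniform_filter1d(
        np.asarray(points, dtype=float), size=w, axis=0, mode="nearest"
    )


def _step_lengths(points: np.ndarray) -> np.ndarray:
    return np.linalg.norm(np.diff(points, axis=0), axis=1)


def bout_speed(
    trajectory: Trajectory,
    bout: Bout,
    smooth_window_s: float = DEFAULT_SMOOTH_WINDOW_S,
) -> float:
    """Mean horizontal back speed (mm/s) over a bout, from smoothed positions.

    A single-frame bout has no step and returns 0.
    """
    if bout.end_frame > trajectory.n_frames:
        raise ValueError("bout extends past the trajectory")
    smoothed = smooth_positions(
        trajectory.points, smooth_window_s, trajectory.frame_rate
    )
    return _mean_speed(smoothed, bout.start_frame, bout.end_frame, trajectory.frame_rate)


def _mean_speed(smoothed: np.ndarray, start: int, end: int, frame_rate: float) -> float:
    if end - start < 2:
        return 0.0
    steps = _step_lengths(smoothed[start:end])
    return float(steps.mean() * frame_rate)


def apply_corrections(
    ethogram: Ethogram,
    trajectory: Trajectory,
    rules: tuple[CorrectionRule, ...] | list[CorrectionRule] = DEFAULT_RULES,
    smooth_window_s: float = DEFAULT_SMOOTH_WINDOW_S,
    n_passes: int = 1,
) -> Ethogram:
    """Apply kinematic veto rules to an ethogram; returns a new Ethogram.

    Within one pass, bouts are derived once from the input labels and each
    bout is relabeled by the first matching rule; bouts are re-merged after
    the pass.  A frame relabeled by an earlier rule can therefore match a
    later rule only in a subsequent pass (``n_passes > 1``).
    """
    if ethogram.n_frames != trajectory.n_frames:
        raise ValueError("ethogram and trajectory must be frame-aligned")
    for rule in rules:
        if rule.source not in MOVEMENTS:
            raise ValueError(f"unknown rule source {rule.source!r}")

    labels = ethogram.labels.copy()
    if not rules or n_passes <= 0:
        return Ethogram(ethogram.animal_id, ethogram.frame_rate, labels)

    smoothed = smooth_positions(
        trajectory.points, smooth_window_s, trajectory.frame_rate
    )
    fr = ethogram.frame_rate
    for _ in range(int(n_passes)):
        current = Ethogram(ethogram.animal_id, fr, labels)
        changed = False
        for bout in bouts_of(current):
            for rule in rules:
                if bout.movement != rule.source:
                    continue
                if bout.duration_s <= rule.min_duration_s:
                    continue
                speed = _mean_speed(smoothed, bout.start_frame, bout.end_frame, fr)
                if speed < rule.max_speed_mm_s:
                    labels[bout.start_frame : bout.end_frame] = rule.target
                    changed = True
                    break  # first fully qualifying rule decides
        if not changed:
            break
    return Ethogram(ethogram.animal_id, ethogram.frame_rate, labels)
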