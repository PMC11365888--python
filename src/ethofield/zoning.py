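"""Arena calibration and the center/perimeter division of the open field.

The arena floor is a 400 x 400 mm square; raw camera coordinates are
calibrated by mapping its four corners onto (+/-200, +/-200) mm with a
projective (homography) transform, center origin.

Two divisions of the floor into a center square and a perimeter band are
supported:

* **traditional** — the center square spans half the arena length
  (half-width ``a`` = 100 mm);
* **data-driven** — the boundary is read off the *occupancy growth curve*:
  residence counts of the back point inside a centered square frame that
  expands incrementally to the walls.  Thigmotactic occupancy concentrates
  in a band near the walls, producing a peak in the per-area occupancy
  density as a function of the frame half-width ``a``.  The boundary is the
  smallest ``a``, scanning outward from the center along the peak's rising
  flank, at which density reaches within 10% of the peak's topographic
  prominence (the start of the 90%-prominence region).  The standardized
  boundary used when per-group curves are not recomputed is ``a`` = 135 mm.

``a`` is the HALF-width of the center square throughout (the square spans
``[-a, a]^2``); the boundary point itself belongs to the center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, peak_prominences

from .metrics import time_budget
from .ontology import (
    ARENA_HALF_MM,
    ClusterMap,
    Ethogram,
    Trajectory,
)

__all__ = [
    "GrowthCurve",
    "ZoneDivision",
    "traditional_division",
    "standard_data_driven_division",
    "calibrate",
    "growth_curve",
    "find_boundary",
    "assign_zones",
    "zone_metrics",
    "ZoneMetrics",
]

#: Calibrated corner targets, in (x, y): BL, TL, TR, BR.
CORNER_TARGETS = np.array(
    [
        [-ARENA_HALF_MM, -ARENA_HALF_MM],
        [-ARENA_HALF_MM, ARENA_HALF_MM],
        [ARENA_HALF_MM, ARENA_HALF_MM],
        [ARENA_HALF_MM, -ARENA_HALF_MM],
    ]
)


@dataclass
class GrowthCurve:
    """Occupancy growth curve of expanding centered square frames.

    ``counts[k]`` is the number of frames whose back point lies inside
    ``[-a_grid[k], a_grid[k]]^2``; ``density[k]`` is the increment of counts
    normalized by the annular frame area (frames per mm^2).
    """

    a_grid: np.ndarray
    counts: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        self.a_grid = np.asarray(self.a_grid, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if not (self.a_grid.size == self.counts.size == self.density.size):
            raise ValueError("a_grid, counts and density must be equally long")
        if np.any(np.diff(self.a_grid) <= 0):
            raise ValueError("a_grid must be strictly increasing")
        if np.any(np.diff(self.counts) < 0):
            raise ValueError("counts must be non-decreasing")


@dataclass
class ZoneDivision:
    """A center/perimeter split of the arena by a center-square half-width."""

    method: str  # "data_driven" | "traditional"
    a_boundary_mm: float

    def __post_init__(self) -> None:
        if not 0 < self.a_boundary_mm < ARENA_HALF_MM:
            raise ValueError("a_boundary_mm must lie in (0, 200)")

    @property
    def center_area_mm2(self) -> float:
        return (2.0 * self.a_boundary_mm) ** 2

    @property
    def perimeter_area_mm2(self) -> float:
        return (2.0 * ARENA_HALF_MM) ** 2 - self.center_area_mm2

    def area(self, zone: str) -> float:
        return self.center_area_mm2 if zone == "center" else self.perimeter_area_mm2


def traditional_division() -> ZoneDivision:
    """Center = half the arena length: a = 100 mm on the 400 mm floor."""
    return ZoneDivision("traditional", 100.0)


def standard_data_driven_division(a_boundary_mm: float = 135.0) -> ZoneDivision:
    """The standardized data-driven boundary (a = 135 mm by default)."""
    return ZoneDivision("data_driven", a_boundary_mm)


def calibrate(
    points_raw: np.ndarray,
    corner_points: np.ndarray,
    animal_id: str = "calibrated",
    frame_rate: float = 30.0,
) -> Trajectory:
    """Map raw coordinates into the center-origin arena frame.

    *corner_points* are the four observed corners in the order
    bottom-left, top-left, top-right, bottom-right; a projective transform
    sends them exactly onto (+/-200, +/-200).
    """
    src = np.asarray(corner_points, dtype=float)
    if src.shape != (4, 2):
        raise ValueError("corner_points must be four (x, y) pairs")
    if len({tuple(p) for p in src.tolist()}) != 4:
        raise ValueError("corner points must be distinct")
    H = _homography(src, CORNER_TARGETS)
    pts = np.asarray(points_raw, dtype=float)
    ones = np.ones((pts.shape[0], 1))
    hom = np.hstack([pts, ones]) @ H.T
    w = hom[:, 2]
    if np.any(np.abs(w) < 1e-12):
        raise ValueError("degenerate projective transform")
    mapped = hom[:, :2] / w[:, None]
    # round-off guard: calibrated corners may overshoot by float noise
    mapped = np.clip(mapped, -ARENA_HALF_MM, ARENA_HALF_MM)
    return Trajectory(animal_id=animal_id, frame_rate=frame_rate, points=mapped)


def _homography(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Direct linear transform from 4 point correspondences."""
    A = []
    for (x, y), (u, v) in zip(src, dst):
        A.append([x, y, 1, 0, 0, 0, -u * x, -u * y, -u])
        A.append([0, 0, 0, x, y, 1, -v * x, -v * y, -v])
    A = np.asarray(A, dtype=float)
    _, s, vh = np.linalg.svd(A)
    if s[-2] < 1e-9 * s[0]:
        raise ValueError("degenerate corner configuration")
    h = vh[-1]
    H = h.reshape(3, 3)
    return H / H[2, 2]


def growth_curve(trajectory: Trajectory, step_mm: float = 1.0) -> GrowthCurve:
    """Occupancy growth curve on the grid ``{step, 2*step, ..., 200}``."""
    if step_mm <= 0:
        raise ValueError("step_mm must be > 0")
    a_grid = np.arange(step_mm, ARENA_HALF_MM + step_mm / 2, step_mm)
    if a_grid[-1] < ARENA_HALF_MM:
        a_grid = np.append(a_grid, ARENA_HALF_MM)
    cheb = np.maximum(np.abs(trajectory.x), np.abs(trajectory.y))
    cheb_sorted = np.sort(cheb)
    counts = np.searchsorted(cheb_sorted, a_grid, side="right").astype(float)
    areas = (2.0 * a_grid) ** 2
    density = np.diff(counts, prepend=0.0) / np.diff(areas, prepend=0.0)
    return GrowthCurve(a_grid=a_grid, counts=counts, density=density)


def find_boundary(curve: GrowthCurve, prominence_fraction: float = 0.10) -> float:
    """Boundary half-width from the occupancy density peak.

    Locates the most prominent peak of the density curve (curve endpoints
    are treated as valleys, so a high plateau reaching the wall counts as a
    peak) and returns the smallest grid half-width, scanning outward from
    the center along the peak's rising flank, at which density is within
    ``prominence_fraction`` of the peak's prominence below the peak height.

    Raises ``ValueError`` when the density has no occupancy peak away from
    the center (flat density, or mass monotonically concentrated at the
    center), in which case callers may fall back to the traditional
    division.
    """
    if not 0 < prominence_fraction <= 1:
        raise ValueError("prominence_fraction must lie in (0, 1]")
    d = curve.density
    if d.size < 3 or np.ptp(d) < 1e-15:
        raise ValueError("no occupancy peak; cannot divide arena")
    pad_val = d.min() - max(1e-12, 1e-9 * np.ptp(d))
    padded = np.concatenate(([pad_val], d, [pad_val]))
    peaks, _ = find_peaks(padded)
    if peaks.size == 0:
        raise ValueError("no occupancy peak; cannot divide arena")
    prominences, left_bases, _ = peak_prominences(padded, peaks)
    best = int(np.argmax(prominences))
    peak_idx = int(peaks[best])
    if peak_idx <= 1:
        # peak at the innermost grid point: occupancy concentrated at the
        # center, no thigmotaxis peak with a rising flank
        raise ValueError("no occupancy peak; cannot divide arena")
    level = padded[peak_idx] - prominence_fraction * prominences[best]
    lo = max(1, int(left_bases[best]))
    for i in range(lo, peak_idx + 1):
        if padded[i] >= level - 1e-12:
            return float(curve.a_grid[i - 1])
    return float(curve.a_grid[peak_idx - 1])


def assign_zones(trajectory: Trajectory, division: ZoneDivision) -> np.ndarray:
    """Per-frame zone labels; the boundary itself belongs to the center."""
    cheb = np.maximum(np.abs(trajectory.x), np.abs(trajectory.y))
    return np.where(cheb <= division.a_boundary_mm, "center", "perimeter")


@dataclass
class ZoneMetrics:
    """Per-zone occupancy and movement budgets for one animal."""

    division: ZoneDivision
    fractions: pd.Series  # time fraction per zone
    per_unit_area: pd.Series  # fraction / zone area (1/mm^2)
    movement_budgets: dict[str, pd.Series]  # zone -> renormalized fractions
    empty_zones: tuple[str, ...]


def zone_metrics(
    ethogram: Ethogram,
    trajectory: Trajectory,
    division: ZoneDivision,
    cluster_map: ClusterMap | None = None,
) -> ZoneMetrics:
    """Zone time fractions, per-unit-area fractions and per-zone budgets.

    The movement budget of a zone is the time budget restricted to frames
    spent in that zone, renormalized within the zone.  A zone the animal
    never visits yields an empty budget and is flagged, not an error.
    """
    if ethogram.n_frames != trajectory.n_frames:
        raise ValueError("ethogram and trajectory must be frame-aligned")
    zones = assign_zones(trajectory, division)
    n = ethogram.n_frames
    fractions = pd.Series(
        {z: float((zones == z).sum()) / n for z in ("center", "perimeter")}
    )
    per_unit_area = pd.Series(
        {z: fractions[z] / division.area(z) for z in ("center", "perimeter")}
    )
    budgets: dict[str, pd.Series] = {}
    empty: list[str] = []
    for z in ("center", "perimeter"):
        mask = zones == z
        if not mask.any():
            budgets[z] = pd.Series(dtype=float)
            empty.append(z)
            continue
        sub = Ethogram(ethogram.animal_id, ethogram.frame_rate, ethogram.labels[mask])
        budgets[z] = time_budget(sub, cluster_map).fractions
    return ZoneMetrics(
        division=division,
        fractions=fractions,
        per_unit_area=per_unit_area,
        movement_budgets=budgets,
        empty_zones=tuple(empty),
    )
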