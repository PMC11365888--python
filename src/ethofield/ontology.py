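"""Domain types for open-field spontaneous-behavior analysis.

The behavioral record of one animal is an *ethogram*: one movement label per
video frame, drawn from a closed vocabulary of 13 spontaneous movements.
Movements are grouped into 5 functional clusters:

==============  ======================================================
cluster         movements
==============  ======================================================
locomotion      running, trotting, walking, stepping,
                right_turning, left_turning
exploration     rearing, sniffing, rising, climbing
forced_posture  hunching
maintenance     grooming
nap             pausing
==============  ======================================================

Alongside the ethogram runs a *trajectory*: the animal's back keypoint in a
center-origin arena frame (mm), one (x, y) pair per frame.  The arena is a
400 x 400 mm square floor, so calibrated coordinates satisfy |x|, |y| <= 200.

Conventions used throughout the package:

* frames are 0-based; bout intervals are half-open ``[start, end)``;
* times are seconds, coordinates millimetres, center origin;
* labels are stored lower_snake_case; readers normalize case/whitespace.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "MOVEMENTS",
    "CLUSTERS",
    "GENOTYPES",
    "SEXES",
    "ARENA_HALF_MM",
    "ClusterMap",
    "DEFAULT_CLUSTER_MAP",
    "Ethogram",
    "Bout",
    "Trajectory",
    "Subject",
    "Cohort",
    "normalize_label",
    "bouts_of",
    "labels_from_bouts",
]

#: The 13 admissible movement labels (closed vocabulary).
MOVEMENTS: tuple[str, ...] = (
    "running",
    "trotting",
    "walking",
    "right_turning",
    "left_turning",
    "stepping",
    "rearing",
    "sniffing",
    "rising",
    "climbing",
    "hunching",
    "grooming",
    "pausing",
)

#: The 5 functional clusters.
CLUSTERS: tuple[str, ...] = (
    "locomotion",
    "exploration",
    "forced_posture",
    "maintenance",
    "nap",
)

GENOTYPES: tuple[str, ...] = ("WT", "HE", "KO")
SEXES: tuple[str, ...] = ("M", "F")

#: Half-width of the (calibrated) square arena floor, mm.
ARENA_HALF_MM: float = 200.0

MOVEMENT_INDEX: dict[str, int] = {m: i for i, m in enumerate(MOVEMENTS)}
CLUSTER_INDEX: dict[str, int] = {c: i for i, c in enumerate(CLUSTERS)}

_NORM_RE = re.compile(r"[\s\-]+")


def normalize_label(raw: str) -> str:
    """Normalize a movement/cluster label: strip, lower-case, snake_case."""
    return _NORM_RE.sub("_", str(raw).strip().lower())


@dataclass(frozen=True)
class ClusterMap:
    """A total mapping from the 13 movements onto the 5 clusters."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = set(MOVEMENTS) - set(self.mapping)
        extra = set(self.mapping) - set(MOVEMENTS)
        if missing or extra:
            raise ValueError(
                f"cluster map must cover exactly the 13 movements; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        bad = {m: c for m, c in self.mapping.items() if c not in CLUSTERS}
        if bad:
            raise ValueError(f"unknown cluster(s) in map: {bad}")

    def __getitem__(self, movement: str) -> str:
        return self.mapping[movement]

    def members(self, cluster: str) -> tuple[str, ...]:
        """Movements mapped to *cluster*, in canonical order."""
        return tuple(m for m in MOVEMENTS if self.mapping[m] == cluster)

    def apply(self, labels: np.ndarray) -> np.ndarray:
        """Map an array of movement labels to cluster labels, elementwise."""
        lut = np.array([self.mapping[m] for m in MOVEMENTS])
        idx = _labels_to_indices(labels)
        return lut[idx]

    def as_dict(self) -> dict[str, str]:
        return {m: self.mapping[m] for m in MOVEMENTS}


DEFAULT_CLUSTER_MAP = ClusterMap(
    {
        "running": "locomotion",
        "trotting": "locomotion",
        "walking": "locomotion",
        "stepping": "locomotion",
        "right_turning": "locomotion",
        "left_turning": "locomotion",
        "rearing": "exploration",
        "sniffing": "exploration",
        "rising": "exploration",
        "climbing": "exploration",
        "hunching": "forced_posture",
        "grooming": "maintenance",
        "pausing": "nap",
    }
)


def _labels_to_indices(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    sorter = np.argsort(MOVEMENTS)
    keys = np.array(MOVEMENTS)[sorter]
    pos = np.searchsorted(keys, labels)
    pos = np.clip(pos, 0, len(keys) - 1)
    bad = keys[pos] != labels
    if bad.any():
        unknown = sorted(set(np.asarray(labels)[bad].tolist()))
        raise ValueError(f"unknown movement label(s): {unknown}")
    return sorter[pos]


@dataclass
class Ethogram:
    """Per-frame movement labels for one session of one animal."""

    animal_id: str
    frame_rate: float
    labels: np.ndarray

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        self.labels = np.asarray(self.labels, dtype="U13")
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 1-D sequence")
        _labels_to_indices(self.labels)  # raises on unknown labels

    @property
    def n_frames(self) -> int:
        return int(self.labels.size)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    def label_indices(self) -> np.ndarray:
        """Labels as integer indices into :data:`MOVEMENTS`."""
        return _labels_to_indices(self.labels)


@dataclass(frozen=True)
class Bout:
    """A maximal run of identical movement labels, half-open ``[start, end)``."""

    movement: str
    start_frame: int
    end_frame: int
    duration_s: float

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise ValueError("end_frame must exceed start_frame")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


def bouts_of(ethogram: Ethogram) -> list[Bout]:
    """Run-length encode an ethogram into bouts that tile it exactly."""
    labels = ethogram.labels
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    fr = ethogram.frame_rate
    return [
        Bout(str(labels[s]), int(s), int(e), (e - s) / fr)
        for s, e in zip(starts, ends)
    ]


def labels_from_bouts(bouts: Sequence[Bout]) -> np.ndarray:
    """Expand bouts back into a per-frame label array (inverse of bouts_of)."""
    return np.repeat(
        [b.movement for b in bouts], [b.n_frames for b in bouts]
    ).astype("U13")


@dataclass
class Trajectory:
    """Back-keypoint (x, y) positions in mm, center-origin arena frame."""

    animal_id: str
    frame_rate: float
    points: np.ndarray

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must have shape (n_frames, 2)")
        if self.points.shape[0] == 0:
            raise ValueError("trajectory must contain at least one point")
        bad = np.flatnonzero(~np.isfinite(self.points).all(axis=1))
        if bad.size:
            raise ValueError(f"non-finite coordinate at frame {int(bad[0])}")
        out = np.flatnonzero(
            (np.abs(self.points) > ARENA_HALF_MM).any(axis=1)
        )
        if out.size:
            raise ValueError(
                f"coordinate outside the +/-{ARENA_HALF_MM:g} mm arena at "
                f"frame {int(out[0])}; calibrate first"
            )

    @property
    def n_frames(self) -> int:
        return int(self.points.shape[0])

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]


@dataclass(frozen=True)
class Subject:
    """One animal: id, Shank3b genotype (WT/HE/KO) and sex (M/F)."""

    animal_id: str
    genotype: str
    sex: str

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")


@dataclass
class Cohort:
    """A set of subjects with exactly one ethogram and trajectory each."""

    subjects: list[Subject]
    ethograms: dict[str, Ethogram] = field(default_factory=dict)
    trajectories: dict[str, Trajectory] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.animal_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("animal_id values must be unique within a cohort")
        for aid in ids:
            if aid not in self.ethograms:
                raise ValueError(f"subject {aid} has no ethogram")
            if aid not in self.trajectories:
                raise ValueError(f"subject {aid} has no trajectory")
            e, t = self.ethograms[aid], self.trajectories[aid]
            if e.n_frames != t.n_frames:
                raise ValueError(
                    f"subject {aid}: ethogram ({e.n_frames}) and trajectory "
                    f"({t.n_frames}) frame counts differ"
                )

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self) -> Iterator[Subject]:
        return iter(self.subjects)

    def select(self, genotype: str | None = None, sex: str | None = None) -> list[Subject]:
        """Subjects matching the given genotype and/or sex."""
        return [
            s
            for s in self.subjects
            if (genotype is None or s.genotype == genotype)
            and (sex is None or s.sex == sex)
        ]
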