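"""Readers and writers for the pipeline's plain-text file formats.

All files are UTF-8 comma-delimited CSV with ``#``-prefixed comment lines.
The frame rate is carried as a metadata comment ``# frame_rate=30`` on
ethogram and trajectory files; an explicit ``frame_rate`` argument overrides
it.  Formats:

* ethogram:   ``frame,label``       (optional extra ``time_s`` column)
* trajectory: ``frame,x_mm,y_mm``
* subjects:   ``animal_id,genotype,sex``
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ontology import (
    ARENA_HALF_MM,
    DEFAULT_CLUSTER_MAP,
    ClusterMap,
    Cohort,
    Ethogram,
    Subject,
    Trajectory,
    normalize_label,
)

__all__ = [
    "read_ethogram",
    "write_ethogram",
    "read_trajectory",
    "write_trajectory",
    "read_subjects",
    "write_subjects",
    "read_cohort",
    "write_cohort",
    "cluster_map_to_yaml",
    "cluster_map_from_yaml",
]

DEFAULT_FRAME_RATE = 30.0


def _parse_metadata(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    return meta


def _resolve_frame_rate(path: Path, frame_rate: float | None) -> float:
    if frame_rate is not None:
        if frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        return float(frame_rate)
    meta = _parse_metadata(path)
    if "frame_rate" in meta:
        return float(meta["frame_rate"])
    return DEFAULT_FRAME_RATE


def _check_contiguous(frames: np.ndarray, path: Path) -> None:
    frames = frames.astype(int)
    expected = np.arange(frames[0], frames[0] + frames.size)
    if not np.array_equal(frames, expected):
        bad = int(np.flatnonzero(frames != expected)[0])
        raise ValueError(
            f"{path}: frame indices are not contiguous (first gap at row {bad})"
        )


def read_ethogram(path: str | Path, frame_rate: float | None = None) -> Ethogram:
    """Read a ``frame,label`` CSV into a validated :class:`Ethogram`.

    Labels are case/whitespace-normalized; an unknown label raises a
    ``ValueError`` naming the offending row.  Frames must be contiguous and
    are re-indexed from 0.
    """
    path = Path(path)
    fr = _resolve_frame_rate(path, frame_rate)
    df = pd.read_csv(path, comment="#")
    if "frame" not in df.columns or "label" not in df.columns:
        raise ValueError(f"{path}: expected columns 'frame,label'")
    if len(df) == 0:
        raise ValueError(f"{path}: empty ethogram")
    _check_contiguous(df["frame"].to_numpy(), path)
    labels = np.array([normalize_label(s) for s in df["label"]], dtype="U13")
    from .ontology import MOVEMENTS

    known = set(MOVEMENTS)
    for row, lab in enumerate(labels):
        if lab not in known:
            raise ValueError(
                f"{path}: unknown movement '{df['label'].iloc[row]}' at row {row}"
            )
    return Ethogram(animal_id=path.stem, frame_rate=fr, labels=labels)


def write_ethogram(ethogram: Ethogram, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    buf.write(f"# frame_rate={ethogram.frame_rate:g}\n")
    pd.DataFrame(
        {"frame": np.arange(ethogram.n_frames), "label": ethogram.labels}
    ).to_csv(buf, index=False)
    path.write_text(buf.getvalue(), encoding="utf-8")


def read_trajectory(path: str | Path, frame_rate: float | None = None) -> Trajectory:
    """Read a ``frame,x_mm,y_mm`` CSV into a validated :class:`Trajectory`."""
    path = Path(path)
    fr = _resolve_frame_rate(path, frame_rate)
    df = pd.read_csv(path, comment="#")
    for col in ("frame", "x_mm", "y_mm"):
        if col not in df.columns:
            raise ValueError(f"{path}: expected columns 'frame,x_mm,y_mm'")
    if len(df) == 0:
        raise ValueError(f"{path}: empty trajectory")
    _check_contiguous(df["frame"].to_numpy(), path)
    pts = df[["x_mm", "y_mm"]].to_numpy(dtype=float)
    nan_rows = np.flatnonzero(~np.isfinite(pts).all(axis=1))
    if nan_rows.size:
        raise ValueError(f"{path}: NaN coordinate at frame {int(nan_rows[0])}")
    out = np.flatnonzero((np.abs(pts) > ARENA_HALF_MM).any(axis=1))
    if out.size:
        raise ValueError(
            f"{path}: coordinate outside the calibrated +/-{ARENA_HALF_MM:g} mm "
            f"arena at frame {int(out[0])}"
        )
    return Trajectory(animal_id=path.stem, frame_rate=fr, points=pts)


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    buf.write(f"# frame_rate={trajectory.frame_rate:g}\n")
    pd.DataFrame(
        {
            "frame": np.arange(trajectory.n_frames),
            "x_mm": trajectory.x,
            "y_mm": trajectory.y,
        }
    ).to_csv(buf, index=False, float_format="%.4f")
    path.write_text(buf.getvalue(), encoding="utf-8")


def read_subjects(path: str | Path) -> list[Subject]:
    df = pd.read_csv(path, comment="#")
    return [
        Subject(str(r.animal_id), str(r.genotype).upper(), str(r.sex).upper())
        for r in df.itertuples()
    ]


def write_subjects(subjects: list[Subject], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "animal_id": [s.animal_id for s in subjects],
            "genotype": [s.genotype for s in subjects],
            "sex": [s.sex for s in subjects],
        }
    ).to_csv(path, index=False)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write a cohort as ``subjects.csv`` plus per-animal CSV pairs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_subjects(cohort.subjects, out_dir / "subjects.csv")
    for s in cohort.subjects:
        write_ethogram(cohort.ethograms[s.animal_id], out_dir / f"{s.animal_id}_ethogram.csv")
        write_trajectory(
            cohort.trajectories[s.animal_id], out_dir / f"{s.animal_id}_trajectory.csv"
        )


def read_cohort(in_dir: str | Path, frame_rate: float | None = None) -> Cohort:
    """Read a cohort written by :func:`write_cohort`."""
    in_dir = Path(in_dir)
    subjects = read_subjects(in_dir / "subjects.csv")
    ethograms, trajectories = {}, {}
    for s in subjects:
        e = read_ethogram(in_dir / f"{s.animal_id}_ethogram.csv", frame_rate)
        t = read_trajectory(in_dir / f"{s.animal_id}_trajectory.csv", frame_rate)
        e.animal_id = s.animal_id
        t.animal_id = s.animal_id
        ethograms[s.animal_id] = e
        trajectories[s.animal_id] = t
    return Cohort(subjects=subjects, ethograms=ethograms, trajectories=trajectories)


def cluster_map_to_yaml(path: str | Path, cluster_map: ClusterMap = DEFAULT_CLUSTER_MAP) -> None:
    """Serialize a movement-to-cluster map as YAML (documentation format)."""
    Path(path).write_text(
        yaml.safe_dump(cluster_map.as_dict(), sort_keys=True), encoding="utf-8"
    )


def cluster_map_from_yaml(path: str | Path) -> ClusterMap:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return ClusterMap({normalize_label(k): normalize_label(v) for k, v in raw.items()})
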