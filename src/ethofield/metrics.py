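"""Time budgets, bout frequencies, temporal dynamics and travel distance.

For a session the *time fraction* of label ``i`` is ``T_i = M_i / M_total``,
the number of frames carrying label ``i`` over the total frame count; the
*frequency* is the number of bouts of ``i`` per minute of session.  Both are
computed at movement level (13 labels) or, via a cluster map, at cluster
level (5 labels, frames mapped first and bouts re-derived after the merge).

Temporal profiles recompute both quantities within consecutive time bins
(60 s bins for per-minute dynamics, 600 s bins for the six 10-min segments
of a standard hour-long session).  A bout that straddles a bin boundary
contributes its frames to every bin it touches but its *count* only to the
bin containing its start frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correction import smooth_positions
from .ontology import (
    CLUSTERS,
    MOVEMENTS,
    ClusterMap,
    Cohort,
    Ethogram,
    Trajectory,
)

__all__ = [
    "TimeBudget",
    "TemporalProfile",
    "time_budget",
    "temporal_profile",
    "group_profile",
    "total_distance",
    "distance_per_bin",
    "cohort_metrics",
]


@dataclass
class TimeBudget:
    """Whole-session fractions and bout frequencies (bouts/min) per label."""

    unit: str  # "movement" | "cluster"
    fractions: pd.Series
    frequencies: pd.Series
    bout_counts: pd.Series
    duration_s: float


@dataclass
class TemporalProfile:
    """Per-bin fractions and frequencies; rows are bins, columns labels."""

    unit: str
    bin_s: float
    fractions: pd.DataFrame
    frequencies: pd.DataFrame


def _vocab(cluster_map: ClusterMap | None) -> tuple[str, ...]:
    return CLUSTERS if cluster_map is not None else MOVEMENTS


def _session_labels(ethogram: Ethogram, cluster_map: ClusterMap | None) -> np.ndarray:
    if cluster_map is None:
        return ethogram.labels
    return cluster_map.apply(ethogram.labels)


def _run_starts(labels: np.ndarray) -> np.ndarray:
    """Start indices of maximal runs of identical labels."""
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    return np.concatenate(([0], change))


def _count_frames(labels: np.ndarray, vocab: tuple[str, ...]) -> pd.Series:
    counts = pd.Series(0, index=list(vocab), dtype=float)
    uniq, n = np.unique(labels, return_counts=True)
    counts[uniq] = n
    return counts


def time_budget(ethogram: Ethogram, cluster_map: ClusterMap | None = None) -> TimeBudget:
    """Whole-session time fractions and bout frequencies.

    With *cluster_map*, labels are the 5 clusters; adjacent movement bouts
    in the same cluster merge into one cluster bout before counting.
    """
    labels = _session_labels(ethogram, cluster_map)
    vocab = _vocab(cluster_map)
    frames = _count_frames(labels, vocab)
    fractions = frames / labels.size
    starts = _run_starts(labels)
    bout_counts = _count_frames(labels[starts], vocab)
    minutes = ethogram.duration_s / 60.0
    return TimeBudget(
        unit="cluster" if cluster_map is not None else "movement",
        fractions=fractions,
        frequencies=bout_counts / minutes,
        bout_counts=bout_counts,
        duration_s=ethogram.duration_s,
    )


def temporal_profile(
    ethogram: Ethogram, bin_s: float, cluster_map: ClusterMap | None = None
) -> TemporalProfile:
    """Fractions and frequencies recomputed within consecutive time bins.

    A trailing partial bin is dropped with a warning.
    """
    if bin_s <= 0:
        raise ValueError("bin_s must be > 0")
    labels = _session_labels(ethogram, cluster_map)
    vocab = list(_vocab(cluster_map))
    bin_frames = int(round(bin_s * ethogram.frame_rate))
    n_bins = labels.size // bin_frames
    if n_bins < 1:
        raise ValueError("session shorter than one bin")
    if labels.size % bin_frames:
        warnings.warn(
            f"dropping trailing partial bin of {labels.size % bin_frames} frames",
            stacklevel=2,
        )
    frac = np.zeros((n_bins, len(vocab)))
    freq = np.zeros((n_bins, len(vocab)))
    starts = _run_starts(labels)
    start_labels = labels[starts]
    minutes = bin_frames / ethogram.frame_rate / 60.0
    for b in range(n_bins):
        lo, hi = b * bin_frames, (b + 1) * bin_frames
        frac[b] = _count_frames(labels[lo:hi], tuple(vocab)).to_numpy() / bin_frames
        in_bin = (starts >= lo) & (starts < hi)
        freq[b] = (
            _count_frames(start_labels[in_bin], tuple(vocab)).to_numpy() / minutes
        )
    unit = "cluster" if cluster_map is not None else "movement"
    idx = pd.RangeIndex(n_bins, name="bin")
    return TemporalProfile(
        unit=unit,
        bin_s=bin_s,
        fractions=pd.DataFrame(frac, index=idx, columns=vocab),
        frequencies=pd.DataFrame(freq, index=idx, columns=vocab),
    )


def group_profile(
    cohort: Cohort,
    genotype: str,
    sex: str,
    bin_s: float,
    cluster_map: ClusterMap | None = None,
) -> TemporalProfile:
    """Unweighted per-animal mean of temporal profiles for one group."""
    subjects = cohort.select(genotype=genotype, sex=sex)
    if not subjects:
        raise ValueError(f"no animals match genotype={genotype} sex={sex}")
    profiles = [
        temporal_profile(cohort.ethograms[s.animal_id], bin_s, cluster_map)
        for s in subjects
    ]
    frac = sum(p.fractions for p in profiles) / len(profiles)
    freq = sum(p.frequencies for p in profiles) / len(profiles)
    return TemporalProfile(profiles[0].unit, bin_s, frac, freq)


def total_distance(trajectory: Trajectory, smooth_window_s: float = 0.33) -> float:
    """Total path length (mm) of the smoothed back trajectory."""
    if trajectory.n_frames < 2:
        return 0.0
    pts = smooth_positions(trajectory.points, smooth_window_s, trajectory.frame_rate)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def distance_per_bin(
    trajectory: Trajectory, bin_s: float, smooth_window_s: float = 0.33
) -> np.ndarray:
    """Distance travelled (mm) within each full time bin (e.g. 600 s segments)."""
    if bin_s <= 0:
        raise ValueError("bin_s must be > 0")
    pts = smooth_positions(trajectory.points, smooth_window_s, trajectory.frame_rate)
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    bin_frames = int(round(bin_s * trajectory.frame_rate))
    n_bins = trajectory.n_frames // bin_frames
    out = np.empty(n_bins)
    for b in range(n_bins):
        lo, hi = b * bin_frames, (b + 1) * bin_frames
        out[b] = steps[lo : hi - 1].sum()  # steps internal to the bin
    return out


def cohort_metrics(
    cohort: Cohort,
    unit: str = "movement",
    bin_s: float | None = None,
    cluster_map: ClusterMap | None = None,
) -> pd.DataFrame:
    """Tidy long-format metrics table for a cohort.

    Columns: animal_id, genotype, sex, bin, label, fraction, frequency.
    ``bin`` is -1 for whole-session rows (``bin_s=None``).
    """
    if unit not in ("movement", "cluster"):
        raise ValueError("unit must be 'movement' or 'cluster'")
    if unit == "cluster" and cluster_map is None:
        from .ontology import DEFAULT_CLUSTER_MAP

        cluster_map = DEFAULT_CLUSTER_MAP
    cmap = cluster_map if unit == "cluster" else None
    rows = []
    for s in cohort.subjects:
        eth = cohort.ethograms[s.animal_id]
        if bin_s is None:
            tb = time_budget(eth, cmap)
            for lab in tb.fractions.index:
                rows.append(
                    (s.animal_id, s.genotype, s.sex, -1, lab,
                     tb.fractions[lab], tb.frequencies[lab])
                )
        else:
            prof = temporal_profile(eth, bin_s, cmap)
            for b in prof.fractions.index:
                for lab in prof.fractions.columns:
                    rows.append(
                        (s.animal_id, s.genotype, s.sex, int(b), lab,
                         prof.fractions.loc[b, lab], prof.frequencies.loc[b, lab])
                    )
    return pd.DataFrame(
        rows,
        columns=["animal_id", "genotype", "sex", "bin", "label", "fraction", "frequency"],
    )
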