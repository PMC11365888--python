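"""Cluster-level behavioral transition networks.

Frames are mapped onto the 5 clusters and maximal runs merged into
*events*; each cluster fragment, regardless of its length, is one event.
From the event sequence:

* ``state_prob(s)``   = events of cluster s / all events;
* ``trans_prob(s,t)`` = events of s immediately followed by t / events of s
  followed by anything (row-stochastic over observed rows; the diagonal is
  structurally zero, since merged fragments cannot repeat);
* ``self_loop(s)``    = movement-bout transitions that stay inside cluster s
  (e.g. walking -> stepping within locomotion) / movement-bout transitions
  leaving a bout of s.

Edges with transition probability below a threshold (default 0.05) are
omitted from the pruned network, on which directed betweenness centrality
is computed with edge length ``-log(p)`` so that likelier transitions make
shorter paths.  Behavioral stability across a session is summarized by the
correlation between the movement time-budget vectors of its two halves.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .ontology import (
    CLUSTERS,
    DEFAULT_CLUSTER_MAP,
    MOVEMENTS,
    Bout,
    ClusterMap,
    Cohort,
    Ethogram,
    bouts_of,
)

__all__ = [
    "EventSequence",
    "TransitionGraph",
    "to_events",
    "transition_graph",
    "betweenness",
    "half_similarity",
    "group_transition_graph",
    "group_half_similarity",
]

DEFAULT_THRESHOLD = 0.05

_CLUSTER_IDX = {c: i for i, c in enumerate(CLUSTERS)}


def _pair_counts(labels: np.ndarray) -> np.ndarray:
    """5x5 matrix of adjacent-pair counts in a cluster-label sequence."""
    idx = np.array([_CLUSTER_IDX[c] for c in labels])
    out = np.zeros((len(CLUSTERS), len(CLUSTERS)))
    if idx.size >= 2:
        np.add.at(out, (idx[:-1], idx[1:]), 1.0)
    return out


@dataclass
class EventSequence:
    """Merged cluster fragments tiling a session."""

    labels: np.ndarray  # cluster label per event
    start_frames: np.ndarray
    end_frames: np.ndarray
    frame_rate: float

    @property
    def n_events(self) -> int:
        return int(self.labels.size)


def to_events(
    ethogram: Ethogram, cluster_map: ClusterMap = DEFAULT_CLUSTER_MAP
) -> EventSequence:
    """Map frames to clusters and merge maximal runs into events."""
    clusters = cluster_map.apply(ethogram.labels)
    change = np.flatnonzero(clusters[1:] != clusters[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [clusters.size]))
    return EventSequence(
        labels=clusters[starts],
        start_frames=starts,
        end_frames=ends,
        frame_rate=ethogram.frame_rate,
    )


@dataclass
class TransitionGraph:
    """Cluster state probabilities, transition matrix and pruned network."""

    states: tuple[str, ...]
    state_prob: pd.Series
    trans_prob: pd.DataFrame  # row-stochastic over observed rows, zero diag
    self_loop: pd.Series | None
    pruned_edges: list[tuple[str, str, float]]
    threshold: float
    n_events: int
    single_event: bool = False

    @classmethod
    def from_matrix(
        cls,
        trans_prob: pd.DataFrame,
        state_prob: pd.Series | None = None,
        threshold: float = DEFAULT_THRESHOLD,
    ) -> "TransitionGraph":
        """Build a graph from an explicit transition matrix (for analysis
        of constructed networks)."""
        states = tuple(trans_prob.index)
        if state_prob is None:
            state_prob = pd.Series(1.0 / len(states), index=list(states))
        pruned = [
            (s, t, float(trans_prob.loc[s, t]))
            for s in states
            for t in states
            if s != t and trans_prob.loc[s, t] >= threshold
        ]
        return cls(
            states=states,
            state_prob=state_prob,
            trans_prob=trans_prob,
            self_loop=None,
            pruned_edges=pruned,
            threshold=threshold,
            n_events=0,
        )


def transition_graph(
    events: EventSequence,
    movement_bouts: list[Bout] | None = None,
    cluster_map: ClusterMap = DEFAULT_CLUSTER_MAP,
    threshold: float = DEFAULT_THRESHOLD,
) -> TransitionGraph:
    """Estimate the cluster transition network from one event sequence.

    With *movement_bouts*, the per-cluster self-transition probability is
    estimated at movement-bout level (a walking bout followed by a stepping
    bout is a self-transition of locomotion).
    """
    labels = events.labels
    if labels.size == 0:
        raise ValueError("empty event sequence")
    states = CLUSTERS
    state_prob = pd.Series(0.0, index=list(states))
    uniq, n = np.unique(labels, return_counts=True)
    state_prob[uniq] = n / labels.size

    counts = pd.DataFrame(
        _pair_counts(labels), index=list(states), columns=list(states)
    )
    trans = counts.copy()
    row_sums = counts.sum(axis=1)
    observed = row_sums > 0
    trans.loc[observed] = counts.loc[observed].div(row_sums[observed], axis=0)

    self_loop = None
    if movement_bouts is not None:
        bc = np.array([cluster_map[b.movement] for b in movement_bouts])
        self_loop = pd.Series(np.nan, index=list(states))
        for s in states:
            leaving = bc[:-1] == s
            den = int(leaving.sum())
            if den:
                num = int((leaving & (bc[1:] == s)).sum())
                self_loop[s] = num / den

    pruned = [
        (s, t, float(trans.loc[s, t]))
        for s in states
        for t in states
        if s != t and trans.loc[s, t] >= threshold
    ]
    return TransitionGraph(
        states=states,
        state_prob=state_prob,
        trans_prob=trans,
        self_loop=self_loop,
        pruned_edges=pruned,
        threshold=threshold,
        n_events=labels.size,
        single_event=labels.size == 1,
    )


def betweenness(graph: TransitionGraph, weighted: bool = True) -> pd.Series:
    """Directed betweenness centrality on the pruned network.

    With ``weighted=True`` edge distance is ``-log(p)``; normalization is by
    ``(n-1)(n-2)`` with n the number of states.  Disconnected states get 0.
    """
    G = nx.DiGraph()
    G.add_nodes_from(graph.states)
    for s, t, p in graph.pruned_edges:
        if p <= 0:
            continue
        G.add_edge(s, t, weight=-np.log(p), prob=p)
    bc = nx.betweenness_centrality(
        G, normalized=True, weight="weight" if weighted else None
    )
    return pd.Series(bc).reindex(list(graph.states))


def _half_fraction_vectors(
    ethogram: Ethogram, cluster_map: ClusterMap | None, split_s: float
) -> tuple[np.ndarray, np.ndarray]:
    if ethogram.duration_s <= split_s:
        raise ValueError("session must be longer than split_s")
    split_f = int(round(split_s * ethogram.frame_rate))
    labels = (
        ethogram.labels if cluster_map is None else cluster_map.apply(ethogram.labels)
    )
    vocab = MOVEMENTS if cluster_map is None else CLUSTERS
    vecs = []
    for part in (labels[:split_f], labels[split_f:]):
        counts = np.array([(part == m).sum() for m in vocab], dtype=float)
        vecs.append(counts / counts.sum())
    return vecs[0], vecs[1]


def half_similarity(
    ethogram: Ethogram,
    cluster_map: ClusterMap | None = None,
    split_s: float = 1800.0,
    method: str = "pearson",
) -> float:
    """Similarity of the movement time budgets of the two session halves.

    Pearson correlation by default (cosine available); NaN when a half has
    a zero-variance fraction vector (constant behavior).
    """
    a, b = _half_fraction_vectors(ethogram, cluster_map, split_s)
    if method == "cosine":
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            return float("nan")
        return float(a @ b / (na * nb))
    if method != "pearson":
        raise ValueError("method must be 'pearson' or 'cosine'")
    if a.std() < 1e-12 or b.std() < 1e-12:  # flat budget: correlation undefined
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def group_transition_graph(
    cohort: Cohort,
    genotype: str,
    sex: str | None = None,
    cluster_map: ClusterMap = DEFAULT_CLUSTER_MAP,
    threshold: float = DEFAULT_THRESHOLD,
    pool: str = "animals",
    frame_range: tuple[int, int] | None = None,
) -> TransitionGraph:
    """Group-level transition network.

    ``pool='animals'`` (default) averages per-animal state/transition
    estimates; ``pool='events'`` concatenates event counts across animals.
    *frame_range* restricts each session to ``[lo, hi)`` frames (e.g. the
    first or second half hour).
    """
    subjects = cohort.select(genotype=genotype, sex=sex)
    if not subjects:
        raise ValueError(f"no animals match genotype={genotype} sex={sex}")
    if pool not in ("animals", "events"):
        raise ValueError("pool must be 'animals' or 'events'")

    graphs = []
    total_counts = pd.DataFrame(0.0, index=list(CLUSTERS), columns=list(CLUSTERS))
    total_states = pd.Series(0.0, index=list(CLUSTERS))
    n_events = 0
    for s in subjects:
        eth = cohort.ethograms[s.animal_id]
        if frame_range is not None:
            lo, hi = frame_range
            eth = Ethogram(eth.animal_id, eth.frame_rate, eth.labels[lo:hi])
        ev = to_events(eth, cluster_map)
        g = transition_graph(
            ev, bouts_of(eth), cluster_map=cluster_map, threshold=threshold
        )
        graphs.append(g)
        uniq, n = np.unique(ev.labels, return_counts=True)
        total_states[uniq] += n
        total_counts += _pair_counts(ev.labels)
        n_events += ev.n_events

    if pool == "animals":
        trans = sum(g.trans_prob for g in graphs) / len(graphs)
        state_prob = sum(g.state_prob for g in graphs) / len(graphs)
        self_loops = pd.concat([g.self_loop for g in graphs], axis=1)
        self_loop = self_loops.mean(axis=1)
    else:
        row = total_counts.sum(axis=1)
        trans = total_counts.copy()
        obs = row > 0
        trans.loc[obs] = total_counts.loc[obs].div(row[obs], axis=0)
        state_prob = total_states / total_states.sum()
        self_loops = pd.concat([g.self_loop for g in graphs], axis=1)
        self_loop = self_loops.mean(axis=1)

    pruned = [
        (a, b, float(trans.loc[a, b]))
        for a in CLUSTERS
        for b in CLUSTERS
        if a != b and trans.loc[a, b] >= threshold
    ]
    return TransitionGraph(
        states=CLUSTERS,
        state_prob=state_prob,
        trans_prob=trans,
        self_loop=self_loop,
        pruned_edges=pruned,
        threshold=threshold,
        n_events=n_events,
    )


def group_half_similarity(
    cohort: Cohort,
    genotype: str,
    sex: str | None = None,
    cluster_map: ClusterMap | None = None,
    split_s: float = 1800.0,
) -> float:
    """Mean pairwise first-half vs second-half similarity within a group.

    Averages the Pearson correlation between animal i's first-half and
    animal j's second-half movement fraction vectors over all (i, j) pairs.
    """
    subjects = cohort.select(genotype=genotype, sex=sex)
    if not subjects:
        raise ValueError(f"no animals match genotype={genotype} sex={sex}")
    firsts, seconds = [], []
    for s in subjects:
        a, b = _half_fraction_vectors(
            cohort.ethograms[s.animal_id], cluster_map, split_s
        )
        firsts.append(a)
        seconds.append(b)
    vals = []
    for a in firsts:
        for b in seconds:
            if a.std() < 1e-12 or b.std() < 1e-12:
                continue
            vals.append(np.corrcoef(a, b)[0, 1])
    return float(np.mean(vals)) if vals else float("nan")
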