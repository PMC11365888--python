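"""Event merging, transition estimation, pruning, betweenness, similarity."""

import numpy as np
import pandas as pd
import pytest

import ethofield as ef
from ethofield.ontology import MOVEMENTS
from ethofield.transitions import TransitionGraph, _pair_counts
from tests.conftest import make_ethogram

FPS = 30

# five movements, one per cluster: events == bout chain restricted to them
FIVE = ("walking", "rearing", "hunching", "grooming", "pausing")
FIVE_CLUSTERS = ("locomotion", "exploration", "forced_posture", "maintenance", "nap")


def five_state_model(K):
    """Embed a known 5x5 event chain into a 13-movement behavior model."""
    N = len(MOVEMENTS)
    P = np.zeros((N, N))
    idx = [MOVEMENTS.index(m) for m in FIVE]
    for i, mi in enumerate(idx):
        for j, mj in enumerate(idx):
            P[mi, mj] = K[i, j]
    # unused movements are transient: route them uniformly into the 5 states
    for r in range(N):
        if r not in idx:
            P[r, idx] = 1.0 / 5
    return ef.BehaviorModel(
        movement_transition=P,
        dwell_mu_log=np.full(N, np.log(1 / FPS)),  # 1-frame bouts
        dwell_sigma_log=np.zeros(N),
        speed_mm_s=np.zeros(N),
        wall_affinity=0.5,
    )


def _chain_stationary(P):
    A = np.vstack([P.T - np.eye(P.shape[0]), np.ones(P.shape[0])])
    b = np.zeros(P.shape[0] + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return pi


KNOWN_K = np.array(
    [
        [0.0, 0.40, 0.30, 0.20, 0.10],
        [0.25, 0.0, 0.25, 0.25, 0.25],
        [0.30, 0.30, 0.0, 0.20, 0.20],
        [0.10, 0.20, 0.30, 0.0, 0.40],
        [0.25, 0.25, 0.25, 0.25, 0.0],
    ]
)


def test_to_events_merges_within_cluster():
    eth = make_ethogram([("walking", 10), ("stepping", 10), ("grooming", 10)], FPS)
    ev = ef.to_events(eth)
    assert list(ev.labels) == ["locomotion", "maintenance"]
    assert ev.start_frames.tolist() == [0, 20]

    eth = make_ethogram([("pausing", 100)], FPS)
    assert ef.to_events(eth).n_events == 1

    eth = make_ethogram([("walking", 5), ("rearing", 5)] * 3, FPS)
    assert list(ef.to_events(eth).labels) == ["locomotion", "exploration"] * 3


def test_transition_graph_direct_counting():
    eth = make_ethogram([("walking", 5), ("rearing", 5), ("stepping", 5)], FPS)
    ev = ef.to_events(eth)  # L, E, L
    g = ef.transition_graph(ev)
    assert g.state_prob["locomotion"] == pytest.approx(2 / 3)
    assert g.state_prob["exploration"] == pytest.approx(1 / 3)
    assert g.trans_prob.loc["locomotion", "exploration"] == 1.0
    assert g.trans_prob.loc["exploration", "locomotion"] == 1.0
    assert g.state_prob.sum() == pytest.approx(1.0)


def test_single_event_flagged():
    eth = make_ethogram([("pausing", 100)], FPS)
    g = ef.transition_graph(ef.to_events(eth))
    assert g.single_event
    assert g.state_prob["nap"] == 1.0
    assert g.trans_prob.to_numpy().sum() == 0.0


def test_self_loop_counts_within_cluster_movement_transitions():
    eth = make_ethogram([("walking", 5), ("stepping", 5), ("rearing", 5)], FPS)
    g = ef.transition_graph(ef.to_events(eth), ef.bouts_of(eth))
    # walking->stepping is a locomotion self-transition; stepping->rearing leaves
    assert g.self_loop["locomotion"] == pytest.approx(0.5)
    assert np.isnan(g.self_loop["nap"])


def test_pruning_threshold():
    trans = pd.DataFrame(
        [[0.0, 0.96, 0.04], [0.5, 0.0, 0.5], [1.0, 0.0, 0.0]],
        index=list("ABC"), columns=list("ABC"),
    )
    g = TransitionGraph.from_matrix(trans, threshold=0.05)
    edges = {(s, t) for s, t, _ in g.pruned_edges}
    assert ("A", "C") not in edges  # 0.04 < 0.05 is omitted
    assert ("A", "B") in edges and ("C", "A") in edges
    # the stored matrix keeps full row mass
    assert g.trans_prob.loc["A"].sum() == pytest.approx(1.0)


def test_event_chain_recovery_5000_events():
    """Estimated matrix and state probabilities converge to the known chain."""
    model = five_state_model(KNOWN_K)
    stationary = _chain_stationary(KNOWN_K)
    for seed in (101, 102, 103):
        eth, _ = ef.simulate_session(model, 5000 / FPS, FPS, seed=seed)
        ev = ef.to_events(eth)
        assert ev.n_events >= 4900
        g = ef.transition_graph(ev)
        est = g.trans_prob.loc[list(FIVE_CLUSTERS), list(FIVE_CLUSTERS)].to_numpy()
        assert np.max(np.abs(est - KNOWN_K)) < 0.05
        sp = g.state_prob[list(FIVE_CLUSTERS)].to_numpy()
        assert np.max(np.abs(sp - stationary)) < 0.02


def test_estimation_error_shrinks_with_events():
    model = five_state_model(KNOWN_K)
    errs = []
    for n_events in (500, 5000):
        errors = []
        for seed in (7, 8, 9):
            eth, _ = ef.simulate_session(model, n_events / FPS, FPS, seed=seed)
            g = ef.transition_graph(ef.to_events(eth))
            est = g.trans_prob.loc[list(FIVE_CLUSTERS), list(FIVE_CLUSTERS)].to_numpy()
            errors.append(np.max(np.abs(est - KNOWN_K)))
        errs.append(np.mean(errors))
    assert errs[1] < errs[0]


def test_betweenness_directed_path():
    trans = pd.DataFrame(0.0, index=list("ABC"), columns=list("ABC"))
    trans.loc["A", "B"] = 1.0
    trans.loc["B", "C"] = 1.0
    g = TransitionGraph.from_matrix(trans)
    bc = ef.betweenness(g)
    # B lies on the single A->C shortest path: 1/((3-1)(3-2)) = 0.5
    assert bc["B"] == pytest.approx(0.5)
    assert bc["A"] == 0.0 and bc["C"] == 0.0


def test_betweenness_star_hub():
    states = ["locomotion", "exploration", "forced_posture", "maintenance", "nap"]
    trans = pd.DataFrame(0.0, index=states, columns=states)
    for leaf in states[1:]:
        trans.loc["locomotion", leaf] = 0.25
        trans.loc[leaf, "locomotion"] = 1.0
    g = TransitionGraph.from_matrix(trans)
    bc = ef.betweenness(g)
    # hub carries all 4x3 leaf-pair shortest paths: 12/((5-1)(5-2)) = 1
    assert bc["locomotion"] == pytest.approx(1.0)
    for leaf in states[1:]:
        assert bc[leaf] == 0.0


def test_betweenness_symmetric_complete_graph_equal():
    states = list("ABCD")
    trans = pd.DataFrame(
        np.where(np.eye(4, dtype=bool), 0.0, 1 / 3), index=states, columns=states
    )
    bc = ef.betweenness(TransitionGraph.from_matrix(trans))
    assert bc.nunique() == 1


def test_half_similarity_repeat_and_disjoint():
    spec = [("walking", 300), ("grooming", 300), ("pausing", 300)]
    eth = make_ethogram(spec + spec, FPS)
    split = eth.duration_s / 2
    assert ef.half_similarity(eth, split_s=split) == pytest.approx(1.0)

    eth = make_ethogram([("walking", 900), ("pausing", 900)], FPS)
    # disjoint one-hot budgets anticorrelate; oracle: Pearson of two distinct
    # one-hot 13-vectors is exactly -1/12
    sim = ef.half_similarity(eth, split_s=eth.duration_s / 2)
    a = np.zeros(13); a[0] = 1
    b = np.zeros(13); b[1] = 1
    oracle = np.corrcoef(a, b)[0, 1]
    assert sim == pytest.approx(oracle)
    assert sim < 0


def test_half_similarity_errors_and_flags():
    eth = make_ethogram([("walking", 100)], FPS)
    with pytest.raises(ValueError):
        ef.half_similarity(eth, split_s=10.0)
    # a perfectly uniform budget has zero variance -> similarity undefined
    uniform = [(m, 10) for m in ef.MOVEMENTS]
    eth = make_ethogram(uniform + uniform, FPS)
    assert np.isnan(ef.half_similarity(eth, split_s=eth.duration_s / 2))


def test_pair_counts_helper():
    labels = np.array(["locomotion", "nap", "locomotion", "nap"])
    M = _pair_counts(labels)
    li, ni = 0, 4
    assert M[li, ni] == 2 and M[ni, li] == 1 and M.sum() == 3


def test_group_graph_pooling_modes(small_cohort):
    g_an = ef.transitions.group_transition_graph(small_cohort, "WT", "M", pool="animals")
    g_ev = ef.transitions.group_transition_graph(small_cohort, "WT", "M", pool="events")
    for g in (g_an, g_ev):
        assert g.state_prob.sum() == pytest.approx(1.0)
        rows = g.trans_prob.sum(axis=1)
        observed = rows > 0
        np.testing.assert_allclose(rows[observed], 1.0, atol=1e-9)
    maint_nap = g_an.trans_prob.loc["maintenance", "nap"]
    assert 0.0 <= maint_nap <= 1.0
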