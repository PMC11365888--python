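"""Synthetic open-field cohorts: semi-Markov ethograms + wall-biased walks.

The study's recordings are not deposited, so every downstream stage is
exercised on simulated sessions with the genotype x sex structure the
analysis assumes.  A session is generated in two layers:

1. **Ethogram** — a semi-Markov bout process.  Successive bouts follow a
   13-state bout-to-bout Markov chain (zero diagonal: a bout cannot be
   followed by a bout of the same movement); each bout's duration is drawn
   from a per-movement lognormal.  Dwell and selection are decoupled so that
   time fractions and bout frequencies can vary independently, which a
   frame-wise Markov chain cannot do.

2. **Trajectory** — a speed-modulated attractive walk.  Each bout draws an
   attractor: with probability ``wall_affinity`` the nearest wall-band
   midline (thigmotaxis), otherwise a uniform point of the preferred
   central region.  The mean path travels toward the attractor at the
   movement's nominal speed — locomotion carries the animal, slow
   movements park it where it is — with AR(1)-filtered jitter superposed
   and reflection at the walls.

For the closed-form time-fraction law of the bout chain see
:meth:`BehaviorModel.stationary_time_fractions`: the chain's stationary bout
weights multiplied by mean dwell and renormalized.

The genotype contrasts engineered into :func:`default_models` reproduce the
directions reported for Shank3b mutants — less walking/stepping (HE and KO,
KO more extreme), more pausing/grooming/hunching, stronger thigmotaxis in
KO, and elevated maintenance<->nap coupling — as *orderings*, not effect
sizes; the study reports no numeric per-group time-budget table.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .ontology import (
    ARENA_HALF_MM,
    GENOTYPES,
    MOVEMENTS,
    SEXES,
    Cohort,
    Ethogram,
    Subject,
    Trajectory,
)

__all__ = [
    "BehaviorModel",
    "CohortDesign",
    "PAPER_GROUP_SIZES",
    "default_models",
    "simulate_session",
    "simulate_cohort",
    "animal_seed",
]

N_MOV = len(MOVEMENTS)

#: Group sizes of the study cohort (114 animals).
PAPER_GROUP_SIZES: dict[tuple[str, str], int] = {
    ("KO", "M"): 20,
    ("HE", "M"): 15,
    ("WT", "M"): 19,
    ("KO", "F"): 21,
    ("HE", "F"): 12,
    ("WT", "F"): 17,
}


@dataclass
class BehaviorModel:
    """Generative parameters of one genotype x sex group.

    Parameters
    ----------
    movement_transition
        13x13 row-stochastic bout-to-bout transition matrix, zero diagonal,
        rows/columns in :data:`MOVEMENTS` order.
    dwell_mu_log, dwell_sigma_log
        Per-movement lognormal bout-duration parameters (log-seconds).
    speed_mm_s
        Per-movement nominal mean horizontal speed of the back point.
    wall_affinity
        Probability that a bout's walk attractor is the nearest wall-band
        midline rather than the central region (thigmotaxis strength).
    center_halfwidth_mm
        Half-width of the preferred central region from which non-wall
        attractors are drawn uniformly.
    wall_band_mm
        Width of the perimeter band whose midline serves as wall attractor.
    attraction_tau_s
        Relaxation time of the AR(1) pull toward the current attractor.
    jitter_speed_mm_s
        Floor on the raw per-frame jitter of the back keypoint (posture
        sway and tracking noise), applied to movements with nonzero nominal
        speed; movements with speed exactly 0 stay perfectly still.
    """

    movement_transition: np.ndarray
    dwell_mu_log: np.ndarray
    dwell_sigma_log: np.ndarray
    speed_mm_s: np.ndarray
    wall_affinity: float
    center_halfwidth_mm: float = 100.0
    wall_band_mm: float = 35.0
    attraction_tau_s: float = 2.0
    jitter_speed_mm_s: float = 15.0

    def __post_init__(self) -> None:
        P = np.asarray(self.movement_transition, dtype=float)
        if P.shape != (N_MOV, N_MOV):
            raise ValueError(f"movement_transition must be {N_MOV}x{N_MOV}")
        if np.any(np.abs(np.diag(P)) > 1e-12):
            raise ValueError("movement_transition must have a zero diagonal")
        if np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("movement_transition rows must sum to 1")
        self.movement_transition = P
        for name in ("dwell_mu_log", "dwell_sigma_log", "speed_mm_s"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_MOV,):
                raise ValueError(f"{name} must have length {N_MOV}")
            setattr(self, name, arr)
        if np.any(self.dwell_sigma_log < 0):
            raise ValueError("dwell_sigma_log must be >= 0")
        if np.any(self.speed_mm_s < 0):
            raise ValueError("speeds must be >= 0")
        if not 0.0 <= self.wall_affinity <= 1.0:
            raise ValueError("wall_affinity must lie in [0, 1]")

    # ------------------------------------------------------------------
    def mean_dwell_s(self) -> np.ndarray:
        """Lognormal mean bout duration per movement, seconds."""
        return np.exp(self.dwell_mu_log + self.dwell_sigma_log**2 / 2.0)

    def stationary_bout_distribution(self) -> np.ndarray:
        """Stationary law of the bout-to-bout chain (left eigenvector)."""
        P = self.movement_transition
        w, v = np.linalg.eig(P.T)
        k = int(np.argmin(np.abs(w - 1.0)))
        pi = np.real(v[:, k])
        pi = np.abs(pi)
        return pi / pi.sum()

    def stationary_time_fractions(self) -> np.ndarray:
        """Closed-form long-run time fraction per movement.

        Stationary bout weights times mean dwell, renormalized — the
        semi-Markov occupation law against which simulated sessions are
        checked.
        """
        occ = self.stationary_bout_distribution() * self.mean_dwell_s()
        return occ / occ.sum()

    def expected_fraction(self, movement: str) -> float:
        return float(self.stationary_time_fractions()[MOVEMENTS.index(movement)])


@dataclass
class CohortDesign:
    """Cohort layout: group sizes, session length, frame rate, master seed."""

    group_sizes: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(PAPER_GROUP_SIZES)
    )
    duration_s: float = 3600.0
    frame_rate: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        for key, n in self.group_sizes.items():
            g, s = key
            if g not in GENOTYPES or s not in SEXES:
                raise ValueError(f"unknown group {key}")
            if n < 0:
                raise ValueError("group sizes must be >= 0")

    @property
    def n_subjects(self) -> int:
        return sum(self.group_sizes.values())


# ----------------------------------------------------------------------
# Default models
# ----------------------------------------------------------------------

# Bout-selection weights (relative probability that the next bout is of a
# movement) per genotype; the WT column describes a normally exploring
# mouse, HE/KO shift mass from walking/stepping/sniffing toward pausing,
# grooming and hunching, KO more than HE.
_BOUT_WEIGHTS: dict[str, dict[str, float]] = {
    "WT": {
        "running": 0.040, "trotting": 0.070, "walking": 0.140,
        "right_turning": 0.070, "left_turning": 0.070, "stepping": 0.120,
        "rearing": 0.080, "sniffing": 0.160, "rising": 0.060,
        "climbing": 0.060, "hunching": 0.030, "grooming": 0.040,
        "pausing": 0.060,
    },
    "HE": {
        "running": 0.035, "trotting": 0.060, "walking": 0.100,
        "right_turning": 0.065, "left_turning": 0.065, "stepping": 0.090,
        "rearing": 0.075, "sniffing": 0.130, "rising": 0.055,
        "climbing": 0.055, "hunching": 0.040, "grooming": 0.055,
        "pausing": 0.100,
    },
    "KO": {
        "running": 0.030, "trotting": 0.045, "walking": 0.060,
        "right_turning": 0.060, "left_turning": 0.060, "stepping": 0.070,
        "rearing": 0.070, "sniffing": 0.100, "rising": 0.045,
        "climbing": 0.040, "hunching": 0.055, "grooming": 0.080,
        "pausing": 0.130,
    },
}

# Mean bout durations (s) for WT; lognormal sigma_log is shared.
_MEAN_DWELL_S: dict[str, float] = {
    "running": 0.8, "trotting": 1.0, "walking": 1.5, "right_turning": 0.8,
    "left_turning": 0.8, "stepping": 0.7, "rearing": 1.2, "sniffing": 2.0,
    "rising": 0.8, "climbing": 1.5, "hunching": 1.5, "grooming": 4.0,
    "pausing": 3.0,
}
_DWELL_SIGMA_LOG = 0.6

# Genotype-specific dwell multipliers (longer grooming/pausing in mutants,
# shorter walking bouts in KO).
_DWELL_SCALE: dict[str, dict[str, float]] = {
    "WT": {},
    "HE": {"grooming": 1.2, "pausing": 1.15},
    "KO": {"grooming": 1.35, "pausing": 1.3, "walking": 0.8},
}

# Nominal back-point speeds (mm/s) per movement; non-locomotor movements
# still carry residual back-point motion (posture shifts, weight transfer).
_SPEED_MM_S: dict[str, float] = {
    "running": 200.0, "trotting": 120.0, "walking": 60.0,
    "right_turning": 40.0, "left_turning": 40.0, "stepping": 30.0,
    "rearing": 10.0, "sniffing": 20.0, "rising": 10.0, "climbing": 12.0,
    "hunching": 5.0, "grooming": 5.0, "pausing": 5.0,
}

# Multiplicative boost of the grooming<->pausing transition entries
# (maintenance<->nap coupling), rising from WT to KO.
_MAINT_NAP_BOOST: dict[str, float] = {"WT": 1.0, "HE": 1.6, "KO": 2.5}

# Thigmotaxis strength.
_WALL_AFFINITY: dict[str, float] = {"WT": 0.60, "HE": 0.68, "KO": 0.76}

# Sex factor on the walking selection weight; the study reports the walking
# sex contrast as largest in WT and absent in KO.
_WALKING_SEX_FACTOR_F: dict[str, float] = {"WT": 0.82, "HE": 0.90, "KO": 1.0}


def _transition_from_weights(
    weights: np.ndarray, boost: float = 1.0
) -> np.ndarray:
    """Bout chain with next-bout selection proportional to target weights.

    ``P[i, j] ~ w[j]`` for ``j != i``; grooming<->pausing entries are then
    multiplied by *boost* and rows renormalized.
    """
    P = np.tile(weights, (N_MOV, 1)).astype(float)
    np.fill_diagonal(P, 0.0)
    gi, pi = MOVEMENTS.index("grooming"), MOVEMENTS.index("pausing")
    P[gi, pi] *= boost
    P[pi, gi] *= boost
    P /= P.sum(axis=1, keepdims=True)
    return P


def default_models() -> dict[tuple[str, str], BehaviorModel]:
    """The six genotype x sex generative models used as study stand-ins."""
    models: dict[tuple[str, str], BehaviorModel] = {}
    for genotype in GENOTYPES:
        for sex in SEXES:
            w = np.array([_BOUT_WEIGHTS[genotype][m] for m in MOVEMENTS])
            if sex == "F":
                w[MOVEMENTS.index("walking")] *= _WALKING_SEX_FACTOR_F[genotype]
            w = w / w.sum()
            mean_dwell = np.array(
                [
                    _MEAN_DWELL_S[m] * _DWELL_SCALE[genotype].get(m, 1.0)
                    for m in MOVEMENTS
                ]
            )
            mu_log = np.log(mean_dwell) - _DWELL_SIGMA_LOG**2 / 2.0
            models[(genotype, sex)] = BehaviorModel(
                movement_transition=_transition_from_weights(
                    w, _MAINT_NAP_BOOST[genotype]
                ),
                dwell_mu_log=mu_log,
                dwell_sigma_log=np.full(N_MOV, _DWELL_SIGMA_LOG),
                speed_mm_s=np.array([_SPEED_MM_S[m] for m in MOVEMENTS]),
                wall_affinity=_WALL_AFFINITY[genotype],
            )
    return models


# ----------------------------------------------------------------------
# Session simulation
# ----------------------------------------------------------------------

def _sample_bouts(
    model: BehaviorModel, n_frames: int, frame_rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample (movement index, frame count) bout pairs covering n_frames."""
    P_cum = np.cumsum(model.movement_transition, axis=1)
    start_cum = np.cumsum(model.stationary_bout_distribution())
    cur = int(np.searchsorted(start_cum, rng.random()))
    movs: list[int] = []
    lens: list[int] = []
    total = 0
    while total < n_frames:
        dur_s = rng.lognormal(model.dwell_mu_log[cur], model.dwell_sigma_log[cur])
        nf = max(1, int(round(dur_s * frame_rate)))
        nf = min(nf, n_frames - total)
        movs.append(cur)
        lens.append(nf)
        total += nf
        cur = int(np.searchsorted(P_cum[cur], rng.random()))
    return np.asarray(movs), np.asarray(lens)


def _reflect(coords: np.ndarray, half: float = ARENA_HALF_MM) -> np.ndarray:
    """Fold coordinates into [-half, half] by mirror reflection."""
    p = np.mod(coords + half, 4.0 * half)
    p = np.where(p > 2.0 * half, 4.0 * half - p, p)
    return p - half


def _simulate_walk(
    model: BehaviorModel,
    movs: np.ndarray,
    lens: np.ndarray,
    frame_rate: float,
    rng: np.random.Generator,
    start: np.ndarray,
) -> np.ndarray:
    """Speed-capped attractive walk, one attractor per bout.

    Within a bout the mean path travels toward the bout's attractor at the
    movement's nominal speed (switching to an exponential relaxation with
    time constant ``attraction_tau_s`` once close), so slow movements park
    where the animal is while locomotion carries it; AR(1)-filtered
    Gaussian jitter is superposed and positions are reflected at walls.
    """
    phi = float(np.exp(-1.0 / (model.attraction_tau_s * frame_rate)))
    lam = 1.0 - phi
    wall_mid = ARENA_HALF_MM - model.wall_band_mm / 2.0
    # jitter scale: half the nominal per-frame step, floored at the posture
    # jitter so parked animals still sway around their resting point; a
    # movement with nominal speed exactly 0 is perfectly still
    sigma_per_mov = np.where(
        model.speed_mm_s > 0,
        np.maximum(0.5 * model.speed_mm_s, model.jitter_speed_mm_s) / frame_rate,
        0.0,
    )

    pos = np.asarray(start, dtype=float).copy()
    chunks: list[np.ndarray] = []
    b = np.array([1.0])
    a = np.array([1.0, -phi])
    zi = np.zeros((1, 2))
    for mov, nf in zip(movs, lens):
        nf = int(nf)
        if rng.random() < model.wall_affinity:
            attractor = pos.copy()
            axis = int(np.argmax(np.abs(pos)))
            sign = 1.0 if pos[axis] >= 0 else -1.0
            attractor[axis] = sign * wall_mid
            attractor = np.clip(attractor, -wall_mid, wall_mid)
        else:
            c = model.center_halfwidth_mm
            attractor = rng.uniform(-c, c, size=2)

        delta = attractor - pos
        dist = float(np.hypot(*delta))
        cap = model.speed_mm_s[mov] / frame_rate  # mm per frame
        t = np.arange(1, nf + 1, dtype=float)
        if cap <= 0:
            dist_t = np.full(nf, dist)
        elif dist < 1e-12:
            dist_t = np.zeros(nf)
        else:
            d_c = cap / lam  # below this, linear pull is slower than the cap
            n1 = max(0.0, np.ceil((dist - d_c) / cap))
            d_n1 = max(d_c, dist - cap * n1) if n1 > 0 else dist
            lin = np.maximum(dist - cap * t, 0.0)
            expo = min(d_n1, dist) * phi ** np.maximum(t - n1, 0.0)
            dist_t = np.where(t <= n1, lin, expo)
        unit = delta / dist if dist > 1e-12 else np.zeros(2)
        mean_path = attractor[None, :] - unit[None, :] * dist_t[:, None]

        if sigma_per_mov[mov] > 0:
            noise = rng.normal(0.0, sigma_per_mov[mov], size=(nf, 2))
            jitter, zi = lfilter(b, a, noise, axis=0, zi=zi)
        else:
            jitter = np.zeros((nf, 2))
            zi = zi * phi**nf
        y = mean_path + jitter
        pos = y[-1].copy()
        chunks.append(y)
    xy = np.concatenate(chunks, axis=0)
    return _reflect(xy)


def simulate_session(
    model: BehaviorModel,
    duration_s: float,
    frame_rate: float,
    seed: int,
    animal_id: str = "sim",
) -> tuple[Ethogram, Trajectory]:
    """Simulate one open-field session; identical seeds give identical output."""
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    n_frames = int(round(duration_s * frame_rate))
    rng = np.random.default_rng(int(seed))
    movs, lens = _sample_bouts(model, n_frames, frame_rate, rng)
    labels = np.repeat(np.array(MOVEMENTS)[movs], lens)
    # mice are introduced at a fixed corner of the arena
    start = np.array([-(ARENA_HALF_MM - 25.0), -(ARENA_HALF_MM - 25.0)])
    xy = _simulate_walk(model, movs, lens, frame_rate, rng, start)
    eth = Ethogram(animal_id=animal_id, frame_rate=frame_rate, labels=labels)
    traj = Trajectory(animal_id=animal_id, frame_rate=frame_rate, points=xy)
    return eth, traj


def animal_seed(master_seed: int, animal_id: str) -> int:
    """Stable per-animal seed: SHA-256 of ``"{master_seed}:{animal_id}"``."""
    digest = hashlib.sha256(f"{master_seed}:{animal_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def simulate_cohort(
    design: CohortDesign,
    models: dict[tuple[str, str], BehaviorModel] | None = None,
) -> Cohort:
    """Simulate a full cohort; per-animal seeds derive from ``design.seed``."""
    if models is None:
        models = default_models()
    subjects: list[Subject] = []
    ethograms: dict[str, Ethogram] = {}
    trajectories: dict[str, Trajectory] = {}
    for (genotype, sex) in sorted(design.group_sizes):
        n = design.group_sizes[(genotype, sex)]
        for k in range(n):
            aid = f"{sex}-{genotype}-{k + 1:02d}"
            eth, traj = simulate_session(
                models[(genotype, sex)],
                design.duration_s,
                design.frame_rate,
                seed=animal_seed(design.seed, aid),
                animal_id=aid,
            )
            subjects.append(Subject(aid, genotype, sex))
            ethograms[aid] = eth
            trajectories[aid] = traj
    return Cohort(subjects=subjects, ethograms=ethograms, trajectories=trajectories)
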