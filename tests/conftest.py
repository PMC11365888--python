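import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ethofield as ef

settings.register_profile(
    "ci",
    max_examples=25,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def models():
    return ef.default_models()


@pytest.fixture(scope="session")
def small_cohort(models):
    """3 animals/group, 10-min sessions at 30 fps."""
    design = ef.CohortDesign(
        group_sizes={(g, s): 3 for g in ef.GENOTYPES for s in ef.SEXES},
        duration_s=600.0,
        frame_rate=30.0,
        seed=7,
    )
    return ef.simulate_cohort(design, models)


def make_ethogram(spec, frame_rate=30.0, animal_id="t"):
    """Build an ethogram from (movement, n_frames) pairs."""
    labels = np.repeat([m for m, _ in spec], [n for _, n in spec])
    return ef.Ethogram(animal_id, frame_rate, labels)


def make_line_trajectory(segments, frame_rate=30.0, start=(0.0, 0.0), animal_id="t"):
    """Straight-line trajectory from (speed_mm_s, n_frames, direction) pieces.

    direction is +1/-1 along x; y stays constant.
    """
    xs = [start[0]]
    for speed, n, d in segments:
        step = d * speed / frame_rate
        for _ in range(n):
            xs.append(xs[-1] + step)
    xs = np.asarray(xs[1:])
    pts = np.column_stack([xs, np.full_like(xs, start[1])])
    return ef.Trajectory(animal_id, frame_rate, pts)
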