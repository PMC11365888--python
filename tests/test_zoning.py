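"""Calibration, occupancy growth curves, boundary detection, zone budgets."""

import numpy as np
import pytest

import ethofield as ef
from ethofield.ontology import ARENA_HALF_MM
from ethofield.zoning import GrowthCurve, ZoneDivision, calibrate
from tests.conftest import make_ethogram

FPS = 30


# ---------------------------------------------------------------- calibrate
CORNERS = np.array([[-200, -200], [-200, 200], [200, 200], [200, -200]], float)


def test_calibrate_identity_scale_translation():
    pts = np.array([[0.0, 0.0], [100.0, -50.0]])
    t = calibrate(pts, CORNERS)
    assert np.allclose(t.points, pts)

    t = calibrate(pts / 10, CORNERS / 10)  # recorded in cm
    assert np.allclose(t.points, pts)

    shift = np.array([50.0, -30.0])
    t = calibrate(pts + shift, CORNERS + shift)
    assert np.allclose(t.points, pts, atol=1e-9)
    # the observed arena center maps to the origin
    t0 = calibrate(shift[None, :], CORNERS + shift)
    assert np.allclose(t0.points, 0.0, atol=1e-9)


def test_calibrate_rejects_degenerate_corners():
    bad = np.array([[0, 0], [1, 1], [2, 2], [3, 3]], float)
    with pytest.raises(ValueError):
        calibrate(np.zeros((1, 2)), bad)
    dup = np.array([[-200, -200], [-200, -200], [200, 200], [200, -200]], float)
    with pytest.raises(ValueError, match="distinct"):
        calibrate(np.zeros((1, 2)), dup)


# ------------------------------------------------------------- growth curve
def test_growth_curve_origin_and_single_point():
    traj = ef.Trajectory("t", FPS, np.zeros((500, 2)))
    curve = ef.growth_curve(traj)
    assert np.all(curve.counts == 500)
    assert curve.density[0] > 0 and np.all(curve.density[1:] == 0)

    traj = ef.Trajectory("t", FPS, np.array([[150.0, 0.0]]))
    curve = ef.growth_curve(traj)
    jump = np.flatnonzero(np.diff(curve.counts, prepend=0))
    assert curve.a_grid[jump[0]] == 150.0


def test_growth_curve_uniform_density_and_conservation():
    # deterministic uniform grid of points over the arena
    g = np.linspace(-199.5, 199.5, 200)
    xx, yy = np.meshgrid(g, g)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    traj = ef.Trajectory("t", FPS, pts)
    curve = ef.growth_curve(traj, step_mm=10.0)
    assert curve.counts[-1] == pts.shape[0]  # conservation at a = 200
    rel = curve.density / curve.density.mean()
    assert np.all(np.abs(rel - 1) < 0.05)  # flat within grid discreteness
    with pytest.raises(ValueError):
        ef.growth_curve(traj, step_mm=0)


# ------------------------------------------------------------ find_boundary
def _step_occupancy_trajectory(a_step=135.0, seed=0, n_low=30_000, n_high=300_000):
    """Uniform low density inside [-a,a]^2, ~10x higher outside (sharp step)."""
    rng = np.random.default_rng(seed)
    low = rng.uniform(-a_step, a_step, size=(n_low, 2))
    high = []
    while sum(len(h) for h in high) < n_high:
        cand = rng.uniform(-200, 200, size=(n_high, 2))
        keep = np.max(np.abs(cand), axis=1) > a_step
        high.append(cand[keep])
    high = np.concatenate(high)[:n_high]
    return ef.Trajectory("t", FPS, np.vstack([low, high]))


def test_boundary_recovery_sharp_step_at_135():
    traj = _step_occupancy_trajectory()
    curve = ef.growth_curve(traj, step_mm=1.0)
    a = ef.find_boundary(curve)
    assert abs(a - 135.0) <= 1.0


def test_boundary_on_constructed_ramp_crossing_at_186():
    """Density 0 to a=150, linear ramp to a peak at 190: the 90%-prominence
    level is crossed exactly at a = 186."""
    a_grid = np.arange(1.0, 201.0)
    h = 4.0
    density = np.zeros_like(a_grid)
    ramp = (a_grid >= 150) & (a_grid <= 190)
    density[ramp] = (a_grid[ramp] - 150.0) / 40.0 * h
    density[a_grid > 190] = h * (1 - (a_grid[a_grid > 190] - 190.0) / 20.0)
    areas = (2 * a_grid) ** 2
    counts = np.cumsum(density * np.diff(areas, prepend=0.0))
    curve = GrowthCurve(a_grid, counts, density)
    assert ef.find_boundary(curve, 0.10) == pytest.approx(186.0, abs=1.0)
    # prominence_fraction -> 1 pushes the boundary to the peak's left base
    assert ef.find_boundary(curve, 1.0) <= 150.0


def test_boundary_errors_without_wall_peak():
    a_grid = np.arange(1.0, 201.0)
    flat = np.ones_like(a_grid)
    counts = np.cumsum(flat * np.diff((2 * a_grid) ** 2, prepend=0.0))
    with pytest.raises(ValueError, match="no occupancy peak"):
        ef.find_boundary(GrowthCurve(a_grid, counts, flat))
    # monotone decreasing (mass concentrated at the center)
    dec = np.linspace(5, 0.1, a_grid.size)
    counts = np.cumsum(dec * np.diff((2 * a_grid) ** 2, prepend=0.0))
    with pytest.raises(ValueError, match="no occupancy peak"):
        ef.find_boundary(GrowthCurve(a_grid, counts, dec))


def test_boundary_scale_equivariance():
    a_grid = np.arange(1.0, 201.0)
    h = 2.0
    density = np.exp(-0.5 * ((a_grid - 180.0) / 6.0) ** 2) * h
    counts = np.cumsum(density * np.diff((2 * a_grid) ** 2, prepend=0.0))
    a1 = ef.find_boundary(GrowthCurve(a_grid, counts, density))
    c = 0.5
    a2 = ef.find_boundary(GrowthCurve(a_grid * c, counts, density))
    assert a2 == pytest.approx(c * a1)


# ------------------------------------------------------------ zones/budgets
def test_assign_zones_inclusive_boundary():
    division = ef.standard_data_driven_division()  # a = 135
    traj = ef.Trajectory(
        "t", FPS, np.array([[0.0, 0.0], [190.0, 190.0], [135.0, 0.0]])
    )
    assert list(ef.assign_zones(traj, division)) == ["center", "perimeter", "center"]


def test_zone_division_areas():
    d = ZoneDivision("data_driven", 100.0)
    assert d.center_area_mm2 == pytest.approx(40_000)
    assert d.perimeter_area_mm2 == pytest.approx(120_000)
    with pytest.raises(ValueError):
        ZoneDivision("data_driven", 250.0)


def test_zone_metrics_fractions_and_per_area_ratio():
    # 50/50 split with a=100: per-unit-area ratio center/perimeter = 3
    division = ZoneDivision("data_driven", 100.0)
    n = 1000
    pts = np.vstack([
        np.tile([[50.0, 0.0]], (n // 2, 1)),
        np.tile([[150.0, 0.0]], (n // 2, 1)),
    ])
    traj = ef.Trajectory("t", FPS, pts)
    eth = make_ethogram([("walking", n // 2), ("pausing", n // 2)], FPS)
    zm = ef.zone_metrics(eth, traj, division)
    assert zm.fractions.sum() == pytest.approx(1.0)
    assert zm.fractions["center"] == pytest.approx(0.5)
    ratio = zm.per_unit_area["center"] / zm.per_unit_area["perimeter"]
    assert ratio == pytest.approx(3.0)
    # walking happened only in the center
    assert zm.movement_budgets["center"]["walking"] == pytest.approx(1.0)
    assert zm.movement_budgets["perimeter"]["walking"] == pytest.approx(0.0)


def test_zone_metrics_empty_zone_flagged():
    division = ef.traditional_division()
    traj = ef.Trajectory("t", FPS, np.zeros((100, 2)))
    eth = make_ethogram([("pausing", 100)], FPS)
    zm = ef.zone_metrics(eth, traj, division)
    assert zm.fractions["center"] == 1.0
    assert zm.empty_zones == ("perimeter",)
    assert zm.movement_budgets["perimeter"].empty
    assert zm.per_unit_area["center"] == pytest.approx(1.0 / division.center_area_mm2)


def test_center_time_ordering_recovered_on_synthetic_cohort(small_cohort):
    """Engineered thigmotaxis contrast: WT spends more center time than KO."""
    division = ef.standard_data_driven_division()
    means = {}
    for g in ("WT", "KO"):
        vals = [
            ef.zone_metrics(
                small_cohort.ethograms[s.animal_id],
                small_cohort.trajectories[s.animal_id],
                division,
            ).fractions["center"]
            for s in small_cohort.select(genotype=g)
        ]
        means[g] = float(np.mean(vals))
    assert means["WT"] > means["KO"]
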