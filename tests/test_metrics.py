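"""Metric operations against analytic and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from cardiocryo.geometry import REGION_TISSUE
from cardiocryo.metrics import (TransmuralProfile, adhesion_times,
                                extract_profile, ice_volume, isotherm_depth,
                                make_trace_fixture, max_cooling_rate_at,
                                rate_profile, schedule_windows)
from cardiocryo.protocols import Schedule
from cardiocryo.solver import FieldSeries

from conftest import regular_tet_mesh


def _series(mesh, times, fields, phases=None, contact=None):
    times = np.asarray(times, float)
    fields = np.asarray(fields, float)
    ct = contact if contact is not None else (times, np.zeros(len(times)))
    return FieldSeries(times=times, fields=fields, contact_times=np.asarray(ct[0]),
                       contact_T=np.asarray(ct[1]),
                       phases=phases or [("freeze", times[0], times[-1])],
                       energy=pd.DataFrame(), mesh=mesh, dt=1.0)


# ------------------------------------------------------------------ profile

def test_profile_reproduces_linear_field_exactly(coarse_mesh):
    """P1 interpolation is exact for fields linear in the coordinates,
    evaluated at the actual sample points of the metric path."""
    coef = np.array([0.4, -0.2, 7.5])
    a = -30.0
    T = a + coarse_mesh.vertices @ coef
    fs = _series(coarse_mesh, [0.0], [T])
    prof = extract_profile(fs, coarse_mesh, t_ref=0.0)
    direction = (prof.endpoint - prof.origin)
    direction = direction / np.linalg.norm(direction)
    pts = prof.origin[None, :] + prof.depths[:, None] * direction
    expected = a + pts @ coef
    # end samples are nudged ~1e-6 mm inside the tissue for robust location
    assert np.max(np.abs(prof.temps[0] - expected)) < 1e-4
    assert np.max(np.abs(prof.temps[0][1:-1] - expected[1:-1])) < 1e-10


def test_profile_constant_field(coarse_mesh):
    T = np.full(coarse_mesh.n_vertices, 36.5)
    fs = _series(coarse_mesh, [0.0], [T])
    prof = extract_profile(fs, coarse_mesh, t_ref=0.0)
    assert np.allclose(prof.temps, 36.5)
    assert prof.depths[0] == 0.0
    assert prof.depths[-1] == pytest.approx(
        coarse_mesh.config.tissue_thickness, abs=0.2)


def test_coldest_epicardial_point_on_axis_for_symmetric_field(coarse_mesh):
    """A transmurally-graded symmetric field puts the coldest epicardial point
    at the axis end of the transmural segment."""
    v = coarse_mesh.vertices
    T = 36.5 - 60.0 * np.exp(-(v[:, 0] ** 2 + v[:, 1] ** 2) / 20.0)
    fs = _series(coarse_mesh, [0.0], [T])
    prof = extract_profile(fs, coarse_mesh, t_ref=0.0)
    assert np.hypot(prof.endpoint[0], prof.endpoint[1]) < 1.0


# ----------------------------------------------------------------- isotherm

def test_isotherm_depth_basic():
    depths = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    temps = np.array([-40.0, -25.0, -10.0, 5.0, 20.0])
    assert isotherm_depth(depths, temps, -10.0) == pytest.approx(2.0)
    assert isotherm_depth(depths, temps, -17.5) == pytest.approx(1.5)


def test_isotherm_depth_all_warm_is_zero():
    assert isotherm_depth(np.arange(5.0), np.full(5, 20.0), -10.0) == 0.0


def test_isotherm_depth_all_cold_is_full_depth():
    assert isotherm_depth(np.arange(5.0), np.full(5, -30.0), -10.0) == 4.0


def test_isotherm_depth_uses_deepest_crossing():
    depths = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    temps = np.array([-40.0, -5.0, -15.0, -5.0, 10.0])  # non-monotone
    assert isotherm_depth(depths, temps, -10.0) == pytest.approx(2.5)


# --------------------------------------------------------------- ice volume

def test_ice_volume_fully_frozen_equals_region_volume(coarse_mesh, materials):
    T = np.full(coarse_mesh.n_vertices, -40.0)
    vols = coarse_mesh.tet_volumes()
    tissue = vols[coarse_mesh.region == REGION_TISSUE].sum()
    assert ice_volume(T, coarse_mesh, materials) == pytest.approx(tissue, rel=1e-12)


def test_ice_volume_warm_is_zero(coarse_mesh, materials):
    T = np.full(coarse_mesh.n_vertices, 36.5)
    assert ice_volume(T, coarse_mesh, materials) == 0.0


def test_ice_volume_clip_matches_monte_carlo():
    """Mixed tetrahedron: clipped sub-solidus fraction agrees with a 1e6-point
    Monte-Carlo estimate within 0.5 %."""
    mesh = regular_tet_mesh(edge=2.0)
    from cardiocryo.materials import default_materials
    mats = default_materials()
    rng = np.random.default_rng(42)
    T = np.array([-32.0, -14.0, -6.0, 8.0])  # 2 below, 2 above -10
    clip = ice_volume(T, mesh, mats) / mesh.tet_volumes()[0]
    w = rng.dirichlet(np.ones(4), size=1_000_000)
    mc = float(np.mean(w @ T < -10.0))
    assert abs(clip - mc) < 0.005


def test_ice_volume_fraction_method_bounds(coarse_mesh, materials):
    rng = np.random.default_rng(0)
    T = rng.uniform(-30, 10, coarse_mesh.n_vertices)
    clip = ice_volume(T, coarse_mesh, materials, method="clip")
    frac = ice_volume(T, coarse_mesh, materials, method="fraction")
    assert clip > 0 and frac > 0
    assert abs(clip - frac) / clip < 0.5  # crude method stays in the ballpark


# ---------------------------------------------------------------- adhesion

def test_adhesion_crossing_interpolation():
    t = np.arange(0.0, 30.0)
    y = -40.0 + 2.0 * t  # crosses -10 at t=15, 0 at t=20
    ts, tl = adhesion_times(t, y, thaw_start=5.0)
    assert ts == pytest.approx(10.0)
    assert tl == pytest.approx(15.0)


def test_adhesion_already_released():
    t = np.arange(0.0, 10.0)
    y = np.full_like(t, -5.0)
    ts, tl = adhesion_times(t, y, thaw_start=0.0)
    assert ts == 0.0
    assert np.isnan(tl)  # never reaches 0 degC


def test_adhesion_not_reached_is_nan():
    t = np.arange(0.0, 10.0)
    y = np.full_like(t, -60.0)
    ts, tl = adhesion_times(t, y, thaw_start=0.0)
    assert np.isnan(ts) and np.isnan(tl)


# ------------------------------------------------------------- rate profile

def _fixture_three_phase():
    """Freeze to -60, thaw to -10, refreeze twice as steep: CR1=2, TR1=5,
    CR2=4 degC/s by hand evaluation of the rate definition."""
    pts = [(0.0, 20.0), (40.0, -60.0), (50.0, -10.0), (65.0, -70.0)]
    sched = Schedule("fix", (("freeze", 40.0), ("thaw", 10.0), ("freeze", 15.0)))
    return make_trace_fixture({0.0: pts, 1.0: pts}), sched


def test_rate_profile_hand_computed_values():
    prof, sched = _fixture_three_phase()
    rp = rate_profile(prof, sched, depth_grid=np.array([0.0]))
    assert rp.min_T1F[0] == pytest.approx(-60.0)
    assert rp.max_T1T[0] == pytest.approx(-10.0)
    assert rp.T_comp_lo[0] == pytest.approx(-50.0)
    assert rp.T_comp_hi[0] == pytest.approx(-20.0)
    assert rp.CR1[0] == pytest.approx(2.0, rel=1e-12)
    assert rp.TR1[0] == pytest.approx(5.0, rel=1e-12)
    assert rp.CR2[0] == pytest.approx(4.0, rel=1e-12)
    assert rp.CR_increase[0] == pytest.approx(2.0, rel=1e-12)


def test_rate_profile_constant_trace_undefined():
    pts = [(0.0, -30.0), (40.0, -30.0), (50.0, -30.0), (65.0, -30.0)]
    prof = make_trace_fixture({0.0: pts})
    sched = Schedule("fix", (("freeze", 40.0), ("thaw", 10.0), ("freeze", 15.0)))
    rp = rate_profile(prof, sched, depth_grid=np.array([0.0]))
    assert rp.T_rise[0] == 0.0
    assert np.isnan(rp.CR1[0]) and np.isnan(rp.CR2[0]) and np.isnan(rp.TR1[0])


def test_rate_profile_single_phase_leaves_rates_undefined():
    pts = [(0.0, 20.0), (40.0, -60.0)]
    prof = make_trace_fixture({0.0: pts})
    sched = Schedule("fix", (("freeze", 40.0),))
    rp = rate_profile(prof, sched, depth_grid=np.array([0.0]))
    assert rp.min_T1F[0] == pytest.approx(-60.0)
    assert np.isnan(rp.CR2[0]) and np.isnan(rp.TR1[0])


def test_rate_profile_time_shift_invariance():
    prof, sched = _fixture_three_phase()
    shift = 37.0
    pts = [(t + shift, T) for t, T in
           [(0.0, 20.0), (40.0, -60.0), (50.0, -10.0), (65.0, -70.0)]]
    prof2 = make_trace_fixture({0.0: pts, 1.0: pts})
    windows = [(m, a + shift, b + shift) for m, a, b in schedule_windows(sched)]
    rp1 = rate_profile(prof, sched, depth_grid=np.array([0.0]))
    rp2 = rate_profile(prof2, windows, depth_grid=np.array([0.0]))
    for f in ("CR1", "CR2", "TR1"):
        assert getattr(rp1, f)[0] == pytest.approx(getattr(rp2, f)[0], rel=1e-12)


def test_rate_profile_resampling_invariance():
    """Uniform resampling finer than the breakpoints leaves rates unchanged."""
    prof, sched = _fixture_three_phase()
    fine_t = np.union1d(prof.times, np.arange(0.0, 65.0, 0.25))
    fine = TransmuralProfile(depths=prof.depths, times=fine_t,
                             temps=np.column_stack([
                                 np.interp(fine_t, prof.times, prof.temps[:, j])
                                 for j in range(prof.temps.shape[1])]))
    rp1 = rate_profile(prof, sched, depth_grid=np.array([0.0]))
    rp2 = rate_profile(fine, sched, depth_grid=np.array([0.0]))
    for f in ("CR1", "CR2", "TR1"):
        assert getattr(rp1, f)[0] == pytest.approx(getattr(rp2, f)[0], rel=1e-12)


def test_rate_profile_matches_independent_oracle():
    """Random monotone-per-phase fixtures: the implementation agrees with a
    closed-form oracle that inverts each phase trace directly."""
    rng = np.random.default_rng(7)
    for _ in range(20):
        m1 = rng.uniform(-85, -30)
        mx = rng.uniform(m1 + 10, -2.0)
        m2 = rng.uniform(-85, mx - 10)
        t1, t2, t3 = 30.0, 30.0 + rng.uniform(5, 20), 0.0
        t3 = t2 + rng.uniform(10, 40)
        pts = [(0.0, 36.5), (rng.uniform(5, 25), rng.uniform(m1, 30.0)),
               (t1, m1), (t2, mx), (t3, m2)]
        pts = sorted(pts)
        prof = make_trace_fixture({0.0: pts})
        sched_windows = [("freeze", 0.0, t1), ("thaw", t1, t2), ("freeze", t2, t3)]
        rp = rate_profile(prof, sched_windows, depth_grid=np.array([0.0]))

        # oracle: piecewise-linear inversion per phase
        def t_at(level, a, b, pts=pts):
            for (ta, ya), (tb, yb) in zip(pts[:-1], pts[1:]):
                lo_t = max(ta, a)
                hi_t = min(tb, b)
                if hi_t <= lo_t or ya == yb:
                    continue
                yl = ya + (yb - ya) * (lo_t - ta) / (tb - ta)
                yh = ya + (yb - ya) * (hi_t - ta) / (tb - ta)
                if min(yl, yh) - 1e-12 <= level <= max(yl, yh) + 1e-12:
                    return lo_t + (level - yl) * (hi_t - lo_t) / (yh - yl)
            return np.nan
        rise = mx - m1
        lo, hi = m1 + 0.2 * rise, m1 + 0.8 * rise
        span = 0.6 * rise
        cr1 = span / (t_at(lo, 0, t1) - t_at(hi, 0, t1))
        tr1 = span / (t_at(hi, t1, t2) - t_at(lo, t1, t2))
        cr2 = span / (t_at(lo, t2, t3) - t_at(hi, t2, t3))
        for got, want in ((rp.CR1[0], cr1), (rp.TR1[0], tr1), (rp.CR2[0], cr2)):
            if np.isnan(want):  # phase does not traverse T_comp: undefined
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, rel=1e-9)


def test_trace_fixture_rejects_unsorted_breakpoints():
    with pytest.raises(ValueError):
        make_trace_fixture({0.0: [(5.0, 0.0), (1.0, -10.0)]})


# ------------------------------------------------------------- cooling rate

def test_max_cooling_rate_stationary_is_zero(coarse_mesh):
    T = np.full(coarse_mesh.n_vertices, 10.0)
    fs = _series(coarse_mesh, [0.0, 1.0, 2.0], [T, T, T])
    assert max_cooling_rate_at(fs, 1.0) == 0.0


def test_max_cooling_rate_linear_cooling(coarse_mesh):
    T0 = np.full(coarse_mesh.n_vertices, 10.0)
    fs = _series(coarse_mesh, [0.0, 1.0, 2.0],
                 [T0, T0 - 0.5, T0 - 1.0])
    assert max_cooling_rate_at(fs, 1.0) == pytest.approx(-0.5)
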