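"""Solver verification: refrigerant law, assembly, analytic heat-conduction
oracles, schedule behaviour and calibration."""

import math

import numpy as np
import pytest
from scipy.special import erf

from cardiocryo.geometry import GeometryConfig, build_model_mesh
from cardiocryo.materials import BODY_TEMPERATURE_C
from cardiocryo.solver import (BioheatSystem, BoundarySpec, CalibrationError,
                               RefrigerantParams, RobinBC, SolverState,
                               calibrate_refrigerant, refrigerant_flux,
                               run_schedule)

from conftest import (UniformMaterials, box_mesh, constant_material,
                      regular_tet_mesh)


class Sched:
    def __init__(self, *phases):
        self.phases = list(phases)
    name = "test"


# -------------------------------------------------------------- refrigerant

def test_refrigerant_flux_zero_at_valve_open():
    p = RefrigerantParams(h_steady=1e4)
    assert refrigerant_flux(0.0, -30.0, p, "freeze") == pytest.approx(0.0)


def test_refrigerant_flux_zero_at_reservoir_temperature():
    p = RefrigerantParams(h_steady=1e4)
    assert refrigerant_flux(1e3, p.T_ref, p, "freeze") == pytest.approx(0.0)


def test_refrigerant_drain_exponential_decay():
    p = RefrigerantParams(h_steady=1e4)
    q0 = refrigerant_flux(0.0, -30.0, p, "thaw", h_switch_frac=0.8)
    q_tau = refrigerant_flux(p.tau_drain, -30.0, p, "thaw", h_switch_frac=0.8)
    assert q_tau == pytest.approx(q0 * math.exp(-1), rel=1e-12)


def test_refrigerant_flux_sign():
    p = RefrigerantParams(h_steady=1e4)
    assert refrigerant_flux(50.0, -30.0, p, "freeze") > 0


# ----------------------------------------------------------------- assembly

def _system(mesh, m, robin):
    return BioheatSystem(mesh, UniformMaterials(m), BoundarySpec(
        robin=robin, refrigerant=RefrigerantParams(h_steady=1.0)))


def test_single_element_stiffness_matches_hand_computation():
    """P1 stiffness of one tetrahedron equals the analytic grad.grad matrix."""
    mesh = regular_tet_mesh(edge=2.0)
    m = constant_material(lam=1.7)
    sys_ = _system(mesh, m, {})
    v = mesh.vertices * 1e-3
    t = mesh.tets[0]
    J = np.column_stack([v[t[i]] - v[t[0]] for i in (1, 2, 3)])
    V = np.linalg.det(J) / 6.0
    g123 = np.linalg.inv(J)
    grads = np.vstack([-g123.sum(axis=0), g123])
    K_hand = m.lambda_liquid * V * grads @ grads.T
    M, Kdata, *_ = sys_.assemble(np.full(4, 20.0))
    K = sys_._csr(Kdata).toarray()
    assert np.allclose(K, K_hand, rtol=1e-12)
    assert np.allclose(K.sum(axis=1), 0.0, atol=1e-18)  # zero row sums


def test_stiffness_linear_in_conductivity():
    mesh = regular_tet_mesh()
    s1 = _system(mesh, constant_material(lam=0.5), {})
    s2 = _system(mesh, constant_material(lam=1.0), {})
    T = np.full(4, 20.0)
    K1 = s1.assemble(T)[1]
    K2 = s2.assemble(T)[1]
    assert np.allclose(K2, 2 * K1)


def test_equilibrium_preserved():
    """Uniform field at the Robin external temperature with no sources is a
    fixed point of the stepper."""
    mesh = box_mesh(2, 2, 6, 2, 2, 6)
    m = constant_material()
    sys_ = _system(mesh, m, {"a": RobinBC(1500.0, 36.5), "c": RobinBC(200.0, 36.5)})
    state = SolverState(T=np.full(sys_.n, 36.5))
    out = sys_.step(state, 0.1)
    assert np.allclose(out.T, 36.5, atol=1e-12)


def test_crank_nicolson_second_order():
    """Single-DOF exponential relaxation: a uniform regular tetrahedron with
    Robin faces stays uniform and follows dT/dt = -k (T - T_ext); the CN error
    at fixed horizon scales as dt^2."""
    mesh = regular_tet_mesh(edge=1.0)
    m = constant_material(rho=1000.0, c=1000.0, lam=1.0)
    h, Text, T0 = 500.0, 20.0, 36.5
    sys_ = _system(mesh, m, {"a": RobinBC(h, Text)})
    # analytic rate: per node, h * (face area) / (rho c V / 4)
    a_node = sys_.robin_nodal["a"][0]
    vol = mesh.tet_volumes()[0] * 1e-9
    k = h * a_node / (m.rho * m.c_liquid * vol / 4.0)
    horizon = 2.0 / k
    errors = []
    dts = [horizon / 8, horizon / 16, horizon / 32]
    for dt in dts:
        state = SolverState(T=np.full(4, T0))
        n = int(round(horizon / dt))
        for _ in range(n):
            state = sys_.step(state, dt)
        exact = Text + (T0 - Text) * math.exp(-k * n * dt)
        errors.append(abs(state.T[0] - exact))
    order = np.log2(np.array(errors[:-1]) / np.array(errors[1:]))
    assert np.all(order > 1.8) and np.all(order < 2.2)


def test_steady_rod_linear_profile():
    """Robin-ended insulated rod relaxes to the closed-form linear steady
    conduction profile T(z) = T1 + q/h + q z / lambda with
    q = (T2 - T1) / (2/h + L/lambda)."""
    mesh = box_mesh(1, 1, 5, 1, 1, 25)
    m = constant_material(rho=1000.0, c=50.0, lam=0.5)  # fast diffusion
    T1, T2, h = 0.0, 50.0, 2000.0
    L = 5e-3
    sys_ = _system(mesh, m, {"a": RobinBC(h, T1), "c": RobinBC(h, T2)})
    state = SolverState(T=np.full(sys_.n, 25.0))
    for _ in range(400):
        state = sys_.step(state, 0.05)
    q = (T2 - T1) / (2.0 / h + L / m.lambda_liquid)
    z = mesh.vertices[:, 2] * 1e-3
    expected = T1 + q / h + q * z / m.lambda_liquid
    assert np.max(np.abs(state.T - expected)) < 0.05


def test_semi_infinite_slab_erf_solution():
    """Sudden surface temperature drop: interior matches the error-function
    similarity solution within 2 % of the applied temperature step."""
    mesh = box_mesh(1, 1, 20, 1, 1, 100)
    m = constant_material(rho=1060.0, c=3600.0, lam=0.5)
    T0, Ts = 36.5, -50.0
    sys_ = _system(mesh, m, {"a": RobinBC(1e7, Ts)})
    alpha = m.lambda_liquid / (m.rho * m.c_liquid)
    state = SolverState(T=np.full(sys_.n, T0))
    dt = 0.05
    checks = {10.0: [1.0, 2.0, 3.0], 30.0: [1.0, 2.0, 4.0, 6.0]}
    t = 0.0
    z = mesh.vertices[:, 2]
    scale = T0 - Ts
    for _ in range(600):
        state = sys_.step(state, dt)
        t += dt
        for t_chk, depths in checks.items():
            if abs(t - t_chk) < dt / 2:
                for d in depths:
                    nodes = np.isclose(z, d)
                    sim = state.T[nodes].mean()
                    exact = Ts + scale * erf((d * 1e-3) / (2 * math.sqrt(alpha * t)))
                    assert abs(sim - exact) < 0.02 * scale, (t_chk, d, sim, exact)


def test_maximum_principle():
    """Without sources or phase change the field stays within the hull of
    initial and boundary temperatures."""
    mesh = box_mesh(4, 4, 6, 4, 4, 6)
    m = constant_material()
    sys_ = _system(mesh, m, {"a": RobinBC(2000.0, -80.0), "c": RobinBC(200.0, 36.5)})
    state = SolverState(T=np.full(sys_.n, 36.5))
    for _ in range(200):
        state = sys_.step(state, 0.25)
        assert state.T.min() >= -80.0 - 0.1
        assert state.T.max() <= 36.5 + 0.1


# ------------------------------------------------------------ schedule runs

def test_thaw_only_schedule_stays_at_body_temperature(coarse_mesh, materials,
                                                      boundaries):
    fs = run_schedule(coarse_mesh, materials, boundaries,
                      Sched(("thaw", 10.0)), dt=0.5, store_every=5.0)
    assert np.all(np.abs(fs.fields[-1] - BODY_TEMPERATURE_C) < 0.1)


def test_contact_monotone_during_freeze_and_thaw(coarse_mesh, materials,
                                                 boundaries):
    fs = run_schedule(coarse_mesh, materials, boundaries,
                      Sched(("freeze", 60.0), ("thaw", 30.0)),
                      dt=0.2, store_every=10.0)
    t = fs.contact_times
    y = fs.contact_T
    # cooling after the fill ramp has mostly completed (3 time constants)
    tau = boundaries.refrigerant.tau_fill
    freeze = (t > 3 * tau) & (t <= 60.0)
    assert np.all(np.diff(y[freeze]) <= 1e-9)
    thaw = t > 62.0  # past the drain holdover
    assert np.all(np.diff(y[thaw]) >= -1e-9)


def test_run_is_deterministic(coarse_mesh, materials, boundaries):
    runs = [run_schedule(coarse_mesh, materials, boundaries,
                         Sched(("freeze", 5.0)), dt=0.5, store_every=1.0)
            for _ in range(2)]
    assert np.array_equal(runs[0].fields, runs[1].fields)
    assert np.array_equal(runs[0].contact_T, runs[1].contact_T)


def test_energy_ledger_closes(coarse_mesh, materials, boundaries):
    fs = run_schedule(coarse_mesh, materials, boundaries,
                      Sched(("freeze", 30.0), ("thaw", 10.0)),
                      dt=0.2, store_every=10.0)
    E = fs.energy.iloc[-1]
    exchanged = abs(E.E_boundary_J) + abs(E.E_sources_J)
    assert abs(E.E_stored_J - (E.E_boundary_J + E.E_sources_J)) <= 0.01 * exchanged


# -------------------------------------------------------------- calibration

def test_calibration_monotonicity(materials):
    """Stronger refrigerant coupling reaches colder minima (bracket check)."""
    mesh = build_model_mesh(GeometryConfig(resolution=2.0, lateral_extent=8.0))
    from cardiocryo.geometry import REGION_TISSUE
    nodes = np.unique(mesh.tets[mesh.region == REGION_TISSUE])
    mins = []
    for h in (5e3, 5e4):
        b = BoundarySpec.main_defaults(refrigerant=RefrigerantParams(h_steady=h))
        fs = run_schedule(mesh, materials, b, Sched(("freeze", 40.0)),
                          dt=0.2, store_every=40.0)
        mins.append(fs.fields[-1][nodes].min())
    assert mins[1] < mins[0]


def test_calibration_rejects_unreachable_target(coarse_mesh, materials,
                                                boundaries):
    with pytest.raises(CalibrationError):
        calibrate_refrigerant(coarse_mesh, materials, boundaries,
                              target_min_tissue_T=boundaries.refrigerant.T_ref,
                              freeze_duration=10.0)


def test_calibration_converges_on_coarse_model(materials):
    mesh = build_model_mesh(GeometryConfig(resolution=2.0, lateral_extent=8.0))
    b = BoundarySpec.main_defaults()
    params, achieved = calibrate_refrigerant(mesh, materials, b, -60.0,
                                             freeze_duration=30.0, dt=0.2)
    assert abs(achieved + 60.0) <= 0.5
    assert params.h_steady > 0
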