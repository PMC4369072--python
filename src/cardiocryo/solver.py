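"""P1 finite-element solver for the Pennes bioheat equation with phase change.

The transient problem

    rho C(T) dT/dt = div(lambda(T) grad T) + Q_p(T) + Q_m(T)

is discretised with linear tetrahedral elements (lumped capacity) and advanced
with the Crank-Nicolson scheme.  Material nonlinearity is handled by lagging
the coefficients at the previous time level, giving one symmetric positive
definite sparse solve per step (conjugate gradients with Jacobi
preconditioning, relative residual 1e-8).

Boundary conditions
-------------------
Far-field surfaces (labels a, b, c) carry Robin ("Cauchy") conditions
``q = alpha (T - T_ext)``.  The refrigerant chamber surfaces (labels d, e, f)
carry a Robin law to the boiling-refrigerant reservoir modulated by a
time-dependent envelope: during a freeze the convective coefficient ramps up
as ``1 - exp(-t/tau_fill)`` while the supply lines fill; after deactivation the
flux decays from its switch-off value with time constant ``tau_drain`` while
the remaining refrigerant drains.  The single free magnitude ``h_steady`` is
fixed by :func:`calibrate_refrigerant` against a prescribed minimum tissue
temperature.

The per-step energy ledger accounts stored enthalpy change against boundary
and volumetric source fluxes; for the discrete scheme the balance closes to
the linear-solver residual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import (REGION_APPLICATOR, REGION_BLOOD, REGION_TISSUE,
                       ConfigurationError, ModelMesh)
from .materials import (BODY_TEMPERATURE_C, MaterialModel, effective_heat_capacity,
                        liquid_fraction, thermal_conductivity)

MM = 1e-3  # geometry is stored in mm; the solver works in SI


class SolverError(RuntimeError):
    """Linear solve or time-integration failure."""


class CalibrationError(RuntimeError):
    """Refrigerant calibration could not bracket or reach the target."""


@dataclass(frozen=True)
class RobinBC:
    """Convective (Cauchy) boundary condition q = alpha (T - T_ext)."""
    alpha: float          # W m^-2 degC^-1
    T_ext: float          # degC

    def __post_init__(self):
        if self.alpha < 0:
            raise ConfigurationError("Robin alpha must be >= 0")


@dataclass(frozen=True)
class RefrigerantParams:
    """Phenomenological three-phase refrigerant boundary law (N2O boils at
    about -88 degC at catheter working pressure)."""
    T_ref: float = -88.0      # refrigerant boil temperature, degC
    h_steady: float = 1.5e4   # steady convective coefficient, W m^-2 degC^-1
    tau_fill: float = 10.0    # supply-line fill time constant, s
    tau_drain: float = 2.0    # drain decay time constant, s

    def __post_init__(self):
        if self.tau_fill <= 0 or self.tau_drain <= 0 or self.h_steady <= 0:
            raise ConfigurationError("refrigerant time constants and h_steady must be > 0")
        if self.T_ref >= -80.0:
            raise ConfigurationError("T_ref must be below -80 degC")


@dataclass(frozen=True)
class BoundarySpec:
    """Robin data for far-field labels a/b/c plus the refrigerant law on d/e/f."""
    robin: Dict[str, RobinBC]
    refrigerant: RefrigerantParams = field(default_factory=RefrigerantParams)

    @classmethod
    def main_defaults(cls, refrigerant: Optional[RefrigerantParams] = None) -> "BoundarySpec":
        """Closed-chest defaults: strongly convective blood/tissue far field,
        epicardium coupled to the body at alpha = 200 W m^-2 degC^-1."""
        return cls(robin={"a": RobinBC(1500.0, BODY_TEMPERATURE_C),
                          "b": RobinBC(1500.0, BODY_TEMPERATURE_C),
                          "c": RobinBC(200.0, BODY_TEMPERATURE_C)},
                   refrigerant=refrigerant or RefrigerantParams())

    @classmethod
    def wood_defaults(cls, refrigerant: Optional[RefrigerantParams] = None) -> "BoundarySpec":
        """In-vitro bench: water at rest around the preparation (alpha = 700,
        37 degC bath)."""
        return cls(robin={"a": RobinBC(700.0, 37.0),
                          "b": RobinBC(700.0, 37.0),
                          "c": RobinBC(200.0, BODY_TEMPERATURE_C)},
                   refrigerant=refrigerant or RefrigerantParams())


def fill_envelope(t_phase: float, p: RefrigerantParams) -> float:
    """Fraction of steady cooling power reached ``t_phase`` s into a freeze."""
    return 1.0 - math.exp(-max(t_phase, 0.0) / p.tau_fill)


def drain_envelope(t_phase: float, p: RefrigerantParams, h_switch_frac: float) -> float:
    """Envelope during refrigerant drain, decaying from its switch-off value."""
    return h_switch_frac * math.exp(-max(t_phase, 0.0) / p.tau_drain)


def refrigerant_flux(t_phase: float, T_surface, p: RefrigerantParams,
                     mode: str, h_switch_frac: float = 1.0):
    """Outward heat flux (W m^-2) through a refrigerant chamber surface.

    ``mode='freeze'``: flux ramps in with the fill envelope.
    ``mode='thaw'``: flux decays from its value at switch-off (whose envelope
    fraction is ``h_switch_frac``) with time constant ``tau_drain``.
    Positive flux extracts heat whenever the surface is warmer than T_ref.
    """
    if mode == "freeze":
        env = fill_envelope(t_phase, p)
    elif mode == "thaw":
        env = drain_envelope(t_phase, p, h_switch_frac)
    else:
        raise ValueError(f"unknown refrigerant mode {mode!r}")
    return env * p.h_steady * (np.asarray(T_surface, float) - p.T_ref)


@dataclass
class SolverState:
    """Nodal temperature field plus time/phase bookkeeping."""
    T: np.ndarray
    time: float = 0.0
    mode: str = "freeze"
    t_phase: float = 0.0
    h_switch_frac: float = 1.0
    E_stored: float = 0.0
    E_boundary: float = 0.0
    E_sources: float = 0.0

    @property
    def energy_residual(self) -> float:
        return self.E_stored - (self.E_boundary + self.E_sources)


class BioheatSystem:
    """Precomputed P1 operators on a tagged mesh.

    Geometric element matrices, the global sparsity pattern and boundary
    lumped-area vectors are assembled once; per step only the material
    coefficient scalings are recomputed.
    """

    def __init__(self, mesh: ModelMesh, materials: MaterialModel,
                 boundaries: BoundarySpec):
        self.mesh = mesh
        self.materials = materials
        self.boundaries = boundaries

        verts = mesh.vertices * MM
        tets = mesh.tets
        n = mesh.n_vertices
        self.n = n

        # element volumes and shape-function gradients
        v0 = verts[tets[:, 0]]
        J = np.stack([verts[tets[:, i]] - v0 for i in (1, 2, 3)], axis=2)  # (m,3,3)
        detJ = np.linalg.det(J)
        if np.any(detJ <= 0):
            raise SolverError("mesh contains non-positively oriented tetrahedra")
        self.volumes = detJ / 6.0  # m^3
        # gradients of barycentric coordinates: rows of inv(J) give grads of
        # local coords 1..3; grad of coordinate 0 is minus their sum
        g123 = np.linalg.inv(J)  # (m,3,3)
        g0 = -g123.sum(axis=1, keepdims=True)
        grads = np.concatenate([g0, g123], axis=1)  # (m,4,3)
        # geometric stiffness: V * grad_i . grad_j
        self.Ge = np.einsum("mid,mjd->mij", grads, grads) * self.volumes[:, None, None]

        rows = np.repeat(tets, 4, axis=1).ravel()
        cols = np.tile(tets, (1, 4)).ravel()
        key = rows.astype(np.int64) * n + cols
        ukeys, inv = np.unique(key, return_inverse=True)
        self.scatter = inv
        self.nnz = len(ukeys)
        csr_rows = (ukeys // n).astype(np.int32)
        self.csr_indices = (ukeys % n).astype(np.int32)
        self.csr_indptr = np.concatenate([[0], np.cumsum(np.bincount(csr_rows, minlength=n))]).astype(np.int32)
        self.diag_pos = np.searchsorted(ukeys, np.arange(n, dtype=np.int64) * n + np.arange(n))

        # region-wise element bookkeeping
        self.region = mesh.region
        self.region_codes = (REGION_TISSUE, REGION_BLOOD, REGION_APPLICATOR)
        self.tet_flat = tets.ravel()

        # lumped boundary areas per label (m^2 per node)
        self.robin_nodal: Dict[str, np.ndarray] = {}
        for label in ("a", "b", "c"):
            self.robin_nodal[label] = self._lumped_areas(mesh.facets_with_label(label))
        ref = np.zeros(n)
        for label in ("d", "e", "f"):
            ref += self._lumped_areas(mesh.facets_with_label(label))
        self.refrigerant_nodal = ref

        # contact-patch area weights (tissue surface under the tip)
        self.contact_weights = self._lumped_areas(mesh.contact_facets)
        wsum = self.contact_weights.sum()
        if wsum > 0:
            self.contact_weights = self.contact_weights / wsum

        self.tissue_nodes = np.unique(tets[mesh.region == REGION_TISSUE])

    def _lumped_areas(self, facets: np.ndarray) -> np.ndarray:
        out = np.zeros(self.n)
        if len(facets) == 0:
            return out
        areas = self.mesh.facet_areas(facets) * MM * MM
        np.add.at(out, facets.ravel(), np.repeat(areas / 3.0, 3))
        return out

    def contact_mean(self, T: np.ndarray) -> float:
        return float(self.contact_weights @ T)

    # -- per-step operator evaluation (coefficients lagged at T) --------------

    def _element_coeffs(self, T: np.ndarray):
        Tm = T[self.mesh.tets].mean(axis=1)
        lam = np.empty_like(Tm)
        C = np.empty_like(Tm)
        k_perf = np.zeros_like(Tm)
        q_src = np.zeros_like(Tm)
        Tb = np.zeros_like(Tm)
        for code in self.region_codes:
            m = self.materials.region(code)
            sel = self.region == code
            lam[sel] = thermal_conductivity(Tm[sel], m)
            C[sel] = effective_heat_capacity(Tm[sel], m)
            f = liquid_fraction(Tm[sel], m)
            k_perf[sel] = f * m.perfusion_coeff
            q_src[sel] = f * m.q_metabolic
            Tb[sel] = m.T_body
        return lam, C, k_perf, q_src, Tb

    def assemble(self, T: np.ndarray):
        """Operators for the bioheat equation with coefficients at field T.

        Returns ``(M, Kdata, D_vol, load_vol, D_rob, load_rob)``: lumped
        capacity diagonal M (J degC^-1 per node), CSR data of the conduction
        stiffness, implicit-perfusion reaction diagonal and source load
        (volumetric), and the far-field Robin reaction diagonal and load.  The
        refrigerant contribution is added separately because its envelope is
        time-dependent.
        """
        lam, C, k_perf, q_src, Tb = self._element_coeffs(T)
        Kdata = np.bincount(self.scatter,
                            weights=(lam[:, None, None] * self.Ge).ravel(),
                            minlength=self.nnz)
        quarter = self.volumes / 4.0
        M = np.bincount(self.tet_flat, weights=np.repeat(C * quarter, 4),
                        minlength=self.n)
        D_vol = np.bincount(self.tet_flat, weights=np.repeat(k_perf * quarter, 4),
                            minlength=self.n)
        load_vol = np.bincount(self.tet_flat,
                               weights=np.repeat((k_perf * Tb + q_src) * quarter, 4),
                               minlength=self.n)
        D_rob = np.zeros(self.n)
        load_rob = np.zeros(self.n)
        for label, bc in self.boundaries.robin.items():
            a = self.robin_nodal.get(label)
            if a is None or bc.alpha == 0:
                continue
            D_rob += bc.alpha * a
            load_rob += bc.alpha * bc.T_ext * a
        return M, Kdata, D_vol, load_vol, D_rob, load_rob

    def _csr(self, data: np.ndarray) -> sp.csr_matrix:
        return sp.csr_matrix((data, self.csr_indices, self.csr_indptr),
                             shape=(self.n, self.n))

    def step(self, state: SolverState, dt: float) -> SolverState:
        """Advance one Crank-Nicolson step, updating the energy ledger."""
        if dt <= 0:
            raise SolverError("dt must be > 0")
        p = self.boundaries.refrigerant
        t_mid = state.t_phase + dt / 2.0
        if state.mode == "freeze":
            h_t = fill_envelope(t_mid, p) * p.h_steady
        else:
            h_t = drain_envelope(t_mid, p, state.h_switch_frac) * p.h_steady

        T = state.T
        M, Kdata, D_vol, load_vol, D_rob, load_rob = self.assemble(T)
        D_full = D_vol + D_rob + h_t * self.refrigerant_nodal
        load_full = load_vol + load_rob + h_t * p.T_ref * self.refrigerant_nodal

        A = self._csr(0.5 * Kdata)
        A.data[self.diag_pos] += M / dt + 0.5 * D_full

        K = self._csr(Kdata)
        rhs = M / dt * T - 0.5 * (K @ T + D_full * T) + load_full

        diagA = A.data[self.diag_pos].copy()
        precond = spla.LinearOperator((self.n, self.n), matvec=lambda x: x / diagA)
        T_new, info = spla.cg(A, rhs, x0=T, rtol=1e-10, atol=0.0, M=precond,
                              maxiter=500)
        if info != 0:
            res = np.linalg.norm(A @ T_new - rhs) / np.linalg.norm(rhs)
            raise SolverError(f"CG failed to converge (info={info}, rel. residual {res:.2e})")
        if not np.all(np.isfinite(T_new)):
            raise SolverError("non-finite temperatures after step")

        T_half = 0.5 * (T + T_new)
        E_stored = float(M @ (T_new - T))
        # boundary ledger: Robin far field + refrigerant flux at the CN level
        E_boundary = dt * (float(load_rob @ np.ones(self.n)) - float(D_rob @ T_half))
        E_boundary += dt * h_t * float(self.refrigerant_nodal @ (p.T_ref - T_half))
        # volumetric: implicit perfusion + metabolic heat
        E_sources = dt * (float(load_vol.sum()) - float(D_vol @ T_half))

        return SolverState(
            T=T_new, time=state.time + dt, mode=state.mode,
            t_phase=state.t_phase + dt, h_switch_frac=state.h_switch_frac,
            E_stored=state.E_stored + E_stored,
            E_boundary=state.E_boundary + E_boundary,
            E_sources=state.E_sources + E_sources,
        )


@dataclass
class FieldSeries:
    """Stored temperature fields and the contact-patch temperature trace."""
    times: np.ndarray              # stored snapshot times, s
    fields: np.ndarray             # (n_times, n_nodes) temperatures, degC
    contact_times: np.ndarray      # per-step times, s
    contact_T: np.ndarray          # contact-patch area-weighted mean, degC
    phases: List[Tuple[str, float, float]]   # (mode, t_start, t_end)
    energy: pd.DataFrame           # cumulative ledger at stored times
    mesh: ModelMesh
    dt: float

    def field_at(self, t: float) -> np.ndarray:
        """Linear interpolation between stored snapshots."""
        times = self.times
        if t <= times[0]:
            return self.fields[0]
        if t >= times[-1]:
            return self.fields[-1]
        i = int(np.searchsorted(times, t)) - 1
        w = (t - times[i]) / (times[i + 1] - times[i])
        return (1 - w) * self.fields[i] + w * self.fields[i + 1]

    def phase_end(self, index: int) -> float:
        return self.phases[index][2]

    def thaw_starts(self) -> List[float]:
        return [p[1] for p in self.phases if p[0] == "thaw"]


def run_schedule(mesh: ModelMesh, materials: MaterialModel,
                 boundaries: BoundarySpec, schedule,
                 dt: float = 0.1, store_every: float = 1.0,
                 T0: Optional[float] = None,
                 progress=None) -> FieldSeries:
    """Advance an alternating freeze/thaw schedule from a uniform body-
    temperature field and record snapshots plus the contact trace.

    ``schedule`` is a :class:`~cardiocryo.protocols.Schedule` or any object
    with a ``phases`` attribute of ``(mode, duration)`` pairs.  Snapshots are
    stored every ``store_every`` seconds and at every phase boundary.  The run
    is fully deterministic.
    """
    system = BioheatSystem(mesh, materials, boundaries)
    T_init = BODY_TEMPERATURE_C if T0 is None else T0
    state = SolverState(T=np.full(system.n, float(T_init)))

    times = [0.0]
    fields = [state.T.copy()]
    ctimes = [0.0]
    ctrace = [system.contact_mean(state.T)]
    ledger_rows = [(0.0, 0.0, 0.0, 0.0)]
    phase_spans = []

    store_steps = max(1, int(round(store_every / dt)))
    t_global = 0.0
    h_frac_at_switch = 0.0  # no refrigerant loaded before the first freeze
    for mode, duration in schedule.phases:
        p = system.boundaries.refrigerant
        if mode == "freeze":
            state = replace(state, mode="freeze", t_phase=0.0)
        else:
            state = replace(state, mode="thaw", t_phase=0.0,
                            h_switch_frac=h_frac_at_switch)
        n_steps = int(round(duration / dt))
        if n_steps < 1:
            raise ConfigurationError(f"phase duration {duration} shorter than dt")
        t_start = t_global
        for k in range(n_steps):
            state = system.step(state, dt)
            t_global = state.time
            ctimes.append(t_global)
            ctrace.append(system.contact_mean(state.T))
            if (k + 1) % store_steps == 0 or k == n_steps - 1:
                times.append(t_global)
                fields.append(state.T.copy())
                ledger_rows.append((t_global, state.E_stored, state.E_boundary,
                                    state.E_sources))
        if mode == "freeze":
            h_frac_at_switch = fill_envelope(state.t_phase, p)
        else:
            h_frac_at_switch = 1.0  # next freeze refills from empty lines
        phase_spans.append((mode, t_start, t_global))
        if progress is not None:
            progress(mode, t_global, state)

    energy = pd.DataFrame(ledger_rows,
                          columns=["t_s", "E_stored_J", "E_boundary_J", "E_sources_J"])
    # deduplicate snapshots stored twice at phase ends
    times_a = np.asarray(times)
    keep = np.concatenate([[True], np.diff(times_a) > 1e-12])
    return FieldSeries(times=times_a[keep], fields=np.asarray(fields)[keep],
                       contact_times=np.asarray(ctimes), contact_T=np.asarray(ctrace),
                       phases=phase_spans, energy=energy, mesh=mesh, dt=dt)


@dataclass
class _FreezeOnly:
    phases: Sequence[Tuple[str, float]]


def calibrate_refrigerant(mesh: ModelMesh, materials: MaterialModel,
                          boundaries: BoundarySpec,
                          target_min_tissue_T: float,
                          freeze_duration: float = 150.0,
                          dt: float = 0.1,
                          tol: float = 0.5,
                          h_bounds: Tuple[float, float] = (1e3, 3e5),
                          max_iter: int = 30) -> Tuple[RefrigerantParams, float]:
    """Tune ``h_steady`` so a ``freeze_duration`` freeze reaches the target
    minimum tissue temperature (bisection in log h, fixed fill/drain taus).

    Returns the tuned parameters and the achieved minimum.  Raises
    :class:`CalibrationError` if the target lies outside the achievable range.
    """
    p0 = boundaries.refrigerant
    if not (p0.T_ref < target_min_tissue_T < 0.0):
        raise CalibrationError(
            f"target {target_min_tissue_T} degC not between T_ref={p0.T_ref} and 0")

    def min_tissue_T(h: float) -> float:
        b = BoundarySpec(robin=boundaries.robin, refrigerant=replace(p0, h_steady=h))
        series = run_schedule(mesh, materials, b,
                              _FreezeOnly([("freeze", freeze_duration)]),
                              dt=dt, store_every=freeze_duration)
        system_nodes = np.unique(mesh.tets[mesh.region == REGION_TISSUE])
        return float(series.fields[-1][system_nodes].min())

    lo, hi = h_bounds
    f_lo = min_tissue_T(lo)
    if f_lo <= target_min_tissue_T:
        raise CalibrationError(
            f"target warmer than achievable range: min T at h={lo:g} is {f_lo:.1f} degC")
    f_hi = min_tissue_T(hi)
    if f_hi >= target_min_tissue_T:
        raise CalibrationError(
            f"target colder than achievable range: min T at h={hi:g} is {f_hi:.1f} degC")

    achieved = f_hi
    h = hi
    for _ in range(max_iter):
        h = math.sqrt(lo * hi)
        achieved = min_tissue_T(h)
        if abs(achieved - target_min_tissue_T) <= tol:
            break
        if achieved > target_min_tissue_T:
            lo = h
        else:
            hi = h
    else:
        raise CalibrationError(
            f"calibration did not converge: achieved {achieved:.2f} degC "
            f"for target {target_min_tissue_T:.2f}")
    return replace(p0, h_steady=h), achieved
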