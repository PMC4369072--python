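"""Evaluation metrics for simulated freeze-thaw runs.

From a stored :class:`~cardiocryo.solver.FieldSeries` this module computes the
quantities used to compare ablation protocols:

* transmural temperature profiles along the path from the applicator contact
  centre to the coldest epicardial point;
* isotherm depths over time (0, -10, -20 degC) and the iceball volume (tissue
  below the -10 degC solidus), by linear level-set clipping of tetrahedra;
* cryoadhesion times: thaw durations until the contact-patch mean temperature
  crosses the solidus (-10 degC) and liquidus (0 degC) boundaries;
* averaged cooling rates CR_1/CR_2 of the two freezing phases and the thawing
  rate TR_1 of the interim thaw, evaluated over the central 60 % (T_comp) of
  the local rewarming span T_rise, per transmural depth;
* the maximum nodal cooling-rate magnitude (quasi-static check).

A deterministic piecewise-linear trace fixture generator with analytically
known extrema and traversal times supports unit testing of the rate metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import REGION_TISSUE, MeshError, ModelMesh
from .materials import MaterialModel
from .protocols import Schedule
from .solver import FieldSeries


class GeometryError(MeshError):
    """Metric path leaves the expected mesh region."""


# --------------------------------------------------------------------------
# transmural profiles
# --------------------------------------------------------------------------

@dataclass
class TransmuralProfile:
    """Temperatures sampled along the transmural metric path.

    ``temps[i, j]`` is the temperature at ``times[i]`` and ``depths[j]`` (mm
    from the applicator contact surface).
    """

    depths: np.ndarray
    times: np.ndarray
    temps: np.ndarray
    origin: Optional[np.ndarray] = None
    endpoint: Optional[np.ndarray] = None

    def column(self, t: float) -> np.ndarray:
        """Temperatures over depth at time t (linear interpolation in time)."""
        if t <= self.times[0]:
            return self.temps[0]
        if t >= self.times[-1]:
            return self.temps[-1]
        i = int(np.searchsorted(self.times, t)) - 1
        w = (t - self.times[i]) / (self.times[i + 1] - self.times[i])
        return (1 - w) * self.temps[i] + w * self.temps[i + 1]

    def trace(self, depth: float) -> np.ndarray:
        """Temperature over time at a fixed depth (linear interp in depth)."""
        if len(self.depths) == 1:
            return self.temps[:, 0]
        j = np.clip(np.searchsorted(self.depths, depth) - 1, 0, len(self.depths) - 2)
        w = (depth - self.depths[j]) / (self.depths[j + 1] - self.depths[j])
        w = np.clip(w, 0.0, 1.0)
        return (1 - w) * self.temps[:, j] + w * self.temps[:, j + 1]


def interpolation_weights(mesh: ModelMesh, points: np.ndarray,
                          require_region: Optional[int] = None):
    """P1 interpolation data for arbitrary points: (tet index, 4 node ids,
    4 barycentric weights) per point.

    Candidate tetrahedra are found through a centroid kd-tree; a point is
    accepted in the first candidate containing it (barycentric coordinates
    >= -1e-8).  With ``require_region`` the located tet must belong to that
    region (ties on region interfaces prefer it).
    """
    v = mesh.vertices
    tets = mesh.tets
    cents = v[tets].mean(axis=1)
    tree = cKDTree(cents)
    n_pts = len(points)
    out_nodes = np.empty((n_pts, 4), dtype=np.int64)
    out_w = np.empty((n_pts, 4))
    out_tet = np.empty(n_pts, dtype=np.int64)

    for i, p in enumerate(points):
        found = -1
        best_bary = None
        for k in (32, 128, 512):
            _, idx = tree.query(p, k=min(k, len(tets)))
            idx = np.atleast_1d(idx)
            for ti in idx:
                t = tets[ti]
                A = np.column_stack([v[t[1]] - v[t[0]], v[t[2]] - v[t[0]],
                                     v[t[3]] - v[t[0]]])
                try:
                    loc = np.linalg.solve(A, p - v[t[0]])
                except np.linalg.LinAlgError:
                    continue
                bary = np.array([1 - loc.sum(), *loc])
                if bary.min() >= -1e-8:
                    if require_region is not None and mesh.region[ti] != require_region:
                        if best_bary is None:
                            found, best_bary = ti, bary
                        continue
                    found, best_bary = ti, bary
                    break
            if found >= 0 and (require_region is None
                               or mesh.region[found] == require_region
                               or best_bary is not None):
                break
        if found < 0:
            raise GeometryError(f"point {p} not inside the mesh")
        if require_region is not None and mesh.region[found] != require_region:
            raise GeometryError(f"point {p} lies outside the required region")
        out_tet[i] = found
        out_nodes[i] = tets[found]
        out_w[i] = np.clip(best_bary, 0.0, None)
        out_w[i] /= out_w[i].sum()
    return out_tet, out_nodes, out_w


def _contact_centre(mesh: ModelMesh) -> np.ndarray:
    areas = mesh.facet_areas(mesh.contact_facets)
    cents = mesh.vertices[mesh.contact_facets].mean(axis=1)
    return (cents * areas[:, None]).sum(axis=0) / areas.sum()


def coldest_epicardial_point(mesh: ModelMesh, field: np.ndarray) -> np.ndarray:
    """Vertex on the epicardial face (label c) with the lowest temperature;
    ties (e.g. a uniform field) resolve to the node nearest the contact-patch
    axis."""
    epi = mesh.facets_with_label("c")
    if len(epi) == 0:
        raise GeometryError("mesh has no epicardial (c) boundary facets")
    nodes = np.unique(epi)
    temps = field[nodes]
    tied = nodes[temps <= temps.min() + 1e-9]
    if len(tied) > 1:
        centre = _contact_centre(mesh)
        lateral = np.linalg.norm(mesh.vertices[tied, :2] - centre[:2], axis=1)
        return mesh.vertices[tied[np.argmin(lateral)]]
    return mesh.vertices[tied[0]]


def extract_profile(series: FieldSeries, mesh: ModelMesh,
                    t_ref: Optional[float] = None,
                    spacing: float = 0.1) -> TransmuralProfile:
    """Sample all stored fields along the straight path from the contact-patch
    centre to the coldest epicardial point at ``t_ref`` (default: end of the
    last freezing phase)."""
    if t_ref is None:
        freezes = [p for p in series.phases if p[0] == "freeze"]
        t_ref = freezes[-1][2] if freezes else series.times[-1]
    origin = _contact_centre(mesh)
    target = coldest_epicardial_point(mesh, series.field_at(t_ref))
    length = float(np.linalg.norm(target - origin))
    n = max(2, int(np.ceil(length / spacing)) + 1)
    depths = np.linspace(0.0, length, n)
    direction = (target - origin) / length
    pts = origin[None, :] + depths[:, None] * direction
    # nudge endpoints inside the tissue for robust location
    pts[0] = origin + 1e-6 * direction
    pts[-1] = target - 1e-6 * direction
    _, nodes, w = interpolation_weights(mesh, pts, require_region=REGION_TISSUE)
    temps = np.einsum("tpk,pk->tp", series.fields[:, nodes], w)
    return TransmuralProfile(depths=depths, times=series.times.copy(),
                             temps=temps, origin=origin, endpoint=target)


# --------------------------------------------------------------------------
# isotherms and ice volume
# --------------------------------------------------------------------------

def isotherm_depth(depths: np.ndarray, temps: np.ndarray, T_star: float) -> float:
    """Deepest point (mm) at which the profile crosses ``T_star``.

    Linear interpolation between bracketing samples; 0 if the whole profile is
    warmer than ``T_star``; the full depth if it is entirely colder.
    """
    d = np.asarray(depths, float)
    y = np.asarray(temps, float) - T_star
    if np.all(y > 0):
        return 0.0
    if y[-1] <= 0:
        return float(d[-1])
    sign = y[:-1] * y[1:]
    cross = np.nonzero((sign <= 0) & (y[:-1] != y[1:]))[0]
    if len(cross) == 0:
        return 0.0
    i = cross[-1]
    frac = y[i] / (y[i] - y[i + 1])
    return float(d[i] + frac * (d[i + 1] - d[i]))


def _positive_volume_fraction(d: np.ndarray) -> np.ndarray:
    """Fraction of each tetrahedron where the linear field ``d`` is positive.

    Uses the simplex identity  V+/V = sum_{i: d_i>0} d_i^3 / prod_{j != i}
    (d_i - d_j); ties are perturbed to keep denominators finite.
    """
    d = d.astype(float).copy()
    frac = np.zeros(len(d))
    frac[np.all(d >= 0, axis=1)] = 1.0
    mixed = np.any(d > 0, axis=1) & np.any(d < 0, axis=1)
    if not np.any(mixed):
        return frac
    dm = d[mixed]
    # perturb exact ties deterministically so denominators stay finite
    scale = np.abs(dm).max(axis=1, keepdims=True)
    for k in range(1, 4):
        coincide = np.abs(dm[:, k:k + 1] - dm[:, :k]).min(axis=1) < 1e-12 * scale[:, 0]
        dm[coincide, k] += 1e-9 * (k + 1) * scale[coincide, 0]
    fm = np.zeros(len(dm))
    for i in range(4):
        di = dm[:, i]
        mask = di > 0
        if not np.any(mask):
            continue
        denom = np.ones(mask.sum())
        for j in range(4):
            if j == i:
                continue
            denom *= di[mask] - dm[mask, j]
        fm[mask] += di[mask] ** 3 / denom
    frac[mixed] = fm
    return np.clip(frac, 0.0, 1.0)


def ice_volume(field: np.ndarray, mesh: ModelMesh, materials: MaterialModel,
               region: int = REGION_TISSUE, method: str = "clip",
               T_star: Optional[float] = None) -> float:
    """Volume (mm^3) of the region colder than the solidus temperature.

    ``method='clip'`` (default) clips each tetrahedron by the linear level set
    of the nodal field; ``method='fraction'`` counts sub-solidus nodes / 4 as
    a cruder approximation.
    """
    if T_star is None:
        T_star = materials.region(region).T_solidus
    sel = mesh.region == region
    tets = mesh.tets[sel]
    vols = mesh.tet_volumes()[sel]
    Tn = field[tets]
    if method == "clip":
        frac = _positive_volume_fraction(T_star - Tn)
    elif method == "fraction":
        frac = (Tn < T_star).sum(axis=1) / 4.0
    else:
        raise ValueError(f"unknown ice-volume method {method!r}")
    return float((frac * vols).sum())


def max_isotherm_depth(field: np.ndarray, mesh: ModelMesh, T_star: float,
                       origin: np.ndarray, direction: np.ndarray) -> float:
    """Maximum depth (projection on the transmural direction) reached by the
    ``T_star`` isotherm anywhere in the tissue (3-D variant of the path-based
    depth; reported as a diagnostic)."""
    sel = mesh.region == REGION_TISSUE
    tets = mesh.tets[sel]
    proj = (mesh.vertices - origin) @ direction
    Tn = field[tets]
    below = Tn <= T_star
    depth = 0.0
    nodes_below = np.unique(tets[np.any(below, axis=1)])
    nodes_below = nodes_below[field[nodes_below] <= T_star]
    if len(nodes_below):
        depth = float(proj[nodes_below].max())
    # refine along crossing edges
    edges = np.concatenate([tets[:, e] for e in
                            ([0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3])])
    y = field[edges] - T_star
    crossing = (y[:, 0] * y[:, 1]) < 0
    if np.any(crossing):
        e = edges[crossing]
        yc = y[crossing]
        t = yc[:, 0] / (yc[:, 0] - yc[:, 1])
        pz = proj[e[:, 0]] + t * (proj[e[:, 1]] - proj[e[:, 0]])
        depth = max(depth, float(pz.max()))
    return depth


# --------------------------------------------------------------------------
# cryoadhesion
# --------------------------------------------------------------------------

def adhesion_times(contact_times: np.ndarray, contact_T: np.ndarray,
                   thaw_start: float, T_solidus: float = -10.0,
                   T_liquidus: float = 0.0) -> Tuple[float, float]:
    """Thaw durations until the contact-patch mean temperature first crosses
    the solidus and liquidus boundaries (seconds from ``thaw_start``).

    A crossing not reached within the trace is reported as ``nan``.  If the
    trace is already above a boundary at thaw start the time is 0.
    """
    t = np.asarray(contact_times, float)
    y = np.asarray(contact_T, float)
    sel = t >= thaw_start - 1e-12

    def first_crossing(level: float) -> float:
        tt, yy = t[sel], y[sel]
        if yy[0] >= level:
            return 0.0
        above = yy >= level
        if not np.any(above):
            return float("nan")
        i = int(np.argmax(above))
        frac = (level - yy[i - 1]) / (yy[i] - yy[i - 1])
        return float(tt[i - 1] + frac * (tt[i] - tt[i - 1]) - thaw_start)

    return first_crossing(T_solidus), first_crossing(T_liquidus)


# --------------------------------------------------------------------------
# cooling / thawing rates
# --------------------------------------------------------------------------

@dataclass
class RateProfile:
    """Per-depth freeze/thaw rate summary (nan = undefined at that depth)."""

    depths: np.ndarray
    min_T1F: np.ndarray
    max_T1T: np.ndarray
    T_rise: np.ndarray
    T_comp_lo: np.ndarray
    T_comp_hi: np.ndarray
    CR1: np.ndarray
    CR2: np.ndarray
    TR1: np.ndarray

    @property
    def CR_increase(self) -> np.ndarray:
        return self.CR2 - self.CR1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "depth_mm": self.depths, "min_T1F_C": self.min_T1F,
            "max_T1T_C": self.max_T1T, "T_rise_C": self.T_rise,
            "T_comp_lo_C": self.T_comp_lo, "T_comp_hi_C": self.T_comp_hi,
            "CR1_C_per_s": self.CR1, "CR2_C_per_s": self.CR2,
            "TR1_C_per_s": self.TR1, "CR_increase_C_per_s": self.CR_increase,
        })


def _window_trace(t: np.ndarray, y: np.ndarray, a: float, b: float):
    """Trace restricted to [a, b] with interpolated endpoint samples."""
    ya = np.interp(a, t, y)
    yb = np.interp(b, t, y)
    inside = (t > a) & (t < b)
    tt = np.concatenate([[a], t[inside], [b]])
    yy = np.concatenate([[ya], y[inside], [yb]])
    return tt, yy


def _crossing_time(tt: np.ndarray, yy: np.ndarray, level: float,
                   direction: str, which: str) -> float:
    """Time of the first/last crossing of ``level`` in the given direction
    (``down`` = from above to below, ``up`` = from below to above)."""
    d = yy - level
    if direction == "down":
        hits = (d[:-1] >= 0) & (d[1:] < 0) | ((d[:-1] > 0) & (d[1:] <= 0))
    else:
        hits = (d[:-1] <= 0) & (d[1:] > 0) | ((d[:-1] < 0) & (d[1:] >= 0))
    idx = np.nonzero(hits)[0]
    if len(idx) == 0:
        return float("nan")
    i = idx[0] if which == "first" else idx[-1]
    if d[i] == d[i + 1]:
        return float(tt[i])
    frac = d[i] / (d[i] - d[i + 1])
    return float(tt[i] + frac * (tt[i + 1] - tt[i]))


def _phase_windows(phases: Sequence[Tuple[str, float, float]]):
    """First freeze, interim thaw and second freeze windows; the latter two
    are None when absent (their rates are then undefined)."""
    freezes = [(a, b) for m, a, b in phases if m == "freeze"]
    thaws = [(a, b) for m, a, b in phases if m == "thaw"]
    if not freezes:
        raise ValueError("rate profile requires at least one freezing phase")
    interim = None
    if len(freezes) >= 2:
        interim = next(((a, b) for (a, b) in thaws
                        if a >= freezes[0][1] - 1e-9 and b <= freezes[1][0] + 1e-9), None)
    elif thaws:
        interim = thaws[0]
    second = freezes[1] if len(freezes) >= 2 else None
    return freezes[0], interim, second


def schedule_windows(schedule: Schedule) -> List[Tuple[str, float, float]]:
    """Absolute (mode, t_start, t_end) windows of a schedule."""
    out, t = [], 0.0
    for mode, dur in schedule.phases:
        out.append((mode, t, t + dur))
        t += dur
    return out


def rate_profile(profile: TransmuralProfile, schedule,
                 depth_grid: Optional[np.ndarray] = None) -> RateProfile:
    """Average cooling rates of both freezing phases and the interim thawing
    rate, per transmural depth.

    For each depth the comparison interval T_comp is the central 60 % of the
    local rewarming span T_rise = max(T_1T) - min(T_1F).  A rate is the span
    of T_comp divided by the time the phase trace needs to traverse it (first
    entry to last exit within the phase); depths where a phase does not fully
    traverse T_comp report nan.
    """
    if isinstance(schedule, Schedule):
        phases = schedule_windows(schedule)
    else:
        phases = list(schedule)
    (f1a, f1b), interim, second = _phase_windows(phases)

    if depth_grid is None:
        dmax = float(profile.depths[-1])
        depth_grid = np.arange(0.0, dmax + 1e-9, 0.25)

    n = len(depth_grid)
    res = {k: np.full(n, np.nan) for k in
           ("min_T1F", "max_T1T", "T_rise", "lo", "hi", "CR1", "CR2", "TR1")}
    t = profile.times
    for j, depth in enumerate(depth_grid):
        y = profile.trace(depth)
        t1, y1 = _window_trace(t, y, f1a, f1b)
        mn = float(y1.min())
        res["min_T1F"][j] = mn
        if interim is None:
            continue
        tt, yt = _window_trace(t, y, *interim)
        mx = float(yt.max())
        rise = mx - mn
        res["max_T1T"][j] = mx
        res["T_rise"][j] = rise
        if rise <= 0:
            continue
        lo = mn + 0.2 * rise
        hi = mn + 0.8 * rise
        span = 0.6 * rise
        res["lo"][j] = lo
        res["hi"][j] = hi
        t_hi = _crossing_time(t1, y1, hi, "down", "first")
        t_lo = _crossing_time(t1, y1, lo, "down", "last")
        if np.isfinite(t_hi) and np.isfinite(t_lo) and t_lo > t_hi:
            res["CR1"][j] = span / (t_lo - t_hi)
        if second is not None:
            t2, y2 = _window_trace(t, y, *second)
            t_hi = _crossing_time(t2, y2, hi, "down", "first")
            t_lo = _crossing_time(t2, y2, lo, "down", "last")
            if np.isfinite(t_hi) and np.isfinite(t_lo) and t_lo > t_hi:
                res["CR2"][j] = span / (t_lo - t_hi)
        t_lo = _crossing_time(tt, yt, lo, "up", "first")
        t_hi = _crossing_time(tt, yt, hi, "up", "last")
        if np.isfinite(t_lo) and np.isfinite(t_hi) and t_hi > t_lo:
            res["TR1"][j] = span / (t_hi - t_lo)

    return RateProfile(depths=np.asarray(depth_grid), min_T1F=res["min_T1F"],
                       max_T1T=res["max_T1T"], T_rise=res["T_rise"],
                       T_comp_lo=res["lo"], T_comp_hi=res["hi"],
                       CR1=res["CR1"], CR2=res["CR2"], TR1=res["TR1"])


def max_cooling_rate_at(series: FieldSeries, t: float,
                        mesh: Optional[ModelMesh] = None) -> float:
    """Signed temperature rate (degC/s) of the tissue node with the largest
    |dT/dt| at time ``t``, by central difference over stored snapshots."""
    mesh = mesh or series.mesh
    times = series.times
    if not (times[0] < t < times[-1]):
        raise ValueError("t must be interior to the stored series")
    i = int(np.clip(np.searchsorted(times, t), 1, len(times) - 2))
    rate = (series.fields[i + 1] - series.fields[i - 1]) / (times[i + 1] - times[i - 1])
    nodes = np.unique(mesh.tets[mesh.region == REGION_TISSUE])
    r = rate[nodes]
    return float(r[np.argmax(np.abs(r))])


# --------------------------------------------------------------------------
# synthetic trace fixture
# --------------------------------------------------------------------------

def make_trace_fixture(spec: Dict[float, Sequence[Tuple[float, float]]]) -> TransmuralProfile:
    """Piecewise-linear synthetic transmural profile for metric unit tests.

    ``spec`` maps depth (mm) to a time-sorted list of (time, temperature)
    breakpoints.  All traces are resampled onto the union of breakpoint times,
    where linear interpolation keeps every trace exact; extrema and traversal
    times are therefore analytically known.
    """
    depths = np.array(sorted(spec))
    all_times = sorted({t for pts in spec.values() for t, _ in pts})
    times = np.asarray(all_times, float)
    temps = np.empty((len(times), len(depths)))
    for j, d in enumerate(depths):
        pts = spec[d]
        ts = [p[0] for p in pts]
        if any(b <= a for a, b in zip(ts[:-1], ts[1:])):
            raise ValueError(f"breakpoints for depth {d} are not time-sorted")
        temps[:, j] = np.interp(times, ts, [p[1] for p in pts])
    return TransmuralProfile(depths=depths, times=times, temps=temps)


# --------------------------------------------------------------------------
# aggregate report
# --------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """All evaluation quantities of one simulated scenario."""

    scenario: str
    times: np.ndarray
    isotherm_depths: Dict[float, np.ndarray]     # T_star -> depth(t), mm
    ice_volume_mm3: np.ndarray
    frozen_blood_mm3: np.ndarray
    adhesion: List[Dict[str, float]]             # per thaw phase
    rates: Optional[RateProfile]
    profile: TransmuralProfile
    phase_ends: List[Tuple[str, float]]

    def phase_table(self) -> pd.DataFrame:
        """Per-phase-end (-10 depth, -20 depth, ice volume) triplets."""
        rows = []
        for name, t in self.phase_ends:
            i = int(np.argmin(np.abs(self.times - t)))
            rows.append({
                "phase": name, "t_s": t,
                "depth_-10C_mm": self.isotherm_depths[-10.0][i],
                "depth_-20C_mm": self.isotherm_depths[-20.0][i],
                "ice_volume_mm3": self.ice_volume_mm3[i],
            })
        return pd.DataFrame(rows)


def compute_report(series: FieldSeries, mesh: ModelMesh,
                   materials: MaterialModel, scenario: str = "") -> MetricsReport:
    """Full metric evaluation of a stored run."""
    profile = extract_profile(series, mesh)
    iso = {ts: np.array([isotherm_depth(profile.depths, profile.temps[i], ts)
                         for i in range(len(series.times))])
           for ts in (0.0, -10.0, -20.0)}
    iv = np.array([ice_volume(f, mesh, materials) for f in series.fields])
    fbv = np.array([ice_volume(f, mesh, materials, region=2) for f in series.fields])

    adhesion = []
    for mode, a, b in series.phases:
        if mode != "thaw":
            continue
        t_sol, t_liq = adhesion_times(series.contact_times, series.contact_T, a)
        adhesion.append({"thaw_start_s": a, "t_solidus_s": t_sol, "t_liquidus_s": t_liq})

    rates = None
    n_freezes = sum(1 for m, _, _ in series.phases if m == "freeze")
    if n_freezes >= 2:
        rates = rate_profile(profile, series.phases)

    labels = []
    counts = {"freeze": 0, "thaw": 0}
    for mode, a, b in series.phases:
        counts[mode] += 1
        labels.append((f"{counts[mode]}{'F' if mode == 'freeze' else 'T'}", b))
    return MetricsReport(scenario=scenario, times=series.times.copy(),
                         isotherm_depths=iso, ice_volume_mm3=iv,
                         frozen_blood_mm3=fbv, adhesion=adhesion, rates=rates,
                         profile=profile, phase_ends=labels)
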