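"""Simulation geometry: tagged tetrahedral meshes of the applicator/myocardium model.

Two variants are supported:

* ``main`` — a 9 Fr (3 mm) 8 mm-tip cryoapplicator pressed side-on against a
  planar myocardial slab of 6 mm transmural thickness, surrounded by a 3 mm
  blood layer.  The tip is idealised as a hollow rectangular shell whose
  footprint on the endocardium equals the configured contact-patch area; the
  shell's inner (refrigerant chamber) surfaces carry the refrigerant boundary
  labels.
* ``wood_slab`` — a 20 x 20 x 10 mm inactive tissue block with a 3 mm static
  blood layer, used as an in-vitro verification bench.

Coordinates are millimetres, right handed, with the transmural axis along +z:
the endocardial contact plane is z = 0 and the epicardium is at
z = tissue_thickness.  Blood (and the applicator) occupy z < 0.

Boundary facet labels:

====== =========================================================
label  surface
====== =========================================================
a      blood far field (lateral blood faces and the cavity bottom)
b      tissue far field (lateral tissue faces)
c      epicardial face (z = tissue_thickness)
d      refrigerant chamber face nearest the tissue
e      refrigerant chamber side walls
f      refrigerant chamber top (catheter-shaft side)
====== =========================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

REGION_TISSUE = 1
REGION_BLOOD = 2
REGION_APPLICATOR = 3

REGION_NAMES = {REGION_TISSUE: "tissue", REGION_BLOOD: "blood", REGION_APPLICATOR: "applicator"}

BOUNDARY_CODES = {"a": 1, "b": 2, "c": 3, "d": 4, "e": 5, "f": 6}
BOUNDARY_NAMES = {v: k for k, v in BOUNDARY_CODES.items()}

_GEOM_TOL = 1e-9


class ConfigurationError(ValueError):
    """Invalid geometry/material/protocol configuration."""


class MeshError(RuntimeError):
    """Mesh generation or consistency failure."""


@dataclass(frozen=True)
class GeometryConfig:
    """Dimensions and discretisation of the simulated geometry.

    All lengths in mm.  ``resolution`` is the target edge length near the
    applicator; element size grows away from the contact region up to
    ``coarsening`` times the base resolution.
    """

    applicator_diameter: float = 3.0   # 9 Fr
    tip_length: float = 8.0
    tissue_thickness: float = 6.0
    blood_layer_thickness: float = 3.0
    contact_patch_area: float = 20.0   # mm^2, flat-contact tip footprint
    lateral_extent: float = 15.0       # half-width of the modelled slab
    resolution: float = 0.9
    coarsening: float = 4.0
    wall_thickness: float = 0.5        # applicator shell wall
    variant: str = "main"              # "main" | "wood_slab"

    def __post_init__(self):
        if self.variant not in ("main", "wood_slab"):
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        if self.variant == "wood_slab":
            # the verification bench is a fixed 20 x 20 x 10 mm block
            object.__setattr__(self, "tissue_thickness", 10.0)
            object.__setattr__(self, "lateral_extent", 10.0)
        for name in ("applicator_diameter", "tip_length", "tissue_thickness",
                     "blood_layer_thickness", "contact_patch_area",
                     "lateral_extent", "resolution", "wall_thickness"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.contact_width >= 2 * self.lateral_extent or \
                self.tip_length >= 2 * self.lateral_extent:
            raise ConfigurationError("contact patch does not fit inside lateral extent")
        tip_lateral_area = self.tip_length * 2 * (self.contact_width + self.applicator_diameter)
        if self.contact_patch_area >= tip_lateral_area:
            raise ConfigurationError("contact_patch_area exceeds tip lateral surface area")
        if 2 * self.wall_thickness >= min(self.contact_width, self.tip_length,
                                          self.applicator_diameter):
            raise ConfigurationError("wall_thickness too large for applicator dimensions")

    @property
    def contact_width(self) -> float:
        """Width (y extent) of the rectangular contact patch, mm."""
        return self.contact_patch_area / self.tip_length

    @property
    def applicator_height(self) -> float:
        """z extent of the tip shell (its diameter)."""
        return self.applicator_diameter

    @property
    def cavity_depth(self) -> float:
        """Total depth of the blood cavity: the tip is surrounded by a blood
        layer of ``blood_layer_thickness`` on its free surfaces."""
        return self.applicator_height + self.blood_layer_thickness

    def with_preset(self, preset: str) -> "GeometryConfig":
        """Return a copy at a named resolution preset (``reduced`` or
        ``paper``); ``custom`` keeps the configured resolution."""
        if preset == "custom":
            return self
        if preset == "reduced":
            return replace(self, resolution=0.9)
        if preset == "paper":
            return replace(self, resolution=0.4, coarsening=3.0)
        raise ConfigurationError(f"unknown resolution preset {preset!r}")


@dataclass
class ModelMesh:
    """Tagged tetrahedral mesh of the simulation domain.

    ``vertices`` in mm; ``tets`` index quadruples with positive orientation;
    ``region`` per-tet region code; ``boundary_facets``/``boundary_labels``
    exterior triangles with labels a-f (code 0 = untagged exterior);
    ``contact_facets`` the tissue-applicator interface triangles at z=0.
    """

    vertices: np.ndarray
    tets: np.ndarray
    region: np.ndarray
    boundary_facets: np.ndarray
    boundary_labels: np.ndarray
    contact_facets: np.ndarray
    config: GeometryConfig

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_tets(self) -> int:
        return self.tets.shape[0]

    def tet_volumes(self) -> np.ndarray:
        """Signed tetrahedron volumes (mm^3); positive for a conforming mesh."""
        v = self.vertices
        a = v[self.tets[:, 1]] - v[self.tets[:, 0]]
        b = v[self.tets[:, 2]] - v[self.tets[:, 0]]
        c = v[self.tets[:, 3]] - v[self.tets[:, 0]]
        return np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0

    def region_volume(self, code: int) -> float:
        return float(self.tet_volumes()[self.region == code].sum())

    def facet_areas(self, facets: np.ndarray) -> np.ndarray:
        v = self.vertices
        n = np.cross(v[facets[:, 1]] - v[facets[:, 0]], v[facets[:, 2]] - v[facets[:, 0]])
        return 0.5 * np.linalg.norm(n, axis=1)

    def facets_with_label(self, label: str) -> np.ndarray:
        return self.boundary_facets[self.boundary_labels == BOUNDARY_CODES[label]]

    def contact_patch_area(self) -> float:
        return float(self.facet_areas(self.contact_facets).sum())


def _axis_points(breaks: np.ndarray, h0: float, hmax: float, focus: float,
                 ramp: float = 3.0) -> np.ndarray:
    """Graded 1-D grid through mandatory breakpoints.

    Local spacing is ``h0`` within ``focus`` of the origin and grows linearly
    (over a ``ramp`` mm distance scale) up to ``hmax`` beyond it.  Within each
    breakpoint interval the grid marches from the end nearer the origin with
    growing steps, then is rescaled to land exactly on the far breakpoint.
    """

    def local_h(d):
        return min(max(h0 * (1.0 + max(0.0, d - focus) / ramp), h0), hmax)

    pts = [breaks[0]]
    for a, b in zip(breaks[:-1], breaks[1:]):
        start, end = (a, b) if abs(a) <= abs(b) else (b, a)
        sgn = 1.0 if end > start else -1.0
        steps = []
        pos = start
        while sgn * (end - pos) > 1e-12:
            h = local_h(abs(pos))
            h = min(h, abs(end - pos)) if abs(end - pos) < 1.5 * h else h
            steps.append(h)
            pos += sgn * h
        scale = abs(end - start) / sum(steps)
        rel = np.cumsum(steps) * scale
        new = start + sgn * rel
        new[-1] = end
        if start == a:
            pts.extend(new.tolist())
        else:  # marched from b down toward a: reverse into ascending order
            pts.extend(new[::-1].tolist()[1:] + [b])
    return np.asarray(pts)


_KUHN_PERMS = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]


def _kuhn_tets(corner: np.ndarray, strides: Tuple[int, int, int]) -> np.ndarray:
    """Split each hexahedron (given by its min-corner vertex id) into 6 tets.

    The Kuhn subdivision cuts every hex face along the same diagonal, so
    neighbouring hexes conform.
    """
    sx, sy, sz = strides
    s = (sx, sy, sz)
    out = np.empty((corner.size, 6, 4), dtype=np.int64)
    for t, (p, q, r) in enumerate(_KUHN_PERMS):
        v0 = corner
        v1 = v0 + s[p]
        v2 = v1 + s[q]
        v3 = v2 + s[r]
        out[:, t, 0] = v0
        out[:, t, 1] = v1
        out[:, t, 2] = v2
        out[:, t, 3] = v3
    return out.reshape(-1, 4)


def _classify_cells(cx, cy, cz, cfg: GeometryConfig):
    """Region code per hex centroid; -1 marks the refrigerant chamber void."""
    hx = cfg.tip_length / 2.0
    hy = cfg.contact_width / 2.0
    H = cfg.applicator_height
    tw = cfg.wall_thickness
    region = np.full(cx.shape, REGION_BLOOD, dtype=np.int8)
    region[cz > 0] = REGION_TISSUE
    in_app = (np.abs(cx) < hx) & (np.abs(cy) < hy) & (cz < 0) & (cz > -H)
    region[in_app] = REGION_APPLICATOR
    in_void = (np.abs(cx) < hx - tw) & (np.abs(cy) < hy - tw) \
        & (cz < -tw) & (cz > -H + tw)
    region[in_void] = -1
    return region


def build_model_mesh(config: GeometryConfig) -> ModelMesh:
    """Construct the tagged tetrahedral mesh for the configured variant."""
    cfg = config
    L = cfg.lateral_extent
    hx = cfg.tip_length / 2.0
    hy = cfg.contact_width / 2.0
    H = cfg.applicator_height
    B = cfg.blood_layer_thickness
    T = cfg.tissue_thickness
    tw = cfg.wall_thickness
    h0 = cfg.resolution
    hmax = cfg.coarsening * h0

    bx = np.unique(np.array([-L, -hx, -(hx - tw), hx - tw, hx, L]))
    by = np.unique(np.array([-L, -hy, -(hy - tw), hy - tw, hy, L]))
    bz = np.unique(np.array([-(H + B), -H, -(H - tw), -tw, 0.0, T]))
    x = _axis_points(bx, h0, hmax, focus=hx + 1.0)
    y = _axis_points(by, h0, hmax, focus=hy + 1.0)
    # keep the transmural direction uniformly fine: isotherm depths live here
    zf = min(h0, 0.75)
    z = _axis_points(bz, zf, zf * 1.5, focus=T)

    nx, ny, nz = len(x), len(y), len(z)
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    verts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    strides = (ny * nz, nz, 1)

    ix, iy, iz = np.meshgrid(np.arange(nx - 1), np.arange(ny - 1), np.arange(nz - 1),
                             indexing="ij")
    corner = (ix * strides[0] + iy * strides[1] + iz * strides[2]).ravel()
    cx = ((x[ix] + x[ix + 1]) / 2).ravel()
    cy = ((y[iy] + y[iy + 1]) / 2).ravel()
    cz = ((z[iz] + z[iz + 1]) / 2).ravel()

    cell_region = _classify_cells(cx, cy, cz, cfg)
    keep = cell_region != -1
    corner = corner[keep]
    cell_region = cell_region[keep]

    tets = _kuhn_tets(corner, strides)
    region = np.repeat(cell_region, 6)

    # compact vertex numbering
    used, inv = np.unique(tets, return_inverse=True)
    tets = inv.reshape(-1, 4).astype(np.int64)
    verts = verts[used]

    mesh = ModelMesh(verts, tets, region, np.empty((0, 3), np.int64),
                     np.empty(0, np.int8), np.empty((0, 3), np.int64), cfg)

    vol = mesh.tet_volumes()
    neg = vol < 0
    if np.any(neg):  # Kuhn permutation parity: fix orientation
        t = mesh.tets[neg]
        t[:, [2, 3]] = t[:, [3, 2]]
        mesh.tets[neg] = t
    if np.any(mesh.tet_volumes() <= _GEOM_TOL):
        raise MeshError("degenerate tetrahedra in generated mesh")

    _tag_boundaries(mesh)
    area = mesh.contact_patch_area()
    if not np.isclose(area, cfg.contact_patch_area, rtol=0.1):
        raise MeshError(
            f"contact patch area {area:.2f} mm^2 deviates from configured "
            f"{cfg.contact_patch_area:.2f} mm^2")
    return mesh


def _all_faces(tets: np.ndarray) -> np.ndarray:
    f = np.concatenate([tets[:, [1, 2, 3]], tets[:, [0, 3, 2]],
                        tets[:, [0, 1, 3]], tets[:, [0, 2, 1]]])
    return f


def exterior_faces(tets: np.ndarray) -> np.ndarray:
    """Faces that belong to exactly one tetrahedron (outward-oriented)."""
    f = _all_faces(tets)
    key = np.sort(f, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return f[counts[inv] == 1]


def _tag_boundaries(mesh: ModelMesh) -> None:
    cfg = mesh.config
    v = mesh.vertices
    tol = 1e-6

    ext = exterior_faces(mesh.tets)
    cent = v[ext].mean(axis=1)
    labels = np.zeros(len(ext), dtype=np.int8)

    hx = cfg.tip_length / 2.0 - cfg.wall_thickness
    hy = cfg.contact_width / 2.0 - cfg.wall_thickness
    H = cfg.applicator_height
    in_void = (np.abs(cent[:, 0]) < hx + tol) & (np.abs(cent[:, 1]) < hy + tol) \
        & (cent[:, 2] < -cfg.wall_thickness + tol) & (cent[:, 2] > -(H - cfg.wall_thickness) - tol)
    labels[in_void & np.isclose(cent[:, 2], -cfg.wall_thickness, atol=tol)] = BOUNDARY_CODES["d"]
    labels[in_void & np.isclose(cent[:, 2], -(H - cfg.wall_thickness), atol=tol)] = BOUNDARY_CODES["f"]
    labels[in_void & (labels == 0)] = BOUNDARY_CODES["e"]

    outer = ~in_void
    labels[outer & np.isclose(cent[:, 2], cfg.tissue_thickness, atol=tol)] = BOUNDARY_CODES["c"]
    lateral = (np.isclose(np.abs(cent[:, 0]), cfg.lateral_extent, atol=tol)
               | np.isclose(np.abs(cent[:, 1]), cfg.lateral_extent, atol=tol))
    bottom = np.isclose(cent[:, 2], -cfg.cavity_depth, atol=tol)
    labels[outer & (lateral | bottom) & (cent[:, 2] > 0) & (labels == 0)] = BOUNDARY_CODES["b"]
    labels[outer & (lateral | bottom) & (cent[:, 2] <= 0) & (labels == 0)] = BOUNDARY_CODES["a"]

    mesh.boundary_facets = ext
    mesh.boundary_labels = labels

    # tissue-applicator interface (the contact patch) at z = 0
    faces = _all_faces(mesh.tets)
    owner_region = np.tile(mesh.region, 4)
    key = np.sort(faces, axis=1)
    uniq, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    shared = counts == 2
    # regions of the two owners of each shared face
    reg_sum = np.zeros(len(uniq), dtype=np.int64)
    np.add.at(reg_sum, inv, owner_region)
    is_contact_key = shared & (reg_sum == REGION_TISSUE + REGION_APPLICATOR)
    tissue_side = is_contact_key[inv] & (owner_region == REGION_TISSUE)
    contact = faces[tissue_side]
    zc = v[contact].mean(axis=1)[:, 2]
    mesh.contact_facets = contact[np.isclose(zc, 0.0, atol=tol)]
    if len(mesh.contact_facets) == 0:
        raise MeshError("no tissue-applicator contact patch found")


def facet_normals(mesh: ModelMesh, facets: np.ndarray) -> np.ndarray:
    """Unit normals of the given (oriented) triangles."""
    v = mesh.vertices
    n = np.cross(v[facets[:, 1]] - v[facets[:, 0]], v[facets[:, 2]] - v[facets[:, 0]])
    return n / np.linalg.norm(n, axis=1, keepdims=True)


def transmural_axis(mesh: ModelMesh) -> Tuple[np.ndarray, np.ndarray]:
    """Oriented segment from the contact-patch centre, along the tissue-inward
    patch normal, to the epicardial face.

    Computed purely from mesh data (facet geometry), so it is invariant under
    rigid transformations of the mesh.
    """
    if len(mesh.contact_facets) == 0:
        raise MeshError("mesh has no contact patch")
    areas = mesh.facet_areas(mesh.contact_facets)
    cents = mesh.vertices[mesh.contact_facets].mean(axis=1)
    origin = (cents * areas[:, None]).sum(axis=0) / areas.sum()

    normals = facet_normals(mesh, mesh.contact_facets)
    n = (normals * areas[:, None]).sum(axis=0)
    n /= np.linalg.norm(n)
    # orient toward the tissue: tissue centroid lies on the tissue side
    vols = mesh.tet_volumes()
    tmask = mesh.region == REGION_TISSUE
    tcent = (mesh.vertices[mesh.tets[tmask]].mean(axis=1)
             * vols[tmask, None]).sum(axis=0) / vols[tmask].sum()
    if np.dot(tcent - origin, n) < 0:
        n = -n

    epi = mesh.facets_with_label("c")
    s = _ray_hit(mesh.vertices, epi, origin, n)
    if not np.isfinite(s):
        raise MeshError("transmural ray does not reach the epicardial face")
    return origin, origin + s * n


def _ray_hit(verts: np.ndarray, tris: np.ndarray, origin: np.ndarray,
             direction: np.ndarray) -> float:
    """Smallest positive ray parameter hitting any triangle (Moller-Trumbore)."""
    p0 = verts[tris[:, 0]]
    e1 = verts[tris[:, 1]] - p0
    e2 = verts[tris[:, 2]] - p0
    h = np.cross(np.broadcast_to(direction, e2.shape), e2)
    a = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(a) > 1e-12
    f = np.zeros_like(a)
    f[ok] = 1.0 / a[ok]
    s = origin - p0
    u = f * np.einsum("ij,ij->i", s, h)
    q = np.cross(s, e1)
    vv = f * np.einsum("j,ij->i", direction, q)
    t = f * np.einsum("ij,ij->i", e2, q)
    eps = 1e-9
    hit = ok & (u >= -eps) & (vv >= -eps) & (u + vv <= 1 + eps) & (t > eps)
    return float(t[hit].min()) if np.any(hit) else np.inf
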