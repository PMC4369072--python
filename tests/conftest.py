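"""Shared fixtures: coarse study meshes and simple analytic-benchmark meshes.

Unit and property tests run on deliberately coarse meshes (edge length
~1.6 mm) so the whole suite stays desk-scale; the acceptance tests use the
package's default reduced resolution.
"""

import numpy as np
import pytest

from cardiocryo.geometry import (GeometryConfig, ModelMesh, BOUNDARY_CODES,
                                 REGION_TISSUE, build_model_mesh,
                                 exterior_faces, _kuhn_tets)
from cardiocryo.materials import RegionMaterial, default_materials
from cardiocryo.solver import BoundarySpec, RefrigerantParams

# fixed representative refrigerant magnitude for non-acceptance tests (the
# acceptance suite calibrates its own)
TEST_H_STEADY = 5.0e4


@pytest.fixture(scope="session")
def coarse_config():
    return GeometryConfig(resolution=1.6, lateral_extent=10.0)


@pytest.fixture(scope="session")
def coarse_mesh(coarse_config):
    return build_model_mesh(coarse_config)


@pytest.fixture(scope="session")
def materials():
    return default_materials()


@pytest.fixture()
def boundaries():
    return BoundarySpec.main_defaults(
        refrigerant=RefrigerantParams(h_steady=TEST_H_STEADY))


class UniformMaterials:
    """Same material law in every region (for analytic benchmarks)."""

    def __init__(self, m: RegionMaterial):
        self._m = m

    def region(self, code):
        return self._m


def constant_material(rho=1060.0, c=3600.0, lam=0.5):
    """Linear heat conduction material: no phase change, no sources."""
    return RegionMaterial(rho=rho, c_liquid=c, c_frozen=c,
                          lambda_liquid=lam, lambda_frozen=lam,
                          latent_heat=0.0, T_solidus=-10.0, T_liquidus=0.0,
                          perfusion_coeff=0.0, q_metabolic=0.0)


def box_mesh(lx, ly, lz, nx, ny, nz, end_labels=("a", "c")):
    """Structured all-tissue box [0,lx]x[0,ly]x[0,lz] (mm); the z=0 face is
    tagged ``end_labels[0]``, the z=lz face ``end_labels[1]`` (None = untagged,
    i.e. insulated); all other faces insulated."""
    x = np.linspace(0, lx, nx + 1)
    y = np.linspace(0, ly, ny + 1)
    z = np.linspace(0, lz, nz + 1)
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    verts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    strides = ((ny + 1) * (nz + 1), nz + 1, 1)
    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    corner = (ix * strides[0] + iy * strides[1] + iz * strides[2]).ravel()
    tets = _kuhn_tets(corner, strides)
    mesh = ModelMesh(vertices=verts, tets=tets,
                     region=np.full(len(tets), REGION_TISSUE, np.int8),
                     boundary_facets=np.empty((0, 3), np.int64),
                     boundary_labels=np.empty(0, np.int8),
                     contact_facets=np.empty((0, 3), np.int64),
                     config=GeometryConfig())
    vol = mesh.tet_volumes()
    neg = vol < 0
    if np.any(neg):
        t = mesh.tets[neg]
        t[:, [2, 3]] = t[:, [3, 2]]
        mesh.tets[neg] = t
    ext = exterior_faces(mesh.tets)
    cent = verts[ext].mean(axis=1)
    labels = np.zeros(len(ext), dtype=np.int8)
    if end_labels[0]:
        labels[np.isclose(cent[:, 2], 0.0)] = BOUNDARY_CODES[end_labels[0]]
    if end_labels[1]:
        labels[np.isclose(cent[:, 2], lz)] = BOUNDARY_CODES[end_labels[1]]
    mesh.boundary_facets = ext
    mesh.boundary_labels = labels
    return mesh


def regular_tet_mesh(edge=1.0, label="a"):
    """A single regular tetrahedron with all four faces carrying ``label``."""
    verts = edge * np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                            dtype=float) / np.sqrt(2.0)
    tets = np.array([[0, 1, 2, 3]])
    mesh = ModelMesh(vertices=verts, tets=tets,
                     region=np.array([REGION_TISSUE], np.int8),
                     boundary_facets=np.empty((0, 3), np.int64),
                     boundary_labels=np.empty(0, np.int8),
                     contact_facets=np.empty((0, 3), np.int64),
                     config=GeometryConfig())
    if mesh.tet_volumes()[0] < 0:
        mesh.tets[0, [2, 3]] = mesh.tets[0, [3, 2]]
    ext = exterior_faces(mesh.tets)
    mesh.boundary_facets = ext
    mesh.boundary_labels = np.full(len(ext), BOUNDARY_CODES[label], np.int8)
    return mesh
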