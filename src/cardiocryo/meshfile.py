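"""Mesh and field file I/O.

Writers for VTK XML unstructured grids (.vtu, ASCII) and Gmsh MSH v2.2
(ASCII), plus an MSH reader for user-supplied meshes.  Region and boundary
tags are stored as integer cell data / physical tags using the table below.

Tag table (cell data ``region`` on tetrahedra, ``boundary`` on triangles):

====== =====================
value  meaning
====== =====================
1      tissue region
2      blood region
3      applicator region
1..6   boundary labels a..f
====== =====================
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np

from .geometry import GeometryConfig, MeshError, ModelMesh


def write_vtu(path, mesh: ModelMesh,
              point_data: Optional[Dict[str, np.ndarray]] = None,
              cell_data: Optional[Dict[str, np.ndarray]] = None) -> None:
    """Write the tetrahedral mesh (and optional nodal/cell fields) as ASCII VTU."""
    point_data = point_data or {}
    cell_data = dict(cell_data or {})
    cell_data.setdefault("region", mesh.region.astype(np.int32))
    n_pts, n_cells = mesh.n_vertices, mesh.n_tets

    def arr(a, fmt="%.9g"):
        return "\n".join(" ".join(fmt % x for x in np.atleast_1d(row))
                         for row in np.asarray(a))

    parts = ['<?xml version="1.0"?>',
             '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
             '<UnstructuredGrid>',
             f'<Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">',
             '<Points>',
             '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
             arr(mesh.vertices), '</DataArray>', '</Points>', '<Cells>',
             '<DataArray type="Int64" Name="connectivity" format="ascii">',
             arr(mesh.tets, "%d"), '</DataArray>',
             '<DataArray type="Int64" Name="offsets" format="ascii">',
             arr(np.arange(1, n_cells + 1) * 4, "%d"), '</DataArray>',
             '<DataArray type="UInt8" Name="types" format="ascii">',
             arr(np.full(n_cells, 10), "%d"), '</DataArray>', '</Cells>']
    if point_data:
        parts.append('<PointData>')
        for name, data in point_data.items():
            parts += [f'<DataArray type="Float64" Name="{name}" format="ascii">',
                      arr(data), '</DataArray>']
        parts.append('</PointData>')
    parts.append('<CellData>')
    for name, data in cell_data.items():
        typ = "Int32" if np.issubdtype(np.asarray(data).dtype, np.integer) else "Float64"
        fmt = "%d" if typ == "Int32" else "%.9g"
        parts += [f'<DataArray type="{typ}" Name="{name}" format="ascii">',
                  arr(data, fmt), '</DataArray>']
    parts += ['</CellData>', '</Piece>', '</UnstructuredGrid>', '</VTKFile>']
    with open(path, "w") as fh:
        fh.write("\n".join(parts) + "\n")


def write_msh(path, mesh: ModelMesh) -> None:
    """Write mesh as Gmsh MSH v2.2 ASCII; tets carry the region tag, boundary
    triangles the boundary-label tag."""
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes",
             str(mesh.n_vertices)]
    for i, (x, y, z) in enumerate(mesh.vertices, start=1):
        lines.append(f"{i} {x:.10g} {y:.10g} {z:.10g}")
    lines += ["$EndNodes", "$Elements"]
    tagged = mesh.boundary_labels > 0
    tris = mesh.boundary_facets[tagged]
    tri_tags = mesh.boundary_labels[tagged]
    lines.append(str(len(tris) + mesh.n_tets))
    eid = 1
    body = []
    for t, tag in zip(tris, tri_tags):
        body.append(f"{eid} 2 2 {tag} {tag} {t[0]+1} {t[1]+1} {t[2]+1}")
        eid += 1
    for t, tag in zip(mesh.tets, mesh.region):
        body.append(f"{eid} 4 2 {tag} {tag} {t[0]+1} {t[1]+1} {t[2]+1} {t[3]+1}")
        eid += 1
    lines += body + ["$EndElements"]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_msh(path, config: Optional[GeometryConfig] = None) -> ModelMesh:
    """Read a tagged MSH v2.2 mesh written by :func:`write_msh` (or produced
    externally with the same tag table)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    try:
        i_nodes = lines.index("$Nodes")
        n_nodes = int(lines[i_nodes + 1])
        verts = np.array([[float(v) for v in lines[i_nodes + 2 + k].split()[1:4]]
                          for k in range(n_nodes)])
        i_el = lines.index("$Elements")
        n_el = int(lines[i_el + 1])
    except (ValueError, IndexError) as exc:
        raise MeshError(f"cannot parse MSH file {path}: {exc}") from exc

    tets, regions, tris, tri_tags = [], [], [], []
    for k in range(n_el):
        parts = lines[i_el + 2 + k].split()
        etype = int(parts[1])
        n_tags = int(parts[2])
        tag = int(parts[3]) if n_tags else 0
        conn = [int(p) - 1 for p in parts[3 + n_tags:]]
        if etype == 4:
            tets.append(conn)
            regions.append(tag)
        elif etype == 2:
            tris.append(conn)
            tri_tags.append(tag)
    if not tets:
        raise MeshError(f"no tetrahedra in {path}")
    mesh = ModelMesh(vertices=verts,
                     tets=np.asarray(tets, np.int64),
                     region=np.asarray(regions, np.int8),
                     boundary_facets=np.asarray(tris, np.int64) if tris
                     else np.empty((0, 3), np.int64),
                     boundary_labels=np.asarray(tri_tags, np.int8) if tris
                     else np.empty(0, np.int8),
                     contact_facets=np.empty((0, 3), np.int64),
                     config=config or GeometryConfig())
    from .geometry import _tag_boundaries  # recover contact patch and checks
    _tag_boundaries(mesh)
    return mesh


def write_vtu_series(outdir, basename: str, mesh: ModelMesh, times, fields,
                     materials=None) -> list:
    """Write one VTU per stored snapshot (plus a liquid-fraction field when
    materials are given); returns the file list."""
    import os
    from .materials import liquid_fraction
    paths = []
    for i, t in enumerate(times):
        pd_ = {"temperature_C": fields[i]}
        if materials is not None:
            f = np.empty(mesh.n_tets)
            Tm = fields[i][mesh.tets].mean(axis=1)
            for code in (1, 2, 3):
                sel = mesh.region == code
                f[sel] = liquid_fraction(Tm[sel], materials.region(code))
            cd = {"liquid_fraction": f}
        else:
            cd = None
        p = os.path.join(outdir, f"{basename}_{i:04d}.vtu")
        write_vtu(p, mesh, point_data=pd_, cell_data=cd)
        paths.append(p)
    return paths
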