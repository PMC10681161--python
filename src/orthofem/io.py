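"""Mesh and field I/O in legacy ASCII VTK (plus helpers).

Volume meshes travel as VTK unstructured grids: tet cells, an integer
``region`` cell-data field and one 0/1 point-data field per named
boundary node set. Surfaces go out as VTK polydata or (via
``SurfaceMesh.save``) STL/PLY. The legacy ASCII format is written and
parsed directly — it is a simple line-oriented text format and keeps the
artifacts human-diffable.
"""

from __future__ import annotations

import numpy as np

from .compare import SurfaceMesh
from .phantom import LabeledMesh

_VTK_TET = 10
_VTK_TRI = 5


def write_vtk_mesh(
    mesh: LabeledMesh, path, point_vectors: dict[str, np.ndarray] | None = None
) -> None:
    """Write a labeled tet mesh (+ optional nodal vector fields) as legacy VTK."""
    n, m = mesh.n_nodes, len(mesh.tets)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\northofem labeled mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {n} double\n")
        for p in mesh.nodes:
            fh.write(f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g}\n")
        fh.write(f"CELLS {m} {5 * m}\n")
        for t in mesh.tets:
            fh.write(f"4 {t[0]} {t[1]} {t[2]} {t[3]}\n")
        fh.write(f"CELL_TYPES {m}\n")
        fh.write("\n".join([str(_VTK_TET)] * m) + "\n")
        fh.write(f"CELL_DATA {m}\nSCALARS region int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(int(r)) for r in mesh.element_region) + "\n")
        fh.write(f"POINT_DATA {n}\n")
        for name, nodes in mesh.node_sets.items():
            flags = np.zeros(n, dtype=int)
            flags[nodes] = 1
            fh.write(f"SCALARS {name} int 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join(map(str, flags)) + "\n")
        for name, vec in (point_vectors or {}).items():
            fh.write(f"VECTORS {name} double\n")
            for v in vec:
                fh.write(f"{v[0]:.12g} {v[1]:.12g} {v[2]:.12g}\n")


def read_vtk_mesh(path) -> tuple[LabeledMesh, dict[str, np.ndarray]]:
    """Read a legacy-VTK tet mesh written by :func:`write_vtk_mesh`.

    Returns the mesh (landmark targets left empty — they are config, not
    geometry) and any nodal vector fields found.
    """
    with open(path) as fh:
        tokens = fh.read().split()
    it = iter(range(len(tokens)))

    def find(word: str, start: int = 0) -> int:
        for i in range(start, len(tokens)):
            if tokens[i] == word:
                return i
        raise ValueError(f"{path}: missing {word} section")

    ip = find("POINTS")
    n = int(tokens[ip + 1])
    coords = np.array(tokens[ip + 3 : ip + 3 + 3 * n], dtype=float).reshape(n, 3)
    ic = find("CELLS")
    m = int(tokens[ic + 1])
    raw = np.array(tokens[ic + 3 : ic + 3 + 5 * m], dtype=np.int64).reshape(m, 5)
    if not np.all(raw[:, 0] == 4):
        raise ValueError(f"{path}: only tetrahedral cells are supported")
    tets = raw[:, 1:]
    ir = find("region")
    region = np.array(tokens[ir + 5 : ir + 5 + m], dtype=np.int32)

    node_sets: dict[str, np.ndarray] = {}
    vectors: dict[str, np.ndarray] = {}
    ipd = find("POINT_DATA")
    i = ipd + 2
    while i < len(tokens):
        if tokens[i] == "SCALARS":
            name = tokens[i + 1]
            start = i + 6  # SCALARS name type 1 LOOKUP_TABLE default
            flags = np.array(tokens[start : start + n], dtype=int)
            node_sets[name] = np.flatnonzero(flags)
            i = start + n
        elif tokens[i] == "VECTORS":
            name = tokens[i + 1]
            start = i + 3
            vectors[name] = np.array(tokens[start : start + 3 * n], dtype=float).reshape(n, 3)
            i = start + 3 * n
        else:
            i += 1

    # skin triangles are re-derived from the boundary of the volume mesh
    faces = tets[:, [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]]].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, first, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    boundary = faces[first[counts == 1]]
    ymax = coords[:, 1].max()
    on_skin = np.all(np.isclose(coords[boundary][:, :, 1], ymax, atol=1e-9), axis=1)
    skin = boundary[on_skin]

    mesh = LabeledMesh(
        nodes=coords,
        tets=tets,
        element_region=region,
        skin_faces=skin,
        node_sets=node_sets,
        landmark_targets={},
    )
    return mesh, vectors


def write_vtk_surface(
    surface: SurfaceMesh, path, point_scalars: dict[str, np.ndarray] | None = None
) -> None:
    """Write a triangulated surface (+ per-vertex scalars) as legacy VTK polydata."""
    n, m = len(surface.vertices), len(surface.faces)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\northofem surface\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {n} double\n")
        for p in surface.vertices:
            fh.write(f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g}\n")
        fh.write(f"POLYGONS {m} {4 * m}\n")
        for f in surface.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        if point_scalars:
            fh.write(f"POINT_DATA {n}\n")
            for name, values in point_scalars.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{v:.12g}" for v in values) + "\n")
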