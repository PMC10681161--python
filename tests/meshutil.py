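"""Tiny labeled block meshes for solver tests."""

from __future__ import annotations

import numpy as np

from orthofem.phantom import LabeledMesh, tetrahedral_block
from orthofem.regions import Region


def block_mesh(
    shape: tuple[int, int, int] = (2, 2, 2),
    lengths: tuple[float, float, float] = (1.0, 1.0, 1.0),
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    region: Region = Region.SOFT_TISSUE,
) -> LabeledMesh:
    """Uniform single-region block: `shape` cells spanning `lengths` mm."""
    xs = np.linspace(origin[0], origin[0] + lengths[0], shape[0] + 1)
    ys = np.linspace(origin[1], origin[1] + lengths[1], shape[1] + 1)
    zs = np.linspace(origin[2], origin[2] + lengths[2], shape[2] + 1)
    nodes, tets, _ = tetrahedral_block(xs, ys, zs)
    faces = tets[:, [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]]].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, first, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    boundary = faces[first[counts == 1]]
    ymax = ys[-1]
    skin = boundary[np.all(np.isclose(nodes[boundary][:, :, 1], ymax), axis=1)]
    return LabeledMesh(
        nodes=nodes,
        tets=tets,
        element_region=np.full(len(tets), int(region), dtype=np.int32),
        skin_faces=skin,
        node_sets={},
        landmark_targets={},
    )


def plane_nodes(mesh: LabeledMesh, axis: int, value: float) -> np.ndarray:
    return np.flatnonzero(np.isclose(mesh.nodes[:, axis], value))


def boundary_nodes(mesh: LabeledMesh) -> np.ndarray:
    lo = mesh.nodes.min(axis=0)
    hi = mesh.nodes.max(axis=0)
    on = np.zeros(mesh.n_nodes, dtype=bool)
    for ax in range(3):
        on |= np.isclose(mesh.nodes[:, ax], lo[ax]) | np.isclose(mesh.nodes[:, ax], hi[ax])
    return np.flatnonzero(on)
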