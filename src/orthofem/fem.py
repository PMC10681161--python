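"""Small-strain isotropic linear elasticity on labeled tetrahedral meshes.

Reproduces the surgical simulation setup: region-wise (E, nu) materials,
full fixation of the top of the head, back of the head, neck and the
whole mandible, and a prescribed rigid displacement of the LeFort I
segment u_LF1 = (0, advancement, impaction) in mm. The element is the
4-node constant-strain tetrahedron; the global system is solved by a
sparse direct factorization of the reduced (free-DoF) matrix with the
prescribed values re-inserted exactly.

Because the stiffness of each region is linear in its Young's modulus at
fixed Poisson's ratio, :class:`RegionStiffnessCache` pre-assembles one
unit-modulus matrix per region; a design-of-experiments sweep then only
re-scales and re-factorizes instead of re-assembling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .materials import MaterialMap, homogeneous_materials
from .phantom import LabeledMesh, LandmarkSet
from .regions import Region

#: Default LeFort I movement: mean advancement / impaction of the cohort (mm).
DEFAULT_ADVANCEMENT = 5.4
DEFAULT_IMPACTION = 3.8

_DEGENERACY_TOL = 1e-12


class FEMError(RuntimeError):
    """Assembly or solve failure (degenerate geometry, singular system...)."""


def _elasticity_matrix(E: float, nu: float) -> np.ndarray:
    """6x6 isotropic elasticity matrix, Voigt order (xx,yy,zz,xy,yz,zx)."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] = lam + 2 * mu
    D[np.arange(3, 6), np.arange(3, 6)] = mu
    return D


def _shape_gradients(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shape-function gradients and signed volumes for a batch of tets.

    ``coords`` has shape (m, 4, 3); returns gradients (m, 4, 3) and
    volumes (m,).
    """
    J = coords[:, 1:] - coords[:, :1]  # rows = edge vectors from node 0
    vol = np.linalg.det(J) / 6.0
    Jinv = np.linalg.inv(J)
    G = np.empty_like(coords)
    G[:, 1:] = np.transpose(Jinv, (0, 2, 1))  # grad(lambda_m) = row m of J^-T
    G[:, 0] = -G[:, 1:].sum(axis=1)
    return G, vol


def _batch_stiffness(coords: np.ndarray, E: float, nu: float) -> np.ndarray:
    """12x12 stiffness matrices K_e = V B^T D B for a batch of tets."""
    G, vol = _shape_gradients(coords)
    if np.any(vol <= 0):
        raise FEMError("non-positive tetrahedron volume in stiffness batch")
    m = len(coords)
    B = np.zeros((m, 6, 12))
    for i in range(4):
        gx, gy, gz = G[:, i, 0], G[:, i, 1], G[:, i, 2]
        c = 3 * i
        B[:, 0, c] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c] = gz
        B[:, 5, c + 2] = gx
    D = _elasticity_matrix(E, nu)
    return vol[:, None, None] * np.einsum("mji,jk,mkl->mil", B, D, B)


def element_stiffness_tet4(node_coords: np.ndarray, E: float, nu: float) -> np.ndarray:
    """Stiffness matrix of one constant-strain tetrahedron.

    ``node_coords`` is 4x3 (mm); E in MPa. The result is symmetric
    positive semidefinite with six rigid-body zero-energy modes. A tet
    whose volume is below ``1e-12 * (max edge)^3`` is rejected as
    degenerate.
    """
    coords = np.asarray(node_coords, dtype=float).reshape(1, 4, 3)
    if not E > 0:
        raise FEMError(f"E must be > 0, got {E}")
    if not (-1.0 < nu < 0.5):
        raise FEMError(f"nu must lie in (-1, 0.5), got {nu}")
    edges = coords[0][:, None, :] - coords[0][None, :, :]
    char = np.linalg.norm(edges, axis=-1).max()
    J = coords[0, 1:] - coords[0, :1]
    vol = np.linalg.det(J) / 6.0
    if vol <= _DEGENERACY_TOL * char**3:
        raise FEMError(f"degenerate tetrahedron (volume {vol:.3e}, edge {char:.3e})")
    return _batch_stiffness(coords, E, nu)[0]


@dataclass
class StiffnessSystem:
    """Assembled global sparse stiffness matrix tied to its mesh."""

    K: sp.csr_matrix  # (3n, 3n)
    mesh: LabeledMesh


def _element_dofs(tets: np.ndarray) -> np.ndarray:
    """(m, 12) global DoF indices for each element."""
    return (3 * tets[:, :, None] + np.arange(3)[None, None, :]).reshape(len(tets), 12)


def assemble(mesh: LabeledMesh, materials: MaterialMap) -> StiffnessSystem:
    """Assemble the global stiffness matrix, region by region."""
    n = mesh.n_nodes
    rows, cols, vals = [], [], []
    for region in mesh.regions_present():
        if region not in materials:
            raise FEMError(f"materials missing region {region.name}")
        E, nu = materials[region]
        sel = mesh.element_region == int(region)
        Ke = _batch_stiffness(mesh.nodes[mesh.tets[sel]], E, nu)
        dofs = _element_dofs(mesh.tets[sel])
        rows.append(np.repeat(dofs, 12, axis=1).ravel())
        cols.append(np.tile(dofs, (1, 12)).ravel())
        vals.append(Ke.ravel())
    K = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(3 * n, 3 * n),
    ).tocsr()
    return StiffnessSystem(K=K, mesh=mesh)


class RegionStiffnessCache:
    """Per-region unit-modulus stiffness matrices for fast material sweeps.

    K(materials) = sum_r E_r * A_r where A_r is the region's matrix
    assembled at E = 1 MPa with that region's Poisson's ratio. Valid as
    long as nu per region does not change between sweeps (it does not:
    soft regions keep 0.45, bone keeps 0.2).
    """

    def __init__(self, mesh: LabeledMesh, nu_by_region: dict[Region, float]):
        self.mesh = mesh
        self._unit: dict[Region, sp.csr_matrix] = {}
        self._nu = dict(nu_by_region)
        n = mesh.n_nodes
        for region in mesh.regions_present():
            sel = mesh.element_region == int(region)
            Ke = _batch_stiffness(mesh.nodes[mesh.tets[sel]], 1.0, self._nu[region])
            dofs = _element_dofs(mesh.tets[sel])
            A = sp.coo_matrix(
                (
                    Ke.ravel(),
                    (np.repeat(dofs, 12, axis=1).ravel(), np.tile(dofs, (1, 12)).ravel()),
                ),
                shape=(3 * n, 3 * n),
            ).tocsr()
            self._unit[region] = A

    @classmethod
    def for_materials(cls, mesh: LabeledMesh, materials: MaterialMap) -> "RegionStiffnessCache":
        nus = {r: materials[r][1] for r in mesh.regions_present()}
        return cls(mesh, nus)

    def system(self, materials: MaterialMap) -> StiffnessSystem:
        K = None
        for region, A in self._unit.items():
            E, nu = materials[region]
            if nu != self._nu[region]:
                raise FEMError(
                    f"cache built for nu={self._nu[region]} on {region.name}, got {nu}"
                )
            K = E * A if K is None else K + E * A
        return StiffnessSystem(K=K.tocsr(), mesh=self.mesh)


@dataclass(frozen=True)
class BoundaryConditionSet:
    """Zero-displacement node sets plus the prescribed LF1 movement."""

    fixed_nodes: np.ndarray
    prescribed_nodes: np.ndarray
    u_lf1: np.ndarray  # (3,) mm, (0, advancement, impaction)

    def __post_init__(self) -> None:
        if np.intersect1d(self.fixed_nodes, self.prescribed_nodes).size:
            raise FEMError("fixed and prescribed node sets overlap")
        if not np.all(np.isfinite(self.u_lf1)):
            raise FEMError("prescribed LF1 displacement must be finite")


def build_boundary_conditions(
    mesh: LabeledMesh,
    advancement: float = DEFAULT_ADVANCEMENT,
    impaction: float = DEFAULT_IMPACTION,
) -> BoundaryConditionSet:
    """Fix head/neck surfaces and the mandible; prescribe LF1 motion."""
    fixed = np.unique(
        np.concatenate(
            [
                mesh.node_sets["TOP_HEAD"],
                mesh.node_sets["BACK_HEAD"],
                mesh.node_sets["NECK"],
                mesh.region_nodes(Region.MANDIBLE),
            ]
        )
    )
    return BoundaryConditionSet(
        fixed_nodes=fixed,
        prescribed_nodes=mesh.region_nodes(Region.LF1),
        u_lf1=np.array([0.0, advancement, impaction]),
    )


@dataclass
class DisplacementField:
    """Per-node displacement vectors (mm) on the whole volume mesh."""

    u: np.ndarray  # (n_nodes, 3)

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.u, axis=1)

    def at(self, node: int) -> np.ndarray:
        return self.u[node]


def solve_with_dirichlet(
    system: StiffnessSystem,
    dirichlet_nodes: np.ndarray,
    dirichlet_values: np.ndarray,
    rtol: float = 1e-8,
) -> DisplacementField:
    """Solve K u = 0 subject to per-node Dirichlet values.

    ``dirichlet_values`` has shape (len(dirichlet_nodes), 3). The reduced
    system is factorized (sparse LU); the solution is accepted only if the
    relative residual of the free equations is <= ``rtol``. Prescribed
    values are re-inserted exactly.
    """
    n = system.mesh.n_nodes
    dirichlet_nodes = np.asarray(dirichlet_nodes)
    dofs = (3 * dirichlet_nodes[:, None] + np.arange(3)).ravel()
    vals = np.asarray(dirichlet_values, dtype=float).ravel()
    if dofs.size == 0:
        raise FEMError("no Dirichlet constraints: rigid-body modes unconstrained")
    mask = np.zeros(3 * n, dtype=bool)
    mask[dofs] = True
    free = np.flatnonzero(~mask)

    u = np.zeros(3 * n)
    u[dofs] = vals
    K = system.K.tocsc()
    Kff = K[free][:, free]
    rhs = -K[free][:, dofs] @ vals
    try:
        lu = spla.splu(Kff.tocsc())
        uf = lu.solve(rhs)
    except RuntimeError as exc:  # singular factorization
        raise FEMError(f"singular reduced system: {exc}") from exc
    if not np.all(np.isfinite(uf)):
        raise FEMError("solver produced non-finite values (singular reduced system?)")
    resid = np.linalg.norm(Kff @ uf - rhs)
    scale = max(np.linalg.norm(rhs), 1e-30)
    if resid / scale > rtol:
        raise FEMError(f"solver did not converge: relative residual {resid / scale:.2e}")
    u[free] = uf
    return DisplacementField(u=u.reshape(n, 3))


def solve(system: StiffnessSystem, bcs: BoundaryConditionSet) -> DisplacementField:
    """Solve the surgical load case defined by a BoundaryConditionSet."""
    nodes = np.concatenate([bcs.fixed_nodes, bcs.prescribed_nodes])
    values = np.vstack(
        [
            np.zeros((len(bcs.fixed_nodes), 3)),
            np.tile(bcs.u_lf1, (len(bcs.prescribed_nodes), 1)),
        ]
    )
    return solve_with_dirichlet(system, nodes, values)


def landmark_displacements(field: DisplacementField, landmarks: LandmarkSet) -> dict[str, float]:
    """Total (Euclidean-norm) displacement of each landmark node, mm."""
    return {name: float(np.linalg.norm(field.at(landmarks.node(name)))) for name in landmarks.names()}


def simulate_advancement(
    mesh: LabeledMesh,
    landmarks: LandmarkSet,
    materials: MaterialMap,
    advancement: float = DEFAULT_ADVANCEMENT,
    impaction: float = DEFAULT_IMPACTION,
    cache: RegionStiffnessCache | None = None,
) -> tuple[DisplacementField, dict[str, float]]:
    """Simulate the LeFort I repositioning and report landmark totals.

    The LF1 segment is displaced rigidly by (0, advancement, impaction)
    mm; head, neck and mandible are fully constrained. Returns the nodal
    displacement field and each landmark's total displacement.
    """
    system = cache.system(materials) if cache is not None else assemble(mesh, materials)
    bcs = build_boundary_conditions(mesh, advancement, impaction)
    field = solve(system, bcs)
    return field, landmark_displacements(field, landmarks)


def homogeneous_model(
    mesh: LabeledMesh,
    landmarks: LandmarkSet,
    materials_H: MaterialMap | None = None,
    advancement: float = DEFAULT_ADVANCEMENT,
    impaction: float = DEFAULT_IMPACTION,
    cache: RegionStiffnessCache | None = None,
) -> tuple[DisplacementField, dict[str, float]]:
    """The H model: muscles share the bulk soft-tissue properties."""
    if materials_H is None:
        materials_H = homogeneous_materials()
    return simulate_advancement(mesh, landmarks, materials_H, advancement, impaction, cache)
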