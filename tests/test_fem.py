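"""Linear-elastic solver: element oracles, assembly, solves, surgical BCs."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings
from hypothesis import strategies as st

from meshutil import block_mesh, boundary_nodes, plane_nodes

from orthofem.fem import (
    BoundaryConditionSet,
    FEMError,
    RegionStiffnessCache,
    assemble,
    build_boundary_conditions,
    element_stiffness_tet4,
    homogeneous_model,
    landmark_displacements,
    simulate_advancement,
    solve,
    solve_with_dirichlet,
)
from orthofem.materials import MaterialMap, homogeneous_materials
from orthofem.phantom import LandmarkSet, place_landmarks
from orthofem.regions import Region

UNIT_RIGHT_TET = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])


def energy_stiffness_oracle(coords, E, nu):
    """Independent stiffness oracle via the elastic energy bilinear form.

    For each unit nodal displacement pattern the (constant) displacement
    gradient is recovered by fitting an affine field to the nodal values;
    K_ij is then V * [lambda tr(eps_i) tr(eps_j) + 2 mu eps_i : eps_j],
    with no Voigt notation or B matrix involved.
    """
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    M = np.hstack([np.ones((4, 1)), coords])  # affine fit: u(x) = a + G x
    vol = abs(np.linalg.det(coords[1:] - coords[0])) / 6.0
    strains = []
    for k in range(12):
        nodal = np.zeros((4, 3))
        nodal[k // 3, k % 3] = 1.0
        coeff = np.linalg.solve(M, nodal)  # rows: [a; G^T]
        G = coeff[1:].T
        strains.append(0.5 * (G + G.T))
    K = np.empty((12, 12))
    for i in range(12):
        for j in range(12):
            K[i, j] = vol * (
                lam * np.trace(strains[i]) * np.trace(strains[j])
                + 2 * mu * np.sum(strains[i] * strains[j])
            )
    return K


class TestElementStiffness:
    def test_unit_right_tet_matches_energy_oracle(self):
        K = element_stiffness_tet4(UNIT_RIGHT_TET, E=1.0, nu=0.0)
        assert np.abs(K - energy_stiffness_oracle(UNIT_RIGHT_TET, 1.0, 0.0)).max() < 1e-10

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_random_tets_match_oracle_and_have_rigid_modes(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(-1, 1, size=(4, 3))
        vol = np.linalg.det(coords[1:] - coords[0]) / 6.0
        if abs(vol) < 1e-3:
            return
        if vol < 0:
            coords = coords[[0, 1, 3, 2]]
        E, nu = 10 ** rng.uniform(-1, 3), rng.uniform(0.0, 0.49)
        K = element_stiffness_tet4(coords, E, nu)
        assert np.abs(K - energy_stiffness_oracle(coords, E, nu)).max() < 1e-8 * np.abs(K).max()
        # symmetric, PSD with exactly 6 rigid-body zero modes
        assert np.abs(K - K.T).max() < 1e-10 * np.abs(K).max()
        w = np.linalg.eigvalsh(K)
        tol = 1e-9 * abs(w).max()
        assert (np.abs(w) < tol).sum() == 6
        assert np.all(w > -tol)

    def test_rigid_translations_produce_no_force(self):
        K = element_stiffness_tet4(UNIT_RIGHT_TET, E=2.0, nu=0.3)
        for ax in range(3):
            t = np.zeros(12)
            t[ax::3] = 1.0
            assert np.abs(K @ t).max() < 1e-12

    def test_coplanar_nodes_raise(self):
        flat = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]])
        with pytest.raises(FEMError, match="degenerate"):
            element_stiffness_tet4(flat, E=1.0, nu=0.3)

    def test_invalid_materials_raise(self):
        with pytest.raises(FEMError):
            element_stiffness_tet4(UNIT_RIGHT_TET, E=-1.0, nu=0.3)
        with pytest.raises(FEMError):
            element_stiffness_tet4(UNIT_RIGHT_TET, E=1.0, nu=0.5)


def dense_assemble(mesh, materials):
    """Brute-force dense assembly looping over elements."""
    n = mesh.n_nodes
    K = np.zeros((3 * n, 3 * n))
    for tet, lab in zip(mesh.tets, mesh.element_region):
        E, nu = materials[Region(lab)]
        Ke = element_stiffness_tet4(mesh.nodes[tet], E, nu)
        dofs = (3 * tet[:, None] + np.arange(3)).ravel()
        K[np.ix_(dofs, dofs)] += Ke
    return K


class TestAssembly:
    def test_single_element_equals_element_stiffness(self):
        mesh = block_mesh((1, 1, 1))
        mesh.tets = mesh.tets[:1]
        mesh.element_region = mesh.element_region[:1]
        mats = homogeneous_materials()
        K = assemble(mesh, mats).K.toarray()
        tet = mesh.tets[0]
        dofs = (3 * tet[:, None] + np.arange(3)).ravel()
        E, nu = mats[Region.SOFT_TISSUE]
        assert np.allclose(K[np.ix_(dofs, dofs)], element_stiffness_tet4(mesh.nodes[tet], E, nu))

    def test_matches_dense_oracle_and_symmetry(self):
        mesh = block_mesh((2, 1, 1), lengths=(2.0, 1.0, 1.0))
        mats = homogeneous_materials()
        K = assemble(mesh, mats).K
        dense = dense_assemble(mesh, mats)
        assert np.abs(K.toarray() - dense).max() < 1e-9 * np.abs(dense).max()
        asym = np.abs((K - K.T).toarray()).max()
        assert asym < 1e-12 * np.abs(K.toarray()).max()

    def test_missing_region_raises(self):
        mesh = block_mesh((1, 1, 1), region=Region.MASSETER_L)
        mats = MaterialMap({Region.SOFT_TISSUE: (0.1, 0.45)})
        with pytest.raises(FEMError, match="MASSETER_L"):
            assemble(mesh, mats)

    def test_region_cache_reproduces_direct_assembly(self, default_mesh, h_cache):
        mats = homogeneous_materials().with_muscles({"E_masseter": 0.01})
        direct = assemble(default_mesh, mats).K
        cached = h_cache.system(mats).K
        diff = np.abs((direct - cached)).max()
        assert diff < 1e-9 * np.abs(direct.max())


class TestSolve:
    def test_zero_prescription_gives_zero_field(self, default_mesh, h_cache):
        system = h_cache.system(homogeneous_materials())
        bcs = build_boundary_conditions(default_mesh, advancement=0.0, impaction=0.0)
        field = solve(system, bcs)
        assert np.abs(field.u).max() == 0.0

    def test_uniaxial_bar_closed_form(self):
        """nu=0 bar, bottom fixed, top stretched: u_z = z/L exactly."""
        L = 60.0
        mesh = block_mesh((2, 2, 6), lengths=(10.0, 10.0, L))
        mats = MaterialMap({Region.SOFT_TISSUE: (0.1, 0.0)})
        system = assemble(mesh, mats)
        bottom = plane_nodes(mesh, 2, 0.0)
        top = plane_nodes(mesh, 2, L)
        nodes = np.concatenate([bottom, top])
        values = np.vstack(
            [np.zeros((len(bottom), 3)), np.tile([0.0, 0.0, 1.0], (len(top), 1))]
        )
        field = solve_with_dirichlet(system, nodes, values)
        expected = np.zeros_like(field.u)
        expected[:, 2] = mesh.nodes[:, 2] / L
        assert np.abs(field.u - expected).max() < 1e-8

    def test_small_system_matches_dense_oracle(self):
        mesh = block_mesh((2, 2, 2), lengths=(2.0, 2.0, 2.0))  # 81 DoF
        mats = MaterialMap({Region.SOFT_TISSUE: (0.1, 0.45)})
        system = assemble(mesh, mats)
        bottom = plane_nodes(mesh, 2, 0.0)
        top = plane_nodes(mesh, 2, 2.0)
        nodes = np.concatenate([bottom, top])
        values = np.vstack(
            [np.zeros((len(bottom), 3)), np.tile([0.3, 0.5, 1.0], (len(top), 1))]
        )
        field = solve_with_dirichlet(system, nodes, values)
        # dense elimination oracle
        K = dense_assemble(mesh, mats)
        dofs = (3 * nodes[:, None] + np.arange(3)).ravel()
        u = np.zeros(3 * mesh.n_nodes)
        u[dofs] = values.ravel()
        free = np.setdiff1d(np.arange(3 * mesh.n_nodes), dofs)
        u[free] = np.linalg.solve(K[np.ix_(free, free)], -K[np.ix_(free, dofs)] @ values.ravel())
        assert np.abs(field.u.ravel() - u).max() < 1e-8 * max(np.abs(u).max(), 1.0)

    def test_unconstrained_system_raises(self):
        mesh = block_mesh((1, 1, 1))
        system = assemble(mesh, MaterialMap({Region.SOFT_TISSUE: (0.1, 0.45)}))
        with pytest.raises(FEMError):
            solve_with_dirichlet(system, np.array([], dtype=int), np.zeros((0, 3)))

    def test_patch_test_affine_field(self):
        """Affine displacement on the whole boundary is reproduced inside."""
        mesh = block_mesh((3, 3, 3), lengths=(3.0, 3.0, 3.0))
        mats = MaterialMap({Region.SOFT_TISSUE: (1.0, 0.3)})
        system = assemble(mesh, mats)
        A = np.array([[0.02, 0.01, 0.0], [0.005, -0.01, 0.02], [0.0, 0.03, 0.015]])
        b = np.array([0.1, -0.2, 0.05])
        bnd = boundary_nodes(mesh)
        field = solve_with_dirichlet(system, bnd, mesh.nodes[bnd] @ A.T + b)
        expected = mesh.nodes @ A.T + b
        assert np.abs(field.u - expected).max() < 1e-8


class TestSurgicalSimulation:
    def test_lf1_nodes_move_exactly_by_prescription(self, default_mesh, default_landmarks, h_cache):
        field, _ = simulate_advancement(
            default_mesh, default_landmarks, homogeneous_materials(), cache=h_cache
        )
        lf1 = default_mesh.region_nodes(Region.LF1)
        assert np.abs(field.u[lf1] - np.array([0.0, 5.4, 3.8])).max() == 0.0

    def test_fixed_surfaces_do_not_move(self, default_mesh, default_landmarks, h_cache):
        field, _ = simulate_advancement(
            default_mesh, default_landmarks, homogeneous_materials(), cache=h_cache
        )
        bcs = build_boundary_conditions(default_mesh)
        assert np.abs(field.u[bcs.fixed_nodes]).max() == 0.0

    def test_linearity_in_prescribed_displacement(self, default_mesh, default_landmarks, h_cache):
        mats = homogeneous_materials()
        f1, _ = simulate_advancement(
            default_mesh, default_landmarks, mats, advancement=5.4, impaction=3.8, cache=h_cache
        )
        f2, _ = simulate_advancement(
            default_mesh, default_landmarks, mats, advancement=10.8, impaction=7.6, cache=h_cache
        )
        scale = np.abs(f2.u).max()
        assert np.abs(f2.u - 2 * f1.u).max() < 1e-9 * scale

    def test_landmark_total_is_euclidean_norm(self):
        from orthofem.fem import DisplacementField

        u = np.zeros((5, 3))
        u[2] = [0.0, 3.0, 4.0]
        lms = LandmarkSet({"UL": (2, np.zeros(3))})
        totals = landmark_displacements(DisplacementField(u), lms)
        assert totals["UL"] == 5.0

    def test_disjoint_fixed_and_prescribed_sets(self, default_mesh):
        bcs = build_boundary_conditions(default_mesh)
        assert np.intersect1d(bcs.fixed_nodes, bcs.prescribed_nodes).size == 0
        with pytest.raises(FEMError, match="overlap"):
            BoundaryConditionSet(
                fixed_nodes=np.array([1, 2]),
                prescribed_nodes=np.array([2, 3]),
                u_lf1=np.zeros(3),
            )

    def test_homogeneous_model_equals_uniform_muscle_run(
        self, default_mesh, default_landmarks, h_cache
    ):
        mats = homogeneous_materials().with_muscles(
            {k: 0.1 for k in ("E_masseter", "E_buccinator", "E_orbicularis", "E_zygomaticus")}
        )
        f_het, t_het = simulate_advancement(
            default_mesh, default_landmarks, mats, cache=h_cache
        )
        f_h, t_h = homogeneous_model(default_mesh, default_landmarks, cache=h_cache)
        assert np.abs(f_het.u - f_h.u).max() < 1e-8
        assert t_het == pytest.approx(t_h, abs=1e-10)

    def test_cheek_landmarks_symmetric(self, default_mesh, default_landmarks, h_cache):
        _, totals = homogeneous_model(default_mesh, default_landmarks, cache=h_cache)
        assert abs(totals["LC"] - totals["RC"]) < 1e-6

    def test_landmark_displacements_strictly_positive(
        self, default_mesh, default_landmarks, h_cache
    ):
        _, totals = homogeneous_model(default_mesh, default_landmarks, cache=h_cache)
        assert all(v > 0 for v in totals.values())

    def test_field_scale_invariant_under_uniform_stiffening(
        self, default_mesh, default_landmarks, h_cache
    ):
        """Pure-Dirichlet loading: scaling every E leaves the field unchanged."""
        mats = homogeneous_materials()
        scaled = MaterialMap({r: (10 * E, nu) for r, (E, nu) in mats.table.items()})
        f1, _ = simulate_advancement(default_mesh, default_landmarks, mats, cache=h_cache)
        f2, _ = simulate_advancement(
            default_mesh, default_landmarks, scaled,
            cache=RegionStiffnessCache.for_materials(default_mesh, scaled),
        )
        assert np.abs(f1.u - f2.u).max() < 1e-8
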