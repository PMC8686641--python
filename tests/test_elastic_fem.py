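"""Tet4 elasticity solver: element matrices, oracles, loads, equilibrium."""

import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st

import palate_relief as pr
from palate_relief.elastic_fem import (
    BoundaryConditions,
    LoadPatchError,
    SingularSystemError,
)

E_RESIN, NU_RESIN = 2650.0, 0.3  # humid acrylic plate resin
MAT_RESIN = pr.MaterialParams(E_RESIN, NU_RESIN)


# ------------------------------------------------------------------ oracle
def oracle_element_stiffness(coords, E, nu):
    """Independent constant-strain-tet stiffness via explicit shape functions.

    Hand-coded strain-displacement and constitutive assembly (volume
    coordinates differentiated through the inverse Jacobian), kept separate
    from the implementation's coefficient-matrix route.
    """
    coords = np.asarray(coords, dtype=float)
    # gradients of barycentric shape functions: rows of inv([[1 x y z]...])^T
    A = np.ones((4, 4))
    A[:, 1:] = coords
    V = np.linalg.det(A) / 6.0
    grads = np.linalg.inv(A)[1:, :].T  # (4, 3)

    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.array(
        [
            [lam + 2 * mu, lam, lam, 0, 0, 0],
            [lam, lam + 2 * mu, lam, 0, 0, 0],
            [lam, lam, lam + 2 * mu, 0, 0, 0],
            [0, 0, 0, mu, 0, 0],
            [0, 0, 0, 0, mu, 0],
            [0, 0, 0, 0, 0, mu],
        ]
    )
    B = np.zeros((6, 12))
    for j in range(4):
        bx, by, bz = grads[j]
        B[:, 3 * j : 3 * j + 3] = [
            [bx, 0, 0],
            [0, by, 0],
            [0, 0, bz],
            [by, bx, 0],
            [0, bz, by],
            [bz, 0, bx],
        ]
    return V * B.T @ D @ B


def random_tet(rng):
    while True:
        coords = rng.random((4, 3)) * 4.0
        A = np.ones((4, 4))
        A[:, 1:] = coords
        if np.linalg.det(A) / 6.0 > 0.05:  # well-shaped, positive
            return coords


REF_TET = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)


class TestElementStiffness:
    def test_reference_tet_matches_oracle(self):
        K = pr.element_stiffness(REF_TET, pr.MaterialParams(1.0, 0.25))
        K_oracle = oracle_element_stiffness(REF_TET, 1.0, 0.25)
        np.testing.assert_allclose(K, K_oracle, rtol=1e-12, atol=1e-14)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_tets_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        coords = random_tet(rng)
        K = pr.element_stiffness(coords, MAT_RESIN)
        np.testing.assert_allclose(
            K, oracle_element_stiffness(coords, E_RESIN, NU_RESIN), rtol=1e-9
        )

    def test_symmetric(self):
        rng = np.random.default_rng(7)
        K = pr.element_stiffness(random_tet(rng), MAT_RESIN)
        np.testing.assert_allclose(K, K.T, rtol=0, atol=1e-12 * np.abs(K).max())

    def test_rigid_body_null_space(self):
        rng = np.random.default_rng(8)
        coords = random_tet(rng)
        K = pr.element_stiffness(coords, MAT_RESIN)
        scale = np.abs(K).max()
        # three translations
        for comp in range(3):
            u = np.zeros(12)
            u[comp::3] = 1.0
            assert np.abs(K @ u).max() <= 1e-10 * scale
        # three infinitesimal rotations
        for axis in range(3):
            w = np.zeros(3)
            w[axis] = 1.0
            u = np.cross(np.broadcast_to(w, (4, 3)), coords).ravel()
            assert np.abs(K @ u).max() <= 1e-9 * scale
        # exactly six zero-energy modes
        eig = np.linalg.eigvalsh(K)
        assert np.sum(np.abs(eig) < 1e-9 * scale) == 6
        assert np.all(eig[6:] > 0)

    def test_degenerate_tet_raises(self):
        flat = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)
        with pytest.raises(ValueError):
            pr.element_stiffness(flat, MAT_RESIN)

    def test_energy_positivity(self):
        rng = np.random.default_rng(9)
        mesh = pr.box_mesh(2, 2, 2, n=2)
        K = pr.assemble_stiffness(mesh, MAT_RESIN)
        u = rng.standard_normal(3 * mesh.n_nodes)
        u -= u.mean()  # still generically non-rigid
        assert u @ (K @ u) > 0


class TestSolver:
    def test_zero_load_zero_displacement(self, small_bilayer):
        bc = BoundaryConditions(
            fixed_nodes=small_bilayer.node_sets["bone_surface"],
            loads=np.zeros((small_bilayer.n_nodes, 3)),
        )
        u = pr.assemble_and_solve(
            small_bilayer, {"plate": MAT_RESIN, "mucosa": pr.MUCOSA_DEFAULT}, bc
        )
        assert np.abs(u.values).max() == 0.0

    def test_uniaxial_slab_closed_form(self):
        """10 mm cube of plate resin under 1 MPa pressure on rollers.

        Uniform stress sigma_zz = -p, von Mises = p, top displacement
        p*H/E; exact for consistent loads, so checked to 1e-8 relative.
        """
        H, p = 10.0, 1.0
        mesh = pr.box_mesh(H, H, H, n=3)
        loads = pr.pressure_load(mesh, "top", np.array([0.0, 0.0, -p]))
        dofs, vals = [], []
        for name, comp in (("bottom", 2), ("x0", 0), ("y0", 1)):
            for n in mesh.node_sets[name]:
                dofs.append(3 * n + comp)
                vals.append(0.0)
        bc = BoundaryConditions(
            fixed_nodes=np.empty(0, dtype=int),
            loads=loads,
            prescribed_dofs=np.array(dofs),
            prescribed_values=np.array(vals),
        )
        u = pr.assemble_and_solve(mesh, MAT_RESIN, bc)
        s = pr.recover_stress(mesh, MAT_RESIN, u)
        np.testing.assert_allclose(s.tensor[:, 2], -p, rtol=1e-8)
        np.testing.assert_allclose(s.vm, p, rtol=1e-8)
        top_uz = u.values[mesh.node_sets["top"], 2]
        np.testing.assert_allclose(top_uz, -p * H / E_RESIN, rtol=1e-8)

    @pytest.mark.parametrize("fixture", ["box", "flat", "domed"])
    def test_patch_test_linear_fields_exact(self, fixture, flat_geometry, small_bilayer):
        """Prescribing a linear field on the boundary reproduces it inside."""
        if fixture == "box":
            mesh = pr.box_mesh(2.0, 3.0, 1.0, n=2)
        elif fixture == "flat":
            mesh = pr.mesh_layered(flat_geometry, 4.0)
        else:
            mesh = small_bilayer
        A = np.array([[1e-3, 2e-4, -1e-4], [0, -5e-4, 3e-4], [2e-4, 1e-4, 4e-4]])
        b = np.array([1e-3, -2e-3, 5e-4])
        u_exact = mesh.nodes @ A.T + b

        bnodes = np.unique(mesh.boundary_faces())
        dofs = (3 * bnodes[:, None] + np.arange(3)).ravel()
        bc = BoundaryConditions(
            fixed_nodes=np.empty(0, dtype=int),
            loads=np.zeros((mesh.n_nodes, 3)),
            prescribed_dofs=dofs,
            prescribed_values=u_exact[bnodes].ravel(),
        )
        u = pr.assemble_and_solve(mesh, MAT_RESIN, bc)
        err = np.abs(u.values - u_exact).max() / np.abs(u_exact).max()
        assert err <= 1e-10

    def test_equilibrium_reactions_balance_load(self, small_bilayer):
        bc = pr.make_load(small_bilayer, total_force=111.0, patch_radius=3.0)
        u = pr.assemble_and_solve(
            small_bilayer, {"plate": MAT_RESIN, "mucosa": pr.MUCOSA_DEFAULT}, bc
        )
        total = u.reactions.sum(axis=0) + bc.loads.sum(axis=0)
        assert np.abs(total).max() <= 1e-6 * 111.0

    def test_unconstrained_raises(self, small_bilayer):
        bc = BoundaryConditions(
            fixed_nodes=np.empty(0, dtype=int),
            loads=np.zeros((small_bilayer.n_nodes, 3)),
        )
        with pytest.raises(SingularSystemError):
            pr.assemble_and_solve(small_bilayer, MAT_RESIN, bc)

    def test_refinement_convergence_at_probe(self):
        """Probe von Mises changes less per uniform refinement step.

        The slab dimensions are chosen so halving the edge length doubles
        the element count in every direction (true uniform refinement);
        the probe is a fixed 3 mm ball in the mucosa, volume-averaged to
        be well-defined for piecewise-constant element stresses.
        """
        cfg = pr.PalateConfig(
            arch_length=24.0,
            arch_half_width=12.0,
            dome_height=0.0,
            plate_thickness=4.0,
            thickness_bounds=tuple((8.0, 8.0) for _ in range(14)),
            mesh_edge=2.0,
        )
        g = pr.build_geometry(cfg, pr.sample_thickness_map(cfg))
        mats = {"plate": MAT_RESIN, "mucosa": pr.MUCOSA_DEFAULT}
        probe = np.array([0.0, 12.0, 4.0])
        vals = []
        for h in (4.0, 2.0, 1.0):
            mesh = pr.mesh_layered(g, h)
            bc = pr.make_load(mesh, total_force=111.0, patch_radius=6.0)
            u = pr.assemble_and_solve(mesh, mats, bc)
            s = pr.recover_stress(mesh, mats, u)
            c = mesh.nodes[mesh.tets].mean(axis=1)
            v = mesh.volumes()
            m = (mesh.part == pr.PART_MUCOSA) & (
                np.linalg.norm(c - probe, axis=1) <= 3.0
            )
            vals.append(float((s.vm[m] * v[m]).sum() / v[m].sum()))
        assert abs(vals[2] - vals[1]) <= abs(vals[1] - vals[0])


class TestVonMises:
    def test_analytic_states(self):
        # uniaxial
        assert pr.von_mises(np.array([[-1.7, 0, 0, 0, 0, 0]]))[0] == pytest.approx(1.7)
        # hydrostatic
        assert pr.von_mises(np.array([[2.3, 2.3, 2.3, 0, 0, 0]]))[0] == pytest.approx(0.0, abs=1e-12)
        # pure shear
        tau = 0.8
        assert pr.von_mises(np.array([[0, 0, 0, tau, 0, 0]]))[0] == pytest.approx(np.sqrt(3) * tau)

    @given(
        st.lists(st.floats(-5, 5), min_size=6, max_size=6),
        st.floats(-10, 10),
    )
    def test_hydrostatic_shift_invariance(self, sigma, p):
        t = np.array([sigma])
        shifted = t.copy()
        shifted[0, :3] += p
        np.testing.assert_allclose(
            pr.von_mises(shifted), pr.von_mises(t), rtol=1e-9, atol=1e-9
        )


class TestLoads:
    def test_total_load_exact(self, small_bilayer):
        bc = pr.make_load(small_bilayer, total_force=111.0, patch_radius=3.0)
        total = bc.loads.sum(axis=0)
        assert total[0] == 0.0 and total[1] == 0.0
        assert total[2] == pytest.approx(-111.0, rel=1e-12)

    def test_uniform_pressure_limit(self):
        """Infinite patch radius on a slab reproduces the uniaxial oracle."""
        H = 10.0
        mesh = pr.box_mesh(H, H, H, n=3, part=pr.PART_PLATE)
        mesh.node_sets["oral_surface"] = mesh.node_sets["top"]
        mesh.node_sets["bone_surface"] = mesh.node_sets["bottom"]
        F = 111.0
        bc = pr.make_load(mesh, total_force=F, patch_radius=1e9)
        dofs, vals = [], []
        for name, comp in (("bottom", 2), ("x0", 0), ("y0", 1)):
            for n in mesh.node_sets[name]:
                dofs.append(3 * n + comp)
                vals.append(0.0)
        bc = BoundaryConditions(
            fixed_nodes=np.empty(0, dtype=int),
            loads=bc.loads,
            prescribed_dofs=np.array(dofs),
            prescribed_values=np.array(vals),
        )
        u = pr.assemble_and_solve(mesh, MAT_RESIN, bc)
        s = pr.recover_stress(mesh, MAT_RESIN, u)
        np.testing.assert_allclose(s.tensor[:, 2], -F / H**2, rtol=1e-8)

    def test_single_node_patch_warns(self, flat_geometry):
        # edge length 5 puts a grid node exactly at the plate centre
        mesh = pr.mesh_layered(flat_geometry, 5.0)
        with pytest.warns(UserWarning, match="single node"):
            bc = pr.make_load(mesh, total_force=10.0, patch_radius=0.01)
        assert bc.loads[:, 2].sum() == pytest.approx(-10.0)
        assert np.sum(bc.loads[:, 2] != 0) == 1

    def test_empty_patch_raises(self, flat_geometry):
        mesh = pr.mesh_layered(flat_geometry, 4.0)
        shifted = mesh.copy()
        # move the centre outside any node's reach by using a tiny negative radius
        with pytest.raises(LoadPatchError):
            pr.make_load(shifted, total_force=10.0, patch_radius=-1.0)

    def test_material_validation(self):
        with pytest.raises(ValueError):
            pr.MaterialParams(-1.0, 0.3)
        with pytest.raises(ValueError):
            pr.MaterialParams(100.0, 0.5)
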