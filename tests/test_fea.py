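"""Finite-element machinery: meshing, BCs, solver verification problems."""

import warnings

import numpy as np
import pytest
import trimesh

from craniofab import fea
from craniofab.fea import MaterialProps

SOFT = {"implant": MaterialProps(100.0, 0.3, 10.0)}
PEEK = {"implant": MaterialProps(3738.0, 0.4, 99.9)}


def _unit_cube_mesh(voxel):
    cube = trimesh.creation.box(extents=(1, 1, 1))
    cube.apply_translation((0.5, 0.5, 0.5))
    return fea.build_fe_model(None, cube, voxel_size=voxel,
                              bounds=((0, 0, 0), (1, 1, 1)))


def _patch_test_model(sigma=1.0):
    """Unit cube, bottom held in z (plus minimal lateral restraint),
    uniform traction sigma pressing on the top face."""
    model = _unit_cube_mesh(0.25)
    nodes = model.nodes
    model = fea.fix_nodes(model, np.abs(nodes[:, 2]) < 1e-9, dofs=(2,))
    c0 = np.argmin(np.linalg.norm(nodes - [0, 0, 0], axis=1))
    c1 = np.argmin(np.linalg.norm(nodes - [1, 0, 0], axis=1))
    m0 = np.zeros(len(nodes), bool)
    m0[c0] = True
    model = fea.fix_nodes(model, m0, dofs=(0, 1))
    m1 = np.zeros(len(nodes), bool)
    m1[c1] = True
    model = fea.fix_nodes(model, m1, dofs=(1,))
    faces, _, _, _ = fea.boundary_faces(model)
    top = np.abs(model.nodes[faces].mean(axis=1)[:, 2] - 1) < 1e-9
    return fea.load_faces(model, faces[top], (0, 0, -sigma))


class TestMeshing:
    def test_single_voxel_is_six_tets_volume_one(self):
        model = _unit_cube_mesh(1.0)
        assert model.n_elements == 6
        assert model.element_volumes().sum() == pytest.approx(1.0, abs=1e-12)

    def test_element_volumes_positive_and_conserved(self):
        model = _unit_cube_mesh(0.25)
        v = model.element_volumes()
        assert (v > 0).all()
        assert v.sum() == pytest.approx(1.0, rel=1e-9)

    def test_bonded_interface_shares_nodes(self):
        """Two abutting boxes labelled as different regions share every node
        on their common face: the bonded-contact contract."""
        a = trimesh.creation.box(extents=(4, 4, 4))
        a.apply_translation((2, 2, 2))
        b = trimesh.creation.box(extents=(4, 4, 4))
        b.apply_translation((6, 2, 2))
        model = fea.build_fe_model(a, b, voxel_size=1.0,
                                   bounds=((0, 0, 0), (8, 4, 4)))
        skull_nodes = set(model.elements[model.region_elements("skull")].ravel())
        implant_nodes = set(model.elements[model.region_elements("implant")].ravel())
        shared = skull_nodes & implant_nodes
        interface = np.abs(model.nodes[:, 0] - 4.0) < 1e-9
        assert shared == set(np.where(interface)[0])

    def test_out_of_range_voxel_warns(self):
        cube = trimesh.creation.box(extents=(10, 10, 10))
        with pytest.warns(UserWarning, match="0.5-3"):
            fea.build_fe_model(None, cube, voxel_size=5.0)

    def test_empty_region_raises(self):
        tiny = trimesh.creation.box(extents=(0.1, 0.1, 0.1))
        big = trimesh.creation.box(extents=(10, 10, 10))
        with pytest.raises(ValueError, match="no voxels"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fea.build_fe_model(big, tiny, voxel_size=2.0)


class TestBoundaryConditions:
    def test_load_sums_to_total_on_flat_top(self):
        cube = trimesh.creation.box(extents=(10, 10, 4))
        cube.apply_translation((5, 5, 2))
        model = fea.build_fe_model(None, cube, voxel_size=1.0,
                                   bounds=((0, 0, 0), (10, 10, 4)))
        model = fea.apply_bcs(model, total_load=50.0, load_area=20.0,
                              base_slab=0.5, patch_center=(5.0, 5.0, 4.0))
        total = model.load.reshape(-1, 3).sum(axis=0)
        np.testing.assert_allclose(total, (0, 0, -50.0), atol=1e-9)

    def test_doubling_area_keeps_total(self):
        cube = trimesh.creation.box(extents=(10, 10, 4))
        cube.apply_translation((5, 5, 2))
        model = fea.build_fe_model(None, cube, voxel_size=1.0,
                                   bounds=((0, 0, 0), (10, 10, 4)))
        m1 = fea.apply_bcs(model, total_load=50.0, load_area=10.0, base_slab=0.5)
        m2 = fea.apply_bcs(model, total_load=50.0, load_area=20.0, base_slab=0.5)
        t1 = np.linalg.norm(m1.load.reshape(-1, 3).sum(axis=0))
        t2 = np.linalg.norm(m2.load.reshape(-1, 3).sum(axis=0))
        assert t1 == pytest.approx(t2, abs=1e-9) == pytest.approx(50.0, abs=1e-9)
        assert m2.meta["patch_area"] > m1.meta["patch_area"]

    def test_empty_fixed_set_raises(self):
        model = _unit_cube_mesh(0.5)
        model.fixed_dofs = np.zeros(3 * model.n_nodes, bool)
        model.load = np.zeros(3 * model.n_nodes)
        with pytest.raises(ValueError, match="no fixed"):
            fea.solve_linear_static(model, SOFT)


class TestSolverVerification:
    def test_constant_strain_patch_test_exact(self):
        """Uniaxial compression reproduces the constant stress state to
        solver precision everywhere in the mesh."""
        sigma = 1.0
        model = _patch_test_model(sigma)
        res = fea.solve_linear_static(model, SOFT)
        np.testing.assert_allclose(res.element_stress[:, 2], -sigma, atol=1e-9)
        np.testing.assert_allclose(res.element_von_mises, sigma, atol=1e-9)
        tip = -res.nodal_displacements[:, 2].min()
        assert tip == pytest.approx(sigma / 100.0, abs=1e-12)
        # fixed nodes do not move
        moved = np.abs(res.nodal_displacements.reshape(-1)[model.fixed_dofs])
        assert moved.max() < 1e-12

    def test_cantilever_matches_beam_theory(self):
        beam = trimesh.creation.box(extents=(100, 10, 10))
        beam.apply_translation((50, 5, 5))
        model = fea.build_fe_model(None, beam, voxel_size=1.0,
                                   bounds=((0, 0, 0), (100, 10, 10)))
        model = fea.fix_nodes(model, np.abs(model.nodes[:, 0]) < 1e-9)
        faces, _, _, areas = fea.boundary_faces(model)
        cent = model.nodes[faces].mean(axis=1)
        tip = np.abs(cent[:, 0] - 100) < 1e-9
        P = 10.0
        model = fea.load_faces(model, faces[tip], (0, 0, -P / areas[tip].sum()))
        res = fea.solve_linear_static(model, PEEK)
        delta = -res.nodal_displacements[:, 2].min()
        E, L, b = 3738.0, 100.0, 10.0
        expect = P * L**3 / (3 * E * (b * b**3 / 12))
        assert delta == pytest.approx(expect, rel=0.15)
        assert res.reaction_force[2] == pytest.approx(P, rel=1e-6)
        assert res.equilibrium_residual < 1e-6

    def test_mesh_convergence_on_short_beam(self):
        """Halving the voxel changes the tip deflection by under 10 %."""
        beam = trimesh.creation.box(extents=(40, 8, 8))
        beam.apply_translation((20, 4, 4))
        tips = []
        for h in (1.0, 0.5):
            model = fea.build_fe_model(None, beam, voxel_size=h,
                                       bounds=((0, 0, 0), (40, 8, 8)))
            model = fea.fix_nodes(model, np.abs(model.nodes[:, 0]) < 1e-9)
            faces, _, _, areas = fea.boundary_faces(model)
            cent = model.nodes[faces].mean(axis=1)
            tip = np.abs(cent[:, 0] - 40) < 1e-9
            model = fea.load_faces(model, faces[tip],
                                   (0, 0, -10.0 / areas[tip].sum()))
            res = fea.solve_linear_static(model, PEEK)
            tips.append(-res.nodal_displacements[:, 2].min())
        assert abs(tips[1] - tips[0]) / tips[1] < 0.10

    def test_loaded_floating_part_is_an_error(self):
        a = trimesh.creation.box(extents=(4, 4, 4))
        a.apply_translation((2, 2, 2))
        b = trimesh.creation.box(extents=(4, 4, 4))
        b.apply_translation((12, 2, 2))  # disconnected from a
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fea.build_fe_model(a, b, voxel_size=1.0,
                                       bounds=((0, 0, 0), (16, 4, 4)))
        model = fea.fix_nodes(model, model.nodes[:, 0] < 1e-9)  # anchor a only
        faces, _, _, _ = fea.boundary_faces(model)
        cent = model.nodes[faces].mean(axis=1)
        on_b = cent[:, 0] > 10
        model = fea.load_faces(model, faces[on_b], (0, 0, -1.0))
        with pytest.raises(ValueError, match="free-floating"):
            fea.solve_linear_static(model, {"skull": SOFT["implant"],
                                            "implant": SOFT["implant"]})

    def test_unloaded_floating_fragment_is_pinned(self):
        a = trimesh.creation.box(extents=(4, 4, 4))
        a.apply_translation((2, 2, 2))
        b = trimesh.creation.box(extents=(2, 2, 2))
        b.apply_translation((13, 1, 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fea.build_fe_model(a, b, voxel_size=1.0,
                                       bounds=((0, 0, 0), (16, 4, 4)))
        model = fea.fix_nodes(model, model.nodes[:, 0] < 1e-9)
        faces, _, _, _ = fea.boundary_faces(model)
        cent = model.nodes[faces].mean(axis=1)
        top_a = (np.abs(cent[:, 2] - 4) < 1e-9) & (cent[:, 0] < 5)
        model = fea.load_faces(model, faces[top_a], (0, 0, -1.0))
        with pytest.warns(UserWarning, match="pinning"):
            res = fea.solve_linear_static(model, {"skull": SOFT["implant"],
                                                  "implant": SOFT["implant"]})
        assert res.n_floating_nodes > 0
        assert res.max_von_mises > 0


class TestVonMises:
    def test_hydrostatic_is_zero(self):
        assert fea.von_mises(np.diag([5.0, 5.0, 5.0])) == pytest.approx(0.0)

    def test_uniaxial_identity(self):
        assert fea.von_mises(np.diag([7.0, 0, 0])) == pytest.approx(7.0)

    def test_pure_shear_sqrt3(self):
        tau = 3.0
        s = np.zeros((3, 3))
        s[0, 1] = s[1, 0] = tau
        assert fea.von_mises(s) == pytest.approx(np.sqrt(3) * tau)

    def test_voigt_rows_match_tensor(self, rng):
        v = rng.normal(size=6)
        t = np.array([[v[0], v[3], v[5]], [v[3], v[1], v[4]], [v[5], v[4], v[2]]])
        assert fea.von_mises(v) == pytest.approx(fea.von_mises(t))


class TestSummary:
    def test_pass_flag_and_safety_factor(self):
        model = _patch_test_model(1.0)
        res = fea.solve_linear_static(model, SOFT)
        rep = fea.summarize_fea(res, SOFT)
        assert rep["pass"]
        assert rep["regions"]["implant"]["safety_factor"] == pytest.approx(10.0,
                                                                           rel=1e-6)

    def test_paper_style_safety_factor_arithmetic(self):
        """At the study's reported peak stress the PEEK margin is 99.9/61.92."""
        assert 99.9 / 61.92 == pytest.approx(1.61, abs=0.005)

    def test_zero_load_zero_everything(self):
        model = _patch_test_model(0.0)
        res = fea.solve_linear_static(model, SOFT)
        assert res.max_von_mises == pytest.approx(0.0, abs=1e-12)
        assert res.max_displacement_magnitude == pytest.approx(0.0, abs=1e-12)
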