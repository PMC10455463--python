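"""Implant design: porosity, shelling, rim/core, diamond lattice, metrology."""

import numpy as np
import pytest
import trimesh
from scipy import ndimage

from craniofab import implant as imp


@pytest.fixture(scope="module")
def cube_core():
    box = trimesh.creation.box(extents=(10, 10, 10))
    box.apply_translation((5, 5, 5))
    return box


@pytest.fixture(scope="module")
def cube_fields(cube_core):
    return imp._core_fields(cube_core, 2.5, 0.1)


class TestPorosityFormula:
    def test_printed_design_volumes(self):
        """The study's bulk/scaffold volumes give ~70 % porosity."""
        assert imp.porosity(18719.33, 5571.13) == pytest.approx(70.24, abs=0.01)
        assert round(imp.porosity(18719.33, 5571.13)) == 70

    def test_limits(self):
        assert imp.porosity(123.4, 123.4) == 0.0
        assert imp.porosity(123.4, 0.0) == 100.0

    def test_scale_invariance(self):
        assert imp.porosity(5.0, 2.0) == imp.porosity(5000.0, 2000.0)

    def test_invalid_volumes_rejected(self):
        with pytest.raises(ValueError):
            imp.porosity(0.0, 0.0)
        with pytest.raises(ValueError):
            imp.porosity(10.0, 11.0)


class TestLatticeSpecValidation:
    def test_bad_radius_and_porosity(self):
        with pytest.raises(ValueError):
            imp.LatticeSpec(cell_size=2.0, strut_radius=1.5)
        with pytest.raises(ValueError):
            imp.LatticeSpec(target_porosity=1.0)
        with pytest.raises(ValueError):
            imp.LatticeSpec(cell_type="gyroid")


class TestOuterSurfaceExtraction:
    @staticmethod
    def _shell_template(r_out=30.0, r_in=26.0):
        """Spherical-shell wedge standing in for the implant template."""
        outer = trimesh.creation.icosphere(subdivisions=4, radius=r_out)
        inner = trimesh.creation.icosphere(subdivisions=4, radius=r_in)
        inner.invert()
        shell = trimesh.util.concatenate([outer, inner])
        return outer, shell

    def test_patch_is_outer_surface_only(self):
        outer, shell = self._shell_template()
        patch = imp.extract_outer_surface(shell, shell, eps=0.5)
        r = np.linalg.norm(patch.triangles_center, axis=1)
        assert (r > 28.0).all()
        assert patch.area == pytest.approx(outer.area, rel=0.02)

    def test_patch_normals_point_radially_out(self):
        _, shell = self._shell_template()
        patch = imp.extract_outer_surface(shell, shell, eps=0.5)
        radial = patch.triangles_center / np.linalg.norm(
            patch.triangles_center, axis=1, keepdims=True
        )
        dots = np.einsum("ij,ij->i", patch.face_normals, radial)
        assert dots.min() > 0.5

    def test_empty_patch_raises(self):
        _, shell = self._shell_template()
        far = shell.copy()
        far.apply_translation((200, 0, 0))
        with pytest.raises(ValueError):
            imp.extract_outer_surface(shell, far, eps=0.5)


class TestOffsetShell:
    def test_flat_square_prism(self):
        patch = trimesh.Trimesh(
            vertices=[[0, 0, 0], [10, 0, 0], [10, 10, 0], [0, 10, 0]],
            faces=[[0, 1, 2], [0, 2, 3]],
            process=False,
        )
        solid = imp.offset_shell(patch, 4.0)
        assert solid.volume == pytest.approx(400.0, rel=0.01)

    def test_spherical_cap_shell_closed_form(self):
        R, t = 40.0, 4.0
        sphere = trimesh.creation.icosphere(subdivisions=5, radius=R)
        keep = sphere.triangles_center[:, 2] > 0.6 * R
        cap = sphere.submesh([np.where(keep)[0]], append=True)
        solid = imp.offset_shell(cap, t)
        # exact volume of the spherical shell sector between radii R-t and R
        # subtended by the cap's solid angle
        area = cap.area
        omega = area / R**2
        expect = omega / 3.0 * (R**3 - (R - t) ** 3)
        assert solid.volume == pytest.approx(expect, rel=0.02)

    def test_zero_thickness_rejected(self):
        patch = trimesh.Trimesh(
            vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]], faces=[[0, 1, 2]],
            process=False,
        )
        with pytest.raises(ValueError):
            imp.offset_shell(patch, 0.0)


class TestPartitionRimCore:
    @staticmethod
    def _disk_patch(r=30.0, n=96):
        ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
        verts = np.column_stack([r * np.cos(ang), r * np.sin(ang), np.zeros(n)])
        verts = np.vstack([[0, 0, 0], verts])
        faces = [[0, 1 + i, 1 + (i + 1) % n] for i in range(n)]
        return trimesh.Trimesh(verts, faces, process=False)

    def test_volume_conservation(self):
        patch = self._disk_patch()
        solid = imp.offset_shell(patch, 4.0)
        rim, core = imp.partition_rim_core(solid, 5.0, patch, thickness=4.0,
                                           pitch=0.4)
        assert rim.volume + core.volume == pytest.approx(solid.volume, rel=0.01)

    def test_disk_core_radius_shrinks_by_rim_width(self):
        patch = self._disk_patch(r=30.0)
        solid = imp.offset_shell(patch, 4.0)
        _, core = imp.partition_rim_core(solid, 5.0, patch, thickness=4.0,
                                         pitch=0.4)
        ratio = core.volume / solid.volume
        assert ratio == pytest.approx((25.0 / 30.0) ** 2, rel=0.03)

    def test_zero_rim_returns_whole_core(self):
        patch = self._disk_patch(r=15.0)
        solid = imp.offset_shell(patch, 4.0)
        rim, core = imp.partition_rim_core(solid, 0.0, patch, thickness=4.0)
        assert rim is None
        assert core.volume == pytest.approx(solid.volume, rel=0.02)

    def test_rim_consuming_everything_raises(self):
        patch = self._disk_patch(r=10.0)
        solid = imp.offset_shell(patch, 4.0)
        with pytest.raises(ValueError):
            imp.partition_rim_core(solid, 11.0, patch, thickness=4.0)


class TestDiamondLattice:
    def test_volume_matches_voxel_oracle(self, cube_core):
        spec = imp.LatticeSpec(cell_size=5.0, strut_radius=0.8)
        fields = imp._core_fields(cube_core, 5.0, 0.1)
        mesh = imp.generate_diamond_lattice(cube_core, spec, _fields=fields)
        oracle = imp._scaffold_volume(fields[0], fields[1], 0.8)
        assert mesh.volume == pytest.approx(oracle, rel=0.03)
        assert mesh.is_watertight

    def test_volume_strictly_increasing_in_radius(self, cube_fields):
        grid, d, _ = cube_fields
        vols = [imp._scaffold_volume(grid, d, r) for r in (0.3, 0.5, 0.7)]
        assert vols[0] < vols[1] < vols[2]

    def test_vanishing_radius_vanishing_volume(self, cube_core):
        # fine grid so the anti-aliasing halo of a hairline strut is negligible
        grid, d, _ = imp._core_fields(cube_core, 2.5, 0.05)
        v1 = grid.volume()
        tiny = imp._scaffold_volume(grid, d, 1e-4)
        assert imp.porosity(v1, tiny) > 99.9

    def test_oversized_cell_rejected(self, cube_core):
        with pytest.raises(ValueError):
            imp.generate_diamond_lattice(
                cube_core, imp.LatticeSpec(cell_size=50.0, strut_radius=1.0)
            )

    def test_scaffold_single_connected_component(self, cube_core):
        spec = imp.LatticeSpec(cell_size=2.5, strut_radius=0.4)
        mesh = imp.generate_diamond_lattice(cube_core, spec, pitch=0.1)
        # largest-component filter leaves one strut network
        assert mesh.body_count == 1


class TestSolveStrutRadius:
    def test_hits_target_within_half_point(self, cube_core, cube_fields):
        r = imp.solve_strut_radius(cube_core, 2.5, 0.70, _fields=cube_fields)
        grid, d, _ = cube_fields
        p = imp.porosity(grid.volume(), imp._scaffold_volume(grid, d, r))
        assert 69.5 <= p <= 70.5

    def test_monotone_in_target(self, cube_core, cube_fields):
        r60 = imp.solve_strut_radius(cube_core, 2.5, 0.60, _fields=cube_fields)
        r80 = imp.solve_strut_radius(cube_core, 2.5, 0.80, _fields=cube_fields)
        assert r80 < r60

    def test_degenerate_targets_rejected(self, cube_core, cube_fields):
        for bad in (0.0, 1.0, 1.2):
            with pytest.raises(ValueError):
                imp.solve_strut_radius(cube_core, 2.5, bad, _fields=cube_fields)


class TestPoreDiameter:
    def test_matches_distance_transform_oracle(self, cube_core):
        spec = imp.LatticeSpec(cell_size=2.5, strut_radius=0.35)
        mesh = imp.generate_diamond_lattice(cube_core, spec, pitch=0.08)
        mean_um, samples = imp.measure_pore_diameter(
            mesh, n_samples=5, seed=3, within=cube_core
        )
        # oracle: max inscribed sphere from a 0.05 mm distance transform of
        # the analytic void space (periodic, so one interior block suffices)
        pitch = 0.05
        ax = np.arange(2.0, 8.0, pitch)
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        d = imp.lattice_distance(pts, 2.5).reshape(X.shape)
        void = d > 0.35
        edt = ndimage.distance_transform_edt(void, sampling=pitch)
        oracle_um = 2000.0 * edt.max()  # largest inscribed sphere in the void
        assert mean_um == pytest.approx(oracle_um, rel=0.10)

    def test_thin_struts_leave_cell_scale_voids(self):
        box = trimesh.creation.box(extents=(10, 10, 10))
        box.apply_translation((5, 5, 5))
        spec = imp.LatticeSpec(cell_size=5.0, strut_radius=0.1)
        mesh = imp.generate_diamond_lattice(box, spec, pitch=0.1)
        mean_um, _ = imp.measure_pore_diameter(mesh, n_samples=4, seed=1,
                                               within=box)
        assert mean_um >= 2500.0

    def test_deterministic_under_seed(self, cube_core):
        spec = imp.LatticeSpec(cell_size=2.5, strut_radius=0.4)
        mesh = imp.generate_diamond_lattice(cube_core, spec, pitch=0.12)
        a = imp.measure_pore_diameter(mesh, n_samples=1, seed=7, within=cube_core)
        b = imp.measure_pore_diameter(mesh, n_samples=1, seed=7, within=cube_core)
        assert a == b

    def test_bad_sample_count_rejected(self, cube_core):
        spec = imp.LatticeSpec(cell_size=2.5, strut_radius=0.4)
        mesh = imp.generate_diamond_lattice(cube_core, spec, pitch=0.15)
        with pytest.raises(ValueError):
            imp.measure_pore_diameter(mesh, n_samples=0)


class TestScrewHoles:
    @staticmethod
    def _plate():
        plate = trimesh.creation.box(extents=(30, 30, 4))
        return plate

    def test_volume_deficit_matches_cylinders(self):
        plate = self._plate()
        centers = [(-8, -8, 2), (8, -8, 2), (8, 8, 2), (-8, 8, 2)]
        axes = [(0, 0, 1)] * 4
        drilled = imp.add_screw_holes(plate, centers, diameter=2.0, axes=axes,
                                      length=20.0, pitch=0.1)
        deficit = plate.volume - drilled.volume
        assert deficit == pytest.approx(4 * np.pi * 1.0**2 * 4.0, rel=0.05)

    def test_holes_are_through_holes(self):
        plate = self._plate()
        drilled = imp.add_screw_holes(plate, [(0, 0, 2)], diameter=3.0,
                                      axes=[(0, 0, 1)], length=20.0, pitch=0.1)
        # every probe along the hole axis inside the old plate must now lie
        # outside the drilled solid: the hole goes all the way through
        from craniofab.geometry import SurfaceQuery

        probes = np.column_stack([np.zeros(9), np.zeros(9),
                                  np.linspace(-1.8, 1.8, 9)])
        sd, _, _ = SurfaceQuery(drilled).signed_distance(probes)
        assert (sd > 0).all()

    def test_vanishing_diameter_leaves_plate(self):
        plate = self._plate()
        drilled = imp.add_screw_holes(plate, [(0, 0, 2)], diameter=0.01,
                                      axes=[(0, 0, 1)], length=20.0, pitch=0.2)
        assert drilled.volume == pytest.approx(plate.volume, rel=0.01)

    def test_hole_outside_rim_raises(self):
        plate = self._plate()
        with pytest.raises(ValueError, match="outside"):
            imp.add_screw_holes(plate, [(100, 0, 2)], diameter=2.0,
                                axes=[(0, 0, 1)], length=10.0)


class TestImplantModel:
    def test_invariants_enforced(self, cube_core):
        rim = trimesh.creation.box(extents=(2, 2, 2))
        with pytest.raises(ValueError):
            imp.ImplantModel(rim, cube_core, np.zeros((4, 3)),
                             bulk_volume=10.0, scaffold_volume=11.0)

    def test_porosity_property(self, cube_core):
        rim = trimesh.creation.box(extents=(2, 2, 2))
        m = imp.ImplantModel(rim, cube_core, np.zeros((4, 3)),
                             bulk_volume=100.0, scaffold_volume=30.0)
        assert m.porosity_percent == pytest.approx(70.0)
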