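"""Deviation statistics, accuracy decomposition, gaps, and the MAS t-test."""

import warnings

import numpy as np
import pytest
import trimesh
from scipy import stats

from craniofab import fitting as fit
from craniofab import phantom as ph
from craniofab.geometry import RigidTransform, sample_surface
from craniofab.reconstruct import Plane


@pytest.fixture(scope="module")
def sphere():
    return trimesh.creation.icosphere(subdivisions=4, radius=10.0)


class TestSignedDeviation:
    def test_self_deviation_is_zero(self, sphere):
        dev = fit.signed_deviation(sphere, sphere)
        np.testing.assert_allclose(dev, 0.0, atol=1e-9)

    def test_offset_sphere_reports_offset(self, sphere):
        bigger = trimesh.creation.icosphere(subdivisions=4, radius=10.5)
        dev = fit.signed_deviation(bigger, sphere)
        assert dev.mean() == pytest.approx(0.5, abs=1e-6)

    def test_interior_point_negative(self, sphere):
        dev = fit.signed_deviation(np.array([[0.0, 0.0, 0.0]]), sphere)
        assert dev[0] < 0


class TestMeanOutwardDeviation:
    def test_constant_positive(self):
        assert fit.mean_outward_deviation(np.full(10, 0.7)) == pytest.approx(0.7)

    def test_negatives_excluded_by_definition(self):
        assert fit.mean_outward_deviation(np.array([2.0, -2.0])) == pytest.approx(2.0)

    def test_all_inward_flags_zero(self):
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            val, frac = fit.mean_outward_deviation(np.array([-1.0, -2.0]),
                                                   return_fraction=True)
        assert val == 0.0 and frac == 0.0
        assert any("no outward" in str(w.message) for w in rec)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fit.mean_outward_deviation(np.array([]))


class TestAlignment:
    def test_identity_cloud_aligns_trivially(self, sphere, rng):
        cloud, _ = sample_surface(sphere, 2000, rng)
        _, aligned, rms = fit.best_fit_align(cloud, sphere, coarse=False,
                                             init=RigidTransform.identity())
        assert rms < 1e-6

    def test_noise_floor_reflected_in_rms(self, small_defective, rng):
        cloud, _ = sample_surface(small_defective, 4000, rng)
        noisy = cloud + rng.normal(0, 0.1, cloud.shape)
        _, _, rms = fit.best_fit_align(noisy, small_defective, coarse=False,
                                       init=RigidTransform.identity())
        assert rms == pytest.approx(0.1, rel=0.2)

    def test_too_few_points_rejected(self, sphere):
        with pytest.raises(ValueError):
            fit.best_fit_align(np.zeros((2, 3)), sphere)


class TestRoiDeviation:
    def test_full_roi_equals_global(self, sphere):
        bigger = trimesh.creation.icosphere(subdivisions=3, radius=10.3)
        glob = fit.mean_outward_deviation(fit.signed_deviation(bigger, sphere))
        roi = fit.roi_deviation(bigger, sphere, roi=None)
        assert roi == pytest.approx(glob)

    def test_roi_excludes_outside_perturbation(self, sphere):
        """A bump confined outside the ROI leaves the ROI statistic below
        the global one."""
        bumped = sphere.copy()
        top = bumped.vertices[:, 2] > 8.0
        verts = bumped.vertices.copy()
        verts[top] *= 1.1
        bumped.vertices = verts
        roi_box = (np.array([-11, -11, -11.0]), np.array([11, 11, 0.0]))
        glob = fit.mean_outward_deviation(fit.signed_deviation(bumped, sphere))
        roi = fit.roi_deviation(bumped, sphere, roi=roi_box)
        assert roi <= glob

    def test_mirror_mode_symmetric_object_near_zero(self, small_skull):
        plane = Plane((0, 0, 0), (1, 0, 0))
        val = fit.roi_deviation(small_skull, small_skull, mode="mirror",
                                plane=plane)
        assert val < 0.05

    def test_empty_roi_raises(self, sphere):
        with pytest.raises(ValueError):
            fit.roi_deviation(sphere, sphere,
                              roi=((100, 100, 100), (101, 101, 101)))


class TestDecomposeAccuracy:
    def test_scan_equals_design_gives_zero_manufacturing(self, sphere):
        design = trimesh.creation.icosphere(subdivisions=3, radius=10.2)
        rep = fit.decompose_accuracy(sphere, design, design.vertices)
        assert rep.manufacturing_component == pytest.approx(0.0, abs=1e-9)
        assert rep.total == pytest.approx(rep.modeling_component)

    def test_design_equals_clean_gives_zero_modeling(self, sphere, rng):
        scan, _ = sample_surface(
            trimesh.creation.icosphere(subdivisions=3, radius=10.4), 3000, rng
        )
        rep = fit.decompose_accuracy(sphere, sphere, scan)
        assert rep.modeling_component == pytest.approx(0.0, abs=1e-9)
        assert rep.total == pytest.approx(rep.manufacturing_component)

    def test_reported_total_is_component_sum(self):
        """The decomposition convention: total = modelling + manufacturing,
        as in 0.1114 + 0.3322 = 0.4436."""
        assert 0.1114 + 0.3322 == pytest.approx(0.4436, abs=1e-12)
        s = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        d = trimesh.creation.icosphere(subdivisions=3, radius=10.2)
        m = trimesh.creation.icosphere(subdivisions=3, radius=10.5)
        rep = fit.decompose_accuracy(s, d, m.vertices)
        assert rep.total == pytest.approx(
            rep.modeling_component + rep.manufacturing_component, abs=1e-12
        )

    def test_gross_misalignment_rejected(self, sphere):
        far = sphere.copy()
        far.apply_translation((50, 0, 0))
        with pytest.raises(ValueError, match="misaligned"):
            fit.decompose_accuracy(sphere, far, far.vertices)


class TestGapAnalysis:
    def test_perfect_fill_zero_gap(self, unit_cube):
        rep = fit.gap_analysis(unit_cube, unit_cube)
        assert rep.gap_x == pytest.approx(0.0, abs=1e-12)
        assert rep.gap_y == pytest.approx(0.0, abs=1e-12)

    def test_shrunk_implant_gap(self, unit_cube):
        small = trimesh.creation.box(extents=(0.9, 1.0, 1.0))
        rep = fit.gap_analysis(small, unit_cube)
        assert rep.gap_x == pytest.approx(0.1, abs=1e-9)
        assert rep.gap_y == pytest.approx(0.0, abs=1e-9)

    def test_extents_reported_exactly(self):
        implant = trimesh.creation.box(extents=(62.25, 75.03, 4.0))
        cavity = trimesh.creation.box(extents=(62.20, 75.03, 4.0))
        rep = fit.gap_analysis(implant, cavity)
        assert rep.implant_extent_x == pytest.approx(62.25, abs=1e-9)
        assert rep.implant_extent_y == pytest.approx(75.03, abs=1e-9)
        assert rep.cavity_extent_x == pytest.approx(62.20, abs=1e-9)

    def test_empty_cavity_rejected(self, unit_cube):
        with pytest.raises(ValueError):
            fit.gap_analysis(unit_cube, trimesh.Trimesh())


class TestMASTest:
    def test_matches_independent_t_oracle(self):
        table = ph.simulate_vas(10, 5, mean=3.7, sd=0.6, seed=21)
        r = fit.mas_test(table)
        means = table.scores.mean(axis=1)
        t_o, p_o = stats.ttest_1samp(means, 3.0, alternative="greater")
        assert r.t_statistic == pytest.approx(t_o, abs=1e-9)
        assert r.p_value == pytest.approx(p_o, abs=1e-6)
        assert r.n == 10

    def test_textbook_example(self):
        """Per-expert means {4,4,3,4,3,4,4,3,4,4}: x-bar 3.7, strongly
        significant against mu0 = 3."""
        scores = np.array([[4], [4], [3], [4], [3], [4], [4], [3], [4], [4]])
        r = fit.mas_test(scores)
        x = scores.ravel().astype(float)
        t_manual = (x.mean() - 3.0) / (x.std(ddof=1) / np.sqrt(10))
        assert r.t_statistic == pytest.approx(t_manual, abs=1e-12)
        assert r.reject_null and r.p_value < 0.05

    def test_all_threes_cannot_reject(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = fit.mas_test(np.full((10, 5), 3))
        assert not r.reject_null
        assert r.zero_variance

    def test_alpha_zero_never_rejects(self):
        table = ph.simulate_vas(10, 5, mean=4.5, sd=0.3, seed=2)
        r = fit.mas_test(table, alpha=0.0)
        assert not r.reject_null

    def test_per_rating_variant_uses_all_observations(self):
        table = ph.simulate_vas(10, 5, mean=3.7, sd=0.6, seed=3)
        r = fit.mas_test(table, per_rating=True)
        assert r.n == 50

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError):
            fit.mas_test(np.array([[4]]))
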