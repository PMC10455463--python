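"""Shared fixtures: small phantoms for unit tests, the full-size design
chain (computed once per session) for end-to-end and acceptance checks."""

import warnings

import numpy as np
import pytest
import trimesh

from craniofab import imaging
from craniofab import phantom as ph
from craniofab import reconstruct as rc


@pytest.fixture(scope="session")
def small_spec():
    """Reduced skull phantom for fast unit tests."""
    return ph.PhantomSpec(
        outer_radii=(50.0, 60.0, 42.0),
        shell_thickness=5.0,
        defect_center=(-36.0, 4.0, 27.0),
        defect_radius=15.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def small_skull(small_spec):
    return ph.make_skull_phantom(small_spec, resolution=1.0)


@pytest.fixture(scope="session")
def small_defective(small_spec, small_skull):
    return ph.carve_defect(
        small_skull, small_spec.defect_center, small_spec.defect_radius, pitch=0.5
    )


@pytest.fixture(scope="session")
def default_spec():
    """The full-size study conditions (adult cranial vault)."""
    return ph.PhantomSpec()


@pytest.fixture(scope="session")
def design_chain(default_spec):
    """Full design workflow on the default phantom, computed once.

    Returns a dict with every intermediate from the clean CT-segmented
    skull through the partitioned implant body, shared by the slower
    end-to-end checks.
    """
    from craniofab import implant as imp

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        skull_true = ph.make_skull_phantom(default_spec, resolution=1.0)
        ct = ph.voxelize_to_ct(skull_true, spacing=1.0, noise_sd=30.0, seed=11)
        mask = imaging.region_grow(imaging.threshold_segment(ct, 226.0))
        skull = imaging.mask_to_mesh(mask, smoothing_iterations=10)
        defective = ph.carve_defect(
            skull, default_spec.defect_center, default_spec.defect_radius, pitch=0.5
        )
        plane = rc.fit_midsagittal_plane(defective, seed=12)
        pos, neg = rc.split_by_plane(defective, plane, pitch=0.8)
        dside = plane.signed_distance(np.asarray(default_spec.defect_center)[None])[0]
        healthy = neg if dside >= 0 else pos
        defect_free = rc.merge_and_wrap([rc.mirror_mesh(healthy, plane), healthy], 0.8)
        margin = default_spec.defect_radius + 12.0
        lo = np.asarray(default_spec.defect_center) - margin
        hi = np.asarray(default_spec.defect_center) + margin
        template = rc.largest_component(
            rc.boolean_subtract(defect_free, defective, pitch=0.5, bounds=(lo, hi))
        )
        patch = imp.extract_outer_surface(template, defect_free)
        body = imp.offset_shell(patch, 4.0)
        rim, core = imp.partition_rim_core(body, 6.0, patch, thickness=4.0, pitch=0.3)
        fields = imp._core_fields(core, 2.5, 0.1)
        strut_radius = imp.solve_strut_radius(core, 2.5, 0.70, _fields=fields)
        scaffold = imp.generate_diamond_lattice(
            core,
            imp.LatticeSpec(cell_size=2.5, strut_radius=strut_radius),
            _fields=fields,
        )
    return {
        "spec": default_spec,
        "skull_true": skull_true,
        "skull": skull,
        "defective": defective,
        "plane": plane,
        "defect_free": defect_free,
        "template": template,
        "patch": patch,
        "body": body,
        "rim": rim,
        "core": core,
        "fields": fields,
        "strut_radius": strut_radius,
        "scaffold": scaffold,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def unit_cube():
    return trimesh.creation.box(extents=(1.0, 1.0, 1.0))
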