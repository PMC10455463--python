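"""End-to-end orchestration: phantom -> CT -> design -> FEA -> fitting report.

A single :class:`RunConfig` carries every tunable of the workflow with
defaults matching the study settings it reproduces (4 mm implant shell,
70 % target porosity, 50 N over 200 mm^2, ten experts x five replicate
scores); :func:`run_pipeline` executes the stages in order, fails fast
naming the stage that broke, writes the artifacts of every stage plus a
JSON run manifest with checksums, and returns the manifest. Fixed seed
in, bit-identical metrics out.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import trimesh
import yaml

from . import fea as fea_mod
from . import fitting as fit
from . import imaging, implant as imp
from . import io as io_mod
from . import phantom as ph
from . import reconstruct as rc
from .geometry import RigidTransform

__all__ = ["RunConfig", "RunManifest", "StageError", "run_pipeline"]

log = logging.getLogger("craniofab.pipeline")


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


@dataclass
class RunConfig:
    """Every tunable of the pipeline, schema-validated before any compute."""

    # phantom
    outer_radii: tuple = (70.0, 85.0, 60.0)
    shell_thickness: float = 6.0
    asymmetry_amplitude: float = 0.0
    defect_center: tuple = (-52.0, 5.0, 40.0)
    defect_radius: float = 22.0
    phantom_resolution: float = 1.0
    # CT synthesis + segmentation
    ct_spacing: float = 1.0
    bone_hu: float = 1200.0
    background_hu: float = -1000.0
    ct_noise_sd: float = 30.0
    threshold_hu: float = 226.0
    smoothing_iterations: int = 10
    # reconstruction
    wrap_voxel: float = 0.8
    boolean_pitch: float = 0.5
    # implant design
    implant_thickness: float = 4.0
    rim_width: float = 6.0
    cell_size: float = 2.5
    target_porosity: float = 0.70
    screw_hole_diameter: float = 2.0
    n_pore_samples: int = 5
    lattice_pitch: float = 0.1
    partition_pitch: float = 0.3
    # FEA
    fea_voxel_size: float = 1.5
    total_load: float = 50.0
    load_area: float = 200.0
    base_slab: float = 5.0
    # fitting
    manufacturing_amplitude: float = 0.33
    manufacturing_correlation: float = 15.0
    scan_density: float = 1.0
    scan_noise_sd: float = 0.05
    roi_dilation: float = 5.0
    # aesthetic scoring
    n_experts: int = 10
    n_replicates: int = 5
    vas_mean: float = 3.66
    vas_sd: float = 0.5
    mas_mu0: float = 3.0
    mas_alpha: float = 0.05
    # bookkeeping
    seed: int = 0
    output_dir: str = "runs/craniofab"

    def __post_init__(self):
        self.validate()

    def validate(self) -> "RunConfig":
        r = np.asarray(self.outer_radii, float)
        if len(r) != 3 or (r <= 0).any():
            raise ValueError("outer_radii must be 3 positive semi-axes")
        if not 0 < self.shell_thickness < r.min():
            raise ValueError("shell_thickness must be in (0, min(outer_radii))")
        if self.defect_radius <= 0:
            raise ValueError("defect_radius must be positive")
        if not 0 < self.target_porosity < 1:
            raise ValueError("target_porosity must be in (0, 1)")
        if self.implant_thickness <= 0:
            raise ValueError("implant_thickness must be positive")
        if self.total_load <= 0 or self.load_area <= 0:
            raise ValueError("load and load_area must be positive")
        if not 1 <= self.vas_mean <= 5:
            raise ValueError("vas_mean must lie in [1, 5]")
        for name in ("ct_spacing", "wrap_voxel", "boolean_pitch", "cell_size",
                     "fea_voxel_size", "phantom_resolution"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_experts < 1 or self.n_replicates < 1:
            raise ValueError("need at least one expert and one replicate")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        known = {f_.name for f_ in cls.__dataclass_fields__.values()}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("outer_radii", "defect_center"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def phantom_spec(self) -> ph.PhantomSpec:
        return ph.PhantomSpec(
            outer_radii=tuple(self.outer_radii),
            shell_thickness=self.shell_thickness,
            asymmetry_amplitude=self.asymmetry_amplitude,
            defect_center=tuple(self.defect_center),
            defect_radius=self.defect_radius,
            seed=self.seed,
        )


@dataclass
class RunManifest:
    """Traceable record of one pipeline run: config, artifacts, metrics."""

    config: dict
    version: str = ""
    metrics: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path) -> Path:
        return io_mod.save_json(self.to_dict(), path)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _screw_positions(patch: trimesh.Trimesh, rim_width: float, n: int = 4):
    """Hole/screw sites: n points on the patch, ``rim_width/2`` in from the
    boundary, at even fractions of boundary arc length; axes = local normals."""
    from .geometry import boundary_loops

    loops = boundary_loops(patch)
    loop = max(loops, key=len)
    verts = patch.vertices.view(np.ndarray)[loop]
    normals = patch.vertex_normals.view(np.ndarray)[loop]
    seg = np.linalg.norm(np.roll(verts, -1, axis=0) - verts, axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])[:-1]
    total = arc[-1] + seg[-1]
    centroid = verts.mean(axis=0)
    centers, axes = [], []
    for k in range(n):
        i = int(np.searchsorted(arc, (k + 0.5) / n * total)) % len(loop)
        p = verts[i]
        nrm = normals[i] / np.linalg.norm(normals[i])
        inward = centroid - p
        inward -= (inward @ nrm) * nrm  # move within the surface tangent
        ninw = np.linalg.norm(inward)
        if ninw > 0:
            p = p + inward / ninw * (rim_width / 2.0)
        centers.append(p)
        axes.append(nrm)
    return np.array(centers), np.array(axes)


def _screw_mesh(center, axis, diameter, length) -> trimesh.Trimesh:
    cyl = trimesh.creation.cylinder(radius=diameter / 2.0, height=length, sections=24)
    T = trimesh.geometry.align_vectors([0, 0, 1], axis)
    cyl.apply_transform(T)
    # span from just proud of the outer surface through the shell
    cyl.apply_translation(np.asarray(center) - np.asarray(axis) * (length / 2.0 - 1.0))
    return cyl


def run_pipeline(
    config: RunConfig,
    output_dir=None,
    write_artifacts: bool = True,
) -> RunManifest:
    """Execute the full workflow and return its manifest.

    Stages: phantom -> CT synthesis -> segmentation -> defect ->
    mirror reconstruction -> implant design -> FEA -> fitting analysis ->
    aesthetic scoring. Any stage failure is re-raised as
    :class:`StageError` naming the stage.
    """
    config.validate()
    outdir = Path(output_dir if output_dir is not None else config.output_dir)
    if write_artifacts:
        outdir.mkdir(parents=True, exist_ok=True)
    from . import __version__

    manifest = RunManifest(config=config.to_dict(), version=__version__)
    state: dict = {}

    def artifact(name, obj, writer):
        if not write_artifacts:
            return
        path = writer(obj, outdir / name)
        manifest.artifacts[name] = {"path": str(path), "sha256": _sha256(path)}

    def stage(name):
        class _Ctx:
            def __enter__(self_):
                log.info("stage %s ...", name)
                self_.t0 = time.perf_counter()

            def __exit__(self_, exc_type, exc, tb):
                dt = time.perf_counter() - self_.t0
                manifest.timings_s[name] = round(dt, 3)
                if exc is not None:
                    raise StageError(f"stage {name!r} failed: {exc}") from exc
                log.info("stage %s done in %.1f s", name, dt)

        return _Ctx()

    seed = int(config.seed)
    log.info("run seed %d; per-stage seeds derive from it by fixed offsets", seed)

    with stage("phantom"):
        spec = config.phantom_spec()
        skull_true = ph.make_skull_phantom(spec, resolution=config.phantom_resolution)
        ct = ph.voxelize_to_ct(
            skull_true, spacing=config.ct_spacing, bone_hu=config.bone_hu,
            background_hu=config.background_hu, noise_sd=config.ct_noise_sd,
            seed=seed + 1,
        )
        artifact("phantom_true.stl", skull_true, io_mod.save_mesh)
        artifact("ct.nii.gz", ct, io_mod.save_volume)

    with stage("segment"):
        mask = imaging.threshold_segment(ct, lower=config.threshold_hu)
        mask = imaging.region_grow(mask, mode="largest")
        skull = imaging.mask_to_mesh(mask, config.smoothing_iterations)
        artifact("skull_clean.stl", skull, io_mod.save_mesh)

    with stage("defect"):
        defective = ph.carve_defect(
            skull, config.defect_center, config.defect_radius,
            pitch=config.boolean_pitch,
        )
        artifact("skull_defective.stl", defective, io_mod.save_mesh)

    with stage("reconstruct"):
        plane = rc.fit_midsagittal_plane(defective, seed=seed + 2)
        pos, neg = rc.split_by_plane(defective, plane, pitch=config.wrap_voxel)
        defect_side = plane.signed_distance(
            np.asarray(config.defect_center)[None]
        )[0]
        healthy = neg if defect_side >= 0 else pos
        mirrored = rc.mirror_mesh(healthy, plane)
        defect_free = rc.merge_and_wrap([mirrored, healthy], config.wrap_voxel)
        margin = config.defect_radius + 4 * config.wrap_voxel + 8.0
        lo = np.asarray(config.defect_center) - margin
        hi = np.asarray(config.defect_center) + margin
        template = rc.largest_component(
            rc.boolean_subtract(
                defect_free, defective, pitch=config.boolean_pitch, bounds=(lo, hi)
            )
        )
        state.update(plane=plane, defect_free=defect_free, template=template)
        artifact("skull_reconstructed.stl", defect_free, io_mod.save_mesh)
        artifact("implant_template.stl", template, io_mod.save_mesh)
        manifest.metrics["reconstruction"] = {
            "plane_normal": plane.normal,
            "plane_offset_mm": plane.offset,
            "template_volume_mm3": rc.mesh_volume(template),
        }

    with stage("design"):
        patch = imp.extract_outer_surface(template, defect_free)
        body = imp.offset_shell(patch, config.implant_thickness)
        rim, core = imp.partition_rim_core(
            body, config.rim_width, patch,
            thickness=config.implant_thickness, pitch=config.partition_pitch,
        )
        fields = imp._core_fields(core, config.cell_size, config.lattice_pitch)
        strut_r = imp.solve_strut_radius(
            core, config.cell_size, config.target_porosity,
            pitch=config.lattice_pitch, _fields=fields,
        )
        lattice_spec = imp.LatticeSpec(
            cell_size=config.cell_size, strut_radius=strut_r,
            target_porosity=config.target_porosity,
        )
        scaffold = imp.generate_diamond_lattice(
            core, lattice_spec, pitch=config.lattice_pitch, _fields=fields
        )
        v1 = fields[0].volume()
        v2 = imp._scaffold_volume(fields[0], fields[1], strut_r)
        screw_centers, screw_axes = _screw_positions(patch, config.rim_width)
        rim_holed = imp.add_screw_holes(
            rim, screw_centers, diameter=config.screw_hole_diameter,
            axes=screw_axes, length=4 * config.implant_thickness,
        )
        model = imp.ImplantModel(
            solid_rim=rim_holed, porous_core=scaffold,
            screw_hole_centers=screw_centers,
            bulk_volume=v1, scaffold_volume=v2, lattice=lattice_spec,
        )
        pore_mean, pore_samples = imp.measure_pore_diameter(
            scaffold, n_samples=config.n_pore_samples, seed=seed + 3, within=core
        )
        body_volume = rc.mesh_volume(body)
        state.update(
            patch=patch, body=body, implant=model,
            screw_axes=screw_axes, core=core,
        )
        artifact("implant_rim.stl", rim_holed, io_mod.save_mesh)
        artifact("implant_scaffold.stl", scaffold, io_mod.save_mesh)
        artifact("implant_assembled.stl", model.assembled(), io_mod.save_mesh)
        manifest.metrics["design"] = {
            "V1_core_mm3": v1,
            "V2_scaffold_mm3": v2,
            "porosity_core_percent": imp.porosity(v1, v2),
            "porosity_assembly_percent": imp.porosity(
                body_volume, body_volume - v1 + v2
            ),
            "strut_radius_mm": strut_r,
            "cell_size_mm": config.cell_size,
            "pore_diameter_um_mean": pore_mean,
            "pore_diameter_um_samples": pore_samples,
            "body_volume_mm3": body_volume,
        }

    with stage("fea"):
        screws = [
            _screw_mesh(c, a, config.screw_hole_diameter,
                        length=4 * config.implant_thickness)
            for c, a in zip(state["implant"].screw_hole_centers, state["screw_axes"])
        ]
        model = fea_mod.build_fe_model(
            defective,
            [state["implant"].solid_rim, state["implant"].porous_core],
            screws,
            voxel_size=config.fea_voxel_size,
        )
        model = fea_mod.apply_bcs(
            model, base_slab=config.base_slab,
            total_load=config.total_load, load_area=config.load_area,
        )
        result = fea_mod.solve_linear_static(model)
        summary = fea_mod.summarize_fea(result)
        summary["n_elements"] = model.n_elements
        summary["n_nodes"] = model.n_nodes
        summary["patch_area_mm2"] = model.meta["patch_area"]
        manifest.metrics["fea"] = summary
        if write_artifacts:
            path = io_mod.save_fea_vtk(result, outdir / "fea_solution.vtk")
            manifest.artifacts["fea_solution.vtk"] = {
                "path": str(path), "sha256": _sha256(path)
            }

    with stage("fitting"):
        designed = state["implant"].assembled()
        manufactured = ph.simulate_manufacturing(
            designed, config.manufacturing_amplitude,
            correlation_length=config.manufacturing_correlation, seed=seed + 4,
        )
        pose = RigidTransform.from_axis_angle(
            [0.2, 1.0, 0.3], 0.15, (5.0, -4.0, 3.0)
        )
        scan = ph.simulate_scan(
            manufactured, points_per_mm2=config.scan_density,
            noise_sd=config.scan_noise_sd, pose=pose, seed=seed + 5,
        )
        _, aligned, rms = fit.best_fit_align(
            scan, designed, init=RigidTransform.identity(), coarse=False
        )
        lo = np.asarray(config.defect_center) - config.defect_radius - config.roi_dilation
        hi = np.asarray(config.defect_center) + config.defect_radius + config.roi_dilation
        report = fit.decompose_accuracy(
            clean=skull, designed_reconstruction=designed,
            scanned_reconstruction=aligned, roi=(lo, hi),
        )
        cavity = rc.largest_component(
            rc.boolean_subtract(
                skull, defective, pitch=config.boolean_pitch,
                bounds=(lo - 5, hi + 5),
            )
        )
        gaps = fit.gap_analysis(state["body"], cavity)
        manifest.metrics["fitting"] = {
            **report.to_dict(),
            "n_scan_points": len(scan),
            "scan_alignment_rms_mm": rms,
            "ground_truth_manufacturing_mm": manufactured.metadata[
                "mean_displacement_mm"
            ],
            "gap": gaps.to_dict(),
        }
        artifact("scan_aligned.xyz", aligned, io_mod.save_xyz)
        if write_artifacts:
            path = io_mod.save_deviation_ply(
                aligned, report.per_point, outdir / "deviation_map.ply"
            )
            manifest.artifacts["deviation_map.ply"] = {
                "path": str(path), "sha256": _sha256(path)
            }
            np.savetxt(outdir / "deviation_per_point.csv",
                       report.per_point, fmt="%.6f",
                       header="signed_deviation_mm", comments="")

    with stage("vas"):
        table = ph.simulate_vas(
            config.n_experts, config.n_replicates,
            mean=config.vas_mean, sd=config.vas_sd, seed=seed + 6,
        )
        mas = fit.mas_test(table, mu0=config.mas_mu0, alpha=config.mas_alpha)
        manifest.metrics["vas"] = mas.to_dict()
        artifact("vas_scores.csv", table, io_mod.save_vas)

    if write_artifacts:
        manifest.save(outdir / "manifest.json")
    return manifest
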