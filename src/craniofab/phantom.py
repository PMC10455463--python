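"""Synthetic skull phantom and every other input the pipeline consumes.

The phantom is a bilaterally symmetric ellipsoidal bone shell rather than
an anatomical skull: the design workflow downstream depends only on
bilateral symmetry and two-surface shell topology, and the ellipsoid
gives closed-form volumes to test against. The world frame puts the
midsagittal plane at x = 0 (left negative), y anterior-posterior and
z inferior-superior, all in mm.

Alongside the bone geometry this module fabricates the measurement
inputs of a real study: a CT-like intensity volume, a segmental defect,
a "manufactured" implant with a controlled outward shape error, a noisy
rigidly-posed surface scan, and expert aesthetic-score tables. Every
generator is seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from skimage import measure

from .geometry import RigidTransform, sample_surface, voxelize

__all__ = [
    "PhantomSpec",
    "ImageVolume",
    "VASTable",
    "RigidTransform",
    "make_skull_phantom",
    "voxelize_to_ct",
    "carve_defect",
    "simulate_manufacturing",
    "simulate_scan",
    "simulate_vas",
    "DefectError",
]


class DefectError(ValueError):
    """Raised when a requested defect does not intersect the bone shell."""


# Defaults approximate an adult cranial vault: breadth 140 mm, length
# 170 mm, height 120 mm, cortical shell 6 mm. The defect sits on the left
# parietal region, centred on the mid-surface of the shell.
@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the ellipsoidal skull shell phantom (all mm)."""

    outer_radii: tuple[float, float, float] = (70.0, 85.0, 60.0)
    shell_thickness: float = 6.0
    asymmetry_amplitude: float = 0.0
    defect_center: tuple[float, float, float] = (-52.0, 5.0, 40.0)
    defect_radius: float = 22.0
    seed: int = 0

    def __post_init__(self):
        r = np.asarray(self.outer_radii, dtype=float)
        if len(r) != 3 or np.any(r <= 0):
            raise ValueError("outer_radii must be three positive semi-axes")
        if not 0 < self.shell_thickness < r.min():
            raise ValueError("shell_thickness must be in (0, min(outer_radii))")
        if self.defect_radius <= 0:
            raise ValueError("defect_radius must be positive")
        if self.asymmetry_amplitude < 0:
            raise ValueError("asymmetry_amplitude must be >= 0")

    @property
    def inner_radii(self) -> np.ndarray:
        return np.asarray(self.outer_radii, dtype=float) - self.shell_thickness


@dataclass
class ImageVolume:
    """CT-like scalar volume: intensities (HU), voxel spacing and origin.

    Voxel index (i, j, k) is 0-based; its world centre is
    ``origin + index * spacing``.
    """

    intensities: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities)
        self.spacing = np.broadcast_to(
            np.asarray(self.spacing, dtype=float), (3,)
        ).copy()
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive on all axes")
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3-D array")

    @property
    def affine(self) -> np.ndarray:
        A = np.eye(4)
        A[:3, :3] = np.diag(self.spacing)
        A[:3, 3] = self.origin
        return A


@dataclass
class VASTable:
    """Expert visual-analog scores, experts x replicates, each in 1..5."""

    scores: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.scores)
        if s.ndim != 2 or s.size == 0:
            raise ValueError("scores must be a non-empty experts x replicates grid")
        if not np.issubdtype(s.dtype, np.integer):
            raise ValueError("scores must be integers")
        if s.min() < 1 or s.max() > 5:
            raise ValueError("scores must lie in [1, 5]")
        self.scores = s

    @property
    def n_experts(self) -> int:
        return self.scores.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.scores.shape[1]

    def expert_means(self) -> np.ndarray:
        return self.scores.mean(axis=1)


# ---------------------------------------------------------------------------
# smooth random fields (shared by asymmetry bumps and manufacturing noise)
# ---------------------------------------------------------------------------


def _smooth_field(points: np.ndarray, correlation_length: float, rng, n_modes: int = 12):
    """Zero-mean unit-RMS smooth random field: a sum of random cosine waves.

    Wavelengths cluster around ``correlation_length`` so the field varies
    smoothly on that scale; the analytic RMS of the sum is normalized out.
    """
    k0 = 2.0 * np.pi / correlation_length
    dirs = rng.normal(size=(n_modes, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    mags = k0 * rng.uniform(0.6, 1.4, size=n_modes)
    phases = rng.uniform(0, 2 * np.pi, size=n_modes)
    vals = np.zeros(len(points))
    for m in range(n_modes):
        vals += np.cos(points @ (dirs[m] * mags[m]) + phases[m])
    return vals / np.sqrt(n_modes / 2.0)


# ---------------------------------------------------------------------------
# phantom surface
# ---------------------------------------------------------------------------


def make_skull_phantom(spec: PhantomSpec, resolution: float = 1.0) -> trimesh.Trimesh:
    """Build the watertight two-surface skull shell mesh.

    The shell is the region between concentric ellipsoids (outer semi-axes
    minus ``shell_thickness`` gives the inner ones), extracted by marching
    cubes on a smooth implicit field sampled at ``resolution`` mm. With
    ``asymmetry_amplitude`` > 0, the outer surface of the left (x < 0)
    side is displaced radially by a smooth seeded bump field; at 0 the
    mesh is mirror-symmetric about x = 0 by construction (the sampling
    grid itself is symmetric).
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    outer = np.asarray(spec.outer_radii, dtype=float)
    inner = spec.inner_radii
    margin = spec.asymmetry_amplitude + 3.0 * resolution
    half = outer + margin
    n = 2 * np.ceil(half / resolution).astype(int)
    # cell centres at +-(k + 1/2) * resolution: symmetric about every axis plane
    axes = [(np.arange(n[i]) - (n[i] - 1) / 2.0) * resolution for i in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)

    rho_out = np.sqrt((X / outer[0]) ** 2 + (Y / outer[1]) ** 2 + (Z / outer[2]) ** 2)
    rho_in = np.sqrt((X / inner[0]) ** 2 + (Y / inner[1]) ** 2 + (Z / inner[2]) ** 2)

    g_out = 1.0 - rho_out
    if spec.asymmetry_amplitude > 0:
        rng = np.random.default_rng(spec.seed)
        bump = _smooth_field(pts.reshape(-1, 3), 40.0, rng).reshape(X.shape)
        ramp = np.clip(-X / 15.0, 0.0, 1.0)
        ramp = ramp * ramp * (3 - 2 * ramp)  # smoothstep, 0 at x>=0
        radial = np.maximum(np.sqrt(X**2 + Y**2 + Z**2), 1e-6)
        # radial displacement of the outer surface by amplitude*bump mm
        g_out = g_out + spec.asymmetry_amplitude * bump * ramp * rho_out / radial

    shell = np.minimum(g_out, rho_in - 1.0)  # positive inside the shell wall
    verts, faces, _, _ = measure.marching_cubes(shell, level=0.0)
    verts = verts * resolution + np.array([a[0] for a in axes])
    from .geometry import clean_mesh

    return clean_mesh(trimesh.Trimesh(vertices=verts, faces=faces, process=False))


def analytic_shell_volume(spec: PhantomSpec) -> float:
    """Closed-form volume of the symmetric shell (mm^3): outer minus inner ellipsoid."""
    outer = np.asarray(spec.outer_radii, dtype=float)
    inner = spec.inner_radii
    return float(4.0 / 3.0 * np.pi * (np.prod(outer) - np.prod(inner)))


# ---------------------------------------------------------------------------
# CT synthesis
# ---------------------------------------------------------------------------


def voxelize_to_ct(
    mesh: trimesh.Trimesh,
    spacing: float = 1.0,
    bone_hu: float = 1200.0,
    background_hu: float = -1000.0,
    noise_sd: float = 30.0,
    seed: int = 0,
) -> ImageVolume:
    """Rasterize a watertight bone surface into a CT-like volume.

    Voxels whose centres fall inside the mesh take ``bone_hu``, the rest
    ``background_hu``; independent Gaussian noise of ``noise_sd`` HU is
    added everywhere. Defaults give a conventional cortical-bone/air
    contrast so threshold segmentation behaves like it does on real CT.
    """
    if np.ndim(spacing) != 0:
        spacing = float(np.unique(np.asarray(spacing))[0])
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    from .geometry import is_closed

    if not (mesh.is_watertight or is_closed(mesh)):
        raise ValueError("mesh must be closed to rasterize")
    grid = voxelize(mesh, float(spacing))
    vol = np.where(grid.occ, float(bone_hu), float(background_hu))
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vol = vol + rng.normal(0.0, noise_sd, size=vol.shape)
    return ImageVolume(vol.astype(np.float32), spacing, grid.origin)


# ---------------------------------------------------------------------------
# defect carving
# ---------------------------------------------------------------------------


def carve_defect(
    skull: trimesh.Trimesh,
    center,
    radius: float,
    pitch: float = 0.5,
) -> trimesh.Trimesh:
    """Resect a spherical segmental region from the bone shell.

    Boolean difference skull minus ball(center, radius) on an occupancy
    grid at ``pitch`` mm, returned as a watertight mesh. Raises
    :class:`DefectError` when the ball misses the shell entirely (a
    silent no-op would invalidate every downstream fitting test).
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    center = np.asarray(center, dtype=float).reshape(3)
    from .geometry import occupancy_to_mesh

    grid = voxelize(skull, pitch)
    ball = grid.ball_fraction(center, radius)
    if np.minimum(grid.frac, ball).max() <= 0.5:
        # sub-voxel ball: it still intersects if its centre sits in bone
        ci = grid.world_to_index(center)
        inside = (
            radius < pitch
            and np.all(ci >= 0)
            and np.all(ci < grid.shape)
            and bool(grid.occ[tuple(ci)])
        )
        if not inside:
            raise DefectError("defect ball does not intersect the bone shell")
        return occupancy_to_mesh(grid)
    grid.frac = np.minimum(grid.frac, 1.0 - ball)
    if not (grid.frac > 0.5).any():
        raise DefectError("defect removed the entire shell")
    return occupancy_to_mesh(grid)


# ---------------------------------------------------------------------------
# manufacturing / scanning / scoring simulators
# ---------------------------------------------------------------------------


def simulate_manufacturing(
    designed: trimesh.Trimesh,
    noise_amplitude: float,
    correlation_length: float = 15.0,
    seed: int = 0,
) -> trimesh.Trimesh:
    """Apply a smooth outward shape error emulating the printed part.

    Additive manufacturing of the implant leaves the as-built surface
    slightly proud of the design (over-extrusion, staircase build-up), so
    the error field is one-sided: vertices move *outward* along their
    normals by a smooth, strictly non-negative random field whose
    area-weighted mean equals ``noise_amplitude`` mm. That makes the mean
    outward deviation of the part against its design recover the
    amplitude directly, which is the ground truth the fitting-accuracy
    stage is tested against. The realized mean displacement is stored in
    ``mesh.metadata['mean_displacement_mm']``.
    """
    if noise_amplitude < 0:
        raise ValueError("noise_amplitude must be >= 0")
    out = designed.copy()
    if noise_amplitude == 0:
        out.metadata["mean_displacement_mm"] = 0.0
        return out
    rng = np.random.default_rng(seed)
    verts = designed.vertices.view(np.ndarray)
    g = np.abs(_smooth_field(verts, correlation_length, rng))
    # area weights: a third of each incident face's area per vertex
    w = np.zeros(len(verts))
    np.add.at(
        w,
        designed.faces.view(np.ndarray).ravel(),
        np.repeat(designed.area_faces / 3.0, 3),
    )
    w = w / w.sum()
    g = g * (noise_amplitude / float(w @ g))
    normals = np.nan_to_num(designed.vertex_normals.view(np.ndarray))
    out.vertices = verts + g[:, None] * normals
    out.metadata["mean_displacement_mm"] = float(w @ g)
    return out


def simulate_scan(
    mesh: trimesh.Trimesh,
    points_per_mm2: float = 2.0,
    noise_sd: float = 0.0,
    pose: RigidTransform | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Simulated surface scan: area-uniform samples + noise + rigid pose.

    Stands in for an articulated-arm laser scanner; returns an (n, 3)
    point cloud with n = ceil(area * density).
    """
    if points_per_mm2 <= 0:
        raise ValueError("points_per_mm2 must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    count = int(np.ceil(mesh.area * points_per_mm2))
    pts, _ = sample_surface(mesh, count, rng)
    if noise_sd > 0:
        pts = pts + rng.normal(0.0, noise_sd, size=pts.shape)
    if pose is not None:
        pts = pose.apply(pts)
    return pts


def simulate_vas(
    n_experts: int = 10,
    n_replicates: int = 5,
    mean: float = 3.66,
    sd: float = 0.5,
    seed: int = 0,
) -> VASTable:
    """Draw an expert-scoring table from a discretized, clipped normal.

    Defaults mirror the study design: ten experts each rating five
    replicate implants on a 1-5 visual-analog scale with a population
    mean aesthetic score of 3.66.
    """
    if n_experts < 1 or n_replicates < 1:
        raise ValueError("need at least one expert and one replicate")
    if not 1.0 <= mean <= 5.0:
        raise ValueError("mean must lie within the 1..5 scale")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    raw = rng.normal(mean, sd, size=(n_experts, n_replicates)) if sd > 0 else np.full(
        (n_experts, n_replicates), float(mean)
    )
    scores = np.clip(np.rint(raw), 1, 5).astype(int)
    return VASTable(scores)
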