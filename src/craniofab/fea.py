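"""Linear static finite-element strength check of the skull-implant assembly.

The assembly (cortical-bone skull, PEEK implant, titanium screws) is
meshed on a single shared voxel grid: every cell whose majority content
is solid becomes six linear tetrahedra (Freudenthal subdivision, which
is face-to-face conforming across the lattice), labelled by region with
screws taking priority over implant over skull. Because abutting regions
occupy the same grid they share nodes along their interfaces, which *is*
the bonded-contact condition. The staircase boundary this implies is the
price of guaranteed conformity without an external mesher; element sizes
follow the 0.5-3 mm range customary for cranial models.

Materials are isotropic linear elastic (units mm-N-MPa). The default
load case anchors a basal slab of nodes and presses a 50 N resultant
over a ~200 mm^2 patch at the centre of the implant's outer surface
(0.25 MPa), the resting head-on-pillow condition; results are element
constant stresses, their von Mises equivalents, and displacement maxima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
from scipy import sparse
from scipy.sparse import csgraph, linalg as sla

from .geometry import voxelize

__all__ = [
    "MaterialProps",
    "MATERIALS",
    "FEModel",
    "FEAResult",
    "build_fe_model",
    "apply_bcs",
    "solve_linear_static",
    "von_mises",
    "summarize_fea",
]


@dataclass(frozen=True)
class MaterialProps:
    """Isotropic linear-elastic material (MPa)."""

    youngs_modulus: float
    poisson_ratio: float
    yield_strength: float

    def __post_init__(self):
        if self.youngs_modulus <= 0:
            raise ValueError("Young's modulus must be positive")
        if not 0 < self.poisson_ratio < 0.5:
            raise ValueError("Poisson ratio must be in (0, 0.5)")
        if self.yield_strength <= 0:
            raise ValueError("yield strength must be positive")


#: Assembly materials: porous PEEK implant, cortical bone, titanium screws.
MATERIALS = {
    "implant": MaterialProps(3738.0, 0.4, 99.9),
    "skull": MaterialProps(13700.0, 0.3, 122.0),
    "screw": MaterialProps(120000.0, 0.3, 930.0),
}


@dataclass
class FEModel:
    """Tetrahedral assembly: nodes (mm), tet4 elements, regions, BCs, loads."""

    nodes: np.ndarray  # (n, 3)
    elements: np.ndarray  # (m, 4) int
    element_region: np.ndarray  # (m,) int index into region_names
    region_names: list
    fixed_dofs: np.ndarray | None = None  # (3n,) bool
    load: np.ndarray | None = None  # (3n,) float
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_volumes(self) -> np.ndarray:
        X = self.nodes[self.elements]
        M = X[:, 1:] - X[:, :1]
        return np.linalg.det(M) / 6.0

    def validate(self):
        v = self.element_volumes()
        if (v <= 0).any():
            raise ValueError("model has non-positively oriented elements")
        if self.load is not None and not np.isfinite(self.load).all():
            raise ValueError("load vector has non-finite entries")
        return self

    def region_elements(self, name_prefix: str) -> np.ndarray:
        ids = [i for i, n in enumerate(self.region_names) if n.startswith(name_prefix)]
        return np.isin(self.element_region, ids)


@dataclass
class FEAResult:
    """Solution fields: nodal displacements, element stresses, maxima."""

    model: FEModel
    nodal_displacements: np.ndarray  # (n, 3) mm
    element_stress: np.ndarray  # (m, 6) MPa, Voigt xx yy zz xy yz zx
    element_von_mises: np.ndarray  # (m,) MPa
    max_von_mises: float
    max_displacement_magnitude: float
    reaction_force: np.ndarray  # (3,) N, sum over fixed dofs
    equilibrium_residual: float  # relative, free dofs
    n_floating_nodes: int = 0


# Freudenthal 6-tet subdivision of the unit cube along the (0,0,0)-(1,1,1)
# diagonal; corner codes are (dx, dy, dz). Face diagonals are translation
# invariant, so neighbouring cubes mesh conformingly.
_CUBE_TETS = []
for perm in ((0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)):
    c0 = np.zeros(3, dtype=int)
    c1 = c0.copy()
    c1[perm[0]] = 1
    c2 = c1.copy()
    c2[perm[1]] = 1
    c3 = np.ones(3, dtype=int)
    _CUBE_TETS.append([c0, c1, c2, c3])
_CUBE_TETS = np.array(_CUBE_TETS)  # (6, 4, 3)


def build_fe_model(
    skull: trimesh.Trimesh | list | None,
    implant: trimesh.Trimesh | list | None,
    screws: list | None = None,
    voxel_size: float = 1.5,
    bounds=None,
) -> FEModel:
    """Voxel-mesh the assembly into a conforming tet4 model.

    Each part is rasterized on one shared grid; a cell belongs to a part
    when the part covers the majority of it, with label priority
    screw > implant > skull where parts overlap. Occupied cells split
    into 6 tetrahedra on the shared corner lattice, so touching regions
    are bonded by node sharing. ``voxel_size`` outside the customary
    0.5-3 mm range warns.
    """
    if not 0.5 <= voxel_size <= 3.0:
        warnings.warn(
            f"voxel_size {voxel_size} mm outside the customary 0.5-3 mm range",
            stacklevel=2,
        )

    def aslist(x):
        if x is None:
            return []
        return [x] if isinstance(x, trimesh.Trimesh) else list(x)

    skull_m, implant_m, screws_m = aslist(skull), aslist(implant), aslist(screws)
    allm = skull_m + implant_m + screws_m
    if not allm:
        raise ValueError("no geometry to mesh")
    if bounds is None:
        los = np.array([m.bounds[0] for m in allm])
        his = np.array([m.bounds[1] for m in allm])
        bounds = (los.min(axis=0), his.max(axis=0))

    # label priority through overwrite order: skull, then implant, then screws
    label = None
    region_names = []
    groups = []
    if skull_m:
        groups.append(("skull", skull_m))
    if implant_m:
        groups.append(("implant", implant_m))
    for i, s in enumerate(screws_m):
        groups.append((f"screw_{i + 1}", [s]))
    grid0 = None
    for name, meshes in groups:
        g = voxelize(meshes, voxel_size, bounds=bounds, pad=2)
        if grid0 is None:
            grid0 = g
            label = np.zeros(g.shape, dtype=np.int8)
        occ = g.occ
        label[occ] = len(region_names) + 1
        region_names.append(name)
    for idx, name in enumerate(region_names):
        if not (label == idx + 1).any():
            raise ValueError(f"region {name!r} contains no voxels at {voxel_size} mm")

    vox = np.argwhere(label > 0)
    vlab = label[tuple(vox.T)].astype(np.int64) - 1
    nx1, ny1, nz1 = (np.array(label.shape) + 1).tolist()

    # voxel corners -> global node ids
    corners = vox[:, None, None, :] + _CUBE_TETS[None, :, :, :]  # (v, 6, 4, 3)
    flat = (
        corners[..., 0] * (ny1 * nz1) + corners[..., 1] * nz1 + corners[..., 2]
    ).reshape(-1)
    uniq, inv = np.unique(flat, return_inverse=True)
    elements = inv.reshape(-1, 4).astype(np.int64)  # (6v, 4)
    ii = uniq // (ny1 * nz1)
    jj = (uniq // nz1) % ny1
    kk = uniq % nz1
    nodes = (
        grid0.origin
        - grid0.pitch / 2.0
        + np.stack([ii, jj, kk], axis=1) * grid0.pitch
    )
    element_region = np.repeat(vlab, 6)

    model = FEModel(nodes, elements, element_region, region_names,
                    meta={"voxel_size": voxel_size})
    # enforce positive orientation once (the subdivision has fixed parity)
    v = model.element_volumes()
    neg = v < 0
    if neg.any():
        e = model.elements
        e[neg] = e[neg][:, [0, 1, 3, 2]]
    return model.validate()


# ---------------------------------------------------------------------------
# boundary faces and boundary conditions
# ---------------------------------------------------------------------------

_TET_FACES = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
_TET_OPP = np.array([3, 2, 1, 0])


def boundary_faces(model: FEModel):
    """Exterior triangle faces: (faces (f,3), element index, outward normals, areas)."""
    elem = model.elements
    faces = elem[:, _TET_FACES].reshape(-1, 3)  # (4m, 3)
    opp = elem[np.arange(len(elem))[:, None], _TET_OPP[None, :]].reshape(-1)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    b = counts[inv] == 1
    faces_b = faces[b]
    opp_b = opp[b]
    eidx = np.repeat(np.arange(len(elem)), 4)[b]
    p = model.nodes[faces_b]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    areas = np.linalg.norm(n, axis=1) / 2.0
    n = n / (2.0 * areas[:, None])
    # orient away from the opposite vertex (i.e. out of the element)
    inward = np.einsum(
        "ij,ij->i", model.nodes[opp_b] - p[:, 0], n
    )
    flip = inward > 0
    n[flip] *= -1.0
    return faces_b, eidx, n, areas


def apply_bcs(
    model: FEModel,
    fixed: str = "base",
    base_slab: float = 5.0,
    total_load: float = 50.0,
    load_area: float = 200.0,
    load_region: str = "implant",
    patch_center=None,
) -> FEModel:
    """Anchor the base and press a distributed load on the implant.

    ``fixed='base'`` clamps every node within ``base_slab`` mm of the
    assembly's lowest z (all three DOF). The load is a uniform traction
    over exterior faces of ``load_region``, gathered face-by-face from
    ``patch_center`` (default: the region's outer-surface centroid) until
    the accumulated area reaches ``load_area``; the traction direction is
    the area-weighted mean inward normal of the patch, so the nodal
    forces sum to exactly ``total_load`` along it.
    """
    model = replace(model, meta=dict(model.meta))
    zmin = model.nodes[:, 2].min()
    fixed_nodes = model.nodes[:, 2] <= zmin + base_slab
    if not fixed_nodes.any():
        raise ValueError("empty fixed set; increase base_slab")
    fixed_dofs = np.repeat(fixed_nodes, 3)

    faces, eidx, normals, areas = boundary_faces(model)
    inreg = model.region_elements(load_region)[eidx]
    if not inreg.any():
        raise ValueError(f"region {load_region!r} has no exterior surface")
    faces, normals, areas = faces[inreg], normals[inreg], areas[inreg]
    centroids = model.nodes[faces].mean(axis=1)
    # outward-facing side of the part only
    center_all = model.nodes.mean(axis=0)
    outward = np.einsum("ij,ij->i", normals, centroids - center_all) > 0
    if outward.any():
        faces, normals, areas, centroids = (
            faces[outward], normals[outward], areas[outward], centroids[outward]
        )
    if patch_center is None:
        w = areas / areas.sum()
        patch_center = (centroids * w[:, None]).sum(axis=0)
        patch_center = centroids[np.argmin(np.linalg.norm(centroids - patch_center, axis=1))]
    order = np.argsort(np.linalg.norm(centroids - np.asarray(patch_center), axis=1))
    cum = np.cumsum(areas[order])
    take = order[: int(np.searchsorted(cum, load_area)) + 1]
    patch_area = float(areas[take].sum())
    if patch_area <= 0:
        raise ValueError("empty load patch")
    mean_n = (normals[take] * areas[take, None]).sum(axis=0)
    mean_n /= np.linalg.norm(mean_n)
    direction = -mean_n  # press inward
    load = np.zeros(3 * model.n_nodes)
    f_face = direction[None, :] * (total_load * areas[take] / patch_area)[:, None]
    for c in range(3):
        np.add.at(load, 3 * faces[take] + c, f_face[:, c, None] / 3.0)
    model.fixed_dofs = fixed_dofs
    model.load = load
    model.meta.update(
        patch_area=patch_area,
        patch_faces=len(take),
        load_direction=direction,
        total_load=total_load,
    )
    return model.validate()


def fix_nodes(model: FEModel, node_mask, dofs=(0, 1, 2)) -> FEModel:
    """Clamp selected DOF of selected nodes (building-block for custom BCs)."""
    model = replace(model)
    fd = (
        model.fixed_dofs.copy()
        if model.fixed_dofs is not None
        else np.zeros(3 * model.n_nodes, dtype=bool)
    )
    ids = np.where(np.asarray(node_mask))[0]
    for d in dofs:
        fd[3 * ids + d] = True
    model.fixed_dofs = fd
    return model


def load_faces(model: FEModel, faces, traction) -> FEModel:
    """Apply a uniform traction vector (N/mm^2) over given triangles."""
    model = replace(model)
    load = (
        model.load.copy() if model.load is not None else np.zeros(3 * model.n_nodes)
    )
    faces = np.asarray(faces)
    p = model.nodes[faces]
    areas = np.linalg.norm(
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
    ) / 2.0
    t = np.asarray(traction, dtype=float)
    for c in range(3):
        np.add.at(load, 3 * faces + c, (areas * t[c] / 3.0)[:, None])
    model.load = load
    return model


# ---------------------------------------------------------------------------
# assembly and solve
# ---------------------------------------------------------------------------


def _elastic_D(E: float, nu: float) -> np.ndarray:
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[3:, 3:] = np.eye(3) * mu
    return D


def _element_B(model: FEModel, which=slice(None)):
    """Strain-displacement matrices B (m, 6, 12) and volumes (m,)."""
    X = model.nodes[model.elements[which]]
    M = X[:, 1:] - X[:, :1]  # rows: edge vectors
    vol = np.linalg.det(M) / 6.0
    Minv = np.linalg.inv(M)
    grads = np.empty((len(X), 4, 3))
    grads[:, 1:, :] = np.transpose(Minv, (0, 2, 1))
    grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)
    B = np.zeros((len(X), 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        B[:, 0, c + 0] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c + 0] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c + 0] = gz
        B[:, 5, c + 2] = gx
    return B, vol


def assemble_stiffness(model: FEModel, materials: dict) -> sparse.csr_matrix:
    """Global stiffness matrix (3n x 3n) in CSR, assembled region by region."""
    n3 = 3 * model.n_nodes
    K = sparse.csr_matrix((n3, n3))
    for ridx, rname in enumerate(model.region_names):
        mat = _material_for(rname, materials)
        D = _elastic_D(mat.youngs_modulus, mat.poisson_ratio)
        sel = np.where(model.element_region == ridx)[0]
        for s in range(0, len(sel), 200_000):
            chunk = sel[s : s + 200_000]
            B, vol = _element_B(model, chunk)
            Ke = np.einsum("eji,jk,ekl,e->eil", B, D, B, vol, optimize=True)
            dofs = (3 * model.elements[chunk][:, :, None] + np.arange(3)).reshape(-1, 12)
            rows = np.repeat(dofs, 12, axis=1).reshape(-1)
            cols = np.tile(dofs, (1, 12)).reshape(-1)
            K = K + sparse.coo_matrix(
                (Ke.reshape(-1), (rows, cols)), shape=(n3, n3)
            ).tocsr()
    return K


def _material_for(region_name: str, materials: dict) -> MaterialProps:
    if region_name in materials:
        return materials[region_name]
    base = region_name.split("_")[0]
    if base in materials:
        return materials[base]
    raise KeyError(f"no material for region {region_name!r}")


def _anchored_components(model: FEModel, fixed_nodes: np.ndarray):
    """Split nodes into anchored / floating via element connectivity."""
    e = model.elements
    pairs = np.concatenate([e[:, [0, 1]], e[:, [0, 2]], e[:, [0, 3]],
                            e[:, [1, 2]], e[:, [1, 3]], e[:, [2, 3]]])
    adj = sparse.coo_matrix(
        (np.ones(len(pairs), dtype=np.int8), (pairs[:, 0], pairs[:, 1])),
        shape=(model.n_nodes, model.n_nodes),
    )
    ncomp, lab = csgraph.connected_components(adj, directed=False)
    anchored_labels = np.unique(lab[fixed_nodes])
    return np.isin(lab, anchored_labels), ncomp


def solve_linear_static(
    model: FEModel,
    materials: dict | None = None,
    direct_dof_limit: int = 120_000,
    cg_rtol: float = 1e-8,
) -> FEAResult:
    """Assemble, constrain and solve K u = f; recover stresses and maxima.

    Uses a direct sparse factorization up to ``direct_dof_limit`` free
    DOF and Jacobi-preconditioned conjugate gradients beyond. Components
    of the mesh with no path to a fixed node are pinned at zero if they
    carry no load (stray lattice fragments from voxelization) and counted
    in the result; a *loaded* floating component is an error, naming the
    regions involved.
    """
    if materials is None:
        materials = MATERIALS
    if model.fixed_dofs is None or not model.fixed_dofs.any():
        raise ValueError("model has no fixed DOF; solve would be singular")
    if model.load is None:
        raise ValueError("model has no load vector")
    fixed_nodes = model.fixed_dofs.reshape(-1, 3).any(axis=1)
    anchored, _ = _anchored_components(model, fixed_nodes)
    n_floating = int((~anchored).sum())
    fixed_dofs = model.fixed_dofs.copy()
    if n_floating:
        floating_load = model.load.reshape(-1, 3)[~anchored]
        if np.abs(floating_load).max() > 0:
            regs = np.unique(
                model.element_region[np.isin(model.elements, np.where(~anchored)[0]).any(axis=1)]
            )
            names = [model.region_names[r] for r in regs]
            raise ValueError(
                f"loaded free-floating component involving regions {names}; "
                "the system is singular"
            )
        warnings.warn(
            f"pinning {n_floating} unanchored nodes (stray voxel fragments)",
            stacklevel=2,
        )
        fixed_dofs |= np.repeat(~anchored, 3)

    K = assemble_stiffness(model, materials)
    f = model.load
    free = ~fixed_dofs
    Kff = K[free][:, free].tocsc()
    ff = f[free]
    ndof = int(free.sum())
    if ndof <= direct_dof_limit:
        u_free = sla.spsolve(Kff, ff)
    else:
        Kff = Kff.tocsr()
        dinv = 1.0 / Kff.diagonal()
        M = sla.LinearOperator(Kff.shape, matvec=lambda x: dinv * x)
        u_free, info = sla.cg(Kff, ff, rtol=cg_rtol, atol=0.0, maxiter=20_000, M=M)
        if info != 0:
            raise RuntimeError(f"CG failed to converge (info={info})")
    u = np.zeros(3 * model.n_nodes)
    u[free] = u_free

    resid = Kff @ u_free - ff
    fnorm = np.linalg.norm(ff)
    residual = float(np.linalg.norm(resid) / (fnorm if fnorm > 0 else 1.0))
    reaction = (K @ u - f).reshape(-1, 3)[fixed_dofs.reshape(-1, 3).any(axis=1)]

    # element stresses (constant per tet4)
    m = model.n_elements
    stress = np.empty((m, 6))
    for ridx, rname in enumerate(model.region_names):
        mat = _material_for(rname, materials)
        D = _elastic_D(mat.youngs_modulus, mat.poisson_ratio)
        sel = np.where(model.element_region == ridx)[0]
        for s in range(0, len(sel), 200_000):
            chunk = sel[s : s + 200_000]
            B, _ = _element_B(model, chunk)
            ue = u.reshape(-1, 3)[model.elements[chunk]].reshape(-1, 12)
            stress[chunk] = np.einsum("ij,ejk,ek->ei", D, B, ue, optimize=True)
    vm = von_mises(stress)
    disp = u.reshape(-1, 3)
    return FEAResult(
        model=model,
        nodal_displacements=disp,
        element_stress=stress,
        element_von_mises=vm,
        max_von_mises=float(vm.max()),
        max_displacement_magnitude=float(np.linalg.norm(disp, axis=1).max()),
        reaction_force=reaction.sum(axis=0),
        equilibrium_residual=residual,
        n_floating_nodes=n_floating,
    )


def von_mises(stress: np.ndarray) -> np.ndarray:
    """Von Mises equivalent of stress tensors.

    Accepts a symmetric 3x3 tensor, a stack of them, or Voigt rows
    (sxx, syy, szz, sxy, syz, szx).
    """
    s = np.asarray(stress, dtype=float)
    if s.shape[-2:] == (3, 3):
        sxx, syy, szz = s[..., 0, 0], s[..., 1, 1], s[..., 2, 2]
        sxy, syz, szx = s[..., 0, 1], s[..., 1, 2], s[..., 2, 0]
    else:
        s = np.atleast_2d(s)
        sxx, syy, szz, sxy, syz, szx = (s[..., i] for i in range(6))
    out = np.sqrt(
        0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2)
        + 3.0 * (sxy**2 + syz**2 + szx**2)
    )
    return out if out.size > 1 else float(out.reshape(-1)[0])


def summarize_fea(result: FEAResult, materials: dict | None = None) -> dict:
    """Per-region maxima, safety factors and pass/fail against yield."""
    if materials is None:
        materials = MATERIALS
    model = result.model
    report = {
        "max_displacement_mm": result.max_displacement_magnitude,
        "max_von_mises_mpa": result.max_von_mises,
        "equilibrium_residual": result.equilibrium_residual,
        "regions": {},
    }
    ok = True
    for ridx, rname in enumerate(model.region_names):
        mat = _material_for(rname, materials)
        sel = model.element_region == ridx
        peak = float(result.element_von_mises[sel].max()) if sel.any() else 0.0
        sf = mat.yield_strength / peak if peak > 0 else np.inf
        passed = peak < mat.yield_strength
        ok &= passed
        report["regions"][rname] = {
            "max_von_mises_mpa": peak,
            "yield_strength_mpa": mat.yield_strength,
            "safety_factor": sf,
            "pass": bool(passed),
        }
    report["pass"] = bool(ok)
    return report
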