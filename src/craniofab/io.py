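"""File formats: STL meshes, NIfTI volumes, XYZ clouds, CSV scores, VTK fields."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh

from .phantom import ImageVolume, VASTable

__all__ = [
    "save_mesh", "load_mesh",
    "save_volume", "load_volume",
    "save_xyz", "load_xyz",
    "save_vas", "load_vas",
    "save_fea_vtk", "save_deviation_ply", "save_json",
]


def save_mesh(mesh: trimesh.Trimesh, path) -> Path:
    path = Path(path)
    mesh.export(path, file_type="stl")
    return path


def load_mesh(path) -> trimesh.Trimesh:
    mesh = trimesh.load_mesh(str(path), file_type="stl", process=True)
    if isinstance(mesh, trimesh.Scene):
        mesh = trimesh.util.concatenate(list(mesh.geometry.values()))
    if mesh.is_watertight and mesh.volume < 0:
        mesh.invert()
    return mesh


def save_volume(volume: ImageVolume, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(volume.intensities, dtype=np.float32),
                          volume.affine)
    nib.save(img, str(path))
    return path


def load_volume(path) -> ImageVolume:
    img = nib.load(str(path))
    aff = img.affine
    spacing = np.linalg.norm(aff[:3, :3], axis=0)
    return ImageVolume(np.asarray(img.dataobj, dtype=np.float32), spacing, aff[:3, 3])


def save_xyz(points: np.ndarray, path) -> Path:
    path = Path(path)
    np.savetxt(path, np.asarray(points, dtype=float), fmt="%.6f")
    return path


def load_xyz(path) -> np.ndarray:
    return np.loadtxt(path, dtype=float).reshape(-1, 3)


def save_vas(table: VASTable, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        table.scores,
        index=[f"expert_{i + 1}" for i in range(table.n_experts)],
        columns=[f"replicate_{j + 1}" for j in range(table.n_replicates)],
    )
    df.to_csv(path)
    return path


def load_vas(path) -> VASTable:
    df = pd.read_csv(path, index_col=0)
    return VASTable(df.to_numpy(dtype=int))


def save_fea_vtk(result, path) -> Path:
    """Legacy ASCII VTK unstructured grid: displacements + cell von Mises."""
    model = result.model
    path = Path(path)
    n, m = model.n_nodes, model.n_elements
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write("linear static tet4 solution\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {n} float\n")
        np.savetxt(f, model.nodes, fmt="%.6f")
        f.write(f"CELLS {m} {5 * m}\n")
        cells = np.hstack([np.full((m, 1), 4, dtype=np.int64), model.elements])
        np.savetxt(f, cells, fmt="%d")
        f.write(f"CELL_TYPES {m}\n")
        np.savetxt(f, np.full(m, 10, dtype=np.int64), fmt="%d")  # VTK_TETRA
        f.write(f"POINT_DATA {n}\nVECTORS displacement float\n")
        np.savetxt(f, result.nodal_displacements, fmt="%.6e")
        f.write(f"CELL_DATA {m}\nSCALARS von_mises float 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, result.element_von_mises, fmt="%.6e")
        f.write("SCALARS region int 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, model.element_region, fmt="%d")
    return path


def save_deviation_ply(points: np.ndarray, deviations: np.ndarray, path,
                       span: float | None = None) -> Path:
    """ASCII PLY of a point set coloured by signed deviation.

    Blue-white-red diverging map centred at zero; ``span`` fixes the
    colour range (default: the 95th percentile of |deviation|). The raw
    value is kept in a ``quality`` property for downstream tools.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    dev = np.asarray(deviations, dtype=float).reshape(-1)
    if len(points) != len(dev):
        raise ValueError("one deviation per point required")
    if span is None:
        span = float(np.percentile(np.abs(dev), 95)) or 1.0
    t = np.clip(dev / span, -1.0, 1.0)
    r = np.where(t >= 0, 255, (255 * (1 + t)).astype(int))
    b = np.where(t <= 0, 255, (255 * (1 - t)).astype(int))
    g = (255 * (1 - np.abs(t))).astype(int)
    path = Path(path)
    with open(path, "w") as f:
        f.write("ply\nformat ascii 1.0\n")
        f.write(f"element vertex {len(points)}\n")
        f.write("property float x\nproperty float y\nproperty float z\n")
        f.write("property uchar red\nproperty uchar green\nproperty uchar blue\n")
        f.write("property float quality\nend_header\n")
        for p, rr, gg, bb, q in zip(points, r, g, b, dev):
            f.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f} "
                    f"{int(rr)} {int(gg)} {int(bb)} {q:.6f}\n")
    return path


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def save_json(data: dict, path) -> Path:
    path = Path(path)
    with open(path, "w") as f:
        json.dump(data, f, indent=2, cls=_NumpyEncoder)
    return path
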