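"""Fitting-accuracy assessment: alignment, outward deviation, gaps, scores.

The quantitative yardstick of the whole pipeline is the *mean outward
deviation*: after best-fit alignment of a scan (or a designed surface)
against its reference, the mean of the strictly positive signed
point-to-surface distances — the average amount by which the test
surface sits proud of the reference. The total fitting error of a
printed implant decomposes into a modelling component (mirror
reconstruction vs. the true anatomy) and a manufacturing component
(printed part vs. its design); both are reported, alongside a
region-of-interest variant, an axis-aligned gap analysis between implant
and cavity, and a one-sample t-test on expert aesthetic scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import stats

from .geometry import RigidTransform, SurfaceQuery, icp
from .phantom import VASTable

__all__ = [
    "DeviationReport",
    "GapReport",
    "MASResult",
    "best_fit_align",
    "signed_deviation",
    "mean_outward_deviation",
    "roi_deviation",
    "decompose_accuracy",
    "gap_analysis",
    "mas_test",
]


@dataclass
class DeviationReport:
    """Fitting-accuracy numbers in mm.

    ``total`` is the decomposition sum (modelling + manufacturing); the
    directly measured scan-vs-anatomy deviation is kept alongside with
    their discrepancy, since the two need not coincide exactly.
    """

    mean_outward_deviation: float
    mean_signed_deviation: float
    modeling_component: float
    manufacturing_component: float
    total: float
    total_direct: float
    roi_deviation: float | None = None
    per_point: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.mean_outward_deviation < 0:
            raise ValueError("mean outward deviation cannot be negative")

    @property
    def decomposition_discrepancy(self) -> float:
        return self.total_direct - self.total

    def to_dict(self) -> dict:
        return {
            "mean_outward_deviation_mm": self.mean_outward_deviation,
            "mean_signed_deviation_mm": self.mean_signed_deviation,
            "modeling_component_mm": self.modeling_component,
            "manufacturing_component_mm": self.manufacturing_component,
            "total_mm": self.total,
            "total_direct_mm": self.total_direct,
            "roi_deviation_mm": self.roi_deviation,
        }


@dataclass
class GapReport:
    """Axis-aligned extents of implant and cavity, and their per-axis gaps."""

    implant_extent_x: float
    implant_extent_y: float
    cavity_extent_x: float
    cavity_extent_y: float

    def __post_init__(self):
        for v in (self.implant_extent_x, self.implant_extent_y,
                  self.cavity_extent_x, self.cavity_extent_y):
            if v <= 0:
                raise ValueError("extents must be positive")

    @property
    def gap_x(self) -> float:
        return self.cavity_extent_x - self.implant_extent_x

    @property
    def gap_y(self) -> float:
        return self.cavity_extent_y - self.implant_extent_y

    def to_dict(self) -> dict:
        return {
            "implant_extent_x_mm": self.implant_extent_x,
            "implant_extent_y_mm": self.implant_extent_y,
            "cavity_extent_x_mm": self.cavity_extent_x,
            "cavity_extent_y_mm": self.cavity_extent_y,
            "gap_x_mm": self.gap_x,
            "gap_y_mm": self.gap_y,
        }


@dataclass
class MASResult:
    """One-sample t-test of the mean aesthetic score against a threshold."""

    mas: float
    t_statistic: float
    p_value: float
    reject_null: bool
    n: int
    mu0: float = 3.0
    alpha: float = 0.05
    zero_variance: bool = False

    def __post_init__(self):
        if not 1.0 <= self.mas <= 5.0:
            raise ValueError("MAS must lie on the 1..5 scale")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "mas": self.mas,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "reject_null": self.reject_null,
            "n": self.n,
        }


# ---------------------------------------------------------------------------
# alignment and deviation
# ---------------------------------------------------------------------------


def best_fit_align(
    test: np.ndarray,
    reference: trimesh.Trimesh | SurfaceQuery,
    max_iter: int = 60,
    tol: float = 1e-6,
    init: RigidTransform | None = None,
    coarse: bool = True,
    rms_bound: float = 5.0,
):
    """Best-fit (ICP) alignment of a test cloud onto the reference surface.

    Returns ``(transform, aligned_points, rms)``. Coarse initialization
    matches centroids/principal axes unless ``init`` is given; a final
    RMS above ``rms_bound`` mm is flagged as a likely misalignment.
    """
    pts = np.asarray(test, dtype=float)
    if pts.ndim != 2 or len(pts) < 3:
        raise ValueError("need at least 3 points to align")
    T, aligned, rms, converged = icp(
        pts, reference, init=init, max_iter=max_iter, tol=tol, coarse=coarse
    )
    if not converged or rms > rms_bound:
        warnings.warn(
            f"alignment suspect: rms {rms:.3f} mm (bound {rms_bound}), "
            f"converged={converged}",
            stacklevel=2,
        )
    return T, aligned, rms


def _as_points(test) -> np.ndarray:
    if isinstance(test, trimesh.Trimesh):
        return test.vertices.view(np.ndarray)
    return np.atleast_2d(np.asarray(test, dtype=float))


def signed_deviation(
    test, reference: trimesh.Trimesh | SurfaceQuery
) -> np.ndarray:
    """Signed point-to-surface distances, positive outside the reference.

    ``test`` may be a point cloud or a mesh (its vertices are used); the
    sign comes from the interpolated surface-normal field at the closest
    point.
    """
    query = reference if isinstance(reference, SurfaceQuery) else SurfaceQuery(reference)
    sd, _, _ = query.signed_distance(_as_points(test))
    return sd


def mean_outward_deviation(devs: np.ndarray, return_fraction: bool = False):
    """Mean of the strictly positive deviations (the outward-shift statistic).

    Points at or inside the reference are excluded; with no outward
    points at all the statistic is 0 (flagged by warning). Optionally
    also returns the outward fraction.
    """
    devs = np.asarray(devs, dtype=float)
    if devs.size == 0:
        raise ValueError("empty deviation set")
    pos = devs[devs > 0]
    if len(pos) == 0:
        warnings.warn("no outward deviations; statistic is 0", stacklevel=2)
        mean = 0.0
    else:
        mean = float(pos.mean())
    if return_fraction:
        return mean, len(pos) / devs.size
    return mean


def roi_deviation(
    test,
    reference: trimesh.Trimesh | SurfaceQuery,
    roi=None,
    mode: str = "bbox",
    plane=None,
) -> float:
    """Mean outward deviation restricted to a region of interest.

    ``mode='bbox'``: keep test points inside the axis-aligned box
    ``roi = (lo, hi)`` (``roi=None`` means everything, reproducing the
    global statistic). ``mode='mirror'``: compare the points on the
    negative side of ``plane`` (the reconstructed/implant side) against
    the mirrored reference — the left-vs-healthy-right check.
    """
    pts = _as_points(test)
    if mode == "bbox":
        if roi is not None:
            lo, hi = np.asarray(roi[0], float), np.asarray(roi[1], float)
            keep = np.all((pts >= lo) & (pts <= hi), axis=1)
            pts = pts[keep]
        if len(pts) == 0:
            raise ValueError("ROI contains no test points")
        return mean_outward_deviation(signed_deviation(pts, reference))
    if mode == "mirror":
        if plane is None:
            raise ValueError("mirror mode needs the symmetry plane")
        from .reconstruct import mirror_mesh

        ref_mesh = reference.mesh if isinstance(reference, SurfaceQuery) else reference
        keep = plane.signed_distance(pts) < 0
        if not keep.any():
            raise ValueError("no test points on the implant side of the plane")
        mirrored = mirror_mesh(ref_mesh, plane)
        return mean_outward_deviation(signed_deviation(pts[keep], mirrored))
    raise ValueError(f"unknown ROI mode {mode!r}")


def decompose_accuracy(
    clean: trimesh.Trimesh,
    designed_reconstruction: trimesh.Trimesh,
    scanned_reconstruction,
    roi=None,
    align_rms_bound: float = 5.0,
) -> DeviationReport:
    """Split total fitting error into modelling and manufacturing parts.

    All inputs must already live in the clean skull's frame. The
    modelling component is the designed reconstruction measured against
    the true anatomy; the manufacturing component is the scanned as-built
    surface measured against its design; their sum is the reported total,
    kept alongside the directly measured scan-vs-anatomy deviation.
    """
    q_clean = SurfaceQuery(clean)
    q_design = SurfaceQuery(designed_reconstruction)
    scan_pts = _as_points(scanned_reconstruction)

    dev_design = signed_deviation(designed_reconstruction, q_clean)
    dev_scan_design = signed_deviation(scan_pts, q_design)
    dev_scan_clean = signed_deviation(scan_pts, q_clean)
    for name, d in (("designed vs clean", dev_design),
                    ("scanned vs designed", dev_scan_design)):
        if np.abs(d).mean() > align_rms_bound:
            raise ValueError(f"inputs misaligned: mean |deviation| of {name} "
                             f"is {np.abs(d).mean():.2f} mm")
    modeling = mean_outward_deviation(dev_design)
    manufacturing = mean_outward_deviation(dev_scan_design)
    total_direct = mean_outward_deviation(dev_scan_clean)
    roi_val = (
        roi_deviation(scan_pts, q_clean, roi=roi) if roi is not None else None
    )
    return DeviationReport(
        mean_outward_deviation=total_direct,
        mean_signed_deviation=float(dev_scan_clean.mean()),
        modeling_component=modeling,
        manufacturing_component=manufacturing,
        total=modeling + manufacturing,
        total_direct=total_direct,
        roi_deviation=roi_val,
        per_point=dev_scan_clean,
    )


# ---------------------------------------------------------------------------
# gap analysis
# ---------------------------------------------------------------------------


def gap_analysis(
    implant: trimesh.Trimesh,
    cavity: trimesh.Trimesh,
    axes=(0, 1),
) -> GapReport:
    """Axis-aligned widths of implant vs. defect cavity, and their gaps.

    Both meshes must sit in the common aligned frame; the cavity mesh is
    the solid that exactly fills the defect opening (the resected wall
    piece). Gap per axis = cavity extent - implant extent.
    """
    if cavity.is_empty or len(cavity.vertices) == 0:
        raise ValueError("empty cavity mesh")
    ei = implant.extents
    ec = cavity.extents
    ax = tuple(axes)
    vals = {}
    for a, name in ((0, "x"), (1, "y")):
        vals[f"implant_extent_{name}"] = float(ei[a]) if a in ax else float(ei[a])
        vals[f"cavity_extent_{name}"] = float(ec[a])
    return GapReport(**vals)


# ---------------------------------------------------------------------------
# aesthetic-score hypothesis test
# ---------------------------------------------------------------------------


def mas_test(
    scores,
    mu0: float = 3.0,
    alpha: float = 0.05,
    per_rating: bool = False,
) -> MASResult:
    """One-sided one-sample t-test of the mean aesthetic score vs. ``mu0``.

    The observation unit is the per-expert mean across replicates (so ten
    experts give n = 10), testing H0: MAS <= mu0 against Ha: MAS > mu0;
    H0 is rejected when the upper-tail p-value drops below ``alpha``.
    ``per_rating=True`` switches to treating every individual rating as
    an observation instead. A zero-variance sample has no defined t; the
    decision then falls back to comparing the mean against ``mu0``
    directly (flagged via ``zero_variance``).
    """
    if isinstance(scores, VASTable):
        table = scores.scores
    else:
        table = np.atleast_2d(np.asarray(scores))
    obs = table.astype(float).ravel() if per_rating else table.mean(axis=1).astype(float)
    n = len(obs)
    if n < 2:
        raise ValueError("need at least 2 observations")
    xbar = float(obs.mean())
    s = float(obs.std(ddof=1))
    if s == 0.0:
        warnings.warn("zero variance; t undefined, deciding on the mean alone",
                      stacklevel=2)
        return MASResult(
            mas=xbar,
            t_statistic=float("nan"),
            p_value=0.0 if xbar > mu0 else 1.0,
            reject_null=bool(xbar > mu0 and alpha > 0),
            n=n,
            mu0=mu0,
            alpha=alpha,
            zero_variance=True,
        )
    t = (xbar - mu0) / (s / np.sqrt(n))
    p = float(stats.t.sf(t, df=n - 1))
    return MASResult(
        mas=xbar,
        t_statistic=float(t),
        p_value=p,
        reject_null=bool(p < alpha),
        n=n,
        mu0=mu0,
        alpha=alpha,
    )
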