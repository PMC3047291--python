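"""Rigid alignment of a test model to the optical gold standard.

Two stages, mirroring clinical practice: a coarse alignment from manually
picked corresponding landmark pairs, solved in closed form by the SVD
(Kabsch/Arun) method with reflection correction, followed by surface-based
refinement with a trimmed point-to-point iterative-closest-point (ICP) loop.

ICP design: correspondences are exact point-to-triangle projections (not
vertex-nearest shortcuts, which bias distances by the faceting scale); the
worst ``trim_fraction`` of correspondences is discarded each iteration, which
makes partial overlap (template vs cast regions) harmless and keeps the
update deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .core import DegenerateGeometryError, ParameterError, RigidTransform
from .proximity import SurfaceQuery, sample_surface_points

__all__ = [
    "LandmarkSet",
    "ICPParams",
    "ICPResult",
    "landmark_register",
    "kabsch",
    "apply_transform",
    "icp_refine",
    "read_landmarks",
    "write_landmarks",
]


@dataclass
class LandmarkSet:
    """Index-paired corresponding points picked on two models (mm)."""

    source_points: np.ndarray
    target_points: np.ndarray

    def __post_init__(self) -> None:
        self.source_points = np.atleast_2d(np.asarray(self.source_points, dtype=float))
        self.target_points = np.atleast_2d(np.asarray(self.target_points, dtype=float))
        if self.source_points.shape != self.target_points.shape:
            raise ParameterError(
                f"landmark counts differ: {self.source_points.shape} vs {self.target_points.shape}"
            )
        if len(self.source_points) < 3:
            raise DegenerateGeometryError("need at least 3 landmark pairs")
        centred = self.source_points - self.source_points.mean(axis=0)
        extents = np.linalg.svd(centred, compute_uv=False)
        if extents[1] <= 1e-9:
            raise DegenerateGeometryError(
                "source landmarks are collinear (smallest principal extent <= 1e-9 mm)"
            )


@dataclass
class ICPParams:
    max_iterations: int = 100
    rms_change_tolerance: float = 1e-6  # mm
    trim_fraction: float = 0.1
    sample_count: int = 20000
    seed: int = 0
    capture_distance: float = 10.0  # mm; overlap sanity check under init

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ParameterError("max_iterations must be >= 1")
        if self.rms_change_tolerance <= 0:
            raise ParameterError("rms_change_tolerance must be > 0")
        if not (0 <= self.trim_fraction < 0.5):
            raise ParameterError("trim_fraction must lie in [0, 0.5)")
        if self.sample_count < 3:
            raise ParameterError("sample_count must be >= 3")


@dataclass
class ICPResult:
    transform: RigidTransform
    rms_trace: list = field(default_factory=list)
    converged: bool = False
    iterations: int = 0

    @property
    def final_rms(self) -> float:
        return self.rms_trace[-1] if self.rms_trace else float("nan")


def kabsch(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares proper rigid motion mapping paired source -> target.

    Centroids are subtracted, the cross-covariance decomposed by SVD and a
    reflection (det = -1) corrected by flipping the smallest singular
    direction, so the result is always a proper rotation.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    cs, ct = src.mean(axis=0), tgt.mean(axis=0)
    H = (src - cs).T @ (tgt - ct)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - R @ cs
    return RigidTransform(R, t)


def landmark_register(landmarks: LandmarkSet) -> RigidTransform:
    """SVD point-based registration of manually selected landmark pairs."""
    return kabsch(landmarks.source_points, landmarks.target_points)


def apply_transform(mesh_or_points, transform: RigidTransform):
    """Apply a rigid transform to points or a mesh (connectivity untouched)."""
    if isinstance(mesh_or_points, trimesh.Trimesh):
        out = mesh_or_points.copy()
        out.vertices = transform.apply(out.vertices.view(np.ndarray))
        return out
    return transform.apply(mesh_or_points)


def icp_refine(
    moving: trimesh.Trimesh,
    fixed: trimesh.Trimesh,
    init: RigidTransform | None = None,
    params: ICPParams | None = None,
) -> ICPResult:
    """Trimmed point-to-point ICP refinement of an initial alignment.

    Each iteration samples the moving surface (seeded, area-weighted), finds
    exact closest points on the fixed surface, discards the worst
    ``trim_fraction`` of correspondences and solves the rigid update by the
    same SVD method used for landmarks.  Returns the cumulative transform
    (including ``init``) plus the per-iteration RMS trace; RMS is reported
    over *all* correspondences, before trimming.
    """
    init = init or RigidTransform.identity()
    params = params or ICPParams()
    pts0, _ = sample_surface_points(moving, params.sample_count, seed=params.seed)
    if not np.isfinite(pts0).all() or not np.isfinite(fixed.vertices).all():
        raise DegenerateGeometryError("non-finite geometry passed to icp_refine")
    query = SurfaceQuery(fixed)

    d0, _, _ = query.closest(init.apply(pts0))
    if np.mean(d0 <= params.capture_distance) < 0.5:
        warnings.warn(
            f"poor initial overlap: only {100 * np.mean(d0 <= params.capture_distance):.0f}% "
            f"of sampled points within {params.capture_distance} mm of the fixed surface",
            stacklevel=2,
        )

    T = init
    keep = max(3, int(round((1.0 - params.trim_fraction) * len(pts0))))
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, params.max_iterations + 1):
        p = T.apply(pts0)
        d, cp, _ = query.closest(p)
        rms = float(np.sqrt(np.mean(d**2)))
        trace.append(rms)
        if len(trace) >= 2 and abs(trace[-2] - trace[-1]) < params.rms_change_tolerance:
            converged = True
            break
        order = np.argsort(d)[:keep]
        update = kabsch(p[order], cp[order])
        T = update.compose(T)
    # refresh the RMS at the final transform
    d, _, _ = query.closest(T.apply(pts0))
    trace.append(float(np.sqrt(np.mean(d**2))))
    if abs(trace[-2] - trace[-1]) < params.rms_change_tolerance:
        converged = True
    return ICPResult(transform=T, rms_trace=trace, converged=converged, iterations=it)


# --------------------------------------------------------------------- #
# landmark files: one pair per line, six mm floats (xs ys zs xt yt zt)
# --------------------------------------------------------------------- #
def read_landmarks(path) -> LandmarkSet:
    src, tgt = [], []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        vals = line.split()
        if len(vals) != 6:
            raise ParameterError(f"{path}:{lineno}: expected 6 floats, got {len(vals)}")
        nums = [float(v) for v in vals]
        src.append(nums[:3])
        tgt.append(nums[3:])
    return LandmarkSet(np.asarray(src), np.asarray(tgt))


def write_landmarks(path, landmarks: LandmarkSet) -> None:
    lines = ["# xs ys zs xt yt zt (mm)"]
    for s, t in zip(landmarks.source_points, landmarks.target_points):
        lines.append(" ".join(f"{v:.9g}" for v in (*s, *t)))
    Path(path).write_text("\n".join(lines) + "\n")
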