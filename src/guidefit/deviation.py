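"""Full-field signed surface deviations against the optical gold standard.

The dimensional check at the heart of the workflow: sample the test (usually
CT-derived) surface, measure the exact signed distance of each sample to the
gold (optical) surface and summarize the distribution.  Positive deviations
mean the test model lies outside the gold model (test model larger), negative
inside (test model smaller).  Comparisons may be restricted to a mating-
surface region of interest, since only the surfaces that seat on the cast or
mucosa matter for guide fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .core import GuidefitError, ParameterError
from .proximity import SurfaceQuery, sample_surface_points

__all__ = [
    "DeviationField",
    "DeviationStats",
    "RoiSpec",
    "signed_distances",
    "select_roi",
    "compare_surfaces",
    "deviation_stats",
    "format_stats",
    "write_deviation_ply",
]


@dataclass
class DeviationField:
    """Per-sample signed distances (mm) from a test surface to the gold one."""

    sample_points: np.ndarray
    distances: np.ndarray
    gold_reference: str = ""

    def __post_init__(self) -> None:
        self.sample_points = np.atleast_2d(np.asarray(self.sample_points, dtype=float))
        self.distances = np.asarray(self.distances, dtype=float).ravel()
        if len(self.sample_points) != len(self.distances):
            raise ParameterError("one distance per sample point required")
        if not np.isfinite(self.distances).all():
            raise ParameterError("deviation field contains non-finite distances")

    def __len__(self) -> int:
        return len(self.distances)


@dataclass
class DeviationStats:
    """Mean / SD / histogram of a deviation field (population convention)."""

    mean: float
    sd: float
    n: int
    bin_edges: np.ndarray
    counts: np.ndarray

    def to_dict(self) -> dict:
        return {
            "mean_mm": float(self.mean),
            "sd_mm": float(self.sd),
            "n": int(self.n),
            "bins": {
                "edges_mm": [float(x) for x in self.bin_edges],
                "counts": [int(c) for c in self.counts],
            },
        }


@dataclass
class RoiSpec:
    """Mating-surface selection: seed points + geodesic radius, or vertex ids."""

    seed_points: np.ndarray | None = None
    radius: float | None = None
    vertex_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        by_seed = self.seed_points is not None
        by_index = self.vertex_indices is not None
        if by_seed == by_index:
            raise ParameterError("specify either seed_points+radius or vertex_indices")
        if by_seed:
            self.seed_points = np.atleast_2d(np.asarray(self.seed_points, dtype=float))
            if self.radius is None or self.radius <= 0:
                raise ParameterError("a positive geodesic radius is required with seed points")
        else:
            self.vertex_indices = np.asarray(self.vertex_indices, dtype=np.int64).ravel()
            if len(self.vertex_indices) == 0:
                raise ParameterError("vertex_indices must be nonempty")


def signed_distances(points, gold: trimesh.Trimesh, method: str = "pseudonormal") -> np.ndarray:
    """Exact signed point-to-mesh distances (mm); + outside, - inside gold."""
    return SurfaceQuery(gold).signed_distance(points, method=method)


def select_roi(mesh: trimesh.Trimesh, roi: RoiSpec) -> trimesh.Trimesh:
    """Submesh of faces whose vertices all belong to the ROI.

    Geodesic selection runs a multi-source Dijkstra over the edge graph from
    the mesh vertices nearest to the seed points.  Vertex indices are
    remapped; the original face indices are retained in
    ``metadata["roi_face_map"]`` for traceability.
    """
    nv = len(mesh.vertices)
    if roi.vertex_indices is not None:
        sel = np.zeros(nv, dtype=bool)
        idx = roi.vertex_indices
        if idx.min() < 0 or idx.max() >= nv:
            raise ParameterError("vertex index out of range in RoiSpec")
        sel[idx] = True
    else:
        edges = mesh.edges_unique.view(np.ndarray)
        lengths = np.linalg.norm(
            mesh.vertices.view(np.ndarray)[edges[:, 0]] - mesh.vertices.view(np.ndarray)[edges[:, 1]],
            axis=1,
        )
        graph = coo_matrix(
            (np.concatenate([lengths, lengths]),
             (np.concatenate([edges[:, 0], edges[:, 1]]),
              np.concatenate([edges[:, 1], edges[:, 0]]))),
            shape=(nv, nv),
        ).tocsr()
        from scipy.spatial import cKDTree

        _, seeds = cKDTree(mesh.vertices.view(np.ndarray)).query(roi.seed_points)
        dist = dijkstra(graph, directed=False, indices=np.unique(seeds), min_only=True)
        sel = dist <= roi.radius
    faces = mesh.faces.view(np.ndarray)
    face_keep = np.flatnonzero(sel[faces].all(axis=1))
    if len(face_keep) == 0:
        raise GuidefitError("ROI selects no complete face")
    kept = faces[face_keep]
    used = np.unique(kept)
    remap = -np.ones(nv, dtype=np.int64)
    remap[used] = np.arange(len(used))
    sub = trimesh.Trimesh(
        vertices=mesh.vertices.view(np.ndarray)[used], faces=remap[kept], process=False
    )
    sub.metadata["roi_face_map"] = face_keep
    sub.metadata["roi_vertex_map"] = used
    return sub


def compare_surfaces(
    test: trimesh.Trimesh,
    gold: trimesh.Trimesh,
    roi: RoiSpec | None = None,
    sample_count: int = 20000,
    seed: int = 0,
    gold_reference: str = "gold",
    interior: bool = False,
) -> DeviationField:
    """Sample the (already aligned) test surface and measure signed deviations.

    This operation does not register: run the landmark + ICP stages first.
    """
    surface = select_roi(test, roi) if roi is not None else test
    pts, _ = sample_surface_points(surface, sample_count, seed=seed, interior=interior)
    d = signed_distances(pts, gold)
    return DeviationField(sample_points=pts, distances=d, gold_reference=gold_reference)


def deviation_stats(field: DeviationField, bin_width: float = 0.05) -> DeviationStats:
    """Mean, population SD and a zero-anchored histogram of a deviation field."""
    if len(field) == 0:
        raise GuidefitError("empty deviation field")
    if bin_width <= 0:
        raise ParameterError("bin_width must be > 0")
    d = field.distances
    mean = float(d.mean())
    sd = float(d.std(ddof=0))
    lo = np.floor(d.min() / bin_width) * bin_width
    hi = np.ceil(d.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    nbins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(nbins + 1)
    counts, _ = np.histogram(d, bins=edges)
    return DeviationStats(mean=mean, sd=sd, n=len(d), bin_edges=edges, counts=counts)


def format_stats(stats: DeviationStats) -> str:
    """Render stats the way comparison tables report them."""
    return f"mean value {stats.mean:.3f} mm, SD {stats.sd:.3f} mm"


def write_deviation_ply(path, field: DeviationField) -> None:
    """Export the field as ascii PLY with a per-vertex signed 'quality' (mm).

    The scalar channel is the hand-off for colour-mapped deviation rendering
    in external viewers.
    """
    pts = field.sample_points
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {len(pts)}",
        "property float x",
        "property float y",
        "property float z",
        "property float quality",
        "end_header",
    ]
    for p, q in zip(pts, field.distances):
        lines.append(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {q:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")
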