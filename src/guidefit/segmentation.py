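"""Threshold segmentation and isosurface extraction from CT volumes.

Segmentation of an appliance from CT is done by a manually chosen intensity
threshold tau; the corresponding surface model is the marching-cubes
isosurface at that isovalue.  The comparison is ``>=`` (a closed superlevel
set) so voxel counts are exactly reproducible, and the extracted mesh is not
smoothed or decimated: downstream deviation analysis must measure
segmentation error, not post-processing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
import trimesh
from skimage import measure

from .core import GuidefitError, ParameterError, VoxelVolume

__all__ = ["BinaryMask", "threshold_mask", "largest_component", "extract_isosurface"]

# 26-connectivity: the convention of most medical segmentation tools
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class BinaryMask:
    """Boolean mask congruent with a source volume grid."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def count(self) -> int:
        return int(self.data.sum())


def threshold_mask(volume: VoxelVolume, tau: float) -> BinaryMask:
    """Mask of voxels with intensity >= tau."""
    return BinaryMask(volume.data >= tau, volume.spacing.copy(), volume.origin.copy())


def largest_component(mask: BinaryMask) -> BinaryMask:
    """Keep only the largest 26-connected component.

    Emulates the manual clean-up of structures that do not belong to the
    appliance (e.g. antagonistic teeth).  Ties are broken in favour of the
    component containing the lowest linear voxel index.
    """
    if not mask.data.any():
        raise GuidefitError("empty mask: nothing was segmented at this threshold")
    labels, n = ndi.label(mask.data, structure=_STRUCT26)
    if n == 1:
        return BinaryMask(mask.data.copy(), mask.spacing.copy(), mask.origin.copy())
    counts = np.bincount(labels.ravel())[1:]  # skip background
    best = counts.max()
    tied = np.flatnonzero(counts == best) + 1
    if len(tied) == 1:
        keep = tied[0]
    else:
        flat = labels.ravel()
        first_idx = {lab: np.flatnonzero(flat == lab)[0] for lab in tied}
        keep = min(tied, key=lambda lab: first_idx[lab])
    return BinaryMask(labels == keep, mask.spacing.copy(), mask.origin.copy())


def extract_isosurface(
    volume: VoxelVolume, tau: float, keep_largest: bool = False
) -> trimesh.Trimesh:
    """Marching-cubes isosurface at isovalue tau, in world mm coordinates.

    Vertices are placed by linear interpolation along crossing edges and
    mapped through the shared voxel->world convention; faces are oriented so
    normals point out of the >= tau region.  With ``keep_largest`` only the
    largest (by area) connected surface component is returned.
    """
    lo, hi = float(volume.data.min()), float(volume.data.max())
    if not (lo < tau < hi):
        raise ParameterError(
            f"tau={tau} outside the open intensity range ({lo}, {hi}); surface is empty or degenerate"
        )
    verts, faces, _, _ = measure.marching_cubes(
        volume.data, level=tau, spacing=tuple(volume.spacing), method="lewiner"
    )
    verts = verts + volume.origin  # spacing already applied by marching_cubes
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    # orient outward: a watertight marching-cubes surface encloses positive
    # volume when its normals point away from the >= tau region
    if mesh.is_watertight and mesh.volume < 0:
        mesh.invert()
    if keep_largest:
        parts = mesh.split(only_watertight=False)
        if len(parts) > 1:
            mesh = max(parts, key=lambda p: p.area)
    return mesh
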