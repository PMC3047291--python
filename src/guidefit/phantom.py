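"""Synthetic paired CT / optical-scan phantoms with known ground truth.

Patient scans behind guided-implant workflows are never published, so every
stage of the pipeline is exercised on a desk-scale phantom instead: a bright
rigid horseshoe (the radiographic-template / cast analog) on a dark
background, voxelized at CT-like spacing, blurred by a Gaussian point-spread
function and corrupted with noise; plus a noisy surface sampling of the same
object in a different, known pose (the optical-scan analog).

The arch is a swept tube so its area and volume have analytic references:
the centreline is a circular arc of radius ``arch_radius``, the cross-section
a circle of radius ``tube_radius`` modulated by sinusoidal bumps (tooth-cusp
analogs).  With ``bump_amplitude=0`` and ``arc_span=360`` it degenerates to an
exact torus (surface area 4*pi^2*R*r), which the tests exploit.

Default intensities are fg=1000 / bg=0 — CT-like contrast for an
acrylic-resin appliance — giving a clean mid-level isovalue of 500 for
threshold-recovery experiments.  Optical noise defaults to 0.01 mm, the
accuracy class of structured-light dental scanners.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi
import trimesh

from .core import ParameterError, RigidTransform, VoxelVolume
from .proximity import SurfaceQuery

__all__ = [
    "PhantomSpec",
    "make_arch_mesh",
    "make_sphere_mesh",
    "voxelize_mesh",
    "simulate_ct",
    "simulate_optical_scan",
    "write_phantom_sidecar",
]


def _default_pose() -> RigidTransform:
    return RigidTransform.from_axis_angle((0.3, -0.2, 1.0), 8.0, (4.0, -3.0, 6.0))


@dataclass
class PhantomSpec:
    """Parameters of the synthetic template/cast phantom (lengths in mm)."""

    arch_radius: float = 22.0      # centreline radius, sized like a denture-base ridge
    tube_radius: float = 8.0       # cross-section radius of the ridge
    arc_span: float = 120.0        # degrees of arc covered by the horseshoe
    bump_count: int = 5            # tooth-cusp analogs along the arch
    bump_amplitude: float = 0.8    # mm of sinusoidal radius modulation
    fg_intensity: float = 1000.0   # CT units inside the object
    bg_intensity: float = 0.0      # CT units of the background
    psf_sigma: float = 0.6         # mm, CT partial-volume blur
    ct_noise_sd: float = 0.0       # CT units of additive Gaussian noise
    optical_noise_sd: float = 0.01  # mm, scanner accuracy class
    optical_sample_count: int = 20000  # target vertex budget of the optical mesh
    true_pose: RigidTransform = field(default_factory=_default_pose)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.arch_radius > self.tube_radius > 0):
            raise ParameterError(
                "invariant violated: arch_radius > tube_radius > 0 "
                f"(got {self.arch_radius}, {self.tube_radius})"
            )
        if not (0 < self.arc_span <= 360):
            raise ParameterError(f"invariant violated: 0 < arc_span <= 360 (got {self.arc_span})")
        if self.bump_count < 0 or self.bump_amplitude < 0:
            raise ParameterError("invariant violated: bump_count and bump_amplitude must be >= 0")
        if not (self.fg_intensity > self.bg_intensity):
            raise ParameterError("invariant violated: fg_intensity > bg_intensity")
        if self.psf_sigma < 0:
            raise ParameterError("invariant violated: psf_sigma >= 0")
        if self.ct_noise_sd < 0 or self.optical_noise_sd < 0:
            raise ParameterError("invariant violated: noise SDs must be >= 0")
        if self.optical_sample_count < 3:
            raise ParameterError("invariant violated: optical_sample_count >= 3")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["true_pose"] = self.true_pose.to_dict()
        return d


def _grid_mesh(spec: PhantomSpec, nu: int, nv: int) -> trimesh.Trimesh:
    closed_u = np.isclose(spec.arc_span, 360.0)
    span = np.deg2rad(spec.arc_span)
    # arc centred on the +y axis
    u0 = np.pi / 2 - span / 2
    if closed_u:
        u = u0 + span * np.arange(nu) / nu
    else:
        u = u0 + span * np.arange(nu + 1) / nu
    v = 2 * np.pi * np.arange(nv) / nv
    if closed_u:
        r = spec.tube_radius + spec.bump_amplitude * np.sin(spec.bump_count * (u - u0) / 2.0) ** 2
    else:
        r = spec.tube_radius + spec.bump_amplitude * np.sin(
            spec.bump_count * np.pi * (u - u0) / span
        ) ** 2
    uu, vv = np.meshgrid(u, v, indexing="ij")
    rr = r[:, None]
    e1 = np.stack([np.cos(uu), np.sin(uu), np.zeros_like(uu)], axis=-1)
    e2 = np.array([0.0, 0.0, 1.0])
    centre = spec.arch_radius * e1
    pts = centre + rr[..., None] * (np.cos(vv)[..., None] * e1 + np.sin(vv)[..., None] * e2)
    n_rings = pts.shape[0]
    verts = pts.reshape(-1, 3)

    def vid(i, j):
        return (i % n_rings) * nv + (j % nv)

    faces = []
    last = n_rings if closed_u else n_rings - 1
    for i in range(last):
        for j in range(nv):
            a, b = vid(i, j), vid(i + 1, j)
            c, d = vid(i + 1, j + 1), vid(i, j + 1)
            faces.append((a, b, c))
            faces.append((a, c, d))
    verts = [verts]
    offset = n_rings * nv
    if not closed_u:
        # concentric-ring caps: triangle sizes stay on the tube's scale so
        # downstream spatial queries keep tight bounds
        for end, ring_i in ((0, 0), (1, n_rings - 1)):
            ru = r[ring_i]
            cu = u[ring_i]
            e1u = np.array([np.cos(cu), np.sin(cu), 0.0])
            c0 = spec.arch_radius * e1u
            n_sub = max(2, int(np.ceil(nv / (2 * np.pi))))
            ring_ids = [[vid(ring_i, j) for j in range(nv)]]
            for s in range(n_sub - 1, 0, -1):
                rad = ru * s / n_sub
                ring = c0 + rad * (
                    np.cos(v)[:, None] * e1u + np.sin(v)[:, None] * e2
                )
                ring_ids.append(list(range(offset, offset + nv)))
                verts.append(ring)
                offset += nv
            verts.append(c0[None, :])
            centre_id = offset
            offset += 1
            for outer, inner in zip(ring_ids[:-1], ring_ids[1:]):
                for j in range(nv):
                    a, b = outer[j], outer[(j + 1) % nv]
                    c, d = inner[(j + 1) % nv], inner[j]
                    faces.append((a, b, c))
                    faces.append((a, c, d))
            for j in range(nv):
                faces.append((ring_ids[-1][j], ring_ids[-1][(j + 1) % nv], centre_id))
    mesh = trimesh.Trimesh(
        vertices=np.concatenate(verts, axis=0),
        faces=np.asarray(faces, dtype=np.int64),
        process=False,
    )
    trimesh.repair.fix_normals(mesh)
    if mesh.is_watertight and mesh.volume < 0:
        mesh.invert()
    return mesh


def make_arch_mesh(spec: PhantomSpec, nu: int | None = None, nv: int | None = None) -> trimesh.Trimesh:
    """Closed, outward-oriented swept-tube horseshoe with sinusoidal bumps.

    Geometry is fully deterministic given the spec; resolution defaults are
    derived from ``spec.optical_sample_count`` so the surface mesh carries
    about that many vertices.
    """
    arc_len = spec.arch_radius * np.deg2rad(spec.arc_span)
    circ = 2 * np.pi * (spec.tube_radius + spec.bump_amplitude / 2)
    if nv is None or nu is None:
        n_target = max(spec.optical_sample_count, 200)
        nv_f = np.sqrt(n_target * circ / arc_len)
        nv = nv or max(24, int(round(nv_f)))
        nu = nu or max(32, int(round(n_target / nv)))
    mesh = _grid_mesh(spec, nu=nu, nv=nv)
    if not mesh.is_watertight:
        raise RuntimeError("arch construction produced a non-watertight mesh")
    return mesh


def make_sphere_mesh(radius: float, subdivisions: int = 3) -> trimesh.Trimesh:
    """Icosphere fixture: watertight, outward normals, analytic area/volume."""
    if radius <= 0:
        raise ParameterError(f"radius must be positive, got {radius}")
    if subdivisions < 0:
        raise ParameterError("subdivisions must be >= 0")
    return trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)


def voxelize_mesh(
    mesh: trimesh.Trimesh,
    spacing,
    padding: float = 2.0,
    fg: float = 1000.0,
    bg: float = 0.0,
) -> VoxelVolume:
    """Binary-intensity voxelization: fg where the voxel *centre* is inside.

    The grid covers the mesh bounding box plus ``padding`` on all sides and
    the origin is set so world = origin + index * spacing at voxel centres.

    Inside/outside is resolved exactly: voxels within a guaranteed distance
    band of the surface get a signed-distance test; the remaining connected
    blocks of voxels are uniformly inside or outside, so one representative
    query per block settles each of them.
    """
    spacing = np.asarray(spacing, dtype=float).reshape(-1)
    if spacing.size == 1:
        spacing = np.repeat(spacing, 3)
    if not np.all(spacing > 0):
        raise ParameterError(f"spacing must be positive, got {spacing}")
    if padding < 0:
        raise ParameterError("padding must be >= 0")
    if not mesh.is_watertight:
        raise ParameterError("voxelization requires a watertight mesh (inside test undefined)")
    bmin, bmax = mesh.bounds
    origin = bmin - padding
    extent = (bmax - bmin) + 2 * padding
    dims = np.maximum(np.ceil(extent / spacing).astype(int) + 1, 2)
    query = SurfaceQuery(mesh)
    # distance from a voxel centre to the nearest mesh *vertex* bounds the
    # surface distance within r_max (max triangle circumradius)
    tris = mesh.triangles.view(np.ndarray)
    rmax = float(np.linalg.norm(tris - tris.mean(axis=1, keepdims=True), axis=2).max())
    diag = float(np.linalg.norm(spacing))
    margin = diag + rmax
    from scipy.spatial import cKDTree

    vtree = cKDTree(mesh.vertices.view(np.ndarray))
    ii, jj, kk = np.meshgrid(
        np.arange(dims[0]), np.arange(dims[1]), np.arange(dims[2]), indexing="ij"
    )
    centres = origin + np.stack([ii, jj, kk], axis=-1) * spacing
    flat = centres.reshape(-1, 3)
    dv, _ = vtree.query(flat)
    shell = (dv <= margin).reshape(tuple(dims))
    inside = np.zeros(tuple(dims), dtype=bool)
    if shell.any():
        sd = query.signed_distance(flat[shell.ravel()])
        inside[shell] = sd <= 0
    # blocks away from the surface are uniform; one exact query each
    labels, n_lab = ndi.label(~shell)
    for lab in range(1, n_lab + 1):
        idx = np.argwhere(labels == lab)[0]
        centre = origin + idx * spacing
        sd = query.signed_distance(centre[None, :])[0]
        if sd <= 0:
            inside[labels == lab] = True
    data = np.where(inside, float(fg), float(bg))
    return VoxelVolume(data=data, spacing=spacing, origin=origin)


def simulate_ct(
    volume: VoxelVolume, psf_sigma: float, noise_sd: float, seed: int = 0
) -> VoxelVolume:
    """Partial-volume blur (Gaussian PSF, physical sigma in mm) plus noise.

    Emulates the smooth intensity distributions of real CT around material
    boundaries; spacing and origin are unchanged.
    """
    if psf_sigma < 0 or noise_sd < 0:
        raise ParameterError("psf_sigma and noise_sd must be >= 0")
    data = volume.data.astype(float)
    if psf_sigma > 0:
        data = ndi.gaussian_filter(data, sigma=psf_sigma / volume.spacing, mode="nearest")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    return volume.copy_with(data)


def simulate_optical_scan(
    mesh: trimesh.Trimesh,
    sample_count: int,
    noise_sd: float,
    pose: RigidTransform,
    seed: int = 0,
) -> trimesh.Trimesh:
    """Noisy rigid-posed copy of a mesh, emulating a structured-light scan.

    Vertices are displaced along their (angle-weighted) normals by iid
    N(0, noise_sd^2) — structured-light error is dominantly along the line of
    sight — then mapped through ``pose``.  If the mesh carries fewer vertices
    than ``sample_count`` it is subdivided first, mimicking the dense point
    budget of an optical scanner.  The pose and seed are recorded in
    ``metadata`` so tests can recover them.
    """
    if sample_count < 3:
        raise ParameterError("sample_count must be >= 3")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    out = mesh.copy()
    while len(out.vertices) < sample_count:
        out = out.subdivide()
    rng = np.random.default_rng(seed)
    verts = out.vertices.view(np.ndarray).astype(float)
    if noise_sd > 0:
        normals = out.vertex_normals.view(np.ndarray)
        verts = verts + rng.normal(0.0, noise_sd, size=len(verts))[:, None] * normals
    verts = pose.apply(verts)
    noisy = trimesh.Trimesh(vertices=verts, faces=out.faces.copy(), process=False)
    noisy.metadata["true_pose"] = pose.to_dict()
    noisy.metadata["optical_noise_sd"] = float(noise_sd)
    noisy.metadata["seed"] = int(seed)
    return noisy


def write_phantom_sidecar(path, spec: PhantomSpec, extra: dict | None = None) -> None:
    """JSON sidecar recording the full phantom spec (pose, seed included)."""
    payload = {"phantom_spec": spec.to_dict()}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
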