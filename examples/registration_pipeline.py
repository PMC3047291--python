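"""Two-stage rigid registration: landmark SVD alignment, then trimmed ICP.

Simulates an optical scan of the arch phantom in an unknown pose, aligns it
back onto the reference model from six picked landmark pairs, and refines the
alignment on the full surfaces.  The final RMS lands at the simulated scanner
noise floor.
"""

import numpy as np

import guidefit as gf

spec = gf.PhantomSpec(optical_sample_count=8000)
arch = gf.make_arch_mesh(spec)
pose = gf.RigidTransform.from_axis_angle((0.3, -0.1, 1.0), 7.0, (4.0, -2.0, 3.0))
sigma = 0.02  # mm, per-point scanner noise
scan = gf.simulate_optical_scan(arch, 3, sigma, pose, seed=1)

# landmark pairs a user would click on both models (scan -> reference)
verts = arch.vertices.view(np.ndarray)
idx = np.linspace(0, len(verts) - 1, 6).astype(int)
landmarks = gf.LandmarkSet(source_points=pose.apply(verts[idx]), target_points=verts[idx])
init = gf.landmark_register(landmarks)
print(f"landmark init : rotation {init.rotation_angle_deg():.3f} deg, "
      f"translation {init.translation_norm():.3f} mm")

result = gf.icp_refine(scan, arch, init=init, params=gf.ICPParams(sample_count=5000, seed=0))
err = result.transform.compose(pose)
print(f"ICP refinement: {result.iterations} iterations, converged={result.converged}")
print(f"residual pose error: {err.rotation_angle_deg():.4f} deg, "
      f"{err.translation_norm():.4f} mm")
print(f"final RMS: {result.final_rms:.4f} mm (injected noise sigma = {sigma} mm)")
print("\nThe residual pose error is far below the scanner noise, and the final")
print("RMS matches the per-point noise floor: registration is not the")
print("accuracy bottleneck in the verification chain.")
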