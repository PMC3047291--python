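"""Calibrate a CT segmentation threshold against an optical gold standard.

Builds a blurred-sphere CT phantom (analytic radius 8 mm, contrast 1000 CT
units, 0.6 mm PSF at 0.3 mm voxels), then searches for the threshold whose
isosurface minimizes the absolute mean signed deviation to the known true
surface.  A threshold below the optimum reconstructs the object too large
(positive mean), above it too small (negative mean).
"""

import guidefit as gf

gold = gf.make_sphere_mesh(8.0, 4)
volume = gf.voxelize_mesh(gold, 0.3, padding=3.0, fg=1000.0, bg=0.0)
ct = gf.simulate_ct(volume, psf_sigma=0.6, noise_sd=0.0)

result = gf.optimize_threshold(
    ct, gold, bracket=(200.0, 800.0),
    icp=gf.ICPParams(sample_count=3000, seed=0),
    sample_count=5000, seed=0,
)

print("tau      mean [mm]   sd [mm]")
for tau, mean, sd in sorted(result.trace):
    print(f"{tau:7.1f}  {mean:+9.4f}  {sd:8.4f}")
print(f"\noptimal threshold tau* = {result.tau_star:.1f} CT units")
print(f"|mean deviation| at tau* = {result.objective_at_star:.4f} mm")
print("\nThe mean column falls monotonically through zero: the reconstruction")
print("shrinks as the threshold rises, and tau* sits where the CT surface")
print("matches the gold standard on average (slightly below the 500 mid-level")
print("because the PSF shifts the half-level set inward on convex surfaces).")
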