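# guidefit

Monitor the accuracy lost when CT-based dental implant planning is
transferred to physical surgical guides.

Surgical guides are manufactured from a CT scan of a radiographic template,
but the 3D model extracted from CT depends on an operator-chosen
segmentation threshold τ: too low and the reconstruction is oversized, too
high and it shrinks.  `guidefit` verifies each step of the chain against an
optical structured-light scan used as the gold standard:

* **segmentation** — threshold masks and marching-cubes isosurfaces of CT
  volumes, in world millimetre coordinates;
* **registration** — landmark alignment by the SVD (Kabsch/Arun) method,
  refined by trimmed point-to-point ICP with exact point-to-triangle
  correspondences;
* **deviation** — full-field signed point-to-surface distances d_i of the
  test model against the gold model (positive = test larger), with mean,
  population SD and zero-anchored histograms, optionally restricted to the
  mating surfaces;
* **threshold calibration** — the core method: find
  τ\* = argmin_τ | mean_i d_i(τ) |, exploiting that the mean deviation is
  monotone decreasing in τ (coarse grid, then bisection on the sign of the
  mean);
* **phantom** — a synthetic arch (swept tube with tooth-cusp bumps) paired
  as CT volume + optical scan with known ground truth, so the whole pipeline
  is verifiable without patient data.

I/O: DICOM series (read), NRRD volumes (read/write), binary STL and ascii
PLY meshes (read/write), plain-text landmark files, JSON reports.

## Worked example

`examples/threshold_calibration.py` builds a blurred-sphere CT phantom
(radius 8 mm, contrast 1000 CT units, 0.6 mm PSF, 0.3 mm voxels) and
calibrates the threshold against the known true surface:

```
tau      mean [mm]   sd [mm]
  200.0    +0.4672    0.0155
  275.0    +0.3191    0.0144
  350.0    +0.1892    0.0145
  425.0    +0.0697    0.0141
  462.5    +0.0124    0.0137
  471.9    -0.0025    0.0142
  500.0    -0.0448    0.0137
  575.0    -0.1603    0.0130
  650.0    -0.2800    0.0144
  725.0    -0.4096    0.0145
  800.0    -0.5585    0.0152

optimal threshold tau* = 471.9 CT units
|mean deviation| at tau* = 0.0025 mm
```

The mean signed deviation falls monotonically through zero: low thresholds
reconstruct the object ~0.5 mm too large, high thresholds too small, and at
τ\* the CT surface matches the gold standard to a few microns on average.
τ\* sits slightly below the 500 mid-level because Gaussian blur shifts the
half-level set inward by ≈ σ²·H on convex surfaces (see
`docs/methods.md`).  The other examples print the registration error budget
(`registration_pipeline.py`: landmark + ICP recover a 7° / 5 mm pose to
0.007° / 0.002 mm with the final RMS at the scanner noise floor) and the
deviation-field calibration (`deviation_report.py`: a +0.1 mm offset surface
reads back as mean value 0.100 mm).

The same pipeline is scriptable from the shell:

```sh
guidefit --seed 1 phantom --out-dir phantom/
guidefit segment --volume phantom/ct.nrrd --tau 500 --keep-largest --out seg.stl
guidefit compare --test seg.stl --gold phantom/optical.ply \
    --landmarks phantom/landmarks.txt --out report.json
guidefit optimize-tau --volume phantom/ct.nrrd --gold phantom/optical.ply \
    --bracket 200 800 --landmarks phantom/landmarks.txt --out result.json
guidefit study --out-dir study/        # the full end-to-end bundle
```

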