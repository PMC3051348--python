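# ctvolumetry

Accuracy and precision of threshold-based CT volume measurement,
studied end-to-end on simulated sphere-in-gelatin phantoms.

## The problem

Tumor burden on CT is still mostly reported as a longest diameter
(RECIST), but volumetric assessment is the obvious successor — if its
accuracy under realistic scan protocols is understood.  The dominant
error source for small lesions is the partial-volume effect: a voxel
straddling the lesion boundary reports an intermediate Hounsfield
value, so a fixed segmentation threshold systematically clips or grows
the measured volume depending on where it sits between the two
materials.  The effect scales with voxel size, so slice thickness,
reconstruction field of view (FOV) and reconstruction kernel all move
the answer.

This package reproduces a classical phantom experiment *in silico* and
is aimed at medical-physics and image-analysis work on volumetric
protocol design.  It simulates a gelatin block (≈37.6 HU) containing
55 PMMA spheres (≈118.2 HU; 11 inch-fraction diameters from 1.6 mm to
25.4 mm, 5 replicates each), voxelizes it with exact partial-volume
mixing, emulates reconstruction kernels (in-plane PSF blur plus
kernel-filtered noise), synthesizes thicker slices by averaging
contiguous thin slices, segments by a calibrated global threshold with
filtered 3D connected components, and quantifies accuracy and
precision over the full 3 FOV × 3 kernel × 4 thickness grid.

## The measurements at the core

* Measured volume by voxel counting: `V_CT = N_V · l · w · t`, where
  `N_V` is the voxel count of a labeled component and `l, w, t` the
  voxel dimensions.
* Percent error: `(V_CT − V_true) / V_true × 100`, with
  `V_true = (4/3)πr³` from the known sphere diameter.
* Accuracy per condition: the slope of `V_CT` vs `V_true` regressed
  through the origin (slope 1 = perfect volumeter; < 1 =
  underestimation).
* Precision per sphere size: coefficient of variation and t-based 95%
  confidence interval over the 5 replicates.
* Factor effects: one-way ANOVA on percent error with Bonferroni
  correction; tolerance lookup tables giving the minimum diameter
  measurable within 10% / 20% error per condition.

## Worked example

A reduced grid (5 sphere sizes, 3 replicates, one FOV, three kernels,
three thicknesses) runs in well under a minute:

```python
from ctvolumetry import ExperimentConfig, run_experiment
from ctvolumetry.acquisition import DEFAULT_KERNELS

cfg = ExperimentConfig(
    diameters_mm=(4.7625, 6.35, 9.525, 12.7, 19.05),
    n_replicates=3, container_mm=(120.0, 120.0, 150.0),
    fovs_cm=(20.0,), kernels=dict(DEFAULT_KERNELS),
    thickness_factors=(1, 2, 4), matrix=256, seed=0,
    exclude_smallest=False)
run = run_experiment(cfg)
print(run.results.summary())
```

prints

```
CT volumetry accuracy study
============================================================
measurement slots: 135  detected: 135  (100.0%)
conditions: 9  diameters analyzed: 5

origin-forced slope (measured vs true volume)
  range: 0.849 .. 0.954

mean signed percent error by slice thickness:
   0.625 mm :   -19.1 %
    1.25 mm :   -20.7 %
     2.5 mm :   -28.9 %

one-way ANOVA on percent error (detected only):
  diameter_mm          F =     50.06   p = <0.0001
  slice_thickness_mm   F =      5.84   p = 0.00371
  kernel               F =     16.80   p = <0.0001
```

Every slope is below unity — the 93 HU threshold sits above the
gelatin/PMMA midpoint, so the boundary shell is clipped and volumes
are systematically underestimated.  Error worsens as slices thicken
(−19.1% at 0.625 mm native slices vs −28.9% at 2.5 mm) and the sharp
lung kernel is the most accurate (slope 0.954 at native thickness vs
0.883 for the standard kernel).  Sphere size, thickness and kernel all
test significant; `run.results.slopes`, `.precision`, `.lookup` and
the plotting methods expose the full tables.

The same pipeline is scriptable from the shell:

```sh
ctvolumetry run-all --config my_config.yaml --seed 1 --out results/
ctvolumetry make-fixture --size tiny --out fixtures/
```

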