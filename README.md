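# malsf — multi-atlas level-set label fusion

`malsf` segments a low-contrast structure (the motivating case is the
thalamus in T1-weighted brain MRI) by fusing several candidate
segmentations — atlas labels propagated into the target's coordinate frame
by registration — with the target image's local intensity statistics and a
contour-regularity prior, inside a single variational level-set evolution.
It is aimed at people building multi-atlas segmentation pipelines who want
a fusion stage that can *correct* registration errors instead of merely
averaging them, and that returns smooth, closed contours.

Registration itself is out of scope: the inputs are the target volume, N
binary propagated labels on the same grid, and (optionally) N nonnegative
local-similarity maps to use as fusion weights. A synthetic module
generates phantoms, deformed atlas ensembles and similarity maps, so the
whole pipeline runs with no external data.

## The model

The segmentation contour is the zero level set of a function φ (negative
inside, positive outside) found by minimizing

```
E(φ) = α·F(φ; φ1..φN) + β·D(φ; I) + γ·R(φ)
```

* **Label fusion term** `F = ∫ Σi ωi(x) |φ(x) − φi(x)|² dx`, where φi is
  the signed-distance field of the i-th propagated label and the local
  weights satisfy Σi ωi(x) = 1. Minimizing F alone gives the pointwise
  weighted mean of the atlas fields — the "pure shape prior" solution,
  which is also the default initialization.
* **Image term** `D`: the region-scalable fitting (RSF) energy. Around
  every point y, the image inside/outside the contour is fitted by local
  constants f1(y), f2(y) within a Gaussian window Kρ of scale ρ, and D
  accumulates the kernel-weighted misfits
  `ei(x) = ∫ Kρ(x−y)|I(x) − fi(y)|² dy` weighted by the smoothed region
  memberships M1 = 1 − Hε(φ), M2 = Hε(φ),
  with `Hε(z) = ½[1 + (2/π)·arctan(z/ε)]`.
* **Regularization** `R = ∫ |∇Hε(φ)|`: the smoothed arc length of the
  contour.

φ evolves by explicit gradient descent; a distance-regularization term
`μ(∇²φ − div(∇φ/|∇φ|))` keeps φ close to a signed-distance function so no
reinitialization is needed. Default coefficients are α=0.1, β=1, γ=0.1,
μ=0.1, υ=0.01 (curvature), λ1=λ2=0.0001. Majority voting and weighted
voting are included as baselines, along with the usual evaluation metrics
(Dice/SI, precision, recall, Jaccard/RO, Hausdorff distance).

## Worked example

```bash
python examples/segment_phantom.py
```

builds the standard synthetic fixture — a 64×64 phantom whose structure
differs from the background by only 20 gray levels under noise σ=8, plus
10 atlas labels warped by up to 3 voxels with 2% label flips — and fuses
them with default parameters:

```
iterations run      : 75
segmented voxels    : 1123 (truth: 1122)
similarity index SI : 0.9933
precision / recall  : 0.9929 / 0.9938
Hausdorff distance  : 1.00 voxels
```

SI is the Dice overlap with the hidden ground truth. For context,
`examples/compare_baselines.py` prints the same fixture fused by voting:

```
method                  SI      HD   contour
level-set fusion    0.9933    1.00    120.48
majority vote       0.9897    1.00    120.54
weighted vote       0.9906    1.00    120.52
```

the level-set fusion both overlaps the truth better and produces the
shortest (smoothest) contour. `examples/energy_descent.py` shows the
descended objective falling monotonically, and
`examples/tune_parameters_demo.py` runs the grid tuner.

A thin CLI wraps the same pipeline for on-disk NIfTI data:

```bash
malsf synth --seed 0 --out data/           # phantom + ensemble as NIfTI
malsf segment --target data/target.nii.gz \
    $(for f in data/label_*.nii.gz;  do echo --labels  $f; done) \
    $(for f in data/weight_*.nii.gz; do echo --weights $f; done) \
    --truth data/truth.nii.gz --out run/
malsf eval --auto run/segmentation.nii.gz --truth data/truth.nii.gz
```

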