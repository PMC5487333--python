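# Methods

## Problem setting and model

Multi-atlas segmentation propagates N expert-labelled atlas masks into a
target volume's coordinate frame via nonrigid registration and fuses them
into one consensus mask. Voting fusers use only the propagated labels; when
the structure's boundary is low-contrast and the registrations share a
systematic error, voting cannot recover it. `malsf` instead poses fusion as
energy minimization over a level-set function φ on the target grid
(negative inside, positive outside):

    E(φ) = α·F(φ; φ1..φN) + β·D(φ; I) + γ·R(φ)

with F the weighted squared distance of φ to the atlas signed-distance
fields, D the region-scalable fitting (RSF) image energy and R the smoothed
contour arc length. The evolution is explicit gradient descent

    φ ← φ + Δt·[ −2α Σi ωi(φ − φi)
                 + β·δε(φ)(λ1 e1 − λ2 e2)
                 + cυ·δε(φ)·div(∇φ/|∇φ|)
                 + μ·(∇²φ − div(∇φ/|∇φ|)) ],

where δε is the derivative of the smoothed Heaviside
Hε(z) = ½[1 + (2/π)·arctan(z/ε)], i.e. the Cauchy kernel
δε(z) = (1/π)·ε/(ε² + z²). The fitting functions f1/f2 are refreshed from
the current φ before every step (alternating minimization), which is the
standard RSF scheme.

### Sign of the data-term force

With the membership convention used here — M1 = 1 − Hε(φ) for the inside
(φ < 0), M2 = Hε(φ) for the outside — gradient descent on
D = λ1∑ e1·M1 + λ2∑ e2·M2 gives ∂φ/∂t = +δε(φ)(λ1e1 − λ2e2). Part of the
RSF literature writes this term with the opposite sign because it pairs
with the opposite membership convention (M1 = Hε). The sign used here is
the one that descends D under this package's conventions, and is also the
semantically correct one: a voxel near the contour whose intensity fits
the local inside model worse than the outside model (e1 > e2) is pushed to
positive φ, i.e. relabelled outside. The energy-descent unit tests verify
this direction directly.

### Fusion term in the flow

The evolution includes the analytic gradient of F, −2α Σ ωi(φ − φi);
without it the atlas prior would act only through the initialization and
the α coefficient would be inert. For completeness the variant where the
fusion term acts only through the initialization is selectable
(`fusion_in_flow=False`).

## Parameters

| name | meaning | default | notes |
|---|---|---|---|
| α | fusion (shape prior) weight | 0.1 | reference value |
| β | image term weight | 1.0 | reference value |
| γ | regularization weight in E | 0.1 | reporting only, see below |
| μ | distance-regularization rate | 0.1 | keeps \|∇φ\| ≈ 1, no reinitialization |
| υ | curvature-flow coefficient | 0.01 | drives contour shortening |
| λ1, λ2 | inside/outside misfit weights | 1e-4 | scaled for 0–255 intensities |
| ε | Heaviside width (voxels) | 1.0 | not fixed by the reference setup; common unit-grid choice |
| ρ | kernel scale (voxels) | 3.0 | region scalability: small = local fits, large = global |
| Δt | explicit time step | 0.1 | stable for the default coefficients |
| max_iters / tol | stopping | 200 / 1e-4 | relative objective change over a 5-step window |

Coefficient mapping: the operational evolution equation carries its own
coefficients (λ1, λ2, υ, μ) next to the energy-level ones (α, β, γ). Here
υ drives the curvature flow and γ only scales R in the reported energy;
the alternative γ·υ product is selectable via `curvature_coeff_mode`.
Because of this, the energy trace records both the reported form
αF + βD + γR (`total`) and the functional the flow actually descends,
αF + βD + υR + μP with P = ∑½(|∇φ|−1)² (`objective`). Descent assertions
are made on `objective`; `total` can rise slightly while the image term
pulls φ away from the pure atlas mean.

## Numerical choices

* **Signed distances**: two Euclidean distance transforms,
  φ = dt(outside) − dt(inside), voxel-centre convention, physical spacing
  respected. No voxel lies exactly on the zero level; |φ| ≥ 1 voxel
  adjacent to the interface. Degenerate (all-0/all-1) masks are rejected.
* **Gaussian kernel**: separable, truncated at 3ρ, renormalized to unit
  mass; symmetric boundary extension, so Kρ∗1 = 1 exactly and the
  convolution expansion e_i = I² − 2I·(K∗f_i) + K∗(f_i²) is valid.
* **Fitting functions**: closed-form kernel-weighted means
  f_i = K∗(M_i·I)/K∗(M_i), denominator floored at 1e-10 where a phase is
  locally absent.
* **Finite differences**: central, with mirror boundary padding (zero
  normal slope at the border); gradient magnitude floored at 1e-8 in the
  curvature normal.
* **Arc length**: computed as ∑|∇Hε(φ)| rather than ∑δε(φ)|∇φ|. The two
  agree in the continuum; discretely the ∇Hε form samples the interface
  jump directly and is insensitive to the half-voxel offset of the
  signed-distance convention (the δ form systematically undershoots
  because |φ| < 1 is never sampled).
* **Stopping**: relative change of the descended objective over a
  5-iteration window below `tol`; an empty final mask sets a warning flag
  rather than raising.
* **Tuning**: exhaustive grid product in key insertion order, scored by
  mean Dice over training targets; ties broken by first-in-grid order for
  determinism.
* Voting ties (exactly N/2, or weighted score exactly 0.5) go to
  background. Hausdorff distances are computed between boundary voxels
  (object voxels with at least one opposite-valued face neighbour), via
  KD-trees, in physical units.

## Synthetic fixtures

The generator emulates the regime the method targets, not MRI physics. A
phantom is a two-valued shape image (ellipse/ellipsoid, or a "bean" =
ellipse plus offset lobe, occupying 5–40% of the grid), Gaussian-blurred
at the boundary and corrupted with additive Gaussian noise. The standard
fixture uses a 64² grid, inside/outside means 120/100 (contrast gap 20 on
the 0–255 scale), blur 1 voxel and noise σ=8 — i.e. a boundary whose
contrast is 2.5× the noise, visibly weak. Atlas labels are the truth
resampled through independent smoothed-white-noise displacement fields
(max amplitude 3 voxels, smoothness 4 voxels) with 2% independent label
flips, standing in for registration error; nearest-neighbour resampling
keeps labels binary. Similarity maps are smoothed agreement between each
label and the ensemble consensus — a stand-in for registration-derived
local similarity, since the fixture has no atlas intensity images — and
weights are their pointwise normalization (uniform 1/N where all maps
vanish).

What passing tests show: the energy machinery matches brute-force oracles
exactly, the flow descends its objective, and on ensembles with smooth,
independent, zero-mean registration error the fusion recovers the
structure better, and with smoother contours, than voting. What they do
not show: behaviour under correlated registration bias, intensity
inhomogeneity, partial-volume effects, or anatomy-specific shape
statistics — real-MRI performance claims require real data.

Desk-scale problem sizes (64² grids, 10 atlases, ≤200 iterations) were
chosen so every test and the acceptance script run in seconds on one CPU;
all operations are dimension-agnostic and run identically on 3-D grids.

## Known limitations

* Two-phase model only (one structure vs background); no multi-label
  fusion and no intensity bias-field estimation.
* Explicit Euler stepping: overly large Δt diverges (detected and reported
  rather than silently clipped); no narrowband or fast-marching
  acceleration.
* Curvature uses spacing-scaled gradients but no further anisotropic
  correction.
* The similarity-map contract is only "nonnegative, same grid":
  registration-specific similarity definitions are the caller's business.
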