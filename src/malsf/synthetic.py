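"""Synthetic phantoms and perturbed atlas ensembles.

These fixtures emulate, at desk scale, the regime the fusion method is
built for: a compact structure with a low-contrast, blurred, noisy
boundary, and several imperfect candidate segmentations standing in for
atlas labels propagated through imperfect registration.  Atlas labels are
produced by warping the ground truth through independent smooth random
displacement fields (plus optional voxelwise label flips); similarity maps
are derived from smoothed agreement between each label and the ensemble
consensus, mimicking the local-similarity weights a registration method
would supply.

Everything is deterministic given the spec seeds, so tests and scripts can
regenerate identical data with no files on disk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .fusion import AtlasEnsemble, normalize_weights
from .levelset import BinaryMask, ImageVolume, signed_distance

__all__ = [
    "PhantomSpec",
    "AtlasPerturbSpec",
    "make_phantom",
    "make_atlas_ensemble",
    "standard_fixture",
]


@dataclass
class PhantomSpec:
    """Recipe for a low-contrast phantom.

    Defaults give the standard desk-scale fixture: a 64² grid, a bean-shaped
    structure, inside/outside means 120/100 on the 0-255 scale (contrast gap
    20), boundary blur 1 voxel and noise σ=8.
    """

    grid_size: tuple[int, ...] = (64, 64)
    shape: str = "bean"
    inside_mean: float = 120.0
    outside_mean: float = 100.0
    boundary_blur_sigma: float = 1.0
    noise_sigma: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if self.inside_mean == self.outside_mean:
            raise ParameterError("inside_mean must differ from outside_mean")
        if self.boundary_blur_sigma < 0 or self.noise_sigma < 0:
            raise ParameterError("sigmas must be >= 0")
        if self.shape not in ("ellipse", "ellipsoid", "bean"):
            raise ParameterError(f"unknown phantom shape {self.shape!r}")
        if len(self.grid_size) not in (2, 3):
            raise ParameterError("grid must be 2-D or 3-D")


@dataclass
class AtlasPerturbSpec:
    """Recipe for an ensemble of imperfect atlas labels.

    ``deform_amplitude`` is the maximum displacement (voxels) of the smooth
    random warp applied to the truth; ``deform_smoothness`` the Gaussian
    scale (voxels) of the displacement field; ``label_flip_rate`` the
    probability of flipping each voxel's label independently.
    """

    n_atlases: int = 10
    deform_amplitude: float = 3.0
    deform_smoothness: float = 4.0
    label_flip_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_atlases < 1:
            raise ParameterError("need at least one atlas")
        if self.deform_amplitude < 0 or self.deform_smoothness <= 0:
            raise ParameterError("amplitude must be >= 0 and smoothness > 0")
        if not 0 <= self.label_flip_rate < 0.5:
            raise ParameterError("label_flip_rate must lie in [0, 0.5)")


def _shape_mask(spec: PhantomSpec) -> np.ndarray:
    size = np.asarray(spec.grid_size, dtype=float)
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in spec.grid_size], indexing="ij")
    center = (size - 1) / 2.0

    def ellipse(ctr, semi):
        q = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, ctr, semi))
        return q <= 1.0

    semi = size * 0.28
    mask = ellipse(center, semi)
    if spec.shape == "bean":
        # a lobe offset along the first two axes makes the outline non-elliptic
        lobe_ctr = center + size * np.array([0.18, 0.12] + [0.0] * (len(size) - 2))
        mask = mask | ellipse(lobe_ctr, size * 0.16)
    frac = mask.mean()
    if not 0.05 <= frac <= 0.40:
        raise ParameterError(
            f"phantom shape occupies {frac:.1%} of the grid (need 5-40%)"
        )
    return mask.astype(np.uint8)


def make_phantom(spec: PhantomSpec) -> tuple[ImageVolume, BinaryMask]:
    """Build (image, truth) for the given recipe; deterministic per seed."""
    mask = _shape_mask(spec)
    img = spec.inside_mean * mask + spec.outside_mean * (1 - mask)
    img = img.astype(float)
    if spec.boundary_blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.boundary_blur_sigma)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    return ImageVolume(img), BinaryMask(mask)


def _smooth_displacement(rng, shape, smoothness: float, amplitude: float):
    """Smoothed white noise per axis, scaled so the largest displacement
    vector has length ``amplitude`` voxels."""
    comps = [ndimage.gaussian_filter(rng.normal(size=shape), smoothness) for _ in shape]
    mag = np.sqrt(sum(c * c for c in comps))
    peak = mag.max()
    if peak == 0:
        return [np.zeros(shape) for _ in shape]
    scale = amplitude / peak
    return [c * scale for c in comps]


def make_atlas_ensemble(truth, spec: AtlasPerturbSpec) -> AtlasEnsemble:
    """Deform the truth into N imperfect atlas labels with similarity maps.

    Each label resamples the truth (nearest-neighbor, so labels stay
    binary) through its own smooth random displacement field, then applies
    independent voxel flips.  Similarity maps are the Gaussian-smoothed
    agreement of each label with the ensemble consensus, and the fusion
    weights are their pointwise normalization.
    """
    t = (truth.values if isinstance(truth, BinaryMask) else np.asarray(truth)).astype(
        np.uint8
    )
    rng = np.random.default_rng(spec.seed)
    base_coords = np.meshgrid(*[np.arange(n, dtype=float) for n in t.shape], indexing="ij")

    labels = []
    for _ in range(spec.n_atlases):
        if spec.deform_amplitude > 0:
            disp = _smooth_displacement(
                rng, t.shape, spec.deform_smoothness, spec.deform_amplitude
            )
            coords = [g + d for g, d in zip(base_coords, disp)]
            lab = ndimage.map_coordinates(t, coords, order=0, mode="nearest")
        else:
            lab = t.copy()
        if spec.label_flip_rate > 0:
            flips = rng.random(t.shape) < spec.label_flip_rate
            lab = np.where(flips, 1 - lab, lab).astype(np.uint8)
        labels.append(BinaryMask(lab))

    consensus = sum(l.values.astype(float) for l in labels) / spec.n_atlases
    sims = []
    for l in labels:
        agreement = 1.0 - np.abs(l.values.astype(float) - consensus)
        s = ndimage.gaussian_filter(agreement, spec.deform_smoothness)
        sims.append(np.clip(s, 0.0, None))

    lsfs = [signed_distance(l) for l in labels]
    weights = normalize_weights(sims)
    return AtlasEnsemble(labels=labels, lsfs=lsfs, weights=weights)


def standard_fixture(seed: int = 0):
    """The standard desk-scale test case: 64² bean phantom (contrast gap 20,
    noise σ=8) with 10 atlases deformed by amplitude 3 and 2% label flips.

    Returns (ImageVolume, BinaryMask truth, AtlasEnsemble); fully
    deterministic given ``seed``.
    """
    pspec = PhantomSpec(seed=seed)
    aspec = AtlasPerturbSpec(seed=seed + 1)
    img, truth = make_phantom(pspec)
    ensemble = make_atlas_ensemble(truth, aspec)
    return img, truth, ensemble
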