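"""Independent brute-force reference implementations used as test oracles.

Everything here is written as directly as possible (explicit loops over
voxels and kernel offsets) and shares no code path with the package.
"""

from __future__ import annotations

import numpy as np


def brute_signed_distance(mask: np.ndarray, spacing=None) -> np.ndarray:
    """|phi| by exhaustive nearest-opposite-voxel search; negative inside."""
    mask = np.asarray(mask).astype(bool)
    if spacing is None:
        spacing = (1.0,) * mask.ndim
    spacing = np.asarray(spacing, dtype=float)
    coords = np.argwhere(np.ones_like(mask)) * spacing
    flat = mask.ravel()
    inside = coords[flat]
    outside = coords[~flat]
    out = np.empty(mask.size)
    for k, (c, is_in) in enumerate(zip(coords, flat)):
        other = outside if is_in else inside
        d = np.sqrt(((other - c) ** 2).sum(axis=1)).min()
        out[k] = -d if is_in else d
    return out.reshape(mask.shape)


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """Object voxels with an opposite-valued face neighbor (explicit scan)."""
    mask = np.asarray(mask).astype(bool)
    pts = []
    for idx in np.argwhere(mask):
        for axis in range(mask.ndim):
            for step in (-1, 1):
                nb = idx.copy()
                nb[axis] += step
                if 0 <= nb[axis] < mask.shape[axis] and not mask[tuple(nb)]:
                    pts.append(idx)
                    break
            else:
                continue
            break
    return np.asarray(pts, dtype=float)


def brute_hausdorff(a: np.ndarray, b: np.ndarray, spacing=None) -> float:
    """max of directed max-min distances over boundary voxels, O(|A|·|B|)."""
    if spacing is None:
        spacing = (1.0,) * np.asarray(a).ndim
    spacing = np.asarray(spacing, dtype=float)
    pa = boundary_points(a) * spacing
    pb = boundary_points(b) * spacing
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2))
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def reflect_index(i: int, n: int) -> int:
    """Symmetric (edge-repeating) boundary extension index, iterated."""
    while i < 0 or i >= n:
        if i < 0:
            i = -i - 1
        else:
            i = 2 * n - 1 - i
    return i


def kernel_weights(rho: float, ndim: int, truncate: float = 3.0):
    """Truncated n-D Gaussian weights on the offset box, unit total mass."""
    radius = max(1, int(np.ceil(truncate * rho)))
    offs = np.arange(-radius, radius + 1)
    grids = np.meshgrid(*([offs] * ndim), indexing="ij")
    sq = sum(g.astype(float) ** 2 for g in grids)
    w = np.exp(-sq / (2.0 * rho * rho))
    return offs, w / w.sum()


def kernel_convolve(field: np.ndarray, rho: float, truncate: float = 3.0) -> np.ndarray:
    """Direct double-loop evaluation of the kernel convolution with the same
    symmetric boundary extension as the package."""
    offs, w = kernel_weights(rho, field.ndim, truncate)
    out = np.zeros_like(field, dtype=float)
    for idx in np.ndindex(field.shape):
        acc = 0.0
        for koff in np.ndindex(w.shape):
            src = tuple(
                reflect_index(i + offs[k], n)
                for i, k, n in zip(idx, koff, field.shape)
            )
            acc += w[koff] * field[src]
        out[idx] = acc
    return out


def brute_e_field(img: np.ndarray, f: np.ndarray, rho: float) -> np.ndarray:
    """e(x) = sum_y K(x-y)|I(x) - f(y)|^2 by explicit double loop."""
    offs, w = kernel_weights(rho, img.ndim)
    out = np.zeros_like(img, dtype=float)
    for idx in np.ndindex(img.shape):
        acc = 0.0
        for koff in np.ndindex(w.shape):
            src = tuple(
                reflect_index(i + offs[k], n)
                for i, k, n in zip(idx, koff, img.shape)
            )
            acc += w[koff] * (img[idx] - f[src]) ** 2
        out[idx] = acc
    return out


def brute_fusion_energy(phi, weights, lsfs) -> float:
    total = 0.0
    for idx in np.ndindex(phi.shape):
        for w, p in zip(weights, lsfs):
            total += w[idx] * (phi[idx] - p[idx]) ** 2
    return total
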