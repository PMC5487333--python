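"""Segmentation evaluation metrics.

Volumetric overlap between a ground-truth mask A and an automatic mask B,
with V(·) the voxel count:

    SI = 2V(A∩B)/(V(A)+V(B))   (similarity index / Dice)
    P  = V(A∩B)/V(B)           (precision)
    R  = V(A∩B)/V(A)           (recall)
    RO = V(A∩B)/V(A∪B)         (relative overlap / Jaccard)

and the Hausdorff distance HD = max(H1, H2) with H1 = max_a min_b d(a,b),
H2 = max_b min_a d(a,b) over boundary voxels in physical units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import ParameterError, UndefinedMetricsError
from .levelset import BinaryMask, _as_spacing, check_congruent

__all__ = ["MetricsReport", "overlap_metrics", "hausdorff", "evaluate", "boundary_voxels"]


@dataclass
class MetricsReport:
    si: float
    precision: float
    recall: float
    ro: float
    hd: float | None = None

    def as_dict(self) -> dict:
        d = {"SI": self.si, "P": self.precision, "R": self.recall, "RO": self.ro}
        if self.hd is not None:
            d["HD"] = self.hd
        return d


def _mask(m) -> np.ndarray:
    return (m.values if isinstance(m, BinaryMask) else np.asarray(m)).astype(bool)


def overlap_metrics(truth, auto) -> MetricsReport:
    """SI, P, R and RO for a (ground-truth, automatic) mask pair.

    Raises UndefinedMetricsError if both masks are empty.  An empty truth
    gives recall NaN; an empty automatic mask gives precision NaN.
    """
    a = _mask(truth)
    b = _mask(auto)
    check_congruent(a.shape, b.shape)
    va = int(a.sum())
    vb = int(b.sum())
    if va == 0 and vb == 0:
        raise UndefinedMetricsError("both masks are empty; overlap metrics undefined")
    inter = int((a & b).sum())
    union = int((a | b).sum())
    return MetricsReport(
        si=2.0 * inter / (va + vb),
        precision=inter / vb if vb else float("nan"),
        recall=inter / va if va else float("nan"),
        ro=inter / union,
    )


def boundary_voxels(mask) -> np.ndarray:
    """Indices (k, ndim) of object voxels with ≥1 opposite-valued face
    neighbor (out-of-grid neighbors do not count)."""
    m = _mask(mask)
    structure = ndimage.generate_binary_structure(m.ndim, 1)
    eroded = ndimage.binary_erosion(m, structure=structure, border_value=1)
    return np.argwhere(m & ~eroded)


def hausdorff(truth, auto, spacing=None) -> float:
    """Symmetric Hausdorff distance between the two mask surfaces, in
    physical units.  Both masks must be nonempty."""
    a = _mask(truth)
    b = _mask(auto)
    check_congruent(a.shape, b.shape)
    if not a.any() or not b.any():
        raise ParameterError("Hausdorff distance requires two nonempty masks")
    spacing = np.asarray(_as_spacing(spacing, a.ndim))
    pa = boundary_voxels(a) * spacing
    pb = boundary_voxels(b) * spacing
    h1 = cKDTree(pb).query(pa)[0].max()
    h2 = cKDTree(pa).query(pb)[0].max()
    return float(max(h1, h2))


def evaluate(truth, auto, spacing=None) -> MetricsReport:
    """Full report: overlap metrics plus Hausdorff distance."""
    report = overlap_metrics(truth, auto)
    report.hd = hausdorff(truth, auto, spacing)
    return report
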