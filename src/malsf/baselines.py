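"""Voting label-fusion baselines.

Majority voting assigns each voxel the label agreed on by more than half
of the atlases; weighted voting thresholds the weight-averaged label at
0.5.  Ties go to background in both (conservative convention).
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError
from .levelset import BinaryMask, check_congruent

__all__ = ["majority_vote", "weighted_vote"]


def _mask(m) -> np.ndarray:
    return (m.values if isinstance(m, BinaryMask) else np.asarray(m)).astype(float)


def majority_vote(labels) -> BinaryMask:
    """Voxelwise strict-majority fusion: 1 iff ∑_i L_i > N/2."""
    if len(labels) < 1:
        raise ParameterError("need at least one label")
    arrs = [_mask(l) for l in labels]
    check_congruent(*[a.shape for a in arrs])
    votes = sum(arrs)
    return BinaryMask((votes > len(arrs) / 2.0).astype(np.uint8))


def weighted_vote(labels, weights) -> BinaryMask:
    """Weighted fusion: 1 iff ∑_i ω_i(x)·L_i(x) > 0.5, with pointwise-
    normalized weights (see :func:`malsf.fusion.normalize_weights`)."""
    if len(labels) != len(weights):
        raise ParameterError(
            f"{len(labels)} labels but {len(weights)} weight maps"
        )
    arrs = [_mask(l) for l in labels]
    wts = [np.asarray(w, dtype=float) for w in weights]
    check_congruent(*([a.shape for a in arrs] + [w.shape for w in wts]))
    score = sum(a * w for a, w in zip(arrs, wts))
    return BinaryMask((score > 0.5).astype(np.uint8))
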