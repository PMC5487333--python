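"""NIfTI I/O, preprocessing and the end-to-end pipeline.

Preprocessing follows the standard recipe for this kind of study: linear
min-max normalization of intensities to 0-255 and restriction of the
computation to a region of interest (ROI) built from the bounding box of
the union of all propagated labels, dilated by a safety margin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import CongruenceError, FormatError, ParameterError
from .fusion import AtlasEnsemble, FusionParams, SegmentationResult, segment
from .levelset import BinaryMask, ImageVolume
from .metrics import MetricsReport, evaluate

__all__ = [
    "RunConfig",
    "normalize_intensity",
    "roi_union",
    "load_volume",
    "load_mask",
    "save_mask",
    "save_volume",
    "run_pipeline",
]


def normalize_intensity(I: ImageVolume) -> ImageVolume:
    """Linearly rescale intensities to [0, 255]:
    (I − I_min)/(I_max − I_min) × 255."""
    data = I.data
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        raise ParameterError("constant image cannot be intensity-normalized")
    return ImageVolume((data - lo) / (hi - lo) * 255.0, I.spacing)


def roi_union(labels, margin: int = 5) -> tuple[slice, ...]:
    """Bounding box of the voxelwise union of the labels, dilated by
    ``margin`` voxels and clipped to the grid.  Returned as index slices."""
    if len(labels) < 1:
        raise ParameterError("need at least one label")
    arrs = [
        (l.values if isinstance(l, BinaryMask) else np.asarray(l)).astype(bool)
        for l in labels
    ]
    union = np.zeros(arrs[0].shape, dtype=bool)
    for a in arrs:
        if a.shape != union.shape:
            raise CongruenceError(f"label shapes differ: {a.shape} vs {union.shape}")
        union |= a
    if not union.any():
        raise ParameterError("all labels are empty; ROI undefined")
    idx = np.argwhere(union)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, union.shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def _load_nifti(path):
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[: data.ndim])
    return img, data, spacing


def load_volume(path) -> ImageVolume:
    """Load a NIfTI grayscale volume with its voxel spacing."""
    _, data, spacing = _load_nifti(path)
    return ImageVolume(np.squeeze(data), spacing[: np.squeeze(data).ndim])


def load_mask(path) -> BinaryMask:
    """Load a NIfTI label volume; {0, k} files are relabelled to {0, 1}."""
    _, data, _ = _load_nifti(path)
    data = np.squeeze(data)
    values = np.unique(data)
    if len(values) > 2:
        raise FormatError(
            f"{path}: mask has {len(values)} distinct values {values[:8]}; "
            "expected binary {0, k}"
        )
    return BinaryMask((data == values.max()).astype(np.uint8) if values.max() != 0 else data.astype(np.uint8))


def _reference_affine(reference):
    if reference is None:
        return np.eye(4)
    if isinstance(reference, (str, Path)):
        return nib.load(str(reference)).affine
    return reference  # assume affine matrix

def save_mask(mask: BinaryMask, path, reference=None) -> None:
    """Write a binary mask as NIfTI, copying the affine from ``reference``
    (a NIfTI path or a 4x4 affine) when given."""
    nib.save(nib.Nifti1Image(mask.values.astype(np.uint8), _reference_affine(reference)), str(path))


def save_volume(vol: ImageVolume, path, reference=None) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float32), _reference_affine(reference))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


@dataclass
class RunConfig:
    """Everything one segmentation run needs."""

    target_path: str
    atlas_label_paths: list[str]
    similarity_map_paths: list[str] | None = None
    truth_path: str | None = None
    params: FusionParams = field(default_factory=FusionParams)
    roi_mode: str = "union"  # or "none"
    roi_margin: int = 5
    output_dir: str = "malsf_out"
    normalize: bool = True

    def __post_init__(self):
        if self.similarity_map_paths is not None and len(
            self.similarity_map_paths
        ) != len(self.atlas_label_paths):
            raise ParameterError("one similarity map per atlas label is required")
        if self.roi_mode not in ("union", "none"):
            raise ParameterError(f"unknown roi_mode {self.roi_mode!r}")


def run_pipeline(config: RunConfig):
    """Normalize → ROI crop → build ensemble → segment → un-crop → write.

    Returns (SegmentationResult on the full grid, MetricsReport or None).
    Outputs written to ``config.output_dir``: the mask (NIfTI), the
    per-iteration energy trace (CSV), metrics (CSV, when a truth mask is
    given) and a JSON manifest of the run.
    """
    import pandas as pd

    target = load_volume(config.target_path)
    labels = []
    for p in config.atlas_label_paths:
        m = load_mask(p)
        if m.shape != target.shape:
            raise CongruenceError(f"{p}: grid {m.shape} != target {target.shape}")
        labels.append(m)
    sims = None
    if config.similarity_map_paths:
        sims = []
        for p in config.similarity_map_paths:
            v = load_volume(p)
            if v.shape != target.shape:
                raise CongruenceError(f"{p}: grid {v.shape} != target {target.shape}")
            sims.append(v.data)

    if config.normalize:
        target = normalize_intensity(target)

    if config.roi_mode == "union":
        roi = roi_union(labels, config.roi_margin)
    else:
        roi = tuple(slice(0, n) for n in target.shape)

    cropped = ImageVolume(target.data[roi], target.spacing)
    ensemble = AtlasEnsemble.from_labels(
        [BinaryMask(l.values[roi]) for l in labels],
        spacing=target.spacing,
        similarity_maps=[s[roi] for s in sims] if sims is not None else None,
    )
    result = segment(cropped, ensemble, config.params)

    full_mask = np.zeros(target.shape, dtype=np.uint8)
    full_mask[roi] = result.mask.values
    full_phi = result.phi  # kept on the ROI grid; the mask is un-cropped
    full_result = SegmentationResult(
        mask=BinaryMask(full_mask),
        phi=full_phi,
        energy_trace=result.energy_trace,
        iterations_run=result.iterations_run,
        empty_mask=result.empty_mask,
    )

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_mask(full_result.mask, out / "segmentation.nii.gz", config.target_path)
    result.trace_frame().to_csv(out / "energy_trace.csv", index=False)

    report = None
    if config.truth_path:
        truth = load_mask(config.truth_path)
        report = evaluate(truth, full_result.mask, target.spacing)
        pd.DataFrame([report.as_dict()]).to_csv(out / "metrics.csv", index=False)

    manifest = {
        "target": str(config.target_path),
        "atlas_labels": [str(p) for p in config.atlas_label_paths],
        "similarity_maps": [str(p) for p in config.similarity_map_paths or []],
        "params": config.params.to_dict(),
        "roi_mode": config.roi_mode,
        "roi_margin": config.roi_margin,
        "iterations_run": full_result.iterations_run,
        "empty_mask": full_result.empty_mask,
        "deterministic": True,  # the core uses no randomness
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return full_result, report
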