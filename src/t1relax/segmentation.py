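"""Three-class tissue segmentation, CSF exclusion and label resampling.

A deterministic intensity-clustering stand-in for a full segmentation tool:
in-brain voxels of a T1-weighted structural volume are clustered into three
intensity classes and mapped, in ascending mean-intensity order, to
CSF < GM < WM (the T1-weighted contrast ordering).  Bias-field estimation is
out of scope; segmentation accuracy degrades accordingly if a multiplicative
field is present.

The CSF mask derived from the labels removes CSF voxels from a T1 map's
validity mask before ROI averaging — the guard against ventricular
enlargement and atrophy contaminating tissue means.  An optional one-voxel
dilation of the CSF mask additionally strips the partial-volume shell at
CSF/tissue boundaries.

Registration is out of scope: volumes are assumed to share a grid, and a
known-affine nearest-neighbour resampler covers the structural-to-FLASH
alignment step only.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .t1fit import T1Map

__all__ = [
    "BACKGROUND",
    "CSF",
    "GM",
    "WM",
    "TissueLabelVolume",
    "segment_three_class",
    "remove_csf",
    "resample_labels",
]

BACKGROUND, CSF, GM, WM = 0, 1, 2, 3

# deterministic 1-D k-means settings
_INIT_PERCENTILES = (10.0, 50.0, 90.0)
_MAX_ITER = 100
_REL_TOL = 1e-4


@dataclass
class TissueLabelVolume:
    """Integer label volume: 0 background, 1 CSF, 2 GM, 3 WM."""

    labels: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.isin(np.unique(self.labels), [BACKGROUND, CSF, GM, WM]).all():
            raise ValueError("labels must be restricted to {0, 1, 2, 3}")

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


def segment_three_class(
    structural: np.ndarray,
    brain_mask: np.ndarray,
    seed: int = 0,
    affine: np.ndarray | None = None,
) -> TissueLabelVolume:
    """Cluster in-mask intensities into three classes ordered CSF < GM < WM.

    Deterministic 1-D k-means: means initialized at the 10th/50th/90th
    in-mask intensity percentiles, at most 100 Lloyd iterations, convergence
    at 1e-4 relative change.  ``seed`` is accepted for interface parity but
    unused — the procedure has no random element.  Raises when the mask is
    empty, intensities are not finite, or the intensity histogram does not
    separate into three distinguishable modes.
    """
    del seed  # deterministic percentile initialization; no randomness
    structural = np.asarray(structural, dtype=float)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if structural.shape != brain_mask.shape:
        raise ValueError("structural and brain_mask must share a shape")
    if not brain_mask.any():
        raise ValueError("brain mask is empty")
    vals = structural[brain_mask]
    if not np.isfinite(vals).all():
        raise ValueError("structural volume contains non-finite values inside the mask")

    centers = np.percentile(vals, _INIT_PERCENTILES).astype(float)
    for _ in range(_MAX_ITER):
        assign = np.argmin(np.abs(vals[:, None] - centers[None, :]), axis=1)
        new = centers.copy()
        for k in range(3):
            members = vals[assign == k]
            if members.size:
                new[k] = members.mean()
        scale = max(np.ptp(vals), np.finfo(float).eps)
        if np.max(np.abs(new - centers)) / scale < _REL_TOL:
            centers = new
            break
        centers = new
    assign = np.argmin(np.abs(vals[:, None] - centers[None, :]), axis=1)

    order = np.argsort(centers)  # ascending intensity -> CSF, GM, WM
    means, spreads, counts = [], [], []
    for k in order:
        members = vals[assign == k]
        counts.append(members.size)
        means.append(members.mean() if members.size else np.nan)
        spreads.append(members.std() if members.size else 0.0)
    if min(counts) == 0 or any(
        means[k + 1] - means[k] < 2.0 * (spreads[k] + spreads[k + 1]) for k in range(2)
    ):
        raise ValueError(
            "could not separate three distinguishable intensity modes; "
            "check the structural contrast (synthetic volumes need three "
            "well-separated class means)"
        )

    rank = np.empty(3, dtype=int)
    rank[order] = np.array([CSF, GM, WM])
    labels = np.zeros(structural.shape, dtype=np.int16)
    labels[brain_mask] = rank[assign]
    return TissueLabelVolume(labels=labels, affine=np.eye(4) if affine is None else affine)


def remove_csf(t1map: T1Map, labels: TissueLabelVolume, dilation: int = 0) -> T1Map:
    """Drop CSF-labeled voxels from a T1 map's validity mask.

    ``dilation`` > 0 additionally removes an n-voxel shell around CSF,
    guarding against partial-volume contamination at ventricle and sulcal
    boundaries.  Returns a new map; never adds voxels; idempotent.
    """
    if labels.labels.shape != t1map.t1.shape:
        raise ValueError(
            f"label shape {labels.labels.shape} does not match T1 map shape {t1map.t1.shape}"
        )
    csf = labels.mask(CSF)
    if dilation > 0:
        csf = ndimage.binary_dilation(csf, iterations=dilation)
    return dataclasses.replace(t1map, valid_mask=t1map.valid_mask & ~csf)


def resample_labels(
    labels: TissueLabelVolume,
    target_shape: tuple[int, int, int],
    target_affine: np.ndarray,
) -> TissueLabelVolume:
    """Nearest-neighbour resampling of a label volume onto a target grid.

    Voxel coordinates of the target grid are mapped through the target
    affine into world space and back through the inverse source affine;
    labels are looked up at the nearest source voxel (background outside).
    The label set is preserved or shrunk, never extended.
    """
    src_affine = np.asarray(labels.affine, dtype=float)
    target_affine = np.asarray(target_affine, dtype=float)
    for name, aff in (("source", src_affine), ("target", target_affine)):
        if abs(np.linalg.det(aff)) < 1e-12:
            raise ValueError(f"{name} affine is singular")
    mapping = np.linalg.inv(src_affine) @ target_affine
    ijk = np.indices(target_shape, dtype=float).reshape(3, -1)
    src = mapping[:3, :3] @ ijk + mapping[:3, 3:4]
    out = ndimage.map_coordinates(
        labels.labels.astype(np.int16), src, order=0, mode="constant", cval=BACKGROUND
    )
    return TissueLabelVolume(labels=out.reshape(target_shape), affine=target_affine)
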