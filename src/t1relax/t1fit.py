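"""Voxelwise T1 estimation by grid-search least squares over candidate T1 values.

The fitter takes the measured reference-angle intensity of a voxel as the
constant c, predicts the intensities at the remaining flip angles for every
candidate T1 on a uniform grid (default 1 ms steps over (0, 4000] ms), and
assigns the candidate minimizing the sum of squared prediction errors.  The
reference-angle image contributes only c; it is not a residual term.

Ties in the objective are broken toward the smaller T1.  Voxels whose argmin
lands on a grid endpoint are flagged boundary-saturated and excluded from the
validity mask, as are voxels with a non-positive or non-finite reference
intensity (background).

:func:`despot1_fit` provides the classical DESPOT1 linearization of the SPGR
equation (regress I/sin(a) on I/tan(a); the slope is E1) as an independent
closed-form route; it is exact on noiseless model data and is used in tests
to cross-check the grid fitter.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .signal_model import AcquisitionProtocol, predicted_signal

__all__ = ["T1Grid", "T1Map", "VoxelFit", "fit_voxel", "fit_volume", "despot1_fit"]


@dataclass(frozen=True)
class T1Grid:
    """Uniform candidate grid for the T1 search.

    ``t1_min_ms`` is exclusive when zero (the prediction is undefined at
    T1 = 0), in which case the grid starts at ``step_ms``.
    """

    t1_min_ms: float = 0.0
    t1_max_ms: float = 4000.0
    step_ms: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.t1_min_ms < self.t1_max_ms):
            raise ValueError("require 0 <= t1_min_ms < t1_max_ms")
        if self.step_ms <= 0:
            raise ValueError("step_ms must be positive")
        if len(self.values()) < 2:
            raise ValueError("grid must contain at least 2 candidate values")

    def values(self) -> np.ndarray:
        start = self.t1_min_ms if self.t1_min_ms > 0 else self.step_ms
        return np.arange(start, self.t1_max_ms + 0.5 * self.step_ms, self.step_ms)


@dataclass
class T1Map:
    """Fitted T1 volume (ms) with the minimized residual and validity mask.

    ``valid_mask`` marks voxels where a fit was attempted and did not
    saturate at a grid endpoint.  ``t1`` is NaN where no fit was attempted.
    """

    t1: np.ndarray
    residual: np.ndarray
    valid_mask: np.ndarray
    affine: np.ndarray
    boundary_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (self.t1.shape == self.residual.shape == self.valid_mask.shape):
            raise ValueError("t1, residual and valid_mask must share a shape")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")


class VoxelFit(NamedTuple):
    t1_ms: float
    residual: float
    boundary: bool
    valid: bool


def _prediction_matrix(protocol: AcquisitionProtocol, grid: T1Grid):
    """Candidate T1 values and the unit-c prediction matrix (n_grid, n_nonref)."""
    candidates = grid.values()
    angles = protocol.non_reference_angles_deg
    cols = [
        predicted_signal(1.0, protocol.reference_angle_deg, a, protocol.tr_ms, candidates)
        for a in angles
    ]
    return candidates, np.stack(cols, axis=1)


def _fit_flat(
    intensities: np.ndarray,
    protocol: AcquisitionProtocol,
    grid: T1Grid,
    chunk: int = 2048,
):
    """Grid-search fit of flattened voxel data.

    ``intensities`` has shape (n_angles, n_voxels), rows aligned with
    ``protocol.flip_angles_deg``.  Returns (t1, residual, boundary, valid)
    flat arrays.  Voxels with non-finite data or non-positive reference
    intensity are invalid and carry NaN.
    """
    intensities = np.asarray(intensities, dtype=float)
    n_angles, n_vox = intensities.shape
    if n_angles != len(protocol.flip_angles_deg):
        raise ValueError(
            f"got {n_angles} intensity rows for {len(protocol.flip_angles_deg)} protocol angles"
        )
    ref_idx = protocol.reference_index
    nonref_idx = [i for i in range(n_angles) if i != ref_idx]

    candidates, pred = _prediction_matrix(protocol, grid)
    n_grid = len(candidates)

    t1 = np.full(n_vox, np.nan)
    residual = np.full(n_vox, np.nan)
    boundary = np.zeros(n_vox, dtype=bool)
    attempted = np.isfinite(intensities).all(axis=0) & (intensities[ref_idx] > 0)

    # SSE(g, v) = c_v^2 * sum_a P_ga^2 - 2 c_v * (P I_v)_g + sum_a I_va^2.
    # Since c_v > 0 for every attempted voxel, the argmin over g equals that
    # of q(g, v) = c_v * sum_a P_ga^2 - 2 (P I_v)_g, which needs one GEMM
    # and no constant term; the residual is then evaluated directly at the
    # argmin so it is exactly non-negative and exactly zero for
    # self-consistent data.
    pred_sq = (pred * pred).sum(axis=1)  # (n_grid,)
    idx_attempted = np.flatnonzero(attempted)
    for lo in range(0, len(idx_attempted), chunk):
        sel = idx_attempted[lo : lo + chunk]
        c = intensities[ref_idx, sel]
        meas = intensities[nonref_idx][:, sel]  # (n_nonref, m)
        q = pred_sq[:, None] * c[None, :] - 2.0 * (pred @ meas)
        best = np.argmin(q, axis=0)  # first minimum -> smaller T1 on ties
        diff = pred[best, :].T * c[None, :] - meas  # exact residual at argmin
        t1[sel] = candidates[best]
        residual[sel] = (diff * diff).sum(axis=0)
        boundary[sel] = (best == 0) | (best == n_grid - 1)

    valid = attempted & ~boundary
    return t1, residual, boundary, valid


def fit_voxel(
    intensities: Sequence[float],
    protocol: AcquisitionProtocol,
    grid: T1Grid | None = None,
) -> VoxelFit:
    """Fit a single voxel's flip-angle intensity series.

    Returns the grid candidate minimizing the sum of squared differences
    between measured and predicted non-reference intensities, the minimized
    sum, a boundary-saturation flag, and a validity flag.  A non-positive or
    non-finite reference intensity marks the voxel invalid (background)
    rather than raising.
    """
    grid = grid or T1Grid()
    arr = np.asarray(intensities, dtype=float).reshape(-1, 1)
    t1, res, boundary, valid = _fit_flat(arr, protocol, grid)
    return VoxelFit(float(t1[0]), float(res[0]), bool(boundary[0]), bool(valid[0]))


def _as_array_and_affine(img):
    """Accept a nibabel spatial image or a bare ndarray (affine -> identity)."""
    if hasattr(img, "get_fdata"):
        return np.asarray(img.get_fdata(), dtype=float), np.asarray(img.affine)
    return np.asarray(img, dtype=float), None


def fit_volume(
    images: Sequence,
    protocol: AcquisitionProtocol,
    grid: T1Grid | None = None,
    mask: Optional[np.ndarray] = None,
    affine: Optional[np.ndarray] = None,
) -> T1Map:
    """Voxelwise grid-search T1 fit of a FLASH series.

    ``images`` is one volume per protocol flip angle, in protocol order;
    nibabel images and plain arrays are both accepted but must share shape
    and affine.  The fit runs inside ``mask`` (default: reference-angle
    signal > 0); boundary-saturated voxels are excluded from the validity
    mask.  Deterministic: identical inputs give identical maps.
    """
    grid = grid or T1Grid()
    if len(images) != len(protocol.flip_angles_deg):
        raise ValueError(
            f"got {len(images)} images for {len(protocol.flip_angles_deg)} protocol angles"
        )
    vols = []
    affines = []
    for i, img in enumerate(images):
        data, aff = _as_array_and_affine(img)
        vols.append(data)
        affines.append(aff)
        if data.shape != vols[0].shape:
            raise ValueError(
                f"image {i} has shape {data.shape}, expected {vols[0].shape} (image 0)"
            )
        if aff is not None and affines[0] is not None and not np.allclose(aff, affines[0]):
            raise ValueError(f"image {i} affine differs from image 0")
    out_affine = affine if affine is not None else next(
        (a for a in affines if a is not None), np.eye(4)
    )

    shape = vols[0].shape
    flat = np.stack([v.reshape(-1) for v in vols], axis=0)
    if mask is not None:
        if mask.shape != shape:
            raise ValueError(f"mask shape {mask.shape} does not match image shape {shape}")
        flat = flat.copy()
        flat[:, ~mask.reshape(-1)] = np.nan  # excluded voxels become invalid

    t1, residual, boundary, valid = _fit_flat(flat, protocol, grid)
    return T1Map(
        t1=t1.reshape(shape),
        residual=residual.reshape(shape),
        valid_mask=valid.reshape(shape),
        affine=np.asarray(out_affine, dtype=float),
        boundary_mask=boundary.reshape(shape),
    )


def despot1_fit(intensities: Sequence[float], protocol: AcquisitionProtocol) -> Optional[float]:
    """Closed-form DESPOT1 estimate of T1 from an SPGR flip-angle series.

    Regresses I/sin(a) on I/tan(a) over all protocol angles; the slope is
    E1 = exp(-TR/T1).  Returns None when the slope falls outside (0, 1),
    which signals non-physical input (e.g. the degenerate T1 -> infinity
    case).  Exact on noiseless model data; used as a test oracle, never by
    the production pipeline.
    """
    y_int = np.asarray(intensities, dtype=float)
    if y_int.shape != (len(protocol.flip_angles_deg),):
        raise ValueError("intensities must align 1:1 with protocol flip angles")
    pos = y_int > 0
    if pos.sum() < 2:
        return None
    a = np.deg2rad(np.asarray(protocol.flip_angles_deg, dtype=float))[pos]
    y_int = y_int[pos]
    x = y_int / np.tan(a)
    y = y_int / np.sin(a)
    slope, _ = np.polyfit(x, y, 1)
    if not (0 < slope < 1):
        return None
    return float(-protocol.tr_ms / np.log(slope))
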