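"""Closed-form steady-state signal equations for spoiled gradient-echo (FLASH) imaging.

The variable flip angle (VFA) method estimates the longitudinal relaxation
time T1 by acquiring several FLASH images at distinct flip angles with a
shared TR/TE and inverting the steady-state signal equation

    I(alpha) = M0 * exp(-TE/T2*) * sin(alpha) * (1 - E1) / (1 - cos(alpha) * E1),

with E1 = exp(-TR/T1).  For a very small flip angle, cos(alpha) ~ 1 and the
T1 dependence nearly cancels, so the small-angle image is treated as a direct
measurement of the constant c = M0 * exp(-TE/T2*) * sin(alpha_ref).  The
remaining images are then predicted from c and a candidate T1 alone:

    I(alpha) = c * (sin(alpha) / sin(alpha_ref)) * (1 - E1) / (1 - cos(alpha) * E1).

The small-angle step is an approximation: at the reference angle itself the
prediction equals c * (1 - E1) / (1 - cos(alpha_ref) * E1), not c.  That
residual factor is an intrinsic, T1-dependent bias of the method and is kept
as-is throughout the package (see docs/methods.md for its magnitude).

All angles are accepted in degrees; conversion to radians is internal.  Every
function is defined pointwise on scalars and lifts elementwise to arrays.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AcquisitionProtocol",
    "TissueState",
    "flash_signal",
    "small_angle_signal",
    "predicted_signal",
    "ernst_angle_deg",
]


@dataclass(frozen=True)
class AcquisitionProtocol:
    """FLASH series description: shared TR/TE plus the ordered flip-angle set.

    ``reference_angle_deg`` is the small angle whose image fixes the constant
    c; it must be a member of ``flip_angles_deg`` and at least two further
    angles are required so the single-unknown T1 fit is overdetermined.
    """

    tr_ms: float = 20.0
    te_ms: float = 4.15
    flip_angles_deg: tuple[float, ...] = (3.0, 5.0, 15.0, 30.0)
    reference_angle_deg: float = 3.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "flip_angles_deg", tuple(float(a) for a in self.flip_angles_deg))
        if not self.tr_ms > 0:
            raise ValueError(f"tr_ms must be positive, got {self.tr_ms}")
        if self.te_ms < 0:
            raise ValueError(f"te_ms must be non-negative, got {self.te_ms}")
        angles = self.flip_angles_deg
        if any(not (0 < a <= 90) for a in angles):
            raise ValueError(f"flip angles must lie in (0, 90] degrees, got {angles}")
        if len(set(angles)) != len(angles):
            raise ValueError(f"flip angles must be pairwise distinct, got {angles}")
        if self.reference_angle_deg not in angles:
            raise ValueError(
                f"reference angle {self.reference_angle_deg} not among flip angles {angles}"
            )
        if len(angles) - 1 < 2:
            raise ValueError("need at least 2 non-reference flip angles for an overdetermined fit")

    @property
    def non_reference_angles_deg(self) -> tuple[float, ...]:
        return tuple(a for a in self.flip_angles_deg if a != self.reference_angle_deg)

    @property
    def reference_index(self) -> int:
        return self.flip_angles_deg.index(self.reference_angle_deg)

    def to_dict(self) -> dict:
        return {
            "tr_ms": self.tr_ms,
            "te_ms": self.te_ms,
            "flip_angles_deg": list(self.flip_angles_deg),
            "reference_angle_deg": self.reference_angle_deg,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionProtocol":
        return cls(
            tr_ms=float(d["tr_ms"]),
            te_ms=float(d["te_ms"]),
            flip_angles_deg=tuple(float(a) for a in d["flip_angles_deg"]),
            reference_angle_deg=float(d.get("reference_angle_deg", 3.0)),
        )


@dataclass(frozen=True)
class TissueState:
    """Per-voxel signal-generating triple (M0, T1, T2*).

    Fields may be scalars or broadcastable arrays; T1 and T2* are in ms,
    M0 in arbitrary units.
    """

    m0: float | np.ndarray
    t1_ms: float | np.ndarray
    t2star_ms: float | np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.m0) < 0):
            raise ValueError("m0 must be non-negative")
        if np.any(np.asarray(self.t1_ms) <= 0):
            raise ValueError("t1_ms must be positive")
        if np.any(np.asarray(self.t2star_ms) <= 0):
            raise ValueError("t2star_ms must be positive")


def _check_alpha(alpha_deg) -> np.ndarray:
    a = np.asarray(alpha_deg, dtype=float)
    if np.any(a < 0) or np.any(a > 180):
        raise ValueError(f"flip angle must lie in [0, 180] degrees, got {alpha_deg}")
    return a


def flash_signal(tissue: TissueState, tr_ms: float, te_ms: float, alpha_deg) -> np.ndarray:
    """Steady-state spoiled gradient-echo signal intensity.

    Returns M0 * exp(-TE/T2*) * sin(a) * (1 - E1) / (1 - cos(a) * E1) with
    E1 = exp(-TR/T1); non-negative for flip angles in [0, 90] degrees.
    """
    if tr_ms <= 0:
        raise ValueError(f"tr_ms must be positive, got {tr_ms}")
    a = np.deg2rad(_check_alpha(alpha_deg))
    e1 = np.exp(-tr_ms / np.asarray(tissue.t1_ms, dtype=float))
    te_factor = np.exp(-te_ms / np.asarray(tissue.t2star_ms, dtype=float))
    out = tissue.m0 * te_factor * np.sin(a) * (1.0 - e1) / (1.0 - np.cos(a) * e1)
    return out if isinstance(out, np.ndarray) and out.ndim else float(out)


def small_angle_signal(tissue: TissueState, te_ms: float, alpha_deg) -> np.ndarray:
    """Small-flip-angle limit of :func:`flash_signal`: M0 * exp(-TE/T2*) * sin(a).

    Independent of T1 and TR; intended for the reference angle, whose image
    fixes the constant c of the T1 fit.  Linear in M0.
    """
    a = np.deg2rad(_check_alpha(alpha_deg))
    te_factor = np.exp(-te_ms / np.asarray(tissue.t2star_ms, dtype=float))
    out = tissue.m0 * te_factor * np.sin(a)
    return out if isinstance(out, np.ndarray) and out.ndim else float(out)


def predicted_signal(c, ref_alpha_deg: float, alpha_deg, tr_ms: float, t1_ms) -> np.ndarray:
    """FLASH intensity predicted from the measured reference-angle constant c.

    Returns c * (sin(a) / sin(a_ref)) * (1 - E1) / (1 - cos(a) * E1).  At
    a == a_ref the prediction is c * (1 - E1) / (1 - cos(a_ref) * E1), i.e.
    deliberately NOT exactly c: the small-angle approximation error is part
    of the method and is preserved, not corrected.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("c must be non-negative")
    t1 = np.asarray(t1_ms, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("t1_ms must be positive")
    if tr_ms <= 0:
        raise ValueError(f"tr_ms must be positive, got {tr_ms}")
    a = np.deg2rad(_check_alpha(alpha_deg))
    a_ref = np.deg2rad(_check_alpha(ref_alpha_deg))
    e1 = np.exp(-tr_ms / t1)
    out = c * (np.sin(a) / np.sin(a_ref)) * (1.0 - e1) / (1.0 - np.cos(a) * e1)
    return out if isinstance(out, np.ndarray) and out.ndim else float(out)


def ernst_angle_deg(tr_ms: float, t1_ms: float) -> float:
    """Flip angle maximizing the FLASH signal: arccos(exp(-TR/T1)), in degrees."""
    if tr_ms <= 0 or t1_ms <= 0:
        raise ValueError("tr_ms and t1_ms must be positive")
    return float(np.rad2deg(np.arccos(np.exp(-tr_ms / t1_ms))))
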