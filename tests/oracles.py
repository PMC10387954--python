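"""Independent oracles used by the test suite.

These re-derive expected values from the closed forms with their own
arithmetic and never call the production fitter's internals, so agreement
between the two routes is meaningful.
"""
from __future__ import annotations

import math

import numpy as np


def spgr_signal(m0: float, t1: float, t2star: float, tr: float, te: float, alpha_deg: float) -> float:
    """Scalar spoiled-GRE signal, written factor by factor with math functions."""
    a = math.radians(alpha_deg)
    e1 = math.exp(-tr / t1)
    return m0 * math.exp(-te / t2star) * math.sin(a) * (1.0 - e1) / (1.0 - math.cos(a) * e1)


def grid_candidates(t1_min: float = 0.0, t1_max: float = 4000.0, step: float = 1.0) -> np.ndarray:
    start = t1_min if t1_min > 0 else step
    return np.arange(start, t1_max + 0.5 * step, step)


def brute_force_fit(
    intensities,
    angles_deg,
    ref_angle_deg: float,
    tr_ms: float,
    t1_min: float = 0.0,
    t1_max: float = 4000.0,
    step: float = 1.0,
):
    """Exhaustive least-squares search over the candidate grid.

    The reference-angle intensity is taken as the constant c; predictions at
    the remaining angles use the reference-normalized closed form.  Returns
    (t1, sse) with ties broken toward the smaller candidate.
    """
    intensities = list(intensities)
    angles_deg = list(angles_deg)
    ref_i = angles_deg.index(ref_angle_deg)
    c = intensities[ref_i]
    cand = grid_candidates(t1_min, t1_max, step)
    e1 = np.exp(-tr_ms / cand)
    sse = np.zeros_like(cand)
    sin_ref = math.sin(math.radians(ref_angle_deg))
    for i, a in enumerate(angles_deg):
        if i == ref_i:
            continue
        ar = math.radians(a)
        pred = c * (math.sin(ar) / sin_ref) * (1.0 - e1) / (1.0 - math.cos(ar) * e1)
        sse = sse + (pred - intensities[i]) ** 2
    best = int(np.argmin(sse))
    return float(cand[best]), float(sse[best])


def approximation_bias(
    true_t1: float,
    tr: float = 20.0,
    te: float = 4.15,
    angles=(3.0, 5.0, 15.0, 30.0),
    ref: float = 3.0,
    m0: float = 1000.0,
    t2star: float = 50.0,
    step: float = 1.0,
) -> float:
    """Fitted-minus-true T1 (ms) on noiseless full-model data: the intrinsic
    small-angle approximation bias of the reference-normalized fit."""
    signals = [spgr_signal(m0, true_t1, t2star, tr, te, a) for a in angles]
    fitted, _ = brute_force_fit(signals, angles, ref, tr, step=step)
    return fitted - true_t1
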