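"""Digital two-group brain phantoms and simulated FLASH/structural acquisitions.

The generator produces, per synthetic subject, ground-truth volumes (T1, M0,
T2*, tissue labels, parcel labels) on a shared desk-scale grid plus
simulated acquisitions: one FLASH image per protocol flip angle driven by
the closed-form signal model, and a T1-weighted structural volume with three
well-separated class intensities (CSF < GM < WM).

The cohort emulates the statistical structure a young/old comparison
assumes:

* regionally prolonged T1 in the old group (additive shifts on designated
  parcels),
* enlarged ventricles in the old group (the CSF compartment radii scale by
  ``ventricle_scale_old``, so the CSF voxel count grows roughly by its
  cube), with a one-voxel partial-volume shell of mixed CSF/tissue signal
  at the ventricle boundary — the contamination that CSF removal exists to
  guard against,
* between-subject variability as an additive normal shift on each parcel's
  (and each background tissue's) mean T1,
* additive Gaussian measurement noise (Rician optional), with sigma given
  as a fraction of the mean grey-matter reference-angle signal.

Geometry is parametric — nested ellipsoids and boxes — so every voxel's
truth is exact.  Defaults: a 64 x 64 x 16 grid standing in for 256 x 256
axial acquisitions, tissue T1 of CSF 3500 / GM 1300 / WM 850 ms (typical
3 T literature values, package defaults rather than measured ones), n = 30
subjects per group, and a +150 ms old-group shift on a designated parcel
subset (bilateral hippocampus and left caudate).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from . import segmentation
from .signal_model import AcquisitionProtocol, TissueState, flash_signal

__all__ = [
    "Parcel",
    "PhantomSpec",
    "SyntheticSubject",
    "default_protocol",
    "default_phantom_spec",
    "build_phantom",
    "simulate_acquisition",
    "generate_cohort",
]

_TISSUES = ("csf", "gm", "wm")
_TISSUE_LABEL = {"csf": segmentation.CSF, "gm": segmentation.GM, "wm": segmentation.WM}


@dataclass(frozen=True)
class Parcel:
    """A ground-truth parcel: registry label id, admissible tissue, geometry.

    ``kind`` is ``"ellipsoid"`` (params: center xyz + radii xyz),
    ``"box"`` (params: lo xyz + hi xyz, inclusive), or ``"shell_box"``
    (a box intersected with the cortical GM shell between the white-matter
    core and the brain surface).
    """

    roi_id: int
    tissue_class: str  # "GM" | "WM"
    kind: str
    params: tuple[float, ...]


@dataclass
class PhantomSpec:
    """All knobs of the phantom generator; defaults are the study conditions."""

    shape: tuple[int, int, int] = (64, 64, 16)
    brain_radii: tuple[float, float, float] = (28.0, 26.0, 7.0)
    wm_radii: tuple[float, float, float] = (20.0, 20.0, 5.5)
    ventricle_centers: tuple[tuple[float, float, float], ...] = (
        (24.0, 28.0, 7.5),
        (39.0, 28.0, 7.5),
    )
    ventricle_radii: tuple[float, float, float] = (2.5, 4.5, 2.5)
    parcels: tuple[Parcel, ...] = ()
    tissue_t1_ms: dict = field(
        default_factory=lambda: {"csf": 3500.0, "gm": 1300.0, "wm": 850.0}
    )
    tissue_m0: dict = field(default_factory=lambda: {"csf": 1000.0, "gm": 850.0, "wm": 700.0})
    tissue_t2star_ms: dict = field(default_factory=lambda: {"csf": 200.0, "gm": 55.0, "wm": 45.0})
    structural_intensity: dict = field(
        default_factory=lambda: {"csf": 300.0, "gm": 600.0, "wm": 900.0}
    )
    structural_noise_sigma: float = 20.0
    group_effect_ms: dict = field(default_factory=lambda: {1: 150.0, 2: 150.0, 3: 150.0})
    ventricle_scale_old: float = 1.35
    csf_shell_fraction: float = 0.4  # CSF volume fraction in the partial-volume shell
    subject_sd_ms: float = 40.0
    noise_sigma: float = 0.02  # fraction of mean GM reference-angle signal
    noise_model: str = "gaussian"
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        if self.ventricle_scale_old < 1:
            raise ValueError("ventricle_scale_old must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not 0 <= self.csf_shell_fraction < 0.5:
            # above 0.5 the shell's majority tissue would be CSF, changing label semantics
            raise ValueError("csf_shell_fraction must lie in [0, 0.5)")
        for t1 in self.tissue_t1_ms.values():
            if not (0 < t1 < 4000):
                raise ValueError("tissue T1 means must lie within (0, 4000) ms")


@dataclass
class SyntheticSubject:
    """Ground truth and (after simulation) acquired volumes of one subject."""

    subject_id: str
    group_label: str  # "young" | "old"
    true_t1: np.ndarray
    m0: np.ndarray
    t2star: np.ndarray
    tissue_labels: np.ndarray  # ground-truth 0/1/2/3 labels
    roi_labels: np.ndarray
    brain_mask: np.ndarray
    shell_mask: np.ndarray  # partial-volume shell at the ventricle boundary
    structural_truth: np.ndarray
    affine: np.ndarray
    flash: Optional[list[np.ndarray]] = None  # one volume per protocol angle
    structural: Optional[np.ndarray] = None
    protocol: Optional[AcquisitionProtocol] = None


def default_protocol() -> AcquisitionProtocol:
    """The FLASH series settings emulated by the simulator (TR 20 ms, TE 4.15 ms,
    flip angles 3/5/15/30 degrees, 3-degree reference)."""
    return AcquisitionProtocol()


def default_phantom_spec(**overrides) -> PhantomSpec:
    """The standard 12-parcel desk-scale phantom.

    Six subcortical nuclei flank the ventricles (the bias-sensitive
    position), four cortical patches live in the GM shell, and two
    cerebellar parcels sit postero-inferiorly.  Parcel ids map onto the
    packaged registry: 1/2 hippocampus L/R, 3/4 caudate L/R, 5/6 thalamus
    L/R, 101/102 precentral L/R, 153/154 postcentral L/R, 205/206
    cerebellum III L/R.
    """
    parcels = (
        Parcel(3, "GM", "ellipsoid", (18.0, 28.0, 7.5, 3.0, 5.0, 3.0)),    # caudate L
        Parcel(4, "GM", "ellipsoid", (45.0, 28.0, 7.5, 3.0, 5.0, 3.0)),    # caudate R
        Parcel(5, "GM", "ellipsoid", (24.0, 38.0, 7.5, 3.5, 3.5, 3.0)),    # thalamus L
        Parcel(6, "GM", "ellipsoid", (39.0, 38.0, 7.5, 3.5, 3.5, 3.0)),    # thalamus R
        Parcel(1, "GM", "ellipsoid", (20.0, 46.0, 7.5, 3.0, 3.0, 2.5)),    # hippocampus L
        Parcel(2, "GM", "ellipsoid", (43.0, 46.0, 7.5, 3.0, 3.0, 2.5)),    # hippocampus R
        Parcel(101, "GM", "shell_box", (0, 30, 6, 18, 5, 11)),             # precentral L
        Parcel(102, "GM", "shell_box", (33, 63, 6, 18, 5, 11)),            # precentral R
        Parcel(153, "GM", "shell_box", (0, 30, 54, 63, 5, 11)),            # postcentral L
        Parcel(154, "GM", "shell_box", (33, 63, 54, 63, 5, 11)),           # postcentral R
        Parcel(205, "GM", "ellipsoid", (26.0, 50.0, 3.5, 3.0, 3.0, 2.0)),  # cerebellum III L
        Parcel(206, "GM", "ellipsoid", (37.0, 50.0, 3.5, 3.0, 3.0, 2.0)),  # cerebellum III R
    )
    spec = PhantomSpec(parcels=parcels)
    for key, value in overrides.items():
        if not hasattr(spec, key):
            raise TypeError(f"unknown phantom spec field {key!r}")
        setattr(spec, key, value)
    return spec


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = np.zeros(shape)
    for g, c, r in zip(grids, center, radii):
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def _box(shape, lo_hi) -> np.ndarray:
    x0, x1, y0, y1, z0, z1 = lo_hi
    m = np.zeros(shape, dtype=bool)
    m[int(x0) : int(x1) + 1, int(y0) : int(y1) + 1, int(z0) : int(z1) + 1] = True
    return m


def _parcel_mask(parcel: Parcel, spec: PhantomSpec, brain, gm_shell) -> np.ndarray:
    if parcel.kind == "ellipsoid":
        c, r = parcel.params[:3], parcel.params[3:]
        return _ellipsoid(spec.shape, c, r) & brain
    if parcel.kind == "box":
        return _box(spec.shape, parcel.params) & brain
    if parcel.kind == "shell_box":
        return _box(spec.shape, parcel.params) & gm_shell
    raise ValueError(f"unknown parcel kind {parcel.kind!r}")


def build_phantom(
    spec: PhantomSpec, group: str, seed: int, subject_id: str = "sub"
) -> SyntheticSubject:
    """Assemble one subject's ground-truth volumes.

    Deterministic given ``seed``.  The old group receives the per-parcel T1
    shifts of ``spec.group_effect_ms`` and ventricles scaled by
    ``spec.ventricle_scale_old``; parcels must not overlap.
    """
    if group not in ("young", "old"):
        raise ValueError(f"group must be 'young' or 'old', got {group!r}")
    rng = np.random.default_rng(seed)
    shape = spec.shape
    center = tuple((n - 1) / 2.0 for n in shape)

    brain = _ellipsoid(shape, center, spec.brain_radii)
    wm_core = _ellipsoid(shape, center, spec.wm_radii) & brain
    gm_shell = brain & ~wm_core

    tissue = np.zeros(shape, dtype=np.int16)
    tissue[gm_shell] = segmentation.GM
    tissue[wm_core] = segmentation.WM

    roi_labels = np.zeros(shape, dtype=np.int32)
    for parcel in spec.parcels:
        m = _parcel_mask(parcel, spec, brain, gm_shell)
        clash = m & (roi_labels != 0)
        if clash.any():
            raise ValueError(
                f"parcel {parcel.roi_id} overlaps parcel(s) {sorted(set(roi_labels[clash]))}"
            )
        roi_labels[m] = parcel.roi_id
        tissue[m] = _TISSUE_LABEL[parcel.tissue_class.lower()]

    # ventricles: CSF core (+ enlarged radii for the old group) and a
    # one-voxel partial-volume shell of mixed CSF/tissue signal around it
    vscale = spec.ventricle_scale_old if group == "old" else 1.0
    vradii = tuple(r * vscale for r in spec.ventricle_radii)
    core = np.zeros(shape, dtype=bool)
    for c in spec.ventricle_centers:
        core |= _ellipsoid(shape, c, vradii)
    core &= brain
    shell = ndimage.binary_dilation(core) & ~core & brain
    tissue[core] = segmentation.CSF

    # subject-level T1 variability: one normal shift per background tissue
    # and one per parcel, all SD = spec.subject_sd_ms
    tissue_shift = {t: rng.normal(0.0, spec.subject_sd_ms) for t in _TISSUES}
    parcel_shift = {p.roi_id: rng.normal(0.0, spec.subject_sd_ms) for p in spec.parcels}

    t1 = np.zeros(shape)
    m0 = np.zeros(shape)
    t2s = np.ones(shape)
    struct = np.zeros(shape)
    for t in _TISSUES:
        m = tissue == _TISSUE_LABEL[t]
        t1[m] = spec.tissue_t1_ms[t] + tissue_shift[t]
        m0[m] = spec.tissue_m0[t]
        t2s[m] = spec.tissue_t2star_ms[t]
        struct[m] = spec.structural_intensity[t]
    for parcel in spec.parcels:
        m = (roi_labels == parcel.roi_id) & (tissue != segmentation.CSF)
        base = spec.tissue_t1_ms[parcel.tissue_class.lower()]
        shift = parcel_shift[parcel.roi_id]
        effect = spec.group_effect_ms.get(parcel.roi_id, 0.0) if group == "old" else 0.0
        t1[m] = base + shift + effect

    # partial-volume shell: linear mixing with the subject's CSF values
    f = spec.csf_shell_fraction
    if f > 0:
        csf_t1 = spec.tissue_t1_ms["csf"] + tissue_shift["csf"]
        t1[shell] = f * csf_t1 + (1 - f) * t1[shell]
        m0[shell] = f * spec.tissue_m0["csf"] + (1 - f) * m0[shell]
        t2s[shell] = f * spec.tissue_t2star_ms["csf"] + (1 - f) * t2s[shell]
        struct[shell] = f * spec.structural_intensity["csf"] + (1 - f) * struct[shell]

    t1 = np.clip(t1, 1.0, None)
    return SyntheticSubject(
        subject_id=subject_id,
        group_label=group,
        true_t1=t1,
        m0=m0,
        t2star=t2s,
        tissue_labels=tissue,
        roi_labels=roi_labels,
        brain_mask=brain,
        shell_mask=shell,
        structural_truth=struct,
        affine=np.asarray(spec.affine, dtype=float).copy(),
    )


def simulate_acquisition(
    subject: SyntheticSubject,
    protocol: AcquisitionProtocol,
    noise_sigma: float = 0.02,
    noise_model: str = "gaussian",
    b1_scale: float = 1.0,
    seed: int = 0,
    structural_noise_sigma: float = 20.0,
) -> SyntheticSubject:
    """Simulate the FLASH series and the structural image for one subject.

    Each FLASH volume is the closed-form signal at the (b1_scale-perturbed)
    flip angle plus noise; ``noise_sigma`` is the additive SD as a fraction
    of the mean grey-matter reference-angle signal.  ``noise_model`` is
    ``"gaussian"`` (default) or ``"rician"`` (magnitude of a complex signal
    with i.i.d. Gaussian components; converges to Gaussian at high SNR).
    Seeded and reproducible; returns a new subject, truth untouched.
    """
    if b1_scale <= 0:
        raise ValueError(f"b1_scale must be positive, got {b1_scale}")
    if noise_model not in ("gaussian", "rician"):
        raise ValueError(f"noise_model must be 'gaussian' or 'rician', got {noise_model!r}")
    rng = np.random.default_rng(seed)
    brain = subject.brain_mask

    tissue = TissueState(
        m0=subject.m0[brain], t1_ms=subject.true_t1[brain], t2star_ms=subject.t2star[brain]
    )
    clean = []
    for alpha in protocol.flip_angles_deg:
        vol = np.zeros(subject.true_t1.shape)
        vol[brain] = flash_signal(tissue, protocol.tr_ms, protocol.te_ms, b1_scale * alpha)
        clean.append(vol)

    gm = subject.tissue_labels == segmentation.GM
    ref = clean[protocol.reference_index]
    sigma = noise_sigma * float(ref[gm].mean()) if gm.any() else 0.0

    def add_noise(vol: np.ndarray) -> np.ndarray:
        if sigma == 0:
            return vol.copy()
        if noise_model == "gaussian":
            return vol + rng.normal(0.0, sigma, vol.shape)
        return np.sqrt(
            (vol + rng.normal(0.0, sigma, vol.shape)) ** 2
            + rng.normal(0.0, sigma, vol.shape) ** 2
        )

    flash = [add_noise(v) for v in clean]
    structural = subject.structural_truth.copy()
    if structural_noise_sigma > 0:
        structural = structural + np.where(
            brain, rng.normal(0.0, structural_noise_sigma, structural.shape), 0.0
        )
    return dataclasses.replace(
        subject, flash=flash, structural=structural, protocol=protocol
    )


def generate_cohort(
    spec: PhantomSpec,
    n_young: int = 30,
    n_old: int = 30,
    seed: int = 0,
    protocol: AcquisitionProtocol | None = None,
) -> list[SyntheticSubject]:
    """Generate a fully simulated two-group cohort.

    Per-subject truth and acquisition seeds derive deterministically from
    the master seed, so regeneration with the same seed is bitwise
    identical.  Group sizes default to 30/30.
    """
    protocol = protocol or default_protocol()
    n_total = n_young + n_old
    child = np.random.SeedSequence(seed).generate_state(2 * max(n_total, 1)) % (2**31)
    subjects = []
    for i in range(n_total):
        group = "young" if i < n_young else "old"
        idx = i + 1 if group == "young" else i - n_young + 1
        sid = f"sub-{'Y' if group == 'young' else 'O'}{idx:02d}"
        truth = build_phantom(spec, group, seed=int(child[2 * i]), subject_id=sid)
        subjects.append(
            simulate_acquisition(
                truth,
                protocol,
                noise_sigma=spec.noise_sigma,
                noise_model=spec.noise_model,
                seed=int(child[2 * i + 1]),
                structural_noise_sigma=spec.structural_noise_sigma,
            )
        )
    return subjects
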