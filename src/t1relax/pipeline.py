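"""Pipeline orchestration: config, NIfTI round-tripping, and the end-to-end driver.

``run_all`` executes the whole analysis on a synthetic cohort in the
pipeline order segment -> fit -> CSF removal -> ROI measurement -> group
statistics, writing every intermediate to disk together with a JSON
provenance record (package version, master seed, config hash).  No stage
mutates its inputs, and a rerun with the same config and seed is
bit-identical for the deterministic stages.  Existing intermediates are
reused only with an explicit ``resume`` flag.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__, phantom, roi, stats
from .phantom import PhantomSpec, SyntheticSubject, default_phantom_spec
from .segmentation import remove_csf, segment_three_class
from .signal_model import AcquisitionProtocol
from .t1fit import T1Grid, T1Map, fit_volume

__all__ = [
    "PipelineConfig",
    "save_volume",
    "load_volume",
    "save_cohort",
    "measure_cohort",
    "run_all",
    "write_csv_with_provenance",
]

log = logging.getLogger("t1relax")


@dataclass
class PipelineConfig:
    """Validated bundle of every knob the end-to-end run needs."""

    protocol: AcquisitionProtocol = field(default_factory=AcquisitionProtocol)
    grid: T1Grid = field(default_factory=T1Grid)
    n_young: int = 30
    n_old: int = 30
    alpha: float = 0.05
    alpha_norm: float = 0.05
    normality_method: str = "ks"
    bonferroni: str = "pair"
    min_voxels: int = roi.DEFAULT_MIN_VOXELS
    csf_dilation: int = 1
    phantom_overrides: dict = field(default_factory=dict)
    seed: int = 17

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1) or not (0 < self.alpha_norm < 1):
            raise ValueError("alpha and alpha_norm must lie in (0, 1)")
        if self.n_young < 0 or self.n_old < 0:
            raise ValueError("group sizes must be non-negative")
        if self.bonferroni not in ("pair", "global"):
            raise ValueError("bonferroni must be 'pair' or 'global'")
        if self.min_voxels < 0 or self.csf_dilation < 0:
            raise ValueError("min_voxels and csf_dilation must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {
            "seed", "protocol", "grid", "cohort", "phantom", "stats", "roi",
        }
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config section(s): {sorted(unknown)}")
        kwargs: dict = {}
        if "protocol" in raw:
            kwargs["protocol"] = AcquisitionProtocol.from_dict(raw["protocol"])
        if "grid" in raw:
            kwargs["grid"] = T1Grid(**raw["grid"])
        cohort = raw.get("cohort", {})
        kwargs["n_young"] = int(cohort.get("n_young", 30))
        kwargs["n_old"] = int(cohort.get("n_old", 30))
        st = raw.get("stats", {})
        kwargs["alpha"] = float(st.get("alpha", 0.05))
        kwargs["alpha_norm"] = float(st.get("alpha_norm", 0.05))
        kwargs["normality_method"] = st.get("normality_method", "ks")
        kwargs["bonferroni"] = st.get("bonferroni", "pair")
        r = raw.get("roi", {})
        kwargs["min_voxels"] = int(r.get("min_voxels", roi.DEFAULT_MIN_VOXELS))
        kwargs["csf_dilation"] = int(r.get("csf_dilation", 1))
        kwargs["phantom_overrides"] = dict(raw.get("phantom", {}))
        kwargs["seed"] = int(raw.get("seed", 17))
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "protocol": self.protocol.to_dict(),
            "grid": dataclasses.asdict(self.grid),
            "cohort": {"n_young": self.n_young, "n_old": self.n_old},
            "phantom": dict(self.phantom_overrides),
            "stats": {
                "alpha": self.alpha,
                "alpha_norm": self.alpha_norm,
                "normality_method": self.normality_method,
                "bonferroni": self.bonferroni,
            },
            "roi": {"min_voxels": self.min_voxels, "csf_dilation": self.csf_dilation},
        }

    def phantom_spec(self) -> PhantomSpec:
        return default_phantom_spec(**self.phantom_overrides)


def save_volume(data: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a volume as 32-bit float NIfTI-1."""
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), np.asarray(img.affine)


def _provenance(config: PipelineConfig) -> dict:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return {
        "t1relax_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "config": config.to_dict(),
    }


def write_csv_with_provenance(df: pd.DataFrame, path, provenance: dict) -> None:
    """CSV with a commented provenance header (read back with comment='#')."""
    with open(path, "w") as fh:
        for key in ("t1relax_version", "seed", "config_sha256"):
            fh.write(f"# {key}: {provenance[key]}\n")
        df.to_csv(fh, index=False)


def save_cohort(subjects: list[SyntheticSubject], cohort_dir) -> Path:
    """Write per-subject NIfTI volumes plus a manifest CSV; returns the manifest path."""
    cohort_dir = Path(cohort_dir)
    cohort_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        if s.flash is None or s.protocol is None:
            raise ValueError(f"subject {s.subject_id} has no simulated acquisition to save")
        row = {"subject_id": s.subject_id, "group_label": s.group_label}
        for alpha, vol in zip(s.protocol.flip_angles_deg, s.flash):
            name = f"{s.subject_id}_flash{alpha:g}.nii.gz"
            save_volume(vol, s.affine, cohort_dir / name)
            row[f"flash_{alpha:g}"] = name
        for key, vol in (
            ("structural", s.structural),
            ("roi_labels", s.roi_labels),
            ("brain_mask", s.brain_mask.astype(np.float32)),
            ("true_t1", s.true_t1),
        ):
            name = f"{s.subject_id}_{key}.nii.gz"
            save_volume(vol, s.affine, cohort_dir / name)
            row[key] = name
        rows.append(row)
    manifest = cohort_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def measure_cohort(
    subjects: list[SyntheticSubject],
    protocol: AcquisitionProtocol,
    grid: T1Grid | None = None,
    csf_dilation: int = 1,
    min_voxels: int = roi.DEFAULT_MIN_VOXELS,
    registry=None,
) -> pd.DataFrame:
    """In-memory segment -> fit -> CSF removal -> ROI measurement over a cohort.

    The same per-subject processing as :func:`run_all` without the disk
    round-trip; returns the pooled measurement table.
    """
    grid = grid or T1Grid()
    registry = registry if registry is not None else roi.load_registry()
    frames = []
    for s in subjects:
        if s.flash is None:
            raise ValueError(f"subject {s.subject_id} has no simulated acquisition")
        labels = segment_three_class(s.structural, s.brain_mask, affine=s.affine)
        t1map = fit_volume(s.flash, protocol, grid, mask=s.brain_mask, affine=s.affine)
        t1map = remove_csf(t1map, labels, dilation=csf_dilation)
        frames.append(
            roi.measure_all(
                t1map, s.roi_labels, labels, registry,
                min_voxels=min_voxels, subject_id=s.subject_id, group_label=s.group_label,
            )
        )
    return pd.concat(frames, ignore_index=True)


def _stage(name: str):
    """Tiny context manager logging per-stage wall time at INFO."""
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, *exc):
            log.info("stage %s: %.1f s", name, time.perf_counter() - self.t0)
            return False

    return _Timer()


def run_all(
    config: PipelineConfig,
    out_dir,
    cohort_dir=None,
    resume: bool = False,
) -> pd.DataFrame:
    """Full analysis on a synthetic cohort; returns the comparison table.

    Writes, under ``out_dir``: the cohort (unless ``cohort_dir`` points at
    an existing one), per-subject T1 maps and tissue labels, the pooled
    ``measurements.csv``, the per-region ``comparisons.csv`` and
    ``provenance.json``.  With ``resume`` existing per-subject maps are
    reloaded instead of recomputed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)
    registry = roi.load_registry()

    if cohort_dir is None:
        cohort_dir = out_dir / "cohort"
        manifest = Path(cohort_dir) / "manifest.csv"
        if not (resume and manifest.exists()):
            with _stage("simulate"):
                subjects = phantom.generate_cohort(
                    config.phantom_spec(),
                    n_young=config.n_young,
                    n_old=config.n_old,
                    seed=config.seed,
                    protocol=config.protocol,
                )
                save_cohort(subjects, cohort_dir)
    manifest = Path(cohort_dir) / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(
            f"stage 'simulate' output missing: no manifest at {manifest}"
        )
    table = pd.read_csv(manifest)

    measurements = []
    with _stage("per-subject processing"):
        for _, row in table.iterrows():
            sid = row["subject_id"]
            flash_cols = [c for c in table.columns if c.startswith("flash_")]
            angles = sorted(float(c.split("_", 1)[1]) for c in flash_cols)
            if tuple(angles) != tuple(sorted(config.protocol.flip_angles_deg)):
                raise ValueError(
                    f"stage 'fit' input mismatch: cohort angles {angles} vs "
                    f"protocol {config.protocol.flip_angles_deg}"
                )
            vols, affine = {}, None
            for alpha in config.protocol.flip_angles_deg:
                vols[alpha], affine = load_volume(Path(cohort_dir) / row[f"flash_{alpha:g}"])
            structural, _ = load_volume(Path(cohort_dir) / row["structural"])
            roi_labels, _ = load_volume(Path(cohort_dir) / row["roi_labels"])
            brain_mask = load_volume(Path(cohort_dir) / row["brain_mask"])[0] > 0.5

            labels = segment_three_class(structural, brain_mask, affine=affine)
            save_volume(labels.labels, affine, out_dir / f"{sid}_tissue_labels.nii.gz")

            map_path = out_dir / f"{sid}_t1map.nii.gz"
            if resume and map_path.exists():
                t1_data, _ = load_volume(map_path)
                valid = load_volume(out_dir / f"{sid}_t1map_valid.nii.gz")[0] > 0.5
                t1map = T1Map(
                    t1=t1_data, residual=np.zeros_like(t1_data),
                    valid_mask=valid, affine=affine,
                )
            else:
                t1map = fit_volume(
                    [vols[a] for a in config.protocol.flip_angles_deg],
                    config.protocol, config.grid, mask=brain_mask, affine=affine,
                )
                save_volume(t1map.t1, affine, map_path)
                save_volume(
                    t1map.valid_mask.astype(np.float32), affine,
                    out_dir / f"{sid}_t1map_valid.nii.gz",
                )

            t1map = remove_csf(t1map, labels, dilation=config.csf_dilation)
            measurements.append(
                roi.measure_all(
                    t1map, np.rint(roi_labels).astype(np.int32), labels, registry,
                    min_voxels=config.min_voxels,
                    subject_id=sid, group_label=row["group_label"],
                )
            )

    measured = pd.concat(measurements, ignore_index=True)
    write_csv_with_provenance(measured, out_dir / "measurements.csv", prov)

    with _stage("stats"):
        comparisons = stats.run_group_analysis(
            measured, registry,
            alpha=config.alpha, alpha_norm=config.alpha_norm,
            method=config.normality_method, bonferroni=config.bonferroni,
        )
    write_csv_with_provenance(comparisons, out_dir / "comparisons.csv", prov)
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(prov, fh, indent=2, sort_keys=True)
    summary = stats.summarize_comparisons(comparisons)
    log.info("significant regions: %d of %d tested", summary["n_significant"], summary["n_tested"])
    return comparisons
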