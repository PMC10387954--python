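"""ROI registry and tissue-restricted mean-T1 measurement.

The packaged registry mirrors a whole-brain macro-label parcellation:
134 measurement regions (12 subcortical, 72 cortical, 25 cerebellar GM,
25 cerebellar WM) plus 72 auxiliary cortical white-matter masks used to
strip the WM rim surrounding gyri (partial-volume control).  Bilateral
regions come as L/R pairs sharing a base name; vermis regions are
unilateral.

A region's mean T1 for one subject is the average over voxels that are
simultaneously (a) inside the region's label, (b) in the T1 map's validity
mask (hence CSF-free after CSF removal), and (c) of the region's admissible
tissue class.  Means over fewer than ``min_voxels`` voxels are flagged
rather than silently dropped.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import segmentation
from .segmentation import TissueLabelVolume
from .t1fit import T1Map

__all__ = [
    "RoiRecord",
    "RoiMeasurement",
    "Registry",
    "load_registry",
    "measure_roi",
    "measure_all",
    "DEFAULT_MIN_VOXELS",
]

DEFAULT_MIN_VOXELS = 10

_VALID_GROUPS = {"subcortical", "cortex", "cerebellum_gm", "cerebellum_wm", "cortex_wm_mask"}
_VALID_HEMI = {"L", "R", "unilateral"}
_VALID_TISSUE = {"GM", "WM"}
_TISSUE_LABEL = {"GM": segmentation.GM, "WM": segmentation.WM}


@dataclass(frozen=True)
class RoiRecord:
    """Registry entry: label id, display name, anatomical group, hemisphere, admissible tissue."""

    roi_id: int
    name: str
    group: str
    hemisphere: str
    tissue_class: str


@dataclass(frozen=True)
class RoiMeasurement:
    """Per-subject summary of one region: mean T1 (ms) and contributing voxel count."""

    subject_id: str
    group_label: str
    roi_id: int
    name: str
    mean_t1_ms: float
    voxel_count: int
    flag: str  # "ok" | "too_few_voxels" | "absent"


@dataclass(frozen=True)
class Registry:
    """The 134 measurement regions plus the auxiliary cortical-WM mask list."""

    records: tuple[RoiRecord, ...]
    cortical_wm_masks: tuple[RoiRecord, ...]

    def group_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.group] = counts.get(r.group, 0) + 1
        return counts

    def by_id(self) -> dict[int, RoiRecord]:
        return {r.roi_id: r for r in self.records}


def load_registry(path=None) -> Registry:
    """Load the ROI registry from a TSV (default: the packaged table).

    Columns: roi_id, name, group, hemisphere, tissue_class.  Auxiliary
    cortical-WM mask rows (group ``cortex_wm_mask``) are returned in a
    separate list.  Malformed rows raise with their (1-based, post-header)
    row number.
    """
    if path is None:
        source = resources.files("t1relax.data").joinpath("roi_registry.tsv")
        text = source.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    lines = text.strip().splitlines()
    header = lines[0].split("\t")
    expected = ["roi_id", "name", "group", "hemisphere", "tissue_class"]
    if header != expected:
        raise ValueError(f"registry header {header} does not match {expected}")

    records, aux = [], []
    seen_ids: set[int] = set()
    for row_no, line in enumerate(lines[1:], start=1):
        fields = line.split("\t")
        if len(fields) != 5:
            raise ValueError(f"registry row {row_no}: expected 5 fields, got {len(fields)}")
        raw_id, name, group, hemi, tissue = fields
        try:
            roi_id = int(raw_id)
        except ValueError:
            raise ValueError(f"registry row {row_no}: roi_id {raw_id!r} is not an integer")
        if group not in _VALID_GROUPS:
            raise ValueError(f"registry row {row_no}: unknown group {group!r}")
        if hemi not in _VALID_HEMI:
            raise ValueError(f"registry row {row_no}: unknown hemisphere {hemi!r}")
        if tissue not in _VALID_TISSUE:
            raise ValueError(f"registry row {row_no}: unknown tissue_class {tissue!r}")
        if roi_id in seen_ids:
            raise ValueError(f"registry row {row_no}: duplicate roi_id {roi_id}")
        seen_ids.add(roi_id)
        rec = RoiRecord(roi_id, name, group, hemi, tissue)
        (aux if group == "cortex_wm_mask" else records).append(rec)

    _check_bilateral_pairs(records, "measurement regions")
    _check_bilateral_pairs(aux, "cortical WM masks")
    return Registry(records=tuple(records), cortical_wm_masks=tuple(aux))


def _check_bilateral_pairs(records: Sequence[RoiRecord], what: str) -> None:
    from collections import Counter

    base = Counter()
    for r in records:
        if r.hemisphere in ("L", "R"):
            base[(r.name.rsplit(" ", 1)[0], r.hemisphere)] += 1
    names = {n for n, _ in base}
    for n in names:
        if base[(n, "L")] != base[(n, "R")]:
            raise ValueError(f"{what}: bilateral region {n!r} lacks its L/R counterpart")


def measure_roi(
    t1map: T1Map,
    roi_labels: np.ndarray,
    tissue_labels: TissueLabelVolume,
    roi: RoiRecord,
    min_voxels: int = DEFAULT_MIN_VOXELS,
    subject_id: str = "",
    group_label: str = "",
) -> RoiMeasurement:
    """Mean T1 of one region for one subject, restricted to admissible tissue.

    All volumes must be co-registered (same grid).  Returns NaN with a flag
    when the region is absent from the label volume or survives masking
    with fewer than ``min_voxels`` voxels.
    """
    roi_labels = np.asarray(roi_labels)
    if roi_labels.shape != t1map.t1.shape or tissue_labels.labels.shape != t1map.t1.shape:
        raise ValueError("t1map, roi_labels and tissue_labels must share a shape")
    in_roi = roi_labels == roi.roi_id
    if not in_roi.any():
        return RoiMeasurement(subject_id, group_label, roi.roi_id, roi.name, np.nan, 0, "absent")
    want = _TISSUE_LABEL[roi.tissue_class]
    sel = in_roi & t1map.valid_mask & (tissue_labels.labels == want)
    n = int(sel.sum())
    if n < min_voxels:
        return RoiMeasurement(
            subject_id, group_label, roi.roi_id, roi.name, np.nan, n, "too_few_voxels"
        )
    return RoiMeasurement(
        subject_id, group_label, roi.roi_id, roi.name, float(t1map.t1[sel].mean()), n, "ok"
    )


def measure_all(
    t1map: T1Map,
    roi_labels: np.ndarray,
    tissue_labels: TissueLabelVolume,
    registry: Registry | Iterable[RoiRecord],
    min_voxels: int = DEFAULT_MIN_VOXELS,
    subject_id: str = "",
    group_label: str = "",
) -> pd.DataFrame:
    """One measurement row per registry entry, ordered by roi_id.

    Per-region flags propagate into the table; the batch never aborts on a
    missing or underpopulated region.
    """
    records = registry.records if isinstance(registry, Registry) else tuple(registry)
    rows = [
        measure_roi(
            t1map, roi_labels, tissue_labels, rec,
            min_voxels=min_voxels, subject_id=subject_id, group_label=group_label,
        )
        for rec in records
    ]
    df = pd.DataFrame(
        {
            "subject_id": [m.subject_id for m in rows],
            "group_label": [m.group_label for m in rows],
            "roi_id": [m.roi_id for m in rows],
            "name": [m.name for m in rows],
            "mean_t1_ms": [m.mean_t1_ms for m in rows],
            "voxel_count": [m.voxel_count for m in rows],
            "flag": [m.flag for m in rows],
        }
    )
    return df.sort_values("roi_id", kind="stable").reset_index(drop=True)
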