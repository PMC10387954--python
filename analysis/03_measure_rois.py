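#!/usr/bin/env python
"""Segment, remove CSF and measure per-region mean T1 for every subject.

Demonstrates the CSF-removal rationale along the way: for the
ventricle-adjacent caudate in the old group, the measured mean is reported
both with and without (dilated) CSF-mask removal; only the former is free
of the enlarged-ventricle partial-volume bias.
"""
import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from t1relax.roi import load_registry, measure_all
from t1relax.pipeline import load_volume
from t1relax.segmentation import remove_csf, segment_three_class
from t1relax.t1fit import T1Map


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--t1maps", type=Path, default=Path("results/t1maps"))
    ap.add_argument("--out", type=Path, default=Path("results/measurements.csv"))
    args = ap.parse_args()

    registry = load_registry()
    manifest = pd.read_csv(args.cohort / "manifest.csv")
    frames, no_removal_caudate = [], []
    for _, row in manifest.iterrows():
        sid = row["subject_id"]
        structural, affine = load_volume(args.cohort / row["structural"])
        mask = load_volume(args.cohort / row["brain_mask"])[0] > 0.5
        labels = segment_three_class(structural, mask, affine=affine)
        t1, _ = load_volume(args.t1maps / f"{sid}_t1map.nii.gz")
        valid = load_volume(args.t1maps / f"{sid}_t1map_valid.nii.gz")[0] > 0.5
        t1map = T1Map(t1=t1, residual=np.zeros_like(t1), valid_mask=valid, affine=affine)
        roi_labels = np.rint(load_volume(args.cohort / row["roi_labels"])[0]).astype(np.int32)

        cleaned = remove_csf(t1map, labels, dilation=1)
        frames.append(
            measure_all(cleaned, roi_labels, labels, registry,
                        subject_id=sid, group_label=row["group_label"])
        )
        if row["group_label"] == "old":
            raw = measure_all(t1map, roi_labels, labels, registry,
                              subject_id=sid, group_label="old")
            merged = frames[-1].merge(raw, on="roi_id", suffixes=("_clean", "_raw"))
            sub = merged[merged["roi_id"].isin([3, 4])]
            no_removal_caudate.append(
                float((sub["mean_t1_ms_raw"] - sub["mean_t1_ms_clean"]).mean())
            )

    measured = pd.concat(frames, ignore_index=True)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    measured.to_csv(args.out, index=False)
    ok = measured[measured["flag"] == "ok"]
    print(f"wrote {args.out}: {len(ok)} measurements over {ok['roi_id'].nunique()} regions")
    print(
        "old-group caudate mean shift if CSF removal is DISABLED: "
        f"+{np.mean(no_removal_caudate):.1f} ms (enlarged-ventricle partial-volume bias)"
    )


if __name__ == "__main__":
    main()
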