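#!/usr/bin/env python
"""Fit per-subject T1 maps from the simulated FLASH series.

Reads the cohort written by 01_simulate_cohort.py, runs the grid-search
fit (1 ms candidates over (0, 4000] ms) per subject, writes the maps, and
prints the recovery statistics against the known ground truth — including
the method's intrinsic small-angle approximation bias, which makes fitted
T1 systematically lower than true T1.
"""
import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from t1relax.pipeline import load_volume, save_volume
from t1relax.signal_model import AcquisitionProtocol
from t1relax.t1fit import fit_volume


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results/t1maps"))
    args = ap.parse_args()

    protocol = AcquisitionProtocol()
    manifest = pd.read_csv(args.cohort / "manifest.csv")
    args.out.mkdir(parents=True, exist_ok=True)

    rows = []
    for _, row in manifest.iterrows():
        vols, affine = [], None
        for alpha in protocol.flip_angles_deg:
            v, affine = load_volume(args.cohort / row[f"flash_{alpha:g}"])
            vols.append(v)
        mask = load_volume(args.cohort / row["brain_mask"])[0] > 0.5
        t1map = fit_volume(vols, protocol, mask=mask, affine=affine)
        save_volume(t1map.t1, affine, args.out / f"{row['subject_id']}_t1map.nii.gz")
        save_volume(
            t1map.valid_mask.astype(np.float32), affine,
            args.out / f"{row['subject_id']}_t1map_valid.nii.gz",
        )
        true_t1 = load_volume(args.cohort / row["true_t1"])[0]
        err = t1map.t1[mask] - true_t1[mask]
        rows.append(
            {"subject_id": row["subject_id"], "group": row["group_label"],
             "median_error_ms": float(np.median(err)),
             "mad_ms": float(np.median(np.abs(err - np.median(err))))}
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(args.out / "fit_summary.csv", index=False)
    print(summary.groupby("group")[["median_error_ms", "mad_ms"]].mean().round(1))
    print(
        "\nNote: the negative median error is the documented small-angle\n"
        "approximation bias of the reference-normalized fit, not noise."
    )


if __name__ == "__main__":
    main()
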