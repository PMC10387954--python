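#!/usr/bin/env python
"""Young/old group comparison per region.

Applies the normality gate (Kolmogorov-Smirnov per group), then an
independent-samples t-test or Mann-Whitney U per region, Bonferroni n = 2
for bilateral pairs, threshold p < 0.05; prints the significant regions
and their direction.
"""
import argparse
from pathlib import Path

import pandas as pd

from t1relax.roi import load_registry
from t1relax.stats import run_group_analysis, summarize_comparisons


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--measures", type=Path, default=Path("results/measurements.csv"))
    ap.add_argument("--alpha", type=float, default=0.05)
    ap.add_argument("--bonferroni", choices=["pair", "global"], default="pair")
    ap.add_argument("--out", type=Path, default=Path("results/comparisons.csv"))
    args = ap.parse_args()

    measured = pd.read_csv(args.measures, comment="#")
    comparisons = run_group_analysis(
        measured, load_registry(), alpha=args.alpha, bonferroni=args.bonferroni
    )
    args.out.parent.mkdir(parents=True, exist_ok=True)
    comparisons.to_csv(args.out, index=False)

    summary = summarize_comparisons(comparisons)
    print(f"{summary['n_significant']} of {summary['n_tested']} regions significant "
          f"at alpha = {args.alpha} ({args.bonferroni} Bonferroni)")
    sig = comparisons[comparisons["significant"]]
    if not sig.empty:
        print(sig[["roi_id", "name", "test_used", "p_corrected", "direction"]]
              .to_string(index=False))


if __name__ == "__main__":
    main()
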