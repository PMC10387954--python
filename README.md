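# t1relax

Whole-brain T1 relaxometry by the variable-flip-angle (VFA) method, built
as a tested analysis pipeline that runs entirely on digital brain phantoms:
FLASH signal model, grid-search T1 mapping, three-class tissue segmentation
with CSF exclusion, mean-T1 measurement over a 134-region atlas-style
registry, normality-gated young/old group statistics, and a flip-angle (B1)
robustness sweep.

It is aimed at quantitative-MRI researchers who want a reproducible,
inspectable implementation of this ROI-based aging workflow — including its
intrinsic biases — without access to subject data.

## The method

A spoiled gradient-echo image at flip angle α follows

    I(α) = M0 · e^(−TE/T2*) · sin α · (1 − E1) / (1 − cos α · E1),   E1 = e^(−TR/T1)

with TR/TE fixed across the series (defaults TR = 20 ms, TE = 4.15 ms,
α ∈ {3°, 5°, 15°, 30°}).  The 3° image is taken as a direct measurement of
the amplitude constant c = M0·e^(−TE/T2*)·sin 3°; the other angles are then
predicted from c and a candidate T1,

    Î(α; T1) = c · (sin α / sin 3°) · (1 − E1) / (1 − cos α · E1),

and each voxel's T1 is the least-squares argmin over a 1 ms candidate grid
on (0, 4000] ms.  CSF voxels (from a three-class segmentation of the
structural image) are removed before ROI averaging; per region, groups are
compared with a t-test or Mann–Whitney U according to a Kolmogorov–Smirnov
normality gate, Bonferroni-corrected n = 2 for bilateral pairs, p < 0.05.

The small-angle normalization is deliberately preserved with its intrinsic
T1-dependent underestimation bias (−3% at T1 = 300 ms to −26% at 3500 ms);
see `docs/methods.md` for the quantification and its consequences.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic cohort (30 young + 30 old, +150 ms old-group prolongation in the
bilateral hippocampus and left caudate, 1.35× enlarged old-group
ventricles, SNR 50):

```sh
python analysis/01_simulate_cohort.py     # writes results/cohort/
python analysis/02_fit_t1_maps.py         # writes results/t1maps/
python analysis/03_measure_rois.py        # writes results/measurements.csv
python analysis/04_group_statistics.py    # writes results/comparisons.csv
python analysis/05_b1_tolerance.py        # writes results/b1_sweep.csv
```

Output of the run above (seed 17):

```
mean CSF voxels  young: 244   old: 580   (ratio 2.38, radii scale 1.35)

       median_error_ms  mad_ms
old             -125.4    41.7
young           -122.4    39.7

old-group caudate mean shift if CSF removal is DISABLED: +37.7 ms

3 of 12 regions significant at alpha = 0.05 (pair Bonferroni)
 roi_id          name test_used  p_corrected  direction
      1 Hippocampus L    t_test 1.095570e-19 old_higher
      2 Hippocampus R    t_test 7.843300e-22 old_higher
      3     Caudate L    t_test 5.726616e-19 old_higher

tolerated |delta| <= 2% at a 5% excess-error bound (binding T1 = 500 ms)
```

Reading this: the ventricle voxel count grows by ≈ 1.35³ in the old group
as constructed; the ≈ −125 ms median fit error is the method's documented
approximation bias, not noise; skipping CSF removal inflates the
ventricle-adjacent caudate mean by ≈ +38 ms (the atrophy artifact the CSF
mask exists to prevent); exactly the three parcels given a true +150 ms
old-group shift come out significant, all with direction old_higher; and a
uniform flip-angle miscalibration of ±10% would add 16–20% T1 error, with
only ±2% tolerated at a 5% excess-error bound.

The same stages are available as a CLI —
`t1relax {simulate,fit,segment,roi,stats,b1sweep,run-all}` — e.g.

```sh
t1relax run-all --n-young 10 --n-old 10 --seed 17 --out results/run
```

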