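# lutidose

Contour-agreement metrics and single-time-point voxel dosimetry for
¹⁷⁷Lu-DOTATATE SPECT/CT, with a seeded synthetic phantom-cohort simulator
and cohort-level paired statistics.

In ¹⁷⁷Lu-DOTATATE peptide receptor radionuclide therapy, absorbed doses to
organs at risk (kidneys, liver, spleen) are computed from quantitative
SPECT/CT by delineating organs on CT, converting count rate to activity,
convolving with a voxel S-value kernel, and integrating the dose rate over
time. This package is for medical physicists and methods researchers who
want a tested, scriptable implementation of that chain — in particular to
study how contouring variability (e.g. between human observers and a
deep-learning segmentation) propagates into organ dose statistics, without
needing clinical images: a synthetic phantom cohort with controllable
contour noise, gross segmentation failures, organ absences and imaging
physics stands in for the patient data.

## What it computes

**Contour agreement** between a candidate mask and a reference mask on a
common voxel grid, with anisotropic spacing honoured in mm:

- Dice similarity coefficient `DSC(A,B) = 2|A∩B| / (|A|+|B|)` (voxel counts);
- Hausdorff distance `HD(A,B) = max(h(A,B), h(B,A))` with
  `h(A,B) = max_{a∈∂A} min_{b∈∂B} ‖a−b‖` over boundary voxel centers
  (exact, 100th percentile);
- mean distance to agreement (MDA): `h` with the maximum replaced by a
  mean, symmetrized by pooling both boundaries;
- tolerance flags (defaults DSC ≥ 0.800, HD ≤ 3.0 mm, MDA ≤ 3.0 mm) and
  criteria rates over a cohort.

**Voxel dosimetry** from one quantitative SPECT/CT time point:

- activity `A = C / ccf` from the count-rate map and the scanner
  cross-calibration factor (cps/MBq);
- optional CT-number → mass-density conversion (piecewise-linear table);
- dose rate `Ḋ = A ⊛ S` by 3-D convolution with a voxel S-value kernel;
- single-time-point dose `D = Ḋ(t) · 2t / ln 2` (Hänscheid), which assumes
  monoexponential washout and needs no per-patient effective half-life;
- organ `D_mean` / `D_max` / `D_min` over masks, and the closed-form bias
  ratio `r = (t/T) · 2^(1−t/T)` of the single-time-point estimate against
  the true monoexponential integral for an organ with effective half-life
  `T`.

**Cohort statistics**: median (IQR), exact / Monte-Carlo / normal-approx
two-sided Wilcoxon signed-rank tests, relative dose differences, and
report tables (accuracy, criteria rates, dose) assembled per organ and
method.

## Worked example

The closed-form single-time-point bias, for imaging at 24.49 h after
administration:

```python
from lutidose import TimingParams, underestimation_ratio

for organ, t_eff in (("kidneys", 51.0), ("liver", 67.0), ("spleen", 68.0)):
    r = underestimation_ratio(TimingParams(t_hours=24.49, t_eff_hours=t_eff))
    print(f"{organ}: r={r:.4f}  underestimation={100 * (1 - r):.1f}%")
```

prints

```
kidneys: r=0.6885  underestimation=31.2%
liver: r=0.5674  underestimation=43.3%
spleen: r=0.5612  underestimation=43.9%
```

i.e. imaging at roughly half the organ effective half-life makes the
`2t/ln 2` window miss ~31–44% of the true time-integrated dose — which is
why relative comparisons between contouring methods are still valid while
absolute doses from early imaging are biased low.

A small end-to-end cohort (3 synthetic cases on a 48³ demo grid):

```
lutidose run --n-cases 3 --seed 7 --out demo_out
```

writes per-case NIfTI images and masks, per-case metric/dose CSVs, report
tables and a hash manifest. For that seed, `report_dose.csv` contains, for
`d_mean` (Gy):

```
organ         method     n  median   q1    q3    p_vs_reference
liver         reference  3  3.66     3.43  3.88
liver         manual     3  3.67     3.44  3.89   0.50
liver         ai         3  3.66     3.43  3.93   1.00
kidney_right  reference  3  1.80     1.77  1.84
kidney_right  ai         3  1.80     1.77  1.84   1.00
```

Organ mean doses are a few Gy per cycle, manual-contour doses sit within a
fraction of a percent of the reference, and the paired Wilcoxon p-values
are large — contouring noise at realistic amplitudes barely moves
`D_mean`. The matching `report_accuracy.csv` shows median manual DSC
≈ 0.94–0.98 and AI DSC ≈ 1.0 with median MDA below 1 mm, while
`report_criteria_rates.csv` tabulates how many cases meet each tolerance.

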