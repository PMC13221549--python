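# Methods

This note documents the models, conventions and design choices behind
`lutidose`: what is computed, under which assumptions, and what the
synthetic phantom cohort does and does not emulate.

## Grids and conventions

All images live on a common 3-D lattice with per-axis spacing in mm, axis
order (slice, row, column). The world position of voxel (i, j, k) is its
center at (i·s₀, j·s₁, k·s₂) mm, so the origin is the center of voxel
(0,0,0). Grids carry an explicit physical-quantity tag (HU, cps, MBq,
Gy/s, Gy, g/cm³) and operations refuse tags that make no physical sense
(e.g. convolving a dose map with an S-value kernel). Mismatched grids are
an error everywhere; nothing is silently resampled. Masks serialize as
uint8 NIfTI with organ/source/absent labels in a JSON sidecar, because the
NIfTI header has no standard slot for them.

## Contour-agreement metrics

DSC is computed from voxel counts. HD and MDA operate on boundary point
sets: a boundary voxel is a mask voxel with at least one of its six
face-neighbours outside the mask, with out-of-lattice counting as outside,
and distances are Euclidean between voxel centers in mm. This voxel-native
reading of "points on the perimeter" is exact and directly checkable by a
brute-force all-pairs oracle, which the test suite runs on hundreds of
random anisotropic lattices; sub-voxel mesh surfaces are deliberately out
of scope. HD is the exact maximum, not a 95th-percentile variant.

"Replace the maximum by a mean" underdetermines MDA symmetrization. The
default pools all nearest-neighbour distances of both boundaries into one
mean (weighted by point counts); the mean-of-directed-means alternative is
available via `symmetrization="directed_mean"`. The two differ only when
the boundaries have very different point counts.

Nearest-neighbour distances are computed with a k-d tree over the boundary
point sets. This was chosen over distance transforms of the complement
because the tree query is exact for arbitrary anisotropic spacing and for
point sets (the Euclidean distance transform samples distances on one
lattice only); the brute-force oracle validates it to 1e-9 mm.

Comparisons where either mask is empty are undefined and raise, rather
than returning 0 or infinity; organs flagged *absent* (post-surgical
spleens) produce skipped records so cohort code must handle them
explicitly rather than accidentally averaging degenerate values.

## Dosimetry chain

Count rate → activity is a division by the scanner cross-calibration
factor (default 9.64 cps/MBq, a Symbia T6-class value). CT → density is
piecewise-linear interpolation through an ordered (HU, g/cm³) table that
must anchor water at (0, 1.0); values outside the table clamp to its ends.

Dose rate is the discrete 3-D convolution of the activity map with a
voxel S-value kernel whose spacing must match the grid exactly (kernel
resampling is out of scope). The lattice is zero-padded: tissue outside
the scanned volume contributes and receives nothing, a deliberate
approximation that also yields the exact bookkeeping identity
Σ(dose-rate) = Σ(activity) · Σ(kernel) for activity fully interior to the
grid, which the tests assert to 1e-12 relative. An optional mass
correction divides each voxel's dose rate by its density relative to
water; it defaults to off because vendor engines differ in whether and
how they apply it, and both behaviors are tested.

The single-time-point integral is D = Ḋ(t) · 2t/ln 2 voxel-wise, hours at
the interface, seconds internally (one stated 3600 constant). Under truly
monoexponential washout with effective half-life T, the ratio of this
estimate to the true time-integrated dose is

    r(x) = x · 2^(1−x),  x = t/T,

exact at x = 1, maximal near x = 1/ln 2 ≈ 1.443, and within 12% of unity
for x ∈ [0.75, 2.5]. The often-quoted 10% accuracy for that window comes
from empirical patient kinetics, which are not exactly monoexponential;
the closed form gives ≤ 12%, and the tests assert only the closed form.
Organ effective half-lives default to kidneys 51 h, liver 67 h, spleen
68 h — the values used by the single-time-point method this chain follows
— and are configuration, not hard-coded truth. At the 24.49 h default
imaging time these give underestimations of 31.2% / 43.3% / 43.9%.

The bundled synthetic kernel (`make_test_kernel`) carries a configurable
self-dose fraction at the center plus an exponential cross-dose tail
truncated at three range lengths, normalized to an exact total. The total
defaults to 7.5e-4 Gy/s per MBq at a 27 mm³ voxel, scaled inversely with
voxel volume since absorbed dose is energy per mass. With self-fraction 1
it degenerates to pure local deposition, for which every dose statistic
has a closed form — the basis of the analytic-recovery test. It is a
synthetic stand-in with controlled integral properties, not a Monte-Carlo
kernel; users with a published voxel S-value table can load it through
the documented JSON-header + CSV file dialect.

## Synthetic phantom cohort

The generator emulates the statistical structure of a ~23-patient
single-time-point cohort, not anatomy. Organs are ellipsoids (liver
optionally a union of two under hepatomegaly) on an 80³ grid at 3 mm
isotropic spacing — a typical reconstructed-SPECT-scale lattice, chosen
since the acquisition matrix alone does not fix a voxel size. Defaults,
with reasons:

- **Spleen absent with probability 6/23; hepatomegaly with probability
  4/23.** Organ absence is the real bookkeeping hazard of cohort code;
  hepatomegaly is the condition that drives gross AI failures.
- **Activity concentrations** liver 0.90, spleen 0.46, kidneys 1.00
  MBq/mL (lesions 2.5× liver, background 0.02), log-normally jittered
  (σ = 0.2) per case. After PSF spill-out these put reference D_mean
  medians near 4.2 / 1.5 / 2.2 Gy — the few-Gy-per-cycle range typical of
  this therapy — which is what the concentrations exist to set.
- **SPECT degradation = Gaussian blur + Poisson noise only**, since the
  simulated input stands for an already attenuation- and
  scatter-corrected reconstruction. PSF FWHM defaults to 15 mm (a
  post-reconstruction SPECT resolution; the ~4 mm figure often quoted is
  a post-filter, not total resolution). Poisson resampling of a rate map
  needs a counting time to be well-posed; `count_time_s` defaults to
  120 s, of the order of a SPECT acquisition, and sets the noise level.
- **Observer contours** come from warping the reference mask with a
  smooth random displacement field (white vector noise smoothed at 10 mm,
  rescaled to an RMS displacement magnitude σ). A displacement field was
  chosen over morphological operations so DSC/HD/MDA degrade continuously
  with σ. Manual σ = 1.8 mm and AI σ = 0.7 mm are illustrative magnitudes
  — no inter-observer displacement amplitudes are published for this
  setting — chosen so manual contours sit visibly below AI in DSC while
  both remain within tolerance, and with AI ≤ 1 mm so the dose-stability
  property (|ΔD_mean| < 2% for σ ≤ 1 mm) applies to it. Four manual
  observer sets and one AI set are generated per case.
- **Gross failures**: in hepatomegaly cases the AI liver mask is
  truncated by a random plane 45 mm deep (probability 0.8) and the AI
  spleen mask bleeds into the liver within 65 mm (probability 0.55),
  producing the rare HD > 30 mm outliers; which cases carry failures is
  recorded so tests can assert that large HD occurs *only* there.
- **Kidney reference masks exclude a cold renal-pelvis ellipsoid**, which
  is also cold in the activity map and darker in CT.

Determinism: every generator output is a pure function of (config, seed).
Per-case and per-observer seeds derive from the master seed by a
splitmix64-style hash (golden-ratio increment, two xor-multiply
finalization rounds, reduced mod 2³¹−1), stated so cohorts are portable.

What passing cohort tests do **not** show: the phantom has no real
anatomy, no attenuation/scatter residuals, no registration error, no
systematic inter-observer bias (the displacement field is zero-mean), and
its contour-noise magnitudes are assumptions. Cohort-level assertions are
therefore qualitative — median DSC within tolerance, monotone degradation
with σ, gross outliers only where injected, small D_mean shifts for small
σ — and the clinical tables' numerical medians are not reproduction
targets.

## Statistics

Quartiles use linear interpolation between order statistics (quantile q at
position (n−1)·q), stated because statistics packages differ. The Wilcoxon
signed-rank test discards zero differences, mid-ranks ties, and reports
twice the smaller tail capped at 1. Tie-free samples use an exact
dynamic-programming null; tied samples use 10⁵ seeded random sign flips
(the integer-lattice DP no longer applies); a normal approximation with
continuity and tie corrections is available. The exact path is verified
against full 2ⁿ enumeration for every n ≤ 12 and against an independent
reference implementation, and its null rejection rate at α = 0.05 is
checked by simulation at n = 23. No multiple-testing correction is
applied by default, matching the single-threshold p < 0.05 convention of
the workflow this mirrors.

For cohort tables, the several manual observers of one case collapse to
their per-case median before pairing, so every paired test compares one
value per patient per method. The ambiguous phrase "median relative
difference" is reported under both readings — relative difference of the
medians, and median of the per-case relative differences.

## Problem sizes

Default test-suite sizes: 200 random lattices ≤ 12³ for the metric
oracle, 2000 replicates for the Wilcoxon null, a 23-case cohort on the
default 80³ grid for the cohort checks, and 3-case 48³ demo runs for the
pipeline; the whole suite completes in well under a minute on one core.
These sizes were chosen as the smallest at which the checks are
statistically meaningful.

## Known limitations

Single grid only (no resampling or registration); zero-padding edge
approximation; no multi-time-point fitting, Monte-Carlo transport, BED or
EQD2; no tumor dosimetry beyond lesions being part of the whole-liver
mask; the U-net segmentation itself is emulated by mask perturbation, not
modeled.
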