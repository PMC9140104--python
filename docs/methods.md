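# Methods

This note documents the models, algorithms, and numerical choices in
`idifpet`, and what validation on the synthetic phantom does and does not
demonstrate.

## Generative model

All components share one generative picture of a dynamic brain PET scan.
Arterial whole-blood activity follows the Feng bolus model with delay `tau`
(min), amplitudes `A1` (activity/min), `A2`, `A3` (activity), and decay rates
`l1 > l2 > l3 >= 0` (1/min); the curve is defined as zero for `t <= tau` and
is continuous there. Tissue activity is the convolution of that input with
the two-tissue-compartment impulse response parameterized by `K1`
(mL·cm⁻³·min⁻¹) and `k2, k3, k4` (1/min), with eigen-rates `B1 <= B2` solving
`s² − (k2+k3+k4)s + k2·k4 = 0`. A voxel near the carotid artery measures the
convex mixture `alpha·C_AIF + (1−alpha)·C_TISSUE`, and a frame reports the
time-average of the underlying curve over its interval. Activities are
assumed decay-corrected upstream; nothing in the package handles decay.

Time is minutes internally; interfaces accept seconds for frame timing and
blood-sample tables. The total distribution volume of the reversible 2TC
model, `V_T = K1/k2·(1 + k3/k4)`, serves as the analytic ground truth
throughout.

## Carotid segmentation

Only slices between the bottom of the field of view and the slice below the
lowest cerebellum label are searched (the carotids run through the neck; the
cerebellum caps them superiorly). The early-intensity volume is the
duration-weighted mean of all frames fully inside the first 60 s — on the
default schedule, exactly the six 10-second frames. Design choices where the
procedure itself is underdetermined:

- The left/right split is at the midline column of the left–right axis
  (resolved from NIfTI orientation metadata, defaulting to
  first-axis = left→right); the midline column belongs to the left half.
- Ties in the argmax break to the lowest linear (C-order) index, for
  reproducibility.
- A half-slice that is identically zero yields no seed and is skipped.
- The 5×5 diamond (Manhattan radius 2) is fixed in voxel units regardless of
  voxel size, matching the procedure it implements; dilations from different
  seeds/slices are unioned without double counting.

The mask is invariant to positive rescaling of the image, and on the phantom
the mean true mixing fraction over masked voxels strictly exceeds the
image-wide mean.

## Model-based matrix factorization

Given the n×m voxel matrix `A`, the candidate component matrix `H` holds the
frame-averaged model AIF and tissue curves; `W` is solved row-wise by linear
least squares (no sign constraint by default; a nonnegative mode exists
behind a config flag), and the 11 parameters are optimized by multi-start
bound-constrained trust-region-reflective least squares.

**Frame weighting.** By default the residual is inverse-variance weighted
per frame, with weights `sqrt(duration / mean activity)` normalized to mean
one — the post-reconstruction PET noise model in which frame variance scales
with activity over duration. This matters: with an unweighted Frobenius
norm the factorization has a sloppy direction in which the slow tail of the
input trades against the tissue component at a residual cost below the noise
of the short early frames. On 5%-noise phantoms that direction produced
input-scale errors up to 2× and V_T errors of 30–40% on some noise
realizations; with the likelihood-consistent weighting the same realizations
give V_T errors of 0.5–10%. The unweighted objective remains available via
`MBMFConfig(frame_weighting="none")`.

**Identifiability.** `A1` and `K1` only scale their respective rows of `H`
and are absorbed by `W`, so the objective is flat along them; they are kept
in the parameter vector (bounded) and the degeneracy is removed by the final
normalization, which rescales both rows of `H` to unit frame-sum with `W`
adjusted so `W·H` is unchanged. Component labels are themselves symmetric in
a bilinear factorization; the arterial component is identified as the row
peaking earlier, asserted after every fit (a violated assertion raises a
convergence error rather than silently mislabeling).

**Parameterization and bounds.** The rate ordering `l1 > l2 > l3` is
enforced by optimizing `l3` plus positive gaps (`l2 = l3 + d2`,
`l1 = l2 + d1`). Bounds (scan time in minutes): `tau ∈ [0, 3]`,
`l3 ∈ [0.001, 0.5]`, gaps `d2 ∈ [0.04, 4.5]`, `d1 ∈ [0.5, 49]`,
`K1 ∈ (0, 2]`, `k2 ∈ [0.01, 2]`, `k3, k4 ∈ [0.001, 1]`; amplitude bounds are
wide since only amplitude ratios shape the curve. These are physiologic
ranges for bolus-injected lipophilic tracers.

**Starts and convergence.** Start 1 is data-driven: `tau` from the earliest
frame whose mask-mean activity exceeds 10% of the maximum frame mean,
mid-range values elsewhere. Remaining starts are a seeded Latin-hypercube
draw over narrower start ranges. Default 8 starts; the best residual wins.
In practice the data-driven start dominates, so the test-suite and
acceptance experiments use 2–4 starts. Convergence per start: relative
residual change below 1e-8 or the evaluation cap. Fits are deterministic
given the config seed.

## Scaling to physical units

Because true mixing fractions sum to one, the weight rows satisfy
`omega_AIF/S_A + omega_TISSUE/S_T = 1`, where `S_A`, `S_T` are the physical
frame-sums of the component curves. The estimator minimizes
`sum_i (omega_i,AIF·s_A + omega_i,TISSUE·s_T − 1)²`, which is linear least
squares and solved in closed form (a trust-region numerical path is retained
and tested for parity). Note the two published ways of writing this
objective — scales multiplying versus dividing the weights — are the same
linear problem in `s` and `1/s` respectively, so their solutions are exact
reciprocals; `ScalingFactors` carries a convention tag and `scale_idif`
always applies the multiplicative unit-restoring factor, so both conventions
yield the identical physical input function. The weight-multiplying form is
the package default.

With unit-sum-normalized components the physical scale is of the order of
the frame-summed activity (hundreds of kBq/mL·frames), so the pipeline
checks scales against a wide plausibility window and flags only sign
pathologies; the bare `optimize_scaling` defaults to a stricter `[0.01, 100]`
window for O(1)-scaled uses. Rank-deficient `W` (all voxels sharing one
mixing ratio) raises a non-identifiability error.

## Metabolite correction

The whole-blood IDIF is converted to metabolite-corrected plasma by the
population multiplier `1 − a(1 − e^(−b·t))`, `t` in minutes, with shipped
defaults `a = 0.29`, `b = 0.03`/min. The multiplier is 1 at injection,
decreases monotonically, and is bounded below by `1 − a`. Fitting from
cohort blood tables multiplies each subject's parent fraction by the
plasma-to-whole-blood ratio at the 5/15/30/60-minute assay times, averages
across subjects per time point, and fits (a, b) by bounded nonlinear least
squares; subjects missing an assay time are dropped with a warning. When
`a = 0` the rate `b` is unidentified (flat direction); the amplitude is then
pinned only to optimizer tolerance.

## Quantification

Logan analysis regresses `∫₀ᵗ C_tis / C_tis(t)` on `∫₀ᵗ C_inp / C_tis(t)`
over frames whose midpoints reach `t* = 30` min (six frames on the default
schedule); the slope is V_T. Running integrals are trapezoid with a leading
triangle from (0, 0) to the first sample; the input integral uses the input
function's own (finer) grid where available. The reference-region variant
replaces the blood integral with the reference TAC integral and is reported
without a k2′ correction term. The slope is invariant to joint positive
rescaling of tissue and input, and the reference slope never sees the input
at all.

Logan's linearization is exact only past the slowest transient `1/B1`; with
binding-level kinetics (`B1 ≈ 0.026`/min) a 30–60-minute window
underestimates V_T by ~6% — visible in both the phantom and the oracle
tests, which therefore use longer noise-free acquisitions (120–150 min)
when validating convergence to the analytic value to 2–3%. On the standard
60-minute window this equilibration bias is part of the measured V_T error
budget, affecting IDIF- and blood-input analyses alike.

SUV is the duration-weighted mean activity over frames with midpoints in
40–60 min, divided by injected dose per body weight (kBq/g at unit tissue
density). The group comparison is an unpaired two-sample t-test (pooled
variance by default, Welch by flag) plus the percent difference of group
means; two degenerate zero-variance groups with equal means return p = 1.

## The phantom

Geometry: a 48×48×40 grid at 2 mm isotropic voxels. Two parallel carotid
tubes (radius 2 voxels) run through the inferior 16 slices, one per side;
the cerebellum is a slab directly above; eight further regions tile the
superior volume in 2×2×2 blocks. The mixing fraction across a tube is a
radial Gaussian clipped to the tube (1 on the axis, `e^(−2) ≈ 0.14` at the
wall, 0 outside), emulating partial-volume blur of a vessel against a single
surrounding-tissue background.

Kinetic presets: all regions share `K1 = 0.15`, `k2 = 0.15`, `k4 = 0.04`,
with `k3` set per region to hit distribution volumes of 1.9–3.5 in the
high-affinity ("HAB-like") preset; the mixed-affinity ("MAB-like") preset
divides every regional V_T by 1.35 through `k3` alone, so binding class
changes the bound-pool rate and nothing else — in particular both presets
share the identical arterial input. Between-subject variation for cohort
studies applies seeded lognormal jitter (default CV 8%) to `K1` and `k3`.

Noise is seeded Gaussian with standard deviation proportional to
`sqrt(activity / frame duration)`, calibrated so `noise_cv` (default 5%) is
the coefficient of variation at the image peak; negative values are clipped
at zero. Blood samples are point draws of the true input at the standard
draw schedule (end-of-interval: every 6 s for one minute, every 10 s for the
next, per-minute to 5 min, then every 5 min — 30 samples over 60 min);
plasma ratio and parent fraction are generated as equal square-root shares
of the composite-fraction model so their product reproduces it exactly.

What the phantom does **not** emulate: scanner point-spread blurring beyond
the alpha profile, scatter and randoms, motion, attenuation artifacts,
anatomical realism, venous structures near the carotids, subject-specific
input-function shapes, or plasma kinetics distinct from whole blood during
the scan. Passing phantom tests therefore demonstrates correctness of the
algorithmic chain and its noise robustness under the stated model — not
clinical accuracy on scanner data.

## Validation experiment sizes

The packaged experiments (test suite and `scripts/acceptance.py`) use: three
5%-noise subjects for input-recovery and nine-region V_T accuracy, pooling
errors across subjects × regions the way a small validation cohort would —
a single subject's mean error has a spread of several percent driven by how
the noise realization projects onto the weakly identified input-scale
direction, so pooling is the meaningful summary; and eight subjects per
binding-affinity arm for the group comparison, where the built-in ~35% V_T
contrast is detected at p < 0.05 while the reference-region analogue shows
only a small contrast (both target and reference scale together and cancel
in the ratio). Factorizations in these experiments run with 2–4 starts as
noted above.

## Numerical choices

- Fine grid 0.1 s (1/600 min) over the scan for model evaluation;
  convolution by FFT with trapezoid end-point correction; frame averages by
  cumulative trapezoid with linear interpolation at frame edges.
- Repeated eigen-rate roots (`|B2 − B1| < 1e-9`) use the analytic limit
  `K1·e^(−Bt)(1 + (k3+k4−B)t)` rather than perturbation.
- Trapezoid quadrature converges at O(dt²) except at the bolus-onset kink
  `t = tau`, where accuracy is judged relative to the curve peak.
- Frame-window membership everywhere is by frame midpoint; the Logan and
  SUV windows include midpoints equal to the bound within 1e-9.
- `k4 = 0` with `k3 > 0` (irreversible trapping) has no finite V_T and is
  rejected; `k3 = 0` returns `K1/k2` regardless of `k4`.

## Known limitations

- The carotid segmentation is intensity-argmax only; veins or injection
  artifacts brighter than the carotids would capture seeds.
- The input-function scale is the method's weakest estimate (the
  weight-sum-to-one constraint is the only anchor); its variance dominates
  the V_T error budget.
- Population metabolite correction cannot reflect individual metabolism;
  errors there propagate multiplicatively into plasma-referenced V_T.
- The 60-minute Logan window carries a systematic few-percent equilibration
  underestimate for slowly equilibrating regions.
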