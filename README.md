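# idifpet

Noninvasive image-derived input functions (IDIF) for dynamic brain PET
quantification.

Kinetic quantification of reversible PET tracers — here modeled on
¹⁸F-DPA-714 imaging of the 18-kDa translocator protein (TSPO), a marker of
microglial activation — classically requires an arterial input function (AIF)
measured by arterial blood sampling. Catheterization is invasive and slow,
and for TSPO tracers the usual escape hatch, reference-region modeling,
is unreliable because no brain region is free of specific binding. `idifpet`
implements the third option: estimate the input function directly from the
carotid-artery signal in the dynamic images themselves, and use it to compute
the total distribution volume V_T by Logan graphical analysis.

The package is aimed at PET methods researchers: it includes the full
extraction pipeline, a Logan/SUV quantification layer, the population
metabolite correction, and a synthetic dynamic-PET phantom with exact ground
truth for validating every stage.

## Method

A carotid voxel is a partial-volume mixture of arterial blood and
surrounding tissue:

    C_i(t) = α_i · C_AIF(t) + (1 − α_i) · C_TISSUE(t)

Extraction runs in three automatic steps:

1. **Carotid segmentation.** On every axial slice below the cerebellum, the
   brightest voxel of the first-minute frames is found on each patient side
   and dilated with a 5×5 diamond (≈ 6 mm carotid caliber).
2. **Model-based matrix factorization (MBMF).** The n×m matrix A of
   segmented-voxel time courses is factorized as A ≈ W·H, where the two rows
   of H are not free curves but *model outputs*: the Feng bolus model

       C_AIF(t) = (A₁(t−τ) − A₂ − A₃)e^(−λ₁(t−τ)) + A₂e^(−λ₂(t−τ)) + A₃e^(−λ₃(t−τ))

   and the two-tissue-compartment (2TC) curve it drives,
   C_TISSUE = C_AIF ⊗ h(t; K₁, k₂, k₃, k₄). For each candidate of the
   11-parameter set Φ = {τ, A₁, A₂, A₃, λ₁, λ₂, λ₃, K₁, k₂, k₃, k₄}, W is the
   exact least-squares solution; the outer problem Φ̂ = argmin ‖WH − A‖²
   (inverse-variance frame-weighted by default) is solved by multi-start
   trust-region-reflective least squares. H rows are reported normalized to
   unit frame-sum.
3. **Scaling.** Since the true mixing fractions satisfy α + (1−α) = 1, the
   scales (s_AIF, s_TISSUE) minimizing Σᵢ (ω_i,AIF·s_AIF + ω_i,TISSUE·s_TISSUE − 1)²
   restore the normalized arterial component to whole-blood activity units
   (closed-form linear least squares).

A population metabolite model converts whole blood to metabolite-corrected
plasma, multiplying by 1 − 0.29(1 − e^(−0.03 t)) (t in minutes; constants
refittable from cohort blood tables). Quantification is Logan graphical
analysis over the 30–60-minute window (slope = V_T), a reference-region
Logan variant, and SUV over 40–60 minutes.

## Worked example

```python
import idifpet as ip

# a 5%-noise synthetic subject with known kinetics
truth = ip.default_truth("HAB-like", seed=7, noise_cv=0.05)
image, labels, truth = ip.simulate_phantom(truth)

ext = ip.extract_idif(image, labels, ip.MBMFConfig(n_starts=4, seed=0))
print(ext.factorization.summary())

for region in ("putamen", "thalamus", "cerebellum"):
    tac = ip.extract_tac(image, labels, region)
    vt = ip.logan_vt(tac, ext.whole_blood).vt
    suv = ip.compute_suv(tac, truth.dose_MBq, truth.weight_kg)
    err = ip.percent_error(vt, truth.true_vt(region))
    print(f"{region:<12} VT_IDIF = {vt:.2f}  (true {truth.true_vt(region):.2f}, "
          f"error {err:+.1f}%)   SUV = {suv:.2f}")
```

prints

```
Model-based matrix factorization
================================
voxels (n):            416
frames (m):            36
starts used:           4
converged:             True
residual ||WH-A||^2:   11967.8
relative residual:     7.694e-02

Arterial input (Feng) parameters
  tau = 0.4998 min
  A1 = 19.74, A2 = 0.3776, A3 = 0.2901
  l1 = 3.983, l2 = 0.4637, l3 = 0.009503 (1/min)

Surrounding-tissue (2TC) parameters
  K1 = 1.682 mL/cm^3/min, k2 = 0.2754, k3 = 0.01961, k4 = 0.0424 (1/min)

putamen      VT_IDIF = 2.45  (true 2.44, error +0.5%)   SUV = 4.81
thalamus     VT_IDIF = 2.98  (true 2.97, error +0.3%)   SUV = 5.64
cerebellum   VT_IDIF = 3.17  (true 3.16, error +0.3%)   SUV = 5.91
```

The factorization recovers the injection delay (τ ≈ 0.5 min) and decay rates
of the generating input; A₁ and K₁ are pure component scales absorbed by W,
so only their shape-relevant ratios are meaningful. V_T here is computed
against the whole-blood IDIF to compare with the phantom's analytic
K₁/k₂·(1 + k₃/k₄) truth; `ext.plasma` holds the metabolite-corrected plasma
input used for patient-style analyses.

A CLI wraps the same pipeline for on-disk data
(`idif simulate`, `idif extract`, `idif quantify`, `idif all`); inputs are 4D
NIfTI volumes plus a two-column frame-timing TSV, a co-registered integer
label map, and optional blood-sample TSV tables.

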