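# dcenms

Dual-gradient-echo DCE-MRI pharmacokinetics: ΔR1 estimation, nested model
selection, and knowledge-based shallow-ANN adaptive models.

## The problem

Dynamic contrast-enhanced (DCE) MRI tracks a gadolinium bolus through tissue
to quantify microvasculature: the plasma volume fraction `v_p`, the forward
volumetric transfer constant `Ktrans` (min⁻¹), and the extravascular
extracellular fraction `v_e = Ktrans / k_ep`. In brain tumor studies with a
dual-gradient-echo (DGE) spoiled-gradient-echo sequence, two echoes per
excitation allow the longitudinal relaxation change ΔR1(t) — the
concentration surrogate — to be separated from confounding T2\* effects.

This package implements that full analysis chain for small-animal protocols
(128×64 matrix, 3 slices, 400 frames at ~1.55 s, bolus at frame 15, TR/TE1/TE2
= 24/2/4 ms, 18° flip angle), plus a digital phantom generator so every stage
can be validated against known ground truth:

1. **`dge_signal`** — forward SPGR signal model and its exact inversion.
   The per-frame combination `F^(μ/(μ−1)) / S^(1/(μ−1))` of the two echoes
   (μ = TE2/TE1) cancels T2\* identically; window sums over a pre-injection
   window (frames m..n) and a late saturation window (o..p, equal length),
   together with the externally measured T1 factors `E^pre = e^(−TR/T1pre)`
   and `E^post`, determine the local tip angle and then ΔR1(t) per frame.
   The ΔR1 estimate needs only `E^pre`, is invariant under global rescaling
   of both echoes, and cancels arbitrary shared T2\* dynamics at μ = 2.
2. **`pk_models` / `aif`** — three physiologically nested tissue models
   driven by a plasma input `C_p = C_AIF / (1 − Hct)`:

       model 1:  C_t = v_p C_p                                   (no leakage)
       model 2:  C_t = v_p C_p + Ktrans ∫ C_p dλ                 (Patlak)
       model 3:  C_t = v_p C_p + Ktrans ∫ C_p e^{−k_ep(t−λ)} dλ  (extended)

   The population AIF shape is normalized to the ΔR1 trace of a normal
   reference ROI (caudate putamen) under the assumption `v_p(ref) = 1%`,
   an exact closed-form projection because model 1 is linear in `v_p`.
3. **`nms_engine`** — voxel-wise fitting of all three models and sequential
   F-tests at 95% confidence select the deepest justified model; parameter
   maps are masked by estimability (no `Ktrans` in model-1 voxels, no `v_e`
   outside model 3).
4. **`features` / `adaptive_models`** — each voxel's raw dual-echo signals
   are reduced to 190 normalized features (tail-normalized, first 20 frames
   dropped, down-sampled ×4), and four single-hidden-layer perceptrons
   trained by Levenberg–Marquardt regress the model label and the three
   parameters directly from those features — no AIF needed at prediction
   time. Class-separation thresholds on the label-net response are
   optimized with a per-class misclassification tolerance, and everything
   is validated by study-level tenfold nested cross-validation.
5. **`phantom`** — forward-simulated dual-echo rat-brain studies (normal
   tissue / leaking rim / leaking core with back-flux) with complete stored
   ground truth and configurable signal SNR.

## Worked example

```python
import numpy as np
from dcenms import (PhantomSpec, make_phantom_study, estimate_study_delta_r1,
                    run_nms_maps)

study = make_phantom_study(PhantomSpec.small(snr=20.0), seed=7)
dr1, theta, flags, _ = estimate_study_delta_r1(
    study.study, roi_pooled_theta=True, clamp=True)
maps = run_nms_maps(dr1, study.truth.aif, study.study.mask)

m = study.study.mask
print(f"brain voxels: {int(m.sum())}")
print(f"estimated tip angle: {np.degrees(np.nanmedian(theta[m])):.2f} deg "
      f"(nominal 18.00)")
for label in (1, 2, 3):
    print(f"model {label} voxels: {int(np.sum(maps.model_map[m] == label))}")
sel = np.isfinite(maps.vp) & (study.truth.label_map == 1) & m
print(f"normal-tissue vp: median {np.median(maps.vp[sel]):.4f} "
      f"(true median {np.median(study.truth.vp[sel]):.4f})")
```

prints

```
brain voxels: 340
estimated tip angle: 17.47 deg (nominal 18.00)
model 1 voxels: 47
model 2 voxels: 215
model 3 voxels: 78
normal-tissue vp: median 0.0296 (true median 0.0281)
```

The tip angle is recovered from the signals alone to within ~0.5° at this
noise level; the fitted normal-tissue plasma volume tracks the generating
value. At SNR 20 the F-test escalates a substantial share of no-leakage
voxels (noise masquerading as leakage) — exactly the instability of
conventional nested model selection that the adaptive models are designed
to smooth out; with noise off the label map reproduces the truth exactly.

A command-line interface covers the same pipeline:

```bash
dcenms simulate --out cohort --n 10 --seed 7 --small
dcenms estimate-dr1 --study cohort/study-000 --out maps
dcenms fit-nms --dr1 maps/dr1.nii --aif cohort/study-000/aif_truth.csv \
       --mask cohort/study-000/mask.nii --out nms
dcenms featurize --study cohort/study-000 --out features.csv
dcenms train-ams --cohort cohort --out bundle.json --seed 7
dcenms predict --bundle bundle.json --study cohort/study-000 --out pred
```

`predict` maps labels and parameters from raw signals only — no AIF input.

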