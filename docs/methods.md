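# Methods

## Signal model and the ΔR1 estimator

Each echo of the dual-gradient-echo (DGE) spoiled-gradient-echo sequence is
modeled in steady state as

    F(t) = M0 sinθ (1 − E(t)) e^{−TE1/T2*(t)} / (1 − cosθ E(t)),
    S(t) = M0 sinθ (1 − E(t)) e^{−TE2/T2*(t)} / (1 − cosθ E(t)),
    E(t) = e^{−TR/T1(t)},   μ = TE2/TE1.

The combination `h(t) = F^{μ/(μ−1)} / S^{1/(μ−1)}` removes the transverse
factor exactly for any μ > 1, because the echo-time exponents cancel:
`h(t) = M0 sinθ (1 − E)/(1 − cosθ E)`. All estimation proceeds through h.

**Tip angle.** With two equal-length signal windows — pre-injection frames
m..n and a late "saturation" window o..p (p − o = n − m, p the last frame) —
and the independently measured T1 factors `E^pre`, `E^post` (pre/post
contrast T1 mapping), form the window statistics
`H = (ΣF)^{μ/(μ−1)} / (ΣS)^{1/(μ−1)}` for each window. Solving the two
steady-state h-equations for cosθ gives

    W    = (H_pre / H_sat) · (1 − E^post) / (1 − E^pre),
    cosθ = (1 − W) / (E^post − E^pre·W).

This is an exact inversion of the signal model: on noise-free
forward-simulated voxels it recovers θ to machine precision. A voxel with no
enhancement (H_sat = H_pre and E^post = E^pre) makes the expression 0/0 —
such voxels carry no angle information and are flagged degenerate rather
than silently clamped (clamping is available as an option).

**ΔR1 per frame.** With `x(t) = (n−m+1)·(ΣS^pre)^{1/(μ−1)}/(ΣF^pre)^{μ/(μ−1)}·h(t)`
(= h(t)/h_pre written with the window sums),

    E(t)   = [(1 − cosθ E^pre) − x(t)(1 − E^pre)] /
             [(1 − cosθ E^pre) − cosθ x(t)(1 − E^pre)],
    ΔR1(t) = −(1/TR)·ln(E(t)/E^pre).

Only `E^pre` enters; the post-contrast factor affects the tip-angle estimate
alone. The estimate is invariant under global rescaling of both echoes (M0
cancels) and under any shared T2\* dynamics, with the qualification that the
*window sums* cancel T2\* only when it is steady within each window — the
per-frame cancellation is unconditional. At baseline frames x = 1 and
ΔR1 = 0 identically.

The estimator assumes the saturation window sits at a steady state. With a
physiological washout the late tail still drifts by ~1–2% across the
window, which leaves a second-order residual: on noise-free pharmacokinetic
phantoms θ is recovered to ~1e−7 rad and ΔR1 to ~1e−6 s⁻¹ — far below any
measurement noise, and exactly zero when the programmed dynamics truly
plateau.

**Tip-angle pooling.** Per-voxel angle estimation needs strong enhancement;
in weakly enhancing voxels the arccos argument is noise-dominated. The
study-level driver therefore offers ROI pooling: the median of strictly
valid per-voxel estimates over voxels with >5% signal change. Summing the
raw signals across voxels before inversion was rejected — a sum of SPGR
signals from heterogeneous voxels is not an SPGR signal, and that pooling
is measurably biased even at negligible noise.

## Tissue models and the AIF

The three nested models (no leakage / Patlak / extended Patlak) are linear
in `v_p` and `Ktrans` and nonlinear only in `k_ep`. The exponential-kernel
convolution is discretized by a recursive exact-exponential scheme that
treats the input as piecewise linear between frames: unconditionally
stable, O(n), exact for piecewise-linear inputs, and reducing to the
cumulative trapezoid at `k_ep = 0`. Against high-resolution quadrature the
relative error at the 1.55 s study sampling is <1e−7. Units are SI seconds
internally; `Ktrans`/`k_ep` are exposed in min⁻¹ and converted at the API
boundary. Hematocrit enters once, as the plasma conversion
`C_p = C_AIF/(1 − Hct)` with default Hct = 0.45 (configurable). ΔR1 is used
directly as the concentration surrogate; the unknown relaxivity multiplies
both tissue and AIF and cancels from every fitted parameter.

The population AIF shape is a gamma-variate first pass (α = 2, β = 2 s,
peak ~4 s after arrival) on a biexponential washout (70%/30% split, rates
0.01 and 0.0011 s⁻¹ — distribution half-life ≈ 70 s, elimination ≈ 10 min,
emulating small-animal gadolinium kinetics; the measured group trace it
stands in for is not public, so every quantitative contract here is
shape-agnostic). Reference normalization is the closed-form projection
`scale = (1 − Hct)·⟨ref, shape⟩ / (v_p^ref·⟨shape, shape⟩)` so that a
no-leakage fit of the reference ROI returns exactly `v_p^ref` (default 1%).
Dispersion uses a normalized exponential transit kernel; because the finite
grid truncates the dispersed tail, the output is rescaled to preserve the
discrete zeroth moment exactly (a uniform factor ≲0.5% that leaves shape,
peak ordering and delay properties intact).

## Nested model selection

Models 1–2 are solved by exact linear least squares; model 3 profiles
`k_ep` on a log grid (including 0, which enforces rss1 ≥ rss2 ≥ rss3) with
bounded scalar refinement; a seeded multi-start Nelder–Mead path serves as
a cross-check. Sequential F-tests (2 vs 1 with F(1, n−2), then 3 vs 2 with
F(1, n−3)) at α = 0.05 select the deepest accepted model.

Two deliberate statistical choices:

* **Unconstrained selection fits.** The classical nested-F null requires
  the extra parameter to be free in sign; constraining `Ktrans ≥ 0` halves
  the test size from 5% to 2.5%. Out-of-range estimates are flagged, never
  clipped; box-constrained refitting is available separately. A null
  simulation (10,000 voxels) confirms the 5% escalation rate.
* **A machine-round-off rss floor** (1e−24·Σy²) declares numerically
  perfect nested fits equal, so noise-free voxels do not escalate on ratios
  of round-off residuals.

### Recovery at finite SNR

Phantom noise is Gaussian on each echo with σ = (mean baseline first-echo
signal)/SNR, default SNR 20. Noise propagates through the log-inversion with
a large gain: per frame, δΔR1 ≈ (1/TR)·√(4(σ/F)² + (σ/S)²)·(sensitivity)
≈ 0.1 s⁻¹ at SNR 20 — and the pre-window sums give each voxel a coherent
≈3.5% gain error that a longer time series cannot average away. The
consequence, measured on phantoms: median parameter errors of ≈15% (v_p),
≈20% (Ktrans) and ≈30% (v_e) at SNR 20, falling to a few percent by SNR 200,
and voxel-wise label agreement of ≈50% at SNR 20 (noise masquerading as
leakage — the familiar instability of F-test model selection at modest SNR,
and the motivation for the adaptive models). The fitting engine itself is
near-optimal: with white concentration-domain noise of matched magnitude it
recovers all parameters to 3–5% and 96% label agreement.

## Features and adaptive models

Features: the last 10 first-echo frames (391..400) are averaged into a
single normalization factor shared by both echoes (preserving the echo
ratio); the first 20 frames are dropped; both echoes are sampled on the
frame ladder 21, 25, …, 397 (95 frames each) — 190 features per voxel. The
grid is parameterized for scaled-down studies; the defaults lock to the
400-frame protocol.

The four networks are single-hidden-layer perceptrons (tanh hidden units,
linear output) trained by batch Levenberg–Marquardt: damped Gauss–Newton on
the full Jacobian, multiplicative damping (×10 / ×0.1), accepted steps never
increasing the batch MSE, and a sample-space dual solve (JJᵀ + μI, N×N)
when samples < parameters. Initialization is seeded Gaussian with the output
bias at the target mean; training is deterministic given the seed.

The label net regresses the class labels {1, 2, 3} with a single continuous
output — which is what makes response thresholds near 1.5–2.5 meaningful.
Thresholds per class pair are chosen by exhaustive scan over midpoints of
the sorted unique responses, maximizing balanced correct classification
subject to a per-class misclassification tolerance (default 5%); when
infeasible, the minimax-error cut is returned and flagged. Classification
is right-closed: label 1 below θ12, label 3 at/above θ23, else label 2.
The parameter nets train on the strata where their parameter is estimable,
stratified by the label net's own predictions by default (truth-label
stratification is available). Training truth comes from the conventional
nested-model-selection results, as in the pipeline this package models.

Validation is a study-level tenfold nested cross-validation: disjoint outer
test folds covering the cohort; an inner random-permutation-sampled k-fold
loop on the remaining studies tunes the hidden size (one for the label net,
one shared by the parameter nets, proxied by the Ktrans regression) and the
stopping epoch — the first epoch whose smoothed validation-metric curve
reaches 90% of its plateau (the within-10%-of-plateau reading of the
stopping rule; the 10%-of-plateau-value reading is exposed as an option).
Metrics: rank-based (Mann–Whitney) ROC AUC for class separations, Pearson r
and adjusted R² (p = 1: prediction vs truth is a single-predictor relation)
for the regressions, and the correct classification fraction. The fold unit
is the study, not the voxel — voxel-level splits would leak within-study
structure, and a deliberate-leak mode exists purely as a test detector.

## The phantom

Geometry: an elliptical brain (model-1 normal tissue) with a circular tumor
rim (model 2) and core (model 3), plus a small reference ROI at exactly
`v_p = 1%` inside normal tissue. Parameter draws per voxel:
`v_p ∈ [0.005, 0.05]`, `Ktrans ∈ [0.005, 0.05]` min⁻¹ (labels ≥ 2),
`k_ep ∈ [0.05, 0.5]` min⁻¹ (label 3); baseline T1 ∈ [1.3, 1.9] s,
T2\* ∈ [0.03, 0.05] s, M0 ∈ [800, 1200], per-voxel tip angle 18° ± 5% (a
smooth-B1 stand-in). The blood ΔR1 peak is 12 s⁻¹ — a 0.25 mmol/kg
hand-push gadolinium bolus reaches roughly 3–4 mM in first pass at
r1 ≈ 3.3 s⁻¹mM⁻¹. T2\* dynamics are vascular-weighted,
ΔR2\* = 20·v_p·C_AIF(t) (factor 0 disables them), chosen to exercise the
μ = 2 cancellation. Noise is signal-domain (where the pipeline's first
stage operates), Gaussian by default with a Rician option. Every
intermediate (labels, parameters, ΔR1(t), θ, T1/T2\*/M0, E^pre/E^post, the
AIF) is stored as truth.

What the phantom does *not* emulate: partial-volume mixing at region
boundaries, motion and inflow artifacts, spatially correlated noise, B0/B1
field structure beyond the per-voxel angle jitter, water-exchange effects,
and the "tapering" model misspecification of real tissue. Passing tests on
the phantom therefore demonstrate correctness of the estimators and the
training/validation machinery under the stated physics — not performance
on real animals.

## Problem sizes

The emulated cohort (66 animals, 128×64×3 voxels) is represented at desk
scale: unit tests use a 32×16×1 grid (~340 brain voxels); the nested-CV
evaluation uses 20 studies on a 48×24×1 grid (~770 brain voxels each),
hidden-size grid {3, 6}, 2-fold × 1-repeat inner loop, 25-epoch cap and 150
training voxels per study — sizes chosen so a full from-scratch re-run of
every stage completes in minutes on one core. Library defaults keep the
full-scale values (128×64×3 grid, hidden grid {5, 7, 10, 15}, 5-fold × 3
repeat inner loop). With ~1,400 usable training voxels per study stratum at
most, the shallow networks sit close to their parameter count; the
inner-loop early stopping is what controls overfitting at this scale.

## Known limitations

* The tip-angle/ΔR1 estimator requires the saturation window near steady
  state; rapidly evolving late kinetics bias θ at second order in the drift.
* Per-voxel tip angles are unreliable in weakly enhancing voxels at
  realistic noise; the pooled-median mode trades the B1 map for robustness.
* At signal SNR 20 the conventional F-test label map is noise-dominated in
  the model-1/model-2 boundary sense; parameter medians carry a ≈12–15%
  noise floor from the estimator's window normalization (see "Recovery at
  finite SNR"). These are properties of the analysis chain being modeled,
  reproduced faithfully rather than suppressed.
* `v_e` requires `k_ep` identification within a 10-minute acquisition; at
  the slow end of the `k_ep` range the washout time constant exceeds the
  experiment duration and `v_e` estimates degrade accordingly.
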