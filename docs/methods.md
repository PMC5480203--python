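# Methods

## Excitation physics

The package models a 1–1 binomial excitation: two RF pulses of flip angle α
about the same transverse axis, separated by a bipolar gradient pair. A spin
with through-plane velocity v accrues the interpulse phase φ = γ m₁ v, where
m₁ = ∫ G(t) t dt is the gradient first moment evaluated with t = 0 at the
first RF pulse center. Setting γ m₁ v_enc = π defines the encoding velocity.

Two descriptions of the resulting excitation coexist and both are exposed:

* **Closed-form relative profiles** s(v) = |sin((v_enc − v)/v_enc · π/2)| and
  M_z(v) = |cos(·)|, normalized to conventional single-pulse excitation.
  They satisfy s² + M_z² = 1 exactly and are the forms used for profile
  bounds and for the preserved-magnetization integral.
* **Exact rotation composition** R_x(α)·R_z(φ)·R_x(α) applied to equilibrium
  (`bloch_binomial`, with vectorized closed forms `binomial_transverse` /
  `binomial_longitudinal`). At α = 30° per pulse the normalized exact
  transverse magnitude deviates from s(v) by up to ≈ 7 % at intermediate
  phases; the endpoints (φ = 0: sin 2α; φ = π: 0) are exact for any α.

Note an intentional asymmetry of the relative forms: M_z(v=0) = 0 although a
finite-angle 2×30° in-phase pair actually leaves cos 60° = 0.5 longitudinal.
The relative form quantifies the *tip-back* fraction, not absolute
longitudinal magnetization; absolute values come from the rotation treatment.
The dynamic phantom uses the exact rotation forms per pixel.

The expected preserved magnetization over a Gaussian velocity distribution
is computed by Gauss–Hermite quadrature (default 128 nodes; ≥ 64 nodes keeps
the error below 1e−6 because the |cos| kinks lie ≈ 5 σ from the LV mean).

## Bipolar gradient design

Lobes are trapezoids ramping at maximum slew. If the target moment
|m₁| = π/(γ v_enc) is reachable below the amplitude limit, lobes are
triangular with G = (m₁ S²/2)^(1/3); otherwise the amplitude saturates and
the plateau solves G(p + r)(p + 2r) = m₁. This yields the minimum-duration
pair; ties cannot arise because duration is strictly monotone in the free
parameter. The analytic moment (−area·shift) is exact; `first_moment`
integrates any sampled waveform trapezoidally for cross-checks.

Echo time is modeled as TE = TE_base + gap/2, the gap being the bipolar-pair
duration plus a fixed RF/slice-select overhead (default 3.1 ms, chosen so
the designed gaps reproduce the 6.8 ms (v_enc 50 cm/s) to 8.4 ms (25 cm/s)
range of a 30 mT/m, 200 T/m/s clinical system). TE is therefore
non-increasing in v_enc. Gyromagnetic ratios: γ(¹³C) = 67.2828×10⁶,
γ(¹H) = 267.522×10⁶ rad/s/T.

## Digital cardiac phantom

Geometry: a mid-ventricular short-axis slice on a 38×38 matrix at 3 mm
pixels (110 mm-class FOV): circular LV cavity (r = 12 mm), myocardial
annulus (12–21 mm) split into six 60° sectors counterclockwise from the
anterior RV insertion (140°), and an RV crescent from an offset circle.

Velocities: pixelwise Gaussian draws per compartment at the trigger phase —
LV 33.4 ± 6.2 cm/s (early systole) or −42 cm/s class filling velocities
(early diastole), myocardium −0.82 ± 5.2 cm/s, RV 25 ± 8 cm/s (the RV
distribution is not constrained by measurement and is a documented free
parameter). LV velocities taper linearly to zero over the outer 8 % of the
cavity radius, emulating slow trabecular flow; this is what leaves residual
LV rim signal in velocity-selective images.

Bolus kinetics: the arterial input is a peak-normalized gamma-variate
a t^b e^(−t/c) with b = 3, c = 0.5 s, arriving 1.0 s after the first frame
(imaging starts seven heartbeats after injection; the RV bolus leads the LV
bolus by 2.5 s and is largely cleared). Myocardial uptake is a
one-compartment model, inflow MBF·AIF (MBF 4.0 mL/g/min per sector,
dobutamine-stress range) and washout rate MBF/λ with λ = 0.95 mL/g, with a
0.3 s coronary transit delay. With these frozen defaults the pure-kinetics
myocardial peak lags the LV peak by 2.8 s, in the physiologically expected
2–3 s window. An optional defect scales one sector's MBF (default ×0.3),
emulating a septal infarct.

Signal model, per pixel and frame:

    signal = concentration · polarization · exp(−t/T1) · depletion
             · amplitude(v) · exp(−TE/T2*)

with polarization 0.29 at injection, T1 = 34 s (urea in blood), T2* = 25 ms.
`amplitude(v)` is sin 60° in conventional mode and the exact binomial
transverse magnitude at φ = π v/v_enc in velocity-selective mode. Blood is
fully replaced in-slice every beat at stress velocities and accumulates no
RF depletion; myocardial tissue accumulates it *inside* the uptake
recursion — each frame the surviving tissue magnetization is multiplied by
the per-pixel longitudinal retention (cos 60° conventional; binomial M_z(φ)
velocity-selective) while newly delivered magnetization enters undepleted.
Applying depletion multiplicatively to the concentration curve itself would
wrongly deplete magnetization that had not yet arrived and destroy the
observed 2–3 s tissue peak lag.

The arterial magnetization feeding the myocardium additionally carries a
per-mode transfer factor for its one upstream in-slice excitation during LV
transit: cos 60° = 0.5 conventionally versus the mean preserved M_z over the
LV velocity distribution (≈ 0.956) for velocity-selective encoding at the LV
mean. This bolus-preservation mechanism is the method's central benefit and
yields a tissue-signal gain of 0.956/0.5 × exp(−ΔTE/T2*) ≈ 1.66. Measured
per-sector CNR gains in the default phantom are smaller (≈ 1.2) because
blood-pool spillover inflates the conventional-mode sector curves — the same
contamination that raises the conventional mode's cross-sector variability.

Spillover is produced by a Gaussian point-spread function (FWHM = one 3 mm
pixel) applied to the noiseless image: the finite-resolution signal
contamination that motivates blood-pool suppression in the first place.
Noise is complex Gaussian followed by magnitude (Rician), with σ specified
relative to the analytic conventional-mode LV peak so both modes share one
absolute noise level (default 0.002, matching an LV blood SNR of several
hundred in conventional mode). An optional linear coil-sensitivity plane
multiplies the image. All draws flow from a single `numpy` Generator seeded
by the config; identical configs are bit-identical.

Not emulated: cardiac/respiratory motion, EPI k-space effects (partial
Fourier, ghosting — the readout enters only through TE), multi-coil
combination, B1 inhomogeneity beyond the plane, and gadolinium
saturation-recovery physics (the "contrast" analysis path exists for
pipeline testing on generic non-hyperpolarized curves). Passing tests on
this phantom therefore demonstrate correctness of the physics and pipeline
under idealized anatomy and motion, not robustness to in-vivo confounders.

The flow-tube phantom integrates s(v) over a plug (with linear boundary
layer) or parabolic laminar profile and applies the mode's T2*(TE) weighting;
it reproduces > 80 % flow-signal suppression at nominal encoding and ≈ 79 %
recovery at half the nominal velocity (accumulated phase 2π, limited by the
boundary layer and the longer TE).

## Quantification pipeline

* **Plane correction**: least-squares plane over myocardial pixels at the
  frame of peak myocardial signal (post-bolus frames carry no signal to fit
  against in hyperpolarized data); the series is divided by the plane
  normalized to unit mean over the mask. Collinear or tiny masks raise.
* **Curves**: mean over each sector mask and the LV mask; baseline offset =
  mean of the last 10 frames (hyperpolarized) or the pre-bolus frames
  (contrast) is subtracted.
* **First-pass window**: starts at the first frame where the LV curve
  exceeds 5× the baseline sd; ends when the LV curve falls below 10 % of its
  peak, extended per sector to the fitted myocardial peak + 3c. The window
  definition is operational — the underlying notion of "first pass" is not
  otherwise specified.
* **Fits**: gamma-variate by bounded nonlinear least squares (a, b, c > 0,
  b ≤ 10, tolerances 1e−8, ≤ 500 evaluations) initialized from the
  log-linearization log s = log a + b log t − t/c; the bolus-arrival origin
  t₀ is half a frame before the window. Non-convergence is flagged, never
  raised. Contrast curves use degree-4 polynomials.
* **Metrics**: AUC = a c^(b+1) Γ(b+1) when the window covers the full pass
  (numeric quadrature of the fitted curve otherwise); pCNR = fitted peak /
  noise sd; upslope = maximum derivative of the fitted curve between arrival
  and peak (an operational definition — "upslope" has no canonical one).
  AUC/pCNR/upslope are computed from fitted curves for both modalities.
* **SNR/CNR**: noise sd = sd of the difference of two noise-only frames over
  the mask, divided by √2 (two independent realizations); SNR(t) = mask mean
  / noise sd; CNR = peak SNR − mean baseline SNR. Default noise frames: last
  two (hyperpolarized), first two (contrast).
* **Statistics**: CoV = sample sd / mean across the six sectors; paired
  comparisons use the two-sided Wilcoxon signed-rank test, exact for n ≤ 25
  without ties or zeros (n = 6 one-signed differences give p = 2/2⁶ =
  0.03125), normal approximation otherwise; α = 0.05.

Zero-filling/interpolation before extraction is deliberately omitted: mask
means are interpolation-invariant up to boundary pixels.

## Problem sizes and determinism

Default runs use a 38×38 matrix, 40 frames at TR = 0.5 s (120 bpm), chosen
as the native resolution of the emulated protocol; the replicate studies in
the test suite use 20 seeds. All stochastic tests fix seeds; hypothesis
property tests run derandomized.

## Known limitations

* The sector CoV magnitudes in the phantom (2–8 %) are smaller than in-vivo
  values because the phantom has no motion, segmentation error, or B1/coil
  residuals; only orderings between modes are meaningful.
* The printed RF gaps and echo times depend on unprinted RF and slice-select
  timings; the overhead constant matches their scale and ordering, not an
  independent prediction.
* Absolute myocardial blood flow quantification (arterial-input
  deconvolution) is out of scope; the pipeline is semi-quantitative.
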