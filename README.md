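# vsperf

Simulation and analysis of **velocity-selective binomial excitation** for
hyperpolarized ¹³C urea first-pass myocardial perfusion MRI.

## The problem

First-pass perfusion imaging with hyperpolarized, metabolically inert ¹³C
urea offers gadolinium-free myocardial perfusion assessment, but the left-
and right-ventricular blood pools are far brighter than the myocardium and
contaminate the tissue signal at achievable resolutions. Spoiling the blood
signal with flow-sensitizing gradients destroys the non-renewable
hyperpolarized bolus magnetization before it ever reaches the myocardium.

The velocity-selective alternative splits the excitation into a 1–1 binomial
pair of RF pulses with a bipolar gradient between them. A spin moving at
through-plane velocity *v* accrues the phase

&nbsp;&nbsp;&nbsp;&nbsp;φ = γ m₁ v, &nbsp;&nbsp; m₁ = ∫ G(t) t dt,

between the two pulses. Scaling the bipolar pair so that γ m₁ v_enc = π makes
the second pulse tip blood moving at the encoding velocity v_enc **back** to
the longitudinal axis: the blood pool appears dark in the image while its
magnetization survives for later myocardial delivery. Stationary myocardium
experiences the full composite flip. Relative to conventional single-pulse
excitation,

&nbsp;&nbsp;&nbsp;&nbsp;s(v) = |sin( (v_enc − v)/v_enc · π/2 )|, &nbsp;&nbsp;
M_z(v) = |cos( (v_enc − v)/v_enc · π/2 )|,

with s² + M_z² = 1. `vsperf` implements this physics (closed forms plus an
exact rotation-matrix treatment), designs minimum-duration bipolar gradient
pairs under hardware limits, generates a seeded dynamic short-axis cardiac
phantom (LV/RV blood pools, 6-sector myocardial annulus, gamma-variate bolus,
T1 decay, RF depletion, spillover, Rician noise), and runs the
semi-quantitative perfusion pipeline: sector curve extraction, gamma-variate /
4th-order polynomial fitting, AUC, peak CNR, upslope, SNR by the
difference-of-noise-frames method, cross-sector coefficients of variance, and
paired Wilcoxon signed-rank comparisons.

## Worked example

```python
import numpy as np
from vsperf.phantom import PhantomConfig, simulate_both_modes
from vsperf.quantify import analyze_series, paired_compare

results = simulate_both_modes(PhantomConfig().with_seed(1))
metrics = {mode: analyze_series(r.series, r.labels, "hyperpolarized")
           for mode, r in results.items()}

lv = results["conventional"].labels == 1
peaks = {m: r.series.data[:, lv].mean(axis=1).max() for m, r in results.items()}
print(f"LV suppression ratio (conv/VS): {peaks['conventional']/peaks['velocity_selective']:.2f}")
for mode, met in metrics.items():
    print(f"{mode}: AUC CoV {met.cov['auc']:.1%}, upslope CoV {met.cov['upslope']:.1%}, "
          f"mean sector CNR {np.nanmean(met.cnr):.1f}")
res = paired_compare(metrics["velocity_selective"].auc, metrics["conventional"].auc)
print(f"paired Wilcoxon on sector AUC: p = {res.p_value:.5f} (n = {res.n})")
```

prints

```
LV suppression ratio (conv/VS): 4.19
conventional: AUC CoV 5.6%, upslope CoV 7.9%, mean sector CNR 32.2
velocity_selective: AUC CoV 2.2%, upslope CoV 3.6%, mean sector CNR 38.0
paired Wilcoxon on sector AUC: p = 0.03125 (n = 6)
```

The velocity-selective mode suppresses the LV blood-pool peak more than
three-fold, and its sector-to-sector variability of AUC and upslope is
substantially lower than with conventional excitation (the conventional mode
suffers blood-pool spillover into the septal sectors); with six sectors the
exact two-sided Wilcoxon p-value for a fully one-signed difference is
2/2⁶ = 0.03125.

The same workflow is available from the shell:

```bash
vsperf design --venc 50                       # bipolar pair + TE, JSON
vsperf profile --venc 33.4 -o profile.csv     # s(v), Mz(v) tables
vsperf simulate -c config.yaml -o out/        # NIfTI series per mode
vsperf analyze --series out/series_velocity_selective.nii \
               --labels out/labels.nii -o out/vs
vsperf compare out/vs_metrics.json out/conv_metrics.json
```

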