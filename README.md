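# aptperf

Quantitative MRI pipeline for differentiating **glioblastoma (GBM)** from
**solitary brain metastases (MET)** using amide proton transfer weighted
(APTw) CEST MRI and dynamic susceptibility contrast (DSC) perfusion MRI.
Intended for imaging scientists who want a tested, scriptable
implementation of the full chain — Z-spectrum processing, Bloch-McConnell
simulation, leakage-corrected perfusion quantification, ROI statistics and
two-group ROC analysis — plus a digital-phantom cohort simulator with known
ground truth for validating every stage.

## What it computes

**APTw.** Per voxel, the Z-spectrum Z(Δω) = S_sat/S0 is B0-corrected by
shifting its minimum to 0 ppm, and the APTw contrast is the asymmetry
integral of the linearly interpolated spectrum over the amide band:

    APTw(%) = 100 · [ ∫₋₃.₉⁻³·¹ Z(ω) dω − ∫₃.₁³·⁹ Z(ω) dω ] / 0.8

Fluid suppression rescales APTw by (σ'_WM / Z_ref)², where Z_ref = Z(−3.5
ppm) and σ'_WM is the white-matter value of Z(−3.5 ppm) for the same
saturation scheme, derived here by multi-pool Bloch-McConnell simulation of
the pulsed saturation module (5 hyperbolic-secant pulses × 100 ms, 61 ms
gaps, 2 μT RMS, 3 T).

**DSC.** ΔR2\*(t) = −ln(S/S_pre)/TE; semi-automatic arterial input function
selection; Boxerman linear leakage fit c ≈ K1·ref − K2·∫ref giving K2 and
leakage-corrected CBV; CBF by delay-insensitive block-circulant
truncated-SVD deconvolution; all values relative and normalized to
normal-appearing white matter (NAWM) downstream — except K2, which is never
normalized.

**Statistics.** Region mean/max per subject (enhancing tumor, necrosis,
edema, whole tumor, NAWM), two-sided Mann-Whitney U (exact at small n),
nonparametric ROC AUC with Hanley-McNeil SE and unclipped 95% CI, and
in-sample logistic-regression combinations of parameters.

**Synthetic cohorts.** Because patient data are not available, a phantom
module generates labelled two-group cohorts: CEST stacks from
Bloch-McConnell tissue spectra under a smooth B0 field, and DSC series from
a gamma-variate bolus with per-tissue flow/volume/delay and a leakage term
— with every generating parameter recorded for recovery testing.

## Worked example

```python
import numpy as np
from aptperf import derive_sigma_wm, wm_pools
from aptperf.phantom import CohortConfig, generate_cohort
from aptperf.cohort import analyze_cohort

sigma = derive_sigma_wm(wm_pools())
print(f"sigma_wm = {sigma:.3f}")

cfg = CohortConfig()
subjects = generate_cohort(n_gbm=10, n_met=8, config=cfg, master_seed=7)
_, group_table, roc_table, combo_table = analyze_cohort(subjects, cfg)
et_max = roc_table[(roc_table.region == "ET") & (roc_table.statistic == "max")]
print(et_max[["parameter", "auc", "se", "p", "ci_low", "ci_high"]]
      .round(3).to_string(index=False))
best = combo_table[combo_table.statistic == "max"]
print(best[["parameters", "auc", "ci_low", "ci_high"]]
      .round(3).to_string(index=False))
```

prints (about 15 s):

```
sigma_wm = 0.415
parameter   auc    se     p  ci_low  ci_high
    nAPTw 0.725 0.121 0.122   0.488    0.962
 nAPTw_FS 0.675 0.129 0.237   0.423    0.927
     nCBF 0.775 0.112 0.055   0.556    0.994
    ncCBV 0.762 0.114 0.068   0.539    0.986
       K2 0.525 0.140 0.897   0.250    0.800
        parameters   auc  ci_low  ci_high
     nAPTw + ncCBV 0.838   0.649    1.026
      nAPTw + nCBF 0.825   0.630    1.020
        nAPTw + K2 0.750   0.521    0.979
nAPTw + ncCBV + K2 0.838   0.649    1.026
```

Reading this: the simulated white-matter fluid-suppression factor is 0.415
(Z at −3.5 ppm under the protocol's saturation).  On one seeded 10-vs-8
synthetic cohort, the enhancing-tumor *maximum* of normalized APTw and of
leakage-corrected CBV each discriminate the groups (AUC ≈ 0.73–0.78), K2
does not (AUC ≈ 0.5), and combining APTw with a perfusion parameter raises
the in-sample AUC to ≈ 0.84 — the qualitative pattern the pipeline is built
to quantify.  Upper CI bounds above 1 are reported unclipped by convention.

A command-line interface mirrors the library: `aptperf aptw`, `aptperf
dsc`, `aptperf bmsim`, `aptperf derive-sigma`, `aptperf simulate-cohort`,
`aptperf report` (see `aptperf --help`); NIfTI volumes in, NIfTI maps and
CSV tables out.

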