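# Methods

`aptperf` implements a quantitative-MRI pipeline for differentiating
glioblastoma (GBM) from solitary brain metastases (MET) using amide proton
transfer weighted (APTw) CEST MRI together with dynamic susceptibility
contrast (DSC) perfusion MRI, and a digital-phantom cohort simulator used to
exercise and validate the pipeline end to end.

## APTw Z-spectrum processing (`aptperf.zspectrum`)

Per voxel, the saturated signals S_sat(Δω) at 21 offsets (±5 ppm, 0.5 ppm
steps) are normalized by the unsaturated reference S0 acquired at −150 ppm,
giving the Z-spectrum Z(Δω) = S_sat/S0.  Voxelwise B0 correction shifts the
spectral minimum to 0 ppm; the sub-sample minimum is located by a parabola
through the discrete minimum and its two neighbours, the minimal sub-sample
refinement consistent with 0.5 ppm sampling.  Shifts beyond ±1 ppm, boundary
minima, and flat spectra are flagged uncorrectable (the voxel keeps an
unshifted APTw value and a missing B0 value).  The metric is the asymmetry
integral of the linearly interpolated spectrum over the amide band,

    APTw(%) = 100 × [∫_{−3.9}^{−3.1} Z dω − ∫_{3.1}^{3.9} Z dω] / 0.8 ,

computed exactly on the piecewise-linear interpolant, including analytic
partial end segments (the bounds 3.1/3.9 ppm fall between the 0.5 ppm
knots).  Fluid suppression rescales APTw by (σ'_WM / Z_ref)², with Z_ref the
corrected-spectrum intensity at −3.5 ppm, down-weighting long-T2 fluid
(CSF, liquefactive necrosis) whose narrow line gives Z_ref > σ'_WM.  Z_ref
is read after B0 correction, since suppression follows correction in the
processing chain.  Missing values are IEEE NaN throughout.

The map-level wrapper vectorizes the identical chain over 4D stacks; the
test suite asserts bitwise-level agreement between the scalar and
vectorized paths.

## Bloch-McConnell simulator (`aptperf.bmsim`)

The saturation module is 5 hyperbolic-secant pulses of 100 ms with 61 ms
interpulse delays at 3 T.  The coupled Bloch-McConnell equations for a star
topology of pools (all exchanging with water, detailed balance) are
propagated by exact matrix exponentials of the augmented linear system over
piecewise-constant B1 segments (midpoint sampling of the sech envelope,
truncated at 1% of peak; 64 segments by default).  Interpulse gaps zero the
transverse components (crusher assumption) and evolve the longitudinal
system freely.  The readout is not simulated: it is a common multiplicative
factor cancelled by S0 normalization.  The semisolid MT pool can be treated
as a full Bloch pool (Lorentzian line) or as a longitudinal-only pool
saturated at π ω1² g(Δω) with a super-Lorentzian lineshape, whose
on-resonance divergence is capped inside ±1 ppm.

Two protocol-interpretation choices matter and are the package's own:

* **B1 convention.** The protocol's "2 μT" is interpreted as the RMS
  amplitude of the saturation module (the clinical APTw convention),
  corresponding to an envelope peak of ≈5.6 μT.  `SaturationModule`
  itself stores the peak; `SaturationModule.with_b1_rms` converts.
* **Steady state.** A 3D GRE CEST acquisition repeats the saturation module
  back-to-back for many seconds per offset, so the water magnetization sits
  in a pseudo-steady state rather than being saturated once from thermal
  equilibrium.  `simulate_offset(..., n_trains=k)` propagates k repeated
  trains; the fluid-suppression factor is derived at n_trains=50 (~37 s).

Under these two choices the white-matter pool set yields
Z(−3.5 ppm) = 0.414, the value used as the default σ'_WM ≈ 0.4.  Single-shot
saturation from equilibrium at a 2 μT envelope peak would instead give
Z(−3.5) ≈ 0.84 — far too little saturation to be compatible with the
protocol-derived factor.

The bundled white-matter pool set (`data/wm_3t_synthetic.yaml`) is a
synthetic stand-in compiled from literature values for 3 T WM: water
T1 = 1.084 s / T2 = 69 ms and a 13.9% super-Lorentzian semisolid pool
(T2 = 10 μs, k = 23 s⁻¹) from Stanisz et al. (MRM 2005), an amide pool
(f = 0.0065, k = 30 s⁻¹, +3.5 ppm) and a relayed-NOE pool (f = 0.005,
k = 16 s⁻¹, −3.5 ppm) at review-article values.

## DSC perfusion (`aptperf.dsc`)

Signal is converted to relative concentration ΔR2*(t) = −ln(S/S_pre)/TE
with S_pre the pre-bolus baseline mean; bolus arrival is detected as the
first frame where the global mean drops 3 SD below its running baseline.
The arterial input function averages the top-10 candidate voxels ranked by
a composite score (peak concentration 0.5, early arrival 0.25, low first
moment 0.25 — documented heuristics standing in for an interactive
selection step).  Leakage correction is the Boxerman linear fit
c(t) ≈ K1·ref(t) − K2·∫ref, where ref is the mean curve over non-enhancing
brain excluding arterial voxels; cCBV integrates the corrected curve, and
K2 is reported signed in min⁻¹ (positive = T2*-dominant extravasation).
CBV is the ratio of curve to AIF areas.  CBF uses delay-insensitive
block-circulant truncated-SVD deconvolution (zero-padding to 2N; singular
values below a threshold × maximum zeroed; default threshold 0.15,
configurable); MTT = cCBV/CBF.  All outputs are relative — downstream
analysis normalizes to NAWM, so no hematocrit/density scaling is applied.

Known numerical properties, verified in the tests: the circulant
formulation is exactly shift-invariant (CBF changes 0% under a two-frame
delay); truncation at 0.10–0.15 of the maximum singular value
underestimates CBF by ≈15–26% for MTT = 4 s at TR = 1.243 s (the truncation
removes the high-frequency content of the sharp residue peak; the estimate
is exact as the threshold → 0).  This bias largely cancels in
NAWM-normalized CBF.  The Boxerman K2 is identifiable only insofar as the
non-leaky part of the tissue curve is shape-matched to the reference;
differences in MTT or bolus delay alias into K2 at the ±0.1–0.3 min⁻¹
level, dwarfing physiological leakage values — a known fragility of the
method that the synthetic cohort reproduces.

## Digital phantom and cohort simulator (`aptperf.phantom`)

Geometry: concentric ellipsoids — necrotic core inside an enhancing-tumor
(ET) rim inside an edema shell — embedded in an NAWM brain ellipsoid with a
small through-plane artery tube; a focal hot-spot sub-ellipsoid sits inside
the ET rim.  Default grid 64×64×24; tumor position/radii jittered per
subject; some subjects lack edema or necrosis (probabilities 1.0/0.75 and
0.5/0.25 for the GBM-like/MET-like groups), exercising absent-region
handling.

CEST forward model: per-tissue Z-spectra are simulated by the
Bloch-McConnell engine (steady-state, 32 segments) on an extended ±6 ppm
grid, broadcast over the label volume, resampled at (offset − B0) under a
smooth random B0 field (±0.15 ppm), scaled to signal units and degraded
with additive Gaussian noise on both the saturated and S0 images.  Spectra
are linear in the amide fraction to excellent approximation over the
simulated range, so each tissue template is simulated once at two anchor
fractions and per-subject spectra interpolate between them (cached across
subjects and replicate cohorts).  Tissue templates modify water relaxation
and MT fraction per tissue; the phantom's semisolid line is centered on
water and the NOE pool is dropped, so the asymmetry metric isolates the
amide pool and NAWM APTw is positive (≈1.8%), making NAWM normalization
well-posed.

DSC forward model: gamma-variate arterial bolus (peak 12 s⁻¹ at 15 s + 4 s);
tissue curves CBF·(AIF ⊛ e^{−t/MTT}) evaluated on an 8× oversampled time
grid (frame-rate convolution distorts short MTTs) with per-tissue delay,
minus K2/60·∫ref in leaking tissue; signal S = S0·exp(−TE·ΔR2*) plus
Gaussian noise; artery voxels carry the AIF.  NAWM defines CBF_rel =
CBV_rel = 1 with MTT 4 s and a ΔR2* peak near 4 s⁻¹.

Group effect sizes are *emulation targets*, not measured-data claims: ET
relative corrected CBV ~N(4.3, 1.8) vs ~N(2.4, 0.86), relative CBF
~N(3.7, 1.7) vs ~N(2.3, 1.0), normalized APTw ~N(2.0, 0.60) vs
~N(1.7, 0.74) for GBM-like vs MET-like subjects; K2 ~N(0.04, 0.03) min⁻¹ in
both groups.  The focal hot spot carries normalized APTw ~N(4.9, 0.4) vs
~N(4.4, 0.4), emulating the intra-tumor heterogeneity that makes the region
*maximum* a stronger discriminator than the mean; the CEST noise level
(0.5% of S0, the effective noise of vendor-smoothed APTw maps) is
calibrated so the region maximum tracks the hot spot rather than the
voxel-noise extreme over the ROI.  Necrosis/edema parameters are
group-independent draws around literature-like means.

What the generator does *not* emulate: anatomically realistic templates,
partial-volume mixing, motion/ghosting, Rician noise (additive Gaussian is
used; the difference is negligible at SNR ≥ 20), recirculation in the
bolus, and B1 inhomogeneity.  Passing tests therefore demonstrate the
*pipeline's* correctness and the statistical machinery's calibration under
controlled conditions, not clinical performance on real data.

## Cohort statistics (`aptperf.roistats`)

Regions: ET (rim + hot spot), necrosis, edema, whole tumor (their union),
NAWM; mean/max/SD/N over non-missing voxels; regions absent in a subject
contribute no row.  All parameters except K2 are divided by the subject's
NAWM mean (K2 is left raw: leakage is absent in healthy WM, so the ratio
would be ill-conditioned); re-normalization is flag-guarded and rejected.

Group comparison uses the two-sided Mann-Whitney U test, reporting the
smaller-orientation U; the exact null distribution is used for n1·n2 ≤ 400
without ties (more defensible than the normal approximation at 10 vs 8),
with a `spss_compat` switch forcing the tie-corrected asymptotic version.
ROC AUC is nonparametric with GBM as the positive class and a fixed
orientation (no flipping, so AUC < 0.5 is reportable); the SE is
Hanley-McNeil and the 95% CI (±1.96 SE) is unclipped by default.  Parameter
combinations are unregularized in-sample binary logistic regressions scored
by the same AUC; complete separation is detected and reported as AUC = 1
with a flag rather than divergent coefficients.  No multiple-comparison
correction is applied (each parameter/combination is assessed
independently); α = 0.05 two-sided.

## Problem sizes and numerical choices

Default cohort runs use 10 + 8 subjects at 64×64×24 (≈15 s per cohort,
generation + analysis); the null-calibration experiment uses 500 replicate
zero-effect cohorts at 32³ with the CEST arm only (~8 minutes), at which
size the empirical rejection rate of the ET nAPTw_max test at α = 0.05 is
checked against its nominal level.  Matrix exponentials use
`scipy.linalg.expm` on the ≤13-dimensional augmented system; the phantom's
spectrum interpolation in amide fraction keeps the Bloch-McConnell cost
independent of cohort size.  The seeded pipeline is bit-reproducible:
per-subject seeds derive from the master seed via `numpy` SeedSequence
spawning.

## Known limitations

* σ'_WM depends on the bundled literature pool set and the two protocol
  interpretation choices above; the ±0.05 acceptance band reflects that the
  vendor's exact HS pulse parameters are unpublished.
* K2 maps in the default (shape-mismatched) cohort are delay/MTT-confounded
  by construction of the Boxerman model; recovery experiments therefore use
  shape-matched phantoms.
* CBF from truncated cSVD is biased low at clinically typical thresholds;
  only NAWM-normalized CBF should be compared across tissues.
* In-sample AUCs (as reported) are optimistic relative to held-out
  validation; no cross-validation is performed by design.
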