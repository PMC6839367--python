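# Methods

## The dual-input forward model

A tissue voxel with plasma flow `F` (mL/min) receives a fraction `γ`
of that flow from the pulmonary artery and `1−γ` from the systemic
(aortic) circulation.  Because the two inputs merge in the capillary
bed, they can be replaced by a single net plasma input

```
C_in(t) = [γ C_PA(t) + (1−γ) C_A(t)] / (1 − H_LV),
```

where `C_PA`, `C_A` are whole-blood concentrations (mM) and the
large-vessel hematocrit `H_LV` (default 0.45) converts blood to plasma
concentration.  The tissue curve is the convolution

```
C_T(t) = f_t · R_T(t) ⊗ C_in(t − t_lag),      f_t = F/V_T = (F/V_P)·v_P,
```

with a single bolus-arrival lag `t_lag` shared by both inputs.
Single-input analyses are the exact `γ = 1` (pulmonary) and `γ = 0`
(systemic) limits.  All five models share the fitting vector
`{F/V_P, PS/V_P, v_P, v_I, t_lag}` (plus `γ` in dual mode), so each
has 5 (single) or 6 (dual) free parameters and information-criterion
comparisons are not confounded by differing complexity.  For TK and ETK
this is achieved by decomposing `K^Trans = E·f_t` with the Renkin–Crone
extraction `E = 1 − exp(−PS/F)` (mixed flow- and permeability-limited
regime); for TK the distribution volume in the exponent is `v_I` alone
(`v_P ≪ v_I`, but `v_P ≠ 0` so `f_t` and `ps_t` remain defined).

### Residue functions

* **TK** `R(t) = E·exp(−E f_t t / v_I)`, `Q_T = f_t R`.
* **ETK** adds the intravascular term `v_P·δ(t)`; the delta is applied
  analytically (the AIF term `v_P·C_in(t − t_lag)` is added after the
  convolution), never as a discretised spike.
* **2CX** solves `v_P Ċ_p = f_t(C_in − C_p) + ps_t(C_i − C_p)`,
  `v_I Ċ_i = ps_t(C_p − C_i)`.  The impulse residue is the analytic
  biexponential `R(t) = a₁e^{λ₁t} + a₂e^{λ₂t}` with `λ₁, λ₂` the
  eigenvalues of the 2×2 rate matrix, pinned by `R(0) = 1` and
  `R'(0⁺) = −f_t/v_P`.  Validated against direct stiff ODE integration
  (agreement ≲1e-8).
* **AATH** `R(t) = 1` for `t < Tc = v_P/f_t`, then
  `E·exp(−E f_t (t−Tc)/v_I)`.
* **DP** plug-flow capillary with distributed exchange
  (Sangren–Sheppard).  `R(t) = 1` for `t < Tc`; for `t ≥ Tc`
  `R(Tc+u) = 1 − e^{−A} − ∫₀ᵘ g(s) ds`, `A = PS/F`, `B = ps_t/v_I`,
  `g(s) = e^{−A−Bs} √(AB/s)·I₁(2√(ABs))`.  The integrand is evaluated
  with the exponentially scaled Bessel function (net exponent
  `−(√A − √(Bs))²`, always ≤ 0) and integrated in the substituted
  variable `w = √s`, in which it is smooth; a uniform u-grid
  under-resolves the peak otherwise.  Validated against an upwind
  finite-volume integration of the plug-flow PDE in which the time step
  is matched to the cell size (CFL = 1, advection an exact shift — this
  preserves the sharp vascular front that a sub-CFL upwind scheme
  smears) and exchange uses the exact 2×2 matrix exponential in a
  Strang splitting.  Agreement is ≤0.1% sup-norm away from the
  discontinuity at `Tc`.

### Convolution operator

Forward curves are evaluated on an internal uniform grid (default
1e-3 min for standalone evaluation, 4e-3 min inside fitting where
residual noise dominates) via FFT convolution with trapezoid end
corrections.  The plug-flow phase of AATH and DP is **not** convolved
through the discontinuous kernel: it is computed exactly as
`f_t·[G(t) − G(t−Tc)]` from the running integral `G` of the input, and
the continuous post-`Tc` tail is convolved separately and shifted.
This keeps the operator second-order accurate; refining the internal
grid by 4× changes curves by <0.01% of peak, and agreement with a
brute-force 1-ms-grid convolution of oracle-integrated residue
functions is within 0.1% of peak across a 3×3×3×3 parameter grid for
all five models.

## Arterial input function

The AIF is the superposition of the first and second pass of the bolus:
a single-pass kernel of Orton's exponential family,
`P(u) = [a_b·u·e^{−μ_b u} + a_g(e^{−μ_g u} − e^{−μ_b u})]·1[u≥0]`,
shifted to the onset time, plus a delayed recirculation copy scaled by
`κ_rc ∈ [0,1]`:

```
C(t) = P(t − t_onset) + κ_rc · P(t − t_onset − τ_rc).
```

The kernel is pluggable behind `evaluate_aif`.  Fitting is seeded
multi-start bound-constrained least squares to the full-pass curve,
seeded from moment-based estimates (peak height/time, tail level).
Measured pulmonary/aortic pairs are checked against three QC criteria:
pulmonary onset earlier, pulmonary peak higher, and late-phase (last
25% of frames) levels within a configurable ratio band (default
[0.7, 1.3]).  Bolus arrival is detected as the first of two consecutive
frames exceeding `max(baseline mean + 3 SD, 5% of peak)`, with the
baseline taken from clearly pre-bolus frames.

## Signal model

SPGR steady state: `S = M0·sin α·(1−E1)/(1−E1·cos α)`, `E1 =
exp(−TR/T1)`.  Native T1 and M0 come from the multi-flip-angle
acquisition (5/15/20/25/30° at TR 4.2 ms by default): the linearised
`S/sin α` vs `S/tan α` regression seeds a nonlinear least-squares
refinement of the SPGR equation itself.  Degenerate voxels (identical
signal at all angles, slope outside (0,1)) are flagged, not silently
NaN'd.  For the dynamic series, M0 is recalibrated per voxel so the
mean baseline signal maps to the native T1; each frame is inverted for
`T1(t)` and `C(t) = (1/T1(t) − 1/T1_native)/r1` with `r1 =
4.5 s⁻¹mM⁻¹`.  Frames outside the invertible range are flagged and (by
default) clamped to the last valid value.  The number of baseline
frames defaults to the detected pre-bolus window (minimum 3).  TE/T2*
effects and B1 inhomogeneity are ignored.

A practical consequence implemented in the pipeline: blood voxels near
the concentration peak sit close to SPGR saturation, where the
inversion amplifies noise enormously.  AIF extraction therefore
averages the raw ROI signal **before** the nonlinear inversion
(`measure_vessel_curve`), which is also how vessel-ROI curves are
produced in practice.  Even so, the measured AIF peak is sensitive to
the estimated blood T1 (≈ −3% peak per +1% T1 at 80% saturation); this
is an intrinsic limitation of AIF measurement at a 15° dynamic flip
angle, not of the implementation.

## Voxelwise fitting

Per voxel and model, the SSE between the forward curve and the data is
minimised with a bound-constrained derivative-free local minimizer
(Powell) inside the physiologic box `F/V_P ∈ [0.01, 50] min⁻¹`,
`PS/V_P ∈ [0, 50] min⁻¹`, `v_P, v_I ∈ [0.001, 0.7]` with
`v_P + v_I ≤ 0.95` via quadratic penalty, `t_lag ∈ [0, 0.5] min`,
`γ ∈ [0, 1]`.  Multi-start uses one physiologic center start, two
near-single-input starts (`γ ≈ 0.95/0.05`, dual mode only — the dual
optimum is often adjacent to a single-input solution), and seeded
sequential random draws (flow and exchange rates log-uniform).  The
draw stream is sequential so the start set for `k` starts is a prefix
of that for `k' > k`: adding starts can only improve the returned SSE.
Ties within a relative SSE tolerance go to the start that used fewer
evaluations.  Non-enhancing voxels (peak below 3× baseline SD) are
flagged and given the SSE of the null prediction rather than fitted.
Fits are bit-reproducible given (seed, config).

## Model selection

For least-squares fits, `cAIC = n·ln(SSE/n) + 2K + 2K(K+1)/(n−K−1)`
with `K = p + 1` — the residual variance is counted as an estimated
parameter.  All five models share `p`, so this convention shifts every
cAIC equally and cannot change a best-model map; it does shift
dual (p=6) vs single (p=5) comparisons by a constant ≈0.3 at n=130,
which is well below the observed margins.  Akaike weights use the
shifted form `w_m = e^{−Δ_m/2}/Σ e^{−Δ_j/2}`, stable for large deltas.
Best-model maps break exact ties by fewer parameters, then the fixed
order TK, ETK, 2CX, AATH, DP.  cAIC comparisons are only made between
models fitted to the identical frame series.

## Digital phantom

The phantom emulates the two acquisition protocols (130 frames × 2 s,
or 5 s frames over the same window; TR 4.2 ms, FA 15°, multi-FA
5–30°).  Layout: one full row of voxels per vessel (pulmonary trunk,
aorta), tumor below split into two regions with distinct ground truth
(2CX with `γ = 0.8` and `γ = 0.3`; flows in the tens of mL/min/100 g —
the regime of voxelwise estimates in dual-supply thoracic tumors).
Vessel voxels carry the analytic blood curves directly, mimicking
arterial ROI sampling.  The default AIFs place the bolus ~24 s into
the acquisition (real protocols acquire 20–30 s of baseline), give the
pulmonary artery a sharp first pass and the aorta a delayed,
substantially dispersed one (the aortic bolus has traversed the
pulmonary capillary bed and the left heart), with matching late-phase
washout — the pair satisfies the dual-AIF QC criteria by construction.

Noise is i.i.d. Gaussian on the signal, with SD quoted as a fraction
of the peak tumor **enhancement** (so `noise_sd = 0.05` means SNR ≈ 20
on the dynamic range that carries the kinetic information; blood
voxels, which enhance ~10× more, sit at correspondingly higher SNR, as
in real data).  The precontrast multi-FA volumes receive one third of
the dynamic-frame noise: they are unhurried 3D acquisitions, not 2-s
frames.  Signal noise maps to heteroscedastic concentration noise
through the nonlinear inversion; baseline concentration noise is
mean-zero (tested).  Rician noise is not modeled (tumor SNR is high
enough that the Gaussian approximation holds); respiratory motion,
anatomic realism and coil artifacts are out of scope.  Everything is
bit-reproducible from (config, seed).

What phantom-based tests do and do not show: they verify the
estimation chain end to end (signal → T1 → concentration → AIF →
kinetic parameters → model selection) under known truth, including an
inverse-crime closure at zero noise used purely as a correctness
check.  They do not probe motion, B1/T2* effects, water exchange,
partial-volume AIF contamination, or deviations of real tissue from
the generating model.

## Statistics

ROI summaries are voxelwise medians with seeded bootstrap 95% CIs
(default 2000 resamples; the CI method for medians is a package
choice).  Paired comparisons between adjacent models (TK–ETK, ETK–2CX,
2CX–AATH, AATH–DP) use the Wilcoxon signed-rank test (exact null for
n ≤ 25, continuity-corrected normal approximation above) and Pearson
correlation.  Raw p-values are reported by default (a Holm option
exists but is off, matching common practice in exploratory voxelwise
comparisons).  The γ kernel density is the plain Gaussian-kernel
estimator `f̂(x) = (nh)⁻¹ Σ φ((x−x_i)/h)` on a grid extended four
bandwidths beyond the data; note that a bandwidth of order 1 on a
[0, 1] variable oversmooths severely — pass `h` on the scale of your γ
values (e.g. 0.02–0.05, or 3 if γ is expressed in percent).

## Problem sizes and numerical defaults

The validation experiments use deliberately compact problem sizes
chosen to exercise the full chain: the oracle grid is 3×3×3×3 per
model; parameter recovery uses 200 replicate voxels at the 130-frame
lung protocol with 8 multi-starts; the identification phantom is
8×8×1 (48 tumor voxels) with 4 multi-starts and all five models.
Forward-model internal resolution is 1e-3 min standalone / 4e-3 min in
fitting; optimizer budget 700 evaluations per start by default.
Degenerate inputs are handled explicitly: `PS = 0` is the `E = 0`
limit (no division), repeated 2CX eigenvalues are perturbed by 1e-12,
`v_P + v_I` is renormalised to <1 before a result record is built.

## Known limitations

* The optimizer is Powell's method (derivative-free, bound
  constrained); BOBYQA semantics, not the BOBYQA algorithm itself.
* Single `t_lag` for both inputs (the physiologic delay difference is
  absorbed by the AIF onsets).
* AIF peak measurement near SPGR saturation is ill-conditioned (see
  above); population or prebolus AIFs are not implemented.
* MTT is defined as `(v_P + v_I)/f_t` (total distribution volume over
  plasma flow), consistent with the `∫R dt` identity; conventions
  dividing by blood flow differ by `1 − H` factors.
* BV conversion uses a small-vessel hematocrit (default 0.25,
  configurable); only the large-vessel value is standardised.
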