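# Methods

## Signal model and concentration conversion

The spoiled gradient echo (SPGR) steady-state signal is modelled as
`S = M0·sin α·(1−E1)/(1−cos α·E1)` with `E1 = exp(−TR/T1)`. T2*-weighting
(`exp(−TE/T2*)`) is treated as a multiplicative constant absorbed into M0:
TE is short (1.7 ms at the default settings) and the factor cancels in the
baseline-ratio inversion used for conversion, so modelling it explicitly
would add a parameter the data cannot constrain.

Pre-contrast T1 is mapped from multi-flip-angle (MFA) acquisitions
(defaults 1°, 3°, 5°, 10°, 15°, 20°, TR 4.0 ms) by trust-region reflective
least squares on (T1, M0), initialised from the linearised DESPOT1 solution.
Fits are flagged invalid when the solver fails or T1 leaves (0, `t1_max`]
with `t1_max` = 10 000 ms by default — a guard against divergent fits on
flat data.

Concentration conversion estimates the per-voxel equilibrium scale M0 from
the mean of the first `baseline_frames` frames (default 10, ≈ 30 s at 3 s
resolution — no automated bolus-arrival detection is attempted, since
arrival is hard to detect reliably in noisy data) together with the MFA T10.
Each frame's signal is inverted for `E1 = (M0 sin α − S)/(M0 sin α − S cos α)`;
frames with `E1` outside (0, 1) — signal at or beyond the SPGR asymptote
`M0 sin α` — have no real T1 solution and are flagged invalid rather than
clipped. Concentration follows from the linear relation
`C = (1/T1 − 1/T10)/r1` with relaxation times in seconds and relaxivity
`r1` = 3.6 l·mmol⁻¹·s⁻¹ by default (Gd-DOTA at 1.5 T). M0 is taken from the
baseline rather than from the MFA fit's M0 so that inter-sequence scaling
differences cancel; by construction the mean baseline frame maps to exactly
zero concentration. TR and T1 are carried in milliseconds everywhere except
this last step.

## Arterial input functions

Three forms, all represented as plasma concentration versus time:

* **model** — a first-pass bolus template concatenated with the
  biexponential washout `D·(a1·e^(−m1 t) + a2·e^(−m2 t))`. Defaults are
  literature-derived conventions, not fitted values: washout amplitudes
  a1 = 3.99, a2 = 4.78 kg/l with rates m1 = 0.144, m2 = 0.0111 min⁻¹, and a
  gamma-variate-shaped first pass (peak ≈ 4 mM at 0.1 mmol/kg, peak time
  15 s after arrival, plus a recirculation plateau rising to ≈ 0.9 mM)
  standing in for published blood-sampled first-pass curves. The washout is
  rescaled by a continuity factor so the curve is continuous at the
  junction (default 45 s past arrival); the exact concatenation point and
  scaling between first pass and washout are a design choice of this
  package. Concentration is zero before bolus arrival.
* **individual** — masked arterial voxels (e.g. descending aorta) are
  averaged per frame, converted to whole-blood concentration with the blood
  T10 (median MFA T1 inside the mask unless overridden), and divided by
  (1 − hematocrit), default 0.42, to give plasma concentration; hematocrit 0
  disables the correction. An AIF whose conversion fails in more than half
  the frames is flagged.
* **sample-average** — each input AIF is shifted so its bolus arrival
  (linear interpolation of the first crossing of 10 % of peak) coincides
  with the first usable AIF's, interpolated onto that AIF's grid, and
  averaged pointwise. Flat inputs with no detectable bolus (peak < 0.05 mM)
  are excluded with a warning. The alignment rule is deliberately simple
  plumbing; nothing downstream depends on its details.

## Extended Tofts model and fitting

`Ct(t) = vp·Cp(t) + Ktrans·∫₀ᵗ Cp(u)·exp(−kep(t−u))du`, `kep = Ktrans/ve`.
Times are seconds at every interface and minutes inside the evaluation so
Ktrans and kep carry min⁻¹. The convolution is evaluated by the exact
recursion for piecewise-linear Cp (per-interval Taylor fallback when
`kep·Δt < 1e−5` to avoid cancellation; `scipy.signal.lfilter` fast path on
uniform grids). Against a brute-force fine-grid quadrature oracle the
recursion is accurate to ~1e−5 relative at 3 s sampling, comfortably inside
the 1e−3 design tolerance; a naive trapezoid on the kernel would not be.

Fitting minimises unweighted least squares (no weighting scheme is assumed)
over (Ktrans, ve, vp) with a trust-region reflective solver, lower bounds 0
and **no upper bounds** — deliberately, so that non-physical estimates
(ve ≥ 1, extreme Ktrans) are reported and can be caught by the category
checks instead of being silently clipped to the boundary. The default
deterministic start is Ktrans = 0.1 min⁻¹, ve = 0.2, vp = 0.01. Convergence
is recorded as *formal* (gradient test), or the relative step size /
relative residual change falling below 1e−6, with iterations capped at 100;
"iterations" is implemented as the solver's Jacobian evaluations, with
`max_nfev = 4 × max_iter` as the corresponding evaluation budget. ve is
floored at 1e−9 inside the residual only, so kep stays defined while the
reported estimate is untouched.

A symmetry worth noting (and tested): replacing Cp by Cp/β and
(Ktrans, ve, vp) by β·(Ktrans, ve, vp) leaves the model output identical.
An artificially small AIF therefore inflates all three estimates — the
mechanism by which ve can exceed its physical ceiling of 1.

## Error categories

Checks run strictly in order per voxel; the first failure is the category:

1. s.d. of the [Gd] trace ≥ 5 mM (GD_SD_TOO_BIG, cyan)
2. any non-real conversion frame (GD_NOT_REAL, yellow)
3. mean [Gd] ≤ 0.01 mM (GD_TOO_SMALL, red)
4. fit not converged (NON_CONVERGENCE, magenta)
5. ve ≥ 1 (VE_GE_ONE, green)
6. vp ≥ 1 (VP_GE_ONE, green)
7. Ktrans > 10 min⁻¹ or kep > 15 min⁻¹ (PARAM_TOO_LARGE, blue)

Checks 1–3 are pre-fit: a failing voxel is never fitted. The boundary
convention is *fail on ≥ the limit* (a measure-zero choice either way).
Check 2 fires on *any* invalid frame. VE_GE_ONE and VP_GE_ONE are distinct
codes that share green in rendering, because map displays merge them while
analyses distinguish them. Yellow and blue are this package's choices for
the two categories without an established colour; the palette is
configurable. An alternative noise test — post- versus pre-bolus variance
ratio — is implemented but off by default. Out-of-ROI voxels carry a
sentinel (−1) and render white by default.

For histogram extraction the default accepted set is {GOOD, GD_TOO_SMALL},
with GD_TOO_SMALL voxels contributing Ktrans = 0: absence of uptake is a
valid perfusion outcome, not a failure.

## Digital phantom

The generator emulates a 3D SPGR protocol (TR 4.0 ms, flip 18°, 181 frames
at 3 s; MFA at the six default angles) on a 32×32×3 grid — full in-plane
physics at a desk-fast voxel count. Every voxel's curve is synthesised
through the same physics the pipeline inverts, so the noiseless round trip
is exact to solver precision. Bolus arrival is at 30 s (10 baseline frames).
The canonical phantom has six zones engineered to realise the category
repertoire: a clean band (Ktrans 0.15 min⁻¹, ve 0.25, vp 0.03); two
moderate-uptake bands (ve 0.45 and 0.60) that fit cleanly with the true AIF
but cross ve ≥ 1 when fitted with AIF/3 and AIF/2 respectively — giving a
strictly graded VE_GE_ONE count across fit-AIF scales ⅓ → ½ → 1; a
no-uptake core (GD_TOO_SMALL); a deterministic high-variance band with
+25 mM concentration spikes on every third post-bolus frame
(GD_SD_TOO_BIG); and an extreme-rate band (Ktrans 20 min⁻¹, kep 33 min⁻¹,
PARAM_TOO_LARGE). A rectangular artery region carries the generation AIF as
whole blood (hematocrit applied in reverse; blood T10 1440 ms, a
conventional default) so individual-AIF measurement closes the loop.

Noise is Gaussian on signal magnitude, not Rician — simpler, and accurate
at the SNR exercised; signals are clipped at zero after noise. The design
noise level sets the peak enhanced clean-zone signal to 20× the noise s.d.;
the MFA series gets half that s.d. by default, reflecting the higher SNR of
an unaccelerated mapping acquisition. Two design details keep the
categories discriminable at design noise, both documented as generator
choices: the no-uptake core is modelled as fluid-rich necrosis (T10
2000 ms, twice the proton density), which roughly doubles the
signal-per-mM gain and keeps the 0.01 mM mean-[Gd] threshold well clear of
the baseline-anchor noise floor (the dominant error term: the 10-frame
baseline mean enters every frame's concentration); the high-variance band
shares the doubled proton density so its burst frames stay well below the
SPGR asymptote under M0-estimation error. NON_CONVERGENCE has no phantom
zone — genuine solver non-convergence cannot be made deterministic at
realistic noise — and is exercised by unit tests with a starved iteration
budget instead.

What the phantom does **not** emulate: respiratory motion and registration
error, B1/flip-angle inhomogeneity, Rician noise floors at low SNR, bolus
dispersion/delay between aorta and tumour, and spatial parameter
heterogeneity within zones. Passing tests therefore validate the numerics
and the categorization logic, not robustness to those acquisition effects.

## Problem sizes and numerical choices

The bundled phantom runs (32×32×3, 1848 masked voxels, 181 frames) complete
in tens of seconds each on one CPU; the categorization confusion diagonal
is ≥ 95 % per zone at design noise (typically ≥ 97 %), noiseless category
agreement is exact, and the design-noise median relative Ktrans error in
the clean zone is ≈ 6 %. Ties and degenerate inputs: all-invalid traces
categorize as GD_NOT_REAL (the s.d. check skips them); an all-zero trace
fits to Ktrans ≈ 0, vp ≈ 0 and converges; scipy solver status 4 (step and
residual tests met simultaneously) is recorded as `step_tol`.

## Configuration

One validated YAML file (unknown keys rejected) carries acquisition
settings, thresholds (defaults exactly the published settings: 5 mM,
0.01 mM, 10 min⁻¹, 15 min⁻¹, limits 1.0, tolerance 1e−6, 100 iterations),
r1 = 3.6 l·mmol⁻¹·s⁻¹, dose = 0.1 mmol/kg, hematocrit = 0.42, AIF form and
parameters, solver controls, palette and seed. Every run writes a log with
the exact thresholds, config hash and seed.
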