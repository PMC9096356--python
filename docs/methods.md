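# Methods

This note records the models behind each estimator, the tunable parameters
and their defaults, what the synthetic generator does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Facial geometry and monocular distance

All ROIs derive from a face bounding box `(x_box, y_box, w_box, h_box)`, the
eye-line ordinate `y_eye`, and head pose `(θ_pitch, θ_yaw)` produced by an
external detector/pose solver; the package consumes these as fixtures and
does not perform detection itself. The forehead ROI is
`[x_box, x_box+w_box) × [y_box, y_eye)`; the mask ROI is
`[x_box+0.1w, x_box+0.9w) × [y_box+0.5h, y_box+h)`. Pixel rectangles are
half-open, 0-based; fractional bounds round half-away-from-zero. An ROI
that rounds empty raises rather than silently degenerating.

Subject distance comes from the face-box diagonal through the empirical
power law `D = k·L^(−p)`, defaults `k = 140.22`, `p = 1.14` (D in metres, L
in pixels). These constants are overridable and refittable from `(L, D)`
samples by log–log least squares (`fit_distance_law`). The diagonal is
pose-corrected first, `L_corr = √((w/cos θ_yaw)² + (h/cos θ_pitch)²)`:
rotation foreshortens the apparent box, so the apparent extents are divided
by the cosines to recover the frontal extents. Angles at or beyond 90° are
rejected. The power law is applied to the corrected diagonal.

## Thermal compensation

Model: the measured forehead temperature is the true skin temperature plus
a bias linear in distance whose slope depends linearly on ambient
temperature,

```
T_IR = T_true + (a·T_amb + b)·(D + c) − d
```

so compensation subtracts the fitted bias. Parameters: `a` (°C·m⁻¹·°C⁻¹),
`b` (°C·m⁻¹), `c` (m, an additive distance shift), `d` (°C, global offset).
With all parameters zero the compensation is the identity; it is affine in
`T_IR` with unit coefficient by construction. Published constants for this
family exist but are typographically unreliable in their source; they are
retained (converted to metre units) as `ThermalCalibration.reported_constants()`
for reference, and all real use goes through refitting.

Fitting (`ThermalCompensationModel.fit()`) is two-stage ordinary least
squares: (1) bias vs distance within each ambient level (levels grouped by
rounding to 0.01 °C) yields per-level slopes `s_k` and intercepts `i_k`;
(2) `s_k` vs `T_amb` yields `(a, b)`, and `i_k` vs `s_k` yields `(c, −d)`
since `i_k = s_k·c − d`. The design needs ≥ 2 ambient levels and ≥ 2
distinct distances per level; rank-deficient designs raise naming the
missing factor. When the per-level slopes are all equal, `c` is
unidentifiable and set to 0. On noiseless data generated from the model the
fit is exact to machine precision (verified in the tests). Results carry
per-stage R², residuals and a `summary()` table.

The ROI statistic is the arithmetic mean by default (max and 95th
percentile are selectable); the compensated range is 0.5–5 m, outside which
the model extrapolates with a warning. Fever screening is strict:
`T_comp > baseline + margin`, margin default 0.5 °C, baseline a
population-cohort mean.

## Respiratory rate

The raw breathing signal is the per-frame mean of the mask-ROI pixels,
min–max normalized over the record (a constant record is returned raw with
the `normalized` flag unset). Missing detections reuse the previous ROI for
up to 5 consecutive frames.

**FFT estimator** — detrend (linear), zero-phase Butterworth low-pass
(order 4, cutoff 1.0 Hz — comfortably above the tachypnea range, removing
high-frequency sensor noise), magnitude spectrum, argmax over the
physiological band 0.08–0.7 Hz (≈5–42 BPM; keeps drift and cardiac
harmonics out). Bin width is `1/t_w` Hz, so the minimum window for a 3 BPM
resolution is 20 s; off-bin rates report the nearest bin (an optional
zero-padding factor interpolates the spectrum but is off by default so the
stated resolution is honest). A spectral peak under 5× the median in-band
magnitude is flagged low-confidence; an all-zero or flat input is
indeterminate, never a number.

**P2P estimator** — the same low-pass, then drift removal by subtracting a
centred 10 s moving average whose trend is constant-extended at the window
edges (padding the *signal* would let the trend track the edges and erase
edge extrema). Peaks and troughs are detected with minimum prominence
0.2× the interquartile range and minimum spacing 60/RR_max; the rate is
60 over the mean of pooled peak–peak and trough–trough intervals. The
minimum window is one period of the slowest breath (10 s at 6 BPM), which
puts that regime's extrema at or near the window edges, so three
refinements apply there: window-edge samples count as extrema when the
signal leaves them in the falling/rising direction and they are within 90 %
of the global extremum; if fewer than two extrema are found the prominence
threshold is halved once (edge-adjacent extrema have edge-clipped
prominence); and as a last resort a single peak–trough pair — or the global
max/min pair — is read as half a period. Fewer extrema than that is
indeterminate. The P2P reading of "average peak-to-peak value" as a mean
*interval* is the only dimensionally consistent one and is what is
implemented.

Tachypnea is strict: RR > 20 BPM. The Nyquist bound `60·f_s/2` (900 BPM at
30 Hz) is exposed as `max_measurable_rr`. The respiratory heat-exchange
helper implements the standard estimate
`C_res + E_res = 0.0014·M·(34 − T_amb) + 0.0173·M·(5.87 − P_a)` (M in W/m²,
P_a in kPa).

## Heart rate (POS)

Channels are fixed as (r, g, b) = (630, 532, 465 nm) and label-validated,
because the projection is order-sensitive. The pipeline is: temporal
normalization (divide by the window mean — exact intensity invariance),
projection `S₁ = g − b`, `S₂ = −2r + g + b` (both rows of `P` sum to zero,
annihilating common-mode specular signal), and alpha tuning
`h = S₁ + (σ(S₁)/σ(S₂))·S₂` (σ(S₂) = 0 falls back to `h = S₁` with a
warning). POS runs per sliding window of 1.6 s with mean-centred
overlap-add — the convention of the rPPG literature; a single-pass variant
over the whole record is available (`sliding=False`).

HR estimation band-passes the pulse to 0.7–4 Hz (42–240 BPM, Butterworth
order 4 zero-phase) and takes the argmax of a Hann-windowed periodogram,
zero-padded 4× for finer peak localisation (padding interpolates; the true
resolution remains 1/latency). Default latency 10 s, matching the quick
screen. Tachycardia is strict: HR > 100 BPM. A constant input yields an
identically-zero pulse and an indeterminate estimate.

## Synthetic scenes

The generator emulates exactly the features the estimators rely on, under
the conditions the methods were characterised at (30 Hz cameras, 0.5–5 m,
19–28 °C ambient, 6–35 BPM breathing, 45–150 BPM heart rates):

* **Breathing**: `A·cos(2πft − φ)` around a 32 °C mask mean (A default
  0.3 °C — the oscillation amplitude is not physically established, so it
  is a parameter, not an assertion), optional phase-locked-harmonic
  "fast-exhale" shape, drift at a random 0.005–0.02 Hz with default
  amplitude 0.1 °C, i.i.d. Gaussian noise (default sd 0.03 °C = 10 % of the
  oscillation amplitude). Exhalation peaks are maxima.
* **Thermal frames**: background at ambient; face at skin − 1 °C; forehead
  at the true skin temperature plus the bias model; mask pixels carry the
  breathing trace; per-pixel Gaussian noise. The generator's default bias
  (slope −0.26 °C/m at 19 °C, −0.05 °C/m at 28 °C ambient, c = d = 0) is
  chosen so uncompensated errors reach ≈1.3 °C at 5 m in a cold room — the
  worst case of the characterised conditions. The generator deliberately
  uses the same parametric family the compensator fits: round-trip recovery
  is then well-posed, and this circularity is acknowledged — passing it
  shows correct inversion, not that real thermal bias is exactly linear.
* **Detection fixtures**: the pose-corrected diagonal exactly inverts the
  distance power law; the box is a 3-4-5 rectangle on that diagonal with
  the eye line at 40 % height, foreshortened by the pose cosines.
* **Reflectance**: `I₀·m_k·(1 + a_p·w_k·pulse(t) + a_s·s(t))` + noise, with
  pulsatile weights (0.43, 1.0, 0.69) for (r, g, b) — green-dominant, as in
  skin — pulse = fundamental plus a 0.2-weight second harmonic, and `s(t)`
  a two-component 0.05–0.4 Hz disturbance of unit sd shared identically
  across channels. Default a_p = 0.01 (≈1 % green modulation, typical of
  rPPG), noise 0.2 % of the channel mean.

Not emulated: photorealistic faces, emissivity/radiometric camera physics,
motion-induced ROI jitter, channel-dependent specular colour, and
non-stationary heart/breathing rates. Passing tests therefore demonstrate
correct signal processing and model inversion under the stated noise model,
not field performance on human subjects.

All generators consume a single seeded `numpy` Generator; fixed seed means
bit-identical output. Benchmark ensembles (`vitalcam.experiments`) derive
per-trial sub-seeds via `SeedSequence` spawning.

## Benchmark problem sizes

The standard characterisation ensembles use 30 traces of 35 s at 30 Hz for
respiratory rate, a 4-distance × 4-ambient grid with 10 replicates per cell
(half for fitting, half held out) for temperature, and 30 traces of 10 s
for heart rate. The residual distance-slope check uses 50 replicates per
cell: with sensor noise of 0.1 °C, the slope estimate's standard error at
10 replicates (≈0.01 °C/m) is the same order as the 0.02 °C/m criterion,
whereas at 50 it is ≈0.005, so the check measures the compensator rather
than the noise floor.

## Known limitations

* The distance power law and its constants come from one camera geometry;
  other optics require refitting (`fit_distance_law`).
* The thermal-bias family is linear-in-distance by design; strongly
  non-linear atmospheric or optical effects are outside it.
* P2P at the 10 s minimum window on ≤8 BPM breathing rests on the
  edge-extremum refinements above; they assume one dominant oscillation in
  the window.
* POS assumes a fixed, skin-only ROI; skin segmentation and motion
  tracking are out of scope, as are SpO₂ and blood pressure.
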