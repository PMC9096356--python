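# vitalcam

Contactless vital-sign estimation from thermal and tri-channel facial video,
for screening settings where touching the patient (or even standing near
them) is undesirable: triage tents, infectious-disease wards, mobile
tele-examination platforms. From a face bounding box, an eye-landmark line
and head-pose angles — supplied by any external face detector — the package
estimates three vitals and screens each against a clinical threshold:

* **Skin temperature** from a forehead region of a radiometric thermal
  frame, *without a black-body reference*. Uncooled IR readings drift with
  subject distance `D` and ambient temperature `T_amb`; the bias is modelled
  as linear in distance with an ambient-dependent slope and subtracted:

  `T_comp = T_IR − (a·T_amb + b)·(D + c) + d`

  Distance itself is monocular, from the pose-corrected face-box diagonal
  `L_corr = √((w/cos θ_yaw)² + (h/cos θ_pitch)²)` through the power law
  `D = 140.22 · L_corr^(−1.14)` (metres, pixels). Fever screen: compensated
  temperature above a population baseline plus margin.

* **Respiratory rate** from the facemask region of the thermal video: the
  mask traps warm exhaled air, so its mean temperature oscillates at the
  breathing frequency (exhalation peaks, inhalation troughs). Two
  estimators: **P2P** (mean interval between successive extrema of the
  detrended signal; minimum window 60/RR_min = 10 s for 6 BPM) and **FFT**
  (in-band spectral argmax; bin width 1/t_w, so a 3 BPM resolution needs a
  20 s window). The Nyquist bound caps measurable RR at 60·f_s/2 = 900 BPM
  at 30 Hz. Tachypnea screen: RR > 20 BPM.

* **Heart rate** from mean forehead intensities of three monochrome cameras
  (630/532/465 nm) via the plane-orthogonal-to-skin (POS) rPPG method:
  temporally normalize `C_n(t)`, project with `P = [[0,1,−1],[−2,1,1]]`
  (rows sum to zero, so common-mode specular reflections cancel), combine
  `h = S₁ + (σ(S₁)/σ(S₂))·S₂`, then take the cardiac-band spectral peak.
  Tachycardia screen: HR > 100 BPM.

A synthetic-scene generator produces thermal sequences, breathing traces and
dichromatic reflectance traces with known ground truth, so the whole
pipeline is testable end to end without any recording.

## Worked example

```python
from vitalcam import (SceneConfig, generate_thermal_sequence,
                      generate_reflectance_traces, default_scene_calibration,
                      run_screening, AmbientConditions)

cfg = SceneConfig(duration_s=12, true_rr_bpm=18, true_hr_bpm=72,
                  true_skin_temp_c=34.2, ambient_temp_c=19.0,
                  distance_m=2.0, seed=11)
seq, dets, gt = generate_thermal_sequence(cfg)
traces, _ = generate_reflectance_traces(cfg, a_s=0.02, noise_rel=0.002)
report = run_screening(seq, dets, traces, AmbientConditions(19.0),
                       default_scene_calibration())
```

which prints, formatted:

```
distance        : 2.00 m
skin temperature: 33.68 °C raw -> 34.20 °C compensated (fever: False)
respiratory rate: 18.0 BPM via P2P@10s (tachypnea: False)
heart rate      : 72.0 BPM at 10s latency (tachycardia: False)
```

The raw reading at 2 m in a 19 °C room is biased half a degree cold; the
fitted compensation recovers the true 34.2 °C. The quick-screen mode uses
only the first 10 s of input (P2P respiratory rate, 10 s heart-rate
latency); `ScreeningConfig(mode="monitor")` instead emits one FFT
respiratory-rate estimate per sliding 30 s window.

The same pipeline is scriptable from the shell:

```sh
vitalcam simulate --out scene/ --rr 18 --hr 72 --ambient 19 --seed 11
vitalcam screen --thermal scene/thermal.npz --detections scene/detections.json \
                --traces scene/traces.csv --ambient 19 --out report.json
```

Calibration fitting is exposed statsmodels-style:

```python
from vitalcam import ThermalCompensationModel
results = ThermalCompensationModel(samples).fit()   # (t_ir, true_temp, t_ambient, d_m) rows
print(results.summary())                            # params, R², residual MAE
results.compensate(t_ir=33.1, ambient=AmbientConditions(21.0), d_m=3.0)
```

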