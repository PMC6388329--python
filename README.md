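# pulsesim

An in-silico radial pulsation simulator: a lumped-parameter, closed-loop
hemodynamic model of a bench-top pulse generator that reproduces and controls
age-dependent **radial artery pressure waveforms** — the early-systolic peak
(P1), the late-systolic shoulder (P2), and the dicrotic notch — together with
the analytics used to evaluate them.  It is intended for people developing or
testing wearable blood-pressure sensor algorithms who need reproducible,
controllable reference waveforms instead of clinical recordings.

## The model

The closed fluid loop mirrors four bench modules:

* **Left ventricle** — a piston cylinder displacing up to 80 mL every
  750 ms (half-sine ejection, mirrored withdrawal), with a mitral check
  valve cracking at 14 mmHg and an aortic check valve such that ejection
  begins near 100 mmHg LV pressure.  The aortic branch carries the momentum
  of its fluid column, so end-systolic closure cuts off a still-moving flow
  and rings the arterial compartment — the dicrotic incisura.
* **Aorta** — a pressure node combining the silicone-tube compliance with a
  trapped-air **compliance chamber** (isothermal air spring, 0–20 mL).  The
  air volume is the arterial-stiffness control.
* **Wave reflection** — the forward wave returns from an
  abdominal-bifurcation surrogate with coefficient Γ after a round-trip
  delay τ, and the echo rebounds once more off the closed aortic valve.
  The radial pressure is

  `p(t) = p_res + pf(t) + Γ_eff·pf(t−τ) + κ·Γ_eff²·pf(t−2τ)`

  with `Γ_eff = Γ / (1 + V_air/V_atten)`: emptying the chamber strengthens
  the reflected wave, exactly the age/stiffness trend.
* **Peripheral resistance and reservoir** — two throttleable return paths
  into an ideal constant-pressure reservoir (80 mmHg) that clamps the
  diastolic baseline.

The loop is integrated with fixed-step RK4 to a periodic steady state
(successive radial cycles within 0.5 mmHg).  The headline index is the
**radial augmentation index**

```
AI = 100 × (P2 − diastolic) / (P1 − diastolic)   [%]
```

Shipped age presets set the air spring to its maximum / medium / minimum
(20 / 10 / ~0 mL) with reflection parameters calibrated once so the
steady-state radial AI equals **64 % / 75 % / 91 %** for the young /
middle-aged / older-adult groups.

## Worked example

```python
from pulsesim import (age_preset, run_to_steady_state, detect_features,
                      radial_ai, pulse_pressure, build_pv_loop)

res = run_to_steady_state(age_preset("older"))
f = detect_features(res.radial)
print(f"AI = {radial_ai(f):.1f}%  PP = {pulse_pressure(res.radial):.1f} mmHg")
print(f"diastolic = {res.radial.p.min():.1f} mmHg")
loop = build_pv_loop(res)
print(f"stroke volume = {loop.stroke_volume:.1f} mL, "
      f"ejection onset = {loop.ejection_onset_pressure:.1f} mmHg")
```

prints

```
AI = 91.0%  PP = 61.7 mmHg
diastolic = 79.6 mmHg
stroke volume = 78.1 mL, ejection onset = 100.1 mmHg
```

— the older-adult waveform has the published augmentation index (91 %), the
diastolic foot sits on the 80 mmHg reservoir clamp, just under the 80 mL
piston stroke leaves through the aortic valve each beat, and ejection begins
at the ~100 mmHg opening pressure of the aortic check valve.

The same things are available from the shell:

```bash
pulsesim simulate --preset older --out run/       # waveform CSVs + manifest
pulsesim analyze --in run/radial.csv --period 750 # fiducial points as JSON
pulsesim sweep --param opening --values 1.0,0.7,0.4 --out sweep/
pulsesim fixtures --group young --out young.csv   # synthetic test waveform
pulsesim calibrate --preset middle --target-ai 75 --out cal.yaml
```

Throttling the resistance-valve openings raises the afterload: the sweep
shows stroke volume falling and systolic peak rising, the classic
pressure–volume-loop response.

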