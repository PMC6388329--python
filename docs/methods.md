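# Methods

## Model structure

The simulator is a 0-D (lumped-parameter) closed fluid loop plus a single
delayed reflection line.  Seven states are integrated: LV pressure, LV fluid
volume, chamber stored volume, aortic-branch flow, radial-branch flow,
radial-compartment volume, and reservoir volume (bookkeeping).  A 1-D or 3-D
fluid–structure treatment is deliberately out of scope: the quantities of
interest (fiducial-point geometry, augmentation index, pulse pressure,
PV-loop direction) are phenomena a lumped network reproduces at desk scale.

**Left ventricle.**  The piston drive is a half-sine over the systolic
window `Ts = systolic_fraction × cycle_period` whose integral is exactly the
stroke volume, followed by the time-mirrored withdrawal half-sine over
`[Ts, 2Ts]` and a dwell.  The mirror matters: it collapses LV pressure
promptly after ejection, which is what closes the aortic valve sharply (see
*Dicrotic notch* below).  A small LV compliance (`lv_compliance`,
0.05 mL/mmHg) turns LV pressure into a differential state and represents
cylinder/seal elasticity; it also makes the ejected volume slightly less
than the piston displacement (≈78 of 80 mL) and gives the stroke volume its
afterload sensitivity.

**Valves.**  The mitral valve is the algebraic check-valve law: zero at or
below the 14 mmHg cracking differential, linear above it, with a C1 cubic
blend over a configurable band (default 0.5 mmHg) for integrator stability;
tests compare the blended law against the exact piecewise oracle.  The
aortic valve is a momentum branch: `L_ao·dQ/dt = ΔP − ΔP_crack − R·Q` while
open, with a one-sided gate (only the nonnegative part of the state moves
fluid; the state is clamped at zero on closure, and a closed valve below the
threshold stays closed).  The ~100 mmHg opening pressure is interpreted as
LV gauge pressure at ejection onset against the 80 mmHg diastolic baseline,
i.e. a 20 mmHg cracking differential — consistent with both published
numbers at once.

**Aorta node.**  Structural (silicone-tube) compliance in parallel with the
trapped-air spring.  The gas law is isothermal by default
(`P·V = const`; `polytropic_exponent` generalizes to `P·V^n`), referenced
at the 80 mmHg diastolic set point.  The node pressure is recovered from the
stored volume by the closed-form positive root of the resulting quadratic
(Newton iteration for n ≠ 1), so the stored volume is a true state and the
sum of all volume-state derivatives is identically zero — RK4 then conserves
loop volume to round-off (measured drift ~5e-13 mL over a run; the
acceptance budget is 1e-6 × stroke volume per cycle).

**Periphery.**  Two return paths to the reservoir: a resistive direct
return (the aortic resistance valve, `aortic_return_resistance / opening`)
and the radial branch — blood-column inertance and a small characteristic
resistance feeding the radial compartment, which drains through the
peripheral resistance valve.  The *radial site* forward wave is the
pressure of this distal compartment.  The reservoir is an ideal
constant-pressure boundary at 80 mmHg; this is what clamps the steady-state
radial minimum to 80 ± 2 mmHg across presets.

**Wave reflection.**  The radial pressure is assembled from the stored
forward-wave trace after integration:

    p_radial(t) = p_res + pf(t−τ_r) + Γ_eff·pf(t−τ_r−τ) + κ·Γ_eff²·pf(t−τ_r−2τ)

with radial transit delay τ_r, bifurcation round-trip delay τ, and a second
tap for the echo's rebound off the closed aortic valve (κ =
`valve_rebound`, default 0.8).  The compliance chamber absorbs part of the
returning wave, so the effective reflection magnitude is

    Γ_eff = Γ / (1 + V_air / V_atten),   V_atten = 40 mL.

This mapping is the arterial-stiffness control: with every other setting
fixed, emptying the chamber strengthens the echo and raises the
augmentation index monotonically.  The reflection is superposed on the
forward wave but does not feed back into the loop states — a one-way
simplification that is accurate when the reflected wave is a small fraction
of the forward wave at the aortic valve, and the main known limitation of
the model.

## Dicrotic notch

The incisura emerges from two model ingredients, both physical: (1) the
mirrored piston withdrawal collapses LV pressure within milliseconds of
end-systole, so the momentum branch is cut off while still carrying
~60 mL/s; (2) the abrupt inflow stop excites the inertance–compliance
oscillation of the radial branch (≈110 rad/s, damping ratio ≈0.3), whose
first trough — a 2–3 mmHg dip ~25 ms after closure — is the notch, and
whose rebound plus the valve-rebound echo forms the dicrotic wave.  A purely
algebraic valve with a slow withdrawal produces no notch: the half-sine
drive then tapers flow to zero smoothly and nothing rings.

## Age presets and calibration

Air volumes follow the published settings (maximum ≈20 mL for young, medium
≈10 mL, minimum ≈0 mL for older).  The remaining free parameters per group —
Γ and τ — were fixed once by `calibrate()` (deterministic bisection of the
simulated, detector-measured AI against the published values) and frozen:

| group  | V_air (mL) | Γ       | τ (ms) | Γ_eff | steady-state AI |
|--------|-----------|---------|--------|-------|-----------------|
| young  | 20        | 0.19136 | 160    | 0.128 | 64.0 %          |
| middle | 10        | 0.40798 | 140    | 0.326 | 75.0 %          |
| older  | 0         | 0.58863 | 140    | 0.589 | 91.0 %          |

Effective reflection magnitude rises and (non-strictly) the delay falls with
age, matching the physiology of rising pulse-wave velocity and reflected-wave
magnitude.  The default `SimulatorConfig` equals the middle-aged operating
point.  With V_air = 0 the chamber is rigid; no floor volume is needed
because the structural compliance keeps the node well-posed (the standalone
gas-law operation treats V_air = 0 as a bypass).

Remaining constants (resistances, inertances, compliances) are hardware
surrogates chosen once to give a physiological operating point — radial
pulse pressure ≈60 mmHg at the default half-open valves, LV systolic peak
≈160–190 mmHg, diastolic decay completing within the beat — and are exposed
in the configuration for users who want a different bench geometry.

## Fiducial-point detection

Cycles are delimited at the diastolic foot (the latest sample of the
pre-upstroke minimum run); single-period records from the converged
simulator are extended periodically.  The cycle is smoothed with a
Savitzky–Golay filter (window 5 % of the cycle, order 3, wrap mode).
Classification then proceeds on the local maxima with prominence ≥10 % of
pulse pressure:

* **≥3 prominent maxima** — P1, peaking P2 and dicrotic wave all resolved;
  the notch is the most prominent minimum between P2 and the dicrotic wave.
* **2 prominent maxima** — ambiguous: the second may be a peaking P2 *or*
  the dicrotic wave behind a non-peaking shoulder.  If the valley between
  them dominates every later minimum (×2 in prominence) and lies below 60 %
  of pulse height it is taken as the notch and the shoulder is searched
  before it, falling back to the P2 interpretation if no shoulder exists.
* **1 prominent maximum** — the notch is the most prominent post-systolic
  minimum (the closure incisura); the late-systolic shoulder is searched
  between peak and notch.

A non-peaking shoulder is localized as a small-prominence local maximum or,
failing that, the slope plateau — the interior maximum of the first
derivative of the smoothed signal — between the early peak and the notch.
This replaces the fourth-derivative zero-crossing rule sometimes used in
tonometry; at this sampling the two agree where both are defined and the
slope-plateau rule is markedly more robust.  A waveform that decays
monotonically from a single peak has no post-systolic minimum and raises a
feature-absent error naming `late_systolic`.

AI is computed from pulse pressures above the diastolic foot, so it is
exactly invariant under affine pressure transforms; detection thresholds
are all relative to pulse pressure for the same reason.  When the period is
unknown it is inferred from the median spacing of high-prominence systolic
peaks (requires ≥2 cycles); autocorrelation was rejected because the
baseline-heavy pulse shape gives it spurious partial-alignment peaks.

## Synthetic fixtures

`synth_waveform` renders a diastolic baseline plus periodically extended
Gaussian bumps (early-systolic, reflected, dicrotic) with optional seeded
Gaussian noise — bitwise reproducible.  `age_fixture` ships bump sets whose
analytic AI is the published value by construction (reflected amplitude =
AI/100 × early amplitude, components well separated) with pulse pressure
rising with age (40/45/50 mmHg).  These fixtures exercise the detector with
exactly known answers; they emulate only the fiducial geometry and the age
trend of averaged tonometry waveforms — not beat-to-beat variability,
baseline drift, sensor coupling, or morphology outside the three-bump
family — so detector tests passing on them demonstrate correct geometry
recovery, not field robustness on raw recordings.

## Numerics

Fixed-step classical RK4 at dt = 0.5 ms (validated dt ≤ cycle/100); one
steady-state run integrates ≤30 cycles of 1500 steps and completes in well
under a second, so the whole test suite and the acceptance script run in
seconds.  Convergence: max-norm difference between consecutive radial
cycles < 0.5 mmHg after ≥3 warm-up cycles (typically met at cycle 3);
non-convergence is flagged, not raised.  Step-halving agreement of the
steady-state radial cycle is ~1e-4 mmHg (budget 0.2 mmHg); the valve-closure
clamp is the only sub-grid event and contributes below that level.  The
valve smoothing band (0.5 mmHg) regularizes the mitral corner; the aortic
momentum gate needs no smoothing.  Reflection delays are rounded to the
integration grid.  All pressures are gauge mmHg except inside the gas law;
time is ms externally and seconds inside the integrator; flows are mL/s.

## Known limitations

* Reflection is one-way (no afterload feedback from the reflected wave onto
  the ventricle); afterload experiments therefore operate through the
  resistance valves, as on the bench.
* The reflected wave uses two taps of a geometric bounce series; further
  bounces are truncated.
* The piston drive is kinematic — no motor dynamics, residual vibration, or
  turbulence (hardware-only concerns).
* The detector is tuned for single-notch pulse morphologies with AI below
  ~100 %; merged P1/P2 domes (AI ≳ 100 %) shift the prominent-maximum
  classification and are outside the calibrated range.
* Detected AI is reported for one steady-state beat; in a converged periodic
  run every beat is identical, so no ensemble averaging is needed.
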