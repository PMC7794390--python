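# Methods

This note documents the models, parameter choices and numerical
decisions behind `subglot`, and what the synthetic data do and do not
emulate.

## Glottal source

The flow is a pulse train: within each cycle the open phase (fraction
OQ of the period) carries a raised-cosine pulse split into an opening
half-cosine of width `skew·OQ·T` and a closing half-cosine of width
`(1−skew)·OQ·T`; the closed phase sits exactly at the leak flow.  Each
half-cosine lobe averages one half of the peak over its width, so the
cycle mean is `leak + ½·OQ·(peak − leak)` for **any** skew — the peak is
solved in closed form from the requested mean flow, and a final
AC-only rescale removes the sub-0.1 % bias of the partial last cycle,
leaving the sample mean exact and the closed-phase level untouched.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| `f_o` | 106 Hz (resonant) / 126 Hz (anechoic) | the steady-phonation pitches observed in the two tract conditions |
| `mean_flow` | 4.0e-4 m³/s | the 400 mL/s steady operating point |
| `open_quotient` | 0.6 | mid-range for adducted excised-larynx phonation; a calibration choice (the bench larynges' true OQ is unknown) |
| `leak_flow` | 1.0e-4 m³/s | excised larynges rarely seal; chosen together with OQ so the anechoic AC excursion at 400 mL/s lands near the observed ~800 Pa |
| `skew` | 0.65 | speed quotient ≈ 1.9 — glottal flow closes faster than it opens; a symmetric pulse would under-excite the tube resonances that the measured waveforms clearly ring at |
| `sample_rate` | 50 kHz | desk scale; the bench's 200 kHz adds nothing below 10 kHz |
| `jitter_cv` | 0 | deterministic by default; lognormal cycle-length jitter available, seeded |

Cycle-length jitter multiplies each period by a unit-mean lognormal
factor; with jitter off the generator is bit-reproducible.

## Level-2 (load-on-oscillator) effects

No vocal-fold dynamical model is in scope, so the reactions of the
oscillating folds to the acoustic load are *declared*, not emergent.
`Level2Config` holds them:

* `fo_anechoic` = 126 Hz, `fo_resonant` = 106 Hz — the pitch drop under
  a resonant load.
* `offset_effect` = 0.89 — offset threshold pressures 11 % lower in the
  resonant condition; `onset_effect` = 1.0 (onsets unaffected).
* `amplitude_effect` = 1.4 — in the resonant condition the open
  quotient is compressed by this factor, which at fixed mean flow
  deepens the flow modulation by the same factor.  This encodes the
  observation that subglottal oscillation amplitudes roughly double
  under a resonant load.  It cannot be a pure filter effect: with a
  fixed-flow source the fundamental is *attenuated* by |cot(βL)| < 1
  whenever f_o lies above f_R1/4 (near the first antiresonance), so the
  linear waveguide alone yields resonant/anechoic excursion ratios of
  only 0.8–1.4 for the lower resonance settings.  Treating the
  amplitude change as a Level-2 property of the source, like the f_o
  and threshold changes, reproduces the observed ratios (≈ 1.8–3.5
  across the six settings).
* `egg_ripple_gain` = 1e-3 au/Pa — the EGG contact pulse is modulated
  by the AC subglottal pressure, weighted by the contact pulse itself
  so the waveform stays continuous at the contact edges and zero in the
  open phase.  At the default gain the low-resonance settings produce
  two contact-phase maxima per cycle, each within 1 ms of a subglottal
  pressure peak; the weighting (rather than a binary contact mask) is
  deliberate — pressure can only modulate contact area in proportion to
  how much contact there is.

## Subglottal waveguide

Characteristic impedance Z₀ = ρc/A with ρ = 1.18 kg/m³ and a 24-mm
bore.  Two terminations:

* **anechoic** — Z(f) = Z₀, applied directly in the time domain (exact,
  no FFT), giving a subglottal pressure that is the inverted flow with
  perfectly flat closed-phase plateaus;
* **closed piston** — Z(f) = Z₀·coth(Γ(f)L), Γ(f) = k√f + j2πf/c,
  applied by full-signal FFT with the signal padded to the next power
  of two, 10-ms raised-cosine edge tapers (the first/last 10 ms of the
  output are fade regions), and the DC bin forced to zero — DC is
  carried by the glottal-resistance term.

The in-tube **effective sound speed** defaults to 372 m/s, fitted as
the mean of 2·L·f over the four mid-range piston settings of the
hardware's printed length↔f_R1 table (46.5 cm/400 Hz, 37/500, 31/600,
27/700, giving 372.0, 370.0, 372.0, 378.0).  The two end settings
disagree (55 cm/330 Hz → 363; 25 cm/800 Hz → 400), which points to
unmodelled end effects; `fit_effective_sound_speed` logs the per-pair
values, and the 330/800 Hz tubes built from the ideal mapping fall
slightly outside the printed hardware length range (a warning, not an
error).

The **wall-loss scale** k defaults to 0.01 Np·m⁻¹·Hz⁻½, giving a first-
resonance quality factor Q = π/(2kL√f) ≈ 19 at the 500-Hz setting.
Classical viscothermal boundary-layer theory for a clean rigid 24-mm
duct gives k ≈ 0.0025 (Q ≈ 75); a real rig with a mounted larynx,
sensor port and side branch is lossier, and Q near 20 is typical of
measured airway resonances.  The constant is exposed in `TubeSpec`.

The subglottal pressure is p = R_g·u_dc − Z*(u − u_dc).  For steady
signals u_dc is the global mean; for flow sweeps, whose operating point
moves, `dc_split_hz` (10 Hz in the sweep pipeline) splits the flow into
a quasi-static part, sent through the DC resistance, and an AC part,
sent through the impedance.  The minus sign makes an outgoing flow
pulse a subglottal rarefaction (the "inverted flow" waveform).
Per-condition glottal resistances are calibrated to the steady
operating points: anechoic 6.25e6 Pa·s·m⁻³ (25 hPa at 400 mL/s),
resonant 5.0e6 (≈ 20 hPa — the load alters the oscillation and with it
the effective DC resistance).

## Radiation

Free-field simple source: p(t) = ρ/(4πr)·du/dt delayed by r/c, with
r = 0.10 m, room sound speed 350 m/s.  A baffled variant (2πr) adds
6 dB.  The free-field convention is the default because it reproduces
both the ≈ −60 dB subglottal-to-radiated level difference in the
50–200 Hz band and the per-harmonic transfer ratio
A_L(f) = 20·log₁₀(f·A/2rc).

## Measurement pipeline

* **Frequency response** — the microphone signal is cut into
  one-impulse-period windows, averaged in the time domain (noise falls
  10·log₁₀ N dB for N windows), FFT'd, and divided by the loudspeaker
  response (dB subtraction, floor-clamped).  The simulated measurement
  plays 100 impulses at 1/s through a gentle band-pass loudspeaker model
  (first-order corners 120 Hz / 5 kHz) at 20 dB SNR.
* **Spectra** — 4-Hz resolution: 0.25-s periodic-Hann windows, 50 %
  overlap, magnitude-averaged, maximum normalized to 0 dB.  The window
  and overlap are this package's choice.
* **SPL** — 10-Hz 4th-order zero-phase high-pass, squared, one-pole
  exponential detector with 125-ms time constant ("fast"), referenced
  to 20 µPa, floored at −40 dB.  `steady_db` is the median over the
  second half of the track (past the detector's settling).
* **f_o** — frame-wise normalized autocorrelation (100-ms frames, 25-ms
  hop, 30–400 Hz search), voicing if the best peak exceeds 0.5 and the
  frame is not silent; among peaks within 90 % of the best, the
  shortest lag wins (octave-error guard); parabolic interpolation
  refines the lag.  This substitutes a generic pitch tracker for the
  dedicated pitch software used at the bench; only median f_o values
  are consumed downstream.
* **Thresholds** — automated replacement for manual cursor placement:
  band-pass 30–1000 Hz, 25-ms RMS envelope, oscillation episodes =
  envelope above 5 % of its sweep maximum for ≥ 75 ms, with a 0.8
  hysteresis factor for release and a 1-Pa absolute floor (phonation
  drives the subglottal AC to hundreds of Pa, so ramp leakage never
  qualifies).  The threshold pressure is the 10-Hz-low-passed pressure
  averaged over 50 ms before the onset / after the offset, in hPa.  On
  synthetic sweeps the detector recovers the gating thresholds within
  ±0.5 hPa; its parameters are tuning choices validated only against
  synthetic truth.
* **Inverse filtering** — the no-vocal-tract path: anti-aliased
  resampling to 6 kHz, cumulative trapezoidal integration, 4th-order
  zero-phase 20-Hz high-pass against drift.  Output scale is arbitrary;
  on the default anechoic simulation it correlates with the inverted
  subglottal pressure at r > 0.99 after lag alignment.
* **Units** — pressures calibrated in cm H₂O convert to hPa by the
  exact factor 0.981.

## Threshold statistics

The reference model is OLS on log threshold pressure with categorical
fixed effects for condition, larynx, sweep and repetition (the smallest
model that adjusts for all design factors; no random effects, no
interactions).  The condition coefficient β maps to the percent scale
as (1 − e^β)·100, positive when the resonant condition lowers the
pressure; the asymmetric CI transforms the same way.  The log link is
chosen because the condition effect is multiplicative in the generator
and reported as a percent with an asymmetric interval.  The model
formula is embedded in every `EffectEstimate` for auditability.  Two
planned tests (onset, offset), no multiplicity correction.

The threshold **generator** draws each pressure as
base·(condition factor)·lognormal(cv), unit-mean noise with cv = 0.05
by default.  At the study design (3 larynges × 2 conditions × 3 sweeps
× 2 repetitions = 36 rows), the regression recovers the generating 11 %
offset effect to within ±3 % averaged over 50 seeds, and the 95 % CI
covers the generating value in ~95 % of 200 seeded tables.

## Flow-sweep experiment

Each sweep ramps the mean flow 0 → 550 mL/s → 0 (6 s up, 2 s hold, 6 s
down at 20 kHz — the bench took ~1 min per sweep; the compressed
profile preserves every measured quantity because gating depends on
pressure, not time).  Oscillation gates on when the quasi-static
pressure R_g·m(t) first exceeds the onset threshold and off below the
offset threshold, offset multiplied by 0.89 in the resonant condition;
per-sweep lognormal threshold noise models trial-to-trial variability.
The three larynx presets (f_o pairs 126/106, 80/67, 60/50 Hz; onset
12/15/18 hPa, offset 9/11/13 hPa) are free parameters standing in for
biological variation between specimens — real larynx-specific pressures
and level gaps are tissue properties that no generator setting can
reproduce, and are deliberately not asserted anywhere.

## What the synthetic data do not emulate

The source is kinematic: no myoelastic self-oscillation, no
aerodynamic glottis, no turbulence noise, no supraglottal (vocal-tract)
load, no side-branch resonance of the air-supply hole, no tissue
drying or long-term drift.  All Level-2 effects are parameters, so
passing tests show the *pipeline* recovers what the generator encodes —
they validate the measurement and statistics chain, not vocal-fold
physics.  Real recordings can be fed to the analysis path (`analyze`)
as calibrated WAV + JSON sidecars.

## Numerical conventions

Zero-phase (forward-backward) 4th-order Butterworth filters throughout;
full-signal FFT filtering with power-of-two padding and 10-ms edge
tapers; lossless-line poles capped at 10⁶·Z₀ with a saturation warning;
degenerate inputs (silence, constant flow, empty designs) either return
well-defined trivial results or raise `ValueError` as documented per
function.  Every stochastic component takes an explicit seed, and all
experiment outputs embed the seed and a configuration hash.
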