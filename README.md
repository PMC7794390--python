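# subglot

Simulation and analysis of **subglottal acoustics in excised-larynx
phonation experiments**.

Excised larynges are the standard bench model for studying the voice
source, but the air-supply tubing below the larynx (the subglottal
space) has acoustic resonances of its own that interact with the vocal
folds and obscure their inherent behavior.  A reflection-free
("anechoic") subglottal tract removes those resonances; comparing it
with an adjustable resonant tract separates what the folds do from what
the tube does.  `subglot` reproduces that entire experimental programme
in software: a synthetic glottal flow source drives one-dimensional
waveguide models of the anechoic and resonant subglottal tracts and a
simple-source radiation model, and the package implements the complete
measurement chain — impulse-train frequency-response estimation,
normalized spectra, calibrated sound pressure levels, fundamental
frequency (f_o) tracking, phonation-threshold detection, inverse
filtering — plus the threshold-pressure statistics.  It is intended for
voice scientists who want a desk-scale, fully reproducible counterpart
of the bench setup, for method development and for validating
computational models of voice production.

## The model in brief

**Source.** The glottal flow u(t) is a raised-cosine pulse train on a
leak baseline: pulses of width OQ·T (open quotient OQ, period T) with a
skewed opening/closing profile, whose peak is set in closed form so the
mean flow is exact — mean = leak + ½·OQ·(peak − leak).

**Waveguide.** The subglottal tract of cross-section A behaves as a
transmission line with characteristic impedance Z₀ = ρc/A.  The
anechoic termination makes the input impedance Z(f) = Z₀ at every
frequency (an infinite resistive waveguide), so the subglottal pressure
is an inverted copy of the flow: p(t) = R_g·ū − Z₀·(u(t) − ū), with R_g
the DC glottal resistance.  The closed-piston termination gives the
lossy-line impedance Z(f) = Z₀·coth(Γ(f)L), Γ(f) = k√f + j2πf/c, with
resonances f_Rn = n·c/2L and antiresonances f_ARn = (2n−1)·c/4L.

**Radiation.** The glottal exit radiates as a simple source:
p(t) = ρ/(4πr)·du/dt at the retarded time, so the
subglottal-to-radiated amplitude ratio for a harmonic at frequency f is
A_L(f) = 20·log₁₀(f·A / 2rc) dB — rising 6 dB/octave and around −60 dB
in the 50–200 Hz band that dominates low-pitched phonation.

**Level-2 effects.** There is no self-oscillating vocal-fold model;
the documented reactions of the folds to the acoustic load (lower f_o,
~11 % lower offset threshold pressure, larger oscillation amplitude,
EGG secondary peaks) are explicit generator parameters
(`Level2Config`).  See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from subglot import *

params = SourceParams()           # f_o 106 Hz, mean flow 400 mL/s
flow = generate_flow_pulse_train(params)
tube = TubeSpec.anechoic()        # reflection-free subglottal tract
p_sub = subglottal_pressure(flow, tube, 6.25e6)   # R_g in Pa s/m^3
rad = radiated_pressure(flow, RadiationEnv())     # mic at 10 cm

print(f"mean subglottal pressure: {p_sub.samples.mean()/100:.1f} hPa")
g = slice(2500, -2500)            # skip settling edges
ac = p_sub.samples - p_sub.samples.mean()
print(f"AC excursion (peak-to-trough): {np.ptp(ac[g]):.0f} Pa")
spl_sub = compute_spl(p_sub).steady_db
spl_rad = compute_spl(rad).steady_db
print(f"subglottal SPL: {spl_sub:.1f} dB   radiated SPL at 10 cm: {spl_rad:.1f} dB")
print(f"SPL difference: {spl_sub - spl_rad:.1f} dB")
print(f"median f_o from radiated sound: {estimate_fo(rad).median_fo:.1f} Hz")
```

prints

```
mean subglottal pressure: 25.0 hPa
AC excursion (peak-to-trough): 970 Pa
subglottal SPL: 145.0 dB   radiated SPL at 10 cm: 83.5 dB
SPL difference: 61.6 dB
median f_o from radiated sound: 106.0 Hz
```

The mean pressure sits at the 25 hPa operating point of steady
phonation at 400 mL/s; the subglottal oscillation is hundreds of
pascals (an extreme ~145 dB re 20 µPa inside the tract) while the sound
reaching a microphone 10 cm above the glottis is about 60 dB weaker —
the cost of converting a pressure trapped in a narrow tube into
radiated sound.

## Command line

The three bench experiments and the analysis of real recordings are
available as subcommands (all defaults encode the study conditions; a
`--config` YAML overrides them):

```sh
subglot measure-response --out out/response     # impulse-train frequency responses
subglot simulate-steady  --out out/steady       # steady phonation, all tract settings
subglot simulate-sweep   --out out/sweeps       # flow sweeps + threshold statistics
subglot analyze recording.wav --out out/ana     # SPL, f_o, thresholds of a WAV
subglot stats thresholds.csv                    # condition-effect regression report
```

Waveforms are written as 32-bit float WAV with JSON sidecars carrying
the physical scale (Pa or m³/s per unit), seed and configuration hash;
tables as CSV; statistics as JSON.

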