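"""Synthetic glottal source: flow pulse trains, EGG, flow sweeps, thresholds.

The generator emulates the voice source of an excised-larynx preparation.
Because no self-oscillating vocal-fold model is in scope, the acoustic
back-reactions on the folds ("Level 2" interactions) are explicit,
phenomenological parameters of :class:`Level2Config`: the fundamental
frequency per subglottal condition, a multiplicative factor on the
offset (and optionally onset) phonation-threshold pressure in the
resonant condition, and a pressure-coupled ripple gain on the EGG
contact signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd

from .signals import EGGWaveform, FlowWaveform, PressureWaveform

__all__ = [
    "SourceParams",
    "Level2Config",
    "condition_source_params",
    "SweepProtocol",
    "generate_flow_pulse_train",
    "generate_egg",
    "generate_flow_sweep",
    "generate_threshold_dataset",
    "THRESHOLD_TABLE_COLUMNS",
]

#: Default DC pressure-flow ratio of the glottis per subglottal condition,
#: in Pa·s·m^-3.  Calibrated so that 400 mL/s of mean flow produces a mean
#: subglottal pressure of 25 hPa (anechoic) / 20 hPa (resonant), the
#: operating points observed in the steady phonations.
R_G_DEFAULTS = {"anechoic": 6.25e6, "resonant": 5.0e6}

THRESHOLD_TABLE_COLUMNS = [
    "larynx_id",
    "condition",
    "sweep_index",
    "repetition",
    "onset_pressure",
    "offset_pressure",
]


@dataclass
class SourceParams:
    """Parameters of the pulsed glottal flow source.

    Parameters
    ----------
    f_o:
        Fundamental frequency of the pulse train, Hz.
    mean_flow:
        Time-averaged volume flow, m^3/s.  The default 4.0e-4 (400 mL/s)
        is the steady-phonation operating point.
    open_quotient:
        Open-phase fraction of the glottal cycle, in (0, 1].
    leak_flow:
        Minimum (closed-phase) flow, m^3/s.  Excised larynges rarely seal
        completely; the default 1.0e-4 (100 mL/s) is a calibration choice.
    duration:
        Signal duration, s.
    sample_rate:
        Sampling rate, Hz.
    jitter_cv:
        Coefficient of variation of the (lognormal) cycle-length
        perturbation; 0 disables jitter.
    seed:
        RNG seed for the jitter stream.
    skew:
        Fraction of the open phase occupied by the opening ramp; 0.5 is a
        symmetric pulse.  The default 0.65 (speed quotient ~1.9) makes
        the closing phase faster than the opening, as in real glottal
        flow; the pulse mean is skew-invariant.
    """

    f_o: float = 106.0
    mean_flow: float = 4.0e-4
    open_quotient: float = 0.6
    leak_flow: float = 1.0e-4
    duration: float = 2.0
    sample_rate: float = 50_000.0
    jitter_cv: float = 0.0
    seed: int = 0
    skew: float = 0.65

    def __post_init__(self) -> None:
        if not 0 < self.open_quotient <= 1:
            raise ValueError("open_quotient must lie in (0, 1]")
        if not 0 < self.skew < 1:
            raise ValueError("skew must lie in (0, 1)")
        if self.leak_flow < 0:
            raise ValueError("leak_flow must be non-negative")
        if self.leak_flow > self.mean_flow:
            raise ValueError("leak_flow cannot exceed mean_flow")
        if self.f_o <= 0 or self.duration <= 0 or self.sample_rate <= 0:
            raise ValueError("f_o, duration and sample_rate must be positive")
        if self.jitter_cv < 0:
            raise ValueError("jitter_cv must be non-negative")

    @property
    def peak_flow(self) -> float:
        """Closed-form pulse peak so that the waveform mean is mean_flow.

        mean = leak + 0.5·OQ·(peak − leak)  =>  peak = leak + (mean − leak)/(0.5·OQ)
        """
        return self.leak_flow + (self.mean_flow - self.leak_flow) / (
            0.5 * self.open_quotient
        )


@dataclass
class Level2Config:
    """Phenomenological acoustic-load effects on the vocal-fold oscillation.

    ``offset_effect`` multiplies the offset threshold pressure in the
    resonant condition (0.89 encodes the observed ~11 % reduction);
    ``onset_effect`` does the same for onsets (1.0: no effect).
    ``egg_ripple_gain`` adds ``gain * (AC subglottal pressure)`` to the
    EGG contact pulse during the contact phase, in au/Pa.
    """

    fo_anechoic: float = 126.0
    fo_resonant: float = 106.0
    offset_effect: float = 0.89
    onset_effect: float = 1.0
    egg_ripple_gain: float = 1.0e-3
    amplitude_effect: float = 1.4

    def __post_init__(self) -> None:
        if self.fo_anechoic <= 0 or self.fo_resonant <= 0:
            raise ValueError("fundamental frequencies must be positive")
        if self.offset_effect <= 0 or self.onset_effect <= 0:
            raise ValueError("threshold effect factors must be positive")
        if self.amplitude_effect <= 0:
            raise ValueError("amplitude_effect must be positive")
        if self.egg_ripple_gain < 0:
            raise ValueError("egg_ripple_gain must be non-negative")

    def f_o(self, condition: str) -> float:
        return self.fo_anechoic if condition == "anechoic" else self.fo_resonant


def condition_source_params(
    params: SourceParams, cfg: Level2Config, condition: str
) -> SourceParams:
    """Source parameters adjusted for a subglottal condition.

    Sets the condition's fundamental frequency and, in the resonant
    condition, compresses the open quotient by ``amplitude_effect``:
    at fixed mean flow this deepens the pulse modulation by the same
    factor (peak − leak = (mean − leak)/(0.5·OQ)), emulating the larger
    vibratory amplitudes observed under an acoustically loaded glottis.
    """
    if condition not in ("anechoic", "resonant"):
        raise ValueError("condition must be 'anechoic' or 'resonant'")
    oq = params.open_quotient
    if condition == "resonant":
        oq = oq / cfg.amplitude_effect
    return replace(params, f_o=cfg.f_o(condition), open_quotient=oq)


@dataclass
class SweepProtocol:
    """Mean-flow sweep: ramp up, hold, ramp down, with hysteretic gating.

    The thresholds are mean subglottal pressures in hPa at which the
    oscillation switches on (rising) and off (falling); the offset must be
    below the onset (hysteresis).
    """

    peak_flow: float = 5.5e-4
    ramp_up_duration: float = 6.0
    hold_duration: float = 2.0
    ramp_down_duration: float = 6.0
    onset_threshold_pressure: float = 12.0
    offset_threshold_pressure: float = 9.0

    def __post_init__(self) -> None:
        if self.peak_flow <= 0:
            raise ValueError("peak_flow must be positive")
        if min(self.ramp_up_duration, self.hold_duration, self.ramp_down_duration) < 0:
            raise ValueError("durations must be non-negative")
        if not self.offset_threshold_pressure < self.onset_threshold_pressure:
            raise ValueError(
                "hysteresis violated: offset threshold must be below onset threshold"
            )

    @property
    def total_duration(self) -> float:
        return self.ramp_up_duration + self.hold_duration + self.ramp_down_duration


def _cycle_fraction(params: SourceParams) -> np.ndarray:
    """Per-sample cycle fraction in [0, 1): open phase first, then closed.

    With jitter, cycle lengths are multiplied by seeded lognormal factors
    of unit mean and coefficient of variation ``jitter_cv``.
    """
    n = int(round(params.duration * params.sample_rate))
    t = np.arange(n) / params.sample_rate
    if params.jitter_cv == 0:
        return (t * params.f_o) % 1.0
    rng = np.random.default_rng(params.seed)
    base_period = 1.0 / params.f_o
    n_cycles = int(np.ceil(params.duration * params.f_o)) + 8
    sigma = np.sqrt(np.log1p(params.jitter_cv**2))
    factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n_cycles)
    periods = base_period * factors
    starts = np.concatenate(([0.0], np.cumsum(periods)))
    idx = np.searchsorted(starts, t, side="right") - 1
    return (t - starts[idx]) / periods[idx]


def _pulse_shape(
    frac: np.ndarray, open_quotient: float, skew: float = 0.5
) -> np.ndarray:
    """Raised-cosine flow pulse over the open phase, zero in the closed phase.

    ``skew`` splits the open phase into an opening half-cosine of width
    ``skew*OQ`` and a closing half-cosine of width ``(1-skew)*OQ``; each
    half-lobe averages 0.5 over its width, so the pulse mean is
    ``0.5*OQ*peak`` for any skew.
    """
    h = np.zeros_like(frac)
    a = skew * open_quotient
    rising = frac < a
    h[rising] = 0.5 * (1.0 - np.cos(np.pi * frac[rising] / a))
    falling = (frac >= a) & (frac < open_quotient)
    h[falling] = 0.5 * (
        1.0 + np.cos(np.pi * (frac[falling] - a) / (open_quotient - a))
    )
    return h


def generate_flow_pulse_train(params: SourceParams) -> FlowWaveform:
    """Generate a raised-cosine glottal flow pulse train.

    The pulse occupies the open phase (width ``open_quotient / f_o``),
    rides on the ``leak_flow`` baseline, and its peak is chosen in closed
    form so that the waveform mean equals ``mean_flow``.  A final
    amplitude correction (leaving the closed-phase level untouched)
    removes the small bias of the partial last cycle, so the sample mean
    equals ``mean_flow`` to machine precision for the noise-free case.
    """
    open_samples = params.open_quotient / params.f_o * params.sample_rate
    if open_samples < 4:
        raise ValueError(
            "open phase spans fewer than 4 samples; raise sample_rate or open_quotient"
        )
    frac = _cycle_fraction(params)
    h = _pulse_shape(frac, params.open_quotient, params.skew)
    u = params.leak_flow + (params.peak_flow - params.leak_flow) * h
    mean = u.mean()
    if mean > params.leak_flow and params.mean_flow > params.leak_flow:
        # rescale the AC part only: closed-phase samples stay exactly at leak
        u = params.leak_flow + (u - params.leak_flow) * (
            (params.mean_flow - params.leak_flow) / (mean - params.leak_flow)
        )
    elif params.mean_flow == params.leak_flow:
        u = np.full_like(u, params.leak_flow)
    meta = {
        "kind": "pulse_train",
        "f_o": params.f_o,
        "mean_flow": params.mean_flow,
        "open_quotient": params.open_quotient,
        "leak_flow": params.leak_flow,
        "jitter_cv": params.jitter_cv,
        "seed": params.seed,
    }
    return FlowWaveform(u, params.sample_rate, meta=meta)


def generate_egg(
    params: SourceParams,
    cfg: Level2Config,
    p_sub: PressureWaveform | None = None,
) -> EGGWaveform:
    """Generate an EGG-like contact waveform for the same cycle timing.

    A smooth raised-cosine contact pulse (unit amplitude, arbitrary units)
    spans the closed phase.  When ``cfg.egg_ripple_gain > 0`` an additive
    ripple ``gain * (AC subglottal pressure)`` is superimposed inside the
    contact phase, weighted by the contact pulse itself (the pressure
    modulates contact area in proportion to how much contact there is, and
    the weighting keeps the waveform continuous at the contact edges).
    This emulates the pressure-coupled secondary peaks seen with low
    subglottal resonance frequencies.
    """
    frac = _cycle_fraction(params)
    oq = params.open_quotient
    contact = frac >= oq
    egg = np.zeros_like(frac)
    if oq < 1.0:
        local = (frac[contact] - oq) / (1.0 - oq)
        egg[contact] = 0.5 * (1.0 - np.cos(2.0 * np.pi * local))
    if cfg.egg_ripple_gain > 0:
        if p_sub is None:
            raise ValueError("p_sub is required when egg_ripple_gain > 0")
        if p_sub.sample_rate != params.sample_rate:
            raise ValueError("p_sub sample rate does not match source parameters")
        if p_sub.n != frac.size:
            raise ValueError("p_sub length does not match source duration")
        ac = p_sub.samples - p_sub.samples.mean()
        egg = egg * (1.0 + cfg.egg_ripple_gain * ac)
    return EGGWaveform(
        egg,
        params.sample_rate,
        contact=contact,
        meta={"kind": "egg", "f_o": params.f_o, "ripple_gain": cfg.egg_ripple_gain},
    )


def _mean_flow_profile(protocol: SweepProtocol, n: int, sample_rate: float) -> np.ndarray:
    """Trapezoidal mean-flow profile of the sweep, m^3/s."""
    t = np.arange(n) / sample_rate
    up, hold = protocol.ramp_up_duration, protocol.hold_duration
    down = protocol.ramp_down_duration
    m = np.zeros(n)
    if up > 0:
        rising = t < up
        m[rising] = protocol.peak_flow * t[rising] / up
    holding = (t >= up) & (t < up + hold)
    m[holding] = protocol.peak_flow
    if down > 0:
        falling = (t >= up + hold) & (t < up + hold + down)
        m[falling] = protocol.peak_flow * (1.0 - (t[falling] - up - hold) / down)
    return m


def _hysteretic_gate(
    pressure_hpa: np.ndarray, onset_hpa: float, offset_hpa: float
) -> np.ndarray:
    """Boolean oscillation gate: on above the onset, off below the offset."""
    n = pressure_hpa.size
    gate = np.zeros(n, dtype=bool)
    i = 0
    state = False
    while i < n:
        if not state:
            rest = pressure_hpa[i:] >= onset_hpa
            if not rest.any():
                break
            i += int(np.argmax(rest))
            state = True
        else:
            rest = pressure_hpa[i:] < offset_hpa
            if not rest.any():
                gate[i:] = True
                break
            j = i + int(np.argmax(rest))
            gate[i:j] = True
            i = j
            state = False
    return gate


def generate_flow_sweep(
    protocol: SweepProtocol,
    params: SourceParams,
    cfg: Level2Config,
    condition: str,
    r_g: float | None = None,
) -> FlowWaveform:
    """Generate a flow sweep with hysteretic oscillation gating.

    The mean flow ramps 0 → peak → 0; the quasi-static mean subglottal
    pressure is ``r_g * mean_flow`` (hPa after /100).  Oscillatory pulses
    switch on when that pressure first exceeds the onset threshold and
    off when it falls below the offset threshold; in the resonant
    condition the thresholds are multiplied by the Level-2 effect factors
    and the fundamental frequency is ``cfg.fo_resonant``.
    """
    if condition not in ("anechoic", "resonant"):
        raise ValueError("condition must be 'anechoic' or 'resonant'")
    if r_g is None:
        r_g = R_G_DEFAULTS[condition]
    onset = protocol.onset_threshold_pressure
    offset = protocol.offset_threshold_pressure
    if condition == "resonant":
        onset *= cfg.onset_effect
        offset *= cfg.offset_effect
    if not offset < onset:
        raise ValueError("hysteresis violated after applying condition effects")

    cparams = condition_source_params(params, cfg, condition)
    fs = cparams.sample_rate
    n = int(round(protocol.total_duration * fs))
    m = _mean_flow_profile(protocol, n, fs)
    p_hpa = r_g * m / 100.0
    gate = _hysteretic_gate(p_hpa, onset, offset)

    f_o = cparams.f_o
    t = np.arange(n) / fs
    frac = (t * f_o) % 1.0
    h = _pulse_shape(frac, cparams.open_quotient, cparams.skew)
    leak_frac = cparams.leak_flow / cparams.mean_flow if cparams.mean_flow > 0 else 0.0
    leak = leak_frac * m
    amp = (m - leak) / (0.5 * cparams.open_quotient)  # pulse peak − leak
    u_osc = leak + amp * h
    u = np.where(gate, u_osc, m)

    meta = {
        "kind": "flow_sweep",
        "condition": condition,
        "f_o": f_o,
        "r_g": r_g,
        "onset_threshold_hpa": onset,
        "offset_threshold_hpa": offset,
        "peak_flow": protocol.peak_flow,
        "open_quotient": cparams.open_quotient,
        "leak_fraction": leak_frac,
    }
    return FlowWaveform(u, fs, meta=meta)


def generate_threshold_dataset(
    design: dict,
    base_onsets,
    base_offsets,
    cfg: Level2Config,
    noise_cv: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a fully crossed onset/offset threshold-pressure table.

    Parameters
    ----------
    design:
        ``{"n_larynx": 3, "n_sweeps": 3, "n_repetitions": 2}`` (the study
        design: both conditions are always included).
    base_onsets, base_offsets:
        Per-larynx baseline threshold pressures in hPa (anechoic).
    cfg:
        Level-2 effects; resonant rows are multiplied by
        ``onset_effect`` / ``offset_effect``.
    noise_cv:
        Coefficient of variation of the multiplicative lognormal noise
        (unit mean); 0 gives a deterministic table.
    """
    n_larynx = int(design.get("n_larynx", 0))
    n_sweeps = int(design.get("n_sweeps", 0))
    n_reps = int(design.get("n_repetitions", 0))
    if min(n_larynx, n_sweeps, n_reps) <= 0:
        raise ValueError("design must have positive n_larynx, n_sweeps, n_repetitions")
    base_onsets = np.asarray(base_onsets, dtype=float)
    base_offsets = np.asarray(base_offsets, dtype=float)
    if base_onsets.size != n_larynx or base_offsets.size != n_larynx:
        raise ValueError("need one base onset and offset per larynx")
    if np.any(base_offsets >= base_onsets):
        raise ValueError("base offsets must lie below base onsets")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")

    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv**2)) if noise_cv > 0 else 0.0

    def noise() -> float:
        if sigma == 0.0:
            return 1.0
        return float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))

    rows = []
    for li, cond, si, ri in product(
        range(n_larynx), ("anechoic", "resonant"), range(n_sweeps), range(n_reps)
    ):
        on_factor = cfg.onset_effect if cond == "resonant" else 1.0
        off_factor = cfg.offset_effect if cond == "resonant" else 1.0
        rows.append(
            {
                "larynx_id": f"L{li + 1}",
                "condition": cond,
                "sweep_index": si + 1,
                "repetition": ri + 1,
                "onset_pressure": base_onsets[li] * on_factor * noise(),
                "offset_pressure": base_offsets[li] * off_factor * noise(),
            }
        )
    table = pd.DataFrame(rows, columns=THRESHOLD_TABLE_COLUMNS)
    if noise_cv == 0 and not (table.onset_pressure > table.offset_pressure).all():
        warnings.warn("noise-free table violates onset > offset", stacklevel=2)
    return table
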