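"""One-dimensional subglottal waveguide acoustics and radiation.

Two subglottal tract models are provided:

* ``anechoic`` — a reflection-free termination; the tube behaves as an
  infinite, purely resistive waveguide with input impedance Z0 = rho*c/A
  at every frequency.
* ``closed_piston`` — a rigid piston termination at distance L; the input
  impedance of the lossy line is Z0*coth(Gamma*L) with propagation
  constant Gamma(f) = k_loss*sqrt(f) + j*2*pi*f/c, giving harmonic
  resonances f_Rn = n*c/(2L) and antiresonances f_ARn = (2n-1)*c/(4L).

Radiation from the glottal exit is modelled as a simple (monopole)
source: p(t) = rho/(4*pi*r) * du/dt at the retarded time for free-field
geometry; a baffled source doubles the amplitude.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window

from .signals import FlowWaveform, PressureWaveform

logger = logging.getLogger(__name__)

__all__ = [
    "TubeSpec",
    "RadiationEnv",
    "GlottalResistance",
    "EFFECTIVE_SOUND_SPEED",
    "AIR_DENSITY",
    "characteristic_impedance",
    "input_impedance",
    "resonance_frequencies",
    "antiresonance_frequencies",
    "length_for_resonance",
    "fit_effective_sound_speed",
    "subglottal_pressure",
    "radiated_pressure",
    "transfer_ratio_AL",
    "spectral_peak_ratios",
]

#: Effective in-tube sound speed (m/s) fitted from the hardware's printed
#: piston-length <-> f_R1 mapping (mid-range settings); includes the warm
#: humidified air and small end effects of the physical rig.
EFFECTIVE_SOUND_SPEED = 372.0

#: Density of warm humid air, kg/m^3.
AIR_DENSITY = 1.18

#: Sound speed in free room air (radiated path), m/s.
ROOM_SOUND_SPEED = 350.0

#: Magnitude cap (in units of Z0) for a lossless line evaluated at a pole.
_SATURATION_FACTOR = 1.0e6

#: Hardware length range of the adjustable resonant tube, m.
_HARDWARE_LENGTH_RANGE = (0.25, 0.55)


@dataclass
class TubeSpec:
    """Subglottal waveguide description.

    ``length`` is the acoustic length of the closed-piston tube (ignored
    for the anechoic termination), ``diameter`` the bore (24 mm hardware
    default), ``loss_coefficient`` the viscothermal wall-loss scale in
    Np·m^-1·Hz^-1/2.
    """

    length: float | None = None
    diameter: float = 0.024
    termination: str = "anechoic"
    sound_speed: float = EFFECTIVE_SOUND_SPEED
    air_density: float = AIR_DENSITY
    loss_coefficient: float = 0.01
    name: str = ""

    def __post_init__(self) -> None:
        if self.termination not in ("anechoic", "closed_piston"):
            raise ValueError("termination must be 'anechoic' or 'closed_piston'")
        if self.diameter <= 0 or self.sound_speed <= 0 or self.air_density <= 0:
            raise ValueError("diameter, sound_speed and air_density must be positive")
        if self.loss_coefficient < 0:
            raise ValueError("loss_coefficient must be non-negative")
        if self.termination == "closed_piston":
            if self.length is None or self.length <= 0:
                raise ValueError("closed_piston tube requires a positive length")
            lo, hi = _HARDWARE_LENGTH_RANGE
            # ~8 % slack: the ideal half-wave lengths at the fitted sound
            # speed slightly overshoot the printed hardware endpoints
            if not lo * 0.92 <= self.length <= hi * 1.08:
                warnings.warn(
                    f"tube length {self.length:.3f} m outside the hardware range "
                    f"[{lo}, {hi}] m",
                    stacklevel=2,
                )
        if not self.name:
            if self.termination == "anechoic":
                self.name = "anechoic"
            else:
                self.name = f"resonant_{self.f_r1:.0f}Hz"

    @property
    def area(self) -> float:
        """Cross-sectional area, m^2."""
        return np.pi * (self.diameter / 2.0) ** 2

    @property
    def f_r1(self) -> float:
        """First resonance frequency c/(2L) of the closed-piston tube, Hz."""
        if self.termination != "closed_piston":
            raise ValueError("anechoic tube has no resonance frequency")
        return self.sound_speed / (2.0 * self.length)

    @classmethod
    def anechoic(cls, **kwargs) -> "TubeSpec":
        return cls(termination="anechoic", **kwargs)

    @classmethod
    def resonant(cls, f_r1: float, **kwargs) -> "TubeSpec":
        """Closed-piston tube with the piston set for first resonance f_r1."""
        c = kwargs.pop("sound_speed", EFFECTIVE_SOUND_SPEED)
        return cls(
            length=length_for_resonance(f_r1, c),
            termination="closed_piston",
            sound_speed=c,
            **kwargs,
        )


@dataclass
class RadiationEnv:
    """Radiated-sound environment: microphone distance and free-air medium."""

    distance: float = 0.10
    geometry: str = "free_field"
    sound_speed: float = ROOM_SOUND_SPEED
    air_density: float = AIR_DENSITY

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("distance must be positive")
        if self.geometry not in ("free_field", "baffled"):
            raise ValueError("geometry must be 'free_field' or 'baffled'")
        if self.sound_speed <= 0 or self.air_density <= 0:
            raise ValueError("sound_speed and air_density must be positive")


@dataclass
class GlottalResistance:
    """DC pressure-flow ratio across the glottis, Pa·s·m^-3."""

    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("glottal resistance must be non-negative")


def _rg_value(r_g) -> float:
    return float(r_g.value if isinstance(r_g, GlottalResistance) else r_g)


def characteristic_impedance(tube: TubeSpec) -> float:
    """Characteristic impedance Z0 = rho*c/A of the tube, Pa·s·m^-3."""
    return tube.air_density * tube.sound_speed / tube.area


def input_impedance(tube: TubeSpec, freqs) -> np.ndarray:
    """Complex input impedance of the tube on the given frequency grid.

    Anechoic: Z0 everywhere.  Closed piston: Z0*coth(Gamma(f)*L).  At an
    exact lossless pole (k_loss = 0 at f = n*c/2L, including f = 0) the
    magnitude is capped at 1e6*Z0 and a saturation warning is issued.
    """
    f = np.asarray(freqs, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequencies must be non-negative")
    z0 = characteristic_impedance(tube)
    if tube.termination == "anechoic":
        return np.full(f.shape, z0, dtype=complex)
    gamma_l = (
        tube.loss_coefficient * np.sqrt(f) + 1j * 2.0 * np.pi * f / tube.sound_speed
    ) * tube.length
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        z = z0 / np.tanh(gamma_l)
    cap = _SATURATION_FACTOR * z0
    bad = ~np.isfinite(z)
    over = np.zeros(f.shape, dtype=bool)
    over[~bad] = np.abs(z[~bad]) > cap
    if bad.any() or over.any():
        warnings.warn("input impedance saturated at a lossless pole", stacklevel=2)
        z[bad] = cap
        z[over] = cap * z[over] / np.abs(z[over])
    return z


def resonance_frequencies(tube: TubeSpec, n_max: int) -> np.ndarray:
    """Resonances f_Rn = n*c/(2L) for n = 1..n_max (closed-piston tube)."""
    if tube.termination == "anechoic":
        raise ValueError("anechoic tube has no resonances")
    if n_max < 0:
        raise ValueError("n_max must be non-negative")
    n = np.arange(1, n_max + 1)
    return n * tube.sound_speed / (2.0 * tube.length)


def antiresonance_frequencies(tube: TubeSpec, n_max: int) -> np.ndarray:
    """Antiresonances f_ARn = (2n-1)*c/(4L); f_AR1 = f_R1/2."""
    if tube.termination == "anechoic":
        raise ValueError("anechoic tube has no antiresonances")
    if n_max < 0:
        raise ValueError("n_max must be non-negative")
    n = np.arange(1, n_max + 1)
    return (2 * n - 1) * tube.sound_speed / (4.0 * tube.length)


def length_for_resonance(f_r1: float, c: float = EFFECTIVE_SOUND_SPEED) -> float:
    """Piston length L = c/(2*f_R1) giving first resonance f_r1."""
    if f_r1 <= 0:
        raise ValueError("f_r1 must be positive")
    return c / (2.0 * f_r1)


def fit_effective_sound_speed(pairs) -> float:
    """Effective sound speed from (length m, f_R1 Hz) pairs: mean of 2*L*f."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("at least one (length, f_R1) pair is required")
    speeds = [2.0 * length * f for length, f in pairs]
    for (length, f), c in zip(pairs, speeds):
        logger.info("length %.3f m, f_R1 %.1f Hz -> c_eff %.1f m/s", length, f, c)
    return float(np.mean(speeds))


def _zin_filter(
    ac: np.ndarray, sample_rate: float, tube: TubeSpec, taper: float = 0.010
) -> np.ndarray:
    """Apply the input impedance to an AC flow signal in the frequency domain.

    The signal is edge-tapered (``taper`` seconds of raised cosine per
    edge), zero-padded to the next power of two, multiplied by Z(f) with
    the DC bin forced to zero, and transformed back.  The first and last
    ``taper`` seconds of the result are fade regions.
    """
    n = ac.size
    nt = int(round(taper * sample_rate))
    x = ac.astype(float).copy()
    if nt > 1 and n > 2 * nt:
        win = get_window(("tukey", 2.0 * nt / n), n)
        x *= win
    nfft = 1 << int(np.ceil(np.log2(max(n, 2))))
    spec = np.fft.rfft(x, nfft)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / sample_rate)
    z = np.zeros(freqs.size, dtype=complex)
    z[1:] = input_impedance(tube, freqs[1:])  # DC carried by the R_g term
    return np.fft.irfft(spec * z, nfft)[:n]


def subglottal_pressure(
    flow: FlowWaveform,
    tube: TubeSpec,
    r_g,
    dc_split_hz: float | None = None,
) -> PressureWaveform:
    """Subglottal pressure p(t) driven by the glottal flow.

    p(t) = R_g * u_dc(t) - Zin * (u(t) - u_dc(t))

    where ``u_dc`` is the quasi-static flow: the global mean when
    ``dc_split_hz`` is None (steady signals), or a zero-phase low-pass of
    the flow at ``dc_split_hz`` for time-varying sweeps.  The minus sign
    makes an outgoing flow pulse a subglottal rarefaction, so the
    pressure waveform is the vertical inverse of the flow.  The anechoic
    case reduces exactly to p = R_g*u_dc - Z0*(u - u_dc), constant during
    closed phases.
    """
    min_freq = dc_split_hz if dc_split_hz else 20.0
    if flow.duration < 1.0 / min_freq:
        raise ValueError("flow shorter than one period at the lowest analysis frequency")
    u = flow.samples
    if dc_split_hz:
        from scipy.signal import butter, sosfiltfilt

        sos = butter(4, dc_split_hz, btype="low", fs=flow.sample_rate, output="sos")
        u_dc = sosfiltfilt(sos, u)
    else:
        u_dc = np.full_like(u, u.mean())
    ac = u - u_dc
    if tube.termination == "anechoic":
        p_ac = characteristic_impedance(tube) * ac
    else:
        p_ac = _zin_filter(ac, flow.sample_rate, tube)
    p = _rg_value(r_g) * u_dc - p_ac
    meta = dict(flow.meta)
    meta.update({"tube": tube.name, "r_g": _rg_value(r_g), "dc_split_hz": dc_split_hz})
    return PressureWaveform(p, flow.sample_rate, location="subglottal", meta=meta)


def radiated_pressure(flow: FlowWaveform, env: RadiationEnv) -> PressureWaveform:
    """Radiated pressure at the microphone from the simple-source model.

    Free field: p(t) = rho/(4*pi*r) * du/dt at the retarded time
    t - r/c; a baffled source radiates into a half space and doubles the
    amplitude (2*pi*r denominator).
    """
    fs = flow.sample_rate
    dudt = np.gradient(flow.samples, 1.0 / fs)
    denom = 4.0 * np.pi * env.distance
    if env.geometry == "baffled":
        denom = 2.0 * np.pi * env.distance
    p = env.air_density / denom * dudt
    delay = int(round(env.distance / env.sound_speed * fs))
    if delay > 0:
        p = np.concatenate([np.zeros(delay), p[:-delay] if delay < p.size else p[:0]])
        if p.size < flow.n:
            p = np.pad(p, (0, flow.n - p.size))
    meta = dict(flow.meta)
    meta.update({"distance_m": env.distance, "geometry": env.geometry})
    return PressureWaveform(
        p, fs, location=f"mic@{env.distance:g}m", meta=meta
    )


def transfer_ratio_AL(freqs, tube: TubeSpec, env: RadiationEnv) -> np.ndarray:
    """Theoretical subglottal-to-radiated pressure ratio A_L(f), in dB.

    For a unit sinusoidal glottal flow the subglottal amplitude is Z0*U
    and the radiated amplitude rho_env*f*U/(2r) (free field), so

        A_L(f) = 20*log10( rho_env * f * A / (2 * r * rho_tube * c_tube) )

    rising +6.02 dB per octave.  A baffled source adds 6.02 dB.
    """
    f = np.asarray(freqs, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive")
    ratio = (
        env.air_density
        * f
        * tube.area
        / (2.0 * env.distance * tube.air_density * tube.sound_speed)
    )
    al = 20.0 * np.log10(ratio)
    if env.geometry == "baffled":
        al = al + 20.0 * np.log10(2.0)
    return al


def _harmonic_amplitudes(
    w: PressureWaveform, f_o: float, n_harmonics: int
) -> np.ndarray:
    """Peak spectral amplitude in a band around each harmonic of f_o."""
    win = get_window("hann", w.n, fftbins=True)
    spec = np.abs(np.fft.rfft(w.samples * win))
    freqs = np.fft.rfftfreq(w.n, d=1.0 / w.sample_rate)
    amps = np.empty(n_harmonics)
    for k in range(1, n_harmonics + 1):
        lo, hi = (k - 0.4) * f_o, (k + 0.4) * f_o
        band = (freqs >= lo) & (freqs <= hi)
        amps[k - 1] = spec[band].max()
    return amps


def spectral_peak_ratios(
    sub: PressureWaveform,
    rad: PressureWaveform,
    f_o: float,
    n_harmonics: int = 20,
) -> np.ndarray:
    """Radiated / subglottal amplitude ratio (dB) at the first harmonics.

    Harmonics above the Nyquist frequency are truncated with a warning.
    """
    if sub.sample_rate != rad.sample_rate or sub.n != rad.n:
        raise ValueError("waveforms must share sample rate and duration")
    nyquist = sub.sample_rate / 2.0
    max_k = int(np.floor((nyquist * 0.95) / f_o))
    if max_k < n_harmonics:
        warnings.warn(
            f"truncating to {max_k} harmonics below Nyquist", stacklevel=2
        )
        n_harmonics = max_k
    a_sub = _harmonic_amplitudes(sub, f_o, n_harmonics)
    a_rad = _harmonic_amplitudes(rad, f_o, n_harmonics)
    return 20.0 * np.log10(a_rad / a_sub)
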