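"""Measurement and signal-processing procedures.

Covers the full measurement chain of the bench experiments: impulse-train
frequency-response estimation with loudspeaker compensation, 4-Hz
normalized spectra, calibrated sound pressure level with 'fast' time
weighting, autocorrelation pitch tracking, automatic phonation onset /
offset detection with 50-ms pressure windows, radiated-sound inverse
filtering by numerical integration, and the cm H2O -> hPa unit
conversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, correlate, find_peaks, get_window, resample_poly, sosfiltfilt

from .signals import FlowWaveform, PressureWaveform

__all__ = [
    "FrequencyResponse",
    "Spectrum",
    "SplTrack",
    "FoTrack",
    "ThresholdEvent",
    "estimate_frequency_response",
    "compensate_response",
    "compute_spectrum",
    "compute_spl",
    "estimate_fo",
    "detect_thresholds",
    "inverse_filter",
    "cm_h2o_to_hpa",
    "find_first_peak",
    "best_lag_correlation",
]

P_REF = 20e-6  # SPL reference pressure, Pa


@dataclass
class FrequencyResponse:
    """Magnitude (dB) frequency response on a uniform grid."""

    frequencies: np.ndarray
    magnitude_db: np.ndarray
    values: np.ndarray | None = None  # complex spectrum when available
    resolution: float = 0.0
    n_impulses: int | None = None
    compensated: bool = False

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.magnitude_db = np.asarray(self.magnitude_db, dtype=float)
        if self.frequencies.size < 2 or np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if self.magnitude_db.shape != self.frequencies.shape:
            raise ValueError("magnitude grid must match frequency grid")
        if self.resolution <= 0:
            self.resolution = float(self.frequencies[1] - self.frequencies[0])


@dataclass
class Spectrum:
    """Normalized magnitude spectrum (maximum bin = 0 dB)."""

    frequencies: np.ndarray
    level_db: np.ndarray
    resolution: float


@dataclass
class SplTrack:
    """Sound pressure level track, dB re 20 uPa, 'fast' time weighting."""

    time: np.ndarray
    spl: np.ndarray
    time_weighting: str = "fast"

    @property
    def max_db(self) -> float:
        return float(np.max(self.spl))

    @property
    def steady_db(self) -> float:
        """Median level over the second half of the track (post-settling)."""
        half = self.spl.size // 2
        return float(np.median(self.spl[half:]))


@dataclass
class FoTrack:
    """Fundamental-frequency track; NaN marks unvoiced frames."""

    time: np.ndarray
    f_o: np.ndarray

    @property
    def voiced(self) -> np.ndarray:
        return np.isfinite(self.f_o)

    @property
    def median_fo(self) -> float:
        """Median f_o over voiced frames (NaN when fully unvoiced)."""
        if not self.voiced.any():
            return float("nan")
        return float(np.median(self.f_o[self.voiced]))


@dataclass
class ThresholdEvent:
    """Oscillation onset or offset with its 50-ms mean pressure in hPa."""

    kind: str  # "onset" | "offset"
    time: float
    mean_pressure: float


def estimate_frequency_response(
    mic: PressureWaveform,
    impulse_period: float = 1.0,
    n_impulses: int = 100,
) -> FrequencyResponse:
    """Frequency response from a periodic impulse-train recording.

    The microphone signal is segmented into windows of one impulse period,
    the windows are averaged in the time domain to suppress uncorrelated
    noise (a factor sqrt(N) in amplitude), and the FFT of the average is
    the response.  Grid spacing is 1/impulse_period.
    """
    fs = mic.sample_rate
    win_len = int(round(impulse_period * fs))
    available = mic.n // win_len
    if available == 0:
        raise ValueError("signal shorter than one impulse period")
    if available < n_impulses:
        warnings.warn(
            f"only {available} complete windows available (requested {n_impulses})",
            stacklevel=2,
        )
    used = min(available, n_impulses)
    avg = mic.samples[: used * win_len].reshape(used, win_len).mean(axis=0)
    spec = np.fft.rfft(avg)
    freqs = np.fft.rfftfreq(win_len, d=1.0 / fs)
    mag = np.abs(spec)
    mag_db = 20.0 * np.log10(np.maximum(mag, 1e-300))
    return FrequencyResponse(
        frequencies=freqs[1:],
        magnitude_db=mag_db[1:],
        values=spec[1:],
        resolution=1.0 / impulse_period,
        n_impulses=used,
        compensated=False,
    )


def compensate_response(
    tract: FrequencyResponse,
    loudspeaker: FrequencyResponse,
    floor_db: float = -120.0,
) -> FrequencyResponse:
    """Divide the measured tract response by the loudspeaker response.

    Element-wise division (dB subtraction); loudspeaker bins below
    ``floor_db`` relative to its maximum are clamped with a warning.
    """
    if tract.frequencies.shape != loudspeaker.frequencies.shape or not np.allclose(
        tract.frequencies, loudspeaker.frequencies
    ):
        raise ValueError("frequency grids do not match")
    ls_db = loudspeaker.magnitude_db.copy()
    floor = ls_db.max() + floor_db
    clipped = ls_db < floor
    if clipped.any():
        warnings.warn("loudspeaker response clamped at floor", stacklevel=2)
        ls_db[clipped] = floor
    values = None
    if tract.values is not None and loudspeaker.values is not None:
        ls = loudspeaker.values.copy()
        small = np.abs(ls) < np.abs(ls).max() * 10 ** (floor_db / 20.0)
        ls[small] = np.abs(ls).max() * 10 ** (floor_db / 20.0)
        values = tract.values / ls
    return FrequencyResponse(
        frequencies=tract.frequencies,
        magnitude_db=tract.magnitude_db - ls_db,
        values=values,
        resolution=tract.resolution,
        n_impulses=tract.n_impulses,
        compensated=True,
    )


def compute_spectrum(w: PressureWaveform, resolution: float = 4.0) -> Spectrum:
    """Magnitude spectrum at the requested resolution, peak-normalized.

    Window length is 1/resolution (periodic Hann), 50 % overlap,
    magnitude-averaged across segments; the maximum bin is set to 0 dB.
    """
    fs = w.sample_rate
    nper = int(round(fs / resolution))
    if w.n < nper:
        raise ValueError("signal shorter than one analysis window")
    hop = nper // 2
    win = get_window("hann", nper, fftbins=True)
    n_seg = 1 + (w.n - nper) // hop
    acc = np.zeros(nper // 2 + 1)
    for i in range(n_seg):
        seg = w.samples[i * hop : i * hop + nper]
        acc += np.abs(np.fft.rfft(seg * win))
    acc /= n_seg
    freqs = np.fft.rfftfreq(nper, d=1.0 / fs)
    db = 20.0 * np.log10(np.maximum(acc, 1e-300))
    db -= db.max()
    return Spectrum(frequencies=freqs, level_db=db, resolution=resolution)


def compute_spl(
    w: PressureWaveform,
    hp_cutoff: float = 10.0,
    time_constant: float = 0.125,
    floor_db: float = -40.0,
) -> SplTrack:
    """Non-weighted SPL track with 'fast' (125 ms exponential) detection.

    The calibrated pressure (Pa) is high-passed at ``hp_cutoff`` (4th
    order, zero phase) to remove the DC offset, squared, smoothed by a
    one-pole exponential detector with the given time constant, and
    expressed in dB re 20 uPa.  Levels are floored at ``floor_db``.
    """
    if not isinstance(w, PressureWaveform):
        raise TypeError("compute_spl requires a calibrated PressureWaveform in Pa")
    fs = w.sample_rate
    sos = butter(4, hp_cutoff, btype="high", fs=fs, output="sos")
    x = sosfiltfilt(sos, w.samples)
    alpha = np.exp(-1.0 / (time_constant * fs))
    from scipy.signal import lfilter

    ms = lfilter([1.0 - alpha], [1.0, -alpha], x**2)
    floor_power = (P_REF * 10 ** (floor_db / 20.0)) ** 2
    spl = 10.0 * np.log10(np.maximum(ms, floor_power) / P_REF**2)
    return SplTrack(time=w.times, spl=spl)


def _frame_autocorr_fo(
    frame: np.ndarray,
    fs: float,
    fmin: float,
    fmax: float,
    voicing_threshold: float,
) -> float:
    """Single-frame f_o by normalized autocorrelation with octave guard."""
    x = frame - frame.mean()
    if not np.any(np.abs(x) > 0):
        return np.nan
    n = x.size
    spec = np.fft.rfft(x, 2 * n)
    r = np.fft.irfft(spec * np.conj(spec))[:n]
    if r[0] <= 0:
        return np.nan
    r = r / r[0]
    lag_min = max(2, int(np.floor(fs / fmax)))
    lag_max = int(np.ceil(fs / fmin))
    if lag_max >= n - 1:
        lag_max = n - 2
    if lag_max <= lag_min:
        return np.nan
    seg = r[lag_min : lag_max + 1]
    peaks, _ = find_peaks(seg)
    if peaks.size == 0:
        return np.nan
    peak_vals = seg[peaks]
    best = peak_vals.max()
    if best < voicing_threshold:
        return np.nan
    # pick the shortest lag whose peak is close to the global best to
    # avoid subharmonic (octave-down) errors on harmonic-rich frames
    good = peaks[peak_vals >= 0.9 * best]
    lag = lag_min + int(good[0])
    # parabolic interpolation around the peak
    if 1 <= lag < n - 1:
        y0, y1, y2 = r[lag - 1], r[lag], r[lag + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            lag = lag + 0.5 * (y0 - y2) / denom
    return fs / lag


def estimate_fo(
    w,
    frame: float = 0.100,
    hop: float = 0.025,
    fmin: float = 30.0,
    fmax: float = 400.0,
    voicing_threshold: float = 0.5,
    silence_rel: float = 0.01,
) -> FoTrack:
    """Autocorrelation f_o track with voicing decision.

    Frames of ``frame`` seconds every ``hop`` seconds; a frame is voiced
    when its strongest normalized autocorrelation peak in the 30–400 Hz
    lag range exceeds ``voicing_threshold`` and its RMS exceeds
    ``silence_rel`` times the signal's overall RMS.  Unvoiced frames are
    NaN.  Requires sample_rate >= 4*fmax.
    """
    fs = w.sample_rate
    if fs < 4 * fmax:
        raise ValueError("sample rate too low for the requested f_o search range")
    x = np.asarray(w.samples, dtype=float)
    nf = int(round(frame * fs))
    nh = int(round(hop * fs))
    n_frames = max(0, 1 + (x.size - nf) // nh)
    times = np.empty(n_frames)
    fo = np.full(n_frames, np.nan)
    overall_rms = np.sqrt(np.mean((x - x.mean()) ** 2)) if x.size else 0.0
    for i in range(n_frames):
        seg = x[i * nh : i * nh + nf]
        times[i] = (i * nh + nf / 2) / fs
        seg_rms = np.sqrt(np.mean((seg - seg.mean()) ** 2))
        if overall_rms == 0 or seg_rms < silence_rel * overall_rms:
            continue
        fo[i] = _frame_autocorr_fo(seg, fs, fmin, fmax, voicing_threshold)
    return FoTrack(time=times, f_o=fo)


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of True runs in a boolean array."""
    d = np.diff(mask.astype(np.int8), prepend=0, append=0)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def detect_thresholds(
    p_sub: PressureWaveform,
    window: float = 0.050,
    band: tuple = (30.0, 1000.0),
    env_window: float = 0.025,
    rel_threshold: float = 0.05,
    hysteresis: float = 0.8,
    min_hold: float = 0.075,
    dc_cutoff: float = 10.0,
    min_envelope: float = 1.0,
) -> list[ThresholdEvent]:
    """Detect oscillation onsets/offsets and their mean threshold pressures.

    The pressure is band-passed (30–1000 Hz), its 25-ms RMS envelope is
    computed, and oscillation episodes are the intervals where the
    envelope exceeds ``rel_threshold`` of its sweep maximum for at least
    ``min_hold`` seconds (offset uses the ``hysteresis`` fraction of the
    onset threshold).  ``min_envelope`` (Pa) is an absolute floor below
    which the recording is treated as oscillation-free — phonation drives
    the subglottal AC to hundreds of Pa, so residual ramp leakage never
    qualifies.  The reported mean pressure is the low-passed (DC)
    pressure averaged over ``window`` seconds before each onset and
    after each offset, in hPa.
    """
    fs = p_sub.sample_rate
    x = p_sub.samples
    hi = min(band[1], 0.45 * fs)
    sos = butter(4, (band[0], hi), btype="band", fs=fs, output="sos")
    ac = sosfiltfilt(sos, x)
    nw = max(1, int(round(env_window * fs)))
    # clip: the running-sum filter can leave tiny negatives by cancellation
    env = np.sqrt(np.maximum(uniform_filter1d(ac**2, size=nw, mode="nearest"), 0.0))
    peak = env.max()
    if peak <= min_envelope:
        return []
    thr_on = rel_threshold * peak
    thr_off = hysteresis * thr_on
    hold = int(round(min_hold * fs))

    sos_lp = butter(4, dc_cutoff, btype="low", fs=fs, output="sos")
    dc = sosfiltfilt(sos_lp, x)

    def window_mean(i0: int, i1: int) -> float:
        i0c, i1c = max(0, i0), min(x.size, i1)
        if i1c <= i0c:
            warnings.warn("threshold window outside signal; skipped", stacklevel=2)
            return float("nan")
        if i1c - i0c < i1 - i0:
            warnings.warn("threshold window shrunk at signal edge", stacklevel=2)
        return float(dc[i0c:i1c].mean() / 100.0)  # Pa -> hPa

    nwin = int(round(window * fs))
    events: list[ThresholdEvent] = []
    episodes = [(a, b) for a, b in _runs(env >= thr_off) if b - a >= hold]
    for a, b in episodes:
        # require the envelope to actually reach the onset threshold
        if env[a:b].max() < thr_on:
            continue
        # the episode start, not the thr_on crossing, marks the gating
        # instant: the envelope rise begins there
        onset_i = a
        events.append(
            ThresholdEvent("onset", onset_i / fs, window_mean(onset_i - nwin, onset_i))
        )
        events.append(ThresholdEvent("offset", b / fs, window_mean(b, b + nwin)))
    return events


def inverse_filter(
    mic: PressureWaveform,
    target_rate: float = 6000.0,
    hp_cutoff: float = 20.0,
) -> FlowWaveform:
    """Flow-like source estimate from the radiated pressure.

    Implements the no-vocal-tract radiated-sound path: anti-aliased
    downsampling to ``target_rate``, cumulative trapezoidal integration
    (undoing the du/dt of the radiation), and a 4th-order zero-phase
    high-pass at ``hp_cutoff`` to suppress integration drift.  The output
    amplitude scale is arbitrary.
    """
    fs = mic.sample_rate
    x = mic.samples
    if target_rate >= fs:
        warnings.warn("target rate above input rate; skipping resampling", stacklevel=2)
        out_fs = fs
    else:
        from fractions import Fraction

        frac = Fraction(int(round(target_rate)), int(round(fs)))
        x = resample_poly(x, frac.numerator, frac.denominator)
        out_fs = fs * frac.numerator / frac.denominator
    y = cumulative_trapezoid(x, dx=1.0 / out_fs, initial=0.0)
    if np.any(y != 0):
        sos = butter(4, hp_cutoff, btype="high", fs=out_fs, output="sos")
        y = sosfiltfilt(sos, y)
    return FlowWaveform(
        y, out_fs, meta={"kind": "inverse_filtered", "scale": "arbitrary"}
    )


def cm_h2o_to_hpa(p):
    """Convert pressure from cm H2O to hPa (factor 0.981)."""
    return np.asarray(p, dtype=float) * 0.981 if np.ndim(p) else p * 0.981


def find_first_peak(
    fr: FrequencyResponse,
    f_min: float = 50.0,
    prominence_db: float = 8.0,
) -> float | None:
    """Frequency of the first prominent magnitude peak above ``f_min``.

    Returns None (not an error) when no peak exceeds the prominence floor.
    """
    mask = fr.frequencies >= f_min
    mag = fr.magnitude_db[mask]
    freqs = fr.frequencies[mask]
    peaks, _ = find_peaks(mag, prominence=prominence_db)
    if peaks.size == 0:
        return None
    return float(freqs[peaks[0]])


def best_lag_correlation(x, y, sample_rate: float, max_lag: float = 0.05) -> float:
    """Maximum Pearson-like correlation of two signals over small lags.

    Both signals are mean-removed; the cross-correlation is normalized by
    the zero-lag energies, so the value is a slight underestimate of the
    per-lag Pearson r away from zero lag.  Used to compare inverse-filtered
    radiated sound with the inverted subglottal pressure.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = min(x.size, y.size)
    x = x[:n] - x[:n].mean()
    y = y[:n] - y[:n].mean()
    denom = np.sqrt((x**2).sum() * (y**2).sum())
    if denom == 0:
        return 0.0
    c = correlate(y, x, mode="full")
    lags = np.arange(-n + 1, n)
    keep = np.abs(lags) <= int(max_lag * sample_rate)
    return float(c[keep].max() / denom)
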