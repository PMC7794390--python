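"""In-silico versions of the three bench experiments.

* :func:`run_response_measurement` — 100 impulse excitations per tube
  with additive noise, time-domain averaging, FFT, loudspeaker
  compensation, first-peak search.
* :func:`run_steady_experiment` — steady phonation at 400 mL/s through
  the anechoic and six resonant settings: waveforms, 4-Hz spectra, SPL,
  f_o, inverse-filter comparison.
* :func:`run_sweep_experiment` — hysteretic flow sweeps per larynx and
  condition: threshold detection, f_o / SPL vs. pressure curves, and the
  log-linear condition-effect regression.
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .analysis import (
    FrequencyResponse,
    best_lag_correlation,
    compensate_response,
    compute_spectrum,
    compute_spl,
    detect_thresholds,
    estimate_fo,
    estimate_frequency_response,
    find_first_peak,
    inverse_filter,
)
from .config import ExperimentConfig
from .signals import PressureWaveform
from .source import (
    condition_source_params,
    generate_egg,
    generate_flow_pulse_train,
    generate_flow_sweep,
)
from .stats import fit_threshold_model, spl_difference_by_pressure
from .source import _cycle_fraction  # cycle timing shared with the generator
from .waveguide import (
    TubeSpec,
    _harmonic_amplitudes,
    characteristic_impedance,
    input_impedance,
    radiated_pressure,
    subglottal_pressure,
)

logger = logging.getLogger(__name__)

__all__ = [
    "run_response_measurement",
    "run_steady_experiment",
    "run_sweep_experiment",
]


# ---------------------------------------------------------------------------
# response measurement


def _loudspeaker_response(freqs: np.ndarray) -> np.ndarray:
    """Smooth band-limited response of the small measurement loudspeaker.

    First-order high-pass at 120 Hz and low-pass at 5 kHz — a gentle,
    invertible tilt typical of a miniature electret driver.
    """
    f = np.asarray(freqs, dtype=float)
    s = 1j * f
    return (s / 120.0) / (1.0 + s / 120.0) / (1.0 + s / 5000.0)


def _simulate_impulse_measurement(
    tube: TubeSpec, cfg: ExperimentConfig, rng: np.random.Generator
):
    """Impulse-train recording of one tube through the loudspeaker chain."""
    fs = cfg.response_sample_rate
    win = int(round(fs))  # one-second impulse period
    freqs = np.fft.rfftfreq(win, d=1.0 / fs)
    z0 = characteristic_impedance(tube)
    zn = np.ones(freqs.size, dtype=complex)
    zn[1:] = input_impedance(tube, freqs[1:]) / z0
    g = _loudspeaker_response(freqs)
    h_spec = zn * g
    h_spec[0] = 0.0
    h = np.fft.irfft(h_spec, win)
    signal = np.tile(h, cfg.response_n_impulses)
    p_sig = np.mean(h**2)
    sigma = np.sqrt(p_sig * 10 ** (-cfg.response_snr_db / 10.0))
    signal = signal + rng.normal(0.0, sigma, signal.size)
    mic = PressureWaveform(signal, fs, location="response_mic")
    speaker_fr = FrequencyResponse(
        frequencies=freqs[1:],
        magnitude_db=20.0 * np.log10(np.abs(g[1:])),
        values=g[1:],
        resolution=1.0,
    )
    return mic, speaker_fr


def run_response_measurement(cfg: ExperimentConfig, outdir=None) -> dict:
    """Simulated frequency-response measurement for every configured tube."""
    rng = np.random.default_rng(cfg.seed)
    results = {}
    for tube in cfg.tubes():
        mic, speaker_fr = _simulate_impulse_measurement(tube, cfg, rng)
        raw = estimate_frequency_response(
            mic, impulse_period=1.0, n_impulses=cfg.response_n_impulses
        )
        comp = compensate_response(raw, speaker_fr)
        peak = find_first_peak(comp, f_min=100.0)
        band = (comp.frequencies >= 100.0) & (comp.frequencies <= 2500.0)
        mag = comp.magnitude_db[band]
        flatness = float(np.max(np.abs(mag - np.median(mag))))
        results[tube.name] = {
            "tube": tube,
            "response": comp,
            "first_peak_hz": peak,
            "flatness_db": flatness,
        }
        logger.info(
            "tube %s: first peak %s Hz, flatness %.2f dB",
            tube.name,
            f"{peak:.0f}" if peak else "none",
            flatness,
        )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, res in results.items():
            sio.write_frequency_response(outdir / f"response_{name}.csv", res["response"])
        summary = {
            name: {
                "first_peak_hz": res["first_peak_hz"],
                "flatness_db": res["flatness_db"],
            }
            for name, res in results.items()
        }
        (outdir / "response_summary.json").write_text(
            json.dumps({**cfg.output_meta(), "tubes": summary}, indent=1, default=float)
        )
    return results


# ---------------------------------------------------------------------------
# steady phonations


def _first_formant_hz(p_sub: PressureWaveform, f_o: float, f_max: float = 2500.0):
    """Frequency of the first maximum of the harmonic-amplitude envelope."""
    n_harm = int(f_max / f_o)
    amps = _harmonic_amplitudes(p_sub, f_o, n_harm)
    db = 20.0 * np.log10(amps)
    for k in range(1, n_harm - 1):
        if db[k] >= db[k - 1] and db[k] > db[k + 1]:
            return (k + 1) * f_o
    return None


def _closed_phase_ripple_hz(
    p_sub: PressureWaveform, params, band=(150.0, 1500.0)
) -> float:
    """Dominant ringing frequency inside the closed phases.

    During glottal closure the flow is constant, so the subglottal
    pressure there is DC plus free ringing of the tract resonances; no
    filtering is needed.  Each closed-phase segment is detrended
    (linear), Hann-windowed and zero-padded; the averaged power spectra
    give the peak frequency within ``band``.
    """
    from scipy.signal import detrend, get_window

    fs = p_sub.sample_rate
    x = p_sub.samples
    frac = _cycle_fraction(params)
    closed = frac >= params.open_quotient
    nfft = 8192
    power = np.zeros(nfft // 2 + 1)
    n_seg = 0
    edges = np.flatnonzero(np.diff(closed.astype(np.int8)))
    bounds = np.concatenate(([0], edges + 1, [closed.size]))
    for a, b in zip(bounds[:-1], bounds[1:]):
        if not closed[a] or b - a < 32:
            continue
        seg = detrend(x[a:b]) * get_window("hann", b - a)
        power += np.abs(np.fft.rfft(seg, nfft)) ** 2
        n_seg += 1
    if n_seg == 0 or power.max() == 0:
        return float("nan")
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(freqs[sel][np.argmax(power[sel])])


def _closed_phase_stats(p_sub: PressureWaveform, params, margin: float = 0.08):
    """Closed-phase flatness: SD of p in the plateau vs. AC peak-to-trough."""
    frac = _cycle_fraction(params)
    oq = params.open_quotient
    plateau = (frac >= oq + margin * (1 - oq)) & (frac <= 1 - margin * (1 - oq))
    guard = int(0.05 * p_sub.sample_rate)
    interior = np.zeros(p_sub.n, dtype=bool)
    interior[guard:-guard] = True
    p = p_sub.samples
    sel = plateau & interior
    excursion = float(np.ptp(p[interior]))
    sd = float(np.std(p[sel]))
    return sd, excursion


def run_steady_experiment(cfg: ExperimentConfig, outdir=None) -> list[dict]:
    """Steady phonation through each tube; returns one record per setting."""
    records = []
    env = cfg.radiation
    for tube in cfg.tubes():
        condition = "anechoic" if tube.termination == "anechoic" else "resonant"
        params = condition_source_params(
            replace(cfg.source, seed=cfg.seed), cfg.level2, condition
        )
        flow = generate_flow_pulse_train(params)
        p_sub = subglottal_pressure(flow, tube, cfg.r_g[condition])
        egg = generate_egg(params, cfg.level2, p_sub)
        rad = radiated_pressure(flow, env)

        spec_sub = compute_spectrum(p_sub)
        spec_rad = compute_spectrum(rad)
        spl_sub = compute_spl(p_sub)
        spl_rad = compute_spl(rad)
        fo_track = estimate_fo(rad)
        sd, excursion = _closed_phase_stats(p_sub, params)

        # inverse-filtered radiated sound vs. the inverted subglottal AC,
        # resampled to the inverse-filter rate
        inv = inverse_filter(rad)
        from fractions import Fraction

        from scipy.signal import resample_poly

        frac = Fraction(int(round(inv.sample_rate)), int(round(p_sub.sample_rate)))
        target_rs = resample_poly(
            -(p_sub.samples - p_sub.samples.mean()), frac.numerator, frac.denominator
        )
        r = best_lag_correlation(inv.samples, target_rs, inv.sample_rate)

        rec = {
            "condition": condition,
            "tube": tube.name,
            "f_r1": tube.f_r1 if condition == "resonant" else None,
            "f_o_source": params.f_o,
            "f_o_measured": fo_track.median_fo,
            "mean_pressure_hpa": float(p_sub.samples.mean() / 100.0),
            "ac_excursion_pa": excursion,
            "closed_phase_sd_pa": sd,
            "closed_phase_sd_rel": sd / excursion if excursion else np.nan,
            "spl_sub_db": spl_sub.steady_db,
            "spl_rad_db": spl_rad.steady_db,
            "spl_gap_db": spl_sub.steady_db - spl_rad.steady_db,
            "first_formant_hz": (
                _first_formant_hz(p_sub, params.f_o) if condition == "resonant" else None
            ),
            "closed_phase_ripple_hz": (
                _closed_phase_ripple_hz(p_sub, params)
                if condition == "resonant"
                else None
            ),
            "inverse_filter_r": r,
            "_waveforms": {"flow": flow, "p_sub": p_sub, "egg": egg, "rad": rad},
            "_spectra": {"sub": spec_sub, "rad": spec_rad},
        }
        records.append(rec)
        logger.info(
            "%s: mean %.1f hPa, excursion %.0f Pa, SPL gap %.1f dB, f_o %.1f Hz",
            tube.name,
            rec["mean_pressure_hpa"],
            excursion,
            rec["spl_gap_db"],
            rec["f_o_measured"],
        )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = cfg.output_meta()
        for rec in records:
            tag = rec["tube"]
            for name, w in rec["_waveforms"].items():
                sio.write_waveform(outdir / f"steady_{tag}_{name}.wav", w, meta)
            for side, spec in rec["_spectra"].items():
                pd.DataFrame(
                    {"frequency_hz": spec.frequencies, "level_db": spec.level_db}
                ).to_csv(outdir / f"steady_{tag}_spectrum_{side}.csv", index=False)
        summary = pd.DataFrame(
            [{k: v for k, v in rec.items() if not k.startswith("_")} for rec in records]
        )
        summary.to_csv(outdir / "steady_summary.csv", index=False)
        (outdir / "steady_meta.json").write_text(json.dumps(meta, indent=1))
    return records


# ---------------------------------------------------------------------------
# flow sweeps


def _sweep_tube(cfg: ExperimentConfig, condition: str) -> TubeSpec:
    if condition == "anechoic":
        return TubeSpec.anechoic()
    return TubeSpec.resonant(cfg.sweep_f_r1)


def run_sweep_experiment(cfg: ExperimentConfig, outdir=None) -> dict:
    """Flow sweeps over larynges × conditions × sweeps × repetitions.

    Gating thresholds receive per-sweep multiplicative lognormal noise
    (``cfg.threshold_noise_cv``); the resonant condition applies the
    Level-2 factors inside the sweep generator.  Detected thresholds are
    assembled into the measured table and fed to the log-linear
    condition-effect regression.
    """
    if not cfg.larynx_presets:
        raise ValueError("at least one larynx preset is required")
    if not cfg.tubes():
        raise ValueError("tube list is empty")
    rng = np.random.default_rng(cfg.seed)
    sigma = (
        np.sqrt(np.log1p(cfg.threshold_noise_cv**2))
        if cfg.threshold_noise_cv > 0
        else 0.0
    )

    def noise() -> float:
        if sigma == 0.0:
            return 1.0
        return float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))

    env = cfg.radiation
    rows = []
    curve_rows = []
    for preset in cfg.larynx_presets:
        lvl2 = replace(
            cfg.level2, fo_anechoic=preset.fo_anechoic, fo_resonant=preset.fo_resonant
        )
        for condition in ("anechoic", "resonant"):
            tube = _sweep_tube(cfg, condition)
            r_g = cfg.r_g[condition]
            for sweep_i in range(1, cfg.n_sweeps + 1):
                for rep in range(1, cfg.n_repetitions + 1):
                    protocol = replace(
                        cfg.sweep,
                        onset_threshold_pressure=preset.onset_hpa * noise(),
                        offset_threshold_pressure=preset.offset_hpa * noise(),
                    )
                    params = replace(
                        cfg.source, sample_rate=cfg.sweep_sample_rate, seed=cfg.seed
                    )
                    flow = generate_flow_sweep(protocol, params, lvl2, condition, r_g)
                    p_sub = subglottal_pressure(flow, tube, r_g, dc_split_hz=10.0)
                    events = detect_thresholds(p_sub)
                    onsets = [e for e in events if e.kind == "onset"]
                    offsets = [e for e in events if e.kind == "offset"]
                    if not onsets or not offsets:
                        logger.warning(
                            "no oscillation episode detected (%s %s sweep %d rep %d)",
                            preset.name,
                            condition,
                            sweep_i,
                            rep,
                        )
                        continue
                    rows.append(
                        {
                            "larynx_id": preset.name,
                            "condition": condition,
                            "sweep_index": sweep_i,
                            "repetition": rep,
                            "onset_pressure": onsets[0].mean_pressure,
                            "offset_pressure": offsets[-1].mean_pressure,
                        }
                    )
                    if rep == 1:
                        rad = radiated_pressure(flow, env)
                        fo_track = estimate_fo(rad)
                        spl_sub = compute_spl(p_sub)
                        spl_rad = compute_spl(rad)
                        from scipy.signal import butter, sosfiltfilt

                        sos = butter(
                            4, 10.0, btype="low", fs=p_sub.sample_rate, output="sos"
                        )
                        dc = sosfiltfilt(sos, p_sub.samples) / 100.0
                        idx = np.clip(
                            (fo_track.time * p_sub.sample_rate).astype(int),
                            0,
                            p_sub.n - 1,
                        )
                        for ti, fi, pi in zip(
                            fo_track.time, fo_track.f_o, dc[idx]
                        ):
                            if np.isfinite(fi):
                                j = int(round(ti * p_sub.sample_rate))
                                j = min(j, p_sub.n - 1)
                                curve_rows.append(
                                    {
                                        "larynx_id": preset.name,
                                        "condition": condition,
                                        "sweep_index": sweep_i,
                                        "time_s": ti,
                                        "pressure_hpa": pi,
                                        "f_o_hz": fi,
                                        "spl_sub_db": spl_sub.spl[j],
                                        "spl_rad_db": spl_rad.spl[j],
                                    }
                                )

    table = pd.DataFrame(rows)
    curves = pd.DataFrame(curve_rows)
    effects = {
        response: fit_threshold_model(table, response)
        for response in ("onset", "offset")
    }
    spl_diffs = {}
    for preset in cfg.larynx_presets:
        sub = curves[curves.larynx_id == preset.name]
        try:
            spl_diffs[preset.name] = spl_difference_by_pressure(
                sub[sub.condition == "anechoic"][["pressure_hpa", "spl_sub_db"]].values,
                sub[sub.condition == "resonant"][["pressure_hpa", "spl_sub_db"]].values,
            )
        except ValueError:
            spl_diffs[preset.name] = None

    result = {
        "threshold_table": table,
        "curves": curves,
        "effects": effects,
        "spl_differences": spl_diffs,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = cfg.output_meta()
        sio.write_threshold_table(outdir / "threshold_table.csv", table)
        curves.to_csv(outdir / "fo_spl_curves.csv", index=False)
        (outdir / "sweep_stats.json").write_text(
            json.dumps(
                {
                    **meta,
                    "effects": {k: v.to_dict() for k, v in effects.items()},
                    "spl_differences": spl_diffs,
                },
                indent=1,
            )
        )
    return result
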