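"""File I/O: WAV + JSON sidecars for waveforms, CSV for tables.

Waveforms are written as 32-bit float RIFF WAV, normalized to unit peak,
with a JSON sidecar (``<name>.json``) carrying the physical scale
(Pa or m^3/s per unit), the sample rate, and any metadata (seed, config
hash, sensor location).  Threshold tables are plain CSV with exactly the
canonical columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .signals import FlowWaveform, PressureWaveform
from .source import THRESHOLD_TABLE_COLUMNS

__all__ = [
    "write_waveform",
    "read_waveform",
    "write_threshold_table",
    "read_threshold_table",
    "write_frequency_response",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_waveform(path, w, extra_meta: dict | None = None) -> Path:
    """Write a waveform as float32 WAV plus a JSON sidecar with the scale."""
    path = Path(path)
    peak = float(np.max(np.abs(w.samples))) or 1.0
    data = (w.samples / peak).astype(np.float32)
    wavfile.write(path, int(round(w.sample_rate)), data)
    units = "m^3/s" if isinstance(w, FlowWaveform) else "Pa"
    sidecar = {
        "sample_rate": w.sample_rate,
        "scale": peak,
        "units": f"{units} per unit",
        "location": getattr(w, "location", None),
        "meta": getattr(w, "meta", {}),
    }
    if extra_meta:
        sidecar["meta"] = {**sidecar["meta"], **extra_meta}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, default=str))
    return path


def read_waveform(path, kind: str = "pressure"):
    """Read a WAV + sidecar pair back into a physical waveform."""
    path = Path(path)
    rate, data = wavfile.read(path)
    data = np.asarray(data, dtype=float)
    if data.ndim > 1:
        data = data[:, 0]
    scale = 1.0
    location = "subglottal"
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        scale = float(info.get("scale", 1.0))
        location = info.get("location") or location
        meta = info.get("meta", {})
        rate = info.get("sample_rate", rate)
    samples = data * scale
    if kind == "flow":
        return FlowWaveform(samples, rate, meta=meta)
    return PressureWaveform(samples, rate, location=location, meta=meta)


def write_threshold_table(path, table: pd.DataFrame) -> Path:
    path = Path(path)
    table[THRESHOLD_TABLE_COLUMNS].to_csv(path, index=False)
    return path


def read_threshold_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(THRESHOLD_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"threshold table missing columns: {sorted(missing)}")
    return table


def write_frequency_response(path, fr) -> Path:
    """Export a frequency response as CSV (frequency, real, imag, dB)."""
    path = Path(path)
    values = fr.values if fr.values is not None else np.full(
        fr.frequencies.shape, np.nan, dtype=complex
    )
    pd.DataFrame(
        {
            "frequency_hz": fr.frequencies,
            "real": values.real,
            "imag": values.imag,
            "magnitude_db": fr.magnitude_db,
        }
    ).to_csv(path, index=False)
    return path
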