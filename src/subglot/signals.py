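"""Sampled waveform containers shared by the synthesis and analysis layers.

All waveforms are one-dimensional, uniformly sampled, and carry physical
units in their values: glottal flow in m^3/s and acoustic pressure in Pa
(DC included).  A small ``meta`` dict travels with every waveform and is
propagated into file sidecars by :mod:`subglot.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class _Sampled:
    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("waveform samples must be one-dimensional")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.n / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n) / self.sample_rate


@dataclass
class FlowWaveform(_Sampled):
    """Glottal volume-flow signal u(t) in m^3/s, DC included."""

    meta: dict = field(default_factory=dict)


@dataclass
class PressureWaveform(_Sampled):
    """Acoustic pressure signal in Pa (DC included) at a named location.

    ``location`` identifies the virtual sensor: ``"subglottal"`` for the
    wall-mounted pressure transducer just below the glottis, or
    ``"mic@<r>m"`` for the radiated-sound microphone at distance r.
    """

    location: str = "subglottal"
    meta: dict = field(default_factory=dict)


@dataclass
class EGGWaveform(_Sampled):
    """Electroglottograph-like contact signal in arbitrary units.

    ``contact`` is a per-sample boolean mask that is True during the
    vocal-fold contact (closed) phase.  The signal is zero during the open
    phase when no pressure-coupled ripple is configured.
    """

    contact: np.ndarray = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.contact is None:
            self.contact = np.zeros(self.n, dtype=bool)
        self.contact = np.asarray(self.contact, dtype=bool)
        if self.contact.shape != self.samples.shape:
            raise ValueError("contact mask must match sample count")
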