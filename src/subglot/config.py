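"""Experiment configuration: shipped defaults and YAML round-trip.

``default_config()`` encodes the bench defaults of the study conditions:
400 mL/s steady flow, 550 mL/s sweep peak, 24-mm tube, 10-cm microphone,
resonant settings f_R1 = 330–800 Hz, anechoic/resonant fundamental
frequencies 126/106 Hz, the 0.89 offset-threshold factor, and the
per-condition glottal resistances calibrated to the 25 / ~20 hPa
operating points.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .source import Level2Config, R_G_DEFAULTS, SourceParams, SweepProtocol
from .waveguide import RadiationEnv, TubeSpec

__all__ = ["LarynxPreset", "ExperimentConfig", "default_config"]

DEFAULT_F_R1 = (330.0, 400.0, 500.0, 600.0, 700.0, 800.0)

#: Resonant setting used in the flow-sweep experiment.
SWEEP_F_R1 = 500.0


@dataclass
class LarynxPreset:
    """Per-larynx free parameters for the flow-sweep simulations.

    The steady-experiment f_o pair (126/106 Hz) is used for the first
    larynx; the other presets span the lower f_o range typical of the
    larger specimens used in sweeps.  Thresholds are baseline (anechoic)
    mean pressures in hPa.
    """

    name: str
    fo_anechoic: float
    fo_resonant: float
    onset_hpa: float
    offset_hpa: float


DEFAULT_LARYNX_PRESETS = (
    LarynxPreset("L1", 126.0, 106.0, 12.0, 9.0),
    LarynxPreset("L2", 80.0, 67.0, 15.0, 11.0),
    LarynxPreset("L3", 60.0, 50.0, 18.0, 13.0),
)


@dataclass
class ExperimentConfig:
    """Complete configuration of the three in-silico experiments."""

    source: SourceParams = field(default_factory=SourceParams)
    level2: Level2Config = field(default_factory=Level2Config)
    radiation: RadiationEnv = field(default_factory=RadiationEnv)
    resonant_f_r1: tuple = DEFAULT_F_R1
    sweep_f_r1: float = SWEEP_F_R1
    r_g: dict = field(default_factory=lambda: dict(R_G_DEFAULTS))
    sweep: SweepProtocol = field(default_factory=SweepProtocol)
    larynx_presets: tuple = DEFAULT_LARYNX_PRESETS
    n_sweeps: int = 3
    n_repetitions: int = 2
    threshold_noise_cv: float = 0.05
    sweep_sample_rate: float = 20_000.0
    response_sample_rate: float = 20_000.0
    response_n_impulses: int = 100
    response_snr_db: float = 20.0
    seed: int = 0
    outdir: str | None = None

    def tubes(self) -> list[TubeSpec]:
        """Anechoic tube plus the resonant settings, in order."""
        return [TubeSpec.anechoic()] + [
            TubeSpec.resonant(f) for f in self.resonant_f_r1
        ]

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["larynx_presets"] = [asdict(p) for p in self.larynx_presets]
        d["resonant_f_r1"] = list(self.resonant_f_r1)
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "source" in d:
            d["source"] = SourceParams(**d["source"])
        if "level2" in d:
            d["level2"] = Level2Config(**d["level2"])
        if "radiation" in d:
            d["radiation"] = RadiationEnv(**d["radiation"])
        if "sweep" in d:
            d["sweep"] = SweepProtocol(**d["sweep"])
        if "larynx_presets" in d:
            d["larynx_presets"] = tuple(
                LarynxPreset(**p) for p in d["larynx_presets"]
            )
        if "resonant_f_r1" in d:
            d["resonant_f_r1"] = tuple(d["resonant_f_r1"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        """Short hash identifying the configuration in output sidecars."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    def output_meta(self) -> dict:
        return {"seed": self.seed, "config_hash": self.config_hash}


def default_config(seed: int = 0, **overrides) -> ExperimentConfig:
    """The shipped study-matched configuration."""
    cfg = ExperimentConfig(seed=seed)
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg
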