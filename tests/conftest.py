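import numpy as np
import pytest

from subglot import (
    Level2Config,
    RadiationEnv,
    SourceParams,
    TubeSpec,
    generate_flow_pulse_train,
    subglottal_pressure,
)

ANECHOIC_R_G = 6.25e6
RESONANT_R_G = 5.0e6


@pytest.fixture
def default_source() -> SourceParams:
    return SourceParams()


@pytest.fixture
def level2() -> Level2Config:
    return Level2Config()


@pytest.fixture
def anechoic_tube() -> TubeSpec:
    return TubeSpec.anechoic()


@pytest.fixture
def radiation() -> RadiationEnv:
    return RadiationEnv()


@pytest.fixture
def anechoic_pressure(default_source, anechoic_tube):
    """Steady anechoic subglottal pressure at the 400 mL/s operating point."""
    flow = generate_flow_pulse_train(default_source)
    return subglottal_pressure(flow, anechoic_tube, ANECHOIC_R_G)


def interior(w, guard_s: float = 0.05) -> np.ndarray:
    """Samples away from the taper/settling edges."""
    g = int(guard_s * w.sample_rate)
    return w.samples[g:-g]
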