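import numpy as np
import pytest

from bluefin.scenes import SceneEvent, SceneSpec, render_scene

FS = 250.0


@pytest.fixture(scope="session")
def sample_rate() -> float:
    return FS


@pytest.fixture(scope="session")
def blue_scene():
    """A 1200 s scene with twelve 15 dB Z-calls plus FM confounders."""
    events = [SceneEvent("Bm-Ant-Z", 40.0 + i * 90.0, 15.0) for i in range(12)]
    events += [SceneEvent("Bm-D", 75.0 + i * 180.0, 12.0) for i in range(6)]
    spec = SceneSpec(duration_s=1200.0, events=events, seed=7)
    audio, truth = render_scene(spec)
    return spec, audio, truth


@pytest.fixture(scope="session")
def fin_scene():
    """A 660 s scene with twenty 15 dB fin 20 Hz pulses."""
    events = [SceneEvent("Bp-20Hz", 20.0 + i * 30.0, 15.0) for i in range(20)]
    spec = SceneSpec(duration_s=660.0, events=events, seed=11)
    audio, truth = render_scene(spec)
    return spec, audio, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
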