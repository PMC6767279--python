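import numpy as np
import pytest

from piezosleep import SimConfig, simulate
from piezosleep.signal_model import PeriodWindow, SampledSeries


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def default_sim():
    """60 s occupied recording with default vitals (18/min, 75 bpm), no noise."""
    cfg = SimConfig(
        duration_s=60.0,
        resp_rate_per_min=18.0,
        heart_rate_per_min=75.0,
        white_noise_sd=0.0,
        mains_amplitude=0.0,
        seed=5,
    )
    rec, truth = simulate(cfg)
    return cfg, rec, truth


@pytest.fixture
def chest_window(default_sim):
    """The chest channel of the default simulation as one 60 s period."""
    cfg, rec, _ = default_sim
    ch = rec.layout.channel_at_cell(cfg.chest_position)
    return PeriodWindow(data=rec.channel(ch), period_s=60.0, t_index=0, channel=ch)


def make_window(values, fs=100.0, channel=1, t_index=0):
    values = np.asarray(values, dtype=float)
    return PeriodWindow(
        data=SampledSeries(values, fs),
        period_s=values.size / fs,
        t_index=t_index,
        channel=channel,
    )
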