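import numpy as np
import pytest

from phenoscan.core import Layout, SensorKind, SensorSpec, SensorStream, View
from phenoscan.simulate import NoiseConfig, SimConfig, simulate_field, simulate_pass


@pytest.fixture(scope="session")
def zero_noise_cfg() -> SimConfig:
    """One deterministic row of three fully covered plots."""
    return SimConfig(
        layout=Layout(n_rows=1, m_plots=3, plot_length_mm=1200, gap_mm=500),
        noise=NoiseConfig.zero(),
        coverage_range=(1.0, 1.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def zero_noise_sim(zero_noise_cfg):
    plan, truths = simulate_field(zero_noise_cfg)
    recordings = simulate_pass(plan, truths, zero_noise_cfg)
    return plan, truths, recordings


@pytest.fixture(scope="session")
def noisy_cfg() -> SimConfig:
    """Default-noise two-row layout for repeatability checks."""
    return SimConfig(
        layout=Layout(n_rows=1, m_plots=4, plot_length_mm=1200, gap_mm=500),
        seed=13,
    )


def make_scalar_stream(values, positions=None, name="LDS1", offset_mm=0, rate=500.0):
    """Hand-built laser-distance stream for unit tests."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    positions = np.arange(n) if positions is None else np.asarray(positions)
    spec = SensorSpec(
        name=name, kind=SensorKind.LASER_DISTANCE, view=View.TOP,
        frame_rate_hz=rate, offset_mm=offset_mm,
    )
    return SensorStream(spec=spec, time_ms=np.arange(n), position_mm=positions, payload=values)


def make_lc_stream(columns, positions=None, name="LC_lower", offset_mm=0):
    """Hand-built light-curtain stream; ``columns`` is (n, 288) boolean."""
    columns = np.asarray(columns, dtype=np.uint8)
    n = columns.shape[0]
    positions = np.arange(n) if positions is None else np.asarray(positions)
    spec = SensorSpec(
        name=name, kind=SensorKind.LIGHT_CURTAIN, view=View.SIDE,
        frame_rate_hz=170.0, offset_mm=offset_mm,
    )
    return SensorStream(spec=spec, time_ms=np.arange(n), position_mm=positions, payload=columns)
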