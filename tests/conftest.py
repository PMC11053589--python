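import numpy as np
import pytest

from gaitfuse.fusion import ObserverParams
from gaitfuse.series import ImuStream
from gaitfuse.synthetic import GRAVITY, ImuNoiseModel


@pytest.fixture
def params():
    return ObserverParams()


@pytest.fixture
def noiseless():
    return ImuNoiseModel.noiseless()


def make_stationary_stream(
    n=200,
    rate=50.0,
    accel=(0.0, 0.0, GRAVITY),
    gyro=(0.0, 0.0, 0.0),
    accel_noise=0.0,
    gyro_noise=0.0,
    seed=0,
    sensor_id="static",
):
    """Constant-reading stream with optional white noise."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) / rate
    a = np.tile(np.asarray(accel, dtype=float), (n, 1))
    g = np.tile(np.asarray(gyro, dtype=float), (n, 1))
    if accel_noise > 0:
        a = a + rng.normal(0.0, accel_noise, size=(n, 3))
    if gyro_noise > 0:
        g = g + rng.normal(0.0, gyro_noise, size=(n, 3))
    return ImuStream(sensor_id, t, a, g, nominal_rate=rate)


@pytest.fixture
def stationary_stream():
    return make_stationary_stream()
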