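import math

import numpy as np
import pytest

from posturekit import (
    ActivityScript,
    ClassifierConfig,
    NoiseModel,
    RecordingWindow,
    SensorStream,
    generate_signal,
)


@pytest.fixture
def mixed_script():
    """15 min sitting / 10 min standing / 5 min stepping."""
    return ActivityScript(bouts=[("sitting", 900), ("standing", 600), ("stepping", 300)])


@pytest.fixture
def mixed_session(mixed_script):
    return generate_signal(mixed_script, seed=42)


@pytest.fixture
def toy_pairs():
    """Five-subject paired minutes used for hand-computed statistic checks."""
    test = np.array([182.0, 150.0, 95.5, 210.0, 125.0])
    criterion = np.array([180.0, 160.0, 100.0, 200.0, 130.0])
    return test, criterion


def constant_posture_stream(z_value: float, n: int, rate: float = 6.25) -> SensorStream:
    """A noiseless stream whose normalized z equals ``z_value`` throughout."""
    t = np.arange(n) / rate
    acc = np.zeros((n, 3))
    acc[:, 2] = z_value
    acc[:, 0] = math.sqrt(max(0.0, 1.0 - z_value**2))
    return SensorStream(t=t, acc=acc, sampling_rate_hz=rate)
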