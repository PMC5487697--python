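import numpy as np
import pytest

from monalloc import RunConfig, StationSeries


@pytest.fixture
def rng():
    return np.random.default_rng(424242)


@pytest.fixture
def config():
    return RunConfig()


def make_series(station_id, times, values):
    return StationSeries(station_id, np.asarray(times, float), np.asarray(values, float))
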