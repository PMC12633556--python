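import numpy as np
import pytest

from waveminer import ActivityMovie, ElectrodeMap, SpikeEvents


@pytest.fixture
def small_map():
    """A 4x3 recording grid at 87.5 um pitch, channel = x*3 + y."""
    xs, ys = np.meshgrid(np.arange(4), np.arange(3), indexing="ij")
    xs, ys = xs.ravel(), ys.ravel()
    return ElectrodeMap(
        channel=xs * 3 + ys,
        x_um=xs * 87.5,
        y_um=ys * 87.5,
        is_reference=np.zeros(xs.size, dtype=bool),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_events(emap, channels, times, duration=None):
    times = np.asarray(times, dtype=float)
    duration = duration if duration is not None else (times.max() if times.size else 0.0)
    return SpikeEvents(
        channel=np.asarray(channels, dtype=np.int64),
        time_s=times, duration_s=float(duration), emap=emap,
    )


def movie_from_array(data, **kw):
    return ActivityMovie(data=np.asarray(data), **kw)
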