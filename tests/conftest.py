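import numpy as np
import pandas as pd
import pytest

from whalemove.features import StepTurnSeries, steps_and_turns
from whalemove.params import SEX_LEVELS, SexLabel
from whalemove.simulate import simulate_track


def make_series(speeds, turns, sex=SexLabel.unknown, segment=None, sid="s"):
    """Assemble a StepTurnSeries directly from step-level arrays."""
    speeds = np.asarray(speeds, dtype=float)
    n = speeds.size
    times = pd.date_range("2016-10-01", periods=n, freq="6h", tz="UTC")
    return StepTurnSeries(
        id=sid,
        sex=sex,
        realization=0,
        times=times,
        speed=speeds,
        turn=np.asarray(turns, dtype=float),
        segment=np.zeros(n, dtype=int) if segment is None else np.asarray(segment),
    )


@pytest.fixture(scope="session")
def sim_series_12():
    """12 noise-free simulated tracks (4 per sex level) at the study scale,
    as step/turn series — the standard HMM fitting fixture."""
    rng = np.random.default_rng(20160915)
    out = []
    for i in range(12):
        sex = SEX_LEVELS[i % 3]
        path = simulate_track(f"sim{i:02d}", sex, n_steps=425, seed=rng, start_lonlat=(100.0, -50.0))
        out.append((path, steps_and_turns(path)))
    return out
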