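import numpy as np
import pytest

from tmequant.simulate import SimConfig
from tmequant.track_io import Track, TrackSet


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def make_track(track_id, xy, dt=1.0, cell_type=None, z=None):
    xy = np.asarray(xy, dtype=float)
    t = np.arange(len(xy)) * dt
    return Track(
        track_id=track_id,
        t=t,
        x=xy[:, 0],
        y=xy[:, 1],
        z=z,
        cell_type=cell_type,
    )


def random_trackset(rng, n_tracks=10, n_steps=20, scale=5.0, dt=1.0):
    tracks = []
    for i in range(n_tracks):
        steps = rng.normal(0, scale, size=(n_steps, 2))
        xy = np.vstack([[0, 0], np.cumsum(steps, axis=0)]) + rng.uniform(0, 100, 2)
        tracks.append(make_track(i, xy, dt=dt))
    return TrackSet(tracks, frame_interval=dt)


@pytest.fixture
def small_config():
    return SimConfig(
        n_cells=64,
        n_steps=12,
        domain_size=(400.0, 400.0, 120.0),
        seed=7,
    )
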