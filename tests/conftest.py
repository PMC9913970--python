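"""Shared fixtures: hand-built tracks and small synthetic cohorts."""

import numpy as np
import pytest

from ctltrack.tracks import Track, TrackSet


def make_track(steps, start=(0.0, 0.0, 0.0), dt=30.0, track_id=0,
               experiment_id="e1", group="WT"):
    """Build a Track from a sequence of 3D step vectors (um per interval)."""
    steps = np.atleast_2d(np.asarray(steps, dtype=float))
    positions = np.vstack([np.asarray(start, dtype=float),
                           np.asarray(start, dtype=float) + np.cumsum(steps, axis=0)])
    return Track(
        track_id=track_id,
        positions=positions,
        frames=np.arange(len(positions)),
        dt=dt,
        experiment_id=experiment_id,
        group=group,
    )


def random_track(rng, n_intervals=20, max_step=5.0, **kwargs):
    steps = rng.uniform(-max_step, max_step, size=(n_intervals, 3))
    return make_track(steps, start=rng.uniform(0, 100, 3), **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_trackset(rng):
    tracks = [random_track(rng, n_intervals=10, track_id=i) for i in range(8)]
    return TrackSet(tracks=tracks)
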