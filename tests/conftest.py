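import numpy as np
import pytest

from memkin import SimConfig, Track


def make_track(track_id, frames, x, y, intensity=None, dt=0.05):
    frames = np.asarray(frames, dtype=int)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if intensity is None:
        intensity = np.full(frames.size, 5500.0)
    return Track(track_id=track_id, frames=frames, t=(frames - 1) * dt,
                 x=x, y=y, intensity=np.asarray(intensity, dtype=float))


@pytest.fixture
def toy_filter_tracks():
    """Six hand-built tracks: one violating each hygiene rule, one clean.

    Movie: 50 frames, 10 x 10 um field (default edge margin 0.5 um).
    """
    def drift(n, x0=5.0, y0=5.0, step=0.2):
        return (x0 + step * np.arange(n), y0 + step * np.arange(n))

    tracks = [
        # begins in first frame
        make_track(1, [1, 2, 3, 4], *drift(4)),
        # present in last movie frame
        make_track(2, [47, 48, 49, 50], *drift(4)),
        # too short (2 frames)
        make_track(3, [10, 11], *drift(2)),
        # immobile (never leaves its start)
        make_track(4, [10, 11, 12, 13, 14],
                   5.0 + np.zeros(5), 5.0 + np.zeros(5)),
        # near the field edge (mean position within 0.5 um of border)
        make_track(5, [10, 11, 12, 13], *drift(4, x0=0.1, y0=5.0)),
        # clean
        make_track(6, [10, 11, 12, 13, 14], *drift(5)),
    ]
    return tracks, {"movie_n_frames": 50, "field_bounds": (10.0, 10.0)}


@pytest.fixture
def base_sim_config():
    return SimConfig(seed=42, arrival_rate=0.02, n_frames=400)
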