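import numpy as np
import pytest

from matchload.config import default_cohort_config
from matchload.synthetic_data import PlayerMatchTrack, simulate_season
from matchload.time_motion import summarize_tracks


def make_track(t, x, y, *, match_id="M1", player_id="P1", role="entire", entry=0.0):
    """Hand-built track helper for kinematics and segmentation tests."""
    return PlayerMatchTrack(
        match_id=match_id,
        player_id=player_id,
        role=role,
        entry_minute=entry,
        exit_minute=90.0,
        t=np.asarray(t, dtype=float),
        x=np.asarray(x, dtype=float),
        y=np.asarray(y, dtype=float),
    )


def constant_speed_track(v_ms, duration_s=60.0, fs=5.0, **kwargs):
    """Straight-line motion at constant speed along x."""
    t = np.arange(0.0, duration_s, 1.0 / fs)
    return make_track(t, v_ms * t, np.zeros_like(t), **kwargs)


@pytest.fixture(scope="session")
def small_cfg():
    return default_cohort_config(
        n_players=6, matches_per_player=5, sampling_rate=2.0, seed=11
    )


@pytest.fixture(scope="session")
def small_season(small_cfg):
    return simulate_season(small_cfg)


@pytest.fixture(scope="session")
def small_summaries(small_season):
    tracks, _ = small_season
    return summarize_tracks(tracks)
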