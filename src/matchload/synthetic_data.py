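"""Synthetic season generator for player position tracking data.

Each player-match trajectory is built from alternating activity bouts: a
state (stand/walk/jog/run/sprint) is drawn from the player's propensities,
a duration from a clipped exponential, and a speed uniformly within the
state's range.  The speed of every bout is scaled by the 5-minute-period
decline factor (entire-match players only), the match underperformance
multiplier, the per-match intensity jitter and the player's habitual
intensity.  Heading follows a bounded random walk and positions are the
time integral of velocity, kept on the pitch by reflective (billiard)
folding of the unbounded path.

One global seed fans out to per-player-match :class:`numpy.random.Generator`
streams via ``SeedSequence(seed, spawn_key=(player, match))``, so generation
is order-independent and reproducible per track.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .config import GeneratorConfig

__all__ = [
    "PlayerProfile",
    "PlayerMatchTrack",
    "make_profile",
    "simulate_player_match",
    "iter_season",
    "simulate_season",
]

_MIN_BOUT_S = 1.0
_MAX_BOUT_FACTOR = 4.0


@dataclass(frozen=True)
class PlayerProfile:
    """A player's habitual-intensity profile (latent, generator-side)."""

    player_id: str
    state_weights: np.ndarray  # per-player deviation of the bout propensities
    intensity: float  # habitual multiplicative intensity factor
    target_match_distance: float  # latent season-mean full-match distance, m

    def __post_init__(self):
        # zero only in the degenerate all-zero-speed configuration
        if self.target_match_distance < 0:
            raise ValueError("target_match_distance must be nonnegative")


@dataclass
class PlayerMatchTrack:
    match_id: str
    player_id: str
    role: str  # 'entire' | 'substitute' | 'goalkeeper'
    entry_minute: float
    exit_minute: float
    t: np.ndarray  # s, strictly increasing, constant step
    x: np.ndarray  # m, pitch-centered
    y: np.ndarray  # m, pitch-centered
    # generator-only ground truth
    is_underperformance: bool = False
    multiplier: float = 1.0

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.size > 1 else np.nan


def make_profile(player_index: int, config: GeneratorConfig, seed_seq=None) -> PlayerProfile:
    """Draw a player's habitual profile from the cohort distribution."""
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(config.seed, spawn_key=(0, player_index))
    rng = np.random.default_rng(seed_seq)
    base = config.state_weights()
    w = base * rng.lognormal(0.0, config.propensity_sd, size=base.size)
    w /= w.sum()
    intensity = float(rng.lognormal(0.0, config.player_intensity_sd))
    # expected full-match distance under this profile (level intensity)
    mean_speeds = np.array(
        [(s.speed_lo_kmh + s.speed_hi_kmh) / 2.0 / 3.6 for s in config.states]
    )
    durs = np.array([s.mean_duration_s for s in config.states])
    frac = w * durs / (w * durs).sum()
    target = float(frac @ mean_speeds * config.match_length_s * intensity)
    return PlayerProfile(f"P{player_index:03d}", w, intensity, target)


def _fold(z: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect an unbounded coordinate into [lo, hi] (triangle-wave map)."""
    width = hi - lo
    m = np.mod(z - lo, 2.0 * width)
    return lo + np.where(m <= width, m, 2.0 * width - m)


def simulate_player_match(
    profile: PlayerProfile,
    config: GeneratorConfig,
    role: str = "entire",
    entry_minute: float = 0.0,
    rng: np.random.Generator | None = None,
    *,
    match_id: str = "M00000",
    is_underperformance: bool = False,
    multiplier: float = 1.0,
) -> PlayerMatchTrack:
    """Simulate one player-match trajectory.

    Samples run at ``config.sampling_rate`` over the half-open play span
    ``[entry_minute*60, 5400)`` s of the cumulative match clock.  Substitutes
    (role != 'entire') use decline factor 1 for all their periods.
    """
    if not 0.0 <= entry_minute < 90.0:
        raise ValueError(f"entry_minute must lie in [0, 90), got {entry_minute}")
    if config.sampling_rate <= 0:
        raise ValueError("sampling_rate must be > 0")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    fs = config.sampling_rate
    start_s = entry_minute * 60.0
    end_s = config.match_length_s
    n = int(round((end_s - start_s) * fs))
    t = start_s + np.arange(n) / fs

    # -- bouts ----------------------------------------------------------
    span = end_s - start_s
    durs_mean = np.array([s.mean_duration_s for s in config.states])
    # each bout lasts >= _MIN_BOUT_S, so this many bouts always cover the span
    n_est = int(np.ceil(span / _MIN_BOUT_S)) + 2
    weights = profile.state_weights
    states = rng.choice(len(config.states), size=n_est, p=weights)
    raw = rng.exponential(durs_mean[states])
    dur = np.clip(raw, _MIN_BOUT_S, _MAX_BOUT_FACTOR * durs_mean[states])
    lo = np.array([s.speed_lo_kmh for s in config.states])[states]
    hi = np.array([s.speed_hi_kmh for s in config.states])[states]
    speed_kmh = rng.uniform(lo, hi)
    starts = start_s + np.concatenate([[0.0], np.cumsum(dur)[:-1]])
    keep = starts < end_s
    starts, speed_kmh = starts[keep], speed_kmh[keep]

    # intensity scaling: decline (entire only) x multiplier x jitter x player
    jitter = rng.lognormal(0.0, config.noise)
    profile_factor = config.intensity_scale * profile.intensity * jitter * multiplier
    if role == "entire":
        periods = np.minimum((starts // 300.0).astype(int), 17)
        decline = np.asarray(config.decline_profile)[periods]
    else:
        decline = np.ones(starts.size)
        profile_factor *= config.substitute_intensity
    bout_speed = speed_kmh / 3.6 * decline * profile_factor

    # per-sample speed: map each sample to the bout containing it
    idx = np.searchsorted(starts, t, side="right") - 1
    v = bout_speed[idx]

    # -- heading random walk and positions ------------------------------
    theta = rng.uniform(0.0, 2.0 * np.pi) + np.cumsum(
        rng.normal(0.0, config.heading_rate / np.sqrt(fs), size=n)
    )
    dt = 1.0 / fs
    half_l = config.pitch_length_m / 2.0
    half_w = config.pitch_width_m / 2.0
    x0 = rng.uniform(-0.6 * half_l, 0.6 * half_l)
    y0 = rng.uniform(-0.6 * half_w, 0.6 * half_w)
    dx = v * np.cos(theta) * dt
    dy = v * np.sin(theta) * dt
    x_raw = x0 + np.concatenate([[0.0], np.cumsum(dx[:-1])])
    y_raw = y0 + np.concatenate([[0.0], np.cumsum(dy[:-1])])
    x = _fold(x_raw, -half_l, half_l)
    y = _fold(y_raw, -half_w, half_w)

    return PlayerMatchTrack(
        match_id=match_id,
        player_id=profile.player_id,
        role=role,
        entry_minute=entry_minute,
        exit_minute=90.0,
        t=t,
        x=x,
        y=y,
        is_underperformance=is_underperformance,
        multiplier=multiplier,
    )


def _draw_entry_minute(config: GeneratorConfig, rng: np.random.Generator) -> int:
    minutes = np.array(sorted(config.substitute_entry), dtype=int)
    probs = np.array([config.substitute_entry[int(m)] for m in minutes])
    return int(rng.choice(minutes, p=probs / probs.sum()))


def iter_season(config: GeneratorConfig) -> Iterator[PlayerMatchTrack]:
    """Lazily yield every player-match track of a simulated season.

    Memory-friendly companion of :func:`simulate_season`: tracks are
    generated on demand and can be summarized and discarded one at a time.
    """
    config.validate()
    lo, hi = config.underperformance_multiplier
    for p in range(config.n_players):
        profile = make_profile(p, config)
        for m in range(config.matches_per_player):
            ss = np.random.SeedSequence(config.seed, spawn_key=(1 + p, m))
            rng = np.random.default_rng(ss)
            is_under = bool(rng.random() < config.underperformance_rate)
            mult = float(rng.uniform(lo, hi)) if is_under else 1.0
            is_sub = bool(rng.random() < config.substitute_fraction)
            role = "substitute" if is_sub else "entire"
            entry = _draw_entry_minute(config, rng) if is_sub else 0
            match_id = f"M{p * config.matches_per_player + m:05d}"
            yield simulate_player_match(
                profile,
                config,
                role=role,
                entry_minute=float(entry),
                rng=rng,
                match_id=match_id,
                is_underperformance=is_under,
                multiplier=mult,
            )


def truth_table(tracks) -> pd.DataFrame:
    """Ground-truth table for a collection of tracks (generator-only)."""
    rows = [
        {
            "match_id": tr.match_id,
            "player_id": tr.player_id,
            "is_underperformance": tr.is_underperformance,
            "multiplier": tr.multiplier,
            "entry_minute": tr.entry_minute,
            "exit_minute": tr.exit_minute,
        }
        for tr in tracks
    ]
    return pd.DataFrame(rows)


def simulate_season(config: GeneratorConfig) -> tuple[list[PlayerMatchTrack], pd.DataFrame]:
    """Simulate a full season: all tracks plus the ground-truth table."""
    tracks = list(iter_season(config))
    return tracks, truth_table(tracks)
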