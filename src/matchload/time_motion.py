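"""Type-1 load variables: smoothed kinematics, total distance, and distance
per speed category, aggregated to 5-min, 15-min, half and match windows.

Speed is obtained by centered finite differences of the (x, y) positions
followed by a centered moving average (default 1 s); signed tangential
acceleration is the centered finite difference of the smoothed speed.
Distance increments ``v * dt`` are assigned to the speed band containing
each sample's instantaneous speed.  Band bounds (km/h) follow the standard
five intensity categories, with the HIR/VHIR boundary at 25.2 km/h so that
the bands are contiguous; speeds below 0.7 km/h are kept in an explicit
sub-VLIR bucket so band distances sum exactly to the total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .synthetic_data import PlayerMatchTrack
from .tracking_io import PeriodGrid, SegmentedTrack

__all__ = [
    "KinematicSeries",
    "SpeedBands",
    "SPEED_BAND_NAMES",
    "estimate_kinematics",
    "distance_covered",
    "distance_by_speed_category",
    "period_summaries",
    "summarize_tracks",
    "aggregate_windows",
    "WINDOW_PERIODS",
]

#: bucket order used throughout: sub-VLIR first, then the five named bands
SPEED_BAND_NAMES = ("subvlir", "vlir", "lir", "mir", "hir", "vhir")


@dataclass(frozen=True)
class SpeedBands:
    """Half-open speed bands in km/h: [lo, hi) per category.

    VLIR [0.7, 7.2), LIR [7.2, 14.4), MIR [14.4, 19.8), HIR [19.8, 25.2),
    VHIR [25.2, inf); speeds in [0, 0.7) fall into the sub-VLIR bucket.
    A sample exactly on a bound joins the upper band.
    """

    edges_kmh: tuple[float, ...] = (0.7, 7.2, 14.4, 19.8, 25.2)

    def __post_init__(self):
        if any(nxt <= prv for prv, nxt in zip(self.edges_kmh, self.edges_kmh[1:])):
            raise ValueError("band bounds must be strictly increasing")

    def bucket_of(self, v_ms: np.ndarray) -> np.ndarray:
        """0 = sub-VLIR, 1..5 = VLIR..VHIR."""
        v_kmh = np.asarray(v_ms) * 3.6
        return np.searchsorted(self.edges_kmh, v_kmh, side="right")


@dataclass
class KinematicSeries:
    t: np.ndarray  # s
    v: np.ndarray  # m/s, smoothed, >= 0
    a: np.ndarray  # m/s^2, signed tangential
    dt: float  # s


def _centered_diff(z: np.ndarray, dt: float) -> np.ndarray:
    d = np.empty_like(z, dtype=float)
    d[1:-1] = (z[2:] - z[:-2]) / (2.0 * dt)
    d[0] = (z[1] - z[0]) / dt
    d[-1] = (z[-1] - z[-2]) / dt
    return d


def estimate_kinematics(track: PlayerMatchTrack, smoothing_window_s: float = 1.0) -> KinematicSeries:
    """Differentiate positions into smoothed speed and acceleration.

    Requires at least 3 samples at constant step; endpoints use one-sided
    differences.
    """
    if track.n_samples < 3:
        raise ValueError("need at least 3 samples to estimate kinematics")
    steps = np.diff(track.t)
    dt = float(steps[0])
    if not np.allclose(steps, dt, rtol=0, atol=1e-6):
        raise ValueError("samples must be at a constant step")
    vx = _centered_diff(track.x, dt)
    vy = _centered_diff(track.y, dt)
    speed = np.hypot(vx, vy)
    w = max(int(round(smoothing_window_s / dt)), 1)
    if w > 1:
        speed = uniform_filter1d(speed, size=w, mode="nearest")
    a = _centered_diff(speed, dt)
    return KinematicSeries(t=track.t, v=speed, a=a, dt=dt)


def distance_covered(series: KinematicSeries, idx: np.ndarray | slice = slice(None)) -> float:
    """Distance over a sample slice: sum of v * dt."""
    return float(np.sum(series.v[idx]) * series.dt)


def distance_by_speed_category(
    series: KinematicSeries,
    bands: SpeedBands | None = None,
    idx: np.ndarray | slice = slice(None),
) -> np.ndarray:
    """Distance (m) per bucket: [sub-VLIR, VLIR, LIR, MIR, HIR, VHIR]."""
    bands = bands or SpeedBands()
    v = series.v[idx]
    bucket = bands.bucket_of(v)
    out = np.zeros(len(SPEED_BAND_NAMES))
    np.add.at(out, bucket, v * series.dt)
    return out


# -- period summary table ------------------------------------------------

SUMMARY_COLUMNS = (
    ["match_id", "player_id", "role", "period", "coverage", "dist_total_m"]
    + [f"dist_{b}_m" for b in SPEED_BAND_NAMES]
    + ["ee_total_kjkg", "ee_lp", "ee_ip", "ee_hp", "ee_ep", "ee_mp"]
)


def period_summaries(
    track: PlayerMatchTrack,
    segmented: SegmentedTrack,
    series: KinematicSeries | None = None,
    bands: SpeedBands | None = None,
    power_columns: bool = True,
) -> pd.DataFrame:
    """One row per present period with distance (and, optionally, energy)
    columns; energy columns are filled by :mod:`matchload.metabolic_power`.
    """
    from .metabolic_power import EnergyModelParams, energy_by_power_category, metabolic_power

    series = series or estimate_kinematics(track)
    bands = bands or SpeedBands()
    power = metabolic_power(series, EnergyModelParams()) if power_columns else None
    rows = []
    for p in segmented.present:
        idx = segmented.slices[p]
        d = distance_by_speed_category(series, bands, idx)
        row = {
            "match_id": track.match_id,
            "player_id": track.player_id,
            "role": track.role,
            "period": p,
            "coverage": segmented.coverage[p],
            "dist_total_m": float(d.sum()),
        }
        row.update({f"dist_{b}_m": d[i] for i, b in enumerate(SPEED_BAND_NAMES)})
        if power is not None:
            e = energy_by_power_category(power, idx=idx)
            row["ee_total_kjkg"] = float(e.sum())
            for i, name in enumerate(("lp", "ip", "hp", "ep", "mp")):
                row[f"ee_{name}"] = e[i]
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_tracks(
    tracks,
    grid: PeriodGrid | None = None,
    min_coverage: float = 0.5,
    smoothing_window_s: float = 1.0,
    power_columns: bool = True,
) -> pd.DataFrame:
    """Full measurement pipeline for an iterable of post-exclusion tracks.

    Accepts a lazy iterator (e.g. :func:`matchload.synthetic_data.iter_season`)
    so that a large season never needs to be held in memory at once.
    """
    from .tracking_io import segment_periods

    grid = grid or PeriodGrid()
    frames = []
    for tr in tracks:
        seg = segment_periods(tr, grid, min_coverage)
        series = estimate_kinematics(tr, smoothing_window_s)
        frames.append(period_summaries(tr, seg, series, power_columns=power_columns))
    if not frames:
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    return pd.concat(frames, ignore_index=True)


#: constituent periods of each aggregation window
WINDOW_PERIODS: dict[str, tuple[int, ...]] = {
    **{f"q15_{i + 1}": tuple(range(3 * i + 1, 3 * i + 4)) for i in range(6)},
    "half1": tuple(range(1, 10)),
    "half2": tuple(range(10, 19)),
    "match": tuple(range(1, 19)),
}


def aggregate_windows(summaries: pd.DataFrame, windows=None) -> pd.DataFrame:
    """Sum period summaries into 15-min, half and match windows.

    A window is reported for a player-match only when *all* of its
    constituent periods are present (substitutes therefore have no first
    half and no match window).
    """
    windows = windows or WINDOW_PERIODS
    value_cols = [c for c in summaries.columns if c.startswith(("dist_", "ee_"))]
    out = []
    for (mid, pid, role), grp in summaries.groupby(
        ["match_id", "player_id", "role"], sort=False
    ):
        have = set(grp["period"])
        for name, periods in windows.items():
            if not set(periods) <= have:
                continue
            sub = grp[grp["period"].isin(periods)]
            row = {"match_id": mid, "player_id": pid, "role": role, "window": name}
            row.update({c: float(sub[c].sum()) for c in value_cols})
            out.append(row)
    return pd.DataFrame(out)
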