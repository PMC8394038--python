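"""Tracking CSV I/O, exclusion rules and 5-minute-period segmentation.

The tracking dialect is one long CSV with header
``match_id,player_id,role,t_s,x_m,y_m`` (floats with 3 decimals, UTF-8, LF).
``t_s`` is the cumulative playing clock: half 2 starts at the actual end of
half 1 (``half1_end_s`` in the match metadata), which is 2700 s when there
is no extra time.  Exclusions remove goalkeepers, matches flagged erroneous,
and extra time at the end of each half, remapping second-half timestamps
onto the canonical [2700, 5400) clock.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .synthetic_data import PlayerMatchTrack

__all__ = [
    "TRACKING_COLUMNS",
    "MatchMetadata",
    "PeriodGrid",
    "SegmentedTrack",
    "write_tracking",
    "read_tracking",
    "write_truth",
    "write_metadata",
    "read_metadata",
    "apply_exclusions",
    "detect_erroneous",
    "segment_periods",
]

log = logging.getLogger(__name__)

TRACKING_COLUMNS = ("match_id", "player_id", "role", "t_s", "x_m", "y_m")


@dataclass(frozen=True)
class MatchMetadata:
    """Per-match context: actual half end times and the erroneous flag."""

    half1_end_s: float = 2700.0
    half2_end_s: float = 5400.0
    erroneous: bool = False


@dataclass(frozen=True)
class PeriodGrid:
    """The 18 contiguous half-open 5-minute periods of a 90-minute match.

    Period ``p`` (1-based) covers ``[(p-1)*300, p*300)`` s of the canonical
    match clock; periods 1-9 are the first half, 10-18 the second.
    """

    n_periods: int = 18
    period_length_s: float = 300.0

    def bounds(self, p: int) -> tuple[float, float]:
        if not 1 <= p <= self.n_periods:
            raise ValueError(f"period must be in 1..{self.n_periods}")
        return (p - 1) * self.period_length_s, p * self.period_length_s

    def period_of(self, t: np.ndarray) -> np.ndarray:
        """1-based period index of each timestamp (half-open intervals)."""
        return np.floor_divide(np.asarray(t), self.period_length_s).astype(int) + 1


@dataclass
class SegmentedTrack:
    """A player-match track sliced into periods, with per-period coverage."""

    match_id: str
    player_id: str
    role: str
    slices: dict[int, np.ndarray]  # period -> sample index array into track
    coverage: dict[int, float]  # period -> fraction of the period observed
    present: list[int] = field(default_factory=list)  # periods kept


# -- CSV / YAML round trip -----------------------------------------------

def write_tracking(tracks, path) -> None:
    """Write tracks as the long tracking CSV (3-decimal floats, LF)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(TRACKING_COLUMNS) + "\n")
        for tr in tracks:
            head = f"{tr.match_id},{tr.player_id},{tr.role},"
            for ti, xi, yi in zip(tr.t, tr.x, tr.y):
                fh.write(f"{head}{ti:.3f},{xi:.3f},{yi:.3f}\n")


def read_tracking(path, drop_goalkeepers: bool = True) -> list[PlayerMatchTrack]:
    """Parse the tracking CSV into per-player-match tracks.

    Goalkeeper rows are dropped with a logged count.  Malformed rows raise
    with the offending line number; non-monotone timestamps raise naming
    the player-match.
    """
    with open(path, encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or tuple(header) != TRACKING_COLUMNS:
            raise ValueError(f"unexpected tracking header in {path}: {header}")
        data: dict[tuple[str, str], dict] = {}
        n_gk = 0
        for lineno, row in enumerate(reader, start=2):
            if len(row) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 fields, got {len(row)}")
            match_id, player_id, role = row[0], row[1], row[2]
            try:
                t, x, y = float(row[3]), float(row[4]), float(row[5])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            if drop_goalkeepers and role == "goalkeeper":
                n_gk += 1
                continue
            rec = data.setdefault(
                (match_id, player_id), {"role": role, "t": [], "x": [], "y": []}
            )
            rec["t"].append(t)
            rec["x"].append(x)
            rec["y"].append(y)
    if n_gk:
        log.warning("dropped %d goalkeeper samples", n_gk)

    tracks = []
    for (match_id, player_id), rec in data.items():
        t = np.asarray(rec["t"])
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError(
                f"non-monotone timestamps for player-match {match_id}/{player_id}"
            )
        tracks.append(
            PlayerMatchTrack(
                match_id=match_id,
                player_id=player_id,
                role=rec["role"],
                entry_minute=float(t[0] // 60.0) if t.size else 0.0,
                exit_minute=90.0,
                t=t,
                x=np.asarray(rec["x"]),
                y=np.asarray(rec["y"]),
            )
        )
    return tracks


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False, lineterminator="\n")


def write_metadata(meta: dict[str, MatchMetadata], path) -> None:
    doc = {
        mid: {
            "half1_end_s": m.half1_end_s,
            "half2_end_s": m.half2_end_s,
            "erroneous": m.erroneous,
        }
        for mid, m in meta.items()
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_metadata(path) -> dict[str, MatchMetadata]:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return {
        mid: MatchMetadata(
            half1_end_s=float(d.get("half1_end_s", 2700.0)),
            half2_end_s=float(d.get("half2_end_s", 5400.0)),
            erroneous=bool(d.get("erroneous", False)),
        )
        for mid, d in doc.items()
    }


# -- exclusions ----------------------------------------------------------

def apply_exclusions(
    tracks, match_metadata: dict[str, MatchMetadata]
) -> list[PlayerMatchTrack]:
    """Drop goalkeepers and erroneous matches; trim extra time.

    Samples beyond minute 45 of half 1 are removed and second-half samples
    are remapped onto the canonical [2700, 5400) clock; samples beyond
    minute 90 of half 2 are removed.
    """
    out = []
    n_gk = n_err = 0
    for tr in tracks:
        if tr.role == "goalkeeper":
            n_gk += 1
            continue
        if tr.match_id not in match_metadata:
            raise KeyError(f"missing metadata for match {tr.match_id}")
        meta = match_metadata[tr.match_id]
        if meta.erroneous:
            n_err += 1
            continue
        t = tr.t
        first = t < min(2700.0, meta.half1_end_s)
        second = (t >= meta.half1_end_s) & (t < meta.half1_end_s + 2700.0)
        t_new = np.concatenate([t[first], t[second] - (meta.half1_end_s - 2700.0)])
        keep = np.concatenate([np.flatnonzero(first), np.flatnonzero(second)])
        out.append(
            PlayerMatchTrack(
                match_id=tr.match_id,
                player_id=tr.player_id,
                role=tr.role,
                entry_minute=tr.entry_minute,
                exit_minute=tr.exit_minute,
                t=t_new,
                x=tr.x[keep],
                y=tr.y[keep],
                is_underperformance=tr.is_underperformance,
                multiplier=tr.multiplier,
            )
        )
    if n_gk or n_err:
        log.info("excluded %d goalkeeper tracks, %d erroneous-match tracks", n_gk, n_err)
    return out


def detect_erroneous(
    track: PlayerMatchTrack,
    max_missing_fraction: float = 0.05,
    max_speed_ms: float = 12.0,
) -> bool:
    """Flag a track whose data quality disqualifies the match.

    A track is erroneous when more than ``max_missing_fraction`` of the
    expected samples over its play span are missing, or when any
    point-to-point speed exceeds ``max_speed_ms`` (faster than any human
    sprint; a tracking glitch).  Both bounds are configurable — the
    operationalization is this package's convention.
    """
    if track.n_samples < 2:
        return True
    t = track.t
    dt = np.median(np.diff(t))
    expected = (t[-1] - t[0]) / dt + 1
    if 1.0 - track.n_samples / expected > max_missing_fraction:
        return True
    step_speed = np.hypot(np.diff(track.x), np.diff(track.y)) / np.diff(t)
    return bool(np.any(step_speed > max_speed_ms))


# -- segmentation --------------------------------------------------------

def segment_periods(
    track: PlayerMatchTrack, grid: PeriodGrid | None = None, min_coverage: float = 0.5
) -> SegmentedTrack:
    """Slice a post-exclusion track into 5-minute periods.

    A period is present iff the fraction of its span covered by samples is
    ``>= min_coverage`` (ties kept); per-period quantities are never
    pro-rated.  Substitutes' pre-entry periods have coverage 0 and are
    absent.
    """
    if track.n_samples == 0:
        raise ValueError(f"empty track {track.match_id}/{track.player_id}")
    grid = grid or PeriodGrid()
    period = grid.period_of(track.t)
    dt = track.dt if track.n_samples > 1 else grid.period_length_s
    slices: dict[int, np.ndarray] = {}
    coverage: dict[int, float] = {}
    present: list[int] = []
    for p in range(1, grid.n_periods + 1):
        idx = np.flatnonzero(period == p)
        cov = idx.size * dt / grid.period_length_s if idx.size else 0.0
        coverage[p] = min(float(cov), 1.0)
        if idx.size and coverage[p] >= min_coverage:
            slices[p] = idx
            present.append(p)
    return SegmentedTrack(
        match_id=track.match_id,
        player_id=track.player_id,
        role=track.role,
        slices=slices,
        coverage=coverage,
        present=present,
    )
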