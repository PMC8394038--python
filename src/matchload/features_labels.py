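"""Individualized season baselines, normalized feature rows and
underperformance labels.

A player's *personal baseline* is the season mean of each load variable per
5-minute period, computed over that player's entire matches only (players
with fewer than ``min_matches`` entire matches are excluded).  Features
normalize a match against the baseline: for period ``p``,

    pct_avg(p)        = 100 * observed(p) / baseline(p)
    pct_avg_summed(p) = 100 * sum_{1..p} observed / sum_{1..p} baseline

with one row per (player-match, period) and the feature set determined by
the variable set: ``distance`` (total distance; 3 features incl. period),
``speed`` (five speed bands; 11 features), ``power`` (five power bands;
11 features).

A match is labeled underperforming at threshold T in {1.00, 0.95, 0.90}
when the match-total outcome (distance in m, or energy in kJ/kg for the
power set) falls strictly below T times the baseline match total; a tie
counts as performing.  By default the baseline includes all of a player's
entire matches (a match is therefore part of its own baseline);
``holdout=True`` switches to leave-one-match-out baselines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "VARIABLE_SETS",
    "SeasonBaseline",
    "compute_season_baseline",
    "build_features",
    "label_performance",
]

#: quantity columns per variable set (summaries-table column names)
VARIABLE_SETS: dict[str, list[str]] = {
    "distance": ["dist_total_m"],
    "speed": ["dist_vlir_m", "dist_lir_m", "dist_mir_m", "dist_hir_m", "dist_vhir_m"],
    "power": ["ee_lp", "ee_ip", "ee_hp", "ee_ep", "ee_mp"],
}

#: match-level outcome quantity per variable set
OUTCOME_COLUMN: dict[str, str] = {
    "distance": "dist_total_m",
    "speed": "dist_total_m",
    "power": "ee_total_kjkg",
}

DEFAULT_THRESHOLDS = (1.00, 0.95, 0.90)


@dataclass
class SeasonBaseline:
    """Per-player per-period season means over entire matches."""

    per_period: pd.DataFrame  # index (player_id, period), quantity columns
    n_matches: pd.Series  # player_id -> number of entire matches used
    min_matches: int

    def players(self) -> list[str]:
        return list(self.n_matches.index)

    def match_total(self, quantity: str) -> pd.Series:
        """Baseline match total per player: sum of per-period means."""
        return self.per_period[quantity].groupby(level="player_id").sum()


def _entire_complete(summaries: pd.DataFrame) -> pd.DataFrame:
    """Entire-match rows restricted to player-matches with all 18 periods."""
    ent = summaries[summaries["role"] == "entire"]
    counts = ent.groupby(["match_id", "player_id"])["period"].transform("size")
    return ent[counts == 18]


def compute_season_baseline(
    summaries: pd.DataFrame, min_matches: int = 3
) -> SeasonBaseline:
    """Arithmetic per-period means over each player's entire matches.

    Players with fewer than ``min_matches`` entire matches are dropped with
    a logged count.
    """
    ent = _entire_complete(summaries)
    if ent.empty:
        raise ValueError("no complete entire-match rows to build baselines from")
    quantity_cols = [c for c in ent.columns if c.startswith(("dist_", "ee_"))]
    n = ent.groupby("player_id")["match_id"].nunique()
    keep = n[n >= min_matches].index
    if len(keep) < len(n):
        log.info("excluded %d players with < %d entire matches", len(n) - len(keep), min_matches)
    ent = ent[ent["player_id"].isin(keep)]
    if ent.empty:
        raise ValueError(f"no player has >= {min_matches} entire matches")
    per_period = ent.groupby(["player_id", "period"])[quantity_cols].mean()
    return SeasonBaseline(per_period=per_period, n_matches=n.loc[keep], min_matches=min_matches)


def _percent(observed: np.ndarray, base: np.ndarray) -> np.ndarray:
    """100 * observed / base; (0, 0) scores 100.0, (x>0, 0) is NaN."""
    out = np.full(observed.shape, np.nan)
    nz = base != 0
    out[nz] = 100.0 * observed[nz] / base[nz]
    both_zero = (~nz) & (observed == 0)
    out[both_zero] = 100.0
    return out


def build_features(
    summaries: pd.DataFrame,
    baseline: SeasonBaseline,
    variable_set: str,
    holdout: bool = False,
) -> pd.DataFrame:
    """One feature row per (entire player-match, period) for a variable set.

    Rows whose features are undefined (a zero baseline with nonzero
    observation) are dropped with a logged count.
    """
    if variable_set not in VARIABLE_SETS:
        raise ValueError(f"unknown variable_set {variable_set!r}")
    cols = VARIABLE_SETS[variable_set]
    ent = _entire_complete(summaries)
    ent = ent[ent["player_id"].isin(baseline.players())]
    ent = ent.sort_values(["player_id", "match_id", "period"])

    base = baseline.per_period[cols]
    merged = ent.join(base, on=["player_id", "period"], rsuffix="_base")
    n_m = baseline.n_matches

    out = pd.DataFrame(
        {
            "match_id": merged["match_id"].to_numpy(),
            "player_id": merged["player_id"].to_numpy(),
            "period": merged["period"].to_numpy(),
        }
    )
    grp = [merged["player_id"].to_numpy(), merged["match_id"].to_numpy()]
    for c in cols:
        obs = merged[c].to_numpy(float)
        bas = merged[f"{c}_base"].to_numpy(float)
        if holdout:
            n = n_m.reindex(merged["player_id"]).to_numpy(float)
            bas = (bas * n - obs) / (n - 1.0)
        obs_cum = pd.Series(obs).groupby(grp).cumsum().to_numpy()
        bas_cum = pd.Series(bas).groupby(grp).cumsum().to_numpy()
        name = c.removeprefix("dist_").removesuffix("_m").removeprefix("ee_")
        name = "distance" if name == "total" else name
        out[f"pct_avg_{name}"] = _percent(obs, bas)
        out[f"pct_avg_summed_{name}"] = _percent(obs_cum, bas_cum)
    feat_cols = [c for c in out.columns if c.startswith("pct_")]
    bad = out[feat_cols].isna().any(axis=1)
    if bad.any():
        log.info("dropped %d feature rows with undefined (zero-baseline) features", int(bad.sum()))
    return out[~bad].reset_index(drop=True)


def label_performance(
    summaries: pd.DataFrame,
    baseline: SeasonBaseline,
    variable_set: str = "distance",
    thresholds=DEFAULT_THRESHOLDS,
    holdout: bool = False,
) -> pd.DataFrame:
    """Match-level performance labels for entire player-matches.

    Returns one row per player-match with the outcome quantity, the ratio
    to the baseline match total, and nested flags ``underperf_T`` for each
    threshold (ratio < T; a tie is performing).
    """
    outcome_col = OUTCOME_COLUMN[variable_set]
    ent = _entire_complete(summaries)
    ent = ent[ent["player_id"].isin(baseline.players())]
    totals = (
        ent.groupby(["match_id", "player_id"], as_index=False)[outcome_col]
        .sum()
        .rename(columns={outcome_col: "outcome"})
    )
    base_total = baseline.match_total(outcome_col)
    totals["baseline_total"] = base_total.reindex(totals["player_id"]).to_numpy()
    if holdout:
        n = baseline.n_matches.reindex(totals["player_id"]).to_numpy(float)
        totals["baseline_total"] = (totals["baseline_total"] * n - totals["outcome"]) / (n - 1.0)
    totals["ratio"] = totals["outcome"] / totals["baseline_total"]
    for thr in sorted(thresholds, reverse=True):
        totals[f"underperf_{int(round(thr * 100))}"] = totals["ratio"] < thr
    return totals
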