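"""Season baselines, normalized features, and threshold labels."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from matchload.features_labels import (
    VARIABLE_SETS,
    build_features,
    compute_season_baseline,
    label_performance,
)

QUANTITY_COLS = [
    "dist_total_m", "dist_subvlir_m", "dist_vlir_m", "dist_lir_m", "dist_mir_m",
    "dist_hir_m", "dist_vhir_m", "ee_total_kjkg", "ee_lp", "ee_ip", "ee_hp",
    "ee_ep", "ee_mp",
]


def toy_summaries(per_match_scale, player_id="P1", role="entire", base_period=300.0):
    """One row per (match, period); dist_total = scale * base_period, other
    quantities proportional."""
    rows = []
    for m, scale in enumerate(per_match_scale):
        for p in range(1, 19):
            row = {"match_id": f"M{m}", "player_id": player_id, "role": role,
                   "period": p, "coverage": 1.0}
            for c in QUANTITY_COLS:
                row[c] = scale * base_period * (1.0 if c == "dist_total_m" else 0.1)
            rows.append(row)
    return pd.DataFrame(rows)


class TestBaseline:
    def test_identical_matches_baseline_equals_single_match(self):
        summ = toy_summaries([1.0] * 5)
        base = compute_season_baseline(summ, min_matches=3)
        assert np.allclose(base.per_period["dist_total_m"], 300.0)
        assert base.n_matches["P1"] == 5

    def test_player_below_min_matches_excluded(self):
        summ = pd.concat(
            [toy_summaries([1.0] * 5, "P1"), toy_summaries([1.0] * 2, "P2")],
            ignore_index=True,
        )
        base = compute_season_baseline(summ, min_matches=3)
        assert base.players() == ["P1"]

    def test_arithmetic_mean_of_period_values(self):
        # period-1 distances 280/300/320 -> baseline 300
        summ = toy_summaries([280 / 300, 1.0, 320 / 300])
        base = compute_season_baseline(summ, min_matches=3)
        assert base.per_period.loc[("P1", 1), "dist_total_m"] == pytest.approx(300.0)

    def test_substitute_rows_never_enter_baselines(self):
        summ = pd.concat(
            [toy_summaries([1.0] * 4, "P1"), toy_summaries([10.0] * 4, "P1", role="substitute")],
            ignore_index=True,
        )
        base = compute_season_baseline(summ, min_matches=3)
        assert np.allclose(base.per_period["dist_total_m"], 300.0)

    def test_cumulative_baseline_equals_running_sum(self):
        summ = toy_summaries([0.9, 1.0, 1.1])
        base = compute_season_baseline(summ)
        per_p = base.per_period.loc["P1", "dist_total_m"]
        assert per_p.cumsum().iloc[-1] == pytest.approx(base.match_total("dist_total_m")["P1"])


class TestFeatures:
    def test_match_identical_to_baseline_gives_100(self):
        summ = toy_summaries([1.0] * 4)
        base = compute_season_baseline(summ)
        feats = build_features(summ, base, "distance")
        pct_cols = [c for c in feats.columns if c.startswith("pct_")]
        assert np.allclose(feats[pct_cols], 100.0)

    def test_pct_avg_ratio_arithmetic(self):
        # three baseline matches at 350 m per period; the probe match at 280
        base_rows = toy_summaries([350.0 / 300.0] * 3)
        probe = toy_summaries([1.0])
        probe["match_id"] = "M9"
        probe[QUANTITY_COLS] = 280.0
        full = pd.concat([base_rows, probe], ignore_index=True)
        base = compute_season_baseline(base_rows)
        feats = build_features(full, base, "distance")
        row = feats[(feats.match_id == "M9") & (feats.period == 3)]
        assert row["pct_avg_distance"].item() == pytest.approx(80.0)

    def test_cumulative_percentage(self):
        # observed periods 1-3 = 300 each; baseline 350/300/250 -> summed 100%
        per_period_base = {1: 350.0, 2: 300.0, 3: 250.0}
        rows = []
        for m in range(3):
            for p in range(1, 19):
                base_val = per_period_base.get(p, 300.0)
                rows.append({"match_id": f"M{m}", "player_id": "P1", "role": "entire",
                             "period": p, "coverage": 1.0,
                             **{c: base_val for c in QUANTITY_COLS}})
        summ = pd.DataFrame(rows)
        probe = summ[summ.match_id == "M0"].copy()
        probe["match_id"] = "M9"
        probe[QUANTITY_COLS] = 300.0
        full = pd.concat([summ, probe], ignore_index=True)
        base = compute_season_baseline(summ)
        feats = build_features(full, base, "distance")
        row = feats[(feats.match_id == "M9") & (feats.period == 3)]
        assert row["pct_avg_summed_distance"].item() == pytest.approx(100.0 * 900 / 900)

    def test_feature_counts_per_variable_set(self):
        summ = toy_summaries([1.0] * 4)
        base = compute_season_baseline(summ)
        for vset, n_features in (("distance", 3), ("speed", 11), ("power", 11)):
            feats = build_features(summ, base, vset)
            cols = ["period"] + [c for c in feats.columns if c.startswith("pct_")]
            assert len(cols) == n_features

    def test_zero_baseline_zero_observation_scores_100(self):
        summ = toy_summaries([1.0] * 4)
        summ["dist_vhir_m"] = 0.0
        base = compute_season_baseline(summ)
        feats = build_features(summ, base, "speed")
        assert np.allclose(feats["pct_avg_vhir"], 100.0)

    def test_unknown_variable_set_rejected(self):
        summ = toy_summaries([1.0] * 4)
        base = compute_season_baseline(summ)
        with pytest.raises(ValueError, match="variable_set"):
            build_features(summ, base, "heartrate")


class TestLabels:
    def test_threshold_flags_at_094(self):
        summ = toy_summaries([1.0, 1.0, 1.0, 1.0])
        probe = summ[summ.match_id == "M0"].copy()
        probe["match_id"] = "M9"
        probe[QUANTITY_COLS] *= 0.94
        full = pd.concat([summ, probe], ignore_index=True)
        base = compute_season_baseline(summ)
        lab = label_performance(full, base, "distance").set_index("match_id")
        assert lab.loc["M9", "ratio"] == pytest.approx(0.94)
        assert lab.loc["M9", "underperf_100"]
        assert lab.loc["M9", "underperf_95"]
        assert not lab.loc["M9", "underperf_90"]

    def test_exact_ratio_one_is_performing(self):
        summ = toy_summaries([1.0] * 4)
        base = compute_season_baseline(summ)
        lab = label_performance(summ, base, "distance")
        assert not lab[["underperf_100", "underperf_95", "underperf_90"]].any().any()
        assert np.allclose(lab["ratio"], 1.0)

    def test_label_nesting_invariant_on_random_seasons(self):
        rng = np.random.default_rng(5)
        summ = pd.concat(
            [toy_summaries(rng.lognormal(0, 0.1, 8), pid) for pid in ("P1", "P2", "P3")],
            ignore_index=True,
        )
        base = compute_season_baseline(summ)
        lab = label_performance(summ, base, "distance")
        assert (lab["underperf_90"] <= lab["underperf_95"]).all()
        assert (lab["underperf_95"] <= lab["underperf_100"]).all()

    @settings(max_examples=30, deadline=None)
    @given(st.floats(min_value=0.5, max_value=1.5))
    def test_ratio_consistency_with_summed_feature(self, scale):
        """pct_avg_summed at period 18 equals 100 * label ratio."""
        summ = toy_summaries([1.0] * 3)
        probe = summ[summ.match_id == "M0"].copy()
        probe["match_id"] = "M9"
        probe[QUANTITY_COLS] *= scale
        full = pd.concat([summ, probe], ignore_index=True)
        base = compute_season_baseline(summ)
        feats = build_features(full, base, "distance")
        lab = label_performance(full, base, "distance").set_index("match_id")
        p18 = feats[(feats.match_id == "M9") & (feats.period == 18)]
        assert p18["pct_avg_summed_distance"].item() == pytest.approx(
            100.0 * lab.loc["M9", "ratio"], rel=1e-9
        )

    def test_baseline_idempotence(self):
        """A season of identical matches relabels every match at ratio 1."""
        summ = toy_summaries([1.0] * 6)
        base = compute_season_baseline(summ)
        lab = label_performance(summ, base, "distance")
        assert np.allclose(lab["ratio"], 1.0)

    def test_holdout_baseline_excludes_own_match(self):
        summ = toy_summaries([0.8, 1.0, 1.2])
        base = compute_season_baseline(summ)
        lab = label_performance(summ, base, "distance", holdout=True).set_index("match_id")
        # match M0 at 0.8: leave-one-out baseline is mean(1.0, 1.2) = 1.1
        assert lab.loc["M0", "ratio"] == pytest.approx(0.8 / 1.1)
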