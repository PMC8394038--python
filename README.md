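# matchload

Early in-match prediction of a soccer player's physical underperformance
from position tracking data — for sports scientists and performance
analysts who want to know, 15 minutes into a match, whether a player is
likely to fall short of their usual output.

## What it does

Professional matches are tracked at ~10 Hz. From the planar positions
`(x, y)` of one player, `matchload` computes per 5-minute period:

- **type-1 load**: total distance and distance per speed band
  (VLIR 0.7–7.2, LIR 7.2–14.4, MIR 14.4–19.8, HIR 19.8–25.2,
  VHIR ≥ 25.2 km·h⁻¹);
- **type-2 load**: energy expenditure per metabolic-power band
  (LP/IP/HP/EP/MP at 10/20/35/55 W·kg⁻¹ bounds), with instantaneous power
  `P = EC(ES)·v` from the equivalent-slope model `ES = a/g`,
  `EC = poly(ES)·√(ES²+1)·KT`.

Each match is then normalized against the player's *personal baseline* —
their per-period season mean over entire matches — yielding percentage
features per period, and labeled **underperforming** at a threshold
`T ∈ {100%, 95%, 90%}` when the match total falls below `T ×` the baseline
match total. Classifiers (random forest, decision tree, Gaussian naive
Bayes) are trained on a 70/30 split with SMOTE rebalancing and randomized
hyperparameter search, and evaluated with per-period precision curves, so
you can read off how early in the match predictions become reliable.
Nonparametric cohort statistics (Lilliefors/KS normality screen,
Kruskal–Wallis with ε² effect sizes, Conover–Iman post-hoc) cover the
descriptive side, including entire-match vs substitute contrasts.

Because real tracking feeds are proprietary, the package ships a
calibrated synthetic season generator (`matchload.synthetic_data`): a
bout-based kinematic model whose cohort, pushed through the *measurement*
pipeline, reproduces reference half-level descriptives (first-half total
5275 m, LIR 2345 m, MIR 888 m, HIR 290 m; second-half 4906 m; half-time
substitutes 5123 m). See `docs/methods.md` for the model, the calibration
and its limits.

## Worked example

```python
import numpy as np
from matchload import (
    default_cohort_config, iter_season, summarize_tracks,
    compute_season_baseline, build_features, label_performance,
    SplitSpec, run_experiment,
)

cfg = default_cohort_config(n_players=40, matches_per_player=10,
                            sampling_rate=5.0, seed=7)
summaries = summarize_tracks(iter_season(cfg))

ent = summaries[summaries.role == "entire"]
h1 = ent[ent.period <= 9].groupby(["match_id", "player_id"]).dist_total_m.sum()
h2 = ent[ent.period > 9].groupby(["match_id", "player_id"]).dist_total_m.sum()
print(f"first half  {h1.mean():7.1f} m ± {h1.std():.0f}")
print(f"second half {h2.mean():7.1f} m ± {h2.std():.0f}")

baseline = compute_season_baseline(summaries)
features = build_features(summaries, baseline, "power")
labels = label_performance(summaries, baseline, "power")
print("underperformance share at 95%:", round(labels.underperf_95.mean(), 3))

reports = run_experiment(
    {"power": features}, {"power": labels},
    thresholds=(0.95,), algorithms=("random_forest", "naive_bayes"),
    split=SplitSpec(seed=7),
    model_kwargs={"n_search_iterations": 6, "cv_folds": 3}, seed=7,
)
for r in reports:
    print(r.algorithm, "precision(underperforming) =",
          round(r.precision["underperforming"], 3))
```

prints (seed 7):

```
first half   5251.5 m ± 486
second half  4882.7 m ± 462
underperformance share at 95%: 0.266
random_forest precision(underperforming) = 0.822
naive_bayes precision(underperforming) = 0.729
```

— the simulated cohort declines by ~7% from first to second half, roughly
a fifth of matches miss 95% of the player's personal baseline, and the
tuned random forest is more precise than the naive-Bayes baseline at
flagging them. `ModelReport.per_period_precision` holds the per-period
curves behind the "how early is prediction reliable" question.

A baseline caveat: by default a match is included in its own season
baseline (matching the source procedure); pass `holdout=True` to
`build_features`/`label_performance` for leave-one-match-out baselines.

## Command line

```sh
matchload simulate --seed 7 --out season/
matchload features --in season/ --out summaries.csv
matchload label --summaries summaries.csv --variable-set power --out labels.csv
matchload train --summaries summaries.csv --seed 7 --out reports/
matchload stats --summaries summaries.csv --out contrasts.csv
```

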