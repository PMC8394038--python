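# Methods

`matchload` implements an end-to-end pipeline for early in-match prediction
of a professional soccer player's physical underperformance from position
tracking data, together with a calibrated synthetic tracking generator that
makes every stage testable without proprietary data. This note documents
the models, the parameters that matter, the calibration, and the limits of
what the synthetic experiments show.

## Measurement model

**Kinematics.** Player speed is obtained from planar positions by centered
finite differences, followed by a centered moving average (default 1 s,
configurable); signed tangential acceleration is the centered difference of
the smoothed speed. Endpoints use one-sided differences. Vendor tracking
systems apply their own (undisclosed) filtering; the 1 s moving average is
this package's declared convention and all shipped calibration constants
are defined with respect to it.

**Type-1 load variables.** Distance increments `v·Δt` are accumulated per
5-minute period, total and per speed band (km/h, half-open, a tie joins the
upper band):

| band | VLIR | LIR | MIR | HIR | VHIR |
|------|------|-----|-----|-----|------|
| km/h | 0.7–7.2 | 7.2–14.4 | 14.4–19.8 | 19.8–25.2 | ≥ 25.2 |

Speeds below 0.7 km/h go to an explicit sub-VLIR bucket that is counted in
the total, so band distances conserve the total exactly (a published
variant of these bands leaves a 25.1–25.2 km/h gap from rounding; the
contiguous 25.2 boundary is used because conservation requires contiguity).

**Type-2 load variable.** Instantaneous metabolic power follows the
equivalent-slope energy-cost model of accelerated running: `ES = a/g`,
equivalent mass `EM = √(ES²+1)`, energy cost

```
EC(ES) = (155.4·ES⁵ − 30.4·ES⁴ − 43.3·ES³ + 46.3·ES² + 19.5·ES + 3.6) · EM · KT
```

in J·kg⁻¹·m⁻¹ with terrain constant `KT = 1.29` (grass), and power
`P = EC·v` in W·kg⁻¹. Energy increments `P·Δt` are accumulated per power
band (LP 0–10, IP 10–20, HP 20–35, EP 35–55, MP ≥ 55 W·kg⁻¹). Guards:
`ES` is clipped to ±1 and `EC` floored at 0 to contain differentiation
spikes; both are configurable (`EnergyModelParams`) and the defaults are
part of the shipped measurement convention. The running cost function is
applied at all speeds (no walking-specific branch), as is usual in
match-analysis applications of this model.

**Periods and windows.** A match is 18 contiguous half-open 5-minute
periods on the canonical playing clock (periods 1–9 first half, 10–18
second half; a sample at exactly `t = 300k` s joins period `k+1`). Extra
time and goalkeepers are excluded before segmentation; a match can also be
flagged erroneous, either externally (metadata) or by the shipped detector
(> 5% missing samples or any point-to-point speed above 12 m·s⁻¹ — a
configurable convention, since "erroneous" has no standard definition). A substitute's
period is included iff its coverage is ≥ `min_coverage` (default 0.5, ties
kept); partial periods are never pro-rated, because pro-rating would
distort band distances in role comparisons. Window (15-min, half, match)
values are sums of constituent periods and are reported only when all
constituents are present.

## Baselines, features, labels

A player's *personal baseline* is the per-period season mean of each load
variable over all of that player's entire matches (players with fewer than
`min_matches = 3` entire matches are excluded; three repeated measures is
the conventional minimum for a stable habitual-activity estimate).
Features normalize a match against the baseline per period: the percentage
in the period itself and the cumulative percentage up to and including the
period, per variable set (total distance: 3 features including the period
index; five speed bands or five power bands: 11 features). A match is
labeled underperforming at threshold `T ∈ {1.00, 0.95, 0.90}` when its
total outcome (distance, or energy for the power set) is strictly below
`T ×` baseline match total; a tie is performing, so the flags nest.

Two conventions deserve attention:

- **Leakage.** By default a match is part of its own season baseline
  (mirroring the source procedure's description); `holdout=True` computes
  leave-one-match-out baselines. With ≥ 10 matches per player the
  difference in ratios is below 1%.
- **Zero baselines.** A band with baseline 0 and observation 0 scores
  100.0 (at baseline); baseline 0 with a positive observation is undefined
  and the row is dropped with a logged count. Without the first rule the
  speed variable set would lose most rows whenever a player never sprints
  above 25.2 km/h in a season.

## Classification protocol

Feature rows (one per player-match × period; substitutes excluded, since
labels need full-match totals) are split 70/30. The default split is
grouped by player-match so no match contributes rows to both sides;
`unit="rows"` mimics a plain row split, which leaks sibling periods of a
test match into training and inflates early-period metrics — both modes
are first-class and reported separately. Training rows are rebalanced by
SMOTE (synthetic minority rows interpolated between k = 5 minority nearest
neighbours, k reduced with a warning for tiny minorities; test rows are
never touched). Random forest and decision tree hyperparameters are tuned
by randomized search (default 30 draws, 5-fold stratified CV) scored by
the F1 of the underperforming class; Gaussian naive Bayes is the untuned
baseline. Reports contain accuracy, AUC, per-class precision/recall/F1,
confusion counts, and per-period precision curves computed on the test
rows of each period (periods with no prediction of a class are omitted).

## Cohort statistics

Normality screening uses a Kolmogorov–Smirnov test against a normal with
estimated parameters and Lilliefors-corrected critical values (estimating
mean/SD without the correction is anti-conservative). Group contrasts use
the tie-corrected Kruskal–Wallis H with effect size
`ε² = H·(n+1)/(n²−1)`; note that for k equal perfectly-separated groups
this effect size saturates at `1 − 1/k²`, not 1. When every observation is
tied, H is defined as 0. Localized effects use Conover–Iman pairwise tests
on the joint ranks with the pooled variance estimate and t-distributed
p-values (df = n − k), reported unadjusted (the source procedure's
behaviour, α = 0.01) and Holm-adjusted. No multiplicity adjustment is
applied across the many omnibus tests. The substitution-timing question
(are entries concentrated late?) is answered by a chi-square
goodness-of-fit across 5-minute bins plus a binomial contrast of early
(< 60 min) against late entries — the choice of test is this package's
convention.

## Synthetic-data generator

Real tracking feeds are proprietary, so seasons are simulated. Each
player-match trajectory alternates activity bouts: a state
(stand/walk/jog/run/sprint) drawn from the player's propensities, a
duration from an exponential with state-specific mean (clipped to
[1 s, 4× mean]), and a speed uniform within the state's range. Bout speed
is scaled by the period's decline factor (entire-match players only; 1.0
for substitutes), the match's underperformance multiplier, a per-match
lognormal jitter (σ = 0.04), the player's habitual intensity (lognormal
σ = 0.02, plus a lognormal σ = 0.10 perturbation of the state weights),
and the calibrated global intensity scale. Heading performs a Gaussian
random walk (0.8 rad/√s) and positions integrate the velocity; the path is
kept on the 105 × 68 m pitch by reflective folding, which preserves speed
everywhere except at the measure-zero fold instants. One global seed fans
out to per-player-match `SeedSequence(seed, spawn_key=(player, match))`
streams, so generation is deterministic and order-independent.

Season structure: a fraction q = 0.2 of player-matches are
underperformance matches with a global multiplier ~ U(0.80, 0.95); 24% of
appearances are substitutes, entering on 5-minute boundaries with 45% mass
at half-time and the rest between minutes 60 and 85; substitutes use no
decline but a calibrated pacing factor of 0.969 (bench players pace
slightly below fresh starters, which is what the cohort's substitute
descriptive implies). Goalkeepers are not generated; they would be
excluded downstream anyway.

**Calibration.** The shipped profile (`default_cohort_config`) was fitted
once, by damped fixed-point iteration against the *measured* pipeline at
5 Hz averaged over four seeds, to the cohort's printed half-level
descriptives: first-half total 5275 m, LIR 2345 m, MIR 888 m, HIR 290 m;
second-half total 4906 m; half-time substitutes 5123 m in the second half.
The fitted knobs are the five state weights, the second-half decline
factors (linear, 0.962 → 0.898), the substitute pacing factor, and a
global intensity scale (0.9946); the multi-seed calibration residual is
within ±0.1% of every target. Calibration is to means only: simulated
between-match SDs are larger than the cohort's printed SDs chiefly because
the underperformance multiplier adds variance, and the 90-minute energy
distribution is *not* separately calibrated (a bout model with constant
within-bout speed cannot match both the printed distance-band means and
the printed energy-band means; the IP energy of the simulated cohort is
~10 kJ·kg⁻¹ per half against a printed 7.26). Distance-based quantities
are therefore the calibrated ground; power-based quantities are faithful
to the energy model but not to the cohort's printed energy descriptives.

**What the generator does not emulate.** Ball and opponent interactions,
tactical structure, contextual covariates, vendor measurement noise, extra
time, and any within-half autocorrelation of intensity beyond the bout
process. Passing tests therefore show that the *pipeline* recovers the
structure this generator injects — not that the classifier's absolute
metrics transfer to real tracking data.

## Problem sizes in the shipped experiments

The calibration suite simulates 700 player-matches at 5 Hz (≥ 300 entire,
≥ 150 substitutes) and compares cohort means within 3 player-clustered
standard errors (players carry random effects, so the naive per-match SE
would be anti-conservative). The parameter-recovery suite uses seasons of
150 players × 10 matches at 2 Hz across 3 seeds, with a reduced randomized
search (6 draws, 3-fold CV, ≤ 120 trees); the reduced search was verified
to select within a few hundredths of F1 of larger searches on these data.
The acceptance script simulates 135 players × 12 matches at 5 Hz.

## Known limitations

- The bout model's within-bout constant speed under-represents brief
  accelerations; EP/MP energies arise mostly at bout transitions and are
  sampling-rate sensitive below ~5 Hz.
- The decline profile multiplies speeds, so band migration (e.g. jog
  speeds slipping below 7.2 km/h late in the match) is the mechanism
  behind the second-half VLIR rise; real fatigue may instead change bout
  selection.
- `ε²` and the Conover statistics assume independent observations; the
  per-period contrasts reuse players across periods, as in the source
  procedure, and should be read descriptively.
- Classifier metrics on synthetic seasons depend strongly on the injected
  underperformance mechanism (a single global multiplier); real
  underperformance is unlikely to be this homogeneous.
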