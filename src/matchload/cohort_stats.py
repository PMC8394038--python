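"""Nonparametric cohort statistics: normality screening, Kruskal-Wallis
with epsilon-squared effect sizes, Conover-Iman post-hoc comparisons, and
entire-match vs substitute contrasts.

Normality is screened with a Kolmogorov-Smirnov test against a normal with
estimated mean/SD using Lilliefors-corrected critical values (estimating
the parameters without the correction is anti-conservative).  Group
differences use the Kruskal-Wallis H test (tie-corrected, chi-square
approximation) with the rank-based effect size

    epsilon^2 = H * (n + 1) / (n^2 - 1),

0 meaning no relationship and 1 a perfect one.  Localized effects are
probed with Conover-Iman pairwise tests on the joint ranks with the pooled
variance estimate; p-values come from the t distribution with n - k
degrees of freedom and are reported both unadjusted and Holm-adjusted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from .time_motion import WINDOW_PERIODS

log = logging.getLogger(__name__)

__all__ = [
    "KWResult",
    "PosthocMatrix",
    "ks_normality",
    "kruskal_wallis_epsilon",
    "conover_posthoc",
    "contrast_entire_vs_substitutes",
    "substitution_timing_test",
]


@dataclass
class KWResult:
    h: float
    p: float
    epsilon2: float
    group_sizes: tuple[int, ...]
    grouping: str = ""


@dataclass
class PosthocMatrix:
    """Pairwise Conover-Iman p-values (symmetric, diagonal 1)."""

    p_values: np.ndarray
    p_holm: np.ndarray
    reject: np.ndarray  # unadjusted p < alpha, as in the source procedure
    alpha: float


def ks_normality(values) -> float:
    """Lilliefors-corrected KS p-value for normality with estimated mean/SD."""
    values = np.asarray(values, dtype=float)
    if values.size < 8:
        raise ValueError("need at least 8 observations for the normality screen")
    if np.ptp(values) == 0:
        raise ValueError("normality test is undefined for constant input")
    _, p = lilliefors(values, dist="norm")
    return float(p)


def kruskal_wallis_epsilon(*groups, grouping: str = "") -> KWResult:
    """Kruskal-Wallis H (tie-corrected) with the epsilon-squared effect size."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    sizes = tuple(len(g) for g in groups)
    if any(s < 2 for s in sizes):
        raise ValueError("every group needs at least 2 observations")
    n = sum(sizes)
    if np.ptp(np.concatenate(groups)) == 0:
        h, p = 0.0, 1.0  # all observations tied: no rank variation at all
    else:
        h, p = stats.kruskal(*groups)
    eps2 = float(h) * (n + 1) / (n**2 - 1)
    return KWResult(
        h=float(h), p=float(p), epsilon2=float(np.clip(eps2, 0.0, 1.0)),
        group_sizes=sizes, grouping=grouping,
    )


def conover_posthoc(*groups, alpha: float = 0.01, kw: KWResult | None = None) -> PosthocMatrix:
    """Conover-Iman pairwise comparisons on the joint ranks.

    Statistic for groups i, j with mean ranks Rbar_i, Rbar_j:

        t = (Rbar_i - Rbar_j) / sqrt(S^2 * (n - 1 - H) / (n - k) * (1/n_i + 1/n_j))

    with S^2 = (sum R^2 - n (n+1)^2 / 4) / (n - 1) on the pooled ranks and
    two-sided p from t with n - k degrees of freedom.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if kw is None:
        kw = kruskal_wallis_epsilon(*groups)
    if kw.p >= 0.05:
        warnings.warn(
            "Conover post-hoc requested without a significant Kruskal-Wallis result",
            stacklevel=2,
        )
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    bounds = np.cumsum([0] + [len(g) for g in groups])
    rank_groups = [ranks[bounds[i] : bounds[i + 1]] for i in range(k)]
    s2 = (np.sum(ranks**2) - n * (n + 1) ** 2 / 4.0) / (n - 1)
    df = n - k
    pmat = np.ones((k, k))
    for i, j in combinations(range(k), 2):
        ni, nj = len(rank_groups[i]), len(rank_groups[j])
        diff = rank_groups[i].mean() - rank_groups[j].mean()
        denom = np.sqrt(s2 * ((n - 1 - kw.h) / df) * (1.0 / ni + 1.0 / nj))
        tstat = diff / denom if denom > 0 else 0.0
        pmat[i, j] = pmat[j, i] = 2.0 * stats.t.sf(abs(tstat), df)
    iu = np.triu_indices(k, 1)
    holm = np.ones((k, k))
    holm[iu] = multipletests(pmat[iu], method="holm")[1]
    holm.T[iu] = holm[iu]
    return PosthocMatrix(p_values=pmat, p_holm=holm, reject=pmat < alpha, alpha=alpha)


# -- cohort contrasts ----------------------------------------------------

_SECOND_HALF_WINDOWS = ("half2", "q15_4", "q15_5", "q15_6")


def contrast_entire_vs_substitutes(
    summaries: pd.DataFrame,
    windows=_SECOND_HALF_WINDOWS,
    quantities=("dist_total_m",),
    per_period: bool = True,
) -> pd.DataFrame:
    """Entire-match players vs substitutes per window and quantity.

    For each window, sums the constituent present periods per player-match
    (requiring full coverage of the window) and runs a two-group
    Kruskal-Wallis test with epsilon squared.  Second-half per-period
    contrasts are appended when ``per_period``.
    """
    out = []
    targets = [(w, WINDOW_PERIODS[w]) for w in windows]
    if per_period:
        targets += [(f"p{p}", (p,)) for p in range(10, 19)]
    for name, periods in targets:
        sub = summaries[summaries["period"].isin(periods)]
        counts = sub.groupby(["match_id", "player_id", "role"])["period"].nunique()
        complete = counts[counts == len(periods)].reset_index()[
            ["match_id", "player_id", "role"]
        ]
        sub = sub.merge(complete, on=["match_id", "player_id", "role"])
        totals = sub.groupby(["match_id", "player_id", "role"], as_index=False)[
            list(quantities)
        ].sum()
        for q in quantities:
            ent = totals.loc[totals["role"] == "entire", q].to_numpy()
            subs = totals.loc[totals["role"] == "substitute", q].to_numpy()
            if len(ent) < 2 or len(subs) < 2:
                log.warning("window %s: a role group is empty or too small; skipped", name)
                continue
            res = kruskal_wallis_epsilon(ent, subs, grouping=f"{name}:{q}")
            out.append(
                {
                    "window": name,
                    "quantity": q,
                    "n_entire": len(ent),
                    "n_substitute": len(subs),
                    "mean_entire": float(ent.mean()),
                    "mean_substitute": float(subs.mean()),
                    "H": res.h,
                    "p": res.p,
                    "epsilon2": res.epsilon2,
                }
            )
    return pd.DataFrame(out)


def substitution_timing_test(entry_minutes, alpha: float = 0.001) -> dict:
    """Are substitutions concentrated late in the match?

    Chi-square goodness-of-fit of entry counts across 5-minute bins against
    a uniform distribution, plus a two-proportion contrast of early entries
    (first half and up to the 55-minute mark) against late ones (minute 60
    onward).  The choice of test is this package's convention.
    """
    entry_minutes = np.asarray(entry_minutes, dtype=float)
    bins = np.arange(0, 95, 5)
    counts, _ = np.histogram(entry_minutes, bins=bins)
    chi2, p_gof = stats.chisquare(counts)
    early = np.sum(entry_minutes < 60)
    late = np.sum(entry_minutes >= 60)
    res = stats.binomtest(int(early), int(early + late), p=12.0 / 18.0, alternative="less")
    return {
        "bin_counts": counts.tolist(),
        "chi2": float(chi2),
        "p_uniform": float(p_gof),
        "n_early": int(early),
        "n_late": int(late),
        "p_early_deficit": float(res.pvalue),
        "early_significantly_lower": bool(res.pvalue < alpha),
    }
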