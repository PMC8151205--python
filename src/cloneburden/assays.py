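"""Pooled whole-fly luciferase assay model, group statistics, survival curves.

The luciferase screen homogenises k flies per well ("pool") and reads one
activity per homogenate.  Pooling trades per-fly resolution for throughput:
the pool reading is modelled as the *mean* of its members' activities, so
the expected readout is unchanged while its variance falls as 1/k — the
property that makes 3 pools of 10 flies as informative as 30 single-fly
assays.  Group comparisons use the same tests as the screen's figures
(Kruskal–Wallis for skewed readings, one-way ANOVA), and survival curves
are simple per-day percent-alive counts over the observation window.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "pool_homogenates",
    "pooling_variance_profile",
    "compare_groups",
    "pairwise_posthoc",
    "survival_curve",
]


@dataclass(frozen=True)
class GroupComparison:
    test: str
    statistic: float
    pvalue: float
    group_sizes: dict[str, int]


def pool_homogenates(
    per_fly,
    k: int,
    shuffle: bool = False,
    seed: int | None = None,
) -> pd.DataFrame:
    """Form pools of ``k`` flies; each pool's reading is the member mean.

    Pools are formed in input order (reproducible) unless ``shuffle`` is
    set, in which case a seeded permutation is applied first.  When the fly
    count is not divisible by ``k`` the remainder forms a final smaller
    pool flagged ``is_remainder`` — flies are never silently dropped.
    """
    if k < 1:
        raise ValueError(f"pool size k must be >= 1, got {k}")
    values = np.asarray(per_fly, dtype=float)
    if values.size == 0:
        raise ValueError("no per-fly activities supplied")
    if shuffle:
        rng = np.random.default_rng(seed)
        values = values[rng.permutation(values.size)]
    rows = []
    for start in range(0, values.size, k):
        chunk = values[start : start + k]
        rows.append(
            {
                "activity": float(chunk.mean()),
                "pool_size": int(chunk.size),
                "is_remainder": bool(chunk.size < k),
            }
        )
    return pd.DataFrame(rows, columns=["activity", "pool_size", "is_remainder"])


def pooling_variance_profile(
    law,
    ks,
    n_replicates: int,
    seed: int,
) -> pd.DataFrame:
    """Monte-Carlo mean/variance of pool readings as pool size varies.

    ``law`` is any sampling law with ``sample(rng, n)`` (e.g. the per-fly
    lognormal of a preset).  For each pool size k, ``n_replicates`` pools
    are simulated and the mean and variance of their readings recorded.
    For i.i.d. members the variance declines as Var(per-fly)/k while the
    mean stays flat — the pooled assay design's premise.
    """
    ks = list(ks)
    if not ks or any(k < 1 for k in ks):
        raise ValueError(f"ks must be non-empty positive pool sizes, got {ks}")
    if n_replicates < 2:
        raise ValueError(f"n_replicates must be >= 2, got {n_replicates}")
    rows = []
    for i, k in enumerate(ks):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(i)]))
        draws = law.sample(rng, int(n_replicates) * int(k)).reshape(n_replicates, k)
        pools = draws.mean(axis=1)
        rows.append(
            {
                "pool_size": int(k),
                "mean": float(pools.mean()),
                "variance": float(pools.var(ddof=1)),
                "n_replicates": int(n_replicates),
            }
        )
    return pd.DataFrame(rows, columns=["pool_size", "mean", "variance", "n_replicates"])


def _as_groups(groups) -> dict[str, np.ndarray]:
    if isinstance(groups, dict):
        items = groups.items()
    else:
        items = ((f"group{i}", g) for i, g in enumerate(groups))
    out = {str(name): np.asarray(g, dtype=float) for name, g in items}
    if len(out) < 2:
        raise ValueError("need at least two groups to compare")
    for name, g in out.items():
        if g.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    return out


def compare_groups(groups, test: str = "kruskal_wallis") -> GroupComparison:
    """Omnibus comparison of labelled reading groups.

    ``kruskal_wallis`` gives the tie-corrected H statistic (the test used
    for skewed luciferase readings and supra-threshold clone counts);
    ``one_way_anova`` gives the F statistic.  Degenerate all-identical data
    yields statistic 0 and p-value 1 rather than an undefined ratio.
    """
    data = _as_groups(groups)
    arrays = list(data.values())
    sizes = {name: int(g.size) for name, g in data.items()}
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0.0:
        return GroupComparison(test=test, statistic=0.0, pvalue=1.0, group_sizes=sizes)
    if test == "kruskal_wallis":
        statistic, pvalue = stats.kruskal(*arrays)
    elif test == "one_way_anova":
        statistic, pvalue = stats.f_oneway(*arrays)
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(
        test=test, statistic=float(statistic), pvalue=float(pvalue), group_sizes=sizes
    )


def pairwise_posthoc(groups, method: str = "holm") -> pd.DataFrame:
    """Pairwise Mann–Whitney tests with multiplicity correction.

    The screen's figures mark per-pair significance after an omnibus
    Kruskal–Wallis; Holm correction is applied across all pairs.
    """
    data = _as_groups(groups)
    rows = []
    for a, b in combinations(data, 2):
        if np.ptp(np.concatenate([data[a], data[b]])) == 0.0:
            statistic, pvalue = 0.0, 1.0
        else:
            statistic, pvalue = stats.mannwhitneyu(
                data[a], data[b], alternative="two-sided"
            )
        rows.append(
            {"comparison": f"{a} vs {b}", "statistic": float(statistic), "pvalue": float(pvalue)}
        )
    frame = pd.DataFrame(rows, columns=["comparison", "statistic", "pvalue"])
    frame["p_adjusted"] = multipletests(frame["pvalue"], method=method)[1]
    return frame


def survival_curve(events: pd.DataFrame, n_days: int | None = None) -> pd.DataFrame:
    """Per-day percent survival per cohort from a death/censor event table.

    ``events`` needs columns ``condition`` (cohort label), ``day`` and
    ``died``.  Survival at day d is 100 x (flies whose death day exceeds d)
    / initial n; survivors are censored at the final day and never reduce
    the curve.  The curve starts at 100% on day 0 and is monotone
    non-increasing.  A death day outside [1, n_days] is an error.
    """
    required = {"condition", "day", "died"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"events table lacks column(s) {sorted(missing)}")
    if n_days is None:
        n_days = int(events["day"].max()) if len(events) else 0
    if n_days < 1:
        raise ValueError(f"n_days must be >= 1, got {n_days}")
    deaths = events[events["died"].astype(bool)]
    if len(deaths) and ((deaths["day"] < 1) | (deaths["day"] > n_days)).any():
        raise ValueError(f"death days must lie within [1, {n_days}]")

    rows = []
    for cond, cohort in events.groupby("condition", sort=True):
        n0 = len(cohort)
        death_days = cohort.loc[cohort["died"].astype(bool), "day"].to_numpy()
        for day in range(0, n_days + 1):
            alive = n0 - int((death_days <= day).sum())
            rows.append(
                {
                    "condition": cond,
                    "day": day,
                    "percent_survival": 100.0 * alive / n0,
                    "n_at_risk": alive,
                }
            )
    return pd.DataFrame(rows, columns=["condition", "day", "percent_survival", "n_at_risk"])
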