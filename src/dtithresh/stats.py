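"""Cohort statistics: moments, CV, confidence intervals, Kruskal–Wallis.

Across subjects, each (region, condition, measure) cell gets the sample
mean, SD (n−1 denominator), coefficient of variation (SD/mean) and a
Student-t 95 % confidence interval.  Conditions are then compared region
by region with the Kruskal–Wallis rank test (tie-corrected H, chi-square
tail), with a seeded Monte-Carlo permutation p reported alongside for
small samples, and a Bonferroni-corrected alpha controlling the
family-wise error over regions.  Adjacent-condition contrasts use the
same statistic on two groups (equivalent to a rank-sum test).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "KruskalResult",
    "cohort_moments",
    "kruskal_h",
    "kruskal_wallis",
    "bonferroni_alpha",
    "pairwise_adjacent",
    "compare_conditions",
]

# total-n ceiling under which a Monte-Carlo permutation p accompanies the
# chi-square approximation
PERMUTATION_N_MAX = 30
PERMUTATION_RESAMPLES = 10_000


@dataclass(frozen=True)
class KruskalResult:
    h: float
    df: int
    p_chi2: float
    p_permutation: float | None = None
    n_total: int = 0


def cohort_moments(
    table: pd.DataFrame,
    measure: str,
    group_cols: Sequence[str] = ("region", "hemisphere", "condition"),
) -> pd.DataFrame:
    """Across-subject moments of one measure per region × condition cell.

    Excluded rows are dropped first.  SD, CV and the CI need at least two
    contributing subjects; below that only the mean is reported.  CV is
    defined only for a positive mean.
    """
    usable = table[~table["excluded"]].dropna(subset=[measure])
    rows = []
    for key, grp in usable.groupby(list(group_cols), sort=True):
        vals = grp[measure].to_numpy(dtype=float)
        n = vals.size
        mean = float(vals.mean())
        if n >= 2:
            sd = float(vals.std(ddof=1))
            tcrit = float(sps.t.ppf(0.975, n - 1))
            half = tcrit * sd / np.sqrt(n)
            lo, hi = mean - half, mean + half
            cv = sd / mean if mean > 0 else np.nan
        else:
            sd = cv = np.nan
            lo = hi = mean
        rows.append(
            dict(
                zip(group_cols, key),
                measure=measure,
                n_subjects=n,
                mean=mean,
                sd=sd,
                cv=cv,
                ci95_lo=lo,
                ci95_hi=hi,
            )
        )
    return pd.DataFrame(rows)


def kruskal_h(groups: Sequence[np.ndarray]) -> tuple[float, int]:
    """Tie-corrected Kruskal–Wallis H and its degrees of freedom.

    H = (12 / (N(N+1))) · Σ R_j²/n_j − 3(N+1), divided by the tie
    correction 1 − Σ(t³−t)/(N³−N).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()))
    correction = 1.0 - tie_term / (n_total**3 - n_total)
    if correction <= 0:  # all values identical
        return 0.0, len(groups) - 1
    return h / correction, len(groups) - 1


def _permutation_p(
    groups: Sequence[np.ndarray],
    h_obs: float,
    rng: np.random.Generator,
    n_resamples: int,
) -> float:
    """Monte-Carlo permutation tail probability P(H ≥ h_obs).

    All resamples are ranked at once; the tie correction depends only on
    the pooled multiset, so it is a single constant across permutations.
    """
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    sizes = np.array([len(g) for g in groups])
    n_total = pooled.size
    perms = rng.permuted(
        np.broadcast_to(pooled, (n_resamples, n_total)).copy(), axis=1
    )
    ranks = sps.rankdata(perms, axis=1)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    h = np.zeros(n_resamples)
    for j in range(len(sizes)):
        h += ranks[:, bounds[j] : bounds[j + 1]].sum(axis=1) ** 2 / sizes[j]
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (counts**3 - counts).sum() / (n_total**3 - n_total)
    if correction > 0:
        h /= correction
    else:
        h[:] = 0.0
    count = int((h >= h_obs - 1e-12).sum())
    # add-one estimator keeps p in (0, 1]
    return (count + 1) / (n_resamples + 1)


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    seed: int | np.random.Generator | None = 0,
    n_resamples: int = PERMUTATION_RESAMPLES,
    permutation_n_max: int = PERMUTATION_N_MAX,
) -> KruskalResult:
    """Kruskal–Wallis across k ≥ 2 groups.

    The chi-square upper-tail p on the tie-corrected H is the primary
    p-value; when the pooled sample is small (total n ≤ ``permutation_n_max``)
    a seeded Monte-Carlo permutation p (≥ ``n_resamples`` resamples of the
    pooled values) is reported alongside.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    h, df = kruskal_h(arrays)
    p_chi2 = float(sps.chi2.sf(h, df))
    n_total = int(sum(a.size for a in arrays))
    p_perm = None
    if n_total <= permutation_n_max:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        p_perm = _permutation_p(arrays, h, rng, n_resamples)
    return KruskalResult(
        h=float(h), df=df, p_chi2=p_chi2, p_permutation=p_perm, n_total=n_total
    )


def bonferroni_alpha(family_alpha: float, n_comparisons: int) -> float:
    """Family-wise corrected significance cutoff alpha / m."""
    if not 0 < family_alpha < 1:
        raise ValueError("family_alpha must lie in (0, 1)")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return family_alpha / n_comparisons


def pairwise_adjacent(
    groups: Sequence[Sequence[float]],
    condition_names: Sequence[str],
    alpha: float,
    seed: int | np.random.Generator | None = 0,
) -> list[dict]:
    """Two-group contrasts between each pair of adjacent conditions."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    out = []
    for i in range(len(groups) - 1):
        res = kruskal_wallis([groups[i], groups[i + 1]], seed=rng)
        out.append(
            {
                "contrast": f"{condition_names[i]} vs {condition_names[i + 1]}",
                "h": res.h,
                "p_chi2": res.p_chi2,
                "p_permutation": res.p_permutation,
                "significant": res.p_chi2 < alpha,
            }
        )
    return out


def compare_conditions(
    table: pd.DataFrame,
    measure: str,
    conditions: Sequence[str],
    family_alpha: float = 0.05,
    family_size: int = 12,
    seed: int | np.random.Generator | None = 0,
) -> pd.DataFrame:
    """Region-wise Kruskal–Wallis across the threshold conditions.

    One comparison per (region, hemisphere); the working cutoff is the
    exact fraction ``family_alpha / family_size`` (not its rounded
    presentation form) and significance uses a strict inequality.  Regions
    with any empty condition group are reported as skipped with the reason.
    """
    alpha = bonferroni_alpha(family_alpha, family_size)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    usable = table[~table["excluded"]].dropna(subset=[measure])
    rows = []
    for (region, hemi), grp in usable.groupby(["region", "hemisphere"], sort=True):
        groups = [
            grp.loc[grp["condition"] == c, measure].to_numpy(dtype=float)
            for c in conditions
        ]
        empty = [c for c, g in zip(conditions, groups) if g.size == 0]
        if empty:
            rows.append(
                {
                    "region": region,
                    "hemisphere": hemi,
                    "measure": measure,
                    "h": np.nan,
                    "df": len(conditions) - 1,
                    "p_chi2": np.nan,
                    "p_permutation": np.nan,
                    "significant": False,
                    "skipped_reason": f"empty condition(s): {', '.join(empty)}",
                    "pairwise": None,
                }
            )
            continue
        res = kruskal_wallis(groups, seed=rng)
        rows.append(
            {
                "region": region,
                "hemisphere": hemi,
                "measure": measure,
                "h": res.h,
                "df": res.df,
                "p_chi2": res.p_chi2,
                "p_permutation": res.p_permutation,
                "significant": res.p_chi2 < alpha,
                "skipped_reason": "",
                "pairwise": pairwise_adjacent(groups, conditions, alpha, seed=rng),
            }
        )
    return pd.DataFrame(rows)
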