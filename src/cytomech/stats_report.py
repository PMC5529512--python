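"""Statistical layer: t-tests, tie-corrected Kruskal–Wallis, exact
Mann–Whitney, Šidák-adjusted thresholds, and normal-approximation power.

The pooled t-test and distribution tails delegate to scipy; the
tie-corrected Kruskal–Wallis H and the exact Mann–Whitney enumeration are
implemented here so they can be cross-checked against independent
brute-force oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "SidakPlan",
    "PowerSpec",
    "two_sample_t",
    "kruskal_wallis",
    "mann_whitney",
    "sidak_threshold",
    "power_normal_approx",
    "power_noncentral_t",
]


@dataclass(frozen=True)
class GroupComparison:
    test_name: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    two_sided: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value must lie in [0, 1]")


@dataclass(frozen=True)
class SidakPlan:
    """Per-comparison significance threshold under Šidák's correction."""

    m_comparisons: int
    family_alpha: float
    per_comparison_threshold: float


@dataclass(frozen=True)
class PowerSpec:
    n_per_group: int
    effect_size_sd_units: float
    alpha: float
    sided: str
    power: float


def two_sample_t(x, y, paired: bool = False) -> GroupComparison:
    """Pooled-variance unpaired (or paired) t-test, two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 values per group")
    if paired:
        if len(x) != len(y):
            raise ValueError("paired test needs equal lengths")
        if np.all(x == y):
            return GroupComparison("paired t", 0.0, 1.0, (len(x), len(y)))
        res = sps.ttest_rel(x, y)
        name = "paired t"
    else:
        if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
            if x.mean() == y.mean():
                return GroupComparison("unpaired t (pooled)", 0.0, 1.0, (len(x), len(y)))
            raise ValueError("zero variance in both groups with unequal means")
        res = sps.ttest_ind(x, y, equal_var=True)
        name = "unpaired t (pooled)"
    return GroupComparison(name, float(res.statistic), float(res.pvalue), (len(x), len(y)))


def kruskal_wallis(groups) -> GroupComparison:
    """Kruskal–Wallis H with tie correction; chi-square p on k−1 df.

    H = (12/(N(N+1))) Σ R_i²/n_i − 3(N+1), divided by
    1 − Σ(t³−t)/(N³−N) over tie groups. If all values are identical the
    statistic is 0 and p = 1 by convention.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 groups with >= 1 value each")
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    denom = 1.0 - tie_term / (n_total**3 - n_total)
    if denom <= 0:  # every value identical
        return GroupComparison("Kruskal-Wallis (tie-corrected)", 0.0, 1.0, tuple(len(g) for g in groups))
    h /= denom
    p = float(sps.chi2.sf(h, df=len(groups) - 1))
    return GroupComparison("Kruskal-Wallis (tie-corrected)", float(h), p, tuple(len(g) for g in groups))


def _u_statistic(x, y) -> float:
    """U for sample x against y using midranks (handles ties)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


def _exact_u_distribution(pooled_ranks: np.ndarray, n1: int):
    """Exact permutation distribution of U1 by enumerating subsets."""
    n = len(pooled_ranks)
    offset = n1 * (n1 + 1) / 2.0
    us = [sum(c) - offset for c in combinations(pooled_ranks, n1)]
    return np.asarray(us)


def mann_whitney(x, y, alternative: str = "two-sided", exact_max_n: int = 20) -> GroupComparison:
    """Wilcoxon rank-sum (Mann–Whitney U) test.

    Exact p by enumeration of all C(n+m, n) group assignments when
    n + m ≤ ``exact_max_n`` (ties handled through midranks); otherwise
    the normal approximation with tie and continuity correction.
    Two-sided exact p is twice the smaller tail, capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("need >= 1 value per group")
    n1, n2 = len(x), len(y)
    u1 = _u_statistic(x, y)
    mu = n1 * n2 / 2.0

    if n1 + n2 <= exact_max_n:
        pooled_ranks = sps.rankdata(np.concatenate([x, y]))
        dist = _exact_u_distribution(pooled_ranks, n1)
        total = len(dist)
        eps = 1e-9
        p_less = np.count_nonzero(dist <= u1 + eps) / total
        p_greater = np.count_nonzero(dist >= u1 - eps) / total
        if alternative == "less":
            p = p_less
        elif alternative == "greater":
            p = p_greater
        else:
            p = min(1.0, 2.0 * min(p_less, p_greater))
        name = "Mann-Whitney U (exact)"
    else:
        pooled = np.concatenate([x, y])
        _, tie_counts = np.unique(pooled, return_counts=True)
        n = n1 + n2
        tie_term = float((tie_counts**3 - tie_counts).sum())
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        sigma = np.sqrt(sigma2)
        if sigma == 0:
            p = 1.0
        else:
            if alternative == "less":
                z = (u1 - mu + 0.5) / sigma
                p = float(sps.norm.cdf(z))
            elif alternative == "greater":
                z = (u1 - mu - 0.5) / sigma
                p = float(sps.norm.sf(z))
            else:
                z = (u1 - mu - np.sign(u1 - mu) * 0.5) / sigma if u1 != mu else 0.0
                p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
        name = "Mann-Whitney U (normal approx)"
    return GroupComparison(name, u1, p, (n1, n2), two_sided=alternative == "two-sided")


def sidak_threshold(m_comparisons: int, family_alpha: float = 0.05) -> SidakPlan:
    """Šidák per-comparison threshold 1 − (1 − α)^(1/m).

    With m = 3 post hoc comparisons at family α = 0.05 this gives 0.01695,
    i.e. the conventional P < 0.017 cutoff.
    """
    if m_comparisons < 1:
        raise ValueError("m_comparisons must be >= 1")
    if not 0 < family_alpha < 1:
        raise ValueError("family_alpha must lie in (0, 1)")
    thr = 1.0 - (1.0 - family_alpha) ** (1.0 / m_comparisons)
    return SidakPlan(m_comparisons, family_alpha, float(thr))


def power_normal_approx(
    n_per_group: int,
    effect_size_sd_units: float,
    alpha: float = 0.05,
    sided: str = "one",
) -> PowerSpec:
    """Normal-approximation power for a two-group mean comparison.

    power = Φ(d·√(n/2) − z_{1−α}) one-sided; the two-sided form uses
    z_{1−α/2} and ignores the opposite tail. With n = 5 per group and a
    1.5 SD effect the one-sided 5% power is 76.6%.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if effect_size_sd_units < 0:
        raise ValueError("effect size must be >= 0")
    z = sps.norm.ppf(1.0 - alpha) if sided == "one" else sps.norm.ppf(1.0 - alpha / 2.0)
    power = float(sps.norm.cdf(effect_size_sd_units * np.sqrt(n_per_group / 2.0) - z))
    return PowerSpec(n_per_group, effect_size_sd_units, alpha, sided, power)


def power_noncentral_t(
    n_per_group: int,
    effect_size_sd_units: float,
    alpha: float = 0.05,
    sided: str = "two",
) -> PowerSpec:
    """Exact power of the pooled two-sample t-test via the noncentral t.

    Provided alongside the normal approximation; the two differ by a few
    points at small n (the approximation ignores the estimated-variance
    penalty and, two-sided, the opposite tail).
    """
    n = n_per_group
    df = 2 * n - 2
    ncp = effect_size_sd_units * np.sqrt(n / 2.0)
    if sided == "one":
        tcrit = sps.t.ppf(1.0 - alpha, df)
        power = float(sps.nct.sf(tcrit, df, ncp))
    else:
        tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
        power = float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))
    return PowerSpec(n, effect_size_sd_units, alpha, sided, power)
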