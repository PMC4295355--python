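"""Group-level statistics for the specimen cohort.

Covers the three descriptive/inferential layers used on the cohort tables:
mean +/- SD / range / high-low ratio summaries per group, two-sided Wilcoxon
rank-sum comparisons between groups (exact by full enumeration for small
samples, normal approximation with tie correction otherwise), and Spearman
rank correlations of each diffusion parameter with each morphological
constituent within subgroups (control, stroma < 50%, stroma >= 50%).

All p-values are two-sided and uncorrected for multiple testing; outputs
carry that convention in their metadata rather than silently adjusting.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import InvalidInputError, UndefinedStatisticError

__all__ = [
    "GroupSummary",
    "RankTestResult",
    "CorrelationEntry",
    "group_summary",
    "summary_table",
    "wilcoxon_rank_sum",
    "spearman",
    "correlation_table",
    "correlation_frame",
    "DIFFUSION_COLUMNS",
    "CONSTITUENT_COLUMNS",
]

#: specimen-table column -> display label for the diffusion parameters.
DIFFUSION_COLUMNS = {
    "adc_1e9": "ADC_m",
    "d_fast_1e9": "D_FDP",
    "p1": "P1",
    "d_slow_1e11": "D_SDP",
}

#: specimen-table column -> display label for the morphology constituents.
CONSTITUENT_COLUMNS = {
    "p": "P",
    "st": "St",
    "at": "AT",
    "pce": "PCE",
    "pve": "PVE",
    "v": "V",
}


@dataclass(frozen=True)
class GroupSummary:
    """mean +/- SD, range and high/low ratio of one variable in one group.

    ``sd`` is ``None`` for a singleton (undefined with the n-1 denominator);
    ``ratio_high_low`` is ``None`` when the minimum is not positive.
    """

    variable: str
    group: str
    n: int
    mean: float
    sd: float | None
    min: float
    max: float
    ratio_high_low: float | None


@dataclass(frozen=True)
class RankTestResult:
    """Two-sided Wilcoxon rank-sum result; ``statistic`` is the first
    sample's rank sum (mid-ranks for ties)."""

    statistic: float
    p_two_sided: float
    method: str  # "exact" | "normal_approx"


@dataclass(frozen=True)
class CorrelationEntry:
    """Spearman rho of one diffusion parameter vs one constituent in one subgroup."""

    diffusion_param: str
    constituent: str
    subgroup: str
    n: int
    rho: float
    p_value: float


def group_summary(values, variable: str = "", group: str = "") -> GroupSummary:
    """Descriptive summary of one variable: mean, sample SD, range, max/min."""
    x = np.asarray(values, dtype=float).reshape(-1)
    if x.size == 0:
        raise InvalidInputError("group_summary requires at least one value")
    lo, hi = float(x.min()), float(x.max())
    return GroupSummary(
        variable=variable,
        group=group,
        n=int(x.size),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)) if x.size > 1 else None,
        min=lo,
        max=hi,
        ratio_high_low=(hi / lo) if lo > 0 else None,
    )


def summary_table(df: pd.DataFrame, columns, group_col: str = "group") -> pd.DataFrame:
    """Per-group :func:`group_summary` of each column, as a tidy frame."""
    rows = []
    for grp, sub in df.groupby(group_col, sort=False):
        for col in columns:
            s = group_summary(sub[col].to_numpy(), variable=col, group=str(grp))
            rows.append(vars(s) | {})
    return pd.DataFrame(rows)


def _exact_ranksum_p(ranks: np.ndarray, n_a: int, w_obs: float) -> float:
    """Exact two-sided p over all C(N, n_a) rank assignments.

    The full permutation distribution of the rank sum is built by dynamic
    programming (the shift algorithm) on doubled mid-ranks, which are exact
    integers even with ties; equivalent to, but much faster than, explicit
    enumeration of the subsets.
    """
    n = ranks.size
    r2 = np.rint(2 * ranks).astype(int)  # doubled mid-ranks are integers
    total_sum = int(r2.sum())
    # counts[k, s] = number of k-subsets of the ranks with doubled sum s
    counts = np.zeros((n_a + 1, total_sum + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in r2:
        for k in range(min(n_a, 1_000), 0, -1):
            counts[k, r:] += counts[k - 1, : total_sum + 1 - r]
    dist = counts[n_a]
    total = math.comb(n, n_a)
    mu2 = 2 * n_a * ranks.mean()
    dev_obs = abs(2 * w_obs - mu2)
    sums = np.arange(total_sum + 1)
    count = dist[np.abs(sums - mu2) >= dev_obs - 1e-9].sum()
    return float(count / total)


def wilcoxon_rank_sum(a, b, max_exact: int = 10) -> RankTestResult:
    """Two-sided Wilcoxon rank-sum test with mid-ranks for ties.

    The p-value is exact (full enumeration of all rank assignments) when
    both samples have at most ``max_exact`` observations, and a tie-corrected
    normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float).reshape(-1)
    b = np.asarray(b, dtype=float).reshape(-1)
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # mid-ranks
    w_obs = float(ranks[: a.size].sum())
    if a.size <= max_exact and b.size <= max_exact:
        p = _exact_ranksum_p(ranks, a.size, w_obs)
        return RankTestResult(statistic=w_obs, p_two_sided=min(p, 1.0), method="exact")
    # scipy's asymptotic Mann-Whitney U applies the tie correction; convert
    # its U statistic convention back to the rank sum for reporting.
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return RankTestResult(
        statistic=w_obs, p_two_sided=float(res.pvalue), method="normal_approx"
    )


def spearman(
    x,
    y,
    method: str = "t",
    n_resamples: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Spearman rank correlation and two-sided p-value.

    ``method="t"`` uses the t-distribution approximation; ``"permutation"``
    permutes the pairing of y against x — exhaustively for n <= 7
    (n! <= 5040 permutations), otherwise with ``n_resamples`` random
    permutations.  Intended for the small subgroup sizes (n <= 12) where the
    t-approximation is least trustworthy.
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if x.size != y.size or x.size < 3:
        raise InvalidInputError("spearman requires equal-length samples, n >= 3")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise UndefinedStatisticError("zero rank variance: correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if method == "t":
        p = float(sps.spearmanr(x, y).pvalue)
        return rho, p
    if method != "permutation":
        raise InvalidInputError(f"unknown method {method!r}")

    def _rho(perm_ry):
        c = np.corrcoef(rx, perm_ry)[0, 1]
        return 0.0 if np.isnan(c) else c

    obs = abs(rho)
    if x.size <= 7:
        count = total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_rho(np.array(perm))) >= obs - 1e-12:
                count += 1
        return rho, count / total
    rng = np.random.default_rng(seed)
    count = 1  # identity permutation always reaches the observed value
    for _ in range(n_resamples):
        if abs(_rho(rng.permutation(ry))) >= obs - 1e-12:
            count += 1
    return rho, count / (n_resamples + 1)


_DEFAULT_SUBGROUPS = ("control", "stroma_lt50", "stroma_ge50")


def _subgroup_mask(df: pd.DataFrame, subgroup: str) -> pd.Series:
    if subgroup == "control":
        return df["group"] == "control"
    if subgroup == "all_cancer":
        return df["group"] == "cancer"
    # Stroma classes span the whole cohort (control + cancer), cut at 50%
    # with >= 50 in the high class.
    if subgroup == "stroma_lt50":
        return df["st"] < 50.0
    if subgroup == "stroma_ge50":
        return df["st"] >= 50.0
    raise InvalidInputError(f"unknown subgroup {subgroup!r}")


def correlation_table(
    df: pd.DataFrame,
    subgroups=_DEFAULT_SUBGROUPS,
    min_n: int = 3,
) -> list[CorrelationEntry]:
    """Spearman rho of every diffusion parameter vs every constituent.

    One entry per (diffusion parameter) x (constituent) x (subgroup);
    subgroups smaller than ``min_n`` are skipped with a warning.  Entries
    where a variable has zero rank variance carry NaN rho/p.
    """
    entries: list[CorrelationEntry] = []
    for subgroup in subgroups:
        sub = df[_subgroup_mask(df, subgroup)]
        if len(sub) < min_n:
            warnings.warn(
                f"subgroup {subgroup!r} has n={len(sub)} < {min_n}; skipped",
                stacklevel=2,
            )
            continue
        for dcol, dlabel in DIFFUSION_COLUMNS.items():
            for ccol, clabel in CONSTITUENT_COLUMNS.items():
                try:
                    rho, p = spearman(sub[dcol].to_numpy(), sub[ccol].to_numpy())
                except UndefinedStatisticError:
                    rho, p = float("nan"), float("nan")
                entries.append(
                    CorrelationEntry(
                        diffusion_param=dlabel,
                        constituent=clabel,
                        subgroup=subgroup,
                        n=len(sub),
                        rho=rho,
                        p_value=p,
                    )
                )
    return entries


def correlation_frame(entries: list[CorrelationEntry]) -> pd.DataFrame:
    """Correlation entries as a tidy DataFrame."""
    return pd.DataFrame([vars(e) for e in entries])
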