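"""Nonparametric subgroup comparisons, multiplicity, and diversity indices.

Participant-level exposure summaries are compared across demographic
subgroups with the Wilcoxon rank-sum test (two groups) or Kruskal-Wallis
test (three or more), with Bonferroni-multiplied post-hoc pairwise tests
when the omnibus test is significant. Small samples (pooled n <= 10) use
exact enumeration of the permutation distribution with midranks, so ties
are handled without the normal approximation.
"""

from __future__ import annotations

import itertools
import warnings
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

EXACT_MAX_N = 10


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    from statsmodels.stats.multitest import multipletests

    pvals = np.asarray(pvals, dtype=float)
    if len(pvals) == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def bonferroni(pvals, m: int | None = None) -> np.ndarray:
    pvals = np.asarray(pvals, dtype=float)
    m = m if m is not None else len(pvals)
    return np.minimum(pvals * m, 1.0)


# ---------------------------------------------------------------------------
# Rank statistics (midranks, tie-corrected — matching the scipy definitions)


def kw_statistic(groups: list[np.ndarray]) -> float:
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - ((counts**3 - counts).sum()) / (n**3 - n) if n > 1 else 1.0
    return h / tie if tie > 0 else 0.0


def _ranksum_statistic(ranks_a: np.ndarray) -> float:
    return float(ranks_a.sum())


def _exact_perm_pvalue(groups: list[np.ndarray], kind: str) -> float:
    """Exact permutation p-value over all group assignments (pooled n <= 10)."""
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    n = len(pooled)

    if kind == "kw":
        observed = kw_statistic(groups)

        def stat(assign_ranks: list[np.ndarray]) -> float:
            h = sum(r.sum() ** 2 / len(r) for r in assign_ranks)
            h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
            _, counts = np.unique(pooled, return_counts=True)
            tie = 1.0 - ((counts**3 - counts).sum()) / (n**3 - n)
            return h / tie if tie > 0 else 0.0

        count = total = 0
        for parts in _assignments(np.arange(n), sizes):
            total += 1
            if stat([ranks[p] for p in parts]) >= observed - 1e-12:
                count += 1
        return count / total

    # two-sided rank-sum on the first group's rank total
    na = sizes[0]
    observed = _ranksum_statistic(ranks[:na])
    mean_w = na * (n + 1) / 2.0
    count = total = 0
    for idx in itertools.combinations(range(n), na):
        total += 1
        w = ranks[list(idx)].sum()
        if abs(w - mean_w) >= abs(observed - mean_w) - 1e-12:
            count += 1
    return count / total


def _assignments(idx: np.ndarray, sizes: list[int]):
    """All distinct splits of ``idx`` into ordered groups of given sizes."""
    if len(sizes) == 1:
        yield [idx]
        return
    for chosen in itertools.combinations(range(len(idx)), sizes[0]):
        mask = np.zeros(len(idx), dtype=bool)
        mask[list(chosen)] = True
        for rest in _assignments(idx[~mask], sizes[1:]):
            yield [idx[mask]] + rest


def rank_sum_test(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum; exact enumeration when pooled n <= 10."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if len(a) + len(b) <= EXACT_MAX_N:
        ranks = stats.rankdata(np.concatenate([a, b]))
        return float(ranks[: len(a)].sum()), _exact_perm_pvalue([a, b], "ranksum")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def kruskal_test(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis; exact permutation distribution when pooled n <= 10."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    h = kw_statistic(groups)
    if sum(len(g) for g in groups) <= EXACT_MAX_N:
        return h, _exact_perm_pvalue(groups, "kw")
    p = float(stats.chi2.sf(h, len(groups) - 1))
    return h, p


def subgroup_tests(
    df: pd.DataFrame,
    value_col: str,
    factor_col: str,
    alpha: float = 0.05,
    min_n: int = 2,
) -> dict:
    """Omnibus + Bonferroni post-hoc comparison of a value across subgroups.

    Groups with fewer than ``min_n`` observations are excluded with a
    warning. Two groups use the rank-sum test; three or more use
    Kruskal-Wallis, with pairwise rank-sum post-hocs (p multiplied by the
    number of pairs, capped at 1) when the omnibus p < alpha.
    """
    grouped = {
        str(k): sub[value_col].dropna().to_numpy()
        for k, sub in df.groupby(factor_col, sort=True, observed=True)
    }
    small = [k for k, v in grouped.items() if len(v) < min_n]
    if small:
        warnings.warn(f"excluding group(s) with n < {min_n}: {small}", stacklevel=2)
        grouped = {k: v for k, v in grouped.items() if len(v) >= min_n}
    if len(grouped) < 2:
        raise ValueError("need at least two groups with enough observations")
    names = list(grouped)
    values = list(grouped.values())
    if len(values) == 2:
        statval, p = rank_sum_test(values[0], values[1])
        test = "wilcoxon_rank_sum"
    else:
        statval, p = kruskal_test(values)
        test = "kruskal_wallis"

    pairwise = None
    if len(values) >= 3 and p < alpha:
        rows = []
        pairs = list(itertools.combinations(range(len(values)), 2))
        for i, j in pairs:
            s, praw = rank_sum_test(values[i], values[j])
            rows.append({"group_a": names[i], "group_b": names[j],
                         "statistic": s, "p_raw": praw})
        pairwise = pd.DataFrame(rows)
        pairwise["p_bonferroni"] = bonferroni(pairwise["p_raw"].to_numpy(), len(pairs))
    return {
        "test": test,
        "statistic": statval,
        "p": p,
        "groups": {k: len(v) for k, v in grouped.items()},
        "pairwise": pairwise,
    }


# ---------------------------------------------------------------------------
# Land-use diversity


def shannon_entropy(
    labels: pd.DataFrame, by: str | None = "participant_id", class_col: str = "microenv"
):
    """Shannon entropy H = -sum p_i ln p_i over land-use time fractions.

    The vehicle microenvironment counts as a class. With ``by=None`` a
    single pooled entropy is returned.
    """
    if len(labels) == 0:
        raise ValueError("no labelled minutes; entropy undefined")

    def _h(series: pd.Series) -> float:
        p = series.value_counts(normalize=True).to_numpy()
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    if by is None:
        return _h(labels[class_col])
    return labels.groupby(by, observed=True)[class_col].apply(_h).rename("entropy")
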