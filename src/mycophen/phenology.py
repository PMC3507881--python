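"""Nonparametric seasonal statistics for monthly fruiting censuses.

Given the survey x group detection matrix, this module answers the seasonal
questions: do the calendar months differ in fruiting species richness
(Steel-Dwass all-pairs rank comparisons, displayed as compact letters), do a
guild's genera agree on the seasonal ordering of months (Kendall's
coefficient of concordance W), and what does each group's standardized
seasonal profile look like (relative richness).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from string import ascii_lowercase

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2
from scipy.stats import rankdata, studentized_range

from .io import DetectionMatrix

__all__ = [
    "MonthlySamples",
    "ConcordanceResult",
    "PairwiseComparisonSet",
    "monthly_samples",
    "steel_dwass",
    "compact_letters",
    "kendall_w",
    "relative_richness",
    "monthly_rank_matrix",
]

MONTHS = tuple(range(1, 13))


@dataclass
class MonthlySamples:
    """Per calendar month, the vector of one group's per-survey species
    counts across years.  Months never surveyed hold empty vectors."""

    group: str
    samples: dict[int, np.ndarray]

    def n_obs(self, month: int) -> int:
        return len(self.samples.get(month, ()))


def monthly_samples(matrix: DetectionMatrix, group: str) -> MonthlySamples:
    """Assign each survey's count for ``group`` to its calendar month."""
    counts = matrix.column(group)
    buckets: dict[int, list[int]] = {m: [] for m in MONTHS}
    for date, c in zip(matrix.dates, counts):
        buckets[date.month].append(int(c))
    return MonthlySamples(group=group,
                          samples={m: np.asarray(v, dtype=float)
                                   for m, v in buckets.items()})


# ---------------------------------------------------------------------------
# Steel-Dwass all-pairs comparisons

@dataclass
class PairwiseComparisonSet:
    """All-pairs comparison results over the usable months.

    ``table`` has one row per unordered month pair with the rank sum of the
    first month, the standardized statistic t, the p-value and the
    significance flag at ``alpha``.
    """

    group: str
    months: list[int]
    table: pd.DataFrame
    alpha: float
    method: str

    def significant_pairs(self) -> set[frozenset]:
        sig = self.table[self.table["significant"]]
        return {frozenset((int(a), int(b)))
                for a, b in zip(sig["month_a"], sig["month_b"])}

    def letters(self) -> dict[int, str]:
        return compact_letters(self)


def _pair_stat(xa: np.ndarray, xb: np.ndarray) -> tuple[float, float]:
    """Rank sum of the first sample under joint midranks and the
    standardized (tie-adjusted) Steel-Dwass statistic."""
    na, nb = len(xa), len(xb)
    nt = na + nb
    ranks = rankdata(np.concatenate([xa, xb]))
    r_a = ranks[:na].sum()
    e = na * (nt + 1) / 2.0
    v = na * nb / (nt * (nt - 1.0)) * np.sum((ranks - (nt + 1) / 2.0) ** 2)
    if v <= 0.0:  # every observation tied
        return float(r_a), 0.0
    return float(r_a), float((r_a - e) / np.sqrt(v))


def steel_dwass(samples: MonthlySamples, alpha: float = 0.05,
                method: str = "asymptotic", n_perm: int = 2000,
                seed: int | None = None) -> PairwiseComparisonSet:
    """All-pairs rank comparisons among months with family-wise control.

    For each month pair the joint midrank sum is standardized with the
    tie-adjusted variance; the asymptotic p-value refers ``sqrt(2)*|t|`` to
    the studentized range distribution with k = number of compared months and
    infinite degrees of freedom.  ``method="permutation"`` instead uses a
    max-|t| permutation reference (labels shuffled across months), which
    controls the family-wise error exactly up to Monte-Carlo error — the
    small-sample oracle.

    Months with fewer than two observations are excluded with a warning;
    fewer than two usable months is an error.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    usable = [m for m in MONTHS if samples.n_obs(m) >= 2]
    dropped = [m for m in MONTHS if 0 < samples.n_obs(m) < 2]
    if dropped:
        warnings.warn(f"months {dropped} excluded (fewer than 2 surveys)",
                      stacklevel=2)
    if len(usable) < 2:
        raise ValueError("need at least two months with >= 2 observations")
    k = len(usable)
    data = {m: samples.samples[m] for m in usable}

    rows = []
    for a, b in itertools.combinations(usable, 2):
        r_a, t = _pair_stat(data[a], data[b])
        rows.append({"month_a": a, "month_b": b,
                     "n_a": len(data[a]), "n_b": len(data[b]),
                     "rank_sum": r_a, "t": t, "p": np.nan})
    table = pd.DataFrame(rows)

    if method == "asymptotic":
        table["p"] = studentized_range.sf(
            np.sqrt(2.0) * np.abs(table["t"].to_numpy()), k, np.inf)
        # an exactly tied pair has t = 0 and p = 1
        table.loc[table["t"] == 0.0, "p"] = 1.0
    elif method == "permutation":
        table["p"] = _max_t_permutation(data, usable,
                                        np.abs(table["t"].to_numpy()),
                                        n_perm, seed)
    else:
        raise ValueError(f"unknown method {method!r}")

    table["significant"] = table["p"] < alpha
    return PairwiseComparisonSet(group=samples.group, months=usable,
                                 table=table, alpha=alpha, method=method)


def _max_t_permutation(data: dict[int, np.ndarray], months: list[int],
                       observed_abs_t: np.ndarray, n_perm: int,
                       seed: int | None) -> np.ndarray:
    """Pairwise p-values from the permutation distribution of max |t|."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([data[m] for m in months])
    sizes = [len(data[m]) for m in months]
    edges = np.cumsum([0] + sizes)
    pairs = list(itertools.combinations(range(len(months)), 2))
    exceed = np.zeros_like(observed_abs_t)
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        groups = [perm[edges[i]:edges[i + 1]] for i in range(len(months))]
        max_t = max(abs(_pair_stat(groups[i], groups[j])[1])
                    for i, j in pairs)
        exceed += max_t >= observed_abs_t
    return (1.0 + exceed) / (1.0 + n_perm)


def compact_letters(comparisons: PairwiseComparisonSet) -> dict[int, str]:
    """Compact letter display by insert-and-absorb.

    Two months share at least one letter iff their difference is not
    significant.  Letters are assigned deterministically in month order.
    """
    items = list(comparisons.months)
    sig = comparisons.significant_pairs()
    return _insert_absorb(items, sig)


def _insert_absorb(items: list, sig_pairs: set[frozenset]) -> dict:
    columns: list[set] = [set(items)]
    order = {it: i for i, it in enumerate(items)}
    for a, b in sorted((sorted(p, key=lambda x: order[x]) for p in sig_pairs),
                       key=lambda ab: (order[ab[0]], order[ab[1]])):
        new_cols: list[set] = []
        for col in columns:
            if a in col and b in col:
                new_cols.extend((col - {a}, col - {b}))
            else:
                new_cols.append(col)
        # absorb proper subsets, then dedupe preserving order
        kept = [c for c in new_cols if not any(c < d for d in new_cols)]
        columns = []
        for c in kept:
            if c not in columns:
                columns.append(c)
    columns.sort(key=lambda c: min(order[it] for it in c))
    if len(columns) > len(ascii_lowercase):
        raise ValueError("more letter groups than available letters")
    out = {it: "" for it in items}
    for letter, col in zip(ascii_lowercase, columns):
        for it in col:
            out[it] += letter
    return {it: "".join(sorted(s)) for it, s in out.items()}


# ---------------------------------------------------------------------------
# Kendall's coefficient of concordance

@dataclass
class ConcordanceResult:
    """Kendall's W with its chi-square test and optional permutation p."""

    W: float
    m_judges: int
    n_objects: int
    chi2: float
    df: int
    p_chi2: float
    p_perm: float | None
    tie_corrected: bool


def _check_rank_row(row: np.ndarray) -> None:
    if not np.allclose(rankdata(row), row):
        raise ValueError(f"row {row!r} is not a midrank vector of 1..n")


def _w_from_ranks(ranks: np.ndarray, tie_correction: bool) -> float:
    m, n = ranks.shape
    col_sums = ranks.sum(axis=0)
    s = np.sum((col_sums - m * (n + 1) / 2.0) ** 2)
    denom = m * m * (n ** 3 - n)
    if tie_correction:
        t_total = 0.0
        for row in ranks:
            _, counts = np.unique(row, return_counts=True)
            t_total += np.sum(counts.astype(float) ** 3 - counts)
        denom -= m * t_total
    if denom <= 0.0:
        return 0.0
    return float(12.0 * s / denom)


def kendall_w(ranks, tie_correction: bool = True, n_perm: int = 0,
              seed: int | None = None) -> ConcordanceResult:
    """Kendall's coefficient of concordance over an m x n rank matrix.

    Rows are judges (e.g. genera), columns the ranked objects (e.g. calendar
    months); each row must be a valid (mid)ranking of 1..n.  W = 1 means the
    judges rank the objects identically; the chi-square test uses
    ``chi2 = m (n-1) W`` on ``n-1`` df.  ``n_perm > 0`` adds a permutation
    p-value from independent within-row rank shuffles.
    """
    ranks = np.asarray(ranks, dtype=float)
    if ranks.ndim != 2 or ranks.shape[0] < 2 or ranks.shape[1] < 2:
        raise ValueError("need a matrix of >= 2 judges and >= 2 objects")
    for row in ranks:
        _check_rank_row(row)
    m, n = ranks.shape
    w = _w_from_ranks(ranks, tie_correction)
    chi2_val = m * (n - 1) * w
    p_chi2 = float(_chi2.sf(chi2_val, n - 1))
    p_perm = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        count = 0
        shuffled = ranks.copy()
        for _ in range(n_perm):
            for i in range(m):
                shuffled[i] = ranks[i, rng.permutation(n)]
            if _w_from_ranks(shuffled, tie_correction) >= w:
                count += 1
        p_perm = (1.0 + count) / (1.0 + n_perm)
    return ConcordanceResult(W=w, m_judges=m, n_objects=n, chi2=chi2_val,
                             df=n - 1, p_chi2=p_chi2, p_perm=p_perm,
                             tie_corrected=tie_correction)


def monthly_rank_matrix(matrix: DetectionMatrix,
                        groups: list[str] | None = None,
                        months: list[int] | None = None) -> np.ndarray:
    """Rank the calendar months by mean species count, one row per group.

    The judges x objects input to :func:`kendall_w`: each group (genus)
    midranks the months by its mean per-survey count.  By default the objects
    are the months with at least one survey (surveys share dates across
    groups); at least two are required.
    """
    groups = groups if groups is not None else matrix.groups
    if months is None:
        present = {d.month for d in matrix.dates}
        months = [m for m in MONTHS if m in present]
    if len(months) < 2:
        raise ValueError("need at least two months with surveys")
    rows = []
    for g in groups:
        ms = monthly_samples(matrix, g)
        means = []
        for m in months:
            if ms.n_obs(m) == 0:
                raise ValueError(f"month {m} has no surveys; cannot rank")
            means.append(ms.samples[m].mean())
        rows.append(rankdata(means))
    return np.asarray(rows)


# ---------------------------------------------------------------------------
# standardized seasonal profiles

def relative_richness(matrix: DetectionMatrix, group: str) -> np.ndarray:
    """Standardized monthly mean species count: the group's seasonal profile.

    Returns a 12-vector (January..December) of z-scores of the monthly mean
    counts (sample sd over the months with data); months never surveyed are
    NaN and excluded from the standardization.  If all monthly means are
    equal the profile is all zeros, with a warning.
    """
    ms = monthly_samples(matrix, group)
    means = np.full(12, np.nan)
    for m in MONTHS:
        if ms.n_obs(m) > 0:
            means[m - 1] = ms.samples[m].mean()
    have = ~np.isnan(means)
    if have.sum() < 2:
        raise ValueError("need at least two months with data")
    mu = means[have].mean()
    sd = means[have].std(ddof=1)
    out = np.full(12, np.nan)
    if sd == 0.0:
        warnings.warn(f"group {group!r}: all monthly means equal; "
                      "profile set to zero", stacklevel=2)
        out[have] = 0.0
    else:
        out[have] = (means[have] - mu) / sd
    return out
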