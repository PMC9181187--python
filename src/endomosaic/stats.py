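"""Normality-gated paired comparisons, repeated-measures omnibus with
step-down Šidák adjustment, and field-of-view area ratios.

Conventions: the Shapiro-Wilk gate is applied to the paired differences
at alpha = 0.05; the signed-rank test drops zero differences and
midranks ties, with an exact null distribution for n <= 12 and a
continuity-corrected normal approximation above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "AdjustedPValues",
    "RepeatedComparison",
    "normality_gate",
    "wilcoxon_signed_rank",
    "paired_compare",
    "holm_sidak",
    "repeated_compare_days",
    "fov_ratio",
    "area_ratio",
]

ALPHA = 0.05
EXACT_WILCOXON_MAX_N = 12


@dataclass
class ComparisonResult:
    test_name: str  # "paired_t" | "wilcoxon_signed_rank"
    statistic: float
    p_two_tailed: float
    n_pairs: int
    normality_p: float
    alpha: float = ALPHA


@dataclass
class AdjustedPValues:
    """Step-down Šidák ("Holm-Šidák") adjusted p-values.

    ``order`` maps sorted position -> original index.
    """

    raw: np.ndarray
    adjusted: np.ndarray
    order: np.ndarray


@dataclass
class RepeatedComparison:
    omnibus_f: float
    omnibus_p: float
    pair_labels: list[tuple]
    pairwise: AdjustedPValues


def normality_gate(values: Sequence[float], alpha: float = ALPHA) -> tuple[bool, float]:
    """Shapiro-Wilk normality check; normal iff p >= alpha."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("normality test requires at least 3 values")
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: all values identical")
    p = float(sps.shapiro(x).pvalue)
    return p >= alpha, p


def _exact_signed_rank_p(ranks2: np.ndarray, w2_obs: int) -> float:
    """Exact two-tailed p for the positive-rank sum.

    ``ranks2`` are doubled midranks (integers); the distribution of the
    doubled positive-rank sum is built by dynamic programming over all
    2^n sign assignments.  Two-tailed p doubles the smaller tail (capped
    at 1), the convention matching full enumeration.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for v in ranks2:
        new = counts.copy()
        new[v:] += counts[: total + 1 - v]
        counts = new
    counts /= counts.sum()
    lower = counts[: w2_obs + 1].sum()
    upper = counts[w2_obs:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_signed_rank(differences: Sequence[float]) -> tuple[float, float]:
    """Signed-rank statistic (positive-rank sum) and two-tailed p.

    Zero differences are dropped; ties are midranked.  Exact null for
    n <= 12 after zero removal, normal approximation with tie correction
    and continuity correction otherwise.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    r = sps.rankdata(np.abs(d))
    w_plus = float(r[d > 0].sum())

    if n <= EXACT_WILCOXON_MAX_N:
        ranks2 = np.rint(2 * r).astype(int)
        w2 = int(round(2 * w_plus))
        return w_plus, _exact_signed_rank_p(ranks2, w2)

    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(r, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        return w_plus, 1.0
    diff = w_plus - mu
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / math.sqrt(var)
    return w_plus, float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def paired_compare(
    a: Sequence[float],
    b: Sequence[float],
    force_test: str | None = None,
) -> ComparisonResult:
    """Two-tailed paired comparison of ``a`` vs ``b``.

    The paired differences are gated through Shapiro-Wilk: a paired t
    test when they look normal, the signed-rank test otherwise.
    ``force_test`` overrides the gate ("paired_t" or
    "wilcoxon_signed_rank").
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if len(x) < 3:
        raise ValueError("paired comparison requires at least 3 pairs")
    d = x - y

    if np.all(d == 0):
        return ComparisonResult(
            test_name="wilcoxon_signed_rank",
            statistic=0.0,
            p_two_tailed=1.0,
            n_pairs=len(d),
            normality_p=float("nan"),
        )

    if np.ptp(d) == 0:  # constant nonzero differences: not normal-testable
        normal, norm_p = False, float("nan")
    else:
        normal, norm_p = normality_gate(d)

    test = force_test if force_test is not None else (
        "paired_t" if normal else "wilcoxon_signed_rank"
    )
    if test == "paired_t":
        res = sps.ttest_rel(x, y)
        stat, p = float(res.statistic), float(res.pvalue)
    elif test == "wilcoxon_signed_rank":
        stat, p = wilcoxon_signed_rank(d)
    else:
        raise ValueError(f"unknown test {test!r}")

    return ComparisonResult(
        test_name=test,
        statistic=stat,
        p_two_tailed=p,
        n_pairs=len(d),
        normality_p=norm_p,
    )


def holm_sidak(raw_p: Sequence[float]) -> AdjustedPValues:
    """Step-down Šidák adjustment: sorted raw p_(i) becomes
    1 - (1 - p_(i))^(m - i + 1), made monotone non-decreasing."""
    raw = np.asarray(raw_p, dtype=float)
    if len(raw) == 0:
        raise ValueError("no p-values to adjust")
    if ((raw < 0) | (raw > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(raw)
    order = np.argsort(raw, kind="stable")
    adj_sorted = 1.0 - (1.0 - raw[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return AdjustedPValues(raw=raw, adjusted=adjusted, order=order)


def repeated_compare_days(
    values_by_day: Mapping[object, Sequence[float]],
) -> RepeatedComparison:
    """One-way repeated-measures ANOVA across days (subjects paired
    across all days) with Šidák-adjusted pairwise paired comparisons."""
    days = sorted(values_by_day.keys())
    if len(days) < 2:
        raise ValueError("need at least 2 days")
    arrays = [np.asarray(values_by_day[d], dtype=float) for d in days]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("unbalanced input: equal n per day required")
    if n < 2:
        raise ValueError("need at least 2 subjects")

    X = np.column_stack(arrays)  # subjects x days
    k = len(days)
    grand = X.mean()
    ss_subj = k * ((X.mean(axis=1) - grand) ** 2).sum()
    ss_day = n * ((X.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((X - grand) ** 2).sum()
    ss_err = ss_total - ss_subj - ss_day
    df_day = k - 1
    df_err = (k - 1) * (n - 1)
    ms_day = ss_day / df_day
    ms_err = ss_err / df_err
    if ms_err <= 0:
        f_stat, p_omnibus = float("inf"), 0.0
    else:
        f_stat = ms_day / ms_err
        p_omnibus = float(sps.f.sf(f_stat, df_day, df_err))

    pair_labels = [(days[i], days[j]) for i in range(k) for j in range(i + 1, k)]
    raw = [
        paired_compare(X[:, days.index(d1)], X[:, days.index(d2)]).p_two_tailed
        for d1, d2 in pair_labels
    ]
    return RepeatedComparison(
        omnibus_f=float(f_stat),
        omnibus_p=p_omnibus,
        pair_labels=pair_labels,
        pairwise=holm_sidak(raw),
    )


def _round_half_away(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def area_ratio(area_a_um2: float, area_b_um2: float) -> float:
    """Area ratio rounded half-away-from-zero to one decimal."""
    if area_a_um2 <= 0 or area_b_um2 <= 0:
        raise ValueError("areas must be positive")
    return _round_half_away(area_a_um2 / area_b_um2, 1)


def fov_ratio(
    width_a_um: float,
    height_a_um: float,
    width_b_um: float,
    height_b_um: float,
) -> float:
    """Field-of-view area ratio A/B rounded to one decimal."""
    if min(width_a_um, height_a_um, width_b_um, height_b_um) <= 0:
        raise ValueError("dimensions must be positive")
    return area_ratio(width_a_um * height_a_um, width_b_um * height_b_um)
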