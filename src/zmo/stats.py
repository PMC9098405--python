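"""Paired nonparametric statistics and table summaries.

The study design compares each metric before vs after surgery (and result vs
plan) within the same patients, so the workhorse is the Wilcoxon signed-rank
test.  Sample sizes are small (8-15 pairs), hence the two-sided p-value is
computed exactly: zero differences are dropped (classic Wilcoxon; the Pratt
variant is available via ``zero_method``), absolute differences are mid-
ranked, and the null distribution of the positive-rank sum W+ is obtained by
dynamic programming over all 2^n sign assignments — identical to full
enumeration, but O(n * max rank sum).  Above ``exact_n_max`` effective pairs
the usual normal approximation with tie correction takes over.

Summaries follow the tables' house style: mean with min-max range, and
count (percent to one decimal).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .exceptions import ValidationError

EXACT_N_MAX = 25


@dataclass(frozen=True)
class PairedSeries:
    """Matched pre/post values for one metric across cases."""

    case_ids: tuple
    pre: np.ndarray
    post: np.ndarray

    def __post_init__(self):
        pre = np.asarray(self.pre, dtype=float)
        post = np.asarray(self.post, dtype=float)
        if pre.ndim != 1 or pre.shape != post.shape or len(self.case_ids) != pre.size:
            raise ValidationError("pre/post/case_ids must have equal length >= 1")
        if pre.size < 1:
            raise ValidationError("paired series must be non-empty")
        if not (np.all(np.isfinite(pre)) and np.all(np.isfinite(post))):
            raise ValidationError("paired values must be finite")
        object.__setattr__(self, "pre", pre)
        object.__setattr__(self, "post", post)


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float       # min(W+, W-) after zero handling
    p_value: float
    n_effective: int
    exact: bool


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the signed-rank sum with mid-ranked ties.

    Mid-ranks are half-integers; doubling makes them integers, and the null
    distribution of 2*W+ over all sign patterns is built by convolution.
    """
    r2 = np.round(ranks * 2).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[:-r] if r > 0 else counts
    n_patterns = counts.sum()  # == 2**n exactly in float64 for n <= 25
    w2 = int(round(2 * w_plus))
    lo = counts[: w2 + 1].sum() / n_patterns
    hi = counts[w2:].sum() / n_patterns
    return float(min(1.0, 2.0 * min(lo, hi)))


def wilcoxon_signed_rank(
    series: PairedSeries,
    zero_method: str = "wilcox",
    exact_n_max: int = EXACT_N_MAX,
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test of post vs pre.

    Exact by enumeration-equivalent DP for effective n <= ``exact_n_max``;
    normal approximation with tie correction beyond.  All-zero differences
    give p = 1 with a warning.
    """
    d = series.post - series.pre
    if zero_method == "wilcox":
        d = d[d != 0]
    elif zero_method != "pratt":
        raise ValidationError("zero_method must be 'wilcox' or 'pratt'")
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return WilcoxonResult(statistic=0.0, p_value=1.0, n_effective=0, exact=True)

    ranks = sps.rankdata(np.abs(d), method="average")
    if zero_method == "pratt":
        nz = d != 0
        w_plus = float(ranks[(d > 0)].sum())
        w_minus = float(ranks[(d < 0)].sum())
        ranks = ranks[nz]
        d = d[nz]
        n = d.size
        if n == 0:
            warnings.warn("all paired differences are zero; p = 1")
            return WilcoxonResult(0.0, 1.0, 0, True)
    else:
        w_plus = float(ranks[d > 0].sum())
        w_minus = float(ranks[d < 0].sum())

    stat = min(w_plus, w_minus)
    if n <= exact_n_max:
        p = _exact_signed_rank_p(ranks, w_plus)
        return WilcoxonResult(statistic=stat, p_value=p, n_effective=n, exact=True)

    mean = ranks.sum() / 2.0
    # null variance of W+ with mid-rank ties: sum(r_i^2) / 4
    var = float(np.sum(ranks**2)) / 4.0
    z = (w_plus - mean) / np.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return WilcoxonResult(statistic=stat, p_value=p, n_effective=n, exact=False)


@dataclass(frozen=True)
class SummaryRow:
    mean: float
    max: float
    min: float
    n: int

    def __post_init__(self):
        if not (self.min <= self.mean <= self.max):
            raise ValidationError("summary must satisfy min <= mean <= max")


def summarize(values) -> SummaryRow:
    """Mean with min-max range, as printed in the outcome tables."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("cannot summarise an empty sample")
    if not np.all(np.isfinite(v)):
        raise ValidationError("values must be finite")
    return SummaryRow(mean=float(v.mean()), max=float(v.max()),
                      min=float(v.min()), n=int(v.size))


def count_percent(count: int, total: int) -> float:
    """Percent to one decimal, e.g. count_percent(2, 15) -> 13.3."""
    if total <= 0:
        raise ValidationError("total must be positive")
    if count < 0 or count > total:
        raise ValidationError("count must lie in [0, total]")
    return round(100.0 * count / total, 1)
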