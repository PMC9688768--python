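"""Rank correlation and independence testing for landscape summaries.

Two procedures, implemented from first principles on top of numpy (the
reference distributions come from scipy):

* Spearman rank correlation between per-cohort mutation burdens, with the
  optional log2 transform used for burden plots (zero values cannot be
  log-transformed and are excluded pairwise, with a logged notice; the
  rank correlation itself is invariant under strictly monotone
  transforms, so the transform matters only for the exclusion rule).
  Ties receive average ranks; the two-sided p-value uses the
  t-approximation with n-2 degrees of freedom.
* Pearson chi-squared test of independence on a contingency table of
  tumor counts (no continuity correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float
    excluded: int
    notes: tuple[str, ...] = ()


def _average_ranks(values: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties sharing their average rank."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def spearman_rank(
    x, y, log2_transform: bool = False
) -> CorrelationResult:
    """Spearman rank correlation with optional log2-with-zero-exclusion.

    Raises ValueError with fewer than 3 usable pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    notes: list[str] = []
    excluded = 0
    if log2_transform:
        keep = (x > 0) & (y > 0)
        excluded = int((~keep).sum())
        if excluded:
            notes.append(f"excluded {excluded} pair(s) with zero values before log2")
        x, y = np.log2(x[keep]), np.log2(y[keep])
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 usable pairs, got {n}")
    rx = _average_ranks(x)
    ry = _average_ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        raise ValueError("zero rank variance (constant vector)")
    r = float((rx * ry).sum() / denom)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1 - r * r))
        p = float(2 * _sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(r=r, n=n, p=p, excluded=excluded, notes=tuple(notes))


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float
    expected: np.ndarray = field(repr=False, compare=False, default=None)


def chi_square_independence(table) -> ChiSquareResult:
    """Pearson chi-squared test of independence on a 2-D count table.

    statistic = sum (O-E)^2 / E with E from the margins; p from the
    chi-squared survival function with (rows-1)(cols-1) df.  A zero
    expected cell is an error advising a category merge.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("contingency table must be non-negative")
    total = obs.sum()
    if total == 0:
        raise ValueError("empty contingency table")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    if (expected == 0).any():
        raise ValueError(
            "expected count of zero: merge empty rows/columns before testing"
        )
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(_sps.chi2.sf(statistic, df=df))
    return ChiSquareResult(statistic=statistic, df=df, p=p, expected=expected)
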