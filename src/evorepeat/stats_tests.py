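"""From-scratch rank and variance-equality tests.

These are the component statistics the ordered-heterogeneity machinery is
built from: Levene / Brown-Forsythe equality of variances, the
Kruskal-Wallis rank-sum test with tie correction, and Spearman rank
correlation with average ranks.  Only the chi-square and F distribution
functions are delegated to scipy; the statistics themselves are computed
directly so the permutation engine can share their exact definitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps


class InsufficientDataError(ValueError):
    """A group is too small for the requested test."""


class DegenerateInputError(ValueError):
    """All values identical (or otherwise zero-information input)."""


@dataclass(frozen=True)
class GroupedSample:
    """An ordered collection of labelled value groups."""

    groups: tuple[tuple[str, np.ndarray], ...]

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("a GroupedSample needs at least 2 groups")
        object.__setattr__(
            self,
            "groups",
            tuple((str(lab), np.asarray(vals, dtype=float)) for lab, vals in self.groups),
        )
        for lab, vals in self.groups:
            if vals.ndim != 1 or vals.size < 1:
                raise ValueError(f"group {lab!r} must be a non-empty 1-d array")

    @classmethod
    def from_dict(cls, d: dict[str, Iterable[float]]) -> "GroupedSample":
        return cls(tuple((k, np.asarray(list(v), dtype=float)) for k, v in d.items()))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.groups)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(v.size for _, v in self.groups)

    @property
    def n_total(self) -> int:
        return sum(self.sizes)

    def values_concat(self) -> np.ndarray:
        return np.concatenate([v for _, v in self.groups])


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: tuple[float, ...]
    p_value: float
    method: str

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": list(self.df),
            "p_value": self.p_value,
            "method": self.method,
        }


def average_ranks(values: Sequence[float]) -> np.ndarray:
    """Ranks 1..n with ties assigned the mean of the spanned ranks."""
    v = np.asarray(values, dtype=float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(v.size, dtype=float)
    sv = v[order]
    i = 0
    while i < v.size:
        j = i
        while j + 1 < v.size and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0  # mean of ranks i+1 .. j+1
        i = j + 1
    return ranks


def _oneway_f(groups: Sequence[np.ndarray]) -> tuple[float, int, int]:
    """One-way ANOVA F statistic with (k-1, N-k) degrees of freedom."""
    k = len(groups)
    n = np.array([g.size for g in groups])
    N = int(n.sum())
    means = np.array([g.mean() for g in groups])
    grand = float(np.concatenate(groups).mean())
    ss_between = float(np.sum(n * (means - grand) ** 2))
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    df1, df2 = k - 1, N - k
    if ss_within == 0.0:
        f = 0.0 if ss_between == 0.0 else np.inf
    else:
        f = (ss_between / df1) / (ss_within / df2)
    return f, df1, df2


def levene_test(sample: GroupedSample, center: str = "median") -> TestResult:
    """Levene's (center='mean') / Brown-Forsythe (center='median') test.

    The statistic is the one-way ANOVA F computed on the absolute
    deviations z_ij = |y_ij - c_j| from each group's center.
    """
    if center not in ("mean", "median"):
        raise ValueError(f"center must be 'mean' or 'median', got {center!r}")
    for lab, vals in sample.groups:
        if vals.size < 2:
            raise InsufficientDataError(f"group {lab!r} has fewer than 2 values")
    zs = []
    for _, vals in sample.groups:
        c = np.median(vals) if center == "median" else vals.mean()
        zs.append(np.abs(vals - c))
    f, df1, df2 = _oneway_f(zs)
    if f == 0.0:
        p = 1.0
    elif np.isinf(f):
        p = 0.0
    else:
        p = float(sps.f.sf(f, df1, df2))
    return TestResult(float(f), (float(df1), float(df2)), p, f"levene_{center}")


def kruskal_wallis(sample: GroupedSample) -> TestResult:
    """Kruskal-Wallis H with tie correction and a chi-square p-value.

    H = 12/(N(N+1)) * sum_j R_j^2 / n_j - 3(N+1), divided by the tie
    correction 1 - sum(t^3 - t) / (N^3 - N); p from chi-square on k-1 df.
    """
    k = len(sample.groups)
    N = sample.n_total
    if N < 3:
        raise InsufficientDataError("Kruskal-Wallis requires at least 3 observations")
    values = sample.values_concat()
    ranks = average_ranks(values)
    sizes = np.array(sample.sizes)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    rank_sums = np.array([ranks[bounds[j] : bounds[j + 1]].sum() for j in range(k)])
    h = 12.0 / (N * (N + 1)) * float(np.sum(rank_sums**2 / sizes)) - 3.0 * (N + 1)
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    denom = 1.0 - tie_term / (N**3 - N)
    if denom == 0.0:
        raise DegenerateInputError("all values identical; Kruskal-Wallis undefined")
    h /= denom
    h = max(h, 0.0)  # guard tiny negative round-off
    p = float(sps.chi2.sf(h, k - 1))
    return TestResult(float(h), (float(k - 1),), p, "kruskal_wallis")


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-d arrays of length >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateInputError("correlation undefined for a constant vector")
    rx = average_ranks(x)
    ry = average_ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    denom = float(np.sqrt((rx**2).sum() * (ry**2).sum()))
    if denom == 0.0:
        raise DegenerateInputError("ranks are constant after tie-averaging")
    return float(np.clip((rx * ry).sum() / denom, -1.0, 1.0))
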