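"""Ordered Heterogeneity (OH) test with a permutation null.

The OH test turns a nondirectional k-sample heterogeneity test into a
directional test against a predicted ordering of the groups.  Its
statistic is r_s * P_c, where r_s is the Spearman correlation between the
observed group summaries and the predicted ranks (ties allowed, so
composite alternatives like "two treatments equal, one different" are
expressible), and P_c = 1 - p is the complement of the heterogeneity
test's p-value.  Large positive values are evidence for the predicted
order; significance is assessed by randomly reassigning observations to
groups (or exhaustively enumerating all assignments when feasible).

Two heterogeneity kernels are supported: Kruskal-Wallis (location
alternatives; group summary = mean within-group rank) and Levene /
Brown-Forsythe (spread alternatives; group summary = mean absolute
deviation from the group center).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats_tests import GroupedSample

logger = logging.getLogger("evorepeat")

__all__ = ["OrderHypothesis", "OHResult", "oh_test", "oh_test_suite"]

_EPS = 1e-12
_MAX_EXHAUSTIVE = 2_000_000


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class OrderHypothesis:
    """A predicted ordering of group-level summaries.

    ``predicted_ranks`` maps each group label to a real rank; larger rank
    means a larger predicted summary.  Tied ranks (e.g. 1.5/1.5/3)
    express composite alternatives where some groups are predicted equal.
    """

    name: str
    predicted_ranks: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "predicted_ranks", dict(self.predicted_ranks))
        if len(set(self.predicted_ranks.values())) < 2:
            raise ValueError("predicted_ranks must contain at least 2 distinct rank values")

    @classmethod
    def from_order(cls, name: str, labels_ascending: Sequence[str]) -> "OrderHypothesis":
        """Hypothesis that summaries increase along ``labels_ascending``."""
        return cls(name, {lab: float(i + 1) for i, lab in enumerate(labels_ascending)})

    def rank_vector(self, labels: Sequence[str]) -> np.ndarray:
        missing = [lab for lab in labels if lab not in self.predicted_ranks]
        if missing:
            raise KeyError(f"hypothesis {self.name!r} lacks predicted ranks for group(s): {missing}")
        return np.array([self.predicted_ranks[lab] for lab in labels], dtype=float)


@dataclass(frozen=True)
class OHResult:
    hypothesis: str
    r_s: float
    P_c: float
    statistic: float
    p_value: float
    n_permutations: int
    heterogeneity_method: str
    null: str
    group_summaries: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "hypothesis": self.hypothesis,
            "r_s": self.r_s,
            "P_c": self.P_c,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "heterogeneity_method": self.heterogeneity_method,
            "null": self.null,
            "group_summaries": self.group_summaries,
        }


# ---------------------------------------------------------------------------
# Vectorised statistic engine.  Each row of `arrangements` is one assignment
# of the pooled values to groups (columns 0..n_1-1 are group 1, and so on);
# every row is scored with the same formulas as the scalar tests in
# stats_tests, so permutation and observed statistics are exactly comparable.
# ---------------------------------------------------------------------------


def _group_slices(sizes: Sequence[int]) -> list[slice]:
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    return [slice(int(bounds[j]), int(bounds[j + 1])) for j in range(len(sizes))]


def _rows_kruskal(arr: np.ndarray, sizes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row (P_c, group mean ranks) under the Kruskal-Wallis kernel."""
    B, N = arr.shape
    k = sizes.size
    ranks = sps.rankdata(arr, axis=1)
    slices = _group_slices(sizes)
    rank_sums = np.stack([ranks[:, s].sum(axis=1) for s in slices], axis=1)
    h = 12.0 / (N * (N + 1)) * (rank_sums**2 / sizes).sum(axis=1) - 3.0 * (N + 1)
    # The tie pattern is a property of the pooled multiset, identical in
    # every row, so the correction is a scalar.
    _, counts = np.unique(arr[0], return_counts=True)
    denom = 1.0 - float(np.sum(counts**3 - counts)) / (N**3 - N)
    h = np.maximum(h / denom, 0.0)
    p = sps.chi2.sf(h, k - 1)
    return 1.0 - p, rank_sums / sizes


def _rows_levene(
    arr: np.ndarray, sizes: np.ndarray, center: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-row (P_c, group mean |deviation|) under the Levene kernel."""
    B, N = arr.shape
    k = sizes.size
    slices = _group_slices(sizes)
    z_groups = []
    for s in slices:
        g = arr[:, s]
        c = np.median(g, axis=1, keepdims=True) if center == "median" else g.mean(
            axis=1, keepdims=True
        )
        z_groups.append(np.abs(g - c))
    z_means = np.stack([z.mean(axis=1) for z in z_groups], axis=1)
    grand = (z_means * sizes).sum(axis=1) / N
    ss_between = (sizes * (z_means - grand[:, None]) ** 2).sum(axis=1)
    ss_within = np.stack(
        [((z - m[:, None]) ** 2).sum(axis=1) for z, m in zip(z_groups, z_means.T)], axis=0
    ).sum(axis=0)
    df1, df2 = k - 1, N - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df1) / (ss_within / df2)
    f = np.where(ss_within == 0.0, np.where(ss_between == 0.0, 0.0, np.inf), f)
    p = np.where(np.isinf(f), 0.0, np.where(f == 0.0, 1.0, sps.f.sf(np.where(f > 0, f, 1.0), df1, df2)))
    return 1.0 - p, z_means


def _rows_spearman(summaries: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    """Spearman correlation of each row of summaries with the predicted ranks.

    Rows whose summaries are all tied carry no ordering information and get
    r_s = 0 (the scalar spearman_rho raises for such degenerate input; in
    the permutation null a zero contribution is the consistent choice).
    """
    rx = sps.rankdata(summaries, axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = predicted - predicted.mean()
    denom = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum())
    num = (rx * ry).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num / denom
    return np.clip(np.where(denom == 0.0, 0.0, r), -1.0, 1.0)


def _score_rows(
    arr: np.ndarray,
    sizes: np.ndarray,
    predicted: np.ndarray,
    heterogeneity: str,
    levene_center: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if heterogeneity == "kruskal":
        p_c, summaries = _rows_kruskal(arr, sizes)
    elif heterogeneity == "levene":
        p_c, summaries = _rows_levene(arr, sizes, levene_center)
    else:
        raise ValueError(f"heterogeneity must be 'kruskal' or 'levene', got {heterogeneity!r}")
    r_s = _rows_spearman(summaries, predicted)
    return r_s * p_c, r_s, p_c


def _exhaustive_arrangements(values: np.ndarray, sizes: Sequence[int]) -> np.ndarray:
    """All distinct assignments of the pooled observations to groups.

    Observations are treated as labelled items, so the number of
    assignments is the multinomial coefficient N! / prod(n_j!).
    """
    n_total = int(sum(sizes))
    count = math.factorial(n_total)
    for n in sizes:
        count //= math.factorial(n)
    if count > _MAX_EXHAUSTIVE:
        raise ConfigurationError(
            f"{count} assignments exceed the exhaustive-enumeration limit; use null='permutation'"
        )

    rows = np.empty((count, n_total), dtype=float)
    i = 0

    def rec(remaining: tuple[int, ...], chosen: list[int], g: int) -> None:
        nonlocal i
        if g == len(sizes) - 1:
            rows[i] = values[list(chosen) + list(remaining)]
            i += 1
            return
        for combo in itertools.combinations(range(len(remaining)), sizes[g]):
            picked = [remaining[c] for c in combo]
            rest = tuple(x for j, x in enumerate(remaining) if j not in set(combo))
            rec(rest, chosen + picked, g + 1)

    rec(tuple(range(n_total)), [], 0)
    assert i == count
    return rows


def oh_test(
    sample: GroupedSample,
    hypothesis: OrderHypothesis,
    heterogeneity: str = "kruskal",
    levene_center: str = "median",
    null: str = "permutation",
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> OHResult:
    """Run the OH test for one predicted ordering.

    The null distribution reassigns the pooled observations to groups
    (preserving group sizes) and rescores the statistic; the p-value is
    the one-sided tail probability of a statistic at least as large as
    observed.  ``null='exhaustive'`` enumerates every distinct assignment;
    ``null='permutation'`` draws ``n_permutations`` random ones and uses
    the add-one estimator (1 + #{>= observed}) / (B + 1).
    """
    labels = sample.labels
    predicted = hypothesis.rank_vector(labels)
    if heterogeneity == "levene":
        for lab, vals in sample.groups:
            if vals.size < 2:
                raise ValueError(f"levene heterogeneity needs >= 2 values per group ({lab!r})")

    values = sample.values_concat()
    sizes = np.array(sample.sizes)

    if np.all(values == values[0]):
        logger.warning("all observations identical; OH statistic is 0 with p = 1")
        return OHResult(
            hypothesis=hypothesis.name,
            r_s=0.0,
            P_c=0.0,
            statistic=0.0,
            p_value=1.0,
            n_permutations=0,
            heterogeneity_method=heterogeneity,
            null="degenerate",
            group_summaries={lab: float(values[0]) for lab in labels},
        )

    obs_stat, obs_r, obs_pc = _score_rows(
        values[None, :], sizes, predicted, heterogeneity, levene_center
    )
    obs_stat, obs_r, obs_pc = float(obs_stat[0]), float(obs_r[0]), float(obs_pc[0])
    if heterogeneity == "kruskal":
        _, summ = _rows_kruskal(values[None, :], sizes)
    else:
        _, summ = _rows_levene(values[None, :], sizes, levene_center)
    summaries = {lab: float(s) for lab, s in zip(labels, summ[0])}

    if null == "exhaustive":
        arrangements = _exhaustive_arrangements(values, sample.sizes)
        stats, _, _ = _score_rows(arrangements, sizes, predicted, heterogeneity, levene_center)
        n_used = stats.size
        p = float(np.count_nonzero(stats >= obs_stat - _EPS)) / n_used
    elif null == "permutation":
        if n_permutations < 100:
            raise ConfigurationError("n_permutations must be >= 100 in permutation mode")
        rng = np.random.default_rng(seed)
        idx = np.argsort(rng.random((n_permutations, values.size)), axis=1)
        arrangements = values[idx]
        stats, _, _ = _score_rows(arrangements, sizes, predicted, heterogeneity, levene_center)
        n_used = n_permutations
        p = (1.0 + float(np.count_nonzero(stats >= obs_stat - _EPS))) / (n_permutations + 1.0)
    else:
        raise ValueError(f"null must be 'permutation' or 'exhaustive', got {null!r}")

    return OHResult(
        hypothesis=hypothesis.name,
        r_s=obs_r,
        P_c=obs_pc,
        statistic=obs_stat,
        p_value=p,
        n_permutations=int(n_used),
        heterogeneity_method=heterogeneity,
        null=null,
        group_summaries=summaries,
    )


def oh_test_suite(
    responses: pd.DataFrame,
    hypotheses: Sequence[OrderHypothesis],
    target: str = "means",
    levene_center: str = "median",
    null: str = "permutation",
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> list[OHResult]:
    """OH tests on per-replicate selection responses grouped by treatment.

    ``target='means'`` tests ordered differences in mean response with the
    Kruskal-Wallis kernel; ``target='variances'`` tests ordered differences
    in among-replicate response spread with the Levene kernel.
    """
    if target not in ("means", "variances"):
        raise ValueError(f"target must be 'means' or 'variances', got {target!r}")
    groups = tuple(
        (trt, grp["response"].to_numpy(dtype=float))
        for trt, grp in responses.groupby("treatment", sort=False)
    )
    sample = GroupedSample(groups)
    for lab, vals in sample.groups:
        if vals.size < 2:
            raise ValueError(f"treatment {lab!r} has fewer than 2 replicate responses")
    heterogeneity = "kruskal" if target == "means" else "levene"
    results = []
    for i, hyp in enumerate(hypotheses):
        sub_seed = None if seed is None else seed + i
        results.append(
            oh_test(
                sample,
                hyp,
                heterogeneity=heterogeneity,
                levene_center=levene_center,
                null=null,
                n_permutations=n_permutations,
                seed=sub_seed,
            )
        )
    return results
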