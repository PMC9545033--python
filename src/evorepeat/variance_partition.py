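"""Selection / chance / error variance partitioning via nested ANOVA.

Within one treatment, fitness measurements form a two-level nested layout:
week (before vs after selection; a = 2 levels) over replicates nested in
week (b per week) over technical measurements nested in replicate (n per
cell).  The mean squares of the corresponding nested ANOVA quantify the
three strata the analysis interprets as selection (between weeks), chance
(among replicates within week) and measurement error (within replicate),
and each stratum is reported as its share of the summed mean squares.

Real designs are unbalanced (one to three assessment days per replicate),
so the partition is computed on every balanced subsample obtained by
choosing exactly one assessment day per (replicate, week) cell, and the
distribution of proportions across subsamples is reported.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import ExperimentTable

logger = logging.getLogger("evorepeat")

__all__ = [
    "BalancedSubset",
    "NestedANOVAResult",
    "PartitionDistribution",
    "enumerate_balanced_subsets",
    "nested_anova_ms",
    "partition_distribution",
]

COMPONENTS = ("selection", "chance", "error")


class EmptyDesignError(ValueError):
    pass


class BalanceError(ValueError):
    pass


class DegenerateVarianceError(ValueError):
    pass


@dataclass(frozen=True)
class BalancedSubset:
    """One choice of a single assessment day per (replicate, week) cell."""

    choice: tuple[tuple[tuple[str, int], str], ...]  # ((replicate, week) -> day), sorted

    def as_dict(self) -> dict[tuple[str, int], str]:
        return dict(self.choice)


@dataclass(frozen=True)
class NestedANOVAResult:
    ss: dict[str, float]
    df: dict[str, int]
    ms: dict[str, float]
    proportions: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "ss": self.ss,
            "df": self.df,
            "ms": self.ms,
            "proportions": self.proportions,
        }


@dataclass
class PartitionDistribution:
    treatment: str
    results: list[NestedANOVAResult]
    subsets: list[BalancedSubset]
    skipped: int = 0
    quantile_levels: tuple[float, ...] = (0.025, 0.25, 0.5, 0.75, 0.975)

    @property
    def n_subsets(self) -> int:
        return len(self.results) + self.skipped

    def proportions_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.proportions for r in self.results])

    def summary(self) -> dict:
        props = self.proportions_frame()
        out = {"treatment": self.treatment, "n_subsets": self.n_subsets, "skipped": self.skipped}
        for comp in COMPONENTS:
            qs = np.quantile(props[comp].to_numpy(), self.quantile_levels)
            out[comp] = {
                "median": float(np.median(props[comp])),
                "quantiles": {str(lv): float(q) for lv, q in zip(self.quantile_levels, qs)},
            }
        return out


def enumerate_balanced_subsets(
    day_counts: Mapping[tuple[str, int], Sequence[str] | int],
) -> list[BalancedSubset]:
    """All balanced day choices: the Cartesian product over cells.

    ``day_counts`` maps each (replicate, week) cell to its available
    assessment-day labels (or an integer n, meaning labels ``d1..dn``).
    Returns ``prod(day counts)`` subsets in deterministic lexicographic
    order of the sorted cell keys.
    """
    if not day_counts:
        raise EmptyDesignError("no (replicate, week) cells given")
    cells = sorted(day_counts.keys())
    options: list[list[str]] = []
    for cell in cells:
        v = day_counts[cell]
        days = [f"d{i}" for i in range(1, v + 1)] if isinstance(v, int) else sorted(map(str, v))
        if len(days) == 0:
            raise EmptyDesignError(f"cell {cell} has no assessment days")
        options.append(days)
    return [
        BalancedSubset(tuple(zip(cells, combo))) for combo in itertools.product(*options)
    ]


def nested_anova_ms(subset: pd.DataFrame, scale: str = "log") -> NestedANOVAResult:
    """Nested-ANOVA mean squares and proportions for one balanced subset.

    Expects measurements of a single treatment with exactly one assessment
    day per (replicate, week) cell.  With a = 2 weeks, b replicates per
    week and n measurements per cell:

        SS_selection = b n sum_i (ybar_i.. - ybar...)^2      df = a - 1
        SS_chance    = n sum_ij (ybar_ij. - ybar_i..)^2      df = a (b - 1)
        SS_error     = sum_ijk (y_ijk - ybar_ij.)^2          df = a b (n - 1)

    Proportions are each stratum's mean square over the summed mean
    squares (not variance-component estimates).
    """
    if scale not in ("log", "raw"):
        raise ValueError(f"scale must be 'log' or 'raw', got {scale!r}")
    df = subset.copy()
    if scale == "log":
        if (df["population_size"] <= 0).any():
            raise DegenerateVarianceError("zero population sizes cannot enter the log scale")
        df["value"] = np.log(df["population_size"].to_numpy(dtype=float))
    else:
        df["value"] = df["population_size"].astype(float)

    weeks = sorted(df["week"].unique())
    if len(weeks) != 2:
        raise BalanceError(f"expected 2 weeks, found {weeks}")
    cells = df.groupby(["week", "replicate"])["value"]
    sizes = cells.size()
    if sizes.nunique() != 1:
        raise BalanceError("unequal measurement counts per (week, replicate) cell; subset first")
    n = int(sizes.iloc[0])
    reps_per_week = sizes.groupby(level="week").size()
    if reps_per_week.nunique() != 1:
        raise BalanceError("unequal replicate counts per week")
    b = int(reps_per_week.iloc[0])
    a = 2
    if n < 2:
        raise BalanceError("need >= 2 measurements per cell for an error stratum")

    y = df["value"].to_numpy()
    grand = y.mean()
    if np.allclose(y, grand, rtol=0.0, atol=1e-12):
        raise DegenerateVarianceError("all values identical; proportions undefined")

    week_means = df.groupby("week")["value"].mean()
    cell_means = cells.mean()

    ss_sel = b * n * float(((week_means - grand) ** 2).sum())
    ss_cha = n * float(
        ((cell_means - week_means.reindex(cell_means.index.get_level_values("week")).to_numpy())
         ** 2).sum()
    )
    cm_per_row = df.groupby(["week", "replicate"])["value"].transform("mean").to_numpy()
    ss_err = float(((y - cm_per_row) ** 2).sum())

    ss = {"selection": ss_sel, "chance": ss_cha, "error": ss_err}
    dfs = {"selection": a - 1, "chance": a * (b - 1), "error": a * b * (n - 1)}
    ms = {k: ss[k] / dfs[k] for k in COMPONENTS}
    total_ms = sum(ms.values())
    props = {k: ms[k] / total_ms for k in COMPONENTS}
    return NestedANOVAResult(ss=ss, df=dfs, ms=ms, proportions=props)


def partition_distribution(
    table: ExperimentTable,
    treatment: str,
    scale: str = "log",
    max_subsets: int | None = None,
    seed: int | None = None,
) -> PartitionDistribution:
    """Partition over every balanced day-choice subsample of one treatment.

    When the exhaustive product exceeds ``max_subsets`` (if given), a
    uniform random subsample of that size is drawn with ``seed``.
    Degenerate subsets (zero total variance) are skipped with a warning
    and counted.
    """
    sub = table.data[table.data["treatment"] == treatment]
    if sub.empty:
        raise EmptyDesignError(f"treatment {treatment!r} not present")
    if set(sub["week"].unique()) != {0, 15}:
        raise EmptyDesignError(f"treatment {treatment!r} lacks one of the weeks")

    day_map = table.day_counts(treatment)
    subsets = enumerate_balanced_subsets(day_map)
    if max_subsets is not None and len(subsets) > max_subsets:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(subsets), size=max_subsets, replace=False)
        subsets = [subsets[i] for i in sorted(keep)]

    grouped = {
        key: grp for key, grp in sub.groupby(["replicate", "week", "assessment_day"], sort=False)
    }
    results, kept, skipped = [], [], 0
    for bs in subsets:
        frames = []
        for (rep, week), day in bs.choice:
            frames.append(grouped[(rep, week, day)])
        data = pd.concat(frames, ignore_index=True)
        try:
            results.append(nested_anova_ms(data, scale=scale))
            kept.append(bs)
        except DegenerateVarianceError:
            skipped += 1
    if skipped:
        logger.warning(
            "skipped %d degenerate balanced subset(s) for treatment %r", skipped, treatment
        )
    if not results:
        raise DegenerateVarianceError(f"every balanced subset of {treatment!r} was degenerate")
    return PartitionDistribution(treatment=treatment, results=results, subsets=kept, skipped=skipped)


def plot_partition_violin(distributions: Sequence[PartitionDistribution], path=None):
    """Violin plot of component proportions per treatment (one axis per component)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(COMPONENTS), figsize=(4 * len(COMPONENTS), 4), sharey=True)
    for ax, comp in zip(np.atleast_1d(axes), COMPONENTS):
        data = [d.proportions_frame()[comp].to_numpy() for d in distributions]
        ax.violinplot(data, showmedians=True)
        ax.set_xticks(range(1, len(distributions) + 1))
        ax.set_xticklabels([d.treatment for d in distributions])
        ax.set_title(comp)
        ax.set_ylim(0, 1)
    axes[0].set_ylabel("proportion of summed mean squares")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
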