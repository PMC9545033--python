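"""Measurement data model and fitness-proxy computations.

The experimental unit hierarchy is treatment -> replicate population ->
week (0 = ancestral, 15 = evolved) -> fitness assessment day -> technical
measurement.  The fitness proxy for one technical measurement is the
population size reached after one week of growth, extrapolated from worm
counts in small droplets of the assay suspension.  Model fitting happens
on the natural-log scale; selection responses are reported on the raw
scale (differences of population sizes).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("evorepeat")

#: Canonical treatment labels in order of increasing bottleneck strength.
TREATMENT_ORDER = ("no", "moderate", "strong")

#: Columns every measurements table must declare.
REQUIRED_COLUMNS = (
    "treatment",
    "replicate",
    "week",
    "assessment_day",
    "tech_index",
    "population_size",
)

#: Columns identifying a single technical measurement.
KEY_COLUMNS = ("treatment", "replicate", "week", "assessment_day", "tech_index")

VALID_WEEKS = (0, 15)


class SchemaError(ValueError):
    """A required column is missing or has an unusable dtype."""


class ValidationError(ValueError):
    """Row-level values violate the data model."""


class DuplicateKeyError(ValidationError):
    """Two rows share the same (treatment, replicate, week, day, tech) key."""


class PairingError(ValueError):
    """A replicate is present in only one of the two assay weeks."""


def extrapolate_population_size(
    droplet_counts: Sequence[int],
    droplet_volume: float,
    suspension_volume: float,
) -> float:
    """Extrapolate a population size from worm counts in assay droplets.

    Parameters
    ----------
    droplet_counts
        Non-negative worm counts, one per droplet (typically 5 µL droplets).
    droplet_volume
        Volume of a single droplet, in µL.
    suspension_volume
        Total volume of the suspension the droplets were drawn from, in µL.

    Returns
    -------
    float
        ``mean(droplet_counts) * suspension_volume / droplet_volume``,
        the estimated number of individuals in the whole suspension.
    """
    counts = np.asarray(droplet_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("droplet_counts is empty; at least one droplet count is required")
    if np.any(counts < 0):
        raise ValueError("droplet counts must be non-negative")
    if droplet_volume <= 0 or suspension_volume <= 0:
        raise ValueError("droplet_volume and suspension_volume must be positive")
    return float(counts.mean() * suspension_volume / droplet_volume)


@dataclass(frozen=True)
class Measurement:
    """One technical fitness measurement with its full design coordinates."""

    treatment: str
    replicate: str
    week: int
    assessment_day: str
    tech_index: int
    population_size: float
    droplet_counts: tuple[int, ...] | None = None

    @property
    def log_size(self) -> float:
        """Natural log of the population size; NaN when the size is zero."""
        if self.population_size > 0:
            return math.log(self.population_size)
        return float("nan")


@dataclass
class ExperimentTable:
    """A validated tidy table of fitness measurements.

    Wraps a :class:`pandas.DataFrame` with the columns in
    :data:`REQUIRED_COLUMNS` (plus optional ``droplet_count_*`` columns) and
    enforces the design invariants: weeks restricted to 0/15, unique
    measurement keys, and a constant number of technical measurements
    within each (treatment, replicate, week, day) cell.
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = _validate_frame(self.data, self.metadata)

    # -- construction ------------------------------------------------

    @classmethod
    def from_measurements(
        cls, measurements: Iterable[Measurement], metadata: Mapping | None = None
    ) -> "ExperimentTable":
        rows = []
        for m in measurements:
            row = {
                "treatment": m.treatment,
                "replicate": m.replicate,
                "week": m.week,
                "assessment_day": m.assessment_day,
                "tech_index": m.tech_index,
                "population_size": m.population_size,
            }
            if m.droplet_counts is not None:
                for i, c in enumerate(m.droplet_counts, start=1):
                    row[f"droplet_count_{i}"] = c
            rows.append(row)
        return cls(pd.DataFrame(rows), dict(metadata or {}))

    # -- accessors ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def treatments(self) -> list[str]:
        present = self.data["treatment"].unique().tolist()
        ordered = [t for t in TREATMENT_ORDER if t in present]
        return ordered + [t for t in present if t not in ordered]

    def with_log_size(self, warn: bool = True) -> pd.DataFrame:
        """Return a copy with a ``log_size`` column, dropping zero sizes.

        Zero population sizes have no log; such rows are excluded from
        log-scale analyses with a logged warning.
        """
        df = self.data.copy()
        zero = df["population_size"] <= 0
        if zero.any():
            if warn:
                logger.warning(
                    "dropping %d measurement(s) with population_size == 0 "
                    "from log-scale analysis",
                    int(zero.sum()),
                )
            df = df[~zero].copy()
        df["log_size"] = np.log(df["population_size"].to_numpy(dtype=float))
        return df

    def day_counts(self, treatment: str) -> dict[tuple[str, int], list]:
        """Available assessment days per (replicate, week) cell of a treatment."""
        sub = self.data[self.data["treatment"] == treatment]
        out: dict[tuple[str, int], list] = {}
        for (rep, week), grp in sub.groupby(["replicate", "week"], sort=True):
            out[(rep, int(week))] = sorted(grp["assessment_day"].unique().tolist())
        return out

    # -- io ----------------------------------------------------------

    def to_csv(self, path) -> None:
        write_experiment(self, path)


def _validate_frame(df: pd.DataFrame, metadata: Mapping) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    droplet_cols = sorted(
        (c for c in df.columns if c.startswith("droplet_count_")),
        key=lambda c: int(c.rsplit("_", 1)[1]),
    )
    if missing:
        if "population_size" in missing and droplet_cols:
            missing.remove("population_size")
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    df = df.copy()
    for col, dtype in (("week", int), ("tech_index", int)):
        try:
            df[col] = df[col].astype(dtype)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"column {col!r} is not integer-typed: {exc}") from exc
    df["treatment"] = df["treatment"].astype(str)
    df["replicate"] = df["replicate"].astype(str)
    df["assessment_day"] = df["assessment_day"].astype(str)

    bad_week = ~df["week"].isin(VALID_WEEKS)
    if bad_week.any():
        rows = df.index[bad_week].tolist()[:10]
        raise ValidationError(f"week must be one of {VALID_WEEKS}; offending rows: {rows}")
    bad_tech = df["tech_index"] < 1
    if bad_tech.any():
        rows = df.index[bad_tech].tolist()[:10]
        raise ValidationError(f"tech_index must be >= 1; offending rows: {rows}")

    # Fill population_size from droplet counts where needed, and check
    # agreement where both are supplied (within 0.5 individuals).
    if droplet_cols:
        dv = float(metadata.get("droplet_volume_ul", 5.0))
        sv = metadata.get("suspension_volume_ul")
        if sv is None:
            raise SchemaError(
                "droplet_count columns present but metadata lacks "
                "'suspension_volume_ul' needed for extrapolation"
            )
        counts = df[droplet_cols].to_numpy(dtype=float)
        have_counts = ~np.all(np.isnan(counts), axis=1)
        extrap = np.nanmean(counts, axis=1) * float(sv) / dv
        if "population_size" not in df.columns:
            df["population_size"] = np.nan
        pop = df["population_size"].to_numpy(dtype=float)
        supplied = ~np.isnan(pop)
        both = have_counts & supplied
        disagree = both & (np.abs(pop - extrap) > 0.5)
        if disagree.any():
            rows = df.index[disagree].tolist()[:10]
            raise ValidationError(
                "population_size disagrees with droplet-count extrapolation "
                f"by more than 0.5 individuals in rows: {rows}"
            )
        pop = np.where(~supplied & have_counts, extrap, pop)
        df["population_size"] = pop

    df["population_size"] = df["population_size"].astype(float)
    if df["population_size"].isna().any():
        rows = df.index[df["population_size"].isna()].tolist()[:10]
        raise ValidationError(f"population_size missing in rows: {rows}")
    if (df["population_size"] < 0).any():
        rows = df.index[df["population_size"] < 0].tolist()[:10]
        raise ValidationError(f"population_size must be >= 0; offending rows: {rows}")

    dup = df.duplicated(subset=list(KEY_COLUMNS), keep=False)
    if dup.any():
        rows = df.index[dup].tolist()[:10]
        raise DuplicateKeyError(
            f"duplicate (treatment, replicate, week, day, tech_index) keys in rows: {rows}"
        )

    # Constant technical-measurement count within each assessment-day cell.
    cell_sizes = df.groupby(["treatment", "replicate", "week", "assessment_day"]).size()
    per_trt = cell_sizes.groupby(level="treatment").nunique()
    uneven = per_trt[per_trt > 1]
    if not uneven.empty:
        raise ValidationError(
            "unequal technical-measurement counts across assessment-day cells "
            f"in treatment(s): {', '.join(uneven.index)}"
        )
    return df.reset_index(drop=True)


def read_experiment(path, fmt: str = "csv", metadata: Mapping | None = None) -> ExperimentTable:
    """Read and validate a tidy measurements table from CSV.

    ``metadata`` may carry ``droplet_volume_ul`` and ``suspension_volume_ul``
    (used to extrapolate population sizes from any ``droplet_count_*``
    columns) and arbitrary free-form keys.
    """
    if fmt != "csv":
        raise ValueError(f"unsupported format: {fmt!r}")
    df = pd.read_csv(path)
    return ExperimentTable(df, dict(metadata or {}))


def write_experiment(table: ExperimentTable, path) -> None:
    """Write the table to CSV (UTF-8, comma-separated, with header)."""
    table.data.to_csv(path, index=False)


def selection_response(table: ExperimentTable, scale: str = "raw") -> pd.DataFrame:
    """Per-replicate selection response: week-15 mean minus week-0 mean.

    All assessment days and technical measurements of a replicate are
    pooled with equal weight per measurement.  ``scale='raw'`` differences
    population sizes (the scale on which responses are reported);
    ``scale='log'`` differences natural-log sizes (the model-fitting scale).

    Returns
    -------
    pandas.DataFrame
        One row per (treatment, replicate) with columns ``treatment``,
        ``replicate``, ``response`` and the per-week means/measurement
        counts that produced it.
    """
    if scale not in ("raw", "log"):
        raise ValueError(f"scale must be 'raw' or 'log', got {scale!r}")
    df = table.with_log_size() if scale == "log" else table.data
    value_col = "log_size" if scale == "log" else "population_size"

    rows = []
    for (trt, rep), grp in df.groupby(["treatment", "replicate"], sort=True):
        weeks = set(grp["week"].unique())
        if weeks != set(VALID_WEEKS):
            raise PairingError(
                f"replicate {rep!r} of treatment {trt!r} present only in week(s) {sorted(weeks)}"
            )
        m0 = grp.loc[grp["week"] == 0, value_col]
        m15 = grp.loc[grp["week"] == 15, value_col]
        rows.append(
            {
                "treatment": trt,
                "replicate": rep,
                "response": float(m15.mean() - m0.mean()),
                "mean_week0": float(m0.mean()),
                "mean_week15": float(m15.mean()),
                "n_week0": int(len(m0)),
                "n_week15": int(len(m15)),
            }
        )
    out = pd.DataFrame(rows)
    order = {t: i for i, t in enumerate(TREATMENT_ORDER)}
    out = out.sort_values(
        ["treatment", "replicate"],
        key=lambda s: s.map(order).fillna(len(order)) if s.name == "treatment" else s,
        kind="stable",
    )
    return out.reset_index(drop=True)
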