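"""Synthetic experiment generator with the assay's hierarchical structure.

The generator draws log-scale population sizes from a linear mixed model:

    log N(t, r, w, d, k) = mu0 + beta_trt[t]
                           + 1{w=15} * (beta_week + beta_int[t] + b_resp[t,r])
                           + b_rep[t,r] + b_day[t,r,w,d] + e[t,r,w,d,k]

with independent normal random effects b_rep ~ N(0, sigma_replicate^2)
(baseline replicate intercept), b_resp ~ N(0, sigma_response^2) (the
replicate-specific deviation of the selection response — the "chance"
component), b_day ~ N(0, sigma_day^2) (assessment-day block effect) and
residual e ~ N(0, sigma_error^2).  Population sizes are exp(log N), i.e.
lognormal on the raw scale, matching an analysis that models the log of
extrapolated counts.

Random draws use sub-streams seeded deterministically from the design
coordinates, so a table is reproducible bit-for-bit from its seed and is
invariant to generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import ExperimentTable, TREATMENT_ORDER

__all__ = ["DesignSpec", "generate_experiment", "paper_like_spec", "paper_like_experiment_spec"]

#: Assessment-day counts per replicate for the week-15 assay, by scenario.
#: Week-0 populations were assayed on a single day per replicate.
DAY_PATTERNS = {
    "no": (3, 3, 3, 2, 2),
    "moderate": (2, 2, 2, 1, 1),
    "strong": (2, 2, 2, 1, 1),
}

#: Invented calibration: per-scenario SD of the replicate-specific selection
#: response ("chance"), increasing with bottleneck strength.  These defaults
#: are design choices of this package, not estimates from any dataset.
DEFAULT_SIGMA_RESPONSE = {"no": 0.2, "moderate": 0.35, "strong": 0.6}

#: Invented calibration: fixed effects on the log scale.  Chosen to give
#: week-0 populations around e^7.4 ~ 1600 individuals and roughly an
#: order-of-magnitude fitness increase by week 15.
DEFAULT_FIXED_EFFECTS = {
    "mu0": 7.4,
    "beta_week": 2.2,
    "beta_treatment": {"no": 0.0, "moderate": -1.3, "strong": 0.8},
    "beta_interaction": {"no": 0.0, "moderate": 0.9, "strong": -0.9},
}


@dataclass
class DesignSpec:
    """Parameters of a synthetic fitness-assay experiment.

    ``days_per_replicate`` maps (treatment, replicate_index, week) to the
    number of assessment days; missing cells default to 1 day.
    ``sigma_response`` may be a single float or a per-treatment mapping.
    All standard deviations are on the natural-log scale.
    """

    treatments: tuple[str, ...] = TREATMENT_ORDER
    replicates_per_treatment: int = 5
    days_per_replicate: dict = field(default_factory=dict)
    tech_per_day: int = 3
    mu0: float = DEFAULT_FIXED_EFFECTS["mu0"]
    beta_week: float = DEFAULT_FIXED_EFFECTS["beta_week"]
    beta_treatment: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FIXED_EFFECTS["beta_treatment"])
    )
    beta_interaction: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FIXED_EFFECTS["beta_interaction"])
    )
    sigma_replicate: float = 0.5
    sigma_response: float | Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SIGMA_RESPONSE)
    )
    sigma_day: float = 0.4
    sigma_error: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.treatments = tuple(self.treatments)
        if self.replicates_per_treatment < 1:
            raise ValueError("replicates_per_treatment must be >= 1")
        if self.tech_per_day < 1:
            raise ValueError("tech_per_day must be >= 1")
        for name in ("sigma_replicate", "sigma_day", "sigma_error"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for t in self.treatments:
            if self.sigma_response_for(t) < 0:
                raise ValueError("sigma_response must be >= 0")
        for v in self.days_per_replicate.values():
            if v < 1:
                raise ValueError("every days_per_replicate entry must be >= 1")

    def sigma_response_for(self, treatment: str) -> float:
        if isinstance(self.sigma_response, Mapping):
            return float(self.sigma_response.get(treatment, 0.0))
        return float(self.sigma_response)

    def days_for(self, treatment: str, replicate: int, week: int) -> int:
        return int(self.days_per_replicate.get((treatment, replicate, week), 1))

    def day_count_products(self) -> dict[str, int]:
        """Number of balanced day-choice combinations per treatment."""
        out = {}
        for t in self.treatments:
            prod = 1
            for r in range(1, self.replicates_per_treatment + 1):
                for w in (0, 15):
                    prod *= self.days_for(t, r, w)
            out[t] = prod
        return out


def _cell_rng(seed: int, *coords: int) -> np.random.Generator:
    # Deterministic sub-stream per design coordinate tuple; independent of
    # the order in which cells are generated.
    return np.random.default_rng(np.random.SeedSequence((seed, *coords)))


def generate_experiment(spec: DesignSpec) -> ExperimentTable:
    """Draw one synthetic :class:`~evorepeat.data_model.ExperimentTable`.

    The same spec (including its seed) always yields a bit-identical table.
    """
    rows = []
    for ti, trt in enumerate(spec.treatments):
        b_t = float(spec.beta_treatment.get(trt, 0.0))
        g_t = float(spec.beta_interaction.get(trt, 0.0))
        s_resp = spec.sigma_response_for(trt)
        for r in range(1, spec.replicates_per_treatment + 1):
            rep_rng = _cell_rng(spec.seed, 1, ti, r)
            b_rep = spec.sigma_replicate * rep_rng.standard_normal()
            b_resp = s_resp * rep_rng.standard_normal()
            for w in (0, 15):
                for d in range(1, spec.days_for(trt, r, w) + 1):
                    day_rng = _cell_rng(spec.seed, 2, ti, r, w, d)
                    b_day = spec.sigma_day * day_rng.standard_normal()
                    resid = spec.sigma_error * day_rng.standard_normal(spec.tech_per_day)
                    base = spec.mu0 + b_t + b_rep + b_day
                    if w == 15:
                        base += spec.beta_week + g_t + b_resp
                    for k in range(1, spec.tech_per_day + 1):
                        log_size = base + resid[k - 1]
                        rows.append(
                            {
                                "treatment": trt,
                                "replicate": str(r),
                                "week": w,
                                "assessment_day": f"d{d}",
                                "tech_index": k,
                                "population_size": float(np.exp(log_size)),
                            }
                        )
    meta = {"generator_seed": spec.seed, "source": "synthetic"}
    return ExperimentTable(pd.DataFrame(rows), meta)


def _pattern_days(scenario: str, replicates: int) -> dict:
    pattern = DAY_PATTERNS[scenario]
    days = {}
    for r in range(1, replicates + 1):
        days[(scenario, r, 15)] = pattern[(r - 1) % len(pattern)]
        days[(scenario, r, 0)] = 1
    return days


def paper_like_spec(scenario: str, seed: int = 0) -> DesignSpec:
    """Single-treatment preset mirroring the study's assay design.

    Five replicates, three technical measurements per day, one week-0
    assessment day per replicate, and week-15 day counts of (3,3,3,2,2)
    for the "no" bottleneck scenario or (2,2,2,1,1) for "moderate" and
    "strong" — giving 108 and 8 balanced day combinations respectively.
    Variance-component defaults are this package's invented calibration
    (see module docstring), with the chance SD increasing from "no" to
    "strong".
    """
    if scenario not in DAY_PATTERNS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {sorted(DAY_PATTERNS)}")
    return DesignSpec(
        treatments=(scenario,),
        replicates_per_treatment=5,
        days_per_replicate=_pattern_days(scenario, 5),
        tech_per_day=3,
        sigma_response={scenario: DEFAULT_SIGMA_RESPONSE[scenario]},
        seed=seed,
    )


def paper_like_experiment_spec(seed: int = 0) -> DesignSpec:
    """Three-treatment preset: the full no/moderate/strong design."""
    days = {}
    for scenario in TREATMENT_ORDER:
        days.update(_pattern_days(scenario, 5))
    return DesignSpec(
        treatments=TREATMENT_ORDER,
        replicates_per_treatment=5,
        days_per_replicate=days,
        tech_per_day=3,
        seed=seed,
    )


def with_seed(spec: DesignSpec, seed: int) -> DesignSpec:
    """Copy of ``spec`` with a different random seed."""
    return replace(spec, seed=seed)
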