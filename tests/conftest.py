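import numpy as np
import pandas as pd
import pytest

from evorepeat import DesignSpec, ExperimentTable, generate_experiment


def table_from_cells(cells, treatment="no"):
    """Build a validated table from {(replicate, week, day): [values...]}.

    Values are log-scale; population sizes are exp(value) so log-scale
    analyses see the given numbers exactly.
    """
    rows = []
    for (rep, week, day), values in cells.items():
        for k, v in enumerate(values, start=1):
            rows.append(
                {
                    "treatment": treatment,
                    "replicate": str(rep),
                    "week": week,
                    "assessment_day": str(day),
                    "tech_index": k,
                    "population_size": float(np.exp(v)),
                }
            )
    return ExperimentTable(pd.DataFrame(rows))


@pytest.fixture
def tiny_frame():
    """6-row design: 1 treatment, 1 replicate, 2 weeks, 1 day, 3 tech reps."""
    rows = []
    for week, base in ((0, 5000.0), (15, 20000.0)):
        for k in (1, 2, 3):
            rows.append(
                {
                    "treatment": "no",
                    "replicate": "1",
                    "week": week,
                    "assessment_day": "d1",
                    "tech_index": k,
                    "population_size": base + 10 * k,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def noiseless_spec():
    return DesignSpec(
        treatments=("no", "moderate"),
        replicates_per_treatment=2,
        mu0=7.0,
        beta_week=2.0,
        beta_treatment={"no": 0.0, "moderate": 0.0},
        beta_interaction={"no": 0.0, "moderate": 0.0},
        sigma_replicate=0.0,
        sigma_response=0.0,
        sigma_day=0.0,
        sigma_error=0.0,
        seed=0,
    )


@pytest.fixture
def small_noisy_table():
    """Three treatments, 3 replicates, modest noise; quick to fit."""
    spec = DesignSpec(
        replicates_per_treatment=3,
        sigma_replicate=0.3,
        sigma_response=0.2,
        sigma_day=0.2,
        sigma_error=0.3,
        seed=42,
    )
    return generate_experiment(spec)
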