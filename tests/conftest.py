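import numpy as np
import pandas as pd
import pytest

from cohortdem import ProjectionMatrix, StageSchema, cbb_schema


@pytest.fixture
def schema() -> StageSchema:
    return cbb_schema()


@pytest.fixture
def schema2() -> StageSchema:
    return StageSchema(stages=("juvenile", "adult"), reproductive_stage="adult",
                       projection_interval_days=6)


def make_census_frame(rows):
    """rows: (cohort_id, individual_id, day, stage, status) tuples."""
    return pd.DataFrame(
        rows, columns=["cohort_id", "individual_id", "day", "stage", "status"]
    )


def random_valid_matrix(
    rng: np.random.Generator, schema: StageSchema, max_survival: float = 0.98
) -> ProjectionMatrix:
    """A random irreducible Lefkovitch matrix with mortality in every stage.

    Stasis probabilities are bounded away from 0 so the chain is
    aperiodic, and P + G stays below ``max_survival`` so the survival
    part has spectral radius < 1.
    """
    s = schema.n_stages
    P = rng.uniform(0.05, 0.6, size=s)
    G = rng.uniform(0.05, 1.0, size=s - 1)
    G = np.minimum(G, max_survival - P[:-1])
    G = np.maximum(G, 0.02)
    P[:-1] = np.minimum(P[:-1], max_survival - G)
    P[-1] = min(P[-1], max_survival)
    F = rng.uniform(0.5, 20.0)
    return ProjectionMatrix(schema=schema, P=P, G=G, F=F).validate()
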