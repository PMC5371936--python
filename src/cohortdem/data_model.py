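"""Domain types, validation, and file I/O for cohort demography data.

The package revolves around four kinds of data:

* daily cohort census tables (one row per individual per census day),
* daily per-female oviposition tables,
* stage-structured (Lefkovitch) projection matrices with stasis
  probabilities on the diagonal, growth probabilities on the
  subdiagonal, and a single fertility entry in the top-right corner,
* derived demography and LTRE results.

All tabular data are held as pandas DataFrames wrapped in light
dataclasses that know how to validate themselves; every downstream
module calls ``validate()`` before trusting its input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "EstimationError",
    "StageSchema",
    "CBB_STAGES",
    "cbb_schema",
    "CohortCensus",
    "OvipositionTable",
    "ProjectionMatrix",
    "DemographyResult",
    "LtreResult",
    "AnalysisConfig",
    "read_census",
    "write_census",
    "read_oviposition",
    "write_oviposition",
    "read_matrix",
    "write_matrix",
]


class SchemaError(ValueError):
    """A label does not resolve against the stage schema."""


class ValidationError(ValueError):
    """Data violate a structural invariant (monotonicity, mask, ...)."""


class EstimationError(ValueError):
    """An estimator cannot be computed from the available counts."""


# ---------------------------------------------------------------------------
# Stage schema
# ---------------------------------------------------------------------------

#: Life-cycle stages of the coffee berry borer, in developmental order.
CBB_STAGES: tuple[str, ...] = (
    "egg",
    "larva",
    "pre-pupa",
    "pupa",
    "juvenile",
    "adult",
)

CENSUS_COLUMNS = ["cohort_id", "individual_id", "day", "stage", "status"]
OVIPOSITION_COLUMNS = ["female_id", "treatment", "day", "eggs"]


@dataclass(frozen=True)
class StageSchema:
    """Ordered life-cycle stages plus the projection time step.

    Parameters
    ----------
    stages
        Stage names in developmental order.  Individuals may only move
        forward along this sequence (no reverse molts).
    reproductive_stage
        The single stage with nonzero fertility; must be the last stage.
    projection_interval_days
        Days per projection-matrix time step.
    """

    stages: tuple[str, ...]
    reproductive_stage: str
    projection_interval_days: int = 6

    def __post_init__(self) -> None:
        object.__setattr__(self, "stages", tuple(self.stages))
        if len(set(self.stages)) != len(self.stages):
            raise SchemaError("stage names must be unique")
        if len(self.stages) < 1:
            raise SchemaError("schema needs at least one stage")
        if self.reproductive_stage != self.stages[-1]:
            raise SchemaError(
                f"reproductive stage {self.reproductive_stage!r} must be the "
                f"last stage ({self.stages[-1]!r})"
            )
        if int(self.projection_interval_days) < 1:
            raise SchemaError("projection_interval_days must be >= 1")

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    def index(self, stage: str) -> int:
        """Return the 0-based developmental index of ``stage``."""
        try:
            return self.stages.index(stage)
        except ValueError:
            raise SchemaError(f"unknown stage label {stage!r}") from None

    def stage_codes(self, labels: Sequence[str]) -> np.ndarray:
        """Map an array of stage labels to indices, rejecting unknowns."""
        cat = pd.Categorical(labels, categories=list(self.stages))
        codes = np.asarray(cat.codes)
        if (codes < 0).any():
            bad = pd.Index(labels)[codes < 0][0]
            raise SchemaError(f"unknown stage label {bad!r}")
        return codes


def cbb_schema(projection_interval_days: int = 6) -> StageSchema:
    """The six-stage coffee berry borer schema with a 6-day time step."""
    return StageSchema(
        stages=CBB_STAGES,
        reproductive_stage="adult",
        projection_interval_days=projection_interval_days,
    )


# ---------------------------------------------------------------------------
# Census and oviposition tables
# ---------------------------------------------------------------------------


def _group_starts(keys: np.ndarray) -> np.ndarray:
    """Boolean mask marking the first row of each run of equal keys."""
    starts = np.ones(len(keys), dtype=bool)
    starts[1:] = keys[1:] != keys[:-1]
    return starts


@dataclass
class CohortCensus:
    """Longitudinal per-individual stage observations.

    ``records`` has columns cohort_id, individual_id, day (non-negative
    int), stage (a schema label), status ("alive" or "dead").  Days are
    0-based from cohort start; a stage on day *d* means "observed in
    that stage at the day-*d* census".  Individuals missing from a
    census day without a death record are right-censored.
    """

    records: pd.DataFrame
    schema: StageSchema

    def validate(self) -> "CohortCensus":
        df = self.records
        missing = [c for c in CENSUS_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"census table missing columns {missing}")
        if len(df) == 0:
            raise ValidationError("census table is empty")
        if (df["day"].to_numpy() < 0).any():
            raise ValidationError("census days must be non-negative")
        bad_status = set(df["status"].unique()) - {"alive", "dead"}
        if bad_status:
            raise ValidationError(f"invalid status values {sorted(bad_status)}")

        codes = self.schema.stage_codes(df["stage"].to_numpy())

        order = np.lexsort(
            (df["day"].to_numpy(), df["individual_id"].to_numpy(),
             df["cohort_id"].to_numpy())
        )
        key = (
            df["cohort_id"].astype(str) + "\x00" + df["individual_id"].astype(str)
        ).to_numpy()[order]
        day = df["day"].to_numpy()[order]
        code = codes[order]
        dead = (df["status"].to_numpy() == "dead")[order]
        same = ~_group_starts(key)

        if (np.diff(day)[same[1:]] <= 0).any():
            i = np.nonzero(same[1:] & (np.diff(day) <= 0))[0][0]
            raise ValidationError(
                f"days do not strictly increase for individual "
                f"{key[i + 1].replace(chr(0), '/')}"
            )
        # absorbing death: within an individual, dead may never revert
        was_dead = same & np.roll(dead, 1)
        if (was_dead & ~dead).any():
            i = np.nonzero(was_dead & ~dead)[0][0]
            raise ValidationError(
                f"individual {key[i].replace(chr(0), '/')} recorded alive "
                f"after a dead record"
            )
        # no reverse molts among alive records: restrict to alive rows
        # (order preserved) and check stage codes are non-decreasing
        # within each individual
        alive = ~dead
        akey, acode = key[alive], code[alive]
        if len(akey) > 1:
            asame = ~_group_starts(akey)
            drops = asame[1:] & (np.diff(acode) < 0)
            if drops.any():
                i = np.nonzero(drops)[0][0]
                raise ValidationError(
                    f"reverse molt for individual "
                    f"{akey[i + 1].replace(chr(0), '/')}"
                )
        return self

    def individuals(self) -> pd.DataFrame:
        """One row per (cohort_id, individual_id)."""
        return self.records[["cohort_id", "individual_id"]].drop_duplicates()


@dataclass
class OvipositionTable:
    """Per-female daily egg counts.

    ``records`` has columns female_id, treatment, day, eggs.  A female's
    observation window is the span of her recorded days; days without a
    record inside the window count as zero eggs.  Records before first
    oviposition may simply be absent, so non-ovipositing females should
    carry at least one zero-egg record to define their window.
    """

    records: pd.DataFrame

    def validate(self) -> "OvipositionTable":
        df = self.records
        missing = [c for c in OVIPOSITION_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"oviposition table missing columns {missing}")
        if (df["eggs"].to_numpy() < 0).any():
            raise ValidationError("egg counts must be non-negative")
        if (df["day"].to_numpy() < 0).any():
            raise ValidationError("days must be non-negative")
        if df.duplicated(subset=["female_id", "day"]).any():
            dup = df[df.duplicated(subset=["female_id", "day"])].iloc[0]
            raise ValidationError(
                f"duplicate record for female {dup['female_id']!r} "
                f"day {dup['day']}"
            )
        return self


# ---------------------------------------------------------------------------
# Projection matrix
# ---------------------------------------------------------------------------


def structure_mask(n_stages: int) -> np.ndarray:
    """Boolean mask of entries allowed to be nonzero in the Lefkovitch form."""
    mask = np.zeros((n_stages, n_stages), dtype=bool)
    idx = np.arange(n_stages)
    mask[idx, idx] = True              # stasis Pi
    mask[idx[1:], idx[:-1]] = True     # growth Gi
    mask[0, n_stages - 1] = True       # fertility F
    return mask


@dataclass
class ProjectionMatrix:
    """A Lefkovitch stage-structured projection matrix.

    The assembled s×s matrix has the per-interval stasis probabilities
    ``P`` on the diagonal, the growth (molt) probabilities ``G`` on the
    subdiagonal, and the fertility ``F`` (offspring per reproductive
    female per interval) in the top-right entry; everything else is 0.
    """

    schema: StageSchema
    P: np.ndarray
    G: np.ndarray
    F: float

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        self.F = float(self.F)

    @property
    def matrix(self) -> np.ndarray:
        s = self.schema.n_stages
        A = np.zeros((s, s))
        idx = np.arange(s)
        A[idx, idx] = self.P
        if s > 1:
            A[idx[1:], idx[:-1]] = self.G
        A[0, s - 1] += self.F
        return A

    def validate(self) -> "ProjectionMatrix":
        s = self.schema.n_stages
        if self.P.shape != (s,):
            raise ValidationError(f"P must have length {s}")
        if self.G.shape != (max(s - 1, 0),):
            raise ValidationError(f"G must have length {s - 1}")
        if ((self.P < 0) | (self.P > 1)).any():
            raise ValidationError("stasis probabilities must lie in [0, 1]")
        if ((self.G < 0) | (self.G > 1)).any():
            raise ValidationError("growth probabilities must lie in [0, 1]")
        surv = self.P[:-1] + self.G if s > 1 else self.P
        if (surv > 1 + 1e-12).any():
            i = int(np.argmax(surv > 1 + 1e-12))
            raise ValidationError(
                f"P + G > 1 for stage {self.schema.stages[i]!r}"
            )
        if self.F < 0:
            raise ValidationError("fertility must be non-negative")
        return self


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass
class DemographyResult:
    """λ, R₀, T and eigen-structure of a projection matrix.

    ``lam`` is per projection interval; ``T_intervals`` is the mean
    generation time in intervals and ``T_days`` the same in days.
    ``w`` sums to one, ``v`` is scaled so v·w = 1, and the elasticity
    matrix ``E`` sums to one.
    """

    lam: float
    R0: float
    T_intervals: float
    T_days: float
    w: np.ndarray
    v: np.ndarray
    S: np.ndarray
    E: np.ndarray

    def to_dict(self) -> dict:
        return {
            "lambda": self.lam,
            "R0": self.R0,
            "T_intervals": self.T_intervals,
            "T_days": self.T_days,
            "stable_stage_distribution": self.w.tolist(),
            "reproductive_value": self.v.tolist(),
            "sensitivity": self.S.tolist(),
            "elasticity": self.E.tolist(),
        }


@dataclass
class LtreResult:
    """Fixed-design LTRE decomposition of a λ difference.

    ``C`` holds per-entry contributions (units of λ).  ``class_summaries``
    groups contributions into the Gi (growth), Pi (stasis) and Fi
    (fertility) parameter classes by matrix position.
    """

    schema: StageSchema
    C: np.ndarray
    delta_lambda_observed: float
    delta_lambda_approx: float
    class_summaries: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "contributions": self.C.tolist(),
            "delta_lambda_observed": self.delta_lambda_observed,
            "delta_lambda_approx": self.delta_lambda_approx,
            "class_summaries": dict(self.class_summaries),
        }


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """Stage schema plus estimation knobs shared across the pipeline."""

    stages: tuple[str, ...] = CBB_STAGES
    interval_days: int = 6
    #: per-interval survival assigned to adults in place of the census
    #: estimate; adult mortality is too rare in a 50-day census to
    #: estimate, so a high literature-style value is pinned instead.
    adult_survival_override: float | None = 0.99
    #: multiplies fertility; set to the female fraction of offspring to
    #: count daughters only (1.0 counts all eggs).
    sex_ratio_scale: float = 1.0

    @property
    def schema(self) -> StageSchema:
        return StageSchema(
            stages=self.stages,
            reproductive_stage=self.stages[-1],
            projection_interval_days=self.interval_days,
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        raw = json.loads(Path(path).read_text())
        return cls(
            stages=tuple(raw.get("stages", CBB_STAGES)),
            interval_days=int(raw.get("interval_days", 6)),
            adult_survival_override=raw.get("adult_survival_override", 0.99),
            sex_ratio_scale=float(raw.get("sex_ratio_scale", 1.0)),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "stages": list(self.stages),
                    "interval_days": self.interval_days,
                    "adult_survival_override": self.adult_survival_override,
                    "sex_ratio_scale": self.sex_ratio_scale,
                },
                indent=2,
            )
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_census(path: str | Path, schema: StageSchema) -> CohortCensus:
    """Read and validate a census CSV (cohort_id,individual_id,day,stage,status)."""
    df = pd.read_csv(path, dtype={"cohort_id": str, "individual_id": str})
    missing = [c for c in CENSUS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    df["day"] = df["day"].astype(int)
    return CohortCensus(records=df[CENSUS_COLUMNS], schema=schema).validate()


def write_census(census: CohortCensus, path: str | Path) -> None:
    census.records[CENSUS_COLUMNS].to_csv(path, index=False)


def read_oviposition(path: str | Path) -> OvipositionTable:
    """Read and validate an oviposition CSV (female_id,treatment,day,eggs)."""
    df = pd.read_csv(path, dtype={"female_id": str, "treatment": str})
    missing = [c for c in OVIPOSITION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    df["day"] = df["day"].astype(int)
    df["eggs"] = df["eggs"].astype(int)
    return OvipositionTable(records=df[OVIPOSITION_COLUMNS]).validate()


def write_oviposition(table: OvipositionTable, path: str | Path) -> None:
    table.records[OVIPOSITION_COLUMNS].to_csv(path, index=False)


def write_matrix(m: ProjectionMatrix, path: str | Path) -> None:
    """Serialize a projection matrix to JSON at full float precision."""
    m.validate()
    payload = {
        "schema": {
            "stages": list(m.schema.stages),
            "reproductive_stage": m.schema.reproductive_stage,
            "interval_days": m.schema.projection_interval_days,
        },
        "P": m.P.tolist(),
        "G": m.G.tolist(),
        "F": m.F,
        "matrix": m.matrix.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_matrix(path: str | Path) -> ProjectionMatrix:
    """Read a matrix JSON, checking the Lefkovitch structure mask."""
    raw = json.loads(Path(path).read_text())
    schema = StageSchema(
        stages=tuple(raw["schema"]["stages"]),
        reproductive_stage=raw["schema"].get(
            "reproductive_stage", raw["schema"]["stages"][-1]
        ),
        projection_interval_days=int(raw["schema"]["interval_days"]),
    )
    m = ProjectionMatrix(
        schema=schema,
        P=np.asarray(raw["P"], dtype=float),
        G=np.asarray(raw["G"], dtype=float),
        F=float(raw["F"]),
    ).validate()
    if "matrix" in raw:
        A = np.asarray(raw["matrix"], dtype=float)
        s = schema.n_stages
        if A.shape != (s, s):
            raise ValidationError(f"{path}: matrix block has wrong shape")
        mask = structure_mask(s)
        if (A[~mask] != 0).any():
            i, j = map(int, np.argwhere((A != 0) & ~mask)[0])
            raise ValidationError(
                f"{path}: nonzero entry at ({i}, {j}) outside the "
                f"diagonal/subdiagonal/fertility structure"
            )
        if not np.array_equal(A, m.matrix):
            raise ValidationError(
                f"{path}: matrix block inconsistent with P/G/F blocks"
            )
    return m
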