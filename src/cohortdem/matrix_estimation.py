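"""Estimate a Lefkovitch projection matrix from daily cohort data.

Transition probabilities are obtained by direct interval-aligned
counting: the census is read at days 0, k, 2k, ... (k = projection
interval) and each individual alive in stage *i* at a window start is
classified one interval later as staying (still in *i*), advancing
(any later stage — multi-stage advances within a window are credited to
the starting stage's growth probability, since the Lefkovitch form has
no skip entries), or dead.  Individuals with no record at the window
end are right-censored and drop out of that window's denominator.
Counts are pooled over all windows and cohorts before dividing
(binomial pooling), which maximises the effective sample size of small
cohorts.

Fertility is a single per-interval rate for the reproductive stage:
total eggs over all observed females divided by total observed
female-days, times the interval length, optionally scaled by the
female fraction of offspring.  Non-ovipositing females count in the
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import (
    AnalysisConfig,
    CohortCensus,
    EstimationError,
    OvipositionTable,
    ProjectionMatrix,
    StageSchema,
    ValidationError,
)

__all__ = [
    "TransitionCounts",
    "tabulate_transitions",
    "estimate_stage_probs",
    "estimate_fertility",
    "build_projection_matrix",
    "estimate_matrix",
]


@dataclass
class TransitionCounts:
    """Pooled interval-transition counts per stage.

    For stage *i*: ``n_start`` individuals alive in *i* at a window
    start, of which ``n_stay`` were alive in *i* one interval later,
    ``n_advance`` alive in a later stage, ``n_die`` dead; the remainder
    were censored.  ``reached`` flags stages any individual was ever
    observed in (at any census day, not only window starts).
    """

    schema: StageSchema
    n_start: np.ndarray
    n_stay: np.ndarray
    n_advance: np.ndarray
    n_die: np.ndarray
    reached: np.ndarray

    def validate(self) -> "TransitionCounts":
        for name in ("n_start", "n_stay", "n_advance", "n_die"):
            arr = getattr(self, name)
            if (arr < 0).any():
                raise ValidationError(f"{name} has negative counts")
        settled = self.n_stay + self.n_advance + self.n_die
        if (settled > self.n_start).any():
            raise ValidationError("settled counts exceed n_start")
        return self

    @property
    def n_effective(self) -> np.ndarray:
        """Denominator per stage: individuals with a known interval fate."""
        return self.n_stay + self.n_advance + self.n_die


def tabulate_transitions(
    census: CohortCensus, schema: StageSchema
) -> TransitionCounts:
    """Count interval-aligned stage transitions pooled over windows.

    Raises on an empty census or a census horizon shorter than one
    projection interval.
    """
    census.validate()
    df = census.records
    k = schema.projection_interval_days
    horizon = int(df["day"].max())
    if horizon < k:
        raise EstimationError(
            f"census horizon ({horizon} d) shorter than one projection "
            f"interval ({k} d)"
        )

    s = schema.n_stages
    reached = np.zeros(s, dtype=bool)
    all_codes = schema.stage_codes(df["stage"].to_numpy())
    reached[np.unique(all_codes[df["status"].to_numpy() == "alive"])] = True

    sub = df[df["day"] % k == 0].copy()
    sub["code"] = schema.stage_codes(sub["stage"].to_numpy())
    # encode fate in one integer: stage code if alive, s if dead
    sub["state"] = np.where(sub["status"].to_numpy() == "alive", sub["code"], s)
    key = sub["cohort_id"].astype(str) + "\x00" + sub["individual_id"].astype(str)
    piv = (
        sub.assign(key=key)
        .pivot(index="key", columns="day", values="state")
        .to_numpy(dtype=float)
    )  # NaN where no record
    days = np.sort(sub["day"].unique())
    col = {int(d): j for j, d in enumerate(days)}

    n_start = np.zeros(s, dtype=int)
    n_stay = np.zeros(s, dtype=int)
    n_advance = np.zeros(s, dtype=int)
    n_die = np.zeros(s, dtype=int)

    for d0 in range(0, horizon - k + 1, k):
        d1 = d0 + k
        if d0 not in col:
            continue
        start = piv[:, col[d0]]
        end = piv[:, col[d1]] if d1 in col else np.full(len(piv), np.nan)
        alive0 = ~np.isnan(start) & (start < s)
        for i in range(s):
            here = alive0 & (start == i)
            n_start[i] += int(here.sum())
            fate = end[here]
            known = ~np.isnan(fate)
            n_stay[i] += int((fate[known] == i).sum())
            n_advance[i] += int(((fate[known] > i) & (fate[known] < s)).sum())
            n_die[i] += int((fate[known] == s).sum())

    return TransitionCounts(
        schema=schema,
        n_start=n_start,
        n_stay=n_stay,
        n_advance=n_advance,
        n_die=n_die,
        reached=reached,
    ).validate()


def estimate_stage_probs(t: TransitionCounts) -> tuple[np.ndarray, np.ndarray]:
    """Per-interval stasis (P) and growth (G) probabilities from counts.

    Pi = n_stay / n_eff and Gi = n_advance / n_eff with
    n_eff = n_stay + n_advance + n_die (censored individuals excluded).
    A stage that was reached but has no individuals with a known
    interval fate is unestimable and raises ``EstimationError``; stages
    never reached get P = G = 0.
    """
    t.validate()
    s = t.schema.n_stages
    n_eff = t.n_effective
    bad = t.reached & (n_eff == 0)
    if bad.any():
        names = [t.schema.stages[i] for i in np.nonzero(bad)[0]]
        raise EstimationError(
            f"no interval-aligned observations for reached stage(s) "
            f"{names}; cannot estimate their transition probabilities"
        )
    P = np.zeros(s)
    G = np.zeros(max(s - 1, 0))
    ok = n_eff > 0
    P[ok] = t.n_stay[ok] / n_eff[ok]
    ok_g = ok[:-1] if s > 1 else ok[:0]
    G[ok_g] = t.n_advance[:-1][ok_g] / n_eff[:-1][ok_g]
    return P, G


def estimate_fertility(
    ovi: OvipositionTable,
    schema: StageSchema,
    sex_ratio_scale: float = 1.0,
) -> float:
    """Per-interval fertility of the reproductive stage.

    F = sex_ratio_scale × interval_days × (total eggs / total observed
    female-days).  A female's observed days span her first to last
    record; days without a record inside that span count as zero eggs.
    """
    ovi.validate()
    df = ovi.records
    if len(df) == 0:
        raise EstimationError("oviposition table has no records")
    span = df.groupby("female_id")["day"].agg(["min", "max"])
    female_days = int((span["max"] - span["min"] + 1).sum())
    if female_days == 0:
        raise EstimationError("zero observed female-days")
    total_eggs = int(df["eggs"].sum())
    rate = total_eggs / female_days
    return float(sex_ratio_scale) * schema.projection_interval_days * rate


def build_projection_matrix(
    P: np.ndarray,
    G: np.ndarray,
    F: float,
    schema: StageSchema,
    adult_survival_override: float | None = None,
) -> ProjectionMatrix:
    """Assemble the Lefkovitch matrix, optionally pinning adult survival.

    ``adult_survival_override`` replaces the last diagonal entry: the
    census horizon is too short to see adult deaths, so the adult
    stasis probability is pinned rather than estimated.
    """
    P = np.asarray(P, dtype=float).copy()
    G = np.asarray(G, dtype=float)
    if adult_survival_override is not None:
        P[-1] = float(adult_survival_override)
    return ProjectionMatrix(schema=schema, P=P, G=G, F=F).validate()


def estimate_matrix(
    census: CohortCensus,
    ovi: OvipositionTable,
    config: AnalysisConfig,
) -> ProjectionMatrix:
    """Full estimation path: census + oviposition data → projection matrix."""
    schema = config.schema
    counts = tabulate_transitions(census, schema)
    P, G = estimate_stage_probs(counts)
    F = estimate_fertility(ovi, schema, config.sex_ratio_scale)
    return build_projection_matrix(
        P, G, F, schema, adult_survival_override=config.adult_survival_override
    )
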