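"""Treatment-comparison statistics for cohort experiments.

Self-contained classical tests used alongside the demographic
pipeline: Pearson chi-square on contingency tables (e.g. ovipositing
vs. non-ovipositing females per diet), replicate sex-ratio summaries,
per-stage developmental-time summaries from the census, one-way ANOVA,
pairwise Welch t-tests with Holm correction as the post-hoc procedure,
and descriptive Poisson rate summaries with exact intervals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CohortCensus, StageSchema, ValidationError

__all__ = [
    "ContingencyTable",
    "chi_square_independence",
    "sex_ratio_summary",
    "developmental_time_summary",
    "one_way_anova",
    "pairwise_welch_holm",
    "poisson_rate_summary",
]

log = logging.getLogger(__name__)


@dataclass
class ContingencyTable:
    """Non-negative integer counts with row and column labels."""

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.row_labels = tuple(self.row_labels)
        self.col_labels = tuple(self.col_labels)

    def validate(self) -> "ContingencyTable":
        if self.counts.ndim != 2:
            raise ValidationError("contingency table must be 2-dimensional")
        r, c = self.counts.shape
        if r < 2 or c < 2:
            raise ValidationError("need at least 2 rows and 2 columns")
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValidationError("grand total must be positive")
        if len(self.row_labels) != r or len(self.col_labels) != c:
            raise ValidationError("label lengths must match table shape")
        return self


def chi_square_independence(t: ContingencyTable) -> tuple[float, int]:
    """Pearson chi-square statistic and df, without continuity correction.

    statistic = Σ (O − E)² / E with E_ij = row_i · col_j / total and
    df = (r − 1)(c − 1).  Zero row or column margins are rejected.
    """
    t.validate()
    counts = t.counts
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise ValidationError("a row or column margin is zero")
    stat, _, df, _ = stats.chi2_contingency(counts, correction=False)
    return float(stat), int(df)


def sex_ratio_summary(
    counts: list[tuple[int, int]],
) -> dict[str, float]:
    """Mean and SE of per-replicate female:male ratios.

    Each replicate contributes its own F/M ratio; the summary is the
    mean of ratios, not the ratio of means (Jensen's inequality makes
    the former larger for variable male counts).  Replicates with zero
    males are excluded with a warning.
    """
    ratios = []
    for females, males in counts:
        if males < 1:
            log.warning(
                "replicate with %d females and 0 males excluded from "
                "sex-ratio summary", females,
            )
            continue
        ratios.append(females / males)
    if not ratios:
        raise ValidationError("no replicates with at least one male")
    x = np.asarray(ratios, dtype=float)
    n = len(x)
    se = float(np.std(x, ddof=1) / np.sqrt(n)) if n >= 2 else math.nan
    return {"mean": float(np.mean(x)), "se": se, "n": n}


def developmental_time_summary(
    census: CohortCensus, schema: StageSchema
) -> pd.DataFrame:
    """Per-stage duration and egg-to-adult time, as mean ± SE in days.

    An individual's duration in a stage is the number of census days it
    was observed alive in that stage; only individuals that completed
    the stage (were later observed alive in a subsequent stage) are
    counted.  Egg-to-adult time is first-adult day minus first-egg day
    for individuals reaching adulthood.  Stages nobody completed are
    reported with NaN.
    """
    census.validate()
    df = census.records
    alive = df[df["status"] == "alive"].copy()
    alive["code"] = schema.stage_codes(alive["stage"].to_numpy())
    alive["key"] = (
        alive["cohort_id"].astype(str) + "\x00" + alive["individual_id"].astype(str)
    )
    last_code = alive.groupby("key")["code"].max()

    rows = []
    grouped = alive.groupby(["key", "code"])["day"].agg(["count", "min"])
    for i, stage in enumerate(schema.stages[:-1]):
        per = grouped.xs(i, level="code") if i in grouped.index.get_level_values(
            "code"
        ) else pd.DataFrame(columns=["count", "min"])
        completed = per[per.index.map(last_code) > i]["count"]
        n = len(completed)
        mean = float(completed.mean()) if n else math.nan
        se = (
            float(completed.std(ddof=1) / np.sqrt(n)) if n >= 2 else math.nan
        )
        rows.append({"stage": stage, "mean_days": mean, "se_days": se, "n": n})

    adult_i = schema.n_stages - 1
    first_day = grouped["min"]
    if adult_i in grouped.index.get_level_values("code"):
        adults = first_day.xs(adult_i, level="code")
        first_egg = first_day.xs(0, level="code")
        e2a = (adults - first_egg.reindex(adults.index)).dropna()
        n = len(e2a)
        mean = float(e2a.mean()) if n else math.nan
        se = float(e2a.std(ddof=1) / np.sqrt(n)) if n >= 2 else math.nan
    else:
        n, mean, se = 0, math.nan, math.nan
    rows.append({"stage": "egg_to_adult", "mean_days": mean, "se_days": se, "n": n})
    return pd.DataFrame(rows)


def one_way_anova(
    groups: list[np.ndarray],
) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA: (F, df_between, df_within, p).

    Requires at least two groups of at least two values each.  When all
    within-group variances are zero but means differ, p = 0 is reported
    with a warning (the F ratio is unbounded).
    """
    if len(groups) < 2:
        raise ValidationError("ANOVA requires at least 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in groups):
        raise ValidationError("each group needs at least 2 values")
    df_between = len(groups) - 1
    df_within = sum(len(g) for g in groups) - len(groups)
    ssw = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    means = [g.mean() for g in groups]
    if ssw == 0.0 and len(set(np.round(means, 15))) > 1:
        log.warning("zero within-group variance with unequal means; p = 0")
        return math.inf, df_between, df_within, 0.0
    F, p = stats.f_oneway(*groups)
    return float(F), df_between, df_within, float(p)


def pairwise_welch_holm(
    groups: dict[str, np.ndarray],
) -> list[dict]:
    """Pairwise Welch t-tests with Holm step-down correction.

    Post-hoc procedure following a one-way ANOVA; returns one row per
    pair with the raw and Holm-adjusted p-values.
    """
    names = sorted(groups)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    rows = []
    for a, b in pairs:
        t, p = stats.ttest_ind(
            np.asarray(groups[a], dtype=float),
            np.asarray(groups[b], dtype=float),
            equal_var=False,
        )
        rows.append({"pair": f"{a} vs {b}", "t": float(t), "p_raw": float(p)})
    # Holm step-down
    order = np.argsort([r["p_raw"] for r in rows])
    m = len(rows)
    running = 0.0
    for rank, idx in enumerate(order):
        adj = min(1.0, (m - rank) * rows[idx]["p_raw"])
        running = max(running, adj)
        rows[idx]["p_holm"] = running
    return rows


def poisson_rate_summary(
    total_events: int, exposure: float, conf: float = 0.95
) -> dict[str, float]:
    """Descriptive Poisson rate with an exact (Garwood) interval."""
    if exposure <= 0:
        raise ValidationError("exposure must be positive")
    alpha = 1 - conf
    lo = (
        stats.chi2.ppf(alpha / 2, 2 * total_events) / 2 if total_events > 0 else 0.0
    )
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * (total_events + 1)) / 2
    return {
        "rate": total_events / exposure,
        "lower": lo / exposure,
        "upper": hi / exposure,
        "events": total_events,
        "exposure": exposure,
    }
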