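"""Contingency chi-square, sex ratios, developmental times, ANOVA."""

import math

import numpy as np
import pytest

from cohortdem import (
    CohortCensus,
    ContingencyTable,
    ValidationError,
    chi_square_independence,
    developmental_time_summary,
    one_way_anova,
    pairwise_welch_holm,
    poisson_rate_summary,
    sex_ratio_summary,
)

from conftest import make_census_frame


def oviposition_table():
    """Ovipositing / not per diet, reconstructed from 68%, 66%, 38% of n=50."""
    return ContingencyTable(
        counts=np.array([[34, 16], [33, 17], [19, 31]]),
        row_labels=("control", "penicillin", "tetracycline"),
        col_labels=("oviposited", "did_not"),
    )


class TestChiSquare:
    def test_oviposition_counts_give_published_statistic(self):
        stat, df = chi_square_independence(oviposition_table())
        assert round(stat, 2) == 11.50
        assert df == 2

    def test_proportional_table_gives_zero(self):
        t = ContingencyTable(
            counts=np.array([[10, 20], [30, 60]]),
            row_labels=("a", "b"), col_labels=("x", "y"),
        )
        stat, df = chi_square_independence(t)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 1

    def test_two_by_two_hand_formula(self):
        t = ContingencyTable(
            counts=np.array([[10, 20], [20, 10]]),
            row_labels=("a", "b"), col_labels=("x", "y"),
        )
        stat, df = chi_square_independence(t)
        assert stat == pytest.approx(20 / 3)
        assert df == 1

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        base = oviposition_table()
        stat0, _ = chi_square_independence(base)
        perm_r = rng.permutation(3)
        perm_c = rng.permutation(2)
        t = ContingencyTable(
            counts=base.counts[np.ix_(perm_r, perm_c)],
            row_labels=tuple(np.array(base.row_labels)[perm_r]),
            col_labels=tuple(np.array(base.col_labels)[perm_c]),
        )
        stat1, _ = chi_square_independence(t)
        assert stat1 == pytest.approx(stat0)

    def test_count_scaling_scales_statistic(self):
        base = oviposition_table()
        stat0, _ = chi_square_independence(base)
        scaled = ContingencyTable(
            counts=base.counts * 3,
            row_labels=base.row_labels, col_labels=base.col_labels,
        )
        stat1, _ = chi_square_independence(scaled)
        assert stat1 == pytest.approx(3 * stat0)

    def test_zero_margin_rejected(self):
        t = ContingencyTable(
            counts=np.array([[0, 0], [5, 5]]),
            row_labels=("a", "b"), col_labels=("x", "y"),
        )
        with pytest.raises(ValidationError):
            chi_square_independence(t)


class TestSexRatioSummary:
    def test_mean_of_ratios(self):
        out = sex_ratio_summary([(20, 2), (24, 3)])
        assert out["mean"] == pytest.approx(9.0)

    def test_identical_replicates_zero_se(self):
        out = sex_ratio_summary([(20, 2)] * 3)
        assert out["se"] == 0.0

    def test_zero_male_replicate_excluded(self):
        out = sex_ratio_summary([(20, 2), (15, 0)])
        assert out["n"] == 1
        assert out["mean"] == pytest.approx(10.0)

    def test_jensen_direction_on_noisy_replicates(self):
        """Mean of ratios exceeds ratio of means for variable male counts."""
        rng = np.random.default_rng(14)
        females = rng.poisson(20.8, size=200)
        males = rng.poisson(2.4, size=200) + 1  # keep males >= 1
        out = sex_ratio_summary(list(zip(females, males)))
        assert out["mean"] > females.sum() / males.sum()


class TestDevelopmentalTime:
    def make_individual(self, schema, stage_days):
        """stage_days: list of (stage, n_days) visited in order."""
        rows, day = [], 0
        for stage, n in stage_days:
            for _ in range(n):
                rows.append(("c1", "i1", day, stage, "alive"))
                day += 1
        return CohortCensus(records=make_census_frame(rows), schema=schema)

    def test_egg_duration_hand_count(self, schema):
        """Egg on days 0–5, larva from day 6 → egg duration 6 days."""
        census = self.make_individual(schema, [("egg", 6), ("larva", 3)])
        table = developmental_time_summary(census, schema)
        egg = table[table["stage"] == "egg"].iloc[0]
        assert egg["mean_days"] == 6
        assert egg["n"] == 1
        # larva not completed: excluded
        larva = table[table["stage"] == "larva"].iloc[0]
        assert larva["n"] == 0

    def test_single_individual_se_undefined(self, schema):
        census = self.make_individual(schema, [("egg", 6), ("larva", 3)])
        table = developmental_time_summary(census, schema)
        assert math.isnan(table[table["stage"] == "egg"].iloc[0]["se_days"])

    def test_fixed_duration_simulator_recovery(self, schema):
        """Deterministic integer durations are recovered exactly."""
        from cohortdem import control_like, simulate_cohort

        cfg = control_like(
            seed=5,
            stage_duration_means=(6.0, 15.0, 2.0, 6.0, 4.0),
            stage_duration_cv=(0.0,) * 5,
            daily_survival=(1.0,) * 6,
            n_cohorts=1, cohort_size=10, horizon_days=40,
        )
        census, _, _ = simulate_cohort(cfg)
        table = developmental_time_summary(census, schema).set_index("stage")
        for stage, days in zip(
            ["egg", "larva", "pre-pupa", "pupa", "juvenile"],
            [6, 15, 2, 6, 4],
        ):
            assert table.loc[stage, "mean_days"] == days
            assert table.loc[stage, "se_days"] == 0.0
        assert table.loc["egg_to_adult", "mean_days"] == 33


class TestOneWayAnova:
    def test_identical_groups(self):
        g = np.array([1.0, 2.0, 3.0])
        F, dfb, dfw, p = one_way_anova([g, g.copy()])
        assert F == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        """(1,2,3) vs (4,5,6): SSB = 13.5, SSW = 4 → F = 13.5."""
        F, dfb, dfw, p = one_way_anova(
            [np.array([1.0, 2, 3]), np.array([4.0, 5, 6])]
        )
        assert F == pytest.approx(13.5)
        assert (dfb, dfw) == (1, 4)

    def test_textbook_formula_oracle(self):
        """Random 3-group data against the direct SSB/SSW computation."""
        rng = np.random.default_rng(44)
        groups = [rng.normal(loc, 1.0, size=8) for loc in (0.0, 0.5, 1.0)]
        F, dfb, dfw, p = one_way_anova(groups)
        grand = np.concatenate(groups).mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        assert F == pytest.approx((ssb / dfb) / (ssw / dfw))

    def test_shift_invariance_and_scale_invariance(self):
        rng = np.random.default_rng(45)
        groups = [rng.normal(loc, 1.0, size=6) for loc in (0.0, 1.0)]
        F0, *_ = one_way_anova(groups)
        F_shift, *_ = one_way_anova([g + 100.0 for g in groups])
        F_scale, *_ = one_way_anova([g * 7.0 for g in groups])
        assert F_shift == pytest.approx(F0)
        assert F_scale == pytest.approx(F0)

    def test_degenerate_zero_variance(self):
        F, _, _, p = one_way_anova([np.array([1.0, 1.0]), np.array([2.0, 2.0])])
        assert math.isinf(F)
        assert p == 0.0

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValidationError):
            one_way_anova([np.array([1.0, 2.0])])


class TestPairwiseWelchHolm:
    def test_holm_adjustment_monotone_and_bounded(self):
        rng = np.random.default_rng(46)
        groups = {
            "a": rng.normal(0, 1, 10),
            "b": rng.normal(0.2, 1, 10),
            "c": rng.normal(3.0, 1, 10),
        }
        rows = pairwise_welch_holm(groups)
        assert len(rows) == 3
        for r in rows:
            assert r["p_holm"] >= r["p_raw"]
            assert r["p_holm"] <= 1.0


class TestPoissonRate:
    def test_interval_covers_rate(self):
        out = poisson_rate_summary(30, 120.0)
        assert out["lower"] < out["rate"] < out["upper"]
        assert out["rate"] == pytest.approx(0.25)

    def test_zero_events_lower_bound_is_zero(self):
        out = poisson_rate_summary(0, 50.0)
        assert out["lower"] == 0.0
        assert out["upper"] > 0.0
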