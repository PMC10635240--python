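"""Group comparisons, ANCOVA confounder recovery, demographics, trends."""

import numpy as np
import pandas as pd
import pytest

from chromascan import (
    CohortConfig,
    ancova_d,
    compare_groups,
    compare_many,
    demographic_table,
    generate_cohort,
    trend_across_stages,
)
from chromascan.stats import cohens_d


class TestCompareGroups:
    def test_identical_groups_null(self):
        a = np.array([2.5, 2.6, 2.4, 2.55])
        cmp = compare_groups(a, a.copy())
        assert cmp.effect_size == pytest.approx(0.0)
        assert cmp.p_value == pytest.approx(1.0)

    def test_one_pooled_sd_apart_gives_d_one(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 2000)
        a = (a - a.mean()) / a.std(ddof=1)  # exact mean 0, sd 1
        b = a + 1.0
        assert cohens_d(a, b) == pytest.approx(1.0, abs=1e-12)

    def test_simulated_effect_recovered(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 1.0, 100)
        b = rng.normal(0.5, 1.0, 100)
        cmp = compare_groups(a, b)
        assert cmp.effect_size == pytest.approx(0.5, abs=0.15)
        assert cmp.p_value < 0.05

    def test_antisymmetric_and_affine_invariant(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 50)
        b = rng.normal(0.8, 1.2, 60)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))
        assert cohens_d(3 * a + 7, 3 * b + 7) == pytest.approx(cohens_d(a, b))

    def test_holm_adjustment_column(self):
        rng = np.random.default_rng(3)
        groups = {g: rng.normal(m, 0.5, 30) for g, m in
                  [("Control", 0.0), ("AA", 0.6), ("CRC", 1.0)]}
        table = compare_many(groups, reference="Control")
        assert list(table["group"]) == ["AA", "CRC"]
        assert (table["p_holm"] >= table["p_value"] - 1e-15).all()


class TestAncova:
    def test_recovers_injected_age_coefficient(self):
        """Generator truth: age slope -0.008/yr, no sex/smoking/drinking effect."""
        cfg = CohortConfig(
            group_sizes={"Control": 2500, "AA": 2500}, cells_per_patient=1, seed=8
        )
        patients, _ = generate_cohort(cfg)
        res = ancova_d(patients, d_col="true_mean_d")
        assert res.coef("age") == pytest.approx(-0.008, abs=0.002)
        for term in ("female", "smoker", "drinker"):
            assert res.p(term) > 0.001  # no injected effect

    def test_null_case_effect_within_three_se(self):
        """Full null: equal D means and equal age distributions, so the
        age-adjusted case coefficient has expectation zero."""
        cfg = CohortConfig(
            group_sizes={"Control": 800, "AA": 800},
            group_d_mean={"Control": 2.56, "AA": 2.56},  # no case effect injected
            age_mean_case=57.0,  # no demographic confounding either
            cells_per_patient=1,
            seed=9,
        )
        patients, _ = generate_cohort(cfg)
        res = ancova_d(patients, d_col="true_mean_d")
        assert abs(res.coef("is_case")) < 3 * float(res.table.loc["is_case", "se"])

    def test_type_one_error_calibrated(self):
        """Null covariates reject at ~5% across 100 seeded replicates."""
        hits = {"female": 0, "smoker": 0, "drinker": 0}
        n_rep = 100
        for seed in range(n_rep):
            cfg = CohortConfig(
                group_sizes={"Control": 150, "AA": 150}, cells_per_patient=1, seed=seed
            )
            patients, _ = generate_cohort(cfg)
            res = ancova_d(patients, d_col="true_mean_d")
            for term in hits:
                hits[term] += res.p(term) < 0.05
        rate = sum(hits.values()) / (3 * n_rep)
        assert rate == pytest.approx(0.05, abs=0.03)

    def test_constant_covariates_rejected(self):
        patients = pd.DataFrame(
            {
                "group": ["Control", "AA"] * 10,
                "age": [60.0] * 20,
                "sex": ["F"] * 20,
                "smoker": [False] * 20,
                "drinker": [False] * 20,
                "mean_d": np.linspace(2.4, 2.7, 20),
            }
        )
        with pytest.raises(ValueError):
            ancova_d(patients)


class TestDemographics:
    def test_small_cohort_percentages(self):
        patients = pd.DataFrame(
            {
                "group": ["Control", "Control"],
                "age": [50.0, 60.0],
                "sex": ["F", "M"],
                "smoker": [True, False],
                "drinker": [False, False],
            }
        )
        table = demographic_table(patients)
        row = table.iloc[0]
        assert row["n"] == 2
        assert row["pct_female"] == pytest.approx(50.0)
        assert row["pct_smoker"] == pytest.approx(50.0)
        assert row["mean_age"] == pytest.approx(55.0)

    def test_default_cohort_age_structure(self):
        patients, _ = generate_cohort(CohortConfig(cells_per_patient=1, seed=10))
        table = demographic_table(patients).set_index("group")
        assert table.loc["Control", "mean_age"] == pytest.approx(57, abs=2)
        case_age = patients.loc[patients["group"] != "Control", "age"].mean()
        assert case_age == pytest.approx(62, abs=2)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            demographic_table(pd.DataFrame())


class TestTrend:
    def test_strictly_increasing_passes(self):
        report = trend_across_stages(
            ["a", "b", "c"], {"a": 2.5, "b": 2.6, "c": 2.7}
        )
        assert report["monotone"] and report["n_violations"] == 0

    def test_single_inversion_reported(self):
        report = trend_across_stages(
            ["a", "b", "c", "d"], {"a": 2.5, "b": 2.7, "c": 2.6, "d": 2.8}
        )
        assert not report["monotone"]
        assert report["n_violations"] == 1
        assert report["violations"][0]["from"] == "b"

    def test_generated_cohort_trend_holds_at_scale(self):
        """The generator enforces the stage ordering in expectation; at
        n=2000 per group the sample means order deterministically."""
        order = ["Control", "DA", "NDA", "AA", "HNPCC", "CRC"]
        cfg = CohortConfig(
            group_sizes={g: 2000 for g in order}, cells_per_patient=1, seed=12
        )
        patients, _ = generate_cohort(cfg)
        means = patients.groupby("group")["true_mean_d"].mean().to_dict()
        report = trend_across_stages(order, means)
        assert report["monotone"]
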