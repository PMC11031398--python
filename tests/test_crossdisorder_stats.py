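"""Statistical kernels against hand and enumeration oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurotraj.crossdisorder_stats import (
    bh_fdr,
    chi2_2x2,
    diagnostic_importance_chi2,
    donor_attribute_counts,
    dot_statistics,
    km_survival,
    mwu_test,
    pairwise_mwu,
    permutation_enrichment,
    sex_balance_subsample,
    survival_tests,
    temporal_distribution_tests,
)
from neurotraj.synthetic_data import CohortConfig, cohort_observations, \
    generate_cohort, uniform_profile


class TestDotStatistics:
    COUNTS = pd.DataFrame(
        {"attr": [2, 0, 1]}, index=pd.Index(["d1", "d2", "d3"], name="donor_id")
    )
    GROUPS = pd.Series({"d1": "A", "d2": "A", "d3": "A"})

    def test_hand_computed_mean_and_proportion(self):
        stats = dot_statistics(self.COUNTS, self.GROUPS)
        assert stats.iloc[0]["mean_observations"] == pytest.approx(1.0)
        assert stats.iloc[0]["donor_proportion"] == pytest.approx(2 / 3)
        assert stats.attrs["color_cap"] == 5.0

    def test_never_observed_attribute(self):
        counts = self.COUNTS.assign(silent=0)
        stats = dot_statistics(counts, self.GROUPS)
        row = stats[stats["attribute"] == "silent"].iloc[0]
        assert row["mean_observations"] == 0.0
        assert row["donor_proportion"] == 0.0

    def test_everyone_observed_once(self):
        counts = pd.DataFrame({"attr": [1, 1, 1]}, index=self.COUNTS.index)
        stats = dot_statistics(counts, self.GROUPS)
        assert stats.iloc[0]["mean_observations"] == 1.0
        assert stats.iloc[0]["donor_proportion"] == 1.0


class TestPermutationEnrichment:
    def test_exhaustive_three_donor_fixture(self):
        counts = pd.DataFrame({"attr": [1, 1, 0]},
                              index=pd.Index(["d1", "d2", "d3"]))
        groups = pd.Series({"d1": "A", "d2": "A", "d3": "B"})
        result = permutation_enrichment(counts, groups, exhaustive=True)
        p_a = result[result["diagnosis"] == "A"]["p_perm"].iloc[0]
        p_b = result[result["diagnosis"] == "B"]["p_perm"].iloc[0]
        assert p_a == pytest.approx(1 / 3)
        assert p_b == pytest.approx(1.0)  # opposite tail

    def test_constant_attribute_ties_give_p_one(self):
        counts = pd.DataFrame({"attr": [1, 1, 1, 1]},
                              index=pd.Index(list("abcd")))
        groups = pd.Series(dict(zip("abcd", "AABB")))
        result = permutation_enrichment(counts, groups, exhaustive=True)
        assert (result["p_perm"] == 1.0).all()

    def test_sampled_matches_exhaustive_within_monte_carlo_error(self):
        """5-donor fixture: the sampled p with add-one correction converges
        to the exhaustive enumeration p."""
        counts = pd.DataFrame({"attr": [3, 2, 1, 0, 0]},
                              index=pd.Index(list("abcde")))
        groups = pd.Series(dict(zip("abcde", "AABBB")))
        exact = permutation_enrichment(counts, groups, exhaustive=True)
        n_perm = 10_000
        sampled = permutation_enrichment(counts, groups, n_perm=n_perm, seed=42)
        for (_, row_e), (_, row_s) in zip(exact.iterrows(), sampled.iterrows()):
            p = row_e["p_perm"]
            se = np.sqrt(p * (1 - p) / n_perm)
            assert abs(row_s["p_perm"] - p) < 3 * se + 2 / n_perm

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(1.0, (20, 3)),
                              index=[f"d{i}" for i in range(20)],
                              columns=list("xyz"))
        groups = pd.Series(["A"] * 10 + ["B"] * 10, index=counts.index)
        a = permutation_enrichment(counts, groups, n_perm=500, seed=9)
        b = permutation_enrichment(counts, groups, n_perm=500, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_single_group_rejected(self):
        counts = pd.DataFrame({"x": [1, 2]}, index=["a", "b"])
        with pytest.raises(ValueError, match=">= 2 groups"):
            permutation_enrichment(counts, pd.Series({"a": "A", "b": "A"}))


class TestBhFdr:
    def test_hand_applied_step_up(self):
        assert bh_fdr([0.002, 0.01, 0.03, 0.04]) == pytest.approx(
            [0.008, 0.02, 0.04, 0.04]
        )

    def test_all_ones_unchanged(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1, 1, 1])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_q_dominates_p_and_capped(self, p_values):
        q = bh_fdr(p_values)
        assert (q >= np.asarray(p_values) - 1e-12).all()
        assert (q <= 1.0).all()


class TestChi2:
    def test_independence_gives_zero(self):
        chi2, p = chi2_2x2([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_closed_form_examples(self):
        chi2, _ = chi2_2x2([[20, 10], [10, 20]])
        assert chi2 == pytest.approx(20 / 3)
        chi2, _ = chi2_2x2([[20, 0], [0, 20]])
        assert chi2 == pytest.approx(40.0)

    def test_zero_expected_cell_rejected(self):
        with pytest.raises(ValueError, match="expected count 0"):
            chi2_2x2([[5, 5], [0, 0]])

    def test_flag_interface_matches_table(self):
        sig = np.array([True] * 20 + [False] * 10 + [True] * 10 + [False] * 20)
        apriori = np.array([True] * 20 + [True] * 10 + [False] * 10 + [False] * 20)
        chi2, _ = diagnostic_importance_chi2(sig, apriori)
        assert chi2 == pytest.approx(20 / 3)


class TestSexBalance:
    def test_majority_sex_downsampled(self):
        metadata = pd.DataFrame(
            {"donor_id": [f"d{i}" for i in range(16)],
             "group": ["AD"] * 16,
             "sex": ["M"] * 10 + ["F"] * 6}
        )
        kept = sex_balance_subsample(metadata, seed=0)
        sexes = metadata.set_index("donor_id").loc[kept, "sex"]
        assert len(kept) == 12
        assert (sexes == "M").sum() == 6 and (sexes == "F").sum() == 6

    def test_balanced_group_keeps_size(self):
        metadata = pd.DataFrame(
            {"donor_id": list("abcd"), "group": ["X"] * 4,
             "sex": ["M", "M", "F", "F"]}
        )
        assert len(sex_balance_subsample(metadata, seed=0)) == 4

    def test_single_sex_group_dropped_with_warning(self):
        metadata = pd.DataFrame(
            {"donor_id": list("ab"), "group": ["X"] * 2, "sex": ["M", "M"]}
        )
        with pytest.warns(UserWarning, match="single sex"):
            assert sex_balance_subsample(metadata, seed=0) == []


class TestMannWhitney:
    def test_exact_separated_groups(self):
        u, p = mwu_test([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_exact_with_ties(self):
        _, p = mwu_test([5, 5, 5], [0, 0, 0])
        assert p == pytest.approx(0.1)

    def test_identical_distributions(self):
        _, p = mwu_test([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_large_samples_match_scipy_asymptotic(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 300), rng.normal(0.3, 1, 300)
        from scipy.stats import mannwhitneyu
        u, p = mwu_test(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue)

    def test_pairwise_panel_applies_fdr(self):
        values = {"A": [1, 2, 3], "B": [4, 5, 6], "C": [1.5, 2.5, 3.5]}
        frame = pairwise_mwu(values)
        assert len(frame) == 3
        assert (frame["q"] >= frame["p"] - 1e-12).all()

    def test_small_group_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="<2 observations"):
            frame = pairwise_mwu({"A": [1], "B": [1, 2], "C": [3, 4]})
        assert set(frame["group_a"]) | set(frame["group_b"]) == {"B", "C"}


class TestTemporalProfiles:
    def test_planted_early_onset_detected(self):
        config = CohortConfig(
            n_donors=80,
            diseases=[
                uniform_profile("EARLY", 0.5, ["dementia"], onset_mean=55,
                                onset_sd=2, obs_prob=0.6, duration_years=6),
                uniform_profile("LATE", 0.5, ["dementia"], onset_mean=78,
                                onset_sd=2, obs_prob=0.6, duration_years=6),
            ],
            seed=31,
        )
        cohort = generate_cohort(config)
        observations = cohort_observations(cohort)
        groups = pd.Series({d.donor_id: d.nd_codes[0] for d in cohort})
        frame, ages = temporal_distribution_tests(observations, groups, "dementia")
        assert frame.iloc[0]["p"] < 0.01
        assert np.median(ages["EARLY"]) < np.median(ages["LATE"])


class TestSurvival:
    def test_all_censored_curve_stays_at_one(self):
        curve = km_survival([0, 0, 0], [5, 6, 7], censored=[True] * 3)
        assert curve.survival_at(7) == pytest.approx(1.0)

    def test_product_limit_no_censoring(self):
        curve = km_survival([0, 0, 0], [1, 2, 3])
        assert curve.survival_at(1) == pytest.approx(2 / 3)
        assert curve.survival_at(2) == pytest.approx(1 / 3)
        assert curve.survival_at(3) == pytest.approx(0.0)

    def test_product_limit_with_censoring(self):
        curve = km_survival([0, 0, 0], [1, 2, 3], censored=[False, True, False])
        assert curve.survival_at(1) == pytest.approx(2 / 3)
        assert curve.survival_at(3) == pytest.approx(0.0)

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError, match="negative duration"):
            km_survival([10], [5])

    def test_matches_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(3)
        durations = rng.integers(1, 30, 40).astype(float)
        curve = km_survival(np.zeros(40), durations)
        for t in [5, 10, 20]:
            assert curve.survival_at(t) == pytest.approx(np.mean(durations > t))

    def test_survival_tests_recover_planted_direction(self):
        _, p = mwu_test([2, 3], [10, 11])
        frame = survival_tests({"SHORT": [2, 3, 2.5], "LONG": [10, 11, 10.5]})
        assert frame.iloc[0]["p"] == pytest.approx(0.1)  # 2/C(6,3) enumeration
        assert frame.iloc[0]["U"] == 9.0  # group_a=LONG wins every pair


class TestCalibrationAndPower:
    def test_null_cohort_discovery_fraction_controlled(self, null_cohort_config):
        fractions = []
        for seed in range(20):
            cohort = generate_cohort(null_cohort_config(200 + seed))
            observations = cohort_observations(cohort)
            groups = pd.Series({d.donor_id: d.nd_codes[0] for d in cohort})
            counts = donor_attribute_counts(observations, donors=groups.index)
            result = permutation_enrichment(counts, groups, n_perm=1000, seed=seed)
            q = bh_fdr(result["p_perm"].to_numpy())
            fractions.append(float(np.mean(q < 0.1)))
        fractions = np.asarray(fractions)
        se = fractions.std(ddof=1) / np.sqrt(len(fractions)) if fractions.std() else 0.0
        assert fractions.mean() <= 0.1 + 3 * se + 1e-9

    def test_planted_enrichment_power(self):
        from neurotraj.synthetic_data import AttributeProfile, DiseaseProfile

        detected = 0
        for seed in range(20):
            enriched = uniform_profile(
                "A", 0.5, ["target", "base1", "base2"], onset_mean=65,
                obs_prob=0.45, duration_years=10,
            )
            background = DiseaseProfile(
                "B", 0.5,
                {
                    "target": AttributeProfile(65, 3, 0.15, 10),  # 3-fold lower
                    "base1": AttributeProfile(65, 3, 0.45, 10),
                    "base2": AttributeProfile(65, 3, 0.45, 10),
                },
            )
            cohort = generate_cohort(
                CohortConfig(n_donors=100, diseases=[enriched, background],
                             seed=100 + seed)
            )
            observations = cohort_observations(cohort)
            groups = pd.Series({d.donor_id: d.nd_codes[0] for d in cohort})
            counts = donor_attribute_counts(observations, donors=groups.index)
            result = permutation_enrichment(counts, groups, n_perm=2000, seed=seed)
            q = bh_fdr(result["p_perm"].to_numpy())
            result = result.assign(q=q)
            row = result[(result["attribute"] == "target")
                         & (result["diagnosis"] == "A")]
            detected += bool((row["q"] < 0.1).iloc[0])
        assert detected / 20 >= 0.9
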