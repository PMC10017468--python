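"""Group-comparison statistics: linear models, rank tests, bootstrap, AIC."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from focalstage import analysis as an
from focalstage.regions import LOBES, REGIONS
from focalstage.staging import StagingResult
from oracles import ols_f_test


def two_group_frame(x, y, labels=("A", "B")):
    return pd.DataFrame(
        {"group": [labels[0]] * len(x) + [labels[1]] * len(y),
         "y": list(x) + list(y)}
    )


def planted_cohort(n=300, seed=0):
    """Three groups with a planted outcome effect and an age confound."""
    rng = np.random.default_rng(seed)
    group = rng.choice(["G-F-", "G-F+", "G+"], size=n, p=[0.4, 0.2, 0.4])
    age_mean = {"G-F-": 70.0, "G-F+": 75.0, "G+": 72.0}
    age = np.array([rng.normal(age_mean[g], 7.0) for g in group])
    effect = {"G-F-": 6.5, "G-F+": 5.0, "G+": 3.0}
    svlt = np.array([effect[g] for g in group]) - 0.05 * (age - 72) + rng.normal(0, 2, n)
    return pd.DataFrame({"group": group, "age": age, "svlt": svlt})


class TestAnovaAncova:
    def test_identical_groups_give_zero_statistic(self):
        frame = two_group_frame([1, 2, 3, 4], [1, 2, 3, 4])
        res = an.compare_groups(frame, "y", "anova")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_constant_outcome_rejected(self):
        frame = two_group_frame([1.0] * 5, [1.0] * 5)
        with pytest.raises(ValueError, match="zero variance"):
            an.compare_groups(frame, "y", "anova")

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(2)
        frame = two_group_frame(rng.normal(0, 1, 40), rng.normal(0.4, 1, 35))
        res = an.compare_groups(frame, "y", "anova")
        t = sps.ttest_ind(frame.loc[frame.group == "A", "y"],
                          frame.loc[frame.group == "B", "y"])
        assert abs(res.statistic - t.statistic**2) < 1e-10

    def test_ancova_matches_normal_equations_oracle(self):
        cohort = planted_cohort()
        res = an.compare_groups(cohort, "svlt", "ancova_age")
        assert res.p_value < 0.01
        # explicit least-squares F for the group factor, same design matrix
        g = pd.get_dummies(cohort["group"], drop_first=True).to_numpy(float)
        intercept = np.ones((len(cohort), 1))
        age = cohort[["age"]].to_numpy(float)
        f_oracle = ols_f_test(
            cohort["svlt"], np.hstack([intercept, g, age]), np.hstack([intercept, age])
        )
        assert res.statistic == pytest.approx(f_oracle, abs=1e-8)

    def test_empty_group_rejected(self):
        frame = two_group_frame([1.0, 2.0], [])
        with pytest.raises(ValueError, match=">= 2 groups"):
            an.compare_groups(frame, "y", "anova")


class TestTukeyPosthoc:
    def test_matches_statsmodels_without_covariates(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        cohort = planted_cohort(seed=3)
        res = an.compare_groups(cohort, "svlt", "tukey_posthoc")
        sm_res = pairwise_tukeyhsd(cohort["svlt"], cohort["group"])
        mine = [res.pairwise[pair] for pair in sorted(res.pairwise)]
        for (diff, p), sm_diff, sm_p in zip(
            mine, sm_res.meandiffs, sm_res.pvalues
        ):
            assert diff == pytest.approx(sm_diff, abs=1e-8)
            assert p == pytest.approx(sm_p, abs=1e-6)

    def test_age_adjusted_comparisons(self):
        cohort = planted_cohort(seed=4)
        res = an.compare_groups(cohort, "svlt", "tukey_posthoc", covariates=("age",))
        assert set(res.pairwise) == {("G-F+", "G-F-"), ("G+", "G-F+"), ("G+", "G-F-")}
        assert all(0 <= p <= 1 for _, p in res.pairwise.values())
        # planted ordering: G-F- > G-F+ > G+, so the largest gap is G+ vs G-F-
        diff_big = abs(res.pairwise[("G+", "G-F-")][0])
        assert diff_big > abs(res.pairwise[("G+", "G-F+")][0])
        assert res.pairwise[("G+", "G-F-")][1] < 0.001


class TestMannWhitney:
    def test_exact_small_sample_p(self):
        """{1,2,3} vs {4,5,6}: U = 0 and the one-sided exact p is 1/20."""
        frame = two_group_frame([1, 2, 3], [4, 5, 6])
        res = an.compare_groups(frame, "y", "mann_whitney", alternative="less")
        assert res.statistic == 0.0
        assert abs(res.p_value - 0.05) < 1e-12
        assert res.extras["p_method"] == "exact"

    def test_large_or_tied_samples_use_normal_approximation(self):
        rng = np.random.default_rng(6)
        frame = two_group_frame(
            rng.integers(0, 6, 40).astype(float), rng.integers(1, 7, 45).astype(float)
        )
        res = an.compare_groups(frame, "y", "mann_whitney")
        assert res.extras["p_method"] == "asymptotic"
        assert 0 <= res.p_value <= 1

    def test_requires_exactly_two_groups(self):
        frame = pd.DataFrame({"group": ["A"] * 3 + ["B"] * 3 + ["C"] * 3,
                              "y": range(9)})
        with pytest.raises(ValueError, match="exactly 2"):
            an.compare_groups(frame, "y", "mann_whitney")


class TestChiSquare:
    def test_identical_composition_gives_zero(self):
        frame = pd.DataFrame(
            {"group": ["A"] * 10 + ["B"] * 10, "sex": ["F", "M"] * 10}
        )
        res = an.compare_groups(frame, "sex", "chi_square")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_single_category_outcome_is_degenerate(self):
        frame = pd.DataFrame({"group": ["A"] * 5 + ["B"] * 5, "sex": ["F"] * 10})
        res = an.compare_groups(frame, "sex", "chi_square")
        assert (res.statistic, res.p_value) == (0.0, 1.0)

    def test_skewed_table_is_significant(self):
        frame = pd.DataFrame(
            {"group": ["A"] * 50 + ["B"] * 50,
             "apoe4": [1] * 40 + [0] * 10 + [1] * 10 + [0] * 40}
        )
        res = an.compare_groups(frame, "apoe4", "chi_square")
        assert res.p_value < 1e-6


class TestJonckheere:
    def test_maximal_increasing_arrangement(self):
        """Singletons {1},{2},{3}: JT = 3; only 1 of the 3! orderings attains
        it, so the one-sided permutation p is 1/6."""
        res = an.jonckheere_trend([[1.0], [2.0], [3.0]], alternative="increasing",
                                  n_permutations=3000, seed=0)
        assert res.statistic == 3.0
        assert res.extras["p_permutation"] == pytest.approx(1 / 6, abs=0.03)

    def test_all_tied_observations_are_uninformative(self):
        res = an.jonckheere_trend([[2.0, 2.0], [2.0, 2.0], [2.0, 2.0]])
        assert res.statistic == pytest.approx(res.extras["null_mean"])
        assert res.p_value == 1.0

    def test_normal_and_permutation_p_agree_on_small_samples(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(loc, 1.0, 12) for loc in (0.0, 0.6, 1.2)]
        res = an.jonckheere_trend(groups, alternative="increasing",
                                  n_permutations=20_000, seed=1)
        assert abs(res.p_value - res.extras["p_permutation"]) < 0.02

    def test_planted_decreasing_trend_detected(self):
        rng = np.random.default_rng(10)
        groups = [rng.normal(loc, 2.0, 60) for loc in (6.5, 4.5, 2.5)]
        res = an.jonckheere_trend(groups, alternative="decreasing")
        assert res.p_value < 1e-6

    def test_requires_three_groups(self):
        with pytest.raises(ValueError, match=">= 3"):
            an.jonckheere_trend([[1.0, 2.0], [3.0, 4.0]])


def fabricate_staging(flag_matrix, ligand="FMM"):
    """StagingResult list from an (n, 5) lobe-flag matrix (bilateral flags)."""
    results = []
    for i, lobe_flags in enumerate(np.asarray(flag_matrix, dtype=bool)):
        flags = {}
        for j, lobe in enumerate(LOBES):
            flags[f"{lobe}_left"] = flags[f"{lobe}_right"] = bool(lobe_flags[j])
        n_inv = sum(flags.values())
        results.append(StagingResult(
            participant_id=f"s{i}", ligand=ligand, global_cl=10.0,
            global_positive=False, region_flags=flags, n_involved=n_inv,
            group="G-F+" if n_inv else "G-F-",
            subtype="focal" if 0 < n_inv < len(REGIONS)
            else ("whole_brain" if n_inv else "none"),
            discordant_flag=False,
        ))
    return results


class TestInvolvementBootstrap:
    def test_degenerate_separation_hits_p_floor(self):
        flags = np.zeros((40, 5), dtype=bool)
        flags[:, LOBES.index("parietal")] = True  # parietal always, striatum never
        boot = an.involvement_frequency_bootstrap(fabricate_staging(flags),
                                                  n_resamples=500, seed=0)
        assert boot.frequencies["parietal"] == 1.0
        assert boot.frequencies["striatum"] == 0.0
        pair = ("parietal", "striatum")
        assert boot.neg_log10_p[pair] == pytest.approx(math.log10(500), abs=1e-9)

    def test_identical_lobes_are_indistinguishable(self):
        rng = np.random.default_rng(12)
        col = rng.random(80) < 0.4
        flags = np.zeros((80, 5), dtype=bool)
        flags[:, LOBES.index("frontal")] = col
        flags[:, LOBES.index("parietal")] = col
        boot = an.involvement_frequency_bootstrap(fabricate_staging(flags), seed=3)
        assert boot.pairwise_p[("frontal", "parietal")] > 0.9

    def test_bootstrap_mean_matches_point_frequency(self):
        rng = np.random.default_rng(14)
        flags = rng.random((120, 5)) < [0.5, 0.4, 0.6, 0.3, 0.15]
        flags[~flags.any(axis=1), 0] = True  # keep everyone eligible
        staging = fabricate_staging(flags)
        boot = an.involvement_frequency_bootstrap(staging, n_resamples=2000, seed=5)
        n = len(staging)
        for lobe in LOBES:
            f = boot.frequencies[lobe]
            # Monte-Carlo SE of the resample mean of a binomial proportion
            mc_se = math.sqrt(max(f * (1 - f), 1e-12) / n) / math.sqrt(2000)
            assert abs(boot.resample_mean[lobe] - f) <= max(2 * mc_se, 1e-9)

    def test_symmetry_and_eligibility(self):
        flags = np.zeros((10, 5), dtype=bool)
        flags[:5, 2] = True
        boot = an.involvement_frequency_bootstrap(fabricate_staging(flags),
                                                  n_resamples=200, seed=7)
        assert boot.n_subjects == 5  # zero-involvement subjects excluded
        for (a, b), p in boot.pairwise_p.items():
            assert boot.pairwise_p[(b, a)] == p
        with pytest.raises(ValueError, match="focal involvement"):
            an.involvement_frequency_bootstrap(
                fabricate_staging(np.zeros((4, 5))), n_resamples=200
            )


class TestAicComparison:
    def base_frame(self, n=300, seed=15):
        rng = np.random.default_rng(seed)
        group = rng.choice(["G-F-", "G-F+", "G+"], size=n, p=[0.35, 0.15, 0.5])
        cl = {"G-F-": 2.0, "G-F+": 16.0, "G+": 60.0}
        frame = pd.DataFrame({
            "group": group,
            "global_cl": [cl[g] + rng.normal(0, 2) for g in group],
            "age": rng.normal(72, 8, n),
        })
        return frame, rng

    def test_identical_groupings_tie_to_fg(self):
        frame, rng = self.base_frame()
        # outcome driven by the CL bands, which here coincide with the groups
        frame["y"] = rng.normal(0, 1, len(frame))
        res = an.compare_groupings_aic(frame, "y", covariates=())
        assert res.preferred == "fg"
        assert res.aic_fg_grouping == pytest.approx(res.aic_cl_grouping, abs=1e-8)

    def test_outcome_generated_from_fg_labels_prefers_fg(self):
        frame, rng = self.base_frame(seed=16)
        # split G- subjects across the 10-CL band boundary so the two
        # groupings genuinely differ, with the signal following F/G labels
        frame.loc[frame.group == "G-F-", "global_cl"] = rng.uniform(
            0, 20, (frame.group == "G-F-").sum()
        )
        effect = {"G-F-": 0.0, "G-F+": 1.5, "G+": 3.0}
        frame["y"] = [effect[g] for g in frame.group] + rng.normal(0, 1, len(frame))
        res = an.compare_groupings_aic(frame, "y", covariates=())
        assert res.preferred == "fg"
        assert res.aic_fg_grouping < res.aic_cl_grouping

    def test_band_labelling(self):
        cl = pd.Series([-5.0, 9.99, 10.0, 25.10, 25.11, 80.0])
        bands = an.cl_band_labels(cl, (10.0, 25.11)).tolist()
        assert bands == ["negative", "negative", "subthreshold", "subthreshold",
                         "positive", "positive"]

    def test_degenerate_grouping_rejected(self):
        frame = pd.DataFrame({
            "group": ["G+"] * 20, "global_cl": np.linspace(30, 90, 20),
            "age": np.linspace(60, 80, 20), "y": np.random.default_rng(0).normal(size=20),
        })
        with pytest.raises(ValueError, match="degenerate"):
            an.compare_groupings_aic(frame, "y")


def test_result_validation():
    with pytest.raises(ValueError, match="unknown method"):
        an.GroupComparisonResult("y", "bogus", 1.0, 0.5)
    with pytest.raises(ValueError, match="outside"):
        an.GroupComparisonResult("y", "anova", 1.0, 1.5)
    with pytest.raises(ValueError, match="tukey"):
        an.GroupComparisonResult("y", "anova", 1.0, 0.5, pairwise={})
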