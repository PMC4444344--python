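"""Group statistics: ANOVA, Bonferroni post-hoc sub-grouping, corrected CV
and library summaries."""

import numpy as np
import pytest
from scipy import stats as sps

from luxrep.stats import (
    MeasurementGroup, StatsError, anova, bonferroni_threshold, corrected_cv,
    group_cv_procedure, library_summary, mean_spacing, posthoc_subgroups,
)


def groups_from(*arrays, labels=None):
    labels = labels or [chr(65 + i) for i in range(len(arrays))]
    return [MeasurementGroup(l, np.asarray(v, float)) for l, v in zip(labels, arrays)]


class TestAnova:
    def test_hand_computed_f_on_toy_table(self):
        # 3 groups x 3 replicates; F computed by explicit sum-of-squares
        data = [[1.0, 2.0, 3.0], [2.0, 3.0, 4.0], [6.0, 7.0, 8.0]]
        flat = np.concatenate(data)
        grand = flat.mean()
        ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in data)
        ss_within = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in data)
        f_hand = (ss_between / 2) / (ss_within / 6)
        p_hand = sps.f.sf(f_hand, 2, 6)
        assert anova(groups_from(*data)) == pytest.approx(p_hand, rel=1e-12)

    def test_separated_means_give_tiny_p(self):
        p = anova(groups_from([1, 1.001, 0.999], [2, 2.001, 1.999]))
        assert p < 1e-6

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(1000):
            g = groups_from(*(rng.normal(1.0, 0.1, 5) for _ in range(3)))
            ps.append(anova(g))
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_variance_rejected(self):
        with pytest.raises(StatsError, match="variance"):
            anova(groups_from([1, 1, 1], [2, 2, 2]))


class TestPosthocSubgroups:
    def test_bonferroni_threshold_definition(self):
        for n in (2, 3, 5, 8):
            assert bonferroni_threshold(n, 0.05) == 0.05 / (n * (n - 1) / 2)

    def test_two_separated_groups_split(self, rng):
        g = groups_from(rng.normal(1, 0.02, 5), rng.normal(3, 0.02, 5))
        assert posthoc_subgroups(g) == (("A",), ("B",))

    def test_indistinguishable_groups_merge(self, rng):
        g = groups_from(*(rng.normal(1.0, 0.5, 4) for _ in range(3)))
        assert posthoc_subgroups(g) == (("A", "B", "C"),)

    def test_close_pair_merges_against_distant_third(self):
        # means 1.0 vs 1.05 (under one within-group sd apart) merge, while the
        # distant third group always separates.  The merge rate is bounded by
        # the analytic power of the pairwise t-test at the Bonferroni
        # threshold: P(split A,B) ~ 10%, so expect ~83% exact partitions.
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(200):
            g = groups_from(rng.normal(1.0, 0.05, 4), rng.normal(1.05, 0.05, 4),
                            rng.normal(3.0, 0.05, 4))
            parts = posthoc_subgroups(g)
            assert parts[-1] == ("C",)  # distant group always its own block
            if parts == (("A", "B"), ("C",)):
                hits += 1
        assert hits >= 150

    def test_alpha_extremes(self, rng):
        g = groups_from(rng.normal(1, 0.01, 6), rng.normal(1.2, 0.01, 6),
                        rng.normal(1.4, 0.01, 6))
        assert len(posthoc_subgroups(g, alpha=1 - 1e-12)) == 3  # all singletons
        assert posthoc_subgroups(g, alpha=1e-300) == (("A", "B", "C"),)


class TestCorrectedCV:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([1.0, 2.0, 3.0], 0.5 * (1 + 1 / 12)),   # CV 0.5, N=3
            ([5.0, 5.0, 5.0, 5.0], 0.0),
        ],
    )
    def test_hand_arithmetic(self, values, expected):
        assert corrected_cv(values) == pytest.approx(expected, rel=1e-12)

    def test_scales_plain_cv_by_small_sample_factor(self, rng):
        v = rng.normal(10, 2, 4)
        plain = np.std(v, ddof=1) / abs(np.mean(v))
        assert corrected_cv(v) == pytest.approx(plain * (1 + 1 / 16), rel=1e-12)

    def test_correction_vanishes_at_large_n(self, rng):
        v = rng.normal(10, 2, 100000)
        plain = np.std(v, ddof=1) / abs(np.mean(v))
        assert corrected_cv(v) == pytest.approx(plain, rel=1e-4)

    def test_single_value_rejected(self):
        with pytest.raises(StatsError):
            corrected_cv([1.0])


class TestGroupCVProcedure:
    def test_clean_two_subgroup_split_hand_value(self, rng):
        # subgroup means 1.0 and 2.0 -> CV over {1, 2} with N=2 correction
        g = groups_from(rng.normal(1.0, 0.005, 6), rng.normal(2.0, 0.005, 6))
        out = group_cv_procedure(g)
        expected = (np.std([1.0, 2.0], ddof=1) / 1.5) * (1 + 1 / 8)
        assert out.cv_corrected == pytest.approx(expected, rel=0.02)
        assert out.n_used == 2
        assert out.subgroups == (("A",), ("B",))

    def test_non_significant_anova_reports_no_cv(self):
        g = groups_from([1.0, 1.1, 0.9, 1.05], [0.95, 1.08, 1.02, 0.9],
                        [1.03, 0.97, 1.1, 0.95])
        out = group_cv_procedure(g)
        assert out.anova_p >= 0.05
        assert out.cv_corrected is None and "no significant" in out.notes

    def test_significant_anova_without_subgroups_falls_back_to_all_means(self):
        # borderline separations: ANOVA significant, but no Bonferroni pair is
        rng = np.random.default_rng(11)
        for _ in range(200):
            g = groups_from(rng.normal(1.0, 0.1, 3), rng.normal(1.12, 0.1, 3),
                            rng.normal(1.24, 0.1, 3))
            out = group_cv_procedure(g)
            if out.cv_corrected is not None and len(out.subgroups) == 1:
                expected = corrected_cv([gr.mean for gr in g])
                assert out.cv_corrected == pytest.approx(expected, rel=1e-12)
                return
        pytest.skip("fallback branch not reached in 200 draws")

    def test_group_order_invariance(self, rng):
        g = groups_from(rng.normal(1.0, 0.01, 5), rng.normal(2.0, 0.01, 5),
                        rng.normal(4.0, 0.01, 5))
        out1 = group_cv_procedure(g)
        out2 = group_cv_procedure(list(reversed(g)))
        assert out1.cv_corrected == pytest.approx(out2.cv_corrected, rel=1e-12)


class TestLibrarySummary:
    def test_powers_of_two(self):
        s = library_summary([1.0, 2.0, 4.0, 8.0])
        assert s.fold_range == 8.0 and s.mean_spacing == pytest.approx(0.5)

    def test_permutation_invariance(self, rng):
        a = rng.uniform(0.1, 3.0, 10)
        s1 = library_summary(a)
        s2 = library_summary(rng.permutation(a))
        assert s1 == s2

    def test_identical_members_have_zero_spacing(self):
        assert library_summary([2.0, 2.0, 2.0]).mean_spacing == 0.0

    def test_geometric_definition(self):
        assert mean_spacing(np.array([1.0, 2.0, 4.0, 8.0]), "geometric") == \
            pytest.approx(8 ** (1 / 3) - 1)

    def test_nonpositive_rejected(self):
        with pytest.raises(StatsError):
            library_summary([0.0, 1.0])
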