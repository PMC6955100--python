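import math
import warnings

import numpy as np
import pytest

from arborstat.errors import SampleSizeError
from arborstat.group_stats import (
    compare_metric,
    compare_sholl,
    comparisons_table,
    sholl_profiles,
    summarize_group,
    two_sample_t,
)
from arborstat.sholl import ShollProfile
from arborstat.synthetic_data import CohortSpec, generate_cohort


def hand_t_student(xs, ys):
    """Pooled-variance t from first principles (the textbook formula)."""
    xs, ys = np.asarray(xs, float), np.asarray(ys, float)
    n1, n2 = len(xs), len(ys)
    sp2 = ((n1 - 1) * xs.var(ddof=1) + (n2 - 1) * ys.var(ddof=1)) / (n1 + n2 - 2)
    return (xs.mean() - ys.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))


class TestSummarizeGroup:
    def test_mean_and_sem_of_small_sample(self):
        s = summarize_group([1, 2, 3], "g")
        assert s.mean == pytest.approx(2.0)
        assert s.sem == pytest.approx(1 / math.sqrt(3), abs=1e-4)  # sd = 1

    def test_constant_sample_has_zero_sem(self):
        s = summarize_group([5, 5, 5, 5], "g")
        assert (s.mean, s.sem) == (5.0, 0.0)

    def test_matches_two_pass_oracle(self, rng):
        for _ in range(10):
            xs = rng.normal(10, 3, size=rng.integers(5, 40))
            s = summarize_group(xs, "g")
            mean = sum(xs) / len(xs)
            sd = math.sqrt(sum((x - mean) ** 2 for x in xs) / (len(xs) - 1))
            assert s.mean == pytest.approx(mean)
            assert s.sem == pytest.approx(sd / math.sqrt(len(xs)))

    def test_single_observation_rejected(self):
        with pytest.raises(SampleSizeError):
            summarize_group([1.0], "g")

    def test_mean_sem_property_based(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=50))
        @settings(max_examples=100, deadline=None, derandomize=True)
        def check(values):
            s = summarize_group(values, "g")
            mean = sum(values) / len(values)
            var = sum((v - mean) ** 2 for v in values) / (len(values) - 1)
            assert s.mean == pytest.approx(mean, rel=1e-9, abs=1e-6)
            assert s.sem == pytest.approx(math.sqrt(var / len(values)),
                                          rel=1e-6, abs=1e-6)

        check()


class TestTwoSampleT:
    def test_identical_samples(self):
        res = two_sample_t([1, 2, 3], [1, 2, 3])
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_hand_computed_example(self):
        # pooled variance 1, SE = sqrt(2/3)
        res = two_sample_t([1, 2, 3], [2, 3, 4], variant="student")
        assert res.t_statistic == pytest.approx(-1.2247, abs=1e-4)
        assert res.degrees_of_freedom == 4

    def test_matches_first_principles_on_random_samples(self, rng):
        for _ in range(10):
            xs = rng.normal(0, 1, size=12)
            ys = rng.normal(0.5, 2, size=9)
            res = two_sample_t(xs, ys, variant="student")
            assert res.t_statistic == pytest.approx(hand_t_student(xs, ys), rel=1e-10)

    def test_swapping_groups_flips_sign(self, rng):
        xs, ys = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        a = two_sample_t(xs, ys)
        b = two_sample_t(ys, xs)
        assert a.t_statistic == pytest.approx(-b.t_statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_student_equals_welch_for_balanced_equal_variance(self, rng):
        xs, ys = rng.normal(0, 1, 15), rng.normal(0, 1, 15)
        s = two_sample_t(xs, ys, variant="student")
        w = two_sample_t(xs, ys, variant="welch")
        assert s.t_statistic == pytest.approx(w.t_statistic)
        # equal n: Satterthwaite df <= pooled df, equality iff equal variances
        assert w.degrees_of_freedom <= s.degrees_of_freedom

    def test_zero_variance_conventions(self):
        same = two_sample_t([2, 2, 2], [2, 2, 2])
        assert (same.t_statistic, same.p_value) == (0.0, 1.0)
        diff = two_sample_t([3, 3, 3], [2, 2, 2])
        assert diff.p_value == 0.0 and diff.significant
        assert diff.t_statistic == math.inf

    def test_undersized_samples_rejected(self):
        with pytest.raises(SampleSizeError):
            two_sample_t([1], [1, 2])

    def test_null_type_one_error_calibrated(self):
        # both groups from the same normal; rejection rate near alpha
        rng = np.random.default_rng(99)
        rejections = sum(
            two_sample_t(rng.normal(0, 1, 20), rng.normal(0, 1, 20)).significant
            for _ in range(1000)
        )
        # binomial 99% interval around 0.05 at n=1000
        assert 33 <= rejections <= 69


class TestCompareMetric:
    def test_identical_cohorts_give_p_one(self):
        cohort = [t for t, _ in generate_cohort(CohortSpec(label="A", n_neurons=10), seed=3)]
        c = compare_metric(cohort, cohort, "length", label_a="A", label_b="B")
        assert c.test.p_value == pytest.approx(1.0)
        assert c.summary_a.mean == c.summary_b.mean

    def test_singleton_cohorts_rejected(self):
        cohort = [t for t, _ in generate_cohort(CohortSpec(label="A", n_neurons=1), seed=3)]
        with pytest.raises(SampleSizeError):
            compare_metric(cohort, cohort, "length")

    def test_unknown_metric_rejected(self):
        cohort = [t for t, _ in generate_cohort(CohortSpec(label="A", n_neurons=3), seed=3)]
        with pytest.raises(ValueError, match="unknown metric"):
            compare_metric(cohort, cohort, "sholl")

    def test_all_three_metrics_run(self):
        a = [t for t, _ in generate_cohort(CohortSpec(label="A", n_neurons=8), seed=1)]
        b = [t for t, _ in generate_cohort(CohortSpec(label="B", n_neurons=8), seed=2)]
        for metric in ("length", "terminal_count", "spatial_volume"):
            c = compare_metric(a, b, metric)
            assert c.metric == metric
            assert 0.0 <= c.test.p_value <= 1.0
            assert c.summary_a.n == c.summary_b.n == 8


class TestCompareSholl:
    def make_profiles(self, counts_list):
        return [ShollProfile(tuple(30.0 * (i + 1) for i in range(len(c))), tuple(c))
                for c in counts_list]

    def test_identical_cohorts_no_significant_shells(self):
        profs = self.make_profiles([(3, 2, 1), (4, 3, 1), (5, 2, 2), (3, 3, 1)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cmps = compare_sholl(profs, profs, mode="per_shell")
        assert len(cmps) == 3
        assert not any(c.test.significant for c in cmps)

    def test_range_mode_aggregates_per_neuron(self):
        a = self.make_profiles([(3, 2, 1), (4, 3, 1), (5, 2, 2)])
        b = self.make_profiles([(9, 9, 1), (8, 7, 1), (9, 8, 2)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cmps = compare_sholl(a, b, mode="range", ranges=[(30, 60)])
        assert len(cmps) == 1
        c = cmps[0]
        assert c.metric == "sholl_range@30-60"
        assert c.summary_a.mean == pytest.approx(np.mean([5, 7, 7]))
        assert c.summary_b.mean == pytest.approx(np.mean([18, 15, 17]))
        assert c.test.significant

    def test_unequal_lengths_padded_with_zeros(self):
        a = self.make_profiles([(3, 2), (4, 3), (2, 2)])
        b = self.make_profiles([(3, 2, 1), (4, 3, 2), (2, 2, 1)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cmps = compare_sholl(a, b, mode="per_shell")
        assert len(cmps) == 3  # grid extends to the longer profile

    def test_holm_correction_is_conservative(self):
        rng = np.random.default_rng(4)
        a = self.make_profiles(rng.integers(0, 8, size=(12, 5)))
        b = self.make_profiles(rng.integers(2, 10, size=(12, 5)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            plain = compare_sholl(a, b, mode="per_shell")
            corrected = compare_sholl(a, b, mode="per_shell", holm=True)
        n_plain = sum(c.test.significant for c in plain)
        n_corr = sum(c.test.significant for c in corrected)
        assert n_corr <= n_plain

    def test_uncorrected_multiplicity_warns(self):
        profs = self.make_profiles([(3, 2, 1), (4, 3, 1), (5, 2, 2)])
        with pytest.warns(UserWarning, match="uncorrected"):
            compare_sholl(profs, profs, mode="per_shell")


def test_comparisons_table_schema():
    a = [t for t, _ in generate_cohort(CohortSpec(label="A", n_neurons=5), seed=1)]
    b = [t for t, _ in generate_cohort(CohortSpec(label="B", n_neurons=5), seed=2)]
    df = comparisons_table([compare_metric(a, b, "length", label_a="A", label_b="B")])
    assert list(df.columns) == [
        "metric", "group_a", "n_a", "mean_a", "sem_a",
        "group_b", "n_b", "mean_b", "sem_b", "t", "df", "p",
        "significant", "variant"]
    assert df.loc[0, "n_a"] == 5
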