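"""Retention filters, mutation classes, rates, and group comparisons."""

import numpy as np
import pytest
from scipy import stats

from mutsel import (
    classify_mutation,
    compare_rate_groups,
    compute_mutation_rate,
    filter_variants,
    selection_infrequency_tests,
    shared_mutation_summary,
)
from mutsel.variant_filtering import MalformedRecordError

from conftest import make_line, make_record


class TestFilterVariants:
    @pytest.mark.parametrize(
        "override, criterion",
        [
            ({"depth_sample": 4, "forward_support": 2, "reverse_support": 2}, "depth"),
            ({"depth_ancestor": 4}, "depth"),
            ({"forward_support": 0, "reverse_support": 20}, "strand"),
            ({"reverse_support": 0, "forward_support": 20}, "strand"),
            ({"quality": 49.999}, "quality"),
            ({"genotype_homogeneous": False}, "homogeneous"),
            ({"ref": "A", "alt": "A" + "T" * 55}, "indel_length"),
        ],
    )
    def test_rejection_reasons(self, override, criterion):
        retained, tally = filter_variants([make_record(**override)], "haploid")
        assert retained == []
        assert tally[criterion] == 1
        assert sum(tally.values()) == 1

    @pytest.mark.parametrize(
        "override",
        [
            {},
            {"depth_sample": 5, "forward_support": 1, "reverse_support": 1},  # boundary
            {"depth_ancestor": 5},
            {"quality": 50.0},  # inclusive threshold
            {"ref": "A", "alt": "A" + "T" * 49},  # longest retained indel
        ],
    )
    def test_boundary_records_retained(self, override):
        retained, tally = filter_variants([make_record(**override)], "haploid")
        assert len(retained) == 1
        assert sum(tally.values()) == 0

    def test_diploid_relaxes_homogeneity(self):
        rec = make_record(genotype_homogeneous=False)
        assert filter_variants([rec], "haploid")[0] == []
        assert len(filter_variants([rec], "diploid")[0]) == 1

    def test_empty_input(self):
        retained, tally = filter_variants([], "haploid")
        assert retained == []
        assert all(v == 0 for v in tally.values())

    def test_order_independent_and_idempotent(self, rng):
        records = [
            make_record(pos=i + 1, quality=float(q), depth_sample=int(d),
                        forward_support=min(3, int(d)),
                        reverse_support=max(0, min(int(d) - 3, 4)))
            for i, (q, d) in enumerate(zip(rng.uniform(0, 200, 50),
                                           rng.integers(0, 40, 50)))
        ]
        kept, _ = filter_variants(records, "haploid")
        shuffled = list(records)
        rng.shuffle(shuffled)
        kept_shuffled, _ = filter_variants(shuffled, "haploid")
        assert {r.identity for r in kept} == {r.identity for r in kept_shuffled}
        again, tally_again = filter_variants(kept, "haploid")
        assert again == kept
        assert sum(tally_again.values()) == 0

    def test_malformed_record_raises(self):
        bad = make_record(forward_support=20, reverse_support=20, depth_sample=30)
        with pytest.raises(MalformedRecordError):
            filter_variants([bad], "haploid")


class TestClassifyMutation:
    @pytest.mark.parametrize(
        "ref, alt, expected",
        [
            ("C", "T", "C:G>T:A"),
            ("G", "A", "C:G>T:A"),
            ("T", "C", "T:A>C:G"),
            ("A", "G", "T:A>C:G"),
            ("C", "A", "C:G>A:T"),
            ("G", "T", "C:G>A:T"),
            ("C", "G", "C:G>G:C"),
            ("T", "A", "T:A>A:T"),
            ("A", "C", "T:A>G:C"),
            ("A", "AT", "insertion"),
            ("ATT", "A", "deletion"),
        ],
    )
    def test_classes(self, ref, alt, expected):
        assert classify_mutation(ref, alt) == expected

    def test_reverse_complement_invariance(self):
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        for ref in "ACGT":
            for alt in "ACGT":
                if ref == alt:
                    continue
                assert classify_mutation(ref, alt) == classify_mutation(
                    comp[ref], comp[alt]
                )

    def test_errors(self):
        with pytest.raises(ValueError):
            classify_mutation("N", "A")
        with pytest.raises(ValueError):
            classify_mutation("A", "A")
        with pytest.raises(ValueError):
            classify_mutation("", "A")


class TestMutationRate:
    def test_zero_events(self):
        est = compute_mutation_rate(0, 10**7, 1000)
        assert est.rate == 0.0
        assert est.ci_low == 0.0
        assert est.ci_high > 0

    def test_forced_arithmetic(self):
        est = compute_mutation_rate(100, 10**7, 1000)
        assert est.rate == pytest.approx(1e-8, rel=1e-12)

    def test_garwood_interval_four_events(self):
        # exact Poisson 95% bounds on 4 events via the chi-squared relation:
        # [chi2(0.025, 8)/2, chi2(0.975, 10)/2] = [1.0899, 10.2416]
        est = compute_mutation_rate(4, 10**6, 100)
        assert est.ci_low == pytest.approx(1.0899 * 1e-8, rel=1e-4)
        assert est.ci_high == pytest.approx(10.2416 * 1e-8, rel=1e-4)
        assert est.ci_low <= est.rate <= est.ci_high

    def test_scaling(self):
        base = compute_mutation_rate(10, 10**6, 100)
        assert compute_mutation_rate(20, 10**6, 100).rate == pytest.approx(2 * base.rate)
        assert compute_mutation_rate(10, 2 * 10**6, 100).rate == pytest.approx(base.rate / 2)
        assert compute_mutation_rate(10, 10**6, 200).rate == pytest.approx(base.rate / 2)

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            compute_mutation_rate(1, 0, 100)
        with pytest.raises(ValueError):
            compute_mutation_rate(1, 100, 0)


class TestSharedMutations:
    def test_disjoint_lines(self):
        a = make_line("a", [make_record(pos=1), make_record(pos=2)])
        b = make_line("b", [make_record(pos=3), make_record(pos=4)])
        frac, hrun = shared_mutation_summary([a, b])
        assert frac == 0.0 and hrun == 0.0

    def test_identical_lines(self):
        recs = [make_record(pos=1), make_record(pos=2)]
        frac, _ = shared_mutation_summary([make_line("a", recs), make_line("b", recs)])
        assert frac == 1.0

    def test_hrun_indel_fraction(self):
        shared_indel = make_record(pos=5, ref="A", alt="AA",
                                   in_homonucleotide_run=True)
        a = make_line("a", [shared_indel, make_record(pos=1)])
        b = make_line("b", [shared_indel])
        frac, hrun = shared_mutation_summary([a, b])
        assert frac == pytest.approx(2 / 3)
        assert hrun == 1.0

    def test_single_line_rejected(self):
        with pytest.raises(ValueError):
            shared_mutation_summary([make_line("a", [])])


class TestInfrequencyTests:
    def test_observed_equals_expected(self):
        assert selection_infrequency_tests(50, 0.5, total=100) == pytest.approx(1.0)

    def test_exact_binomial_tail(self):
        # oracle: sum of binomial point masses no larger than P(X=30), n=100, p=0.5
        pm = stats.binom.pmf(np.arange(101), 100, 0.5)
        expected = pm[pm <= pm[30] * (1 + 1e-12)].sum()
        p = selection_infrequency_tests(30, 0.5, total=100)
        assert p == pytest.approx(expected, rel=1e-9)
        assert p == pytest.approx(7.85e-5, rel=5e-3)

    def test_chisq_contingency(self):
        p = selection_infrequency_tests(
            np.array([[14, 86], [16, 84]]), test="chisq"
        )
        assert 0 < p < 1

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            selection_infrequency_tests(5, 0.5, total=0)
        with pytest.raises(ValueError):
            selection_infrequency_tests(5, 1.5, total=10)


class TestGroupComparison:
    def test_identical_groups_rank_sum(self):
        assert compare_rate_groups([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_extreme_labeling_exact_p(self):
        # most extreme of C(6,3) = 20 labelings, doubled: 2/20 = 0.1
        assert compare_rate_groups([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_ttest(self):
        p = compare_rate_groups([1.0, 2.0, 3.0], [1.1, 2.1, 2.9], test="ttest")
        assert 0 < p <= 1

    def test_null_calibration(self, rng):
        """Rank-sum rejects at ~alpha under the null."""
        reps = 1500
        rejections = 0
        for _ in range(reps):
            a = rng.normal(size=10)
            b = rng.normal(size=10)
            rejections += compare_rate_groups(a, b) < 0.05
        rate = rejections / reps
        assert 0.03 < rate < 0.07

    def test_insufficient_samples(self):
        with pytest.raises(ValueError):
            compare_rate_groups([1.0], [2.0], test="ttest")
        with pytest.raises(ValueError):
            compare_rate_groups([], [1.0])
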