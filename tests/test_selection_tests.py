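"""Variance decompositions, neutrality bootstrap, and spectrum statistics."""

import numpy as np
import pytest
from scipy import stats

from mutsel import (
    SpectrumCounts,
    TraitTable,
    divergence_squared,
    genetic_variance,
    mutational_variances,
    neutrality_test,
    spectrum_chisq,
    spectrum_summary,
)


def traits(values, progenitor=None, ids=None):
    values = list(values)
    return TraitTable(ids or [f"L{i}" for i in range(len(values))],
                      np.array(values, dtype=float), progenitor)


class TestMutationalVariances:
    def test_identical_values_zero_vm(self):
        d = mutational_variances(traits([2.0, 2.0, 2.0], progenitor=2.0), 1000, 1.0)
        assert d.vm == 0.0 and d.vml == 0.0 and d.vmh == 0.0

    def test_symmetric_pair_splits_evenly(self):
        # values {p-d, p+d}: vml = vmh = d^2/(2 t_corr) by direct evaluation
        p, d, t = 1.0, 0.5, 2000.0
        dec = mutational_variances(traits([p - d, p + d, p], progenitor=p), t, 1.0)
        n = 3
        assert dec.vml == pytest.approx(d**2 / (n * t))
        assert dec.vmh == pytest.approx(d**2 / (n * t))

    @pytest.mark.parametrize(
        "fold, corrected",
        [(104.0, 119_850.0), (580.0, 667_636.0), (16.0, 18_578.0)],
    )
    def test_mutator_correction_wiring(self, fold, corrected):
        """Raw generations times the mutator fold give the corrected total."""
        raw_t = corrected / fold
        dec = mutational_variances(traits([1.0, 2.0, 3.0], progenitor=2.0), raw_t, fold)
        assert dec.corrected_generations == pytest.approx(corrected, rel=1e-9)

    def test_named_corrections(self):
        dec = mutational_variances(traits([1.0, 2.0, 3.0], progenitor=2.0),
                                   1000.0, "indel")
        assert dec.correction == "indel"
        assert dec.corrected_generations == pytest.approx(580_000.0)

    def test_additivity_to_mean_squared_deviation(self, rng):
        values = rng.normal(0.0, 1.0, 50)
        prog = 0.2
        t = 1500.0
        dec = mutational_variances(traits(values, progenitor=prog), t, 104.0)
        msd = np.mean((values - prog) ** 2) / dec.corrected_generations
        assert dec.vml + dec.vmh == pytest.approx(msd, rel=1e-12)

    def test_too_few_lines(self):
        with pytest.raises(ValueError):
            mutational_variances(traits([1.0, 2.0], progenitor=1.5), 1000, 1.0)


class TestGeneticVariance:
    def test_identical_strains(self):
        assert genetic_variance(traits([3.0, 3.0, 3.0])) == 0.0

    def test_forced_value(self):
        assert genetic_variance(traits([0.0, 1.0])) == pytest.approx(0.5)

    def test_too_few(self):
        with pytest.raises(ValueError):
            genetic_variance(traits([1.0]))


class TestDivergenceSquared:
    def test_equal_rates(self):
        assert divergence_squared(1e-10, 1e-10) == 0.0

    def test_log10_decade(self):
        assert divergence_squared(10.0, 1.0) == pytest.approx(1.0)

    def test_yeast_rates(self):
        d2 = divergence_squared(1.95e-10, 7.27e-11)
        assert d2 == pytest.approx(0.1836, abs=5e-4)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            divergence_squared(0.0, 1e-10)


class TestTraitTable:
    def test_log10_from_rates(self):
        tt = TraitTable.from_rates(["a", "b"], [1e-7, 1e-8], progenitor_rate=1e-7)
        np.testing.assert_allclose(tt.values, [-7.0, -8.0])
        assert tt.progenitor_value == pytest.approx(-7.0)
        assert tt.log10_transformed

    def test_log10_rejects_zero(self):
        with pytest.raises(ValueError):
            TraitTable.from_rates(["a", "b"], [0.0, 1e-8])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            TraitTable(["a"], np.array([1.0, 2.0]))


class TestNeutralityTest:
    def _line_traits_with_vm(self, vm, t_corr, n=45, prog=0.0):
        """Symmetric construction with exact sample variance vm * t_corr."""
        d = np.sqrt(vm * t_corr * (n - 1) / (n - (n % 2)))
        half = (n - (n % 2)) // 2
        values = np.r_[np.full(half, prog - d), np.full(half, prog + d),
                       np.full(n % 2, prog)]
        return TraitTable([f"L{i}" for i in range(n)], values, prog)

    def test_fixed_dispersion_ratio(self):
        t_corr = 119_850.0
        lt = self._line_traits_with_vm(3.4e-6, t_corr, n=44)
        res = neutrality_test(lt, t_corr / 104.0, 104.0, 4e7,
                              observed_dispersion=4.5e-2, n_boot=100, seed=0)
        assert res.vm_used == pytest.approx(3.4e-6, rel=1e-9)
        assert res.ratio == pytest.approx(4.5e-2 / 3.4e-6, rel=1e-9)
        assert res.fold_below == pytest.approx(4e7 / res.ratio, rel=1e-9)

    def test_seeded_reproducibility_and_relabeling_invariance(self):
        rng = np.random.default_rng(4)
        values = rng.normal(0, 1, 30)
        lt1 = TraitTable([f"L{i}" for i in range(30)], values, 0.0)
        lt2 = TraitTable([f"X{i}" for i in range(30)], values, 0.0)
        kw = dict(raw_generations=1000.0, fold=1.0, neutral_expectation=10.0,
                  observed_dispersion=5e-3, n_boot=2000, seed=42)
        assert neutrality_test(lt1, **kw).p_value == neutrality_test(lt2, **kw).p_value

    def test_strain_resampling_branch(self):
        rng = np.random.default_rng(5)
        lt = TraitTable([f"L{i}" for i in range(40)], rng.normal(0, 1, 40), 0.0)
        st = TraitTable([f"S{i}" for i in range(7)], rng.normal(0, 0.1, 7))
        res = neutrality_test(lt, 1000.0, 1.0, 4e7, strain_traits=st,
                              n_boot=500, seed=1)
        assert res.observed_dispersion == pytest.approx(
            float(np.var(st.values, ddof=1))
        )
        assert 0.0 <= res.p_value <= 1.0

    def test_degenerate_bootstrap_counts_as_exceeding(self):
        # two distinct values: some replicates resample one value only (vm = 0)
        values = np.array([0.0] * 28 + [1.0, 1.0])
        lt = TraitTable([f"L{i}" for i in range(30)], values, 0.5)
        res = neutrality_test(lt, 1000.0, 1.0, 1e30,
                              observed_dispersion=1.0, n_boot=4000, seed=3)
        # only the vm=0 replicates can exceed 1e30, and some must occur
        assert res.p_value > 0.0

    def test_invalid_arguments(self):
        lt = traits([1.0, 2.0, 3.0], progenitor=2.0)
        with pytest.raises(ValueError):
            neutrality_test(lt, 1000.0, 1.0, 4e7, observed_dispersion=1.0,
                            component="vx")
        with pytest.raises(ValueError):
            neutrality_test(lt, 1000.0, 1.0, 4e7)


class TestSpectrum:
    def test_equal_snv_classes_ts_tv_half(self):
        counts = SpectrumCounts((10, 10, 10, 10, 10, 10), 0, 0)
        out = spectrum_summary(counts)
        assert out["ts_tv"] == pytest.approx(0.5)
        assert out["gc_at_over_at_gc"] == pytest.approx(1.0)

    def test_partition_fractions(self):
        out = spectrum_summary(SpectrumCounts((10, 0, 0, 0, 0, 0), 5, 5))
        assert out["frac_snv"] == pytest.approx(0.5)
        assert out["frac_insertion"] == pytest.approx(0.25)
        assert out["frac_deletion"] == pytest.approx(0.25)

    def test_zero_denominator_is_nan_not_error(self):
        out = spectrum_summary(SpectrumCounts((5, 0, 0, 0, 0, 0), 1, 0))
        assert np.isnan(out["gc_at_over_at_gc"])

    def test_chisq_identical(self):
        c = SpectrumCounts((10, 20, 5, 5, 5, 5), 30, 20)
        assert spectrum_chisq(c, c) == pytest.approx(1.0)

    def test_chisq_proportional_tables(self):
        a = SpectrumCounts((10, 20, 5, 5, 5, 5), 30, 20)
        b = SpectrumCounts((30, 60, 15, 15, 15, 15), 90, 60)
        assert spectrum_chisq(a, b) == pytest.approx(1.0)

    def test_chisq_extreme_2x2(self):
        # Pearson statistic for {{10,90},{90,10}} is 128 by hand
        a = SpectrumCounts((10, 90, 0, 0, 0, 0), 0, 0)
        b = SpectrumCounts((90, 10, 0, 0, 0, 0), 0, 0)
        p = spectrum_chisq(a, b, partition="gc_at")
        assert p == pytest.approx(float(stats.chi2.sf(128.0, 1)), rel=1e-9)
        assert p < 1e-28

    def test_invalid_partition(self):
        c = SpectrumCounts((1, 1, 1, 1, 1, 1), 1, 1)
        with pytest.raises(ValueError):
            spectrum_chisq(c, c, partition="indel_only")
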