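"""Variant retention filters, per-line mutation rates, and selection checks.

Mutation-accumulation (MA) experiments call candidate mutations per line
against the ancestral strain. Before any rate is computed, candidates pass a
small set of hard retention criteria (genotype homogeneity on haploids,
minimum read depth in both line and ancestor, support on both strands, a
minimum quality score). Retained mutations are classified into the six
strand-collapsed SNV classes plus insertions and deletions, and converted to
per-site per-generation rates with exact Poisson confidence intervals.

The module also carries the small statistical checks used to confirm that
selection was infrequent during MA (binomial / chi-squared tests of genic and
nonsynonymous fractions) and the standard two-group rate comparisons
(Wilcoxon rank-sum, t-test).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SNV_CLASSES",
    "MUTATION_CLASSES",
    "VariantRecord",
    "MALine",
    "RateEstimate",
    "MalformedRecordError",
    "filter_variants",
    "classify_mutation",
    "compute_mutation_rate",
    "shared_mutation_summary",
    "selection_infrequency_tests",
    "compare_rate_groups",
]

#: Strand-collapsed SNV classes; the first two are transitions.
SNV_CLASSES = (
    "C:G>T:A",
    "T:A>C:G",
    "C:G>A:T",
    "C:G>G:C",
    "T:A>A:T",
    "T:A>G:C",
)

#: Full 8-class mutation partition (6 SNV classes + indels).
MUTATION_CLASSES = SNV_CLASSES + ("insertion", "deletion")

#: Retention thresholds: depth >= 5 in line and ancestor, >= 1 read on each
#: strand, quality >= 50 (inclusive), indels < 50 nt.
MIN_DEPTH = 5
MIN_STRAND_SUPPORT = 1
MIN_QUALITY = 50.0
MAX_INDEL_LEN = 50


class MalformedRecordError(ValueError):
    """A variant record violates a structural invariant; names the field."""


@dataclass(frozen=True)
class VariantRecord:
    """One candidate mutation in an MA line relative to its ancestor."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    depth_sample: int
    depth_ancestor: int
    forward_support: int
    reverse_support: int
    quality: float
    genotype_homogeneous: bool = True
    in_homonucleotide_run: bool = False
    genic: bool = False
    coding_effect: str = "none"  # none | synonymous | nonsynonymous

    def validate(self) -> None:
        if self.pos < 1:
            raise MalformedRecordError(f"pos must be >= 1, got {self.pos}")
        for name in ("depth_sample", "depth_ancestor", "forward_support", "reverse_support"):
            if getattr(self, name) < 0:
                raise MalformedRecordError(f"{name} must be >= 0")
        if self.forward_support + self.reverse_support > self.depth_sample:
            raise MalformedRecordError(
                "forward_support + reverse_support exceeds depth_sample"
            )
        if not self.ref or not self.alt:
            raise MalformedRecordError("ref and alt must be nonempty")

    @property
    def identity(self) -> tuple[str, int, str, str]:
        """Mutation identity used for cross-line sharing: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


@dataclass
class MALine:
    """One mutation-accumulation line with its retained variants."""

    line_id: str
    generations: float
    callable_sites: int
    variants: list[VariantRecord] = field(default_factory=list)
    ploidy: str = "haploid"  # haploid | diploid

    def __post_init__(self) -> None:
        if self.callable_sites <= 0:
            raise ValueError("callable_sites must be positive")
        if self.generations <= 0:
            raise ValueError("generations must be positive")
        if self.ploidy not in ("haploid", "diploid"):
            raise ValueError(f"unknown ploidy {self.ploidy!r}")

    @property
    def counts_by_class(self) -> dict[str, int]:
        counts = {cls: 0 for cls in MUTATION_CLASSES}
        for rec in self.variants:
            counts[classify_mutation(rec.ref, rec.alt)] += 1
        return counts

    @property
    def n_mutations(self) -> int:
        return len(self.variants)


@dataclass(frozen=True)
class RateEstimate:
    """Per-site per-generation mutation rate with an exact Poisson 95% CI."""

    rate: float
    ci_low: float
    ci_high: float
    n_events: int


# Filter criteria in first-fail tally order; haploid homogeneity first as in
# the retention rules.
_FILTER_ORDER = ("homogeneous", "depth", "strand", "quality", "indel_length")


def _first_failure(rec: VariantRecord, ploidy: str) -> str | None:
    if ploidy == "haploid" and not rec.genotype_homogeneous:
        return "homogeneous"
    if rec.depth_sample < MIN_DEPTH or rec.depth_ancestor < MIN_DEPTH:
        return "depth"
    if rec.forward_support < MIN_STRAND_SUPPORT or rec.reverse_support < MIN_STRAND_SUPPORT:
        return "strand"
    if rec.quality < MIN_QUALITY:
        return "quality"
    if abs(len(rec.alt) - len(rec.ref)) >= MAX_INDEL_LEN:
        return "indel_length"
    return None


def filter_variants(
    records: list[VariantRecord], ploidy: str = "haploid"
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Apply the retention criteria; return (retained, first-failure tally).

    A record is retained iff it is genotype-homogeneous (haploid lines only;
    diploid lines may legitimately carry heterozygous calls), covered by at
    least five reads in both the line and the ancestor, supported by at least
    one forward and one reverse read, has quality >= 50, and — for indels —
    a length difference below 50 nt. The tally reports the first failing
    criterion for each rejected record.
    """
    if ploidy not in ("haploid", "diploid"):
        raise ValueError(f"unknown ploidy {ploidy!r}")
    retained: list[VariantRecord] = []
    tally = {name: 0 for name in _FILTER_ORDER}
    for rec in records:
        rec.validate()
        failure = _first_failure(rec, ploidy)
        if failure is None:
            retained.append(rec)
        else:
            tally[failure] += 1
    return retained, tally


_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# Strand-collapsed lookup: pyrimidine-context key per (ref, alt) base pair.
_SNV_CLASS_BY_PAIR = {
    ("C", "T"): "C:G>T:A",
    ("G", "A"): "C:G>T:A",
    ("T", "C"): "T:A>C:G",
    ("A", "G"): "T:A>C:G",
    ("C", "A"): "C:G>A:T",
    ("G", "T"): "C:G>A:T",
    ("C", "G"): "C:G>G:C",
    ("G", "C"): "C:G>G:C",
    ("T", "A"): "T:A>A:T",
    ("A", "T"): "T:A>A:T",
    ("T", "G"): "T:A>G:C",
    ("A", "C"): "T:A>G:C",
}


def classify_mutation(ref: str, alt: str) -> str:
    """Map a ref/alt pair to one of the 8 mutation classes.

    Single-base substitutions collapse by strand symmetry into six classes
    (e.g. C>T and G>A are the same C:G>T:A class, which counts toward GC→AT);
    length changes are insertions or deletions.
    """
    if not ref or not alt or ref == alt:
        raise ValueError("ref and alt must be nonempty and different")
    if any(b not in _COMPLEMENT for b in ref + alt):
        raise ValueError(f"non-ACGT characters in {ref!r}>{alt!r}")
    if len(ref) == 1 and len(alt) == 1:
        return _SNV_CLASS_BY_PAIR[(ref, alt)]
    if len(alt) > len(ref):
        return "insertion"
    if len(alt) < len(ref):
        return "deletion"
    # equal-length multi-nucleotide substitution: classify by first difference
    for r, a in zip(ref, alt):
        if r != a:
            return _SNV_CLASS_BY_PAIR[(r, a)]
    raise ValueError("ref and alt differ in length bookkeeping only")


def poisson_ci(n_events: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) Poisson CI on an event count via chi-squared quantiles."""
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    alpha = 1.0 - conf
    low = 0.0 if n_events == 0 else stats.chi2.ppf(alpha / 2, 2 * n_events) / 2.0
    high = stats.chi2.ppf(1 - alpha / 2, 2 * n_events + 2) / 2.0
    return low, high


def compute_mutation_rate(
    n_mutations: int, callable_sites: int, generations: float
) -> RateEstimate:
    """Rate = mutations / callable sites / generations, with exact Poisson CI."""
    if callable_sites <= 0 or generations <= 0:
        raise ValueError("callable_sites and generations must be positive")
    if n_mutations < 0:
        raise ValueError("n_mutations must be >= 0")
    denom = callable_sites * generations
    low, high = poisson_ci(n_mutations)
    return RateEstimate(
        rate=n_mutations / denom,
        ci_low=low / denom,
        ci_high=high / denom,
        n_events=n_mutations,
    )


def shared_mutation_summary(lines: list[MALine]) -> tuple[float, float]:
    """Fraction of mutations shared by >= 2 lines, and the homonucleotide-run
    indel fraction among those shared mutations.

    Mutation identity is (chrom, pos, ref, alt). The first fraction is over
    mutation occurrences (each variant record counts once); recurrent slippage
    indels in homonucleotide runs are the expected dominant component of
    sharing in mismatch-repair-deficient lines.
    """
    if len(lines) < 2:
        raise ValueError("shared_mutation_summary requires >= 2 lines")
    line_sets = [{rec.identity for rec in line.variants} for line in lines]
    appearances = Counter(ident for s in line_sets for ident in s)
    total = sum(len(line.variants) for line in lines)
    if total == 0:
        return 0.0, 0.0
    shared_occurrences = 0
    shared_hrun_indels = 0
    for line in lines:
        for rec in line.variants:
            if appearances[rec.identity] >= 2:
                shared_occurrences += 1
                if rec.is_indel and rec.in_homonucleotide_run:
                    shared_hrun_indels += 1
    frac_shared = shared_occurrences / total
    frac_hrun = shared_hrun_indels / shared_occurrences if shared_occurrences else 0.0
    return frac_shared, frac_hrun


def selection_infrequency_tests(
    observed: int | np.ndarray,
    expected_fraction: float | None = None,
    total: int | None = None,
    test: str = "binomial",
) -> float:
    """Tests that mutations fall where chance predicts (selection infrequent).

    ``binomial``: two-sided exact binomial P for ``observed`` successes out of
    ``total`` against ``expected_fraction`` (e.g. the genic fraction of SNVs
    against the genic fraction of the genome). ``chisq``: Pearson chi-squared
    P on a 2x2 contingency table passed as ``observed``.
    """
    if test == "binomial":
        if total is None or expected_fraction is None:
            raise ValueError("binomial test needs observed, total, expected_fraction")
        if total <= 0:
            raise ValueError("total must be positive")
        if not 0 < expected_fraction < 1:
            raise ValueError("expected_fraction must be in (0, 1)")
        return stats.binomtest(int(observed), int(total), expected_fraction).pvalue
    if test == "chisq":
        table = np.asarray(observed, dtype=float)
        if table.size == 0 or table.sum() == 0:
            raise ValueError("empty contingency table")
        return stats.chi2_contingency(table, correction=False).pvalue
    raise ValueError(f"unknown test {test!r}")


def compare_rate_groups(rates_a, rates_b, test: str = "wilcoxon") -> float:
    """Two-sided P comparing two groups of rates.

    ``wilcoxon``: exact Wilcoxon rank-sum (Mann-Whitney) where sample sizes
    permit; ``ttest``: Welch-free two-sample t-test (equal variance, the
    classical form).
    """
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if test == "wilcoxon":
        if len(a) < 1 or len(b) < 1:
            raise ValueError("rank-sum test needs >= 1 value per group")
        return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    if test == "ttest":
        if len(a) < 2 or len(b) < 2:
            raise ValueError("t-test needs >= 2 values per group")
        return float(stats.ttest_ind(a, b).pvalue)
    raise ValueError(f"unknown test {test!r}")
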