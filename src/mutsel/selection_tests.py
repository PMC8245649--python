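"""Neutrality tests of mutation rate and spectrum.

The central question: is a trait of the mutation process (the rate mu, or a
component of the mutation spectrum) evolving neutrally, or is it held by
stabilizing selection? For a neutral quantitative trait in a primarily
asexual diploid, the standing genetic variance among natural strains (Vg)
should equal 4*Ne times the variance injected by new mutations per
generation (Vm, estimated from mutation-accumulation line dispersion); the
squared interspecific divergence D^2 should equal Vm*T, where T is the number
of generations separating the species. Ratios Vg/Vm or D^2/Vm far below
4*Ne or T indicate stabilizing selection.

Because MA in a mutator (mismatch-repair-deficient) background accumulates
mutations faster than wild type, the MA generation count is inflated by the
mutator's fold increase before Vm is computed: the corrected number of
generations is (mean raw t) * fold, where fold is 104x (total SNV+indel
rate), 580x (indel rate), or 16x (SNV rate), giving the three variants
Vm1/Vm2/Vm3. Vm splits directionally into VmL and VmH — squared deviations
from the progenitor trait summed over lines below (above) the progenitor,
divided by the total line count times corrected generations — so VmL + VmH
equals the mean squared deviation from the progenitor per corrected
generation.

Significance comes from a bootstrap: MA lines (and natural strains, where
applicable) are resampled with replacement at the original sizes; P is the
fraction of replicates whose ratio exceeds the neutral expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .variant_filtering import SNV_CLASSES

__all__ = [
    "CORRECTION_FOLDS",
    "TraitTable",
    "VarianceDecomposition",
    "NeutralityResult",
    "SpectrumCounts",
    "mutational_variances",
    "genetic_variance",
    "divergence_squared",
    "neutrality_test",
    "spectrum_summary",
    "spectrum_chisq",
]

#: Mutator-background correction folds: fold increase caused by deleting the
#: mismatch-repair gene, by which the raw MA generation count is multiplied.
CORRECTION_FOLDS = {"total": 104.0, "indel": 580.0, "snv": 16.0, "none": 1.0}


@dataclass
class TraitTable:
    """Trait values (rate or spectrum statistic) per MA line or strain."""

    entity_ids: list[str]
    values: np.ndarray
    progenitor_value: float | None = None
    log10_transformed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.entity_ids) != len(self.values):
            raise ValueError("one value per entity required")

    @classmethod
    def from_rates(
        cls, entity_ids, rates, progenitor_rate=None, log10: bool = True
    ) -> "TraitTable":
        """Build a trait table from raw rates, optionally log10-transformed.

        Rates are not normally distributed across lines, so the default is to
        work on log10 rates (zero-rate entities must have been handled
        upstream by the one-colony substitution rule).
        """
        rates = np.asarray(rates, dtype=float)
        if log10:
            if np.any(rates <= 0):
                raise ValueError("log10 transform requires positive rates")
            values = np.log10(rates)
            prog = None if progenitor_rate is None else float(np.log10(progenitor_rate))
        else:
            values = rates
            prog = None if progenitor_rate is None else float(progenitor_rate)
        return cls(list(entity_ids), values, prog, log10_transformed=log10)


@dataclass(frozen=True)
class VarianceDecomposition:
    vm: float
    vml: float
    vmh: float
    correction: str
    corrected_generations: float
    n_lines: int


@dataclass(frozen=True)
class NeutralityResult:
    observed_dispersion: float
    vm_used: float
    vm_label: str
    ratio: float
    neutral_expectation: float
    fold_below: float
    p_value: float
    n_boot: int
    seed: int


@dataclass(frozen=True)
class SpectrumCounts:
    """Counts of the six SNV classes plus insertions and deletions."""

    snv: tuple[int, ...]
    insertions: int
    deletions: int

    def __post_init__(self) -> None:
        if len(self.snv) != 6 or any(c < 0 for c in self.snv):
            raise ValueError("snv must be 6 nonnegative counts")
        if self.insertions < 0 or self.deletions < 0:
            raise ValueError("indel counts must be >= 0")

    @classmethod
    def from_class_counts(cls, counts: dict[str, int]) -> "SpectrumCounts":
        return cls(
            snv=tuple(counts[c] for c in SNV_CLASSES),
            insertions=counts["insertion"],
            deletions=counts["deletion"],
        )

    @property
    def n_snv(self) -> int:
        return sum(self.snv)

    @property
    def total(self) -> int:
        return self.n_snv + self.insertions + self.deletions


def _vm_components(
    values: np.ndarray, progenitor: float, t_corr: float
) -> tuple[float, float, float]:
    n = len(values)
    vm = float(np.var(values, ddof=1)) / t_corr
    dev2 = (values - progenitor) ** 2
    vml = float(dev2[values < progenitor].sum()) / (n * t_corr)
    vmh = float(dev2[values > progenitor].sum()) / (n * t_corr)
    return vm, vml, vmh


def mutational_variances(
    traits: TraitTable,
    raw_generations,
    fold: float | str = "none",
) -> VarianceDecomposition:
    """Vm / VmL / VmH per corrected generation.

    ``fold`` is either a named mutator correction ('total', 'indel', 'snv',
    'none') or a numeric fold factor; corrected generations = mean(raw t)
    * fold. Vm is the (n-1)-denominator sample variance of trait values per
    corrected generation. VmL (VmH) sums squared deviations from the
    progenitor over lines below (above) it, divided by total line count times
    corrected generations.
    """
    values = traits.values
    if len(values) < 3:
        raise ValueError("mutational_variances requires >= 3 lines")
    if traits.progenitor_value is None:
        raise ValueError("trait table must carry a progenitor value")
    label = fold if isinstance(fold, str) else f"{fold:g}x"
    fold_value = CORRECTION_FOLDS[fold] if isinstance(fold, str) else float(fold)
    if fold_value <= 0:
        raise ValueError("fold must be > 0")
    t_corr = float(np.mean(np.asarray(raw_generations, dtype=float))) * fold_value
    vm, vml, vmh = _vm_components(values, traits.progenitor_value, t_corr)
    return VarianceDecomposition(
        vm=vm, vml=vml, vmh=vmh, correction=label,
        corrected_generations=t_corr, n_lines=len(values),
    )


def genetic_variance(natural_traits: TraitTable) -> float:
    """Standing variance Vg: sample variance (n-1) across natural strains."""
    if len(natural_traits.values) < 2:
        raise ValueError("genetic_variance requires >= 2 strains")
    return float(np.var(natural_traits.values, ddof=1))


def divergence_squared(rate_a: float, rate_b: float, log10: bool = True) -> float:
    """Squared interspecific trait difference D^2 (optionally on log10 rates)."""
    if log10:
        if rate_a <= 0 or rate_b <= 0:
            raise ValueError("log10 requires positive rates")
        return float((np.log10(rate_a) - np.log10(rate_b)) ** 2)
    return float((rate_a - rate_b) ** 2)


def neutrality_test(
    line_traits: TraitTable,
    raw_generations,
    fold: float | str,
    neutral_expectation: float,
    strain_traits: TraitTable | None = None,
    observed_dispersion: float | None = None,
    component: str = "vm",
    n_boot: int = 10_000,
    seed: int = 0,
) -> NeutralityResult:
    """Bootstrap test of Vg/Vm (or D^2/Vm) against its neutral expectation.

    When ``strain_traits`` is given, the dispersion is Vg recomputed per
    bootstrap replicate (strains resampled independently of lines); otherwise
    ``observed_dispersion`` (e.g. D^2) is held fixed. ``component`` selects
    vm, vml, or vmh. P is the fraction of replicates whose ratio exceeds
    (strictly) the neutral expectation; replicates with a zero variance
    component count as exceeding (ratio +inf).
    """
    if component not in ("vm", "vml", "vmh"):
        raise ValueError(f"unknown component {component!r}")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if strain_traits is None and observed_dispersion is None:
        raise ValueError("need strain_traits or a fixed observed_dispersion")

    decomp = mutational_variances(line_traits, raw_generations, fold)
    vm_obs = getattr(decomp, component)
    if vm_obs <= 0:
        raise ValueError(f"observed {component} must be > 0")
    disp_obs = (
        genetic_variance(strain_traits) if strain_traits is not None
        else float(observed_dispersion)
    )
    ratio = disp_obs / vm_obs

    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    values = line_traits.values
    prog = line_traits.progenitor_value
    t_corr = decomp.corrected_generations
    n = len(values)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = values[idx]
    if component == "vm":
        vm_boot = boot.var(axis=1, ddof=1) / t_corr
    else:
        dev2 = (boot - prog) ** 2
        mask = boot < prog if component == "vml" else boot > prog
        vm_boot = (dev2 * mask).sum(axis=1) / (n * t_corr)
    if strain_traits is not None:
        sv = strain_traits.values
        ns = len(sv)
        sidx = rng.integers(0, ns, size=(n_boot, ns))
        disp_boot = sv[sidx].var(axis=1, ddof=1)
    else:
        disp_boot = np.full(n_boot, disp_obs)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_boot = np.where(vm_boot > 0, disp_boot / vm_boot, np.inf)
    p = float(np.mean(ratio_boot > neutral_expectation))
    return NeutralityResult(
        observed_dispersion=disp_obs,
        vm_used=vm_obs,
        vm_label=f"{component}:{decomp.correction}",
        ratio=ratio,
        neutral_expectation=neutral_expectation,
        fold_below=neutral_expectation / ratio,
        p_value=p,
        n_boot=n_boot,
        seed=seed,
    )


def spectrum_summary(counts: SpectrumCounts) -> dict:
    """Spectrum statistics: partition fractions, Ts/Tv, GC->AT / AT->GC.

    Transitions are C:G>T:A and T:A>C:G; the remaining four SNV classes are
    transversions, so Ts/Tv = 0.5 under equal class rates. GC->AT counts are
    C:G>T:A, AT->GC are T:A>C:G. Ratios with a zero denominator are reported
    as NaN rather than raising.
    """
    total = counts.total
    if total == 0:
        raise ValueError("spectrum_summary requires at least one mutation")
    snv = np.array(counts.snv, dtype=float)
    ts = snv[0] + snv[1]
    tv = snv[2:].sum()
    out = {
        "frac_snv": counts.n_snv / total,
        "frac_insertion": counts.insertions / total,
        "frac_deletion": counts.deletions / total,
        "snv_fractions": tuple(snv / counts.n_snv) if counts.n_snv else (np.nan,) * 6,
        "ts_tv": ts / tv if tv > 0 else np.nan,
        "gc_at_over_at_gc": snv[0] / snv[1] if snv[1] > 0 else np.nan,
    }
    return out


_PARTITIONS = {
    "snv_indel": lambda c: [c.n_snv, c.insertions + c.deletions],
    "six_snv": lambda c: list(c.snv),
    "ts_tv": lambda c: [c.snv[0] + c.snv[1], sum(c.snv[2:])],
    "gc_at": lambda c: [c.snv[0], c.snv[1]],
}


def spectrum_chisq(
    strain: SpectrumCounts, progenitor: SpectrumCounts, partition: str = "six_snv"
) -> float:
    """Pearson chi-squared P comparing a strain's spectrum to the progenitor.

    Builds the 2 x k contingency table for the named partition (no continuity
    correction). Proportional tables give chi2 = 0, P = 1.
    """
    if partition not in _PARTITIONS:
        raise ValueError(f"unknown partition {partition!r}")
    rows = np.array([_PARTITIONS[partition](strain), _PARTITIONS[partition](progenitor)],
                    dtype=float)
    keep = rows.sum(axis=0) > 0
    rows = rows[:, keep]
    if rows.shape[1] < 2 or rows.sum() == 0 or np.any(rows.sum(axis=1) == 0):
        raise ValueError("contingency table degenerate for this partition")
    return float(stats.chi2_contingency(rows, correction=False).pvalue)
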