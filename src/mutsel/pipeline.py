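"""End-to-end synthetic study orchestration.

Runs the full flow on generated data: simulate MA lines and fluctuation
assays, round-trip the variants through VCF and the retention filters,
estimate rates and spectra, run the neutrality tests against a simulated
panel of natural strains, and compute the drift-barrier report. Deterministic
given (seed, parameters); reports carry the seed and package version.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import __version__, io
from .drift_barrier import barrier_excess_report
from .fluctuation import FluctuationAssay, estimate_mutations_per_culture
from .selection_tests import (
    SpectrumCounts,
    TraitTable,
    neutrality_test,
    spectrum_summary,
)
from .synthetic_data import (
    SimConfig,
    simulate_fluctuation_counts,
    simulate_ma_lines,
    simulate_natural_traits,
)
from .variant_filtering import compute_mutation_rate, filter_variants

# Study-scale defaults: 44 haploid lines with rate traits, 7 natural strains,
# t = 1511 raw generations, Ne = 1.17e7, modifier sd 0.3 on log10 rate.
_NE = 1.17e7


def run_analysis(
    seed: int = 0,
    n_boot: int = 10_000,
    out_dir: Path | None = None,
    n_lines: int = 44,
    n_strains: int = 7,
    mode: str = "stabilizing",
    shrink: float = 540.0,
) -> dict:
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    # 1. MA lines with modifier variance; VCF round-trip and filtering
    config = SimConfig(seed=seed, n_lines=min(n_lines, 20), modifier_sd=0.3,
                       shared_indel_prob=0.5)
    lines = simulate_ma_lines(config)
    if out_dir is not None:
        io.write_ma_metadata(lines, out_dir / "ma_metadata.tsv")
        io.write_line_vcf(lines[0], out_dir / f"{lines[0].line_id}.vcf")
        reread = io.read_line_vcf(out_dir / f"{lines[0].line_id}.vcf")
    else:
        reread = lines[0].variants
    retained, tally = filter_variants(list(reread), lines[0].ploidy)
    rate0 = compute_mutation_rate(len(retained), lines[0].callable_sites,
                                  lines[0].generations)

    # 2. aggregate spectrum
    totals = {cls: 0 for cls in lines[0].counts_by_class}
    for line in lines:
        for cls, cnt in line.counts_by_class.items():
            totals[cls] += cnt
    spectrum = spectrum_summary(SpectrumCounts.from_class_counts(totals))

    # 3. fluctuation assay on the first line's trait scale
    counts = simulate_fluctuation_counts(
        mu_per_division=2.0 / 2.2e7, n0=1000, nt=2.2e7, z=1.0,
        n_cultures=72, seed=seed + 1,
    )
    est = estimate_mutations_per_culture(
        FluctuationAssay(tuple(int(c) for c in counts), n0=1000, nt=2.2e7)
    )

    # 4. neutrality test on simulated line and strain traits
    rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
    t_raw = 1511.0
    sd_line = 0.3
    prog = -7.0
    line_rates = prog + rng.normal(0.0, sd_line, n_lines)
    vm_true = sd_line**2 / (t_raw * 104.0)
    strains = simulate_natural_traits(
        n_strains, ne=_NE, vm=vm_true, mode=mode, shrink=shrink,
        seed=seed + 2, ancestral_mean=prog,
    )
    line_tt = TraitTable([f"MA{i}" for i in range(n_lines)], line_rates,
                         progenitor_value=prog, log10_transformed=True)
    strain_tt = TraitTable([f"S{i}" for i in range(n_strains)], strains,
                           log10_transformed=True)
    neutral = neutrality_test(
        line_tt, t_raw, "total", 4.0 * _NE,
        strain_traits=strain_tt, n_boot=n_boot, seed=seed,
    )

    # 5. drift-barrier report from the bundled species table
    barrier = barrier_excess_report()

    report = {
        "seed": seed,
        "version": __version__,
        "n_variants_retained_line0": len(retained),
        "rejections_line0": tally,
        "rate_line0": rate0.rate,
        "spectrum": {k: v for k, v in spectrum.items() if k != "snv_fractions"},
        "fluctuation_m_hat": est.m_hat,
        "fluctuation_freq": est.freq,
        "vg_over_vm": neutral.ratio,
        "neutral_expectation": neutral.neutral_expectation,
        "fold_below_neutral": neutral.fold_below,
        "p_value": neutral.p_value,
        "barrier_excess_yeast": float(
            barrier.loc[barrier["name"] == "Saccharomyces cerevisiae", "excess"].iloc[0]
        ),
    }
    if out_dir is not None:
        barrier.to_csv(out_dir / "barrier_report.tsv", sep="\t", index=False)
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, default=float) + "\n"
        )
    return report
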