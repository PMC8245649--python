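# mutsel

Is the mutation rate as low as selection can make it, or is it held at an
intermediate value by stabilizing selection? `mutsel` implements the
computational machinery needed to ask that question of a budding-yeast
mutation-accumulation (MA) study — and answers it on fully synthetic data
with the same statistical structure, so every step is testable without any
sequencing data.

The package covers five stages:

1. **Fluctuation tests** (`mutsel.fluctuation`) — the Luria–Delbrück mutant
   count distribution under the Lea–Coulson model, with a closed-form
   plating-efficiency generalization; maximum-likelihood estimation of the
   expected mutations per culture *m* with profile-likelihood CIs; the
   per-cell-division mutation frequency *m*/(N_t − N_0); CI-overlap strain
   comparison.
2. **Variant filtering and rates** (`mutsel.variant_filtering`) — the MA-line
   retention criteria (genotype homogeneity, depth ≥ 5 in line and ancestor,
   both strands, quality ≥ 50), the eight strand-collapsed mutation classes,
   per-site per-generation rates μ = n / (callable sites × generations) with
   exact (Garwood) Poisson CIs, shared-mutation summaries, and the
   binomial/chi-squared checks that selection during MA was infrequent.
3. **Neutrality tests** (`mutsel.selection_tests`) — the core inference. For
   a neutral trait in an asexual diploid, V_g/V_m = 4N_e and D²/V_m = T,
   where V_m is the mutational variance per generation from MA-line
   dispersion (with mutator-background corrections 104×/580×/16× on the
   generation count), V_g the standing variance among natural strains, D²
   the squared interspecific log₁₀-rate difference, and T the number of
   generations separating the species. Ratios far below the expectation
   indicate stabilizing selection; significance comes from bootstrapping
   lines and strains 10,000 times. Directional components V_mL/V_mH split
   V_m by lines below/above the progenitor. Spectrum statistics (SNV/indel
   fractions, Ts/Tv, GC→AT/AT→GC) get the same treatment.
4. **Drift barriers** (`mutsel.drift_barrier`) — N_e = π_S/(4μ), the
   bottleneck N_e of an MA line, interspecific generation counts, the
   drift-barrier floor U₀ by reproductive mode (10/N_e haploid asexual,
   5/N_e diploid asexual, ≤1500/N_e sexual), observed U = μG, and the
   optimal-U simulation (harmonic mean of gamma-distributed selection
   coefficients above 1/N_e).
5. **Synthetic data** (`mutsel.synthetic_data`) — seeded generators for
   every input above: Lea–Coulson fluctuation counts, MA lines with
   modifier-induced rate variance and recurrent homonucleotide-run indels,
   filter-exercising VCF records with ground-truth labels, and natural-strain
   traits with variance 4N_e·V_m (neutral) or shrunk (stabilizing).

## Worked example

The numbered scripts under `analysis/` run the synthetic study end to end and
write their tables under `results/`. For example:

```sh
$ python analysis/01_simulate_study.py 1
simulated 93 MA lines over 1511 generations; mutations per line: mean 987 (min 67, max 4074)
fluctuation assay: 72 cultures, 7% with zero mutants, max count 455
natural strains: 7 log10-rate traits, sd 0.229 (stabilized 540-fold below the neutral expectation)

$ python analysis/02_fluctuation_estimates.py 1
m_hat = 2.391 (true 2.0), 95% CI [1.925, 2.916]
per-division mutation frequency = 1.087e-07 [8.749e-08, 1.326e-07]
recovery at m=2 over 200 replicate assays: relative bias +0.20%, CI coverage 99.0%

$ python analysis/04_selection_tests.py 1
Vg (7 stabilized strains) = 5.234e-02
Vg/Vm (total correction) = 7.18e+04, 651-fold below 4Ne = 4.7e+07, bootstrap P = 0.0000
D^2 = 0.184; D^2/Vm = 2.52e+05, 11467-fold below T = 2.89e9, bootstrap P = 0.0000
neutral-null calibration (50 worlds, 30 strains): 4% of worlds significant at alpha = 0.01
```

Reading the output: the fluctuation fit recovers the true *m* = 2 inside its
CI; the simulated natural strains carry far less rate variance than neutral
drift would accumulate (hundreds of fold below 4N_e, bootstrap P ≈ 0), which
is the signature of stabilizing selection the test is built to detect; and
under a genuinely neutral simulation the test rejects at roughly its nominal
rate. `analysis/05_drift_barrier.py` prints the species table — the yeast
genomic rate U = 1.7×10⁻³ sits 3400-fold above its drift barrier
U₀ = 5×10⁻⁷ — and `analysis/06_optimal_u.py` shows the optimal U declining
monotonically with N_e.

A `mutsel` console command exposes the same stages
(`mutsel simulate | filter | fluctuation | neutrality | barrier | optimal-u |
full`); see `mutsel --help`.

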