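# Methods

## The model and what is being tested

The package treats the mutation rate μ (and components of the mutation
spectrum) as a quantitative trait and asks what kind of selection acts on it.
Under neutral evolution of a trait in a primarily asexual diploid, the
standing genetic variance among natural strains satisfies V_g = 4N_e·V_m,
where V_m is the variance newly injected per generation, estimated from the
dispersion of mutation-accumulation (MA) lines; between two species separated
by T generations, the squared trait difference satisfies D² = V_m·T. Observed
ratios V_g/V_m or D²/V_m far below 4N_e or T imply stabilizing selection.
The package computes every ingredient of that comparison and, separately,
the drift-barrier arithmetic that locates the theoretical floor of the
genomic mutation rate.

## Fluctuation analysis

**Model.** Lea–Coulson: host growth is deterministic exponential from N₀ to
N_t cells; mutational events per culture are Poisson with mean
m = μ_division·(N_t − N₀); an event occurring uniformly on the growth
trajectory founds a clone whose final size follows P(K = k) = 1/(k(k+1)).
The mutant count per culture is compound Poisson with that clone-size law.

**Plating efficiency.** Each mutant cell is observed independently with
probability z. Binomial thinning composes with the clone-size pgf in closed
form: with d = 1 − z(1 − s), the per-event pgf of the observed clone size is
g(s) = 1 + ((1 − d)/d)·log(1 − d). The apparent pole at d = 0 is removable,
so g is analytic on the unit disc; its Taylor coefficients q_j are computed
by the Cauchy integral as an FFT over a circle of radius just below 1
(naive power-series division is exponentially unstable for z > 1/2, which is
the experimentally relevant regime). The pmf follows from the Panjer
recursion p_n = (m/n)·Σ_{j=1..n} j·q_j·p_{n−j}, p₀ = exp(−m(1 − q₀)); at
z = 1 this is the classical Ma–Sandri–Sarkar recursion with q_j = 1/(j(j+1)).
Both the coefficients and the pmf are verified in the test suite against
independent oracles (direct binomial-mixture summation, Poisson-mixture
convolution, and branching-process Monte Carlo).

**Estimation.** m is the maximizer of the product of pmf values over
cultures, found by a coarse log-grid bracket plus bounded scalar
minimization. The 95% CI is the profile-likelihood interval (log-likelihood
drop of χ²₁(0.95)/2 = 1.92). Counts above a jackpot ceiling (default 1000)
enter the likelihood as right-censored observations P(X > ceiling): the
exact value of a jackpot count carries essentially no information about m,
and the pmf recursion is quadratic in the largest count. If every culture
has zero mutants, one count is set to 1 (flagged `zero_substituted`) so the
estimate is finite and log-transformable downstream. The per-division
frequency divides m and its CI by N_t − N₀. Two strains are called
significantly different when their 95% CIs are disjoint.

Measured on simulated assays (72 cultures, 1000 replicates per m,
m ∈ {0.5, 1, 2, 5, 10}): relative bias of m̂ about 1% or less, CI coverage
92–95%.

## Variant retention and rates

A candidate mutation is retained iff it is genotype-homogeneous (haploid
lines; diploid lines may carry heterozygous calls, controlled by a ploidy
flag), covered by ≥ 5 reads in both the line and its ancestor, supported by
≥ 1 read on each strand, has quality ≥ 50 (inclusive), and — for indels —
is shorter than 50 nt. Rejections are tallied by the first failing
criterion in that order. Rates are n/(callable sites × generations) with the
exact Garwood Poisson CI (χ² quantile form). SNVs collapse by strand
symmetry into six classes; transitions are C:G>T:A and T:A>C:G, so Ts/Tv has
random expectation 0.5 and the AT-bias ratio is C:G>T:A over T:A>C:G.
Mutation identity for cross-line sharing is (chrom, pos, ref, alt).

## Variance decompositions and the bootstrap

V_m is the (n−1)-denominator sample variance of the trait (by default log₁₀
rate) across MA lines, divided by the corrected generation count. Because
the MA ran in a mismatch-repair-deficient (mutator) background, the raw
generation count is multiplied by the mutator's fold acceleration before
dividing: 104× (total SNV+indel rate), 580× (indel), or 16× (SNV), giving
V_m1 ≥ truth ≥ bounds via V_m2/V_m3. The directional components use the
progenitor as origin: V_mL = Σ_{lines below progenitor}(x − x_prog)²/(n·t_corr)
and symmetrically V_mH, with the *total* line count n in the denominator —
the only convention under which V_mL + V_mH equals the mean squared deviation
from the progenitor per corrected generation (and the published component
values are near-additive). When per-line generation counts vary, t_corr uses
their mean.

The significance test bootstraps MA lines and (when V_g is the dispersion)
natural strains independently, with replacement at the original sizes,
10,000 times by default; P is the fraction of replicates whose ratio
strictly exceeds the neutral expectation, with zero-variance replicates
counted as exceeding (ratio +∞). The progenitor value is held fixed.

**Calibration and a known limitation.** On replicate neutral worlds (strain
variance exactly 4N_e·V_m) with 30 strains and 44 lines, the test rejects at
close to its nominal rate (~1–1.5% at α = 0.01 measured over 200 worlds).
With very few strains the percentile bootstrap understates the χ²ₙ₋₁
sampling spread of a variance and becomes anti-conservative near the null
boundary (~10–15% at α = 0.01 with 7 strains). This matters only near the
boundary: worlds stabilized hundreds of fold below the expectation give
P < 0.001 essentially always at either panel size, which is the regime the
analysis actually operates in. The calibration utilities default to 30
strains for this reason; study-scale behavior is obtained by passing
`n_strains=7` explicitly.

## Drift-barrier calculators

Closed forms, exactly as implemented: N_e = π_S/(kμ) with k = 4 (diploid) or
2 (haploid); bottleneck N_e = t/Σ_{i=0..t}2^{−i} (harmonic mean of cells per
generation under binary doubling, ≈ t/2 for large t); T = d_S/mean(μ_a, μ_b);
U₀ = 1/(λN_e) for haploid asexuals, 1/(2λN_e) for diploid asexuals, and
c/(4N_e·s·λ) for sexuals with inflation bound c ≤ 6, using defaults λ = 0.1
and s = 0.01 (so 10/N_e, 5/N_e, ≤1500/N_e). The bundled species table
carries published N_e, U₀ and U values for nine model organisms; U₀ is
always recomputed from the formulas, and the report flags the two bacterial
rows whose published barrier entries (4×10⁻⁷ and 6×10⁻⁶) are not derivable
from the stated formulas (which give 2.5×10⁻⁸ and 1.7×10⁻⁷) rather than
inventing an undocumented variant formula.

The optimal-U simulation draws 100,000 selection coefficients from a gamma
distribution parameterized by shape α ∈ {0.1, 0.2, 0.5} and scale mean_s/α
(so the mean is 0.01), and for each N_e reports the harmonic mean of the
coefficients strictly greater than 1/N_e. One draw is shared across the N_e
grid (common random numbers), so raising the cutoff can only remove the
smallest retained values and the curve is exactly non-increasing per run.
Grids retaining no sample yield NaN with a warning.

## Synthetic data: what it emulates and what it does not

The generators reproduce the statistical structure the estimators assume:
compound-Poisson fluctuation counts with binomial plating thinning (clone
sizes sampled by inversion, K = ⌊1/U⌋); MA lines whose per-line rate is
base_rate·10^N(0, σ_mod) (lognormal modifier model; an additive option
exists because the true distribution of modifier effects is unknown), with
Poisson totals over t generations and multinomial splits over the eight
mutation classes; a 200-site shared homonucleotide-run pool from which a
configurable fraction of indels is drawn, giving cross-line sharing for the
shared-mutation summary to detect; filter-exercising VCF records whose
fields independently violate each criterion with requested probabilities;
and natural-strain traits drawn Normal with variance 4N_e·V_m (optionally
shrunk). Defaults follow the study design: 93 lines, 1511 generations,
~879 mutations per line, 72-culture assays, 7-strain panels, N_e = 1.17×10⁷.

Not modeled: reads and sequencing error (records are generated above the
caller), selection during MA, growth-rate variation, real genomic context
(positions are uniform on a single contig), and linkage. Passing tests
therefore validate the estimators and their wiring, not the upstream
alignment/calling pipeline, which is outside this package.

All generators derive independent deterministic streams from one master seed
(CRC-based stream labels, so results are identical across processes).

## Numerical choices

- pmf truncation: reported tail mass is 1 − Σp; the recursion itself is
  verified to 10⁻¹⁰ against series oracles, and total mass closes to 10⁻⁹.
- MLE search: 25-point log grid spanning [10⁻³, 10]× the (jackpot-clipped)
  mean count, then bounded refinement (xatol 10⁻⁵ on log m); profile roots
  by Brent with xtol 10⁻⁴.
- Ratio traits with a zero denominator (e.g. Ts/Tv with no transversions)
  are reported as NaN, never raised.
- Bootstrap exceedance is strict (>); ties count as non-exceeding.
- Chi-squared spectrum tests drop all-zero columns and use no continuity
  correction; proportional tables give P = 1.
- Coordinates are 1-based (VCF convention); indels ≥ 50 nt are excluded.
- "Larger than 1/N_e" in the optimal-U cutoff is strict (measure-zero
  choice).

## Problem sizes

The test suite and acceptance script run everything at the scales quoted
above — 1000 replicate assays per m value, 100–200 replicate calibration
worlds at 10,000 bootstraps, 100,000 gamma draws, 5000 labeled filter
records — chosen to give sampling error comfortably inside the asserted
tolerances.
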