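"""Seeded generators for every input the analysis consumes.

The generators emulate the statistical structure of a two-round yeast
mutation-accumulation (MA) study without any sequencing data:

* fluctuation-assay mutant counts per culture under the Lea-Coulson model
  (Poisson number of mutational events, Luria-Delbrück clone sizes, binomial
  plating-efficiency thinning);
* MA lines whose per-line mutation rates carry modifier-induced variance
  (by default lognormal on the rate, i.e. Normal on log10 rate), with Poisson
  totals over generations and a multinomial split across the 8 mutation
  classes; a configurable fraction of indels recurs at a small shared pool of
  homonucleotide-run sites, emulating slippage hotspots in
  mismatch-repair-deficient lines;
* natural-strain trait values whose across-strain variance is 4*Ne*Vm under
  neutrality, or that value divided by a shrink factor under stabilizing
  selection;
* labeled VCF-like variant records that exercise every retention filter.

All generators are deterministic given (parameters, seed): every operation
spawns an independent child stream from the master seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .variant_filtering import MALine, MUTATION_CLASSES, VariantRecord

__all__ = [
    "SimConfig",
    "simulate_fluctuation_counts",
    "simulate_clone_sizes",
    "simulate_ma_lines",
    "simulate_variant_records",
    "simulate_natural_traits",
]

# Default study conditions: 93 surviving lines, 1511 generations each, and a
# per-genome rate giving ~879 mutations per line; yeast callable genome ~1.1e7
# sites. The default spectrum is indel-heavy with a GC->AT excess, as expected
# without mismatch repair.
_DEFAULT_SPECTRUM = (0.10, 0.05, 0.03, 0.02, 0.03, 0.02, 0.40, 0.35)


@dataclass
class SimConfig:
    """Parameters of the MA-line generator."""

    seed: int = 0
    n_lines: int = 93
    generations_per_line: float = 1511.0
    genome_sites: int = 11_000_000
    base_rate: float = 879.0 / 1511.0  # mutations per genome per generation
    modifier_sd: float = 0.0  # sd of log10 per-line rate
    modifier_dist: str = "log10_normal"  # or "normal" (additive on the rate)
    spectrum_probs: tuple[float, ...] = _DEFAULT_SPECTRUM
    shared_indel_prob: float = 0.0
    shared_pool_size: int = 200

    def __post_init__(self) -> None:
        if self.n_lines < 1 or self.genome_sites < 1 or self.generations_per_line <= 0:
            raise ValueError("counts must be positive")
        if self.base_rate <= 0:
            raise ValueError("base_rate must be > 0")
        probs = np.asarray(self.spectrum_probs, dtype=float)
        if len(probs) != len(MUTATION_CLASSES) or np.any(probs < 0) or probs.sum() == 0:
            raise ValueError("spectrum_probs must be 8 nonnegative weights")
        self.spectrum_probs = tuple(probs / probs.sum())
        if not 0 <= self.shared_indel_prob <= 1:
            raise ValueError("shared_indel_prob must be in [0, 1]")
        if self.modifier_dist not in ("log10_normal", "normal"):
            raise ValueError(f"unknown modifier_dist {self.modifier_dist!r}")


def _child_rng(seed: int, label: str) -> np.random.Generator:
    """Independent deterministic stream per (seed, purpose)."""
    root = np.random.SeedSequence([seed, zlib.crc32(label.encode())])
    return np.random.default_rng(root)


def simulate_clone_sizes(n: int, rng: np.random.Generator) -> np.ndarray:
    """Clone sizes under the Luria-Delbrück law P(K = k) = 1/(k(k+1)).

    Sampled by inversion: K = floor(1/U) satisfies P(K >= k) = 1/k.
    """
    u = rng.random(n)
    return np.floor(1.0 / u).astype(np.int64)


def simulate_fluctuation_counts(
    mu_per_division: float,
    n0: float,
    nt: float,
    z: float,
    n_cultures: int,
    seed: int,
) -> np.ndarray:
    """Per-culture mutant colony counts under the Lea-Coulson process.

    Mutational events per culture are Poisson with mean
    m = mu_per_division * (nt - n0); each event founds a clone with
    Luria-Delbrück size; each mutant cell is plated with probability z.
    """
    if n_cultures < 1:
        raise ValueError("n_cultures must be >= 1")
    if not (0 < z <= 1):
        raise ValueError("plating efficiency z must be in (0, 1]")
    if not (nt > n0 >= 1):
        raise ValueError("require nt > n0 >= 1")
    if not 0 <= mu_per_division <= 1:
        raise ValueError("mu_per_division must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    m = mu_per_division * (nt - n0)
    n_events = rng.poisson(m, size=n_cultures)
    counts = np.zeros(n_cultures, dtype=np.int64)
    total_events = int(n_events.sum())
    if total_events:
        sizes = np.minimum(simulate_clone_sizes(total_events, rng), int(nt))
        if z < 1.0:
            sizes = rng.binomial(sizes, z)
        owner = np.repeat(np.arange(n_cultures), n_events)
        np.add.at(counts, owner, sizes)
    return counts


_CLASS_REF_ALT = {
    "C:G>T:A": ("C", "T"),
    "T:A>C:G": ("T", "C"),
    "C:G>A:T": ("C", "A"),
    "C:G>G:C": ("C", "G"),
    "T:A>A:T": ("T", "A"),
    "T:A>G:C": ("T", "G"),
    "insertion": ("A", "AA"),
    "deletion": ("AA", "A"),
}


def _make_record(
    chrom: str,
    pos: int,
    cls: str,
    rng: np.random.Generator,
    in_homonucleotide_run: bool = False,
) -> VariantRecord:
    ref, alt = _CLASS_REF_ALT[cls]
    depth = int(rng.integers(20, 60))
    fwd = int(rng.integers(5, depth - 5))
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        depth_sample=depth,
        depth_ancestor=int(rng.integers(20, 60)),
        forward_support=fwd,
        reverse_support=depth - fwd,
        quality=float(rng.uniform(60, 2000)),
        genotype_homogeneous=True,
        in_homonucleotide_run=in_homonucleotide_run,
        genic=bool(rng.random() < 0.73),
        coding_effect="none",
    )


def simulate_ma_lines(config: SimConfig) -> list[MALine]:
    """MA lines with modifier-induced rate variance and multinomial spectra.

    Each line's true per-genome rate is base_rate * 10**Normal(0, modifier_sd)
    (or base_rate + Normal(0, modifier_sd * base_rate) under the additive
    option); the total mutation count is Poisson(rate * t); counts split
    multinomially by spectrum_probs; a fraction shared_indel_prob of indels
    is drawn from a shared pool of homonucleotide-run sites.
    """
    rng = _child_rng(config.seed, "ma_lines")
    t = config.generations_per_line
    if config.modifier_dist == "log10_normal":
        rates = config.base_rate * 10.0 ** rng.normal(0.0, config.modifier_sd, config.n_lines)
    else:
        rates = np.maximum(
            config.base_rate + rng.normal(0.0, config.modifier_sd * config.base_rate,
                                          config.n_lines),
            config.base_rate * 1e-6,
        )
    totals = rng.poisson(rates * t)
    probs = np.asarray(config.spectrum_probs)
    # shared homonucleotide-run indel pool: fixed positions per master seed
    pool_rng = _child_rng(config.seed, "shared_pool")
    pool_pos = np.sort(pool_rng.choice(config.genome_sites, size=config.shared_pool_size,
                                       replace=False)) + 1
    pool_is_ins = pool_rng.random(config.shared_pool_size) < 0.5
    lines: list[MALine] = []
    for i in range(config.n_lines):
        class_counts = rng.multinomial(totals[i], probs)
        variants: list[VariantRecord] = []
        for cls, count in zip(MUTATION_CLASSES, class_counts):
            is_indel = cls in ("insertion", "deletion")
            for _ in range(count):
                if is_indel and rng.random() < config.shared_indel_prob:
                    j = int(rng.integers(config.shared_pool_size))
                    pcls = "insertion" if pool_is_ins[j] else "deletion"
                    variants.append(
                        _make_record("chrI", int(pool_pos[j]), pcls, rng,
                                     in_homonucleotide_run=True)
                    )
                else:
                    pos = int(rng.integers(1, config.genome_sites + 1))
                    variants.append(_make_record("chrI", pos, cls, rng))
        lines.append(
            MALine(
                line_id=f"MA{i + 1:03d}",
                generations=t,
                callable_sites=config.genome_sites,
                variants=variants,
                ploidy="haploid",
            )
        )
    return lines


def simulate_variant_records(
    n: int,
    violation_probs: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[list[VariantRecord], np.ndarray]:
    """Labeled records that independently violate each retention filter.

    ``violation_probs`` keys: depth, strand, quality, homogeneous; each is the
    probability the corresponding field is degraded below its threshold.
    Returns (records, ground-truth pass labels).
    """
    probs = {"depth": 0.0, "strand": 0.0, "quality": 0.0, "homogeneous": 0.0}
    if violation_probs:
        unknown = set(violation_probs) - set(probs)
        if unknown:
            raise ValueError(f"unknown filter keys: {sorted(unknown)}")
        probs.update(violation_probs)
    if any(not 0 <= p <= 1 for p in probs.values()):
        raise ValueError("violation probabilities must be in [0, 1]")
    rng = _child_rng(seed, "variant_records")
    records: list[VariantRecord] = []
    labels = np.ones(n, dtype=bool)
    classes = [c for c in MUTATION_CLASSES]
    for i in range(n):
        viol = {k: rng.random() < p for k, p in probs.items()}
        cls = classes[int(rng.integers(len(classes)))]
        ref, alt = _CLASS_REF_ALT[cls]
        # boundary-inclusive draws: passing depth is >= 5, quality >= 50
        depth = int(rng.integers(0, 5)) if viol["depth"] else int(rng.integers(5, 40))
        anc_depth = int(rng.integers(5, 40))
        if viol["strand"]:
            fwd = 0 if rng.random() < 0.5 else depth
        else:
            fwd = int(rng.integers(1, depth)) if depth >= 2 else depth
        if viol["strand"] and depth == 0:
            fwd = 0
        quality = float(rng.uniform(0, 50)) if viol["quality"] else float(rng.uniform(50, 1000))
        records.append(
            VariantRecord(
                chrom="chrI",
                pos=i + 1,
                ref=ref,
                alt=alt,
                depth_sample=depth,
                depth_ancestor=anc_depth,
                forward_support=fwd,
                reverse_support=depth - fwd,
                quality=quality,
                genotype_homogeneous=not viol["homogeneous"],
            )
        )
        strand_fail = viol["strand"] or depth < 2
        labels[i] = not (viol["depth"] or strand_fail or viol["quality"] or viol["homogeneous"])
    return records, labels


def simulate_natural_traits(
    n_strains: int,
    ne: float,
    vm: float,
    mode: str = "neutral",
    shrink: float = 1.0,
    seed: int = 0,
    ancestral_mean: float = 0.0,
) -> np.ndarray:
    """Natural-strain trait values under neutrality or stabilizing selection.

    Neutral drift around the ancestral mean accumulates across-strain variance
    4*Ne*Vm for an asexual diploid; stabilizing selection shrinks that
    variance by ``shrink``.
    """
    if n_strains < 2:
        raise ValueError("n_strains must be >= 2")
    if vm < 0:
        raise ValueError("vm must be >= 0")
    if shrink < 1:
        raise ValueError("shrink factor must be >= 1")
    if mode not in ("neutral", "stabilizing"):
        raise ValueError(f"unknown mode {mode!r}")
    var = 4.0 * ne * vm
    if mode == "stabilizing":
        var /= shrink
    rng = _child_rng(seed, "natural_traits")
    return ancestral_mean + rng.normal(0.0, np.sqrt(var), size=n_strains)
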