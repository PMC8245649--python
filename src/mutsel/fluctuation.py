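"""Luria-Delbrück fluctuation analysis.

A fluctuation assay grows many parallel cultures from a small inoculum and
counts resistant mutant colonies per culture. Under the Lea-Coulson model
(deterministic exponential host growth, mutation events uniform on the growth
trajectory), the number of mutational events per culture is Poisson with mean
m, and each event founds a clone whose observed size K follows the
Luria-Delbrück clone-size law P(K = k) = 1/(k(k+1)). The mutant count per
culture is therefore compound Poisson, a famously heavy-tailed ("jackpot")
distribution.

With plating efficiency z (each mutant cell independently observed with
probability z), binomial thinning of the clone-size law gives the per-event
pgf in closed form:

    g(s) = 1 + [z(1-s) / (1-z+zs)] * [ln z + ln(1-s)],

because 1 - ((1-z) + zs) = z(1-s). The compound Poisson pmf follows by the
Panjer recursion

    p_0 = exp(-m (1 - q_0)),   p_n = (m/n) * sum_{j=1..n} j q_j p_{n-j},

which for z = 1 (q_j = 1/(j(j+1))) reduces to the Ma-Sandri-Sarkar form
p_n = (m/n) * sum_{i=0..n-1} p_i/(n-i+1).

m is estimated by maximum likelihood over the per-culture counts, with a 95%
profile-likelihood interval (log-likelihood drop of chi2_1(0.95)/2 = 1.92).
The per-cell-division mutation frequency divides m by the number of divisions
per culture, nt - n0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "FluctuationAssay",
    "FrequencyEstimate",
    "clone_size_pgf_coeffs",
    "luria_delbruck_pmf",
    "estimate_mutations_per_culture",
    "compare_estimates",
]

_CHI2_95_HALF = stats.chi2.ppf(0.95, df=1) / 2.0  # 1.9207


@dataclass(frozen=True)
class FluctuationAssay:
    """Per-culture mutant counts plus culture parameters."""

    mutant_counts: tuple[int, ...]
    n0: float
    nt: float
    z: float = 1.0

    def __post_init__(self) -> None:
        if len(self.mutant_counts) < 1:
            raise ValueError("need >= 1 culture")
        if any(c != int(c) or c < 0 for c in self.mutant_counts):
            raise ValueError("mutant counts must be nonnegative integers")
        if not (self.nt > self.n0 >= 1):
            raise ValueError("require nt > n0 >= 1")
        if not (0 < self.z <= 1):
            raise ValueError("plating efficiency z must be in (0, 1]")


@dataclass(frozen=True)
class FrequencyEstimate:
    """MLE of mutations per culture and per-division mutation frequency."""

    m_hat: float
    freq: float
    ci_low: float
    ci_high: float
    zero_substituted: bool
    m_ci_low: float
    m_ci_high: float


def clone_size_pgf_coeffs(z: float, max_k: int) -> np.ndarray:
    """Taylor coefficients q_0..q_max_k of the observed clone-size pgf g(s).

    For z = 1 these are q_0 = 0, q_j = 1/(j(j+1)). For z < 1 write
    d = 1 - z(1-s): then g(s) = 1 + ((1-d)/d) * log1p(-d). The apparent pole
    at d = 0 is removable (the log vanishes there too), so g is analytic on
    the whole unit disc and its coefficients are recovered stably by the
    Cauchy integral, evaluated as an FFT over a circle of radius slightly
    below 1. (Naive power-series division by the linear denominator is
    exponentially unstable for z > 1/2.)
    """
    if not (0 < z <= 1):
        raise ValueError("z must be in (0, 1]")
    if max_k < 0:
        raise ValueError("max_k must be >= 0")
    k = np.arange(1, max_k + 1, dtype=float)
    if z == 1.0:
        q = np.zeros(max_k + 1)
        if max_k >= 1:
            q[1:] = 1.0 / (k * (k + 1.0))
        return q
    m = max_k + 1
    n_fft = 1 << int(np.ceil(np.log2(max(8 * m, 64))))
    # radius < 1: r^{-max_k} <= 1e8^{m/n_fft} <= 10, so roundoff is not
    # amplified, while aliasing of the ~j^{-2} coefficient tail is ~1e-8
    r = (1e-8) ** (1.0 / n_fft)
    s = r * np.exp(2j * np.pi * np.arange(n_fft) / n_fft)
    d = (1.0 - z) + z * s
    g = 1.0 + (1.0 - d) / d * np.log1p(-d)
    coeffs = np.fft.fft(g).real / n_fft
    q = coeffs[:m] / r ** np.arange(m)
    np.clip(q, 0.0, None, out=q)
    return q


def luria_delbruck_pmf(
    m: float, z: float = 1.0, max_k: int = 200
) -> tuple[np.ndarray, float]:
    """pmf p_0..p_max_k of mutant counts per culture, plus truncated tail mass.

    Compound Poisson(m) over the (thinned) Luria-Delbrück clone-size law,
    evaluated by the Panjer recursion. The second return value is the
    probability mass beyond max_k (the distribution has a ~m/n tail, so the
    truncation mass decays only harmonically).
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    if max_k < 0:
        raise ValueError("max_k must be >= 0")
    q = clone_size_pgf_coeffs(z, max_k)
    p = np.zeros(max_k + 1)
    p[0] = np.exp(-m * (1.0 - q[0]))
    if max_k >= 1:
        jq = np.arange(max_k + 1, dtype=float) * q  # j * q_j
        for n in range(1, max_k + 1):
            # p_n = (m/n) * sum_{j=1..n} j q_j p_{n-j}
            p[n] = (m / n) * np.dot(jq[1 : n + 1], p[n - 1 :: -1][:n])
    tail = max(0.0, 1.0 - float(p.sum()))
    return p, tail


def _log_likelihood(m: float, counts: np.ndarray, z: float, max_k: int) -> float:
    """Log-likelihood with right-censoring of counts above max_k.

    Counts above max_k (jackpot cultures) contribute the tail probability
    P(X > max_k) — the correct likelihood of a censored observation — so the
    heavy ~m/n tail of the distribution never forces an unbounded recursion.
    """
    if m <= 0:
        return -np.inf
    p, _ = luria_delbruck_pmf(m, z, max_k)
    censored = counts > max_k
    ll = 0.0
    if np.any(~censored):
        probs = p[counts[~censored]]
        if np.any(probs <= 0):
            return -np.inf
        ll += float(np.log(probs).sum())
    if np.any(censored):
        tail = max(1.0 - float(p.sum()), 0.0)
        if tail <= 0:
            return -np.inf
        ll += float(np.log(tail)) * int(censored.sum())
    return ll


def estimate_mutations_per_culture(
    assay: FluctuationAssay, jackpot_ceiling: int = 1000
) -> FrequencyEstimate:
    """Maximum-likelihood m per culture with 95% profile-likelihood CI.

    If every culture has zero mutants the likelihood is maximized at m = 0;
    following standard practice for log-scale reporting, one culture's count
    is substituted with 1 and the estimate flagged ``zero_substituted``.
    Counts above ``jackpot_ceiling`` are treated as right-censored (their
    exact value carries almost no information about m beyond "large", and the
    pmf recursion is quadratic in the largest count). The per-division
    frequency divides m by the effective number of cell divisions per
    culture, nt - n0.
    """
    counts = np.array(assay.mutant_counts, dtype=int)
    zero_substituted = False
    if counts.max() == 0:
        counts = counts.copy()
        counts[0] = 1
        zero_substituted = True
    max_k = int(min(counts.max(), jackpot_ceiling))
    z = assay.z

    def nll(log_m: float) -> float:
        return -_log_likelihood(np.exp(log_m), counts, z, max_k)

    # coarse log-grid bracket, then bounded refinement; center the grid on a
    # jackpot-robust scale (clipped mean) so one huge count cannot push the
    # search window away from the likelihood peak
    mean_c = counts.clip(max=max_k).mean()
    grid = np.log(np.geomspace(max(mean_c, 1.0) * 1e-3, max(mean_c, 1.0) * 10, 25))
    vals = np.array([nll(g) for g in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-5})
    m_hat = float(np.exp(res.x))
    ll_max = -float(res.fun)

    target = ll_max - _CHI2_95_HALF

    def deficit(log_m: float) -> float:
        return _log_likelihood(np.exp(log_m), counts, z, max_k) - target

    # lower bound: walk left until below the cutoff
    left = res.x - 1.0
    while deficit(left) > 0 and left > res.x - 60:
        left -= 1.0
    m_lo = float(np.exp(optimize.brentq(deficit, left, res.x, xtol=1e-4)))
    right = res.x + 1.0
    while deficit(right) > 0 and right < res.x + 60:
        right += 1.0
    m_hi = float(np.exp(optimize.brentq(deficit, res.x, right, xtol=1e-4)))

    divisions = assay.nt - assay.n0
    return FrequencyEstimate(
        m_hat=m_hat,
        freq=m_hat / divisions,
        ci_low=m_lo / divisions,
        ci_high=m_hi / divisions,
        zero_substituted=zero_substituted,
        m_ci_low=m_lo,
        m_ci_high=m_hi,
    )


def compare_estimates(a: FrequencyEstimate, b: FrequencyEstimate) -> str:
    """CI-overlap comparison: 'significant' iff the 95% CIs are disjoint."""
    if a.ci_high < b.ci_low or b.ci_high < a.ci_low:
        return "significant"
    return "not_significant"
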