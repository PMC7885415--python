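r"""Molecular diversity and neutrality statistics per population.

Statistics are computed from combined-haplotype frequencies and the
haplotype sequences themselves:

* haplotype diversity, the unbiased estimator
  :math:`H_d = \frac{n}{n-1}\bigl(1 - \sum_i \hat p_i^2\bigr)`;
* nucleotide diversity
  :math:`\pi = \sum_{i<j} d_{ij} / \bigl(\binom{n}{2} L\bigr)` with
  :math:`d_{ij}` the raw Hamming difference count between individuals'
  sequences (no multiple-hit correction), and its un-normalised form
  :math:`\hat\theta_\pi = \pi L`, the mean number of pairwise
  differences;
* Fu's Fs, :math:`F_s = \ln\!\bigl(S'/(1-S')\bigr)` where
  :math:`S' = \Pr(K \ge k_{obs} \mid \hat\theta_\pi)` under the Ewens
  sampling formula,

  .. math::

     S' = \sum_{k=k_{obs}}^{n} \frac{|S_1(n,k)|\,\theta^k}{\theta_{(n)}},
     \qquad \theta_{(n)} = \theta(\theta+1)\cdots(\theta+n-1),

  with :math:`|S_1(n,k)|` the unsigned Stirling numbers of the first
  kind. Strongly negative Fs indicates an excess of rare haplotypes
  (demographic expansion); positive Fs a deficiency (bottleneck).

Numerics: Stirling numbers are kept as exact Python integers and the
Ewens terms are combined in log space; ``1 - S'`` is obtained from the
complementary sum over :math:`k < k_{obs}` rather than by subtraction,
so Fs stays accurate when :math:`S'` approaches 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

__all__ = [
    "DiversityStats",
    "haplotype_diversity",
    "nucleotide_diversity",
    "mean_pairwise_differences",
    "stirling_first_unsigned",
    "log_stirling_first",
    "ewens_sprime",
    "fu_fs",
    "population_stats",
]

_MAX_STIRLING_N = 2000


@lru_cache(maxsize=None)
def _stirling_row(n: int) -> tuple[int, ...]:
    # row of |S1(n, k)| for k = 0..n via |S1(n+1,k)| = n|S1(n,k)| + |S1(n,k-1)|
    if n == 0:
        return (1,)
    prev = _stirling_row(n - 1)
    m = n - 1
    row = [0] * (n + 1)
    for k in range(1, n + 1):
        row[k] = m * (prev[k] if k < n else 0) + prev[k - 1]
    return tuple(row)


def stirling_first_unsigned(n: int, k: int) -> int:
    """Exact unsigned Stirling number of the first kind |S1(n, k)|.

    Counts permutations of ``n`` elements with exactly ``k`` cycles.
    Out-of-range ``k`` returns 0 by convention.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if n > _MAX_STIRLING_N:
        raise ValueError(f"n={n} exceeds supported range ({_MAX_STIRLING_N})")
    if k < 0 or k > n:
        return 0
    return _stirling_row(n)[k]


def _log_bigint(x: int) -> float:
    if x < 0:
        raise ValueError("x must be non-negative")
    if x == 0:
        return float("-inf")
    shift = x.bit_length() - 53
    if shift > 0:
        return math.log(x >> shift) + shift * math.log(2.0)
    return math.log(x)


def log_stirling_first(n: int, k: int) -> float:
    """Natural log of |S1(n, k)| (``-inf`` when the number is 0)."""
    return _log_bigint(stirling_first_unsigned(n, k))


def _logsumexp(values: Sequence[float]) -> float:
    finite = [v for v in values if v > float("-inf")]
    if not finite:
        return float("-inf")
    m = max(finite)
    return m + math.log(sum(math.exp(v - m) for v in finite))


def ewens_sprime(n: int, k_obs: int, theta: float) -> float:
    """Pr(K >= k_obs | theta) for the number of distinct haplotypes K.

    Under the Ewens sampling formula,
    ``Pr(K = k) = |S1(n,k)| theta^k / theta_(n)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if k_obs <= 1:
        return 1.0
    if theta <= 0.0:
        # theta = 0: all individuals share one haplotype, K = 1 surely
        return 0.0 if k_obs > 1 else 1.0
    log_theta = math.log(theta)
    log_denom = sum(math.log(theta + i) for i in range(n))
    upper = [
        log_stirling_first(n, k) + k * log_theta for k in range(k_obs, n + 1)
    ]
    return math.exp(_logsumexp(upper) - log_denom)


def fu_fs(n: int, k_obs: int, theta: float) -> tuple[float, float]:
    """Fu's Fs statistic and the S' = Pr(K >= k_obs | theta) diagnostic.

    Conventions: ``k_obs <= 1`` or ``theta <= 0`` reports Fs = 0 (the
    monomorphic case; S' is still 1.0 when ``k_obs <= 1``). If the
    complementary probability underflows to zero while ``k_obs > 1``,
    Fs is reported as ``+inf`` (signed overflow sentinel).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if k_obs <= 1:
        return 0.0, 1.0
    if theta <= 0.0:
        return 0.0, float("nan")
    log_theta = math.log(theta)
    terms = [log_stirling_first(n, k) + k * log_theta for k in range(1, n + 1)]
    log_denom = sum(math.log(theta + i) for i in range(n))
    log_upper = _logsumexp(terms[k_obs - 1 :])
    log_lower = _logsumexp(terms[: k_obs - 1])
    s_prime = math.exp(log_upper - log_denom)
    if log_lower == float("-inf"):
        return float("inf"), s_prime
    # Fs = ln(S'/(1-S')) computed as the log-ratio of the two partial sums
    return log_upper - log_lower, s_prime


def haplotype_diversity(counts: Sequence[int]) -> float:
    """Unbiased haplotype diversity ``n (1 - sum p_i^2) / (n - 1)``.

    ``counts`` are per-haplotype sample counts (all positive). A sample
    of one individual has undefined diversity and returns NaN.
    """
    if not counts:
        raise ValueError("counts must be non-empty")
    if any(c <= 0 for c in counts):
        raise ValueError("all counts must be positive integers")
    n = sum(counts)
    if n == 1:
        return float("nan")
    sum_p2 = sum((c / n) ** 2 for c in counts)
    return n * (1.0 - sum_p2) / (n - 1)


def mean_pairwise_differences(
    hap_counts: Mapping[str, int], hap_seqs: Mapping[str, str]
) -> float:
    """Mean number of pairwise sequence differences over all C(n,2) pairs.

    Unlike-haplotype pairs are weighted by their count products; this is
    the plug-in theta estimate used by Fu's Fs. NaN for n < 2.
    """
    from .differentiation import hamming

    lengths = {len(hap_seqs[h]) for h in hap_counts}
    if len(lengths) > 1:
        raise ValueError(f"sequence length mismatch: {sorted(lengths)}")
    n = sum(hap_counts.values())
    if n < 2:
        return float("nan")
    haps = list(hap_counts)
    total = 0.0
    for i, a in enumerate(haps):
        for b in haps[i + 1 :]:
            total += hap_counts[a] * hap_counts[b] * hamming(hap_seqs[a], hap_seqs[b])
    return total / (n * (n - 1) / 2)


def nucleotide_diversity(
    hap_counts: Mapping[str, int],
    hap_seqs: Mapping[str, str],
    L: int | None = None,
) -> float:
    """Per-site nucleotide diversity (no distance correction). NaN for n < 2."""
    if L is None:
        L = len(next(iter(hap_seqs.values())))
    k = mean_pairwise_differences(hap_counts, hap_seqs)
    return k / L


@dataclass(frozen=True)
class DiversityStats:
    """Per-population diversity/neutrality summary (NaN marks undefined)."""

    population: str
    n: int
    k: int
    hd: float
    pi: float
    theta_pi: float
    fs: float
    s_prime: float

    def rounded(self) -> dict[str, object]:
        """Report-precision view: Hd/Fs to 3 decimals, pi to 5."""

        def r(x: float, nd: int) -> float | str:
            if math.isnan(x):
                return "NA"
            if math.isinf(x):
                return "inf" if x > 0 else "-inf"
            return round(x, nd)

        return {
            "population": self.population,
            "n": self.n,
            "Hn": self.k,
            "Hd": r(self.hd, 3),
            "pi": r(self.pi, 5),
            "fs": r(self.fs, 3),
        }


def population_stats(
    members: Mapping[str, Sequence[str]],
    hap_seqs: Mapping[str, str],
    L: int | None = None,
) -> list[DiversityStats]:
    """Compute :class:`DiversityStats` for each population.

    ``members`` maps a population label to the list of (combined)
    haplotype names carried by its individuals, one entry per individual.
    Populations of a single individual report NaN diversity, matching the
    way singleton rows print as NA.
    """
    out: list[DiversityStats] = []
    for pop, haps in members.items():
        counts: dict[str, int] = {}
        for h in haps:
            counts[h] = counts.get(h, 0) + 1
        n = len(haps)
        k = len(counts)
        if n < 2:
            out.append(
                DiversityStats(
                    pop, n, k, float("nan"), float("nan"), float("nan"), 0.0, 1.0
                )
            )
            continue
        hd = haplotype_diversity(list(counts.values()))
        theta = mean_pairwise_differences(counts, hap_seqs)
        length = L if L is not None else len(hap_seqs[next(iter(counts))])
        pi = theta / length
        fs, s_prime = fu_fs(n, k, theta)
        out.append(DiversityStats(pop, n, k, hd, pi, theta, fs, s_prime))
    return out
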