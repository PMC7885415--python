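r"""Distance matrices, one-level AMOVA with Phi-statistics, pairwise F_ST.

The analysis of molecular variance partitions the total molecular
variance of haplotype sequences into among- and within-population
components (Excoffier's one-level model). With :math:`\delta_{ij}^2`
the squared molecular distance between individuals i and j — here the
raw count of nucleotide differences between their haplotypes, the
default for haplotype data; an identity metric (0/1) is available as an
option —

.. math::

   SSD_{total} = \frac{1}{N}\sum_{i<j}\delta_{ij}^2, \qquad
   SSD_{within} = \sum_p \frac{1}{n_p}\sum_{i<j \in p}\delta_{ij}^2,

:math:`\sigma^2_w = SSD_{within}/(N-P)`,
:math:`\sigma^2_a = (SSD_{among}/(P-1) - \sigma^2_w)/n'` with
:math:`n' = (N - \sum_p n_p^2/N)/(P-1)`, and
:math:`\Phi_{ST} = \sigma^2_a/(\sigma^2_a+\sigma^2_w)`.

Significance is assessed by permuting individuals among populations
(sizes held fixed) and counting permuted :math:`\Phi_{ST}` values at
least as large as observed, with the usual +1/+1 correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

__all__ = [
    "DistanceMatrix",
    "AmovaResult",
    "FstMatrix",
    "hamming",
    "hamming_matrix",
    "amova",
    "pairwise_fst",
]


def hamming(a: str, b: str) -> int:
    """Number of differing sites between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distance matrix with labelled rows/columns."""

    labels: tuple[str, ...]
    values: np.ndarray
    kind: str = "hamming"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "values", v)

    def index(self, label: str) -> int:
        return self.labels.index(label)


def hamming_matrix(hap_seqs: Mapping[str, str]) -> DistanceMatrix:
    """Pairwise site-difference counts between haplotype sequences."""
    labels = tuple(hap_seqs)
    lengths = {len(s) for s in hap_seqs.values()}
    if len(lengths) > 1:
        raise ValueError(f"sequence length mismatch: {sorted(lengths)}")
    # byte-level vectorised comparison
    arr = np.frombuffer(
        "".join(hap_seqs[l] for l in labels).encode(), dtype=np.uint8
    ).reshape(len(labels), -1)
    values = (arr[:, None, :] != arr[None, :, :]).sum(axis=2).astype(float)
    return DistanceMatrix(labels, values, kind="hamming")


@dataclass(frozen=True)
class AmovaResult:
    ssd_among: float
    ssd_within: float
    ssd_total: float
    df_among: int
    df_within: int
    sigma2_a: float
    sigma2_w: float
    n_prime: float
    phi_st: float
    pct_among: float
    pct_within: float
    p_value: float
    n_permutations: int
    seed: int | None


def _squared_distance_matrix(
    hap_per_individual: Sequence[str],
    distances: DistanceMatrix,
    metric: Literal["pairwise_difference", "haplotype_identity"],
) -> np.ndarray:
    idx = np.array([distances.index(h) for h in hap_per_individual])
    if metric == "pairwise_difference":
        # the difference count itself is the squared Euclidean distance
        return distances.values[np.ix_(idx, idx)]
    if metric == "haplotype_identity":
        d2 = (idx[:, None] != idx[None, :]).astype(float)
        return d2
    raise ValueError(f"unknown metric {metric!r}")


def _components(
    d2: np.ndarray, sizes: Sequence[int]
) -> tuple[float, float, float, float, float, float]:
    """(ssd_among, ssd_within, ssd_total, sigma2_a, sigma2_w, phi) for
    individuals ordered population-by-population with the given sizes."""
    n_total = d2.shape[0]
    n_pops = len(sizes)
    ssd_total = d2.sum() / (2.0 * n_total)
    ssd_within = 0.0
    start = 0
    for n_p in sizes:
        block = d2[start : start + n_p, start : start + n_p]
        ssd_within += block.sum() / (2.0 * n_p)
        start += n_p
    ssd_among = ssd_total - ssd_within
    df_among = n_pops - 1
    df_within = n_total - n_pops
    sigma2_w = ssd_within / df_within if df_within > 0 else 0.0
    n_prime = (n_total - sum(n * n for n in sizes) / n_total) / df_among
    sigma2_a = (ssd_among / df_among - sigma2_w) / n_prime
    total_var = sigma2_a + sigma2_w
    phi = sigma2_a / total_var if total_var > 0 else 0.0
    return ssd_among, ssd_within, ssd_total, sigma2_a, sigma2_w, phi


def amova(
    groups: Mapping[str, Sequence[str]],
    distances: DistanceMatrix,
    n_permutations: int = 1000,
    seed: int | None = None,
    metric: Literal["pairwise_difference", "haplotype_identity"] = "pairwise_difference",
) -> AmovaResult:
    """One-level AMOVA over individuals grouped by population.

    ``groups`` maps population name -> haplotype name per individual.
    When every individual is identical (zero total variance) Phi_ST is 0
    by convention. ``n_permutations = 0`` reports a NaN p-value.
    """
    pops = list(groups)
    if len(pops) < 2:
        raise ValueError("AMOVA requires at least two populations")
    sizes = [len(groups[p]) for p in pops]
    if any(s == 0 for s in sizes):
        raise ValueError("populations must be non-empty")
    haps = [h for p in pops for h in groups[p]]
    d2 = _squared_distance_matrix(haps, distances, metric)
    ssd_a, ssd_w, ssd_t, s2a, s2w, phi = _components(d2, sizes)
    total_var = s2a + s2w
    pct_among = 100.0 * s2a / total_var if total_var > 0 else 0.0
    pct_within = 100.0 * s2w / total_var if total_var > 0 else 100.0

    p_value = float("nan")
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        n_total = len(haps)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n_total)
            d2p = d2[np.ix_(perm, perm)]
            phi_p = _components(d2p, sizes)[5]
            if phi_p >= phi:
                hits += 1
        p_value = (hits + 1) / (n_permutations + 1)

    return AmovaResult(
        ssd_among=ssd_a,
        ssd_within=ssd_w,
        ssd_total=ssd_t,
        df_among=len(pops) - 1,
        df_within=len(haps) - len(pops),
        sigma2_a=s2a,
        sigma2_w=s2w,
        n_prime=(len(haps) - sum(s * s for s in sizes) / len(haps)) / (len(pops) - 1),
        phi_st=phi,
        pct_among=pct_among,
        pct_within=pct_within,
        p_value=p_value,
        n_permutations=n_permutations,
        seed=seed,
    )


@dataclass(frozen=True)
class FstMatrix:
    """Pairwise population Phi_ST matrix with optional permutation p-values.

    Negative estimates (sampling noise around zero differentiation) are
    retained as computed.
    """

    populations: tuple[str, ...]
    values: np.ndarray
    p_values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.allclose(v, v.T) or np.any(np.diag(v) != 0):
            raise ValueError("Phi_ST matrix must be symmetric with zero diagonal")
        object.__setattr__(self, "values", v)


def pairwise_fst(
    groups: Mapping[str, Sequence[str]],
    distances: DistanceMatrix,
    n_permutations: int = 0,
    seed: int | None = None,
    metric: Literal["pairwise_difference", "haplotype_identity"] = "pairwise_difference",
) -> FstMatrix:
    """Pairwise Phi_ST: a two-population AMOVA for every population pair."""
    pops = list(groups)
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    m = len(pops)
    values = np.zeros((m, m))
    p_values = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(i + 1, m):
            sub = {pops[i]: groups[pops[i]], pops[j]: groups[pops[j]]}
            res = amova(
                sub, distances, n_permutations=n_permutations, seed=seed, metric=metric
            )
            values[i, j] = values[j, i] = res.phi_st
            p_values[i, j] = p_values[j, i] = res.p_value
    return FstMatrix(tuple(pops), values, p_values)
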