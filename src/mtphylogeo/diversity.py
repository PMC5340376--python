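"""Gene (haplotype) diversity and nucleotide diversity.

Estimators and sampling variances follow Nei (1987):

* gene diversity        h  = n (1 - sum p_i^2) / (n - 1)
* nucleotide diversity  pi = mean per-site proportion of differences over
  all unordered sequence pairs (raw p-differences, the DnaSP convention)

Both are computed on the complete-deletion site set.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .distances import hamming_matrix
from .seqio import Alignment


@dataclass(frozen=True)
class DiversityResult:
    """Diversity summary for one group of sequences.

    ``k_bar`` is the mean number of pairwise differences in sites;
    ``pi = k_bar / L`` with L the retained alignment length.
    """

    n: int
    n_haplotypes: int
    h: float
    h_sd: float
    pi: float
    pi_sd: float
    k_bar: float
    L: int


def gene_diversity(counts) -> float:
    """Gene (haplotype) diversity with the n/(n-1) small-sample correction."""
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    n = counts.sum()
    if n < 2:
        raise ValueError("gene diversity requires n >= 2")
    p = counts / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def gene_diversity_variance(counts) -> float:
    """Sampling variance of h (Nei 1987, eq. 8.12)."""
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    n = counts.sum()
    if n < 2:
        raise ValueError("requires n >= 2")
    p = counts / n
    s2 = float(np.sum(p**2))
    s3 = float(np.sum(p**3))
    return max(0.0, 2.0 / (n * (n - 1)) * (2.0 * (n - 2) * (s3 - s2**2) + s2 - s2**2))


def mean_pairwise_differences(alignment: Alignment) -> tuple[float, int]:
    """(k_bar, retained L): mean raw differences over all unordered pairs."""
    masked = alignment.masked()
    if masked.n < 2:
        raise ValueError("needs at least 2 sequences")
    d = hamming_matrix(masked)
    n = masked.n
    k_bar = float(d[np.triu_indices(n, k=1)].mean())
    return k_bar, masked.length


def nucleotide_diversity(alignment: Alignment) -> float:
    """Per-site nucleotide diversity pi over the complete-deletion site set."""
    k_bar, L = mean_pairwise_differences(alignment)
    if L == 0:
        return 0.0
    return k_bar / L


def nucleotide_diversity_variance(pi: float, n: int, L: int) -> float:
    """Sampling variance of pi (Nei 1987, eq. 10.7; no-recombination form)."""
    if n < 2 or L <= 0:
        raise ValueError("requires n >= 2 and L > 0")
    return (n + 1) / (3.0 * (n - 1) * L) * pi + 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1)) * pi**2


def diversity_summary(alignment: Alignment) -> DiversityResult:
    """Full diversity summary (h +/- sd, pi +/- sd, k_bar) for one group."""
    masked = alignment.masked()
    if masked.n < 2:
        raise ValueError("needs at least 2 sequences")
    counts = np.asarray(list(_haplotype_counts(masked).values()), dtype=float)
    h = gene_diversity(counts)
    h_sd = math.sqrt(gene_diversity_variance(counts))
    k_bar, L = mean_pairwise_differences(alignment)
    pi = k_bar / L if L else 0.0
    pi_sd = math.sqrt(nucleotide_diversity_variance(pi, masked.n, L)) if L else 0.0
    return DiversityResult(masked.n, len(counts), h, h_sd, pi, pi_sd, k_bar, L)


def _haplotype_counts(masked: Alignment) -> dict[str, int]:
    counts: dict[str, int] = {}
    for s in masked.seqs:
        counts[s] = counts.get(s, 0) + 1
    return counts


def brute_force_k_bar(seqs) -> float:
    """Oracle: mean pairwise differences by explicit double loop (small n only)."""
    seqs = list(seqs)
    total = 0
    pairs = 0
    for a, b in itertools.combinations(seqs, 2):
        total += sum(x != y for x, y in zip(a, b))
        pairs += 1
    return total / pairs
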