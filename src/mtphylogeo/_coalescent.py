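"""Neutral coalescent machinery.

Shared by the neutrality tests' significance procedure, the sudden-expansion
parametric bootstrap and the synthetic-data module. Time is measured in
coalescent units of the *current* population (pairwise coalescence rate 1);
mutations fall on branches as a Poisson process with rate theta/2 per unit
scaled time per lineage, so a pair of sequences at equilibrium differs at
theta sites in expectation.

A single ancestral size change is supported: beyond ``epoch_time`` the
coalescence rate is multiplied by ``rate_ratio`` (> 1 means the ancestral
population was smaller). For the sudden-expansion model with parameters
(tau, theta0, theta1) use ``epoch_time = tau / theta1`` and
``rate_ratio = theta1 / theta0`` with mutation parameter theta1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

TRANSITION = {65: 71, 71: 65, 67: 84, 84: 67}  # A<->G, C<->T (byte values)
TRANSVERSIONS = {
    65: (67, 84), 71: (67, 84),  # purines -> pyrimidines
    67: (65, 71), 84: (65, 71),  # pyrimidines -> purines
}


@dataclass
class Genealogy:
    """A binary coalescent genealogy.

    Leaves are nodes ``0..n-1``; internal nodes ``n..2n-2`` in merge order
    (the root is ``2n-2``). ``blen[v]`` is the scaled length of the branch
    above node v (0 for the root).
    """

    n: int
    parent: np.ndarray
    blen: np.ndarray
    children: list[tuple[int, int]]

    @property
    def root(self) -> int:
        return 2 * self.n - 2

    def descendant_counts(self) -> np.ndarray:
        c = np.zeros(2 * self.n - 1, dtype=np.int64)
        c[: self.n] = 1
        for v, (a, b) in enumerate(self.children, start=self.n):
            c[v] = c[a] + c[b]
        return c

    def leaf_masks(self) -> np.ndarray:
        m = np.zeros((2 * self.n - 1, self.n), dtype=bool)
        m[np.arange(self.n), np.arange(self.n)] = True
        for v, (a, b) in enumerate(self.children, start=self.n):
            m[v] = m[a] | m[b]
        return m

    def total_length(self) -> float:
        return float(self.blen.sum())


def sample_genealogy(n: int, rng: np.random.Generator, *, epoch_time: float | None = None,
                     rate_ratio: float = 1.0) -> Genealogy:
    """Draw one neutral genealogy (Hudson's algorithm, piecewise-constant size)."""
    if n < 2:
        raise ValueError("need n >= 2")
    total = 2 * n - 1
    parent = np.full(total, -1, dtype=np.int64)
    node_time = np.zeros(total)
    blen = np.zeros(total)
    children: list[tuple[int, int]] = []
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        base = k * (k - 1) / 2.0
        if epoch_time is not None and t < epoch_time:
            w = rng.exponential(1.0 / base)
            if t + w > epoch_time:
                t = epoch_time  # memoryless: redraw under the ancestral rate
                continue
            t += w
        else:
            mult = rate_ratio if epoch_time is not None else 1.0
            t += rng.exponential(1.0 / (base * mult))
        i = int(rng.integers(len(active)))
        a = active.pop(i)
        j = int(rng.integers(len(active)))
        b = active.pop(j)
        parent[a] = parent[b] = nxt
        node_time[nxt] = t
        blen[a] = t - node_time[a]
        blen[b] = t - node_time[b]
        children.append((a, b))
        active.append(nxt)
        nxt += 1
    return Genealogy(n, parent, blen, children)


def branch_mutations(g: Genealogy, theta: float, rng: np.random.Generator) -> np.ndarray:
    """Poisson(theta/2 * branch length) mutation counts per branch."""
    m = rng.poisson(g.blen * theta / 2.0)
    m[g.root] = 0
    return m


def infinite_sites_stats(g: Genealogy, m: np.ndarray) -> tuple[int, float, int]:
    """(S, mean pairwise differences, haplotype count) under infinite sites.

    A branch carrying ``m_b`` mutations separates ``c_b * (n - c_b)`` pairs;
    two tips share a haplotype iff no mutation lies on the path between them.
    """
    n = g.n
    c = g.descendant_counts()
    S = int(m.sum())
    pairs = n * (n - 1) / 2.0
    k_bar = float((m * c * (n - c)).sum() / pairs)
    # haplotype ids top-down: parent index always exceeds child index
    hap = np.zeros(2 * n - 1, dtype=np.int64)
    fresh = 0
    for v in range(2 * n - 3, -1, -1):
        if m[v] == 0:
            hap[v] = hap[g.parent[v]]
        else:
            fresh += 1
            hap[v] = fresh
    K = len(np.unique(hap[:n]))
    return S, k_bar, K


def pairwise_difference_matrix(g: Genealogy, m: np.ndarray) -> np.ndarray:
    """(n, n) matrix of pairwise differences implied by the branch mutations."""
    n = g.n
    masks = g.leaf_masks()
    d = np.zeros((n, n), dtype=np.int64)
    for v in range(2 * n - 2):
        if m[v]:
            inside = masks[v]
            d[np.ix_(inside, ~inside)] += m[v]
    return d + d.T


def mutate_base(base: int, rng: np.random.Generator, kappa: float) -> int:
    """New base after one mutation with transition:transversion bias kappa."""
    if rng.random() < kappa / (kappa + 2.0):
        return TRANSITION[base]
    return TRANSVERSIONS[base][int(rng.integers(2))]


def drop_sequences(g: Genealogy, m: np.ndarray, ancestral: np.ndarray,
                   rng: np.random.Generator, kappa: float = 4.0) -> np.ndarray:
    """Evolve sequences down the genealogy (finite sites, uniform site choice).

    Returns an (n, L) uint8 byte array of tip sequences.
    """
    L = len(ancestral)
    total = 2 * g.n - 1
    seqs: dict[int, np.ndarray] = {g.root: ancestral.copy()}
    for v in range(total - 2, -1, -1):
        s = seqs[g.parent[v]].copy()
        for _ in range(int(m[v])):
            j = int(rng.integers(L))
            s[j] = mutate_base(int(s[j]), rng, kappa)
        seqs[v] = s
    return np.stack([seqs[i] for i in range(g.n)])
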