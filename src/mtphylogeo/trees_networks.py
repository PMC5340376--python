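"""Neighbour-joining trees with bootstrap support, and median-joining networks.

The median-joining algorithm (Bandelt, Forster & Roehl 1999) alternates two
steps until a fixed point: (i) build the minimum spanning network (all
edges that occur in some minimum spanning tree, within tolerance epsilon)
over the current vertex set; (ii) for triplets connected through a common
vertex, add the quasi-median (majority state per site) as a new vertex
whenever it strictly shortens the local subnetwork. Obsolete median
vectors (degree <= 2 and not shortening any path) are pruned.
"""

from __future__ import annotations

import logging
from collections import Counter

import networkx as nx
import numpy as np
import skbio
from skbio.tree import TreeNode

from .distances import DistanceMatrix, distance_matrix
from .haplotypes import HaplotypeTable
from .seqio import Alignment

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Neighbour joining

def nj_tree(matrix: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbour joining; negative branch lengths clamped to 0."""
    if len(matrix.labels) < 3:
        raise ValueError("NJ needs at least 3 taxa")
    m = matrix.matrix
    if not np.all(np.isfinite(m)):
        raise ValueError("distance matrix contains undefined (saturated) entries")
    dm = skbio.DistanceMatrix(m, ids=list(matrix.labels))
    tree = skbio.tree.nj(dm)
    clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    if clamped:
        logger.info("clamped %d negative NJ branch lengths to 0", clamped)
    return tree


def tree_bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, each canonicalized as the
    lexicographically smaller side."""
    leaves = frozenset(t.name for t in tree.tips())
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        out.add(min(side, other, key=lambda s: sorted(s)))
    return out


def bootstrap_support(alignment: Alignment, *, reps: int = 1000,
                      seed: int | np.random.Generator = 0,
                      metric: str = "k2p") -> dict[frozenset[str], float]:
    """Site-resampling bootstrap support (percent) per bipartition of the NJ tree.

    Columns of the complete-deletion alignment are resampled with
    replacement, the tree rebuilt with the same distance metric, and each
    bipartition's recovery frequency reported.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    masked = alignment.masked()
    L = masked.length
    arr = masked.to_array()
    counts: Counter[frozenset[str]] = Counter()
    for _ in range(reps):
        cols = rng.integers(L, size=L)
        res = arr[:, cols]
        boot = Alignment(masked.ids, tuple(row.tobytes().decode() for row in res))
        try:
            tree = nj_tree(distance_matrix(boot, metric))
        except ValueError:  # saturated replicate under k2p
            continue
        counts.update(tree_bipartitions(tree))
    return {split: 100.0 * c / reps for split, c in counts.items()}


def split_support(support: dict[frozenset[str], float], side: set[str],
                  all_labels: set[str]) -> float:
    """Support for the bipartition separating ``side`` from the rest."""
    other = frozenset(all_labels - side)
    key = min(frozenset(side), other, key=lambda s: sorted(s))
    return support.get(key, 0.0)


# ---------------------------------------------------------------------------
# Median-joining network

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _minimum_spanning_network(seqs: dict[str, str], epsilon: int = 0) -> nx.Graph:
    """All edges joining components that are still separate at distance
    level (d - epsilon); with epsilon = 0 this is the union of all MSTs."""
    names = sorted(seqs)
    g = nx.Graph()
    g.add_nodes_from(names)
    edges = sorted(
        ((_hamming(seqs[a], seqs[b]), a, b)
         for i, a in enumerate(names) for b in names[i + 1:]),
        key=lambda t: (t[0], t[1], t[2]),
    )
    # connection level of each component pair, via Kruskal over distance levels
    parent = {n: n for n in names}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    levels = sorted({w for w, _, _ in edges})
    comp_at_level: dict[int, dict[str, str]] = {}
    for level in levels:
        comp_at_level[level] = {n: find(n) for n in names}
        for w, a, b in edges:
            if w == level and find(a) != find(b):
                parent[find(a)] = find(b)
    g_edges = []
    for w, a, b in edges:
        # include if endpoints were separate considering merges below w - epsilon
        ref_levels = [lv for lv in levels if lv >= w - epsilon]
        ref = comp_at_level[min(ref_levels)] if ref_levels else {n: n for n in names}
        if ref[a] != ref[b]:
            g_edges.append((a, b, w))
    g.add_weighted_edges_from(g_edges)
    return g


def _quasi_median(u: str, v: str, w: str) -> str:
    """Majority state per site; three-way ties resolved to the first sequence."""
    out = []
    for a, b, c in zip(u, v, w):
        if a == b or a == c:
            out.append(a)
        elif b == c:
            out.append(b)
        else:
            out.append(a)
    return "".join(out)


def median_joining_network(sequences, ids=None, *, freqs=None, epsilon: int = 0,
                           max_iter: int = 20) -> nx.Graph:
    """Median-joining network of aligned haplotype sequences.

    Returns a networkx Graph whose nodes carry ``sequence``, ``is_median``
    and ``frequency`` attributes and whose edges carry integer ``weight``
    (mutational steps). Median vectors are named ``mv1, mv2, ...``.
    """
    seq_list = list(sequences)
    if len(set(seq_list)) < 2:
        raise ValueError("need at least 2 distinct haplotypes")
    if len({len(s) for s in seq_list}) != 1:
        raise ValueError("haplotypes must be aligned (equal length)")
    if ids is None:
        ids = [f"H{i + 1}" for i in range(len(seq_list))]
    if freqs is None:
        freqs = [1] * len(seq_list)
    seqs: dict[str, str] = {}
    freq: dict[str, int] = {}
    for name, s, f in zip(ids, seq_list, freqs):
        if s in seqs.values():
            continue
        seqs[name] = s
        freq[name] = int(f)
    observed = set(seqs)
    n_median = 0

    for _ in range(max_iter):
        msn = _minimum_spanning_network(seqs, epsilon)
        added = False
        known = set(seqs.values())
        for v in sorted(msn.nodes):
            nbrs = sorted(msn.neighbors(v))
            for i, u in enumerate(nbrs):
                for w in nbrs[i + 1:]:
                    m = _quasi_median(seqs[u], seqs[v], seqs[w])
                    if m in known:
                        continue
                    old_cost = msn[u][v]["weight"] + msn[v][w]["weight"]
                    new_cost = (_hamming(seqs[u], m) + _hamming(seqs[v], m)
                                + _hamming(seqs[w], m))
                    if new_cost < old_cost:
                        n_median += 1
                        name = f"mv{n_median}"
                        seqs[name] = m
                        freq[name] = 0
                        known.add(m)
                        added = True
        if not added:
            break

    # prune obsolete medians to a fixed point
    while True:
        msn = _minimum_spanning_network(seqs, epsilon)
        removable = []
        for name in sorted(set(seqs) - observed):
            deg = msn.degree(name)
            if deg <= 1:
                removable.append(name)
            elif deg == 2:
                x, y = sorted(msn.neighbors(name))
                if _hamming(seqs[x], seqs[y]) <= msn[x][name]["weight"] + msn[name][y]["weight"]:
                    removable.append(name)
        if not removable:
            break
        for name in removable:
            del seqs[name]
            del freq[name]

    net = _minimum_spanning_network(seqs, epsilon)
    for name in net.nodes:
        net.nodes[name]["sequence"] = seqs[name]
        net.nodes[name]["is_median"] = name not in observed
        net.nodes[name]["frequency"] = freq[name]
    return net


def network_from_table(table: HaplotypeTable, epsilon: int = 0) -> nx.Graph:
    """Median-joining network of a haplotype table, with per-population counts
    attached to each observed vertex (for pie-chart rendering)."""
    net = median_joining_network(
        table.sequences,
        ids=list(table.counts.index),
        freqs=list(table.totals),
        epsilon=epsilon,
    )
    for name in net.nodes:
        if not net.nodes[name]["is_median"]:
            net.nodes[name]["populations"] = {
                p: int(c) for p, c in table.counts.loc[name].items() if c > 0
            }
    return net


def write_network_graphml(net: nx.Graph, path) -> None:
    g = net.copy()
    for _, data in g.nodes(data=True):
        if "populations" in data:
            data["populations"] = ";".join(f"{p}:{c}" for p, c in data["populations"].items())
    nx.write_graphml(g, path)


def write_network_edgelist(net: nx.Graph, path) -> None:
    import pandas as pd

    rows = [{"source": a, "target": b, "steps": d["weight"]} for a, b, d in net.edges(data=True)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
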