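"""Haplotype collapsing and per-site alignment statistics.

Haplotype identity is exact sequence identity over the complete-deletion
site set, so the haplotype table is consistent with every other statistic
in the package (which all use the same retained sites).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import Alignment, Dataset, write_fasta


@dataclass(frozen=True)
class HaplotypeTable:
    """Unique haplotypes with per-population counts.

    Attributes
    ----------
    sequences:
        Haplotype sequences over the retained site set, ordered by
        decreasing total count (ties broken by first occurrence).
    counts:
        DataFrame of shape (n_haplotypes, n_populations); row labels are
        ``H1, H2, ...``; column sums equal population sample sizes.
    assignments:
        Specimen id -> 0-based haplotype index.
    """

    sequences: tuple[str, ...]
    counts: pd.DataFrame
    assignments: dict[str, int]

    @property
    def n_haplotypes(self) -> int:
        return len(self.sequences)

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def expand(self) -> list[str]:
        """Multiset of specimen-level sequences implied by the counts."""
        out: list[str] = []
        for seq, total in zip(self.sequences, self.totals.to_numpy()):
            out.extend([seq] * int(total))
        return out

    def to_frame(self) -> pd.DataFrame:
        df = self.counts.copy()
        df.insert(0, "total", self.totals)
        df.insert(1, "sequence", list(self.sequences))
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="haplotype")

    def write_fasta(self, path: str | Path) -> None:
        ids = tuple(self.counts.index)
        write_fasta(Alignment(ids, self.sequences), path)


@dataclass(frozen=True)
class SiteStats:
    """Per-site summary of an alignment (over retained sites).

    ``S`` counts variable sites, ``parsimony_informative`` the subset where
    at least two states each occur in at least two sequences. ``gc`` and
    ``base_frequencies`` summarise composition over all retained cells.
    """

    n_sites: int
    S: int
    parsimony_informative: int
    gc: float
    base_frequencies: dict[str, float]


def collapse_haplotypes(dataset: Dataset) -> HaplotypeTable:
    """Collapse a dataset's sequences into a haplotype table.

    Equivalence is exact identity over the complete-deletion site set.
    Ordering: decreasing total count, ties by first occurrence in the
    alignment.
    """
    aln = dataset.alignment
    if aln.n == 0:
        raise ValueError("empty alignment")
    masked = aln.masked()
    first_seen: dict[str, int] = {}
    members: dict[str, list[str]] = {}
    for sid, seq in zip(masked.ids, masked.seqs):
        if seq not in first_seen:
            first_seen[seq] = len(first_seen)
        members.setdefault(seq, []).append(sid)

    pops = list(dataset.popmap.populations)
    spec_pop = dataset.popmap.specimen_to_pop
    totals = {seq: len(ms) for seq, ms in members.items()}
    order = sorted(members, key=lambda s: (-totals[s], first_seen[s]))

    counts = pd.DataFrame(0, index=[f"H{i + 1}" for i in range(len(order))], columns=pops)
    assignments: dict[str, int] = {}
    for h_idx, seq in enumerate(order):
        for sid in members[seq]:
            counts.iloc[h_idx, pops.index(spec_pop[sid])] += 1
            assignments[sid] = h_idx
    return HaplotypeTable(tuple(order), counts, assignments)


def site_statistics(alignment: Alignment) -> SiteStats:
    """Variable / parsimony-informative site counts and base composition."""
    if alignment.n == 0:
        raise ValueError("empty alignment")
    masked = alignment.masked()
    arr = masked.to_array()
    n_sites = masked.length
    S = 0
    pi_sites = 0
    for j in range(n_sites):
        col = arr[:, j]
        states, freqs = np.unique(col, return_counts=True)
        if len(states) >= 2:
            S += 1
            if (freqs >= 2).sum() >= 2:
                pi_sites += 1
    total = arr.size
    base_freqs = {}
    for b in "ACGT":
        base_freqs[b] = float((arr == b.encode()).sum() / total) if total else 0.0
    gc = base_freqs["G"] + base_freqs["C"]
    return SiteStats(n_sites, S, pi_sites, gc, base_freqs)


def shared_haplotype_report(table: HaplotypeTable) -> pd.DataFrame:
    """Haplotypes ranked by total count with per-population breakdowns.

    Returns a frame with columns ``total``, ``breakdown`` (formatted
    ``POP:count`` pairs, populations with zero count omitted) plus the raw
    per-population counts.
    """
    df = table.counts.copy()
    df.insert(0, "total", table.totals)
    breakdown = []
    for _, row in table.counts.iterrows():
        nonzero = row[row > 0].sort_values(ascending=False)
        breakdown.append(", ".join(f"{pop}:{int(c)}" for pop, c in nonzero.items()))
    df.insert(1, "breakdown", breakdown)
    return df.sort_values("total", ascending=False, kind="stable")
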