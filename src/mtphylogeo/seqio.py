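"""Reading, validating and writing aligned mtDNA sequence data.

Sequences are stored uppercase over the alphabet ``{A, C, G, T, N, -}``.
All downstream statistics in this package use *complete deletion*: any
alignment column containing a gap or an ``N`` in any sequence is excluded
once, so every statistic (haplotype identity, diversity, distances,
mismatch spectra) is computed on the same retained site set.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_CHARS = frozenset("ACGTN-")
UNAMBIGUOUS = frozenset("ACGT")
#: IUPAC ambiguity codes other than N (mapped to N when ``ambiguous="to_n"``)
AMBIGUITY_CODES = frozenset("RYSWKMBDHV")


class AlignmentError(ValueError):
    """Raised for malformed alignments (ragged rows, duplicate ids, ...)."""


@dataclass(frozen=True)
class Alignment:
    """An aligned set of nucleotide sequences with optional locus partitions.

    Parameters
    ----------
    ids:
        Ordered, unique specimen identifiers.
    seqs:
        Equal-length uppercase strings over ``{A,C,G,T,N,-}``, parallel to
        ``ids``.
    partitions:
        Named half-open site ranges, e.g. ``{"16S": (0, 421), "COI": (421, 792)}``.
        Ranges must be disjoint and lie within ``[0, length]``.
    """

    ids: tuple[str, ...]
    seqs: tuple[str, ...]
    partitions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs must have the same length")
        if len(set(self.ids)) != len(self.ids):
            dups = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dups}")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise AlignmentError(f"ragged alignment: sequence lengths {sorted(lengths)}")
        for s, sid in zip(self.seqs, self.ids):
            bad = set(s) - VALID_CHARS
            if bad:
                raise AlignmentError(f"invalid characters {sorted(bad)} in sequence {sid!r}")
        covered: set[int] = set()
        for name, (start, stop) in self.partitions.items():
            if not (0 <= start <= stop <= self.length):
                raise AlignmentError(f"partition {name!r} out of range: ({start}, {stop})")
            rng = set(range(start, stop))
            if covered & rng:
                raise AlignmentError(f"partition {name!r} overlaps another partition")
            covered |= rng

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def to_array(self) -> np.ndarray:
        """Alignment as an (n, L) array of single-byte characters."""
        return np.frombuffer("".join(self.seqs).encode(), dtype="S1").reshape(self.n, self.length)

    def retained_sites(self) -> np.ndarray:
        """Indices of columns free of gaps and Ns in every sequence (complete deletion)."""
        if self.n == 0:
            return np.arange(0)
        arr = self.to_array()
        keep = np.ones(self.length, dtype=bool)
        for ch in (b"N", b"-"):
            keep &= ~(arr == ch).any(axis=0)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("complete deletion: excluded %d of %d sites", n_dropped, self.length)
        return np.nonzero(keep)[0]

    def masked(self) -> "Alignment":
        """Alignment restricted to the complete-deletion site set (partitions remapped)."""
        sites = self.retained_sites()
        return self.restrict(sites)

    def restrict(self, sites: np.ndarray) -> "Alignment":
        """Alignment restricted to the given sorted site indices."""
        sites = np.asarray(sites, dtype=int)
        arr = self.to_array()[:, sites]
        seqs = tuple(row.tobytes().decode() for row in arr)
        # remap partitions by counting retained sites per (sorted) range
        pos = 0
        new_parts: dict[str, tuple[int, int]] = {}
        for name, (start, stop) in sorted(self.partitions.items(), key=lambda kv: kv[1][0]):
            k = int(((sites >= start) & (sites < stop)).sum())
            new_parts[name] = (pos, pos + k)
            pos += k
        return Alignment(self.ids, seqs, new_parts)

    def subset(self, ids: Sequence[str]) -> "Alignment":
        """Alignment restricted to the given specimens, in the given order."""
        index = {sid: i for i, sid in enumerate(self.ids)}
        missing = [sid for sid in ids if sid not in index]
        if missing:
            raise AlignmentError(f"unknown specimen ids: {missing}")
        return Alignment(tuple(ids), tuple(self.seqs[index[i]] for i in ids), dict(self.partitions))


@dataclass(frozen=True)
class PopulationMap:
    """Specimen-to-population assignments plus per-population metadata."""

    specimen_to_pop: dict[str, str]
    pop_info: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, pop in self.specimen_to_pop.items():
            if not pop:
                raise ValueError(f"empty population code for specimen {sid!r}")

    @property
    def populations(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for pop in self.specimen_to_pop.values():
            seen.setdefault(pop)
        return tuple(seen)

    def members(self, pop: str) -> tuple[str, ...]:
        return tuple(s for s, p in self.specimen_to_pop.items() if p == pop)

    def coordinates(self) -> dict[str, tuple[float, float]]:
        """(lat, lon) per population, for populations that carry coordinates."""
        out = {}
        for pop, info in self.pop_info.items():
            lat, lon = info.get("lat"), info.get("lon")
            if lat is not None and lon is not None:
                out[pop] = (float(lat), float(lon))
        return out


@dataclass(frozen=True)
class Dataset:
    """An alignment joined with its population map and optional lineage labels."""

    alignment: Alignment
    popmap: PopulationMap
    lineages: dict[str, str] | None = None

    def __post_init__(self) -> None:
        unmapped = [i for i in self.alignment.ids if i not in self.popmap.specimen_to_pop]
        if unmapped:
            raise ValueError(f"specimens missing from population map: {unmapped}")
        if self.lineages is not None:
            missing = [i for i in self.alignment.ids if i not in self.lineages]
            if missing:
                raise ValueError(f"specimens missing lineage labels: {missing}")

    def population_labels(self) -> tuple[str, ...]:
        return tuple(self.popmap.specimen_to_pop[i] for i in self.alignment.ids)

    def subset_by_population(self, pops: Iterable[str]) -> "Dataset":
        pops = set(pops)
        ids = [i for i in self.alignment.ids if self.popmap.specimen_to_pop[i] in pops]
        return Dataset(
            self.alignment.subset(ids),
            self.popmap,
            {i: self.lineages[i] for i in ids} if self.lineages else None,
        )

    def subset_by_lineage(self, lineage: str) -> "Dataset":
        if self.lineages is None:
            raise ValueError("dataset carries no lineage labels")
        ids = [i for i in self.alignment.ids if self.lineages[i] == lineage]
        return Dataset(self.alignment.subset(ids), self.popmap, {i: lineage for i in ids})


def read_fasta(path: str | Path, *, partition_name: str | None = None,
               ambiguous: str = "to_n") -> Alignment:
    """Read an aligned FASTA file.

    Parameters
    ----------
    path:
        FASTA file of pre-aligned sequences.
    partition_name:
        Optional name for a single partition covering the whole alignment.
    ambiguous:
        ``"to_n"`` maps IUPAC ambiguity codes (R, Y, ...) to N;
        ``"reject"`` raises on them.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    ids, seqs = [], []
    for rec in records:
        s = str(rec.seq).upper()
        amb = set(s) & AMBIGUITY_CODES
        if amb:
            if ambiguous == "reject":
                raise AlignmentError(f"ambiguity codes {sorted(amb)} in record {rec.id!r}")
            s = re.sub(f"[{''.join(AMBIGUITY_CODES)}]", "N", s)
        ids.append(rec.id)
        seqs.append(s)
    parts = {partition_name: (0, len(seqs[0]))} if partition_name else {}
    return Alignment(tuple(ids), tuple(seqs), parts)


def write_fasta(alignment: Alignment, path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in zip(alignment.ids, alignment.seqs)]
    SeqIO.write(records, str(path), "fasta")


def concatenate_loci(a1: Alignment, a2: Alignment, *, names: tuple[str, str] | None = None,
                     id_strip: str | None = None) -> Alignment:
    """Concatenate two single-locus alignments specimen-wise.

    Ids must match exactly between loci; ``id_strip`` is an optional regex
    removed from ids of both alignments first (e.g. a locus suffix).
    Partitions of the result record each locus' site range.
    """
    def clean(ids: tuple[str, ...]) -> tuple[str, ...]:
        return tuple(re.sub(id_strip, "", i) for i in ids) if id_strip else ids

    ids1, ids2 = clean(a1.ids), clean(a2.ids)
    if set(ids1) != set(ids2):
        only1 = sorted(set(ids1) - set(ids2))
        only2 = sorted(set(ids2) - set(ids1))
        raise AlignmentError(
            f"id sets differ between loci: only in first {only1}, only in second {only2}"
        )
    lookup2 = {i: s for i, s in zip(ids2, a2.seqs)}
    seqs = tuple(s1 + lookup2[i] for i, s1 in zip(ids1, a1.seqs))
    if names is None:
        names = (
            next(iter(a1.partitions), "locus1"),
            next(iter(a2.partitions), "locus2"),
        )
    partitions = {names[0]: (0, a1.length), names[1]: (a1.length, a1.length + a2.length)}
    if a1.length == 0:
        partitions = {names[1]: (0, a2.length)}
    elif a2.length == 0:
        partitions = {names[0]: (0, a1.length)}
    return Alignment(ids1, seqs, partitions)


def load_population_map(path: str | Path) -> PopulationMap:
    """Load a TSV population map with header ``specimen  population  country [lat lon]``."""
    df = pd.read_csv(path, sep="\t", dtype={"specimen": str, "population": str})
    required = {"specimen", "population"}
    if not required <= set(df.columns):
        raise ValueError(f"population map must have columns {sorted(required)}; got {list(df.columns)}")
    if df["specimen"].duplicated().any():
        dups = sorted(df.loc[df["specimen"].duplicated(), "specimen"])
        raise ValueError(f"duplicate specimens in population map: {dups}")
    spec_to_pop = dict(zip(df["specimen"], df["population"]))
    pop_info: dict[str, dict] = {}
    for _, row in df.iterrows():
        info = pop_info.setdefault(row["population"], {})
        for key in ("country", "lat", "lon"):
            if key in df.columns and pd.notna(row[key]):
                info[key] = row[key]
    return PopulationMap(spec_to_pop, pop_info)


def write_population_map(popmap: PopulationMap, path: str | Path) -> None:
    rows = []
    for sid, pop in popmap.specimen_to_pop.items():
        info = popmap.pop_info.get(pop, {})
        rows.append({"specimen": sid, "population": pop, **info})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
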