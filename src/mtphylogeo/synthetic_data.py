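"""Synthetic two-locus mtDNA datasets with the structure the pipeline assumes.

The default configuration emulates the study design this package targets:
ten East Asian sampling sites totalling 239 specimens, two concatenated
loci of 421 and 371 aligned sites, and two deeply diverged maternal
lineages (A and B) mixed within some populations. Each lineage carries a
star-like post-expansion mutation structure: every specimen receives
Poisson(tau/2) private mutations from its lineage founder, so pairwise
differences within a lineage are approximately Poisson(tau) and the
pooled mismatch distribution is bimodal (within-lineage mode near tau,
between-lineage mode near the founder divergence) while the per-lineage
distributions are unimodal.

A full neutral coalescent engine (``simulate_coalescent_alignment``) is
available as an alternative when star genealogies are too idealized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import _coalescent
from .seqio import Alignment, Dataset, PopulationMap

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
#: ancestral base composition (A, C, G, T): AT-biased, GC ~ 36%
BASE_FREQS = (0.315, 0.175, 0.19, 0.32)


@dataclass(frozen=True)
class PopulationSpec:
    """One sampling site: name, country, lineage-A and lineage-B counts."""

    name: str
    country: str
    n_a: int
    n_b: int
    lat: float | None = None
    lon: float | None = None

    @property
    def n(self) -> int:
        return self.n_a + self.n_b


#: Default sampling design: 10 populations, 239 specimens, lineage mix as in
#: the study (A total 118, B total 121). Coordinates are approximate site
#: locations, used only for geographic distance matrices.
DEFAULT_POPULATIONS = (
    PopulationSpec("SMR", "Taiwan", 0, 26, 24.81, 121.24),
    PopulationSpec("MTR", "Taiwan", 19, 5, 24.58, 120.90),
    PopulationSpec("CLR", "Taiwan", 22, 0, 22.66, 120.35),
    PopulationSpec("BLJ", "Japan", 30, 0, 35.33, 136.16),
    PopulationSpec("KLJ", "Japan", 20, 0, 36.04, 140.39),
    PopulationSpec("TLC", "China", 21, 3, 31.23, 120.13),
    PopulationSpec("MRC", "China", 2, 23, 26.05, 119.31),
    PopulationSpec("JRC", "China", 4, 18, 24.48, 117.81),
    PopulationSpec("SRC", "China", 0, 15, 22.58, 114.12),
    PopulationSpec("HRK", "Korea", 0, 31, 37.53, 126.98),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the two-lineage star-expansion generator.

    ``divergence`` is the number of fixed differences between the two
    lineage founders; ``taus`` are the per-lineage expansion parameters
    (expected pairwise differences within a lineage); ``theta0s`` are
    accepted for the coalescent engine (pre-expansion diversity) and are
    zero under the star approximation; ``kappa`` is the
    transition:transversion bias applied to every mutation.
    """

    locus_lengths: tuple[int, int] = (421, 371)
    locus_names: tuple[str, str] = ("16S", "COI")
    populations: tuple[PopulationSpec, ...] = DEFAULT_POPULATIONS
    divergence: int = 12
    taus: dict = field(default_factory=lambda: {"A": 4.713, "B": 1.108})
    theta0s: dict = field(default_factory=lambda: {"A": 0.0, "B": 0.0})
    kappa: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(p.n_a < 0 or p.n_b < 0 for p in self.populations):
            raise ValueError("population counts must be >= 0")
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")

    @property
    def L(self) -> int:
        return sum(self.locus_lengths)

    @property
    def n_total(self) -> int:
        return sum(p.n for p in self.populations)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth emitted with each simulated dataset."""

    lineage_of: dict[str, str]
    founders: dict[str, str]
    mutation_counts: dict[str, int]
    taus: dict[str, float]
    theta0s: dict[str, float]
    divergence_sites: tuple[int, ...]
    seed: int

    def write_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["divergence_sites"] = list(self.divergence_sites)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


def _random_sequence(L: int, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(BASES, size=L, p=BASE_FREQS)


def _mutate_at(seq: np.ndarray, site: int, rng: np.random.Generator, kappa: float) -> None:
    seq[site] = _coalescent.mutate_base(int(seq[site]), rng, kappa)


def simulate_dataset(config: SimulationConfig = SimulationConfig()
                     ) -> tuple[dict[str, Alignment], PopulationMap, TruthRecord]:
    """Generate per-locus alignments, a population map and the truth record.

    Same seed, same config -> byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    L = config.L
    ancestral = _random_sequence(L, rng)

    founders = {"B": ancestral.copy(), "A": ancestral.copy()}
    div_sites = tuple(sorted(rng.choice(L, size=config.divergence, replace=False).tolist()))
    for site in div_sites:
        before = founders["A"][site]
        while founders["A"][site] == before:
            _mutate_at(founders["A"], site, rng, config.kappa)

    ids: list[str] = []
    seqs: list[str] = []
    lineage_of: dict[str, str] = {}
    mutation_counts: dict[str, int] = {}
    spec_to_pop: dict[str, str] = {}
    pop_info: dict[str, dict] = {}
    for pop in config.populations:
        pop_info[pop.name] = {"country": pop.country}
        if pop.lat is not None:
            pop_info[pop.name].update(lat=pop.lat, lon=pop.lon)
        k = 0
        for lineage, count in (("A", pop.n_a), ("B", pop.n_b)):
            tau = float(config.taus[lineage])
            for _ in range(count):
                k += 1
                sid = f"{pop.name}_{k:03d}"
                seq = founders[lineage].copy()
                n_mut = int(rng.poisson(tau / 2.0))
                for _ in range(n_mut):
                    _mutate_at(seq, int(rng.integers(L)), rng, config.kappa)
                ids.append(sid)
                seqs.append(seq.tobytes().decode())
                lineage_of[sid] = lineage
                mutation_counts[sid] = n_mut
                spec_to_pop[sid] = pop.name

    l1, l2 = config.locus_lengths
    n1, n2 = config.locus_names
    combined = Alignment(tuple(ids), tuple(seqs), {n1: (0, l1), n2: (l1, l1 + l2)})
    per_locus = {
        n1: Alignment(tuple(ids), tuple(s[:l1] for s in seqs), {n1: (0, l1)}),
        n2: Alignment(tuple(ids), tuple(s[l1:] for s in seqs), {n2: (0, l2)}),
    }
    per_locus["combined"] = combined
    popmap = PopulationMap(spec_to_pop, pop_info)
    truth = TruthRecord(
        lineage_of,
        {k: v.tobytes().decode() for k, v in founders.items()},
        mutation_counts,
        {k: float(v) for k, v in config.taus.items()},
        {k: float(v) for k, v in config.theta0s.items()},
        div_sites,
        config.seed,
    )
    return per_locus, popmap, truth


def simulate_dataset_object(config: SimulationConfig = SimulationConfig()
                            ) -> tuple[Dataset, TruthRecord]:
    """Convenience: combined-locus Dataset with lineage labels attached."""
    alignments, popmap, truth = simulate_dataset(config)
    return Dataset(alignments["combined"], popmap, dict(truth.lineage_of)), truth


def simulate_star_lineage(n: int, tau: float, L: int = 792,
                          seed: int | np.random.Generator = 0,
                          kappa: float = 4.0) -> Alignment:
    """A single post-expansion (star) lineage: n sequences, Poisson(tau/2)
    private mutations each."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    founder = _random_sequence(L, rng)
    ids, seqs = [], []
    for i in range(n):
        seq = founder.copy()
        for _ in range(int(rng.poisson(tau / 2.0))):
            _mutate_at(seq, int(rng.integers(L)), rng, kappa)
        ids.append(f"S{i + 1:03d}")
        seqs.append(seq.tobytes().decode())
    return Alignment(tuple(ids), tuple(seqs))


def simulate_coalescent_alignment(n: int, theta: float, L: int,
                                  seed: int | np.random.Generator = 0,
                                  kappa: float = 4.0) -> Alignment:
    """Neutral constant-size coalescent sample with Poisson mutations on
    branches, placed at uniform random sites (finite-sites collisions allowed)."""
    if n < 2:
        raise ValueError("need n >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = _coalescent.sample_genealogy(n, rng)
    m = _coalescent.branch_mutations(g, theta, rng)
    ancestral = _random_sequence(L, rng)
    tips = _coalescent.drop_sequences(g, m, ancestral, rng, kappa)
    ids = tuple(f"S{i + 1:03d}" for i in range(n))
    return Alignment(ids, tuple(row.tobytes().decode() for row in tips))
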