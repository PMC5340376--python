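"""Population structure: AMOVA, pairwise Phi-ST, UPGMA and the Mantel test.

AMOVA (Excoffier, Smouse & Quattro 1992) partitions molecular variance
from a matrix of squared inter-individual distances into among-group (AG),
among-populations-within-group (AP/WG) and within-population (WP)
components, with fixation indices

    Phi_CT = sa2 / st2,  Phi_SC = sb2 / (sb2 + sc2),  Phi_ST = (sa2 + sb2) / st2.

Significance uses the three standard permutation schemes (individuals
among populations; individuals among populations within groups; whole
populations among groups), with p = (count + 1) / (n_perm + 1). Negative
variance components are retained, not truncated, when forming Phi.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .distances import DistanceMatrix, distance_matrix
from .seqio import Dataset, PopulationMap

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# AMOVA

@dataclass(frozen=True)
class AmovaResult:
    """Variance components, Phi statistics and permutation p-values."""

    grouping: dict[str, tuple[str, ...]]
    df: dict[str, int]
    ssd: dict[str, float]
    sigma2: dict[str, float]
    percent: dict[str, float]
    phi: dict[str, float]
    p_values: dict[str, float] = field(default_factory=dict)

    @property
    def phi_st(self) -> float:
        return self.phi.get("phi_st", float("nan"))

    @property
    def phi_ct(self) -> float:
        return self.phi.get("phi_ct", float("nan"))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for comp in self.sigma2:
            rows.append({
                "component": comp,
                "df": self.df.get(comp),
                "ssd": self.ssd.get(comp),
                "sigma2": self.sigma2[comp],
                "percent": self.percent[comp],
            })
        return pd.DataFrame(rows)


def _pop_indices(labels: np.ndarray) -> dict[str, np.ndarray]:
    return {p: np.nonzero(labels == p)[0] for p in pd.unique(labels)}


def _ssd_within(d2: np.ndarray, index_sets: list[np.ndarray]) -> float:
    """sum over sets of (1/n_s) * sum_{i<j in s} d2_ij."""
    total = 0.0
    for idx in index_sets:
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            total += sub.sum() / (2.0 * len(idx))
    return total


def amova_from_distances(d2: np.ndarray, pop_labels, grouping=None,
                         n_perm: int = 0, seed: int | np.random.Generator = 0) -> AmovaResult:
    """AMOVA on a squared-distance matrix.

    Parameters
    ----------
    d2:
        (N, N) symmetric matrix of *squared* inter-individual distances.
    pop_labels:
        Population label per individual (length N).
    grouping:
        Mapping group name -> populations. ``None`` (or one group) yields
        the single-level analysis with components AP (among populations)
        and WP (within populations).
    """
    labels = np.asarray(pop_labels)
    N = len(labels)
    if d2.shape != (N, N):
        raise ValueError("distance matrix does not match labels")
    pops = list(pd.unique(labels))
    if len(pops) < 2:
        raise ValueError("AMOVA needs at least two populations")
    if grouping is None:
        grouping = {"all": tuple(pops)}
    grouping = {g: tuple(ps) for g, ps in grouping.items()}
    covered = [p for ps in grouping.values() for p in ps]
    if sorted(covered) != sorted(pops):
        raise ValueError(f"grouping must partition the populations; got {grouping}")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    result = _amova_once(d2, labels, grouping)

    if n_perm > 0:
        result = _amova_permutations(d2, labels, grouping, result, n_perm, rng)
    return result


def _amova_once(d2: np.ndarray, labels: np.ndarray,
                grouping: dict[str, tuple[str, ...]]) -> AmovaResult:
    N = len(labels)
    pop_idx = _pop_indices(labels)
    pops = list(pop_idx)
    P = len(pops)
    G = len(grouping)
    group_idx = {g: np.concatenate([pop_idx[p] for p in ps]) for g, ps in grouping.items()}

    ssd_total = d2.sum() / (2.0 * N)
    ssd_wp = _ssd_within(d2, list(pop_idx.values()))
    n_p = {p: len(idx) for p, idx in pop_idx.items()}

    if G == 1:
        ssd_ap = ssd_total - ssd_wp
        df = {"AP": P - 1, "WP": N - P}
        sc2 = ssd_wp / df["WP"] if df["WP"] else 0.0
        n1 = (N - sum(v**2 for v in n_p.values()) / N) / (P - 1)
        sb2 = (ssd_ap / df["AP"] - sc2) / n1
        st2 = sb2 + sc2
        phi_st = sb2 / st2 if st2 != 0 else float("nan")
        sigma2 = {"AP": sb2, "WP": sc2}
        percent = {k: 100.0 * v / st2 if st2 != 0 else float("nan") for k, v in sigma2.items()}
        return AmovaResult(grouping, df, {"AP": ssd_ap, "WP": ssd_wp, "total": ssd_total},
                           sigma2, percent, {"phi_st": phi_st})

    ssd_wg = _ssd_within(d2, list(group_idx.values()))
    ssd_ap_wg = ssd_wg - ssd_wp
    ssd_ag = ssd_total - ssd_wg
    df = {"AG": G - 1, "AP/WG": P - G, "WP": N - P}
    if df["AP/WG"] <= 0:
        raise ValueError("need more populations than groups for a hierarchical AMOVA")
    sc2 = ssd_wp / df["WP"] if df["WP"] else 0.0
    N_g = {g: len(idx) for g, idx in group_idx.items()}
    sum_np2_over_Ng = sum(sum(n_p[p] ** 2 for p in ps) / N_g[g] for g, ps in grouping.items())
    n1 = (N - sum_np2_over_Ng) / (P - G)
    n2 = (sum_np2_over_Ng - sum(v**2 for v in n_p.values()) / N) / (G - 1)
    n3 = (N - sum(v**2 for v in N_g.values()) / N) / (G - 1)
    sb2 = (ssd_ap_wg / df["AP/WG"] - sc2) / n1
    sa2 = (ssd_ag / df["AG"] - sc2 - n2 * sb2) / n3
    st2 = sa2 + sb2 + sc2
    sigma2 = {"AG": sa2, "AP/WG": sb2, "WP": sc2}
    percent = {k: 100.0 * v / st2 if st2 != 0 else float("nan") for k, v in sigma2.items()}
    phi = {
        "phi_ct": sa2 / st2 if st2 != 0 else float("nan"),
        "phi_sc": sb2 / (sb2 + sc2) if (sb2 + sc2) != 0 else float("nan"),
        "phi_st": (sa2 + sb2) / st2 if st2 != 0 else float("nan"),
    }
    return AmovaResult(grouping, df,
                       {"AG": ssd_ag, "AP/WG": ssd_ap_wg, "WP": ssd_wp, "total": ssd_total},
                       sigma2, percent, phi)


def _amova_permutations(d2, labels, grouping, observed: AmovaResult,
                        n_perm: int, rng: np.random.Generator) -> AmovaResult:
    G = len(grouping)
    p_values: dict[str, float] = {}

    def count_ge(stat: str, perm_labels_fn, perm_grouping_fn=None) -> float:
        obs = observed.phi[stat]
        if not math.isfinite(obs):
            return float("nan")
        count = 0
        for _ in range(n_perm):
            lab = perm_labels_fn()
            grp = perm_grouping_fn() if perm_grouping_fn else grouping
            try:
                res = _amova_once(d2, lab, grp)
            except ValueError:
                continue
            if res.phi.get(stat, -np.inf) >= obs:
                count += 1
        return (count + 1) / (n_perm + 1)

    def shuffle_all() -> np.ndarray:
        return labels[rng.permutation(len(labels))]

    if G == 1:
        p_values["phi_st"] = count_ge("phi_st", shuffle_all)
    else:
        def shuffle_within_groups() -> np.ndarray:
            lab = labels.copy()
            for g, ps in grouping.items():
                mask = np.isin(labels, ps)
                idx = np.nonzero(mask)[0]
                lab[idx] = labels[idx][rng.permutation(len(idx))]
            return lab

        pops = list(pd.unique(labels))

        def shuffle_groups() -> dict[str, tuple[str, ...]]:
            sizes = [len(ps) for ps in grouping.values()]
            perm = [pops[i] for i in rng.permutation(len(pops))]
            out = {}
            start = 0
            for g, size in zip(grouping, sizes):
                out[g] = tuple(perm[start:start + size])
                start += size
            return out

        p_values["phi_st"] = count_ge("phi_st", shuffle_all)
        p_values["phi_sc"] = count_ge("phi_sc", shuffle_within_groups)
        p_values["phi_ct"] = count_ge("phi_ct", lambda: labels, shuffle_groups)

    return AmovaResult(observed.grouping, observed.df, observed.ssd, observed.sigma2,
                       observed.percent, observed.phi, p_values)


def amova(dataset: Dataset, grouping: dict[str, tuple[str, ...]] | None = None,
          metric: str = "raw", n_perm: int = 10_000,
          seed: int | np.random.Generator = 0) -> AmovaResult:
    """AMOVA on a dataset; distances are squared pairwise difference counts
    by default (``metric="k2p"`` squares the K2P distances instead)."""
    dm = distance_matrix(dataset.alignment, metric)
    return amova_from_distances(dm.matrix**2, dataset.population_labels(),
                                grouping, n_perm, seed)


# ---------------------------------------------------------------------------
# Pairwise Phi-ST

@dataclass(frozen=True)
class PairwiseFstMatrix:
    """Pairwise Phi-ST values with their permutation p-values."""

    labels: tuple[str, ...]
    phi: np.ndarray
    p_values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Lower triangle Phi-ST, upper triangle p-values (the usual
        publication layout for pairwise fixation-index matrices)."""
        k = len(self.labels)
        out = np.full((k, k), np.nan)
        for i in range(k):
            for j in range(k):
                if i > j:
                    out[i, j] = self.phi[i, j]
                elif i < j:
                    out[i, j] = self.p_values[i, j]
        return pd.DataFrame(out, index=self.labels, columns=self.labels)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.4f")

    def distance_matrix(self) -> DistanceMatrix:
        """Phi-ST as a distance matrix (negatives clamped to 0) for UPGMA."""
        m = np.clip(self.phi, 0.0, None)
        np.fill_diagonal(m, 0.0)
        return DistanceMatrix(self.labels, m, "phi_st")


def pairwise_phist(dataset: Dataset, pop_a: str, pop_b: str, metric: str = "raw",
                   n_perm: int = 10_000, seed: int | np.random.Generator = 0) -> tuple[float, float]:
    """Phi-ST between two populations (two-population, one-group AMOVA)."""
    sub = dataset.subset_by_population([pop_a, pop_b])
    for p in (pop_a, pop_b):
        if len([i for i in sub.alignment.ids if sub.popmap.specimen_to_pop[i] == p]) < 2:
            raise ValueError(f"population {p!r} has fewer than 2 specimens")
    res = amova(sub, None, metric, n_perm, seed)
    return res.phi_st, res.p_values.get("phi_st", float("nan"))


def pairwise_phist_matrix(dataset: Dataset, metric: str = "raw", n_perm: int = 10_000,
                          seed: int | np.random.Generator = 0) -> PairwiseFstMatrix:
    """All pairwise Phi-ST values among the dataset's populations."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pops = list(dataset.popmap.populations)
    # keep only populations with samples in the alignment
    present = set(dataset.population_labels())
    pops = [p for p in pops if p in present]
    k = len(pops)
    phi = np.zeros((k, k))
    pvals = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        f, p = pairwise_phist(dataset, pops[i], pops[j], metric, n_perm, rng)
        phi[i, j] = phi[j, i] = f
        pvals[i, j] = pvals[j, i] = p
    return PairwiseFstMatrix(tuple(pops), phi, pvals)


def grouping_search(dataset: Dataset, candidates: dict[str, dict[str, tuple[str, ...]]],
                    metric: str = "raw", n_perm: int = 10_000,
                    seed: int | np.random.Generator = 0) -> list[tuple[str, AmovaResult]]:
    """AMOVA for each candidate grouping, ranked by decreasing Phi_CT.

    One-group candidates (no Phi_CT) sort last by their Phi_ST.
    """
    if not candidates:
        raise ValueError("need at least one candidate grouping")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    results = [(name, amova(dataset, grouping, metric, n_perm, rng))
               for name, grouping in candidates.items()]

    def key(item):
        res = item[1]
        ct = res.phi.get("phi_ct")
        return (0, -ct) if ct is not None and math.isfinite(ct) else (1, -res.phi_st)

    return sorted(results, key=key)


# ---------------------------------------------------------------------------
# UPGMA

def upgma(matrix: DistanceMatrix) -> str:
    """UPGMA (average linkage) tree in Newick; node height = half merge distance.

    Negative input distances are clamped to zero with a warning.
    """
    if len(matrix.labels) < 2:
        raise ValueError("need at least 2 labels")
    m = matrix.matrix.copy()
    if (m < 0).any():
        logger.warning("clamping %d negative distances to 0", int((m < 0).sum()))
        m = np.clip(m, 0.0, None)
        np.fill_diagonal(m, 0.0)
    Z = linkage(squareform(m, checks=False), method="average")
    return _linkage_to_newick(Z, matrix.labels)


def _linkage_to_newick(Z: np.ndarray, labels: tuple[str, ...]) -> str:
    n = len(labels)
    height = {i: 0.0 for i in range(n)}
    newick = {i: labels[i] for i in range(n)}
    for k, (a, b, dist, _) in enumerate(Z):
        a, b = int(a), int(b)
        h = dist / 2.0
        node = n + k
        height[node] = h
        la = h - height[a]
        lb = h - height[b]
        newick[node] = f"({newick[a]}:{la:.6g},{newick[b]}:{lb:.6g})"
    return newick[2 * n - 2] + ";"


# ---------------------------------------------------------------------------
# Mantel test and geographic distances

def mantel_r(m1: np.ndarray, m2: np.ndarray) -> float:
    """Pearson correlation of the off-diagonal upper-triangle entries."""
    iu = np.triu_indices(m1.shape[0], k=1)
    x, y = m1[iu], m2[iu]
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def mantel_test(m1: DistanceMatrix | np.ndarray, m2: DistanceMatrix | np.ndarray,
                n_perm: int = 1000, seed: int | np.random.Generator = 0,
                alternative: str = "greater", exact: bool = False) -> tuple[float, float]:
    """Mantel correlation between two distance matrices with permutation p.

    Rows/columns of the second matrix are permuted jointly. ``exact=True``
    enumerates all label permutations (small matrices only) and reports the
    exact proportion with r_perm >= r_obs (or |r| for two-sided).
    """
    a = m1.matrix if isinstance(m1, DistanceMatrix) else np.asarray(m1, dtype=float)
    b = m2.matrix if isinstance(m2, DistanceMatrix) else np.asarray(m2, dtype=float)
    if isinstance(m1, DistanceMatrix) and isinstance(m2, DistanceMatrix):
        if m1.labels != m2.labels:
            raise ValueError("matrices must share labels in the same order")
    if a.shape != b.shape:
        raise ValueError("matrix size mismatch")
    r_obs = mantel_r(a, b)

    def extreme(r_perm: float) -> bool:
        if alternative == "greater":
            return r_perm >= r_obs
        if alternative == "less":
            return r_perm <= r_obs
        return abs(r_perm) >= abs(r_obs)

    n = a.shape[0]
    if exact:
        perms = list(itertools.permutations(range(n)))
        count = sum(extreme(mantel_r(a, b[np.ix_(p, p)])) for p in perms)
        return r_obs, count / len(perms)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        if extreme(mantel_r(a, b[np.ix_(p, p)])):
            count += 1
    return r_obs, (count + 1) / (n_perm + 1)


def great_circle_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Haversine great-circle distance in kilometres."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(h))


def geographic_distance_matrix(popmap: PopulationMap, pops=None) -> DistanceMatrix:
    """Great-circle distances (km) between populations with coordinates."""
    coords = popmap.coordinates()
    pops = tuple(pops) if pops is not None else tuple(p for p in popmap.populations if p in coords)
    missing = [p for p in pops if p not in coords]
    if missing:
        raise ValueError(f"populations without coordinates: {missing}")
    k = len(pops)
    m = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        d = great_circle_km(*coords[pops[i]], *coords[pops[j]])
        m[i, j] = m[j, i] = d
    return DistanceMatrix(pops, m, "km")
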