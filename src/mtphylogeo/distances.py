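"""Pairwise sequence distances: raw differences, p-distance and Kimura 2-parameter.

K2P distinguishes transitions (within purines {A,G} or pyrimidines {C,T})
from transversions:

    d = 1/2 ln(1 / (1 - 2P - Q)) + 1/4 ln(1 / (1 - 2Q))

with P and Q the transition and transversion proportions. Pairs where a
logarithm argument is non-positive are saturated and flagged NaN.
Global matrices are computed on the complete-deletion site set so one
consistent L underlies every pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import Alignment

PURINES = frozenset(b"AG")
PYRIMIDINES = frozenset(b"CT")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with a metric tag."""

    labels: tuple[str, ...]
    matrix: np.ndarray
    metric: str  # "raw" | "p" | "k2p"

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        finite = np.isfinite(m)
        if not np.allclose(m[finite], m.T[finite]):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path, metric: str = "raw") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(df.index), df.to_numpy(dtype=float), metric)


def pairwise_differences(s1: str, s2: str) -> int:
    """Hamming count between two equal-length sequences (retained sites only)."""
    if len(s1) != len(s2):
        raise ValueError(f"length mismatch: {len(s1)} vs {len(s2)}")
    return sum(a != b for a, b in zip(s1, s2))


def transition_transversion_counts(s1: str, s2: str) -> tuple[int, int]:
    """(transitions, transversions) between two equal-length sequences."""
    if len(s1) != len(s2):
        raise ValueError(f"length mismatch: {len(s1)} vs {len(s2)}")
    ts = tv = 0
    for a, b in zip(s1.encode(), s2.encode()):
        if a == b:
            continue
        if (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES):
            ts += 1
        else:
            tv += 1
    return ts, tv


def k2p_from_proportions(P: float, Q: float) -> float:
    """K2P distance from transition/transversion proportions; NaN if saturated."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return float("nan")
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


def k2p_distance(s1: str, s2: str) -> float:
    """K2P distance (substitutions/site) between two aligned sequences."""
    ts, tv = transition_transversion_counts(s1, s2)
    L = len(s1)
    if L == 0:
        raise ValueError("empty sequences")
    return k2p_from_proportions(ts / L, tv / L)


def _encoded(alignment: Alignment) -> tuple[np.ndarray, tuple[str, ...]]:
    """(n, L) uint8 array of the masked alignment, plus its ids."""
    masked = alignment.masked()
    return masked.to_array().view(np.uint8), tuple(masked.ids)


def hamming_matrix(alignment: Alignment) -> np.ndarray:
    """Integer pairwise-difference matrix over the complete-deletion sites.

    The input is masked internally; pass an already-masked alignment to
    skip the second pass.
    """
    arr, _ = _encoded(alignment)
    n = arr.shape[0]
    out = np.zeros((n, n), dtype=int)
    for i in range(n):
        out[i, i + 1:] = (arr[i + 1:] != arr[i]).sum(axis=1)
    return out + out.T


def distance_matrix(alignment: Alignment, metric: str = "raw") -> DistanceMatrix:
    """Pairwise distance matrix (``raw`` counts, ``p`` proportions or ``k2p``)."""
    masked = alignment.masked()
    arr = masked.to_array().view(np.uint8)
    n, L = arr.shape
    if L == 0:
        raise ValueError("no retained sites")
    diff = np.zeros((n, n))
    if metric in ("raw", "p"):
        for i in range(n):
            diff[i, i + 1:] = (arr[i + 1:] != arr[i]).sum(axis=1)
        diff += diff.T
        if metric == "p":
            diff /= L
        return DistanceMatrix(tuple(masked.ids), diff, metric)
    if metric == "k2p":
        purine = (arr == ord("A")) | (arr == ord("G"))
        for i in range(n):
            neq = arr[i + 1:] != arr[i]
            ts = (neq & (purine[i + 1:] == purine[i])).sum(axis=1)
            tv = neq.sum(axis=1) - ts
            for off, (t, v) in enumerate(zip(ts, tv)):
                diff[i, i + 1 + off] = k2p_from_proportions(t / L, v / L)
        diff += diff.T
        return DistanceMatrix(tuple(masked.ids), diff, "k2p")
    raise ValueError(f"unknown metric {metric!r}")
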