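"""Tajima's D and Fu's Fs neutrality tests with coalescent significance.

Tajima's D contrasts the pairwise estimator of theta (mean pairwise
differences k_bar) with Watterson's S/a1; strongly negative values are the
signature of demographic expansion (an excess of rare variants).

Fu's Fs asks how surprising the observed number of haplotypes k_obs is
under the Ewens sampling distribution at theta = k_bar:

    S' = Pr(K >= k_obs | theta),   Fs = ln(S' / (1 - S'))

with Pr(K = k) = |s(n, k)| theta^k / (theta)_n, where |s(n, k)| are
unsigned Stirling numbers of the first kind and (theta)_n is the rising
factorial. Everything is evaluated in log space so n in the hundreds is
safe. P-values come from neutral constant-size coalescent simulation
conditioned on theta_hat = k_bar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import logsumexp

from . import _coalescent
from .diversity import mean_pairwise_differences
from .seqio import Alignment


@dataclass(frozen=True)
class NeutralityResult:
    """Neutrality statistics for one group of sequences.

    ``D`` and ``Fs`` are NaN (flagged) where undefined (S = 0, or a
    degenerate haplotype configuration driving Fs to +/- infinity keeps
    the signed infinity).
    """

    n: int
    S: int
    k_bar: float
    theta_w: float
    D: float
    Fs: float
    p_D: float | None = None
    p_Fs: float | None = None


def tajima_constants(n: int) -> dict[str, float]:
    """The a1, a2, b1, b2, c1, c2, e1, e2 constants of Tajima's test."""
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(n: int, S: int, k_bar: float) -> float:
    """Tajima's D from sample size, segregating sites and mean pairwise diffs.

    Returns NaN when S = 0 (the statistic is undefined, not zero).
    """
    if S == 0:
        return float("nan")
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return (k_bar - S / c["a1"]) / math.sqrt(var)


@lru_cache(maxsize=None)
def log_stirling_first_kind(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0..n via the recursion
    |s(n, k)| = |s(n-1, k-1)| + (n-1) |s(n-1, k)|, carried in log space."""
    row = np.array([0.0])  # |s(0, 0)| = 1
    for m in range(1, n + 1):
        new = np.full(m + 1, -np.inf)
        new[1 : m + 1] = row
        if m > 1:
            new[0:m] = np.logaddexp(new[0:m], math.log(m - 1) + row)
        row = new
    return row


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log Pr(K = k | theta) for k = 1..n under the Ewens sampling formula."""
    if n < 1 or theta <= 0:
        raise ValueError("need n >= 1 and theta > 0")
    ls = log_stirling_first_kind(n)[1 : n + 1]
    k = np.arange(1, n + 1)
    log_rising = float(np.sum(np.log(theta + np.arange(n))))
    return ls + k * math.log(theta) - log_rising


def fus_fs(n: int, k_bar: float, k_obs: int) -> float:
    """Fu's Fs statistic; +inf / -inf flag degenerate tail probabilities."""
    if n < 2:
        raise ValueError("need n >= 2")
    if not 1 <= k_obs <= n:
        raise ValueError("k_obs must be in 1..n")
    if k_obs == 1:
        return float("inf")  # Pr(K >= 1) = 1
    if k_bar <= 0:
        return float("inf")
    logp = ewens_log_pmf(n, k_bar)
    log_tail = logsumexp(logp[k_obs - 1 :])   # ln S'
    log_head = logsumexp(logp[: k_obs - 1])   # ln (1 - S')
    return float(log_tail - log_head)


def coalescent_simulate(n: int, theta: float, reps: int, seed: int | np.random.Generator,
                        *, compute_fs: bool = True) -> dict[str, np.ndarray]:
    """Distributions of (S, k_bar, K, D, Fs) under the neutral constant-size
    coalescent with infinite-sites mutation at rate theta."""
    if n < 2 or theta <= 0 or reps < 1:
        raise ValueError("need n >= 2, theta > 0, reps >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    S = np.zeros(reps, dtype=np.int64)
    kb = np.zeros(reps)
    K = np.zeros(reps, dtype=np.int64)
    D = np.full(reps, np.nan)
    Fs = np.full(reps, np.nan)
    for r in range(reps):
        g = _coalescent.sample_genealogy(n, rng)
        m = _coalescent.branch_mutations(g, theta, rng)
        s, k_bar, k = _coalescent.infinite_sites_stats(g, m)
        S[r], kb[r], K[r] = s, k_bar, k
        if s > 0 and n >= 4:
            D[r] = tajimas_d(n, s, k_bar)
        if compute_fs and k_bar > 0:
            Fs[r] = fus_fs(n, k_bar, k)
    return {"S": S, "k_bar": kb, "K": K, "D": D, "Fs": Fs}


def _empirical_p_two_tailed(obs: float, sims: np.ndarray) -> float:
    sims = sims[np.isfinite(sims)]
    if len(sims) == 0 or not math.isfinite(obs):
        return float("nan")
    n = len(sims)
    p_le = (np.sum(sims <= obs) + 1) / (n + 1)
    p_ge = (np.sum(sims >= obs) + 1) / (n + 1)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _empirical_p_le(obs: float, sims: np.ndarray) -> float:
    sims = sims[np.isfinite(sims)]
    if len(sims) == 0 or not math.isfinite(obs):
        return float("nan")
    return float((np.sum(sims <= obs) + 1) / (len(sims) + 1))


def neutrality_test(alignment: Alignment, *, reps: int = 1000,
                    seed: int | np.random.Generator = 0) -> NeutralityResult:
    """D and Fs for an alignment, with p-values by neutral simulation.

    The null is the constant-size coalescent conditioned on
    theta_hat = k_bar; p_D is two-tailed empirical, p_Fs is
    Pr(Fs_sim <= Fs_obs) (expansion pushes Fs negative).
    """
    masked = alignment.masked()
    n = masked.n
    arr = masked.to_array()
    S = int(sum(len(np.unique(arr[:, j])) > 1 for j in range(masked.length)))
    k_bar, _ = mean_pairwise_differences(masked)
    k_obs = len(set(masked.seqs))
    theta_w = S / tajima_constants(n)["a1"] if n >= 4 else float("nan")
    D = tajimas_d(n, S, k_bar) if n >= 4 else float("nan")
    Fs = fus_fs(n, k_bar, k_obs) if k_bar > 0 else float("inf")
    p_D = p_Fs = None
    if S > 0 and k_bar > 0 and reps > 0:
        sims = coalescent_simulate(n, k_bar, reps, seed)
        p_D = _empirical_p_two_tailed(D, sims["D"])
        p_Fs = _empirical_p_le(Fs, sims["Fs"])
    return NeutralityResult(n, S, k_bar, theta_w, D, Fs, p_D, p_Fs)
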