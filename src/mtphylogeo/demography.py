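"""Mismatch distributions, sudden-expansion fitting and expansion dating.

The sudden-expansion (Rogers-Harpending) model: a population at mutation-
scaled size theta0 grows instantaneously to theta1 at scaled time
tau = 2*mu*T before the present. The expected distribution of pairwise
differences i generations... scaled time tau after the jump is

    F_i(tau, theta0, theta1) = Fhat_i(theta1)
        + exp(-tau (theta1 + 1) / theta1)
          * sum_{j=0..i} tau^j / j! * (Fhat_{i-j}(theta0) - Fhat_{i-j}(theta1))

with the equilibrium distribution Fhat_i(theta) = theta^i / (1+theta)^(i+1).
In the limit theta0 -> 0, theta1 -> inf this collapses to Poisson(tau),
the pure star-genealogy spectrum.

Dating converts the fitted tau to years through tau = 2*mu*T, where
2*mu = 2 * d * L * g with d the per-site divergence rate per year, L the
number of sites and g the generation time in years. Ages of lineages use
A = pi / d. Both conventions are discussed in docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import poisson

from . import _coalescent
from .distances import hamming_matrix
from .seqio import Alignment


@dataclass(frozen=True)
class MismatchSpectrum:
    """Normalized histogram of pairwise difference counts."""

    freqs: np.ndarray  # f_i for i = 0..max
    label: str = ""
    n_pairs: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if (f < 0).any():
            raise ValueError("negative frequencies")
        if f.sum() > 0 and not math.isclose(float(f.sum()), 1.0, rel_tol=1e-9):
            raise ValueError("frequencies must sum to 1")
        object.__setattr__(self, "freqs", f)

    @property
    def support(self) -> np.ndarray:
        return np.arange(len(self.freqs))

    @property
    def mean(self) -> float:
        return float(np.sum(self.support * self.freqs))

    def n_modes(self, min_prominence: float = 0.01) -> int:
        """Count local maxima with at least ``min_prominence`` mass."""
        f = self.freqs
        modes = 0
        for i in range(len(f)):
            left = f[i - 1] if i > 0 else -1.0
            right = f[i + 1] if i < len(f) - 1 else -1.0
            if f[i] > left and f[i] >= right and f[i] >= min_prominence:
                modes += 1
        return modes


@dataclass(frozen=True)
class ExpansionFit:
    """Fitted sudden-expansion parameters for one mismatch spectrum."""

    tau: float
    theta0: float
    theta1: float
    ssd: float
    expected: np.ndarray
    p_ssd: float | None = None


@dataclass(frozen=True)
class DatingConvention:
    """Units for converting tau and pi to calendar years.

    ``rate`` is the pairwise divergence rate per site per year (the
    default 1.42e-8 corresponds to 1.42% per million years, the midpoint
    of the 1.17-1.66%/Myr range used for decapod mtDNA); ``generation_time``
    in years; ``L`` the number of concatenated sites.
    """

    rate: float = 1.42e-8
    rate_range: tuple[float, float] = (1.17e-8, 1.66e-8)
    generation_time: float = 1.0
    L: int = 792

    def __post_init__(self) -> None:
        if self.rate <= 0 or self.generation_time <= 0 or self.L <= 0:
            raise ValueError("rate, generation_time and L must be positive")


def mismatch_distribution(alignment: Alignment, label: str = "") -> MismatchSpectrum:
    """Observed mismatch spectrum over all unordered pairs (retained sites)."""
    masked = alignment.masked()
    if masked.n < 2:
        raise ValueError("need at least 2 sequences")
    d = hamming_matrix(masked)
    diffs = d[np.triu_indices(masked.n, k=1)]
    counts = np.bincount(diffs)
    return MismatchSpectrum(counts / counts.sum(), label, len(diffs))


def equilibrium_mismatch(theta: float, i_max: int) -> np.ndarray:
    """Fhat_i(theta) = theta^i / (1+theta)^(i+1) for i = 0..i_max."""
    i = np.arange(i_max + 1)
    if theta <= 0:
        out = np.zeros(i_max + 1)
        out[0] = 1.0
        return out
    return np.exp(i * math.log(theta) - (i + 1) * math.log1p(theta))


def expected_mismatch(tau: float, theta0: float, theta1: float, i_max: int,
                      *, renormalize: bool = True) -> np.ndarray:
    """Expected sudden-expansion mismatch spectrum over i = 0..i_max."""
    if tau < 0 or theta0 < 0 or theta1 < theta0:
        raise ValueError("require tau >= 0 and 0 <= theta0 <= theta1")
    f1 = equilibrium_mismatch(theta1, i_max)
    f0 = equilibrium_mismatch(theta0, i_max)
    if tau == 0 or theta1 == 0:
        out = f0
    else:
        # exp(-tau (theta1+1)/theta1) * sum_j tau^j/j! = exp(-tau/theta1) * Poisson pmf
        trans = math.exp(-tau / theta1)
        pois = poisson.pmf(np.arange(i_max + 1), tau)
        out = f1 + trans * np.convolve(pois, f0 - f1)[: i_max + 1]
    out = np.clip(out, 0.0, None)
    if renormalize and out.sum() > 0:
        out = out / out.sum()
    return out


def ssd(observed: np.ndarray, expected: np.ndarray) -> float:
    """Sum of squared deviations between two spectra on common support."""
    k = max(len(observed), len(expected))
    o = np.zeros(k)
    e = np.zeros(k)
    o[: len(observed)] = observed
    e[: len(expected)] = expected
    return float(np.sum((o - e) ** 2))


_BOUNDS = {"tau": (0.0, 50.0), "theta0": (0.0, 20.0), "theta1_delta": (0.0, 1.0e4)}


def fit_expansion(spectrum: MismatchSpectrum, *, n_bootstrap: int = 0,
                  bootstrap_n: int | None = None,
                  seed: int | np.random.Generator = 0) -> ExpansionFit:
    """Fit (tau, theta0, theta1) to an observed mismatch spectrum by least squares.

    Multi-start: a 5x5x5 log-spaced grid of seeds (tau additionally seeded at
    the spectrum mean) followed by bounded local refinement of the best
    candidates. If ``n_bootstrap`` > 0, a parametric bootstrap p-value for
    the SSD goodness of fit is computed by simulating ``bootstrap_n``
    sequences under the fitted model, refitting each replicate and counting
    replicate SSDs >= the observed SSD.
    """
    f = spectrum.freqs
    if len(f) < 3:
        raise ValueError("spectrum needs at least 3 support points")
    i_max = len(f) - 1

    lo = np.array([b[0] for b in (_BOUNDS["tau"], _BOUNDS["theta0"], _BOUNDS["theta1_delta"])])
    hi = np.array([b[1] for b in (_BOUNDS["tau"], _BOUNDS["theta0"], _BOUNDS["theta1_delta"])])

    def objective(x: np.ndarray) -> float:
        tau, th0, delta = np.clip(x, lo, hi)
        return ssd(f, expected_mismatch(tau, th0, th0 + delta, i_max))

    tau_seeds = np.unique(np.concatenate([np.geomspace(0.1, 50.0, 5), [max(spectrum.mean, 1e-3)]]))
    th0_seeds = np.geomspace(0.01, 20.0, 5)
    delta_seeds = np.geomspace(1.0, 1.0e4, 5)
    grid = [(t, a, d) for t in tau_seeds for a in th0_seeds for d in delta_seeds]
    grid_scores = sorted(grid, key=lambda x: objective(np.array(x)))
    best_x, best_val = None, math.inf
    for x0 in grid_scores[:5]:
        res = minimize(objective, np.array(x0), method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000})
        x = np.clip(res.x, lo, hi)
        val = objective(x)
        if val < best_val:
            best_x, best_val = x, val
    tau, th0, delta = best_x
    th1 = th0 + delta
    expected = expected_mismatch(tau, th0, th1, i_max)
    p_ssd = None
    if n_bootstrap > 0:
        n_seq = bootstrap_n or max(2, int((1 + math.sqrt(1 + 8 * spectrum.n_pairs)) / 2))
        p_ssd = _bootstrap_p_ssd(tau, th0, th1, best_val, n_seq, n_bootstrap, seed)
    return ExpansionFit(float(tau), float(th0), float(th1), best_val, expected, p_ssd)


def simulate_expansion_spectrum(n: int, tau: float, theta0: float, theta1: float,
                                rng: np.random.Generator) -> MismatchSpectrum:
    """One coalescent sample's mismatch spectrum under sudden expansion."""
    theta1 = max(theta1, 1e-6)
    epoch = tau / theta1
    ratio = theta1 / max(theta0, 1e-6)
    g = _coalescent.sample_genealogy(n, rng, epoch_time=epoch, rate_ratio=ratio)
    m = _coalescent.branch_mutations(g, theta1, rng)
    d = _coalescent.pairwise_difference_matrix(g, m)
    diffs = d[np.triu_indices(n, k=1)]
    counts = np.bincount(diffs)
    return MismatchSpectrum(counts / counts.sum(), "sim", len(diffs))


def _bootstrap_p_ssd(tau: float, th0: float, th1: float, ssd_obs: float,
                     n_seq: int, reps: int, seed: int | np.random.Generator) -> float:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    count = 0
    for _ in range(reps):
        spec = simulate_expansion_spectrum(n_seq, tau, th0, th1, rng)
        i_max = len(spec.freqs) - 1
        lo = np.array([0.0, 0.0, 0.0])
        hi = np.array([_BOUNDS["tau"][1], _BOUNDS["theta0"][1], _BOUNDS["theta1_delta"][1]])

        def objective(x: np.ndarray) -> float:
            t, a, d = np.clip(x, lo, hi)
            return ssd(spec.freqs, expected_mismatch(t, a, a + d, i_max))

        # light refit: moment seed plus the generating parameters
        best = math.inf
        for x0 in ([spec.mean, 0.5, 50.0], [tau, th0, th1 - th0]):
            res = minimize(objective, np.array(x0, dtype=float), method="Nelder-Mead",
                           options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 400})
            best = min(best, float(res.fun))
        if best >= ssd_obs:
            count += 1
    return (count + 1) / (reps + 1)


def expansion_time(tau: float, convention: DatingConvention = DatingConvention()) -> int:
    """Years since expansion: T = tau * g / (2 d L), truncated to integer years."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    years = tau * convention.generation_time / (2.0 * convention.rate * convention.L)
    return int(math.floor(years))


def lineage_age(pi: float, convention: DatingConvention = DatingConvention()) -> float:
    """Approximate lineage age in years from per-site nucleotide diversity: A = pi / d."""
    if pi < 0:
        raise ValueError("pi must be >= 0")
    return pi / convention.rate


def dating_table(taus: dict[str, float],
                 convention: DatingConvention = DatingConvention()) -> "pd.DataFrame":
    """Expansion dates (point and rate-range bounds) for labelled tau values."""
    import pandas as pd

    lo, hi = convention.rate_range
    rows = []
    for label, tau in taus.items():
        rows.append({
            "group": label,
            "tau": tau,
            "years": expansion_time(tau, convention),
            "years_max": expansion_time(tau, DatingConvention(lo, convention.rate_range,
                                                              convention.generation_time, convention.L)),
            "years_min": expansion_time(tau, DatingConvention(hi, convention.rate_range,
                                                              convention.generation_time, convention.L)),
        })
    return pd.DataFrame(rows)
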