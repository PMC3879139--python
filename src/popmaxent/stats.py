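"""Empirical statistics of spike rasters: rates, pairwise moments,
correlation coefficients, synchrony distribution, with bootstrap errors.

Bootstrap resampling draws whole repeats with replacement, because bins
within a repeat are temporally dependent while repeats are plausibly
independent.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .raster import SpikeRaster, shuffle_raster

__all__ = [
    "EmpiricalStats",
    "moment_stats",
    "triplet_correlations",
    "synchrony_distribution",
    "coincidence_probability_empirical",
    "effective_sample_size",
    "psth",
    "pattern_counts",
]


@dataclasses.dataclass
class EmpiricalStats:
    """Measured constraints for maximum-entropy fitting.

    ``rates[i] = <sigma_i>``, ``moments[i, j] = <sigma_i sigma_j>`` (diagonal
    equals the rates), ``corr`` the Pearson coefficients for binary variables,
    ``p_k`` the synchrony distribution over K = 0..N.  ``*_err`` are bootstrap
    standard errors (zero arrays when ``n_bootstrap == 0``).
    """

    rates: np.ndarray
    moments: np.ndarray
    corr: np.ndarray
    p_k: np.ndarray
    rates_err: np.ndarray
    moments_err: np.ndarray
    corr_err: np.ndarray
    p_k_err: np.ndarray
    n_samples: int
    degenerate: np.ndarray = None  # type: ignore[assignment]  # rate in {0,1}

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[0]

    def check(self, atol: float = 1e-9) -> None:
        """Internal consistency: diag(m) = p, sum_K K P(K) = sum_i p_i."""
        assert np.allclose(np.diag(self.moments), self.rates, atol=atol)
        k = np.arange(self.p_k.shape[0])
        assert abs(self.p_k @ k - self.rates.sum()) < max(atol, 1e-9 * self.n_neurons)


def _raw_stats(values: np.ndarray):
    T = values.shape[1]
    x = values.astype(np.float64)
    rates = x.mean(axis=1)
    moments = (x @ x.T) / T
    np.fill_diagonal(moments, rates)
    k_counts = values.sum(axis=0).astype(np.int64)
    p_k = np.bincount(k_counts, minlength=values.shape[0] + 1) / T
    return rates, moments, p_k


def _corr_from(rates, moments):
    var = rates * (1.0 - rates)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(np.outer(var, var))
        corr = (moments - np.outer(rates, rates)) / denom
    np.fill_diagonal(corr, 1.0)
    return corr


def moment_stats(raster: SpikeRaster, n_bootstrap: int = 0, seed: int = 0) -> EmpiricalStats:
    """Plug-in rates/moments/correlations/P(K) with repeat-bootstrap errors.

    Neurons with empirical rate exactly 0 or 1 have undefined correlation
    coefficients; they are flagged in ``stats.degenerate`` and their ``corr``
    rows are NaN rather than silently zeroed.
    """
    if raster.n_bins < 2:
        raise ValueError("need at least two time bins")
    rates, moments, p_k = _raw_stats(raster.values)
    corr = _corr_from(rates, moments)
    degenerate = (rates <= 0.0) | (rates >= 1.0)

    N = raster.n_neurons
    shape_err = (np.zeros(N), np.zeros((N, N)), np.zeros((N, N)), np.zeros(N + 1))
    rates_err, moments_err, corr_err, p_k_err = shape_err
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        cube = raster.by_repeat()
        R = raster.n_repeats
        acc_r = np.zeros((n_bootstrap, N))
        acc_m = np.zeros((n_bootstrap, N, N))
        acc_k = np.zeros((n_bootstrap, N + 1))
        for b in range(n_bootstrap):
            reps = rng.integers(0, R, size=R)
            vals = cube[:, reps, :].reshape(N, -1)
            r_b, m_b, k_b = _raw_stats(vals)
            acc_r[b] = r_b
            acc_m[b] = m_b
            acc_k[b] = k_b
        rates_err = acc_r.std(axis=0, ddof=1)
        moments_err = acc_m.std(axis=0, ddof=1)
        corr_boot = np.array([_corr_from(acc_r[b], acc_m[b]) for b in range(n_bootstrap)])
        with np.errstate(invalid="ignore"):
            corr_err = np.nanstd(corr_boot, axis=0, ddof=1)
        p_k_err = acc_k.std(axis=0, ddof=1)

    stats = EmpiricalStats(rates, moments, corr, p_k, rates_err, moments_err,
                           corr_err, p_k_err, raster.n_bins, degenerate)
    stats.check()
    return stats


def triplet_correlations(raster: SpikeRaster, triplets) -> np.ndarray:
    """Connected three-point correlations
    ``C_ijk = <(s_i - p_i)(s_j - p_j)(s_k - p_k)>`` per (i, j, k)."""
    x = raster.values.astype(np.float64)
    xc = x - x.mean(axis=1, keepdims=True)
    out = np.empty(len(triplets))
    for t, (i, j, k) in enumerate(triplets):
        if len({i, j, k}) != 3:
            raise ValueError(f"triplet {(i, j, k)} has a repeated index")
        out[t] = np.mean(xc[i] * xc[j] * xc[k])
    return out


def all_triplets(n: int, max_count: int = None, seed: int = 0):
    """All (or a random subset of) distinct index triplets i<j<k."""
    from itertools import combinations

    trips = list(combinations(range(n), 3))
    if max_count is not None and len(trips) > max_count:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(trips), size=max_count, replace=False)
        trips = [trips[i] for i in idx]
    return trips


def synchrony_distribution(raster: SpikeRaster) -> np.ndarray:
    """Empirical P(K): frequency of K = sum_i sigma_i per bin, K = 0..N."""
    k_counts = raster.values.sum(axis=0).astype(np.int64)
    return np.bincount(k_counts, minlength=raster.n_neurons + 1) / raster.n_bins


def pattern_counts(words: np.ndarray):
    """Counts of distinct binary words (rows).  Returns (unique, counts)."""
    packed = np.packbits(words.astype(np.uint8), axis=1)
    uniq, counts = np.unique(packed, axis=0, return_counts=True)
    return uniq, counts


def coincidence_probability_empirical(raster: SpikeRaster) -> float:
    """Probability that two distinct random bins carry the identical word:
    ``sum_w n_w (n_w - 1) / (T (T - 1))``, computed exactly from pattern
    counts.  (The with-replacement variant differs by O(1/T).)"""
    T = raster.n_bins
    if T < 2:
        raise ValueError("need at least two time bins")
    _, counts = pattern_counts(raster.words())
    return float((counts * (counts - 1)).sum() / (T * (T - 1)))


def effective_sample_size(raster: SpikeRaster, n_subsets: int = 50, seed: int = 0) -> float:
    """Effective number of independent samples.

    For repeat subsets of several sizes r, the error of the mean-rate estimate
    scales as a/sqrt(r); fitting a on the original raster and on a fully
    time-shuffled raster (which destroys within-repeat dependence) gives
    ``T_eff = T * (a_shuffled / a_observed)**2``.
    """
    R = raster.n_repeats
    if R < 4:
        raise ValueError("need at least 4 repeats")
    rng = np.random.default_rng(seed)

    def _scale_coeff(r: SpikeRaster) -> float:
        cube = r.by_repeat()
        sizes = np.unique(np.clip(np.geomspace(2, R // 2, num=4).astype(int), 2, R // 2))
        coeffs = []
        for sz in sizes:
            ests = np.empty((n_subsets, r.n_neurons))
            for s in range(n_subsets):
                reps = rng.choice(R, size=sz, replace=False)
                ests[s] = cube[:, reps, :].mean(axis=(1, 2))
            err = ests.std(axis=0, ddof=1).mean()
            coeffs.append(err * np.sqrt(sz))
        return float(np.mean(coeffs))

    a_obs = _scale_coeff(raster)
    a_shuf = _scale_coeff(shuffle_raster(raster, seed=int(rng.integers(2**31))))
    if a_obs <= 0:
        raise ValueError("cannot estimate scaling on a constant raster")
    return float(raster.n_bins * (a_shuf / a_obs) ** 2)


def psth(raster: SpikeRaster, neuron: int, as_rate: bool = False) -> np.ndarray:
    """Per-bin spike probability across repeats (length ``bins_per_repeat``);
    divided by the bin width when ``as_rate``."""
    trace = raster.by_repeat()[neuron].mean(axis=0)
    return trace / raster.dt if as_rate else trace
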