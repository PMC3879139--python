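"""Drawing from models: exact enumeration (small N), Metropolis Monte Carlo,
Wang-Landau density of states, and equilibration diagnostics."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from scipy.stats import ks_2samp, kendalltau

from . import _kernels
from .model import MaxEntModel

__all__ = [
    "DensityOfStates",
    "ExactDistribution",
    "enumerate_exact",
    "metropolis_sample",
    "equilibration_check",
    "wang_landau",
    "ENUMERATION_CAP",
]

ENUMERATION_CAP = 25


def _bit_words(offset: int, count: int, n: int) -> np.ndarray:
    """Rows are the binary expansions of offset..offset+count-1 (bit 0 =
    neuron 0)."""
    idx = np.arange(offset, offset + count, dtype=np.uint64)
    return ((idx[:, None] >> np.arange(n, dtype=np.uint64)) & 1).astype(np.uint8)


@dataclasses.dataclass
class ExactDistribution:
    """Full enumeration of a model: per-word log-probabilities plus the exact
    moments.  Word order is integer order of the bit pattern."""

    log_z: float
    rates: np.ndarray
    moments: np.ndarray
    p_k: np.ndarray
    entropy_bits: float
    mean_energy: float
    n_neurons: int

    def log_probs(self, model: MaxEntModel) -> np.ndarray:
        words = _bit_words(0, 2 ** self.n_neurons, self.n_neurons)
        return -model.energies(words) - self.log_z

    def probs(self, model: MaxEntModel) -> np.ndarray:
        return np.exp(self.log_probs(model))


def enumerate_exact(model: MaxEntModel, cap: int = ENUMERATION_CAP,
                    batch_bits: int = 18) -> ExactDistribution:
    """Exact log Z, moments, P(K), entropy and mean energy by summing over
    all 2^N words (batched to bound memory).

    Raises for N above `cap`; use the Monte Carlo samplers there.
    """
    n = model.n_neurons
    if n > cap:
        raise ValueError(
            f"N = {n} exceeds the enumeration cap {cap}; use metropolis_sample"
            " or wang_landau instead"
        )
    total = 1 << n
    batch = min(total, 1 << batch_bits)

    log_weights = []
    acc_r = np.zeros(n)
    acc_m = np.zeros((n, n))
    acc_k = np.zeros(n + 1)
    acc_e = 0.0
    acc_elogw = 0.0  # sum of w * (-E), for entropy

    # first pass: log Z
    for off in range(0, total, batch):
        words = _bit_words(off, min(batch, total - off), n)
        log_weights.append(-model.energies(words))
    log_z = float(logsumexp(np.concatenate(log_weights)))

    for bi, off in enumerate(range(0, total, batch)):
        words = _bit_words(off, min(batch, total - off), n)
        w = np.exp(log_weights[bi] - log_z)
        x = words.astype(np.float64)
        acc_r += w @ x
        acc_m += (x * w[:, None]).T @ x
        acc_k += np.bincount(words.sum(axis=1), weights=w, minlength=n + 1)
        e = -log_weights[bi]
        acc_e += float(w @ e)
        acc_elogw += float(w @ (log_weights[bi] - log_z))

    np.fill_diagonal(acc_m, acc_r)
    entropy_bits = -acc_elogw / np.log(2.0)
    return ExactDistribution(log_z, acc_r, acc_m, acc_k, entropy_bits, acc_e, n)


def metropolis_sample(model: MaxEntModel, n_samples: int, burn_in: int = None,
                      thin: int = 1, seed: int = 0, init="random",
                      beta: float = 1.0):
    """Single-spin-flip Metropolis chain; acceptance min(1, e^{-beta dE}).

    ``burn_in`` and ``thin`` are in sweeps (N attempted flips); burn-in
    defaults to 100 sweeps + 2N.  ``init`` is "random", "silent", or an
    explicit word.  Returns (samples uint8 [n_samples, N], energies).
    """
    n = model.n_neurons
    if burn_in is None:
        burn_in = 100 + 2 * n
    rng = np.random.default_rng(seed)
    if isinstance(init, str):
        if init == "random":
            sigma = (rng.random(n) < 0.5).astype(np.uint8)
        elif init == "silent":
            sigma = np.zeros(n, dtype=np.uint8)
        else:
            raise ValueError(f"unknown init {init!r}")
    else:
        sigma = np.ascontiguousarray(init, dtype=np.uint8).copy()
    kseed = int(rng.integers(0, 2**31 - 1))
    thin_flips = max(1, int(thin * n))  # thin < 1/N still records every flip
    samples, energies = _kernels.metropolis_run(
        model.h, model.J, model.V, float(beta), sigma,
        int(n_samples), thin_flips, int(burn_in * n), kseed)
    return samples, energies


def equilibration_check(model: MaxEntModel, n_chains: int = 8,
                        n_samples: int = 2000, burn_in: int = None,
                        thin: int = 2, seed: int = 0, alpha: float = 0.05,
                        init="random", reference_model: MaxEntModel = None):
    """Compare chains launched from independent random initial states.

    Pairwise two-sample KS tests on the energy and on the summed activity
    (magnetization) across chains at significance `alpha`; a per-chain trend
    test (Kendall tau of energy vs time) flags drifting chains.  The check
    passes when the KS rejection fraction stays near the false-positive rate
    and no chain drifts.

    Returns a dict report with a boolean "pass" key.
    """
    if n_chains < 2:
        raise ValueError("need at least two chains")
    rng = np.random.default_rng(seed)
    energies, mags, drifting = [], [], 0
    for c in range(n_chains):
        # odd chains may come from a reference model (distributions must then
        # differ for the check to fail, as it should)
        m = reference_model if (reference_model is not None and c % 2) else model
        if isinstance(init, str) and init == "ones":
            chain_init = np.ones(model.n_neurons, dtype=np.uint8)
        else:
            chain_init = init
        s, e = metropolis_sample(m, n_samples, burn_in=burn_in, thin=thin,
                                 seed=int(rng.integers(2**31)), init=chain_init)
        if reference_model is not None and c % 2:
            e = model.energies(s)  # score both chains under the same model
        energies.append(e)
        mags.append(s.sum(axis=1))
        # trend on block means to tame autocorrelation
        blocks = np.array_split(e, 20)
        means = np.array([b.mean() for b in blocks])
        tau, p = kendalltau(np.arange(means.size), means)
        if p < 0.01:
            drifting += 1

    def _block_means(x, n_blocks=30):
        return np.array([b.mean() for b in np.array_split(x, n_blocks)])

    n_reject = 0
    n_pairs = 0
    for a in range(n_chains):
        for b in range(a + 1, n_chains):
            n_pairs += 2
            # KS on block means: nearly independent and continuous, unlike
            # the raw autocorrelated, heavily tied samples
            if ks_2samp(_block_means(energies[a]),
                        _block_means(energies[b])).pvalue < alpha:
                n_reject += 1
            if ks_2samp(_block_means(mags[a]),
                        _block_means(mags[b])).pvalue < alpha:
                n_reject += 1
    reject_frac = n_reject / n_pairs
    passed = (reject_frac <= max(3 * alpha, 0.25)) and drifting == 0
    return {
        "pass": bool(passed),
        "ks_rejection_fraction": reject_frac,
        "n_drifting_chains": drifting,
        "mean_energy_per_chain": [float(e.mean()) for e in energies],
        "alpha": alpha,
    }


@dataclasses.dataclass
class DensityOfStates:
    """log g(E) on uniform energy bins; after normalization sum g = 2^N over
    visited bins."""

    edges: np.ndarray
    log_g: np.ndarray
    visited: np.ndarray
    n_neurons: int
    final_ln_f: float = np.nan
    steps: int = 0
    e_mean: np.ndarray = None  # type: ignore[assignment]  # per-bin sampled mean

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def representative_energies(self) -> np.ndarray:
        """Per-bin energy for thermodynamic sums: the within-bin sampled mean
        where available (unbiased to first order), otherwise the center."""
        if self.e_mean is None:
            return self.centers
        return np.where(self.visited, self.e_mean, self.centers)

    def normalized(self) -> "DensityOfStates":
        vis = self.visited.astype(bool)
        shift = self.n_neurons * np.log(2.0) - logsumexp(self.log_g[vis])
        log_g = np.where(vis, self.log_g + shift, -np.inf)
        return dataclasses.replace(self, log_g=log_g)

    def write(self, path) -> None:
        with open(Path(path), "w") as fh:
            fh.write("# energy_center\tlog_g\n")
            for e, lg, v in zip(self.centers, self.log_g, self.visited):
                if v:
                    fh.write(f"{float(e)!r}\t{float(lg)!r}\n")


def _energy_range(model: MaxEntModel, seed: int, n_probe: int = 4000):
    """Bracket the reachable energy range: greedy descent from T = 1 samples
    for the low end, uniform random words for the bulk/high end."""
    rng = np.random.default_rng(seed)
    n = model.n_neurons
    samples, e1 = metropolis_sample(model, 2000, thin=1,
                                    seed=int(rng.integers(2**31)))
    minima, e_min_desc = _kernels.descend_many(
        model.h, model.J, model.V, samples[:: max(1, 2000 // 200)])
    uniform = (rng.random((n_probe, n)) < 0.5).astype(np.uint8)
    e_unif = model.energies(uniform)
    e_silent = model.energy(np.zeros(n, dtype=np.uint8))
    lo = min(e_min_desc.min(), e1.min(), e_silent)
    hi = max(e_unif.max(), e1.max(), e_silent)
    pad = 0.05 * (hi - lo) + 1e-9
    return lo - pad, hi + pad


def wang_landau(model: MaxEntModel, energy_bins: int = 200,
                flatness: float = 0.80, ln_f_final: float = 1e-8,
                seed: int = 0, energy_range=None,
                max_steps: int = 400_000_000, n_runs: int = 1,
                sweeps_per_check: int = 10_000) -> DensityOfStates:
    """Wang-Landau flat-histogram estimate of the density of states.

    Modification factor schedule ln f -> ln f / 2 on histogram flatness
    (min count >= `flatness` * mean over visited bins), terminating below
    ``ln_f_final``.  The result is normalized so that sum g = 2^N.

    With ``n_runs > 1``, independent walkers on the same energy grid are
    averaged (per-bin mean of the normalized log g), reducing the log g noise
    by ~1/sqrt(n_runs); a bin counts as visited when every run visited it.
    """
    rng = np.random.default_rng(seed)
    if energy_range is None:
        lo, hi = _energy_range(model, int(rng.integers(2**31)))
    else:
        lo, hi = energy_range
    edges = np.linspace(lo, hi, energy_bins + 1)

    runs = []
    for _ in range(max(1, n_runs)):
        sigma = (rng.random(model.n_neurons) < 0.5).astype(np.uint8)
        log_g, visited, ln_f, steps, e_mean = _kernels.wang_landau_run(
            model.h, model.J, model.V, float(lo), float(hi), int(energy_bins),
            float(flatness), float(ln_f_final),
            int(sweeps_per_check * model.n_neurons),
            int(max_steps), sigma, int(rng.integers(2**31)))
        dos = DensityOfStates(edges, log_g, visited.astype(bool),
                              model.n_neurons, float(ln_f), int(steps), e_mean)
        runs.append(dos.normalized())
    if len(runs) == 1:
        return runs[0]
    visited = np.logical_and.reduce([d.visited for d in runs])
    log_g = np.where(visited,
                     np.mean([d.log_g for d in runs], axis=0), -np.inf)
    e_mean = np.mean([d.e_mean for d in runs], axis=0)
    combined = DensityOfStates(edges, log_g, visited, model.n_neurons,
                               runs[-1].final_ln_f,
                               int(sum(d.steps for d in runs)), e_mean)
    return combined.normalized()
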