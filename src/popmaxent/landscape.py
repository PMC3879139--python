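"""Energy-landscape analysis: metastable states, basins of attraction,
overlaps, transition paths and barriers, and basin dynamics over repeats.

Descent sweeps neurons in ascending index order and keeps any single-spin
flip that strictly lowers the energy, repeating until a full sweep changes
nothing; this makes basin assignment deterministic.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import _kernels
from .model import MaxEntModel
from .raster import SpikeRaster

__all__ = [
    "LandscapeSummary",
    "TransitionRecord",
    "descend_to_metastable",
    "census_basins",
    "overlaps",
    "explore_transitions",
    "basin_dynamics",
]


@dataclasses.dataclass
class TransitionRecord:
    start_basin: int
    end_basin: int  # -1 when censored (budget exhausted without exit)
    barrier: float
    path_length: int  # attempted flips until the basin was left
    censored: bool = False


@dataclasses.dataclass
class LandscapeSummary:
    """Metastable patterns with their energies, per-data-word basin indices,
    and basin occupancy counts over the *recorded* words."""

    metastable: np.ndarray  # (n_states, N) uint8, sorted by descending size
    energies: np.ndarray
    assignment: np.ndarray  # basin index per data word
    sizes: np.ndarray

    @property
    def n_basins(self) -> int:
        return self.metastable.shape[0]

    def basins_with_at_least(self, count: int) -> int:
        return int((self.sizes >= count).sum())

    def silent_basin(self):
        """Index of the all-silent basin, or None if absent."""
        silent = np.where(~self.metastable.any(axis=1))[0]
        return int(silent[0]) if silent.size else None


def descend_to_metastable(model: MaxEntModel, pattern):
    """Greedy descent from one word; returns (metastable word, its energy).
    The result is audited to be locally stable (every single flip raises E)."""
    sigma = np.ascontiguousarray(pattern, dtype=np.uint8).copy()
    e = _kernels.descend(model.h, model.J, model.V, sigma)
    assert _kernels.is_metastable(model.h, model.J, model.V, sigma)
    return sigma, float(e)


def _assign(model: MaxEntModel, words: np.ndarray):
    minima, energies = _kernels.descend_many(model.h, model.J, model.V,
                                             np.ascontiguousarray(words, dtype=np.uint8))
    uniq, inverse, counts = np.unique(minima, axis=0, return_inverse=True,
                                      return_counts=True)
    e_uniq = np.empty(uniq.shape[0])
    for b in range(uniq.shape[0]):
        e_uniq[b] = energies[np.argmax(inverse == b)]
    return uniq, inverse, counts, e_uniq


def census_basins(model: MaxEntModel, raster: SpikeRaster) -> LandscapeSummary:
    """Descend from every recorded word, deduplicate the metastable states,
    and count basin occupancies (sorted by descending basin size)."""
    if raster.n_neurons != model.n_neurons:
        raise ValueError("model and raster sizes differ")
    uniq, inverse, counts, e_uniq = _assign(model, raster.words())
    order = np.argsort(-counts, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    return LandscapeSummary(uniq[order], e_uniq[order], rank[inverse],
                            counts[order])


def overlaps(patterns) -> np.ndarray:
    """Cosine overlap matrix q(a, b) = a.b / sqrt(|a| |b|) for {0,1} words;
    rows that are all-silent have undefined overlap and yield NaN."""
    x = np.asarray(patterns, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("need a (n_patterns, N) array")
    norms = x.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = (x @ x.T) / np.sqrt(np.outer(norms, norms))
    q[norms == 0, :] = np.nan
    q[:, norms == 0] = np.nan
    return q


def explore_transitions(model: MaxEntModel, start, n_walks: int = 100,
                        max_attempts: int = 10_000, seed: int = 0):
    """Metropolis walks from a metastable state; after every attempted flip
    the walk tests (by greedy descent) whether it has left the starting basin.
    On first exit it records the destination basin's metastable word, the
    barrier (path maximum energy minus start energy) and the number of
    attempted flips.  Walks that never exit are returned censored.

    Returns (records, end_states) where end_states maps the basin indices in
    the records to metastable words (index 0 is the start basin).
    """
    start = np.ascontiguousarray(start, dtype=np.uint8)
    if not _kernels.is_metastable(model.h, model.J, model.V, start):
        raise ValueError("start pattern is not metastable")
    e_start = model.energy(start)
    rng = np.random.default_rng(seed)
    h, J, V = model.h, model.J, model.V
    n = model.n_neurons

    end_states = [start.copy()]
    records = []
    for _ in range(n_walks):
        sigma = start.copy()
        k = int(sigma.sum())
        e = e_start
        e_max = e
        exited = False
        kseed = int(rng.integers(2**31))
        walk_rng = np.random.default_rng(kseed)
        for attempt in range(1, max_attempts + 1):
            i = int(walk_rng.integers(n))
            de = _kernels.delta_energy(h, J, V, sigma, k, i)
            if de <= 0 or walk_rng.random() < np.exp(-de):
                sigma[i] ^= 1
                k += 1 if sigma[i] else -1
                e += de
                e_max = max(e_max, e)
            probe = sigma.copy()
            _kernels.descend(h, J, V, probe)
            if not np.array_equal(probe, start):
                basin = None
                for bi, w in enumerate(end_states):
                    if np.array_equal(w, probe):
                        basin = bi
                        break
                if basin is None:
                    end_states.append(probe.copy())
                    basin = len(end_states) - 1
                records.append(TransitionRecord(0, basin, float(e_max - e_start),
                                                attempt))
                exited = True
                break
        if not exited:
            records.append(TransitionRecord(0, -1, float(e_max - e_start),
                                            max_attempts, censored=True))
    return records, np.array(end_states, dtype=np.uint8)


def basin_dynamics(model: MaxEntModel, raster: SpikeRaster, max_lag: int = 30):
    """Basin occupancy dynamics across the repeat structure.

    Returns a dict with:
      - ``prob``: (bins_per_repeat, n_basins) probability across repeats that
        the population sits in each basin at that point in the stimulus,
      - ``coherence``: per bin, the share of the dominant non-silent basin
        among non-silent basin visits (NaN when every repeat is silent),
      - ``autocorr``: mean autocorrelation of the basin indicator traces,
      - ``tau_bins`` / ``tau_seconds``: exponential fit time constant.
    """
    summary = census_basins(model, raster)
    B, R = raster.bins_per_repeat, raster.n_repeats
    traj = summary.assignment.reshape(R, B)
    n_basins = summary.n_basins

    prob = np.zeros((B, n_basins))
    for b in range(n_basins):
        prob[:, b] = (traj == b).mean(axis=0)

    silent = summary.silent_basin()
    coherence = np.full(B, np.nan)
    for t in range(B):
        occ = prob[t].copy()
        if silent is not None:
            occ[silent] = 0.0
        tot = occ.sum()
        if tot > 0:
            coherence[t] = occ.max() / tot

    # mean autocorrelation of basin-indicator traces (occupancy-weighted)
    occ_tot = prob.mean(axis=0)
    lags = np.arange(max_lag + 1)
    acf = np.zeros(max_lag + 1)
    weight = 0.0
    for b in range(n_basins):
        ind = (traj == b).astype(float)
        xc = ind - ind.mean()
        var = xc.var()
        if var <= 0:
            continue
        a = np.zeros(max_lag + 1)
        for lag in lags:
            a[lag] = np.mean(xc[:, : B - lag] * xc[:, lag:] if lag else xc * xc) / var
        acf += occ_tot[b] * a
        weight += occ_tot[b]
    if weight > 0:
        acf /= weight

    # exponential fit acf ~ exp(-lag/tau) over the positive head
    pos = acf > 0.02
    head = np.argmin(pos) if not pos.all() else len(acf)
    tau = np.nan
    if head >= 3:
        y = np.log(acf[1:head])
        x = lags[1:head].astype(float)
        slope = np.polyfit(x, y, 1)[0]
        if slope < 0:
            tau = -1.0 / slope
    return {
        "summary": summary,
        "prob": prob,
        "coherence": coherence,
        "autocorr": acf,
        "tau_bins": float(tau),
        "tau_seconds": float(tau * raster.dt) if np.isfinite(tau) else np.nan,
    }
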