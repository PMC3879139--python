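"""Model-versus-data validation reports: synchrony distribution, triplet
correlations, effective-field curve, PSTH prediction, coincidence
probability."""

from __future__ import annotations

import numpy as np

from .model import MaxEntModel, conditional_spike_probability
from .raster import SpikeRaster
from .sampling import ENUMERATION_CAP, enumerate_exact, metropolis_sample
from .stats import psth as empirical_psth
from .stats import synchrony_distribution, triplet_correlations

__all__ = [
    "predict_synchrony",
    "triplet_prediction_report",
    "effective_field_curve",
    "predict_psth",
    "coincidence_probability_model",
    "model_raster",
]


def _choose_engine(model: MaxEntModel, engine: str) -> str:
    if engine == "auto":
        return "exact" if model.n_neurons <= ENUMERATION_CAP else "mc"
    return engine


def model_raster(model: MaxEntModel, n_samples: int, seed: int = 0,
                 thin: int = 2, dt: float = 0.02) -> SpikeRaster:
    """Metropolis sample packaged as a single-repeat raster."""
    samples, _ = metropolis_sample(model, n_samples, thin=thin, seed=seed)
    return SpikeRaster(samples.T, 1, n_samples, dt)


def predict_synchrony(model: MaxEntModel, engine: str = "auto",
                      n_samples: int = 200_000, seed: int = 0) -> np.ndarray:
    """Model P(K) by enumeration (small N) or a long Metropolis run."""
    engine = _choose_engine(model, engine)
    if engine == "exact":
        return enumerate_exact(model).p_k
    samples, _ = metropolis_sample(model, n_samples, seed=seed)
    return np.bincount(samples.sum(axis=1), minlength=model.n_neurons + 1) / n_samples


def triplet_prediction_report(model: MaxEntModel, raster: SpikeRaster,
                              triplets, n_bins: int = 1000,
                              n_samples: int = 200_000, seed: int = 0):
    """Data vs model connected triplet correlations.

    Data values are binned into ``n_bins`` equal-population bins; per bin the
    model predictions are summarized by mean and s.d.; the overall mean
    absolute deviation (model - data) is reported.  The bin count shrinks
    with a warning entry when there are fewer triplets than bins.
    """
    c_data = triplet_correlations(raster, triplets)
    sim = model_raster(model, n_samples, seed=seed, dt=raster.dt)
    c_model = triplet_correlations(sim, triplets)

    warn = None
    if len(triplets) < n_bins:
        warn = f"only {len(triplets)} triplets; reduced bins from {n_bins}"
        n_bins = max(1, len(triplets) // 2)

    order = np.argsort(c_data)
    edges = np.array_split(order, n_bins)
    rows = []
    for grp in edges:
        if grp.size == 0:
            continue
        rows.append((c_data[grp].mean(), c_model[grp].mean(),
                     c_model[grp].std(ddof=1) if grp.size > 1 else 0.0))
    binned = np.array(rows)
    mad = float(np.abs(c_model - c_data).mean())
    return {
        "binned": binned,  # columns: data mean, model mean, model s.d.
        "mad": mad,
        "data": c_data,
        "model": c_model,
        "warning": warn,
    }


def effective_field_curve(model: MaxEntModel, raster: SpikeRaster,
                          n_field_bins: int = 30, central: float = 0.99,
                          min_per_bin: int = 50):
    """Empirical spike frequency versus effective field, for every neuron and
    word, against the parameter-free logistic prediction.

    Fields are binned into ``n_field_bins`` equal-width bins over the central
    ``central`` quantile range; bins with fewer than ``min_per_bin``
    observations are dropped.

    Returns a dict with per-bin field centers, empirical frequencies, the
    logistic prediction, counts, and binomial errors.
    """
    words = raster.words()
    fields = np.empty((words.shape[0], model.n_neurons))
    for i in range(model.n_neurons):
        fields[:, i] = model.effective_fields(words, i)
    spikes = words.astype(bool)

    flat_f = fields.ravel()
    flat_s = spikes.ravel()
    tail = (1.0 - central) / 2
    lo, hi = np.quantile(flat_f, [tail, 1 - tail])
    edges = np.linspace(lo, hi, n_field_bins + 1)
    idx = np.digitize(flat_f, edges) - 1
    centers, freq, err, counts = [], [], [], []
    for b in range(n_field_bins):
        mask = idx == b
        n = int(mask.sum())
        if n < min_per_bin:
            continue
        f = flat_s[mask].mean()
        centers.append(0.5 * (edges[b] + edges[b + 1]))
        freq.append(f)
        err.append(np.sqrt(max(f * (1 - f), 1e-12) / n))
        counts.append(n)
    centers = np.array(centers)
    return {
        "field": centers,
        "empirical": np.array(freq),
        "logistic": conditional_spike_probability(centers),
        "stderr": np.array(err),
        "count": np.array(counts),
    }


def predict_psth(model: MaxEntModel, raster: SpikeRaster, neuron: int):
    """Conditional PSTH prediction for one held-out neuron.

    For every (repeat, bin) the spike probability of ``neuron`` is the
    logistic of its effective field given the other neurons' recorded states.
    Two summary correlations against the empirical PSTH are returned:
    (a) the mean of per-repeat correlations and (b) the correlation of the
    across-repeat mean prediction.  Zero-variance traces yield NaN and are
    flagged.
    """
    words = raster.words().copy()
    words[:, neuron] = 0  # condition only on the *other* neurons
    fields = model.effective_fields(words, neuron)
    pred = conditional_spike_probability(fields).reshape(
        raster.n_repeats, raster.bins_per_repeat)
    emp = empirical_psth(raster, neuron)

    def _corr(a, b):
        if a.std() == 0 or b.std() == 0:
            return np.nan
        return float(np.corrcoef(a, b)[0, 1])

    per_repeat = np.array([_corr(pred[r], emp) for r in range(raster.n_repeats)])
    mean_pred = pred.mean(axis=0)
    return {
        "predicted": pred,
        "predicted_mean": mean_pred,
        "empirical": emp,
        "corr_per_repeat_mean": float(np.nanmean(per_repeat)),
        "corr_of_mean": _corr(mean_pred, emp),
        "undefined": bool(np.isnan(per_repeat).all()),
    }


def coincidence_probability_model(model: MaxEntModel, engine: str = "auto",
                                  n_samples: int = 200_000, seed: int = 0):
    """P_c = sum_sigma P(sigma)^2: the probability two independent draws from
    the model coincide.

    Exact route sums P^2 by enumeration; the MC route uses
    P_c = <P(sigma)>_P = <e^{-E}> / Z over model samples, which requires
    log Z (set ``model.log_z`` or stay under the enumeration cap).

    Returns (P_c, -log2(P_c)/N).
    """
    engine = _choose_engine(model, engine)
    n = model.n_neurons
    if engine == "exact":
        dist = enumerate_exact(model)
        lp = dist.log_probs(model)
        from scipy.special import logsumexp

        log_pc = logsumexp(2 * lp)
        pc = float(np.exp(log_pc))
    else:
        if model.log_z is None:
            raise ValueError("MC route needs model.log_z (see thermo module)")
        _, energies = metropolis_sample(model, n_samples, seed=seed)
        pc = float(np.exp(-energies - model.log_z).mean())
    return pc, float(-np.log2(pc) / n)
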