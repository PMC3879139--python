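"""Fitting maximum-entropy models to measured constraints.

The fitter iterates damped multiplicative updates on all parameters until the
model's constrained expectations match the data to within the measurement
error bars (residual z-scores).  Expectations come either from exact
enumeration (small N) or from a Metropolis sample batch reused across
parameter updates through histogram reweighting, with the batch refreshed
when the cumulative parameter change exceeds a trust region or the effective
sample size degrades.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .model import MaxEntModel, gauge_fix
from .sampling import ENUMERATION_CAP, _bit_words, metropolis_sample
from .stats import EmpiricalStats, moment_stats

__all__ = [
    "FitReport",
    "fit_independent",
    "fit_model",
    "evaluate_fit",
    "perturbative_couplings",
]


@dataclasses.dataclass
class FitReport:
    """Diagnostics of a fit: residual z-scores (model minus data, in units of
    the data error bar), convergence trace, and optional train/test
    log-likelihoods (nats per neuron per bin)."""

    converged: bool
    n_iterations: int
    max_abs_z: float
    z_rates: np.ndarray = None  # type: ignore[assignment]
    z_moments: np.ndarray = None  # type: ignore[assignment]
    z_pk: np.ndarray = None  # type: ignore[assignment]
    trace: list = dataclasses.field(default_factory=list)
    engine: str = "exact"
    l1_strength: float = 0.0
    seed: int = 0
    train_loglik: float = None  # type: ignore[assignment]
    test_loglik: float = None  # type: ignore[assignment]
    likelihood_ratio: float = None  # type: ignore[assignment]

    def all_z(self) -> np.ndarray:
        parts = [z for z in (self.z_rates, self.z_moments, self.z_pk) if z is not None]
        return np.concatenate([np.atleast_1d(p).ravel() for p in parts])


def fit_independent(stats: EmpiricalStats, pseudocount: float = 0.0) -> MaxEntModel:
    """Closed-form independent model: h_i = logit(p_i), J = 0, V = 0."""
    p = stats.rates.astype(float).copy()
    if pseudocount > 0:
        p = (p * stats.n_samples + pseudocount) / (stats.n_samples + 2 * pseudocount)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError(
            "rates at 0 or 1 give infinite fields; pass pseudocount > 0")
    return MaxEntModel("independent", np.log(p / (1 - p)))


def _fallback_err(x: np.ndarray, T: int) -> np.ndarray:
    """Binomial standard error used when bootstrap errors are absent."""
    return np.sqrt(np.clip(x * (1 - x), 1e-12, None) / T)


class _ExactEngine:
    def __init__(self, n: int):
        if n > ENUMERATION_CAP:
            raise ValueError(f"exact engine limited to N <= {ENUMERATION_CAP}")
        self.words = _bit_words(0, 1 << n, n).astype(np.float64)
        self.K = self.words.sum(axis=1).astype(int)
        self.n = n

    def expectations(self, h, J, V):
        x = self.words
        e = -(x @ h) - 0.5 * np.einsum("ti,ij,tj->t", x, J, x) + V[self.K]
        logw = -e
        logw -= logw.max()
        w = np.exp(logw)
        z = w.sum()
        w /= z
        p = w @ x
        m = (x * w[:, None]).T @ x
        pk = np.bincount(self.K, weights=w, minlength=self.n + 1)
        return p, m, pk


class _MCEngine:
    """Metropolis batch with histogram reweighting between parameter updates."""

    def __init__(self, n: int, batch_size: int, thin: int, trust: float,
                 min_eff_frac: float, rng: np.random.Generator,
                 batch_size_init: int = None):
        self.n = n
        self.max_batch = max(batch_size, 4 * batch_size)
        self.target_batch = batch_size
        self.batch_size = batch_size_init or max(20_000, batch_size // 8)
        self.thin = thin
        self.trust = trust
        self.min_eff_frac = min_eff_frac
        self.rng = rng
        self.X = None
        self.E0 = None
        self.cum_change = np.inf  # force initial sampling
        self.n_resamples = 0
        self._last_state = None

    def _resample(self, h, J, V):
        model = MaxEntModel.__new__(MaxEntModel)
        # bypass validation in the hot loop; arrays are trusted here
        model.model_class = "k_pairwise"
        model.h, model.J, model.V = h.copy(), J.copy(), V.copy()
        model.log_z = None
        model.gauge = "fitting"
        init = "random" if self._last_state is None else self._last_state
        samples, energies = metropolis_sample(
            model, self.batch_size, thin=self.thin,
            seed=int(self.rng.integers(2**31)), init=init)
        self._last_state = samples[-1].copy()
        self.X = samples.astype(np.float64)
        self.K = samples.sum(axis=1).astype(int)
        self.E0 = energies.copy()
        self.cum_change = 0.0
        self.n_resamples += 1

    def note_update(self, total_abs_change: float):
        self.cum_change += total_abs_change

    def _weights(self, h, J, V):
        x = self.X
        e = -(x @ h) - 0.5 * ((x @ J) * x).sum(axis=1) + V[self.K]
        logw = -(e - self.E0)
        logw -= logw.max()
        w = np.exp(logw)
        w /= w.sum()
        return w

    def expectations(self, h, J, V):
        if self.cum_change > self.trust:
            self._resample(h, J, V)
        if self.cum_change == 0.0:  # fresh batch: weights are uniform
            w = np.full(self.X.shape[0], 1.0 / self.X.shape[0])
        else:
            w = self._weights(h, J, V)
            n_eff = 1.0 / (w @ w)
            if n_eff < self.min_eff_frac * self.X.shape[0]:
                self._resample(h, J, V)
                w = np.full(self.X.shape[0], 1.0 / self.X.shape[0])
        x = self.X
        p = w @ x
        m = (x * w[:, None]).T @ x
        pk = np.bincount(self.K, weights=w, minlength=self.n + 1)[: self.n + 1]
        if pk.size < self.n + 1:
            pk = np.pad(pk, (0, self.n + 1 - pk.size))
        return p, m, pk


def fit_model(stats: EmpiricalStats, model_class: str, engine: str = "exact",
              l1_strength: float = 0.0, eta: float = 0.5, max_iters: int = 2000,
              tol_z: float = 2.0, seed: int = 0, batch_size: int = 200_000,
              thin: int = 2, trust: float = 0.5, step_clip: float = 0.25,
              grow_batch: bool = True, tail_average: bool = True,
              gauge: bool = True):
    """Fit a pairwise or K-pairwise model to measured constraints.

    Parameters are updated in parallel with damped multiplicative steps
    ``lambda += eta * log(data / model)`` (sign-reversed for V, which
    penalizes rather than rewards), clipped at ``step_clip`` per iteration.
    Convergence is declared when every residual z-score (normalized by the
    data error bar, with a binomial fallback) satisfies ``|z| <= tol_z``.
    With ``engine="mc"``, the batch grows geometrically whenever progress
    stalls, and the returned parameters are a tail average over the final
    iterations to suppress the Monte Carlo noise floor.

    The K-pairwise result is returned in the canonical gauge.
    Non-convergence is reported honestly in the FitReport, never silently.
    """
    if model_class == "independent":
        model = fit_independent(stats)
        report = FitReport(True, 0, 0.0, z_rates=np.zeros(stats.n_neurons),
                           engine="closed_form", seed=seed)
        return model, report
    if model_class not in ("pairwise", "k_pairwise"):
        raise ValueError(f"unknown model class {model_class!r}")

    n = stats.n_neurons
    T = stats.n_samples
    rng = np.random.default_rng(seed)
    use_pk = model_class == "k_pairwise"

    p_data = stats.rates.astype(float)
    if np.any((p_data <= 0) | (p_data >= 1)):
        raise ValueError("fit requires rates strictly inside (0, 1)")
    iu = np.triu_indices(n, k=1)
    m_floor = 0.25 / T
    m_data = np.clip(stats.moments[iu], m_floor, None)

    p_err = np.where(stats.rates_err > 0, stats.rates_err, _fallback_err(p_data, T))
    m_err = np.where(stats.moments_err[iu] > 0, stats.moments_err[iu],
                     _fallback_err(m_data, T))
    if use_pk:
        # constrain only synchrony bins with data support (expected count
        # >= 1); V beyond the last constrained K is continued linearly
        k_mask = stats.p_k * T >= 1.0
        k_mask[0] = True
        pk_data = np.clip(stats.p_k, 0.1 / T, None)
        pk_err = np.where(stats.p_k_err > 0, stats.p_k_err,
                          _fallback_err(pk_data, T))

    h = np.log(p_data / (1 - p_data))
    J = np.zeros((n, n))
    V = np.zeros(n + 1)

    if engine == "exact":
        eng = _ExactEngine(n)
    elif engine == "mc":
        eng = _MCEngine(n, batch_size, thin, trust, 0.3, rng)
    else:
        raise ValueError("engine must be 'exact' or 'mc'")

    trace = []
    converged = False
    stall = 0
    best_z = np.inf
    eta0 = eta
    eta_t = eta
    prev_z = np.inf
    n_good = 0
    tail_h, tail_J, tail_V, tail_n = 0.0, 0.0, 0.0, 0
    tail_start = None
    z_p = z_m = z_k = None

    for it in range(max_iters):
        p_mod, m_mod, pk_mod = eng.expectations(h, J, V)
        m_mod_u = np.clip(m_mod[iu], m_floor * 1e-3, None)
        p_mod = np.clip(p_mod, 1e-12, 1 - 1e-12)

        z_p = (p_mod - p_data) / p_err
        z_m = (m_mod_u - m_data) / m_err
        max_z = max(np.abs(z_p).max(), np.abs(z_m).max())
        if use_pk:
            pk_mod_c = np.clip(pk_mod, 1e-4 / T, None)
            z_k = np.where(k_mask, (pk_mod_c - pk_data) / pk_err, 0.0)
            max_z = max(max_z, np.abs(z_k).max())
        trace.append(float(max_z))

        if max_z <= tol_z:
            converged = True
            break

        # adaptive damping: back off when the residual grows (the parallel
        # update can oscillate along near-degenerate parameter directions)
        if engine == "exact":
            if max_z > prev_z * (1 + 1e-9):
                eta_t = max(0.02 * eta0, 0.5 * eta_t)
                n_good = 0
            else:
                n_good += 1
                if n_good >= 10:
                    eta_t = min(eta0, 1.2 * eta_t)
                    n_good = 0
            prev_z = max_z

        dh = np.clip(eta_t * np.log(p_data / p_mod), -step_clip, step_clip)
        dJu = np.clip(eta_t * np.log(m_data / m_mod_u), -step_clip, step_clip)
        if l1_strength > 0:
            # soft-threshold couplings toward zero, scaled by the data error
            J_new = np.zeros_like(J)
            J_new[iu] = J[iu] + dJu
            shrink = l1_strength * eta_t * m_err / np.clip(m_data, m_floor, None)
            J_new[iu] = np.sign(J_new[iu]) * np.maximum(np.abs(J_new[iu]) - shrink, 0.0)
            dJu = J_new[iu] - J[iu]
        h += dh
        J[iu] += dJu
        J.T[iu] = J[iu]
        total_change = np.abs(dh).sum() + 2 * np.abs(dJu).sum()
        if use_pk:
            dV = np.where(k_mask,
                          np.clip(eta_t * np.log(pk_mod_c / pk_data),
                                  -step_clip, step_clip), 0.0)
            V = np.clip(V + dV, -50.0, 50.0)
            # continue V linearly past the last constrained K
            k_last = int(np.max(np.nonzero(k_mask)[0]))
            if k_last < n:
                slope = V[k_last] - V[k_last - 1] if k_last >= 1 else 0.0
                slope = max(slope, 0.0)
                for kk_ in range(k_last + 1, n + 1):
                    V[kk_] = V[k_last] + slope * (kk_ - k_last)
            total_change += np.abs(dV).sum()
            # re-gauge every step: project the linear+quadratic (degenerate)
            # component of V into h and J so updates act in the reduced space
            kk = np.arange(n + 1, dtype=float)
            A = np.stack([np.ones_like(kk), kk, kk * kk], axis=1)
            (a_g, b_g, c_g), *_ = np.linalg.lstsq(A, V, rcond=None)
            V -= a_g + b_g * kk + c_g * kk * kk
            V -= V[0]
            h -= b_g + c_g
            J[iu] -= 2 * c_g
            J.T[iu] = J[iu]
        if isinstance(eng, _MCEngine):
            eng.note_update(float(total_change))
            # grow the batch when stuck above tolerance (MC noise floor)
            if max_z >= best_z - 1e-3:
                stall += 1
            else:
                stall = 0
                best_z = max_z
            if grow_batch and stall >= 20:
                eng.batch_size = min(2 * eng.batch_size,
                                     max(4 * eng.target_batch, eng.batch_size))
                eng.cum_change = np.inf
                stall = 0
            if tail_average and it >= max_iters - max(50, max_iters // 10):
                if tail_start is None:
                    tail_start = it
                tail_h = tail_h + h
                tail_J = tail_J + J
                tail_V = tail_V + V
                tail_n += 1

    if isinstance(eng, _MCEngine) and tail_average and tail_n > 0 and not converged:
        h = tail_h / tail_n
        J = tail_J / tail_n
        V = tail_V / tail_n

    if use_pk:
        model = MaxEntModel("k_pairwise", h, J, V, gauge="fitting")
        if gauge:
            model = gauge_fix(model)
    else:
        model = MaxEntModel("pairwise", h, J)

    report = FitReport(
        converged=converged, n_iterations=len(trace),
        max_abs_z=float(trace[-1]) if trace else np.nan,
        z_rates=z_p, z_moments=z_m, z_pk=z_k, trace=trace, engine=engine,
        l1_strength=l1_strength, seed=seed)
    return model, report


def _log_z_of(model: MaxEntModel, seed: int = 0, n_mc: int = 200_000) -> float:
    """log Z by enumeration (small N), the cached value, or the
    silence-probability route (canonical gauge) from a Monte Carlo run."""
    from .sampling import enumerate_exact

    if model.log_z is not None:
        return float(model.log_z)
    if model.n_neurons <= ENUMERATION_CAP:
        return enumerate_exact(model).log_z
    samples, _ = metropolis_sample(model, n_mc, seed=seed)
    p_sil = (samples.sum(axis=1) == 0).mean()
    if p_sil == 0:
        raise ValueError(
            "log Z unavailable: set model.log_z, use N <= enumeration cap, "
            "or ensure the silent state is sampled (silence route)")
    return float(-np.log(p_sil))


def evaluate_fit(model: MaxEntModel, train, test, seed: int = 0,
                 n_mc: int = None, stats: EmpiricalStats = None) -> FitReport:
    """Per-neuron log-likelihood on train vs test, plus residual z-scores
    recomputed from a fresh Monte Carlo run.

    The likelihood ratio (test / train, both in nats per neuron per bin)
    stays near 1 when there is no overfitting.
    """
    log_z = _log_z_of(model, seed=seed)
    n = model.n_neurons

    def _avg_ll(raster):
        e = model.energies(raster.words())
        return float((-e - log_z).mean() / n)

    ll_train = _avg_ll(train)
    ll_test = _avg_ll(test)

    if stats is None:
        stats = moment_stats(train, n_bootstrap=30, seed=seed)
    T = stats.n_samples
    if n_mc is None:
        n_mc = T
    samples, _ = metropolis_sample(model, n_mc, seed=seed + 1)
    x = samples.astype(np.float64)
    p_mod = x.mean(axis=0)
    m_mod = (x.T @ x) / n_mc
    pk_mod = np.bincount(samples.sum(axis=1), minlength=n + 1) / n_mc

    p_err = np.where(stats.rates_err > 0, stats.rates_err,
                     _fallback_err(stats.rates, T))
    iu = np.triu_indices(n, k=1)
    m_err = np.where(stats.moments_err[iu] > 0, stats.moments_err[iu],
                     _fallback_err(stats.moments[iu], T))
    z_p = (p_mod - stats.rates) / p_err
    z_m = (m_mod[iu] - stats.moments[iu]) / m_err
    z_k = None
    if model.model_class == "k_pairwise":
        pk_err = np.where(stats.p_k_err > 0, stats.p_k_err,
                          _fallback_err(stats.p_k, T))
        z_k = (pk_mod - stats.p_k) / pk_err

    max_z = max(np.abs(z_p).max(), np.abs(z_m).max())
    return FitReport(
        converged=True, n_iterations=0, max_abs_z=float(max_z),
        z_rates=z_p, z_moments=z_m, z_pk=z_k, engine="mc", seed=seed,
        train_loglik=ll_train, test_loglik=ll_test,
        likelihood_ratio=ll_test / ll_train)


def perturbative_couplings(stats: EmpiricalStats) -> np.ndarray:
    """Lowest-order (isolated-pair) coupling estimate

    ``J_ij = log[ m_ij (1 - p_i - p_j + m_ij) / ((p_i - m_ij)(p_j - m_ij)) ]``

    which is the exact solution of the two-neuron pairwise model.  Entries
    whose log argument is non-positive are returned as NaN.
    """
    p = stats.rates
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("requires rates strictly inside (0, 1)")
    m = stats.moments
    n = stats.n_neurons
    out = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            num = m[i, j] * (1 - p[i] - p[j] + m[i, j])
            den = (p[i] - m[i, j]) * (p[j] - m[i, j])
            if num > 0 and den > 0:
                out[i, j] = out[j, i] = np.log(num / den)
    np.fill_diagonal(out, 0.0)
    return out
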