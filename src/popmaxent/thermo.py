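"""Entropy and partition-function estimation by three independent routes:
heat-capacity temperature integration, Wang-Landau density of states, and the
silence-probability trick, plus multi-information and energy-distribution
comparisons.

Internally everything is in nats; entropies are reported in bits, converted
at the boundary only.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import logsumexp

from .model import MaxEntModel
from .sampling import DensityOfStates, metropolis_sample
from .stats import EmpiricalStats

__all__ = [
    "EntropyEstimate",
    "heat_capacity_curve",
    "entropy_via_heat_capacity",
    "partition_and_entropy_from_silence",
    "entropy_from_density_of_states",
    "multi_information",
    "independent_entropy_bits",
    "energy_distribution_report",
]

LN2 = np.log(2.0)


@dataclasses.dataclass
class EntropyEstimate:
    value_bits: float
    method: str
    std_error_bits: float = np.nan
    diagnostics: dict = dataclasses.field(default_factory=dict)


def heat_capacity_curve(model: MaxEntModel, T_grid, n_samples: int = 20_000,
                        thin: int = 2, seed: int = 0, anneal: bool = True):
    """C(T) = Var(E) / T^2 under P_T ~ e^{-E/T}, one Metropolis run per T.

    Runs are annealed (each chain warm-starts from the previous temperature's
    final state, visiting the grid from hot to cold) unless ``anneal=False``.
    Returns (T_grid, C, C_stderr).
    """
    T_grid = np.asarray(sorted(T_grid, reverse=True), dtype=float)
    if np.any(T_grid <= 0):
        raise ValueError("temperatures must be positive")
    rng = np.random.default_rng(seed)
    C = np.empty_like(T_grid)
    C_err = np.empty_like(T_grid)
    state = "random"
    for i, T in enumerate(T_grid):
        samples, e = metropolis_sample(
            model, n_samples, thin=thin, seed=int(rng.integers(2**31)),
            init=state, beta=1.0 / T)
        if anneal:
            state = samples[-1].copy()
        var = e.var(ddof=1)
        C[i] = var / T**2
        # crude autocorrelation-aware error on a variance estimate
        n_blocks = 20
        blocks = np.array_split(e, n_blocks)
        bvars = np.array([b.var(ddof=1) for b in blocks])
        C_err[i] = bvars.std(ddof=1) / np.sqrt(n_blocks) / T**2
    order = np.argsort(T_grid)
    return T_grid[order], C[order], C_err[order]


def _geometric_grid(lo: float, hi: float, per_decade: int) -> np.ndarray:
    n = max(4, int(np.ceil(per_decade * np.log10(hi / lo))) + 1)
    return np.geomspace(lo, hi, n)


def entropy_via_heat_capacity(model: MaxEntModel, direction: str = "1toInf",
                              t_min: float = 0.02, beta_min: float = 0.02,
                              points_per_decade: int = 20,
                              n_samples: int = 20_000, thin: int = 2,
                              seed: int = 0) -> EntropyEstimate:
    """Entropy at T = 1 by thermodynamic integration of the heat capacity.

    direction "0to1":   S(1) = int_0^1 C(T)/T dT, integrated on a geometric
    T grid from ``t_min``; the unintegrated [0, t_min] remainder is bounded
    by C(t_min) and folded into the reported error.

    direction "1toInf": S(1) = N ln 2 - int_1^inf C(T)/T dT.  With beta = 1/T
    the integrand becomes beta * Var_beta(E), evaluated on a geometric beta
    grid down to ``beta_min``; the [0, beta_min] tail is Var_uniform(E) *
    beta_min^2 / 2 to leading order and is added as a correction.
    """
    n = model.n_neurons
    rng = np.random.default_rng(seed)
    if direction == "0to1":
        grid = _geometric_grid(t_min, 1.0, points_per_decade)
        Ts, C, C_err = heat_capacity_curve(model, grid, n_samples, thin,
                                           int(rng.integers(2**31)))
        integrand = C / Ts
        s_nats = np.trapezoid(integrand, Ts)
        tail = C[0]  # C(t)/t integrated over [0, t_min] if C stayed at C(t_min)
        err = np.sqrt(np.trapezoid((C_err / Ts) ** 2, Ts) * np.diff(Ts).mean()) + tail
    elif direction == "1toInf":
        betas = _geometric_grid(beta_min, 1.0, points_per_decade)
        Ts = 1.0 / betas[::-1]
        Ts_sorted, C, C_err = heat_capacity_curve(model, Ts, n_samples, thin,
                                                  int(rng.integers(2**31)))
        # back to ascending beta: C(T) = beta^2 Var(E) -> integrand beta*Var
        betas_sorted = 1.0 / Ts_sorted[::-1]
        var_e = (C * Ts_sorted**2)[::-1]
        integrand = betas_sorted * var_e
        integral = np.trapezoid(integrand, betas_sorted)
        # uniform-measure tail below beta_min
        uniform = (rng.random((4000, n)) < 0.5).astype(np.uint8)
        var_u = model.energies(uniform).var(ddof=1)
        tail = 0.5 * var_u * beta_min**2
        s_nats = n * LN2 - integral - tail
        err_var = (C_err * Ts_sorted**2)[::-1] * betas_sorted
        err = np.sqrt(np.sum((err_var[:-1] * np.diff(betas_sorted)) ** 2))
    else:
        raise ValueError("direction must be '0to1' or '1toInf'")
    return EntropyEstimate(
        float(s_nats / LN2), "heat_capacity", float(err / LN2),
        {"direction": direction, "n_grid": len(Ts), "n_samples": n_samples})


def partition_and_entropy_from_silence(model: MaxEntModel, p_silence: float = None,
                                       n_samples: int = 200_000, thin: int = 2,
                                       seed: int = 0):
    """log Z = -log P(silence) (canonical gauge: E_silence = 0), then
    S = <E> + log Z with <E> from a single T = 1 Monte Carlo run.

    ``p_silence`` may be supplied from data (the K-pairwise model reproduces
    it by construction); otherwise it is estimated from the same MC run.
    Returns (log_Z, EntropyEstimate).
    """
    e_silent = model.energy(np.zeros(model.n_neurons, dtype=np.uint8))
    if abs(e_silent) > 1e-9:
        raise ValueError(
            "silence route requires the canonical gauge (E_silence = 0); "
            "apply gauge_fix first")
    samples, energies = metropolis_sample(model, n_samples, thin=thin, seed=seed)
    source = "data" if p_silence is not None else "mc"
    if p_silence is None:
        p_silence = float((samples.sum(axis=1) == 0).mean())
    if not 0 < p_silence <= 1:
        raise ValueError("p_silence must lie in (0, 1]")
    log_z = -np.log(p_silence)
    mean_e = energies.mean()
    s_nats = mean_e + log_z
    # silence-count error + blocked error on <E>
    n_blocks = 20
    blocks = np.array_split(energies, n_blocks)
    e_err = np.std([b.mean() for b in blocks], ddof=1) / np.sqrt(n_blocks)
    if source == "mc":
        sil_err = np.sqrt(p_silence * (1 - p_silence) / n_samples) / p_silence
    else:
        sil_err = 0.0
    err = np.sqrt(e_err**2 + sil_err**2)
    est = EntropyEstimate(float(s_nats / LN2), "silence", float(err / LN2),
                          {"p_silence": p_silence, "source": source,
                           "mean_energy": float(mean_e)})
    return float(log_z), est


def entropy_from_density_of_states(dos: DensityOfStates):
    """Z = sum_E g(E) e^{-E}; S = <E> + log Z.  The density must be
    normalized (sum g = 2^N).  Returns (log_Z, EntropyEstimate)."""
    vis = dos.visited.astype(bool)
    log_g = dos.log_g[vis]
    e = dos.representative_energies()[vis]
    total = logsumexp(log_g)
    if abs(total - dos.n_neurons * LN2) > 1e-6:
        raise ValueError("density of states is not normalized; call .normalized()")
    log_terms = log_g - e
    log_z = float(logsumexp(log_terms))
    w = np.exp(log_terms - log_z)
    mean_e = float(w @ e)
    s_nats = mean_e + log_z
    est = EntropyEstimate(float(s_nats / LN2), "wang_landau", np.nan,
                          {"mean_energy": mean_e, "n_bins": int(vis.sum())})
    return log_z, est


def independent_entropy_bits(rates: np.ndarray) -> float:
    """sum_i H(p_i) in bits."""
    p = np.clip(np.asarray(rates, dtype=float), 1e-15, 1 - 1e-15)
    h = -(p * np.log2(p) + (1 - p) * np.log2(1 - p))
    return float(h.sum())


def multi_information(s_model: EntropyEstimate, stats: EmpiricalStats) -> float:
    """I_N = sum_i H(p_i) - S_model, in bits (non-negative up to estimator
    error)."""
    return independent_entropy_bits(stats.rates) - s_model.value_bits


def energy_distribution_report(model: MaxEntModel, raster, n_samples: int = 100_000,
                               seed: int = 0, energy_grid: np.ndarray = None):
    """Cumulative energy counts N_<(E) (strict) and N_>(E) (non-strict
    complement) over data words and over model samples, plus relative
    differences of the first two energy moments (model vs data)."""
    e_data = model.energies(raster.words())
    samples, e_model = metropolis_sample(model, n_samples, seed=seed)
    if energy_grid is None:
        lo = min(e_data.min(), e_model.min())
        hi = max(e_data.max(), e_model.max())
        energy_grid = np.linspace(lo, hi, 101)

    def _cum(e):
        below = np.searchsorted(np.sort(e), energy_grid, side="left")
        return below, e.size - below

    below_d, above_d = _cum(e_data)
    below_m, above_m = _cum(e_model)
    rel_mean = (e_model.mean() - e_data.mean()) / abs(e_data.mean())
    rel_std = (e_model.std(ddof=1) - e_data.std(ddof=1)) / e_data.std(ddof=1)
    return {
        "energy_grid": energy_grid,
        "data_below": below_d, "data_above": above_d,
        "model_below": below_m, "model_above": above_m,
        "tie_convention": "below is strict (<), above is non-strict (>=)",
        "relative_mean_energy_difference": float(rel_mean),
        "relative_std_energy_difference": float(rel_std),
    }
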