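"""Synthetic ground-truth models and rasters with the statistical structure
of dense retinal recordings: sparse firing (~3% per 20 ms bin), weak
widespread couplings of both signs, optional synchrony potential, and
optional repeat-locked temporal modulation; plus the dichotomized-Gaussian
control generator.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.stats import multivariate_normal, norm
from scipy.optimize import brentq

from . import _kernels
from .model import MaxEntModel
from .raster import SpikeRaster
from .sampling import metropolis_sample

__all__ = [
    "GeneratorSpec",
    "make_ground_truth_model",
    "generate_raster",
    "dichotomized_gaussian",
]


@dataclasses.dataclass
class GeneratorSpec:
    """Recipe for a ground-truth model and its sampled raster.

    Defaults mirror the recording geometry this pipeline targets: mean spike
    probability 0.031 per 20 ms bin, 297 repeats of 953 bins.  ``j_scale`` is
    the s.d. of the zero-mean symmetric coupling draw, ``j_density`` the
    fraction of pairs coupled; ``v_scale`` adds a smooth synchrony potential.
    ``modulation_*`` control sparse repeat-locked field transients.
    """

    n_neurons: int = 30
    mean_rate: float = 0.031
    rate_spread: float = 0.5  # s.d. of the logit-normal field jitter
    j_scale: float = 0.3
    j_density: float = 1.0
    v_scale: float = 0.0
    n_repeats: int = 297
    bins_per_repeat: int = 953
    dt: float = 0.02
    modulation_amplitude: float = 0.0
    modulation_n_bumps: int = 20
    modulation_width_bins: float = 2.5
    seed: int = 0


def make_ground_truth_model(spec: GeneratorSpec) -> MaxEntModel:
    """Draw a model: fields logit-centered on the target rate, couplings
    i.i.d. zero-mean normal (symmetric in sign, so about half of all coupled
    triplets are frustrated), optional smooth V(K).  Deterministic in
    ``spec.seed``."""
    if not 0 < spec.mean_rate < 1:
        raise ValueError("mean_rate must lie in (0, 1)")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_neurons
    h0 = np.log(spec.mean_rate / (1 - spec.mean_rate))
    h = h0 + spec.rate_spread * rng.standard_normal(n)

    J = np.zeros((n, n))
    if spec.j_scale > 0:
        iu = np.triu_indices(n, k=1)
        vals = spec.j_scale * rng.standard_normal(iu[0].size)
        if spec.j_density < 1.0:
            vals *= rng.random(iu[0].size) < spec.j_density
        J[iu] = vals
        J.T[iu] = vals

    V = np.zeros(n + 1)
    if spec.v_scale > 0:
        # smooth confining potential, zero at K = 0, favoring a heavy P(K) tail
        k = np.arange(n + 1, dtype=float)
        V = spec.v_scale * (np.sqrt(k) - 0.15 * k)
        V -= V[0]
        cls = "k_pairwise"
    elif spec.j_scale > 0:
        cls = "pairwise"
    else:
        cls = "independent"
    return MaxEntModel(cls, h, J if cls != "independent" else None,
                       V if cls == "k_pairwise" else None)


def _modulation_profile(spec: GeneratorSpec, rng) -> np.ndarray:
    """Sparse smooth field bumps shared across repeats (brief transients on a
    near-silent baseline)."""
    B = spec.bins_per_repeat
    offsets = np.zeros(B)
    centers = rng.integers(0, B, size=spec.modulation_n_bumps)
    amps = spec.modulation_amplitude * (0.5 + rng.random(spec.modulation_n_bumps))
    t = np.arange(B)
    for c, a in zip(centers, amps):
        offsets += a * np.exp(-0.5 * ((t - c) / spec.modulation_width_bins) ** 2)
    return offsets - offsets.mean()


def generate_raster(model: MaxEntModel, spec: GeneratorSpec, seed: int = None) -> SpikeRaster:
    """Metropolis-sample a raster of R x B words from the model.

    With ``modulation_amplitude > 0`` a per-bin scalar field offset, shared
    across repeats, is added while sampling, producing repeat-locked temporal
    structure (and within-repeat temporal correlation, as in real data).
    """
    if seed is None:
        seed = spec.seed + 1
    rng = np.random.default_rng(seed)
    R, B = spec.n_repeats, spec.bins_per_repeat
    if spec.modulation_amplitude > 0:
        offsets = _modulation_profile(spec, rng)
        values = _kernels.metropolis_modulated(
            model.h, model.J, model.V, offsets, R, 2,
            50 * model.n_neurons, int(rng.integers(2**31)))
        return SpikeRaster(values.T, R, B, spec.dt)
    samples, _ = metropolis_sample(model, R * B, thin=2,
                                   seed=int(rng.integers(2**31)))
    return SpikeRaster(samples.T, R, B, spec.dt)


def _nearest_pd(cov: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    vals, vecs = np.linalg.eigh(cov)
    if vals.min() >= floor:
        return cov
    vals = np.clip(vals, floor, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d)


def _orthant(gi: float, gj: float, lam: float) -> float:
    """P(X > gi, Y > gj) for standard bivariate normal with correlation lam.

    At |lam| -> 1 the distribution degenerates; the comonotone and
    antithetic closed forms are used there.
    """
    if lam >= 0.9999:
        return float(norm.sf(max(gi, gj)))
    if lam <= -0.9999:
        return float(max(0.0, norm.sf(gi) - norm.cdf(gj)))
    return float(multivariate_normal(mean=[0, 0], cov=[[1, lam], [lam, 1]],
                                     allow_singular=True).cdf([-gi, -gj]))


def dichotomized_gaussian(rates: np.ndarray, moments: np.ndarray, T: int,
                          seed: int = 0, dt: float = 0.02, tol: float = 1e-8):
    """Binary raster from a thresholded latent Gaussian matched to target
    rates and pairwise moments.

    Thresholds solve Phi(gamma_i) = 1 - p_i; each latent correlation is
    root-found so the bivariate orthant probability matches the target second
    moment.  Pairs with no feasible latent correlation are flagged; a
    non-positive-definite latent matrix is repaired by eigenvalue clipping
    (reported).

    Returns (SpikeRaster, info dict with thresholds, latent matrix, flags).
    """
    p = np.asarray(rates, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("target rates must lie strictly inside (0, 1)")
    n = p.size
    gamma = norm.isf(p)  # P(X > gamma_i) = p_i

    lam = np.eye(n)
    infeasible = []
    for i in range(n):
        for j in range(i + 1, n):
            target = moments[i, j]
            lo_m = max(0.0, p[i] + p[j] - 1.0)  # antithetic limit, lam -> -1
            hi_m = min(p[i], p[j])              # comonotone limit, lam -> +1
            if not (lo_m - tol <= target <= hi_m + tol):
                infeasible.append((i, j))
                continue
            if abs(target - p[i] * p[j]) < tol:
                continue  # lam stays 0
            bound = 0.9998
            f_lo = _orthant(gamma[i], gamma[j], -bound) - target
            f_hi = _orthant(gamma[i], gamma[j], bound) - target
            if f_lo >= 0.0:
                lam[i, j] = lam[j, i] = -bound
                continue
            if f_hi <= 0.0:
                lam[i, j] = lam[j, i] = bound
                continue

            def f(x, i=i, j=j, target=target):
                return _orthant(gamma[i], gamma[j], x) - target

            lam[i, j] = lam[j, i] = brentq(f, -bound, bound, xtol=1e-10)

    lam_pd = _nearest_pd(lam)
    repaired = not np.allclose(lam, lam_pd)
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(lam_pd)
    z = rng.standard_normal((T, n)) @ L.T
    values = (z > gamma).astype(np.uint8).T
    raster = SpikeRaster(values, 1, T, dt)
    info = {
        "thresholds": gamma,
        "latent_corr": lam_pd,
        "infeasible_pairs": infeasible,
        "pd_repaired": repaired,
    }
    return raster, info
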