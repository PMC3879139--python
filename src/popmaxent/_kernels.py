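"""Numba kernels for Monte Carlo sampling, Wang-Landau, and greedy descent.

All kernels operate on the canonical {0,1} spin coding with energy

    E(sigma) = - sum_i h_i sigma_i - 1/2 sum_{i != j} J_ij sigma_i sigma_j + V(K),

K = sum_i sigma_i.  J must be symmetric with zero diagonal; V has length N+1.
Kernels are deterministic given the integer seed passed in.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def energy_of(h, J, V, sigma):
    """Energy of a single {0,1} configuration."""
    n = sigma.shape[0]
    e = 0.0
    k = 0
    for i in range(n):
        if sigma[i] != 0:
            k += 1
            e -= h[i]
            for j in range(i + 1, n):
                if sigma[j] != 0:
                    e -= J[i, j]
    return e + V[k]


@njit(cache=True)
def local_field(h, J, sigma, i):
    """h_i + sum_j J_ij sigma_j (J_ii = 0, so sigma_i never contributes)."""
    f = h[i]
    n = sigma.shape[0]
    for j in range(n):
        if sigma[j] != 0:
            f += J[i, j]
    return f


@njit(cache=True)
def delta_energy(h, J, V, sigma, k, i):
    """Energy change from flipping spin i given current spike count k."""
    f = local_field(h, J, sigma, i)
    if sigma[i] == 0:
        return -f + V[k + 1] - V[k]
    return f + V[k - 1] - V[k]


@njit(cache=True)
def metropolis_run(h, J, V, beta, sigma, n_record, thin_flips, burn_flips, seed):
    """Single-spin-flip Metropolis chain at inverse temperature beta.

    Maintains the local fields f_i = h_i + sum_j J_ij sigma_j incrementally,
    so a rejected proposal costs O(1) and an accepted flip O(N).

    Mutates `sigma` in place (it ends at the final state) and returns
    (samples uint8 [n_record, N], energies float64 [n_record]).
    """
    np.random.seed(seed)
    n = sigma.shape[0]
    e = energy_of(h, J, V, sigma)
    k = 0
    fields = h.copy()
    for j in range(n):
        if sigma[j] != 0:
            k += 1
            for i in range(n):
                fields[i] += J[i, j]
    samples = np.empty((n_record, n), dtype=np.uint8)
    energies = np.empty(n_record, dtype=np.float64)

    total = burn_flips + n_record * thin_flips
    t_out = 0
    next_record = burn_flips + thin_flips
    for step in range(1, total + 1):
        i = np.random.randint(0, n)
        if sigma[i] == 0:
            de = -fields[i] + V[k + 1] - V[k]
        else:
            de = fields[i] + V[k - 1] - V[k]
        accept = de <= 0.0
        if not accept:
            arg = -beta * de
            if arg > -35.0 and np.random.random() < np.exp(arg):
                accept = True
        if accept:
            if sigma[i] == 0:
                sigma[i] = 1
                k += 1
                for j in range(n):
                    fields[j] += J[j, i]
            else:
                sigma[i] = 0
                k -= 1
                for j in range(n):
                    fields[j] -= J[j, i]
            e += de
        if step == next_record:
            samples[t_out, :] = sigma
            energies[t_out] = e
            t_out += 1
            next_record += thin_flips
    return samples, energies


@njit(cache=True)
def metropolis_modulated(h, J, V, offsets, n_repeats, n_sweeps_per_bin, burn_flips, seed):
    """Sample one word per (repeat, bin) with a per-bin scalar field offset.

    The chain runs continuously within each repeat: for bin b the fields are
    h_i + offsets[b]; `n_sweeps_per_bin` full sweeps are performed before the
    state is recorded.  Repeats restart from the all-silent word after a short
    burn-in, giving repeat-locked temporal structure plus within-repeat
    temporal correlation.
    """
    np.random.seed(seed)
    n = h.shape[0]
    n_bins = offsets.shape[0]
    out = np.empty((n_repeats * n_bins, n), dtype=np.uint8)
    hmod = np.empty(n, dtype=np.float64)
    sigma = np.zeros(n, dtype=np.uint8)
    for r in range(n_repeats):
        for i in range(n):
            sigma[i] = 0
        k = 0
        for i in range(n):
            hmod[i] = h[i] + offsets[0]
        for _ in range(burn_flips):
            i = np.random.randint(0, n)
            de = delta_energy(hmod, J, V, sigma, k, i)
            if de <= 0.0 or np.random.random() < np.exp(-de):
                if sigma[i] == 0:
                    sigma[i] = 1
                    k += 1
                else:
                    sigma[i] = 0
                    k -= 1
        for b in range(n_bins):
            for i in range(n):
                hmod[i] = h[i] + offsets[b]
            for _ in range(n_sweeps_per_bin * n):
                i = np.random.randint(0, n)
                de = delta_energy(hmod, J, V, sigma, k, i)
                if de <= 0.0 or np.random.random() < np.exp(-de):
                    if sigma[i] == 0:
                        sigma[i] = 1
                        k += 1
                    else:
                        sigma[i] = 0
                        k -= 1
            out[r * n_bins + b, :] = sigma
    return out


@njit(cache=True)
def descend(h, J, V, sigma):
    """Greedy descent: sweep neurons in ascending index, keep strictly
    energy-lowering single flips, repeat until a full sweep changes nothing.

    Mutates sigma in place; returns its final energy.
    """
    n = sigma.shape[0]
    k = 0
    for i in range(n):
        if sigma[i] != 0:
            k += 1
    changed = True
    while changed:
        changed = False
        for i in range(n):
            de = delta_energy(h, J, V, sigma, k, i)
            if de < 0.0:
                if sigma[i] == 0:
                    sigma[i] = 1
                    k += 1
                else:
                    sigma[i] = 0
                    k -= 1
                changed = True
    return energy_of(h, J, V, sigma)


@njit(cache=True)
def descend_many(h, J, V, words):
    """Descend from every row of `words`; returns (minima uint8, energies)."""
    m, n = words.shape
    out = np.empty((m, n), dtype=np.uint8)
    energies = np.empty(m, dtype=np.float64)
    sigma = np.empty(n, dtype=np.uint8)
    for t in range(m):
        for i in range(n):
            sigma[i] = words[t, i]
        energies[t] = descend(h, J, V, sigma)
        out[t, :] = sigma
    return out, energies


@njit(cache=True)
def is_metastable(h, J, V, sigma):
    n = sigma.shape[0]
    k = 0
    for i in range(n):
        if sigma[i] != 0:
            k += 1
    for i in range(n):
        if delta_energy(h, J, V, sigma, k, i) < 0.0:
            return False
    return True


@njit(cache=True)
def wang_landau_run(h, J, V, e_min, e_max, n_bins, flatness, ln_f_final,
                    check_every, max_steps, sigma, seed):
    """Flat-histogram Wang-Landau estimate of log g(E) on uniform energy bins.

    Proposals landing outside [e_min, e_max] are rejected (the current bin is
    still revisited, per the standard algorithm).  Flatness is judged over
    bins visited at least once since the last refinement; ln f halves on each
    flat histogram until it drops below ln_f_final.

    Returns (log_g, visited_mask, final_ln_f, steps_used).
    """
    np.random.seed(seed)
    n = sigma.shape[0]
    width = (e_max - e_min) / n_bins
    log_g = np.zeros(n_bins, dtype=np.float64)
    hist = np.zeros(n_bins, dtype=np.int64)
    ever = np.zeros(n_bins, dtype=np.uint8)
    e_sum = np.zeros(n_bins, dtype=np.float64)
    e_cnt = np.zeros(n_bins, dtype=np.int64)

    e = energy_of(h, J, V, sigma)
    k = 0
    for i in range(n):
        if sigma[i] != 0:
            k += 1
    # walk into range if the start is outside it
    guard = 0
    while (e < e_min or e >= e_max) and guard < 100000:
        i = np.random.randint(0, n)
        de = delta_energy(h, J, V, sigma, k, i)
        target = 0.5 * (e_min + e_max)
        if abs(e + de - target) < abs(e - target):
            if sigma[i] == 0:
                sigma[i] = 1
                k += 1
            else:
                sigma[i] = 0
                k -= 1
            e += de
        guard += 1

    cur = int((e - e_min) / width)
    if cur >= n_bins:
        cur = n_bins - 1
    fields = h.copy()
    for j in range(n):
        if sigma[j] != 0:
            for i in range(n):
                fields[i] += J[i, j]
    ln_f = 1.0
    steps = 0
    while ln_f >= ln_f_final and steps < max_steps:
        for _ in range(check_every):
            i = np.random.randint(0, n)
            if sigma[i] == 0:
                de = -fields[i] + V[k + 1] - V[k]
            else:
                de = fields[i] + V[k - 1] - V[k]
            e_new = e + de
            accept = False
            if e_min <= e_new < e_max:
                nb = int((e_new - e_min) / width)
                if nb >= n_bins:
                    nb = n_bins - 1
                if log_g[cur] - log_g[nb] >= 0.0:
                    accept = True
                elif np.random.random() < np.exp(log_g[cur] - log_g[nb]):
                    accept = True
                if accept:
                    if sigma[i] == 0:
                        sigma[i] = 1
                        k += 1
                        for j in range(n):
                            fields[j] += J[j, i]
                    else:
                        sigma[i] = 0
                        k -= 1
                        for j in range(n):
                            fields[j] -= J[j, i]
                    e = e_new
                    cur = nb
            log_g[cur] += ln_f
            hist[cur] += 1
            ever[cur] = 1
            e_sum[cur] += e
            e_cnt[cur] += 1
            steps += 1
        # flatness over bins visited during this refinement stage
        n_vis = 0
        total = 0
        minh = np.int64(1) << 60
        for b in range(n_bins):
            if hist[b] > 0:
                n_vis += 1
                total += hist[b]
                if hist[b] < minh:
                    minh = hist[b]
        if n_vis > 0 and minh >= flatness * (total / n_vis):
            ln_f *= 0.5
            for b in range(n_bins):
                hist[b] = 0
    e_mean = np.empty(n_bins, dtype=np.float64)
    for b in range(n_bins):
        e_mean[b] = e_sum[b] / e_cnt[b] if e_cnt[b] > 0 else 0.0
    return log_g, ever, ln_f, steps, e_mean
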