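"""Model classes, Hamiltonians, effective fields, gauge fixing.

Spins are {0,1} throughout (0 = silence).  Canonical gauge: the all-silent
word has zero energy, i.e. V(0) = 0.  Energy of a word sigma with K spikes:

    E(sigma) = - sum_i h_i sigma_i - 1/2 sum_{i != j} J_ij sigma_i sigma_j + V(K)
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from . import _kernels

__all__ = [
    "MaxEntModel",
    "conditional_spike_probability",
    "gauge_fix",
    "frustration_fraction",
    "read_model",
    "write_model",
]

MODEL_CLASSES = ("independent", "pairwise", "k_pairwise")


@dataclasses.dataclass
class MaxEntModel:
    """Parameters of an independent / pairwise / K-pairwise model.

    ``h`` is the length-N field vector, ``J`` the symmetric zero-diagonal
    coupling matrix (all-zero for independent models), ``V`` the length-(N+1)
    synchrony potential (all-zero unless ``model_class == "k_pairwise"``).
    ``log_z`` caches log Z when known.
    """

    model_class: str
    h: np.ndarray
    J: np.ndarray = None  # type: ignore[assignment]
    V: np.ndarray = None  # type: ignore[assignment]
    log_z: float = None  # type: ignore[assignment]
    gauge: str = "canonical"

    def __post_init__(self):
        if self.model_class not in MODEL_CLASSES:
            raise ValueError(f"unknown model class {self.model_class!r}")
        h = np.asarray(self.h, dtype=np.float64).copy()
        n = h.shape[0]
        J = np.zeros((n, n)) if self.J is None else np.asarray(self.J, dtype=np.float64).copy()
        V = np.zeros(n + 1) if self.V is None else np.asarray(self.V, dtype=np.float64).copy()
        if J.shape != (n, n):
            raise ValueError("J must be N x N")
        if not np.allclose(J, J.T):
            raise ValueError("J must be symmetric")
        if not np.allclose(np.diag(J), 0.0):
            raise ValueError("J must have zero diagonal")
        if V.shape != (n + 1,):
            raise ValueError("V must have length N + 1")
        if self.model_class == "independent" and (J.any() or V.any()):
            raise ValueError("independent model must have J = 0 and V = 0")
        if self.model_class == "pairwise" and V.any():
            raise ValueError("pairwise model must have V = 0")
        np.fill_diagonal(J, 0.0)
        self.h, self.J, self.V = h, J, V

    @property
    def n_neurons(self) -> int:
        return self.h.shape[0]

    # -- energies ----------------------------------------------------------

    def energy(self, pattern) -> float:
        """Energy of one N-bit word (0 for the all-silent word in canonical
        gauge)."""
        sigma = np.ascontiguousarray(pattern, dtype=np.uint8)
        if sigma.shape != (self.n_neurons,):
            raise ValueError("pattern length must equal N")
        return float(_kernels.energy_of(self.h, self.J, self.V, sigma))

    def energies(self, words: np.ndarray) -> np.ndarray:
        """Vectorized energies of a (n_words, N) array of {0,1} words."""
        x = np.asarray(words, dtype=np.float64)
        e = -(x @ self.h) - 0.5 * np.einsum("ti,ij,tj->t", x, self.J, x)
        k = np.rint(x.sum(axis=1)).astype(int)
        return e + self.V[k]

    def effective_field(self, pattern, neuron: int) -> float:
        """h_eff,i = E(sigma with sigma_i = 0) - E(sigma with sigma_i = 1).

        Defined via the energy difference, which is exact for every model
        class; for the K-pairwise model it includes the synchrony-potential
        increment from the other neurons' spike count.
        """
        if not 0 <= neuron < self.n_neurons:
            raise IndexError("neuron index out of range")
        sigma = np.asarray(pattern, dtype=np.uint8).copy()
        k_rest = int(sigma.sum()) - int(sigma[neuron])
        f = self.h[neuron] + float(self.J[neuron] @ sigma)  # J_ii = 0
        return float(f - (self.V[k_rest + 1] - self.V[k_rest]))

    def effective_fields(self, words: np.ndarray, neuron: int) -> np.ndarray:
        """Vectorized effective field of one neuron over many words."""
        x = np.asarray(words, dtype=np.float64)
        k_rest = np.rint(x.sum(axis=1) - x[:, neuron]).astype(int)
        f = self.h[neuron] + x @ self.J[neuron]
        return f - (self.V[k_rest + 1] - self.V[k_rest])

    def copy(self) -> "MaxEntModel":
        return MaxEntModel(self.model_class, self.h, self.J, self.V,
                           self.log_z, self.gauge)


def conditional_spike_probability(h_eff):
    """P(spike | rest of network) = logistic(h_eff)."""
    h_eff = np.asarray(h_eff, dtype=np.float64)
    out = np.empty_like(h_eff)
    pos = h_eff >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-h_eff[pos]))
    ex = np.exp(h_eff[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def gauge_fix(model: MaxEntModel) -> MaxEntModel:
    """Remove the linear + quadratic component of V(K) by least squares over
    K = 0..N, absorbing it into h and J.

    Because sigma^2 = sigma for {0,1} spins, b*K + c*K^2 equals
    (b + c) * sum_i sigma_i + c * sum_{i != j} sigma_i sigma_j, so subtracting
    it from V while sending h_i -> h_i - (b + c) and J_ij -> J_ij - 2c leaves
    every pattern probability unchanged.  The remaining constant is pinned so
    V(0) = 0 (canonical gauge, absorbed by log Z).
    """
    if model.model_class != "k_pairwise":
        raise ValueError("gauge_fix applies to K-pairwise models only")
    n = model.n_neurons
    k = np.arange(n + 1, dtype=np.float64)
    A = np.stack([np.ones_like(k), k, k * k], axis=1)
    coef, *_ = np.linalg.lstsq(A, model.V, rcond=None)
    a, b, c = coef
    V = model.V - (a + b * k + c * k * k)
    h = model.h - (b + c)
    J = model.J - 2.0 * c
    np.fill_diagonal(J, 0.0)
    V = V - V[0]
    return MaxEntModel("k_pairwise", h, J, V, None, "canonical")


def frustration_fraction(model: MaxEntModel) -> float:
    """Fraction of triplets with J_ij * J_jk * J_ki < 0, among triplets whose
    three couplings are all nonzero."""
    if model.model_class == "independent":
        raise ValueError("frustration requires couplings")
    n = model.n_neurons
    if n < 3:
        raise ValueError("need at least 3 neurons")
    J = model.J
    n_frust = 0
    n_valid = 0
    for i in range(n):
        for j in range(i + 1, n):
            if J[i, j] == 0:
                continue
            for k in range(j + 1, n):
                if J[j, k] == 0 or J[i, k] == 0:
                    continue
                n_valid += 1
                if J[i, j] * J[j, k] * J[i, k] < 0:
                    n_frust += 1
    if n_valid == 0:
        raise ValueError("no fully coupled triplets")
    return n_frust / n_valid


# ---------------------------------------------------------------------------
# model files: key-value text with h / upper-triangle J / V blocks


def write_model(model: MaxEntModel, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"model_class\t{model.model_class}\n")
        fh.write(f"n_neurons\t{model.n_neurons}\n")
        fh.write(f"gauge\t{model.gauge}\n")
        if model.log_z is not None:
            fh.write(f"log_z\t{float(model.log_z)!r}\n")
        for i, hi in enumerate(model.h):
            fh.write(f"h\t{i}\t{float(hi)!r}\n")
        for i in range(model.n_neurons):
            for j in range(i + 1, model.n_neurons):
                if model.J[i, j] != 0.0:
                    fh.write(f"J\t{i}\t{j}\t{float(model.J[i, j])!r}\n")
        if model.model_class == "k_pairwise":
            for k, vk in enumerate(model.V):
                fh.write(f"V\t{k}\t{float(vk)!r}\n")


def read_model(path) -> MaxEntModel:
    kv = {"log_z": None, "gauge": "canonical"}
    hs, js, vs = {}, [], {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "h":
                hs[int(parts[1])] = float(parts[2])
            elif parts[0] == "J":
                js.append((int(parts[1]), int(parts[2]), float(parts[3])))
            elif parts[0] == "V":
                vs[int(parts[1])] = float(parts[2])
            elif parts[0] in ("model_class", "gauge"):
                kv[parts[0]] = parts[1]
            elif parts[0] == "log_z":
                kv["log_z"] = float(parts[1])
            elif parts[0] == "n_neurons":
                kv["n_neurons"] = int(parts[1])
    n = kv["n_neurons"]
    h = np.array([hs[i] for i in range(n)])
    J = np.zeros((n, n))
    for i, j, v in js:
        J[i, j] = J[j, i] = v
    V = np.zeros(n + 1)
    for k, v in vs.items():
        V[k] = v
    return MaxEntModel(kv["model_class"], h, J, V, kv["log_z"], kv["gauge"])
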