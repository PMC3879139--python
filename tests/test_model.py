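import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import popmaxent as pm
from popmaxent.sampling import _bit_words


def _kpair(h, J, V):
    return pm.MaxEntModel("k_pairwise", h, J, V)


class TestEnergy:
    def test_silent_word_is_zero(self, kpair_gen):
        assert kpair_gen.energy(np.zeros(kpair_gen.n_neurons, dtype=np.uint8)) == 0.0

    def test_two_neuron_pairwise(self):
        J = np.array([[0.0, 0.5], [0.5, 0.0]])
        m = pm.MaxEntModel("pairwise", np.array([1.0, 0.0]), J)
        assert m.energy([1, 1]) == pytest.approx(-1.5)

    def test_two_neuron_with_potential(self):
        J = np.array([[0.0, 0.5], [0.5, 0.0]])
        V = np.array([0.0, 0.0, 0.3])
        m = _kpair(np.array([1.0, 0.0]), J, V)
        assert m.energy([1, 1]) == pytest.approx(-1.2)

    def test_length_mismatch(self, kpair_gen):
        with pytest.raises(ValueError):
            kpair_gen.energy([0, 1])

    def test_vectorized_matches_scalar(self, kpair_gen):
        rng = np.random.default_rng(0)
        words = (rng.random((20, kpair_gen.n_neurons)) < 0.3).astype(np.uint8)
        vec = kpair_gen.energies(words)
        scal = [kpair_gen.energy(w) for w in words]
        np.testing.assert_allclose(vec, scal, atol=1e-12)

    def test_relabeling_invariance(self, kpair_gen):
        rng = np.random.default_rng(1)
        perm = rng.permutation(kpair_gen.n_neurons)
        m2 = pm.MaxEntModel("k_pairwise", kpair_gen.h[perm],
                            kpair_gen.J[np.ix_(perm, perm)], kpair_gen.V)
        word = (rng.random(kpair_gen.n_neurons) < 0.4).astype(np.uint8)
        assert m2.energy(word[perm]) == pytest.approx(kpair_gen.energy(word),
                                                      abs=1e-12)


class TestEffectiveField:
    def test_independent_is_field(self, indep_model):
        model, _ = indep_model
        rng = np.random.default_rng(2)
        for _ in range(5):
            w = (rng.random(8) < 0.5).astype(np.uint8)
            i = rng.integers(8)
            assert model.effective_field(w, i) == pytest.approx(model.h[i])

    def test_pairwise_example(self):
        J = np.array([[0.0, 0.5], [0.5, 0.0]])
        m = pm.MaxEntModel("pairwise", np.array([1.0, 0.0]), J)
        assert m.effective_field([1, 0], 1) == pytest.approx(0.5)

    def test_energy_difference_oracle(self, kpair_gen):
        rng = np.random.default_rng(3)
        n = kpair_gen.n_neurons
        for _ in range(20):
            w = (rng.random(n) < 0.3).astype(np.uint8)
            i = int(rng.integers(n))
            w0, w1 = w.copy(), w.copy()
            w0[i], w1[i] = 0, 1
            oracle = kpair_gen.energy(w0) - kpair_gen.energy(w1)
            assert kpair_gen.effective_field(w, i) == pytest.approx(oracle, abs=1e-10)

    def test_index_out_of_range(self, kpair_gen):
        with pytest.raises(IndexError):
            kpair_gen.effective_field(np.zeros(kpair_gen.n_neurons, dtype=np.uint8), 99)


class TestConditionalProbability:
    def test_zero_field(self):
        assert pm.conditional_spike_probability(0.0) == 0.5

    def test_limits(self):
        assert pm.conditional_spike_probability(-800.0) == 0.0
        assert pm.conditional_spike_probability(800.0) == 1.0

    def test_matches_enumeration_conditional(self, kpair_gen):
        # oracle: P(sigma_i = 1 | rest) from the full enumerated distribution
        n = kpair_gen.n_neurons
        dist = pm.enumerate_exact(kpair_gen)
        probs = dist.probs(kpair_gen)
        words = _bit_words(0, 2**n, n)
        rng = np.random.default_rng(4)
        for _ in range(10):
            w = (rng.random(n) < 0.3).astype(np.uint8)
            i = int(rng.integers(n))
            rest = np.delete(np.arange(n), i)
            match = (words[:, rest] == w[rest]).all(axis=1)
            p1 = probs[match & (words[:, i] == 1)].sum()
            p0 = probs[match & (words[:, i] == 0)].sum()
            oracle = p1 / (p0 + p1)
            pred = pm.conditional_spike_probability(kpair_gen.effective_field(w, i))
            assert pred == pytest.approx(oracle, abs=1e-10)


class TestGaugeFix:
    def test_pure_quadratic_potential_absorbed(self):
        n = 5
        b, c = 0.7, -0.2
        k = np.arange(n + 1, dtype=float)
        m = _kpair(np.zeros(n), np.zeros((n, n)), b * k + c * k * k)
        fixed = pm.gauge_fix(m)
        np.testing.assert_allclose(fixed.V, 0.0, atol=1e-12)
        np.testing.assert_allclose(fixed.h, -(b + c), atol=1e-12)
        iu = np.triu_indices(n, k=1)
        np.testing.assert_allclose(fixed.J[iu], -2 * c, atol=1e-12)

    def test_probabilities_unchanged(self):
        rng = np.random.default_rng(5)
        n = 7
        J = rng.normal(0, 0.3, (n, n))
        J = np.triu(J, 1)
        J = J + J.T
        m = _kpair(rng.normal(-2, 1, n), J, rng.normal(0, 1, n + 1) - 0)
        m.V[0] = 0.0
        fixed = pm.gauge_fix(m)
        d0 = pm.enumerate_exact(m)
        d1 = pm.enumerate_exact(fixed)
        lp0 = d0.log_probs(m)
        lp1 = d1.log_probs(fixed)
        assert np.abs(lp0 - lp1).max() < 1e-12

    def test_v0_pinned(self, kpair_gen):
        fixed = pm.gauge_fix(kpair_gen)
        assert fixed.V[0] == 0.0

    def test_rejects_other_classes(self, indep_model):
        with pytest.raises(ValueError):
            pm.gauge_fix(indep_model[0])


class TestFrustration:
    def test_all_positive_unfrustrated(self):
        n = 4
        J = np.full((n, n), 0.5)
        np.fill_diagonal(J, 0.0)
        m = pm.MaxEntModel("pairwise", np.zeros(n), J)
        assert pm.frustration_fraction(m) == 0.0

    def test_symmetric_signs_give_half(self):
        # oracle: of the 8 sign assignments of a triplet, those with an odd
        # number of negative couplings (4 of 8) are frustrated
        signs = [(a, b, c) for a in (-1, 1) for b in (-1, 1) for c in (-1, 1)]
        frustrated = sum(1 for s in signs if s[0] * s[1] * s[2] < 0)
        assert frustrated / len(signs) == 0.5

        rng = np.random.default_rng(6)
        n = 16
        J = rng.choice([-0.3, 0.3], size=(n, n))
        J = np.triu(J, 1)
        J = J + J.T
        m = pm.MaxEntModel("pairwise", np.zeros(n), J)
        n_triplets = n * (n - 1) * (n - 2) / 6
        se = np.sqrt(0.25 / n_triplets)
        assert pm.frustration_fraction(m) == pytest.approx(0.5, abs=6 * se)

    def test_too_small(self):
        J = np.array([[0.0, 1.0], [1.0, 0.0]])
        m = pm.MaxEntModel("pairwise", np.zeros(2), J)
        with pytest.raises(ValueError):
            pm.frustration_fraction(m)


class TestModelIO:
    def test_round_trip(self, kpair_gen, tmp_path):
        path = tmp_path / "model.txt"
        pm.write_model(kpair_gen, path)
        back = pm.read_model(path)
        np.testing.assert_allclose(back.h, kpair_gen.h)
        np.testing.assert_allclose(back.J, kpair_gen.J)
        np.testing.assert_allclose(back.V, kpair_gen.V)
        assert back.model_class == kpair_gen.model_class


class TestValidation:
    def test_asymmetric_J_rejected(self):
        J = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError):
            pm.MaxEntModel("pairwise", np.zeros(2), J)

    def test_independent_with_couplings_rejected(self):
        J = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            pm.MaxEntModel("independent", np.zeros(2), J)


@settings(max_examples=20, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_gauge_invariance_property(seed):
    rng = np.random.default_rng(seed)
    n = 5
    J = np.triu(rng.normal(0, 0.5, (n, n)), 1)
    J = J + J.T
    V = rng.normal(0, 1, n + 1)
    V[0] = 0.0
    m = pm.MaxEntModel("k_pairwise", rng.normal(-1, 1, n), J, V)
    fixed = pm.gauge_fix(m)
    lp0 = pm.enumerate_exact(m).log_probs(m)
    lp1 = pm.enumerate_exact(fixed).log_probs(fixed)
    assert np.abs(lp0 - lp1).max() < 1e-12
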