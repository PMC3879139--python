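import itertools

import numpy as np
import pytest

import popmaxent as pm


def _descent_oracle(model, word):
    """Pure-python reimplementation of the fixed-order greedy descent."""
    sigma = np.array(word, dtype=np.uint8)
    changed = True
    while changed:
        changed = False
        for i in range(len(sigma)):
            flipped = sigma.copy()
            flipped[i] ^= 1
            if model.energy(flipped) < model.energy(sigma):
                sigma = flipped
                changed = True
    return sigma


def _two_cluster_model():
    """Two ferromagnetic clusters of 3 neurons each; silence also stable."""
    n = 6
    J = np.zeros((n, n))
    for a, b in itertools.combinations(range(3), 2):
        J[a, b] = J[b, a] = 3.0
        J[a + 3, b + 3] = J[b + 3, a + 3] = 3.0
    return pm.MaxEntModel("pairwise", np.full(n, -2.0), J)


class TestDescent:
    def test_all_negative_fields_descend_to_silence(self):
        m = pm.MaxEntModel("independent", np.full(5, -1.0))
        rng = np.random.default_rng(0)
        for _ in range(10):
            w = (rng.random(5) < 0.5).astype(np.uint8)
            ms, e = pm.descend_to_metastable(m, w)
            assert ms.sum() == 0
            assert e == 0.0

    def test_output_locally_stable(self, kpair_gen):
        rng = np.random.default_rng(1)
        n = kpair_gen.n_neurons
        for _ in range(15):
            w = (rng.random(n) < 0.4).astype(np.uint8)
            ms, e = pm.descend_to_metastable(kpair_gen, w)
            for i in range(n):
                flipped = ms.copy()
                flipped[i] ^= 1
                assert kpair_gen.energy(flipped) >= e

    def test_matches_brute_force_on_two_neuron_ferromagnet(self):
        J = np.array([[0.0, 3.0], [3.0, 0.0]])
        m = pm.MaxEntModel("pairwise", np.array([-1.0, -1.0]), J)
        for word in itertools.product([0, 1], repeat=2):
            ms, _ = pm.descend_to_metastable(m, np.array(word, dtype=np.uint8))
            np.testing.assert_array_equal(ms, _descent_oracle(m, word))

    def test_matches_oracle_on_random_models(self, kpair_gen):
        rng = np.random.default_rng(2)
        n = kpair_gen.n_neurons
        for _ in range(8):
            w = (rng.random(n) < 0.5).astype(np.uint8)
            ms, _ = pm.descend_to_metastable(kpair_gen, w)
            np.testing.assert_array_equal(ms, _descent_oracle(kpair_gen, w))

    def test_deterministic(self, kpair_gen):
        w = np.ones(kpair_gen.n_neurons, dtype=np.uint8)
        a, _ = pm.descend_to_metastable(kpair_gen, w)
        b, _ = pm.descend_to_metastable(kpair_gen, w)
        np.testing.assert_array_equal(a, b)


class TestCensus:
    def test_sizes_partition_data_words(self, kpair_gen):
        spec = pm.GeneratorSpec(n_neurons=kpair_gen.n_neurons, n_repeats=10,
                                bins_per_repeat=200, seed=50)
        raster = pm.generate_raster(kpair_gen, spec)
        summary = pm.census_basins(kpair_gen, raster)
        assert summary.sizes.sum() == raster.n_bins
        assert summary.assignment.shape == (raster.n_bins,)

    def test_weakly_coupled_sparse_gives_single_silent_basin(self):
        spec = pm.GeneratorSpec(n_neurons=8, mean_rate=0.03, j_scale=0.05,
                                n_repeats=5, bins_per_repeat=200, seed=51)
        model = pm.make_ground_truth_model(spec)
        raster = pm.generate_raster(model, spec)
        summary = pm.census_basins(model, raster)
        assert summary.n_basins == 1
        assert summary.silent_basin() == 0

    def test_every_metastable_state_passes_stability_audit(self, kpair_gen):
        spec = pm.GeneratorSpec(n_neurons=kpair_gen.n_neurons, n_repeats=5,
                                bins_per_repeat=200, seed=52)
        raster = pm.generate_raster(kpair_gen, spec)
        summary = pm.census_basins(kpair_gen, raster)
        for ms in summary.metastable:
            e = kpair_gen.energy(ms)
            for i in range(kpair_gen.n_neurons):
                flipped = ms.copy()
                flipped[i] ^= 1
                assert kpair_gen.energy(flipped) >= e

    def test_order_invariance(self, kpair_gen):
        spec = pm.GeneratorSpec(n_neurons=kpair_gen.n_neurons, n_repeats=4,
                                bins_per_repeat=100, seed=53)
        raster = pm.generate_raster(kpair_gen, spec)
        rev = pm.SpikeRaster(raster.values[:, ::-1], 1, raster.n_bins, raster.dt)
        s1 = pm.census_basins(kpair_gen, raster)
        s2 = pm.census_basins(kpair_gen, rev)
        np.testing.assert_array_equal(np.sort(s1.sizes), np.sort(s2.sizes))


class TestOverlaps:
    def test_identical_words(self):
        w = np.array([[1, 0, 1], [1, 0, 1]], dtype=np.uint8)
        q = pm.overlaps(w)
        assert q[0, 1] == pytest.approx(1.0)

    def test_disjoint_supports(self):
        w = np.array([[1, 1, 0, 0], [0, 0, 1, 1]], dtype=np.uint8)
        assert pm.overlaps(w)[0, 1] == 0.0

    def test_silent_word_flagged_nan(self):
        w = np.array([[0, 0, 0], [1, 0, 1]], dtype=np.uint8)
        q = pm.overlaps(w)
        assert np.isnan(q[0, 1]) and np.isnan(q[0, 0])

    def test_within_basin_exceeds_between(self):
        model = _two_cluster_model()
        rng = np.random.default_rng(3)
        words = []
        labels = []
        for _ in range(40):
            base = np.zeros(6, dtype=np.uint8)
            cluster = rng.integers(2)
            base[cluster * 3:(cluster + 1) * 3] = 1
            flip = rng.integers(6)
            base[flip] ^= 1
            if base.sum() == 0:
                continue
            words.append(base)
            labels.append(cluster)
        q = pm.overlaps(np.array(words))
        labels = np.array(labels)
        same = labels[:, None] == labels[None, :]
        off = ~np.eye(len(labels), dtype=bool)
        assert np.nanmean(q[same & off]) > np.nanmean(q[~same])


class TestTransitions:
    def test_barriers_nonnegative_and_exits_change_basin(self):
        model = _two_cluster_model()
        start, _ = pm.descend_to_metastable(model, np.array([1, 1, 1, 0, 0, 0],
                                                            dtype=np.uint8))
        records, ends = pm.explore_transitions(model, start, n_walks=30,
                                               max_attempts=3000, seed=4)
        uncensored = [r for r in records if not r.censored]
        assert uncensored, "no transitions observed"
        for r in uncensored:
            assert r.barrier >= 0
            assert r.end_basin != 0
            assert r.path_length >= 1

    def test_requires_metastable_start(self, kpair_gen):
        with pytest.raises(ValueError):
            pm.explore_transitions(kpair_gen,
                                   np.ones(kpair_gen.n_neurons, dtype=np.uint8))

    def test_sparse_exits_decay_to_silence(self):
        # deeper fields: dismantling the active cluster (dE = +2 per spin) is
        # cheaper than recruiting the other cluster (dE = +4), so exits decay
        model = _two_cluster_model()
        model = pm.MaxEntModel("pairwise", np.full(6, -4.0), model.J)
        start, _ = pm.descend_to_metastable(model, np.array([1, 1, 1, 0, 0, 0],
                                                            dtype=np.uint8))
        records, ends = pm.explore_transitions(model, start, n_walks=40,
                                               max_attempts=5000, seed=5)
        silent = [b for b, w in enumerate(ends) if w.sum() == 0]
        assert silent
        n_to_silent = sum(r.end_basin == silent[0] for r in records
                          if not r.censored)
        assert n_to_silent > len([r for r in records if not r.censored]) / 2


class TestBasinDynamics:
    def test_probabilities_sum_to_one(self, kpair_gen):
        spec = pm.GeneratorSpec(n_neurons=kpair_gen.n_neurons, n_repeats=8,
                                bins_per_repeat=100, seed=54)
        raster = pm.generate_raster(kpair_gen, spec)
        out = pm.basin_dynamics(kpair_gen, raster)
        np.testing.assert_allclose(out["prob"].sum(axis=1), 1.0, atol=1e-12)

    def test_repeat_locked_drive_revisits_basin(self):
        # asymmetric clusters: the shallower one ignites preferentially at
        # the drive transients, locking the basin identity to the stimulus
        model = _two_cluster_model()
        model = pm.MaxEntModel("pairwise",
                               np.array([-3.0] * 3 + [-4.5] * 3), model.J)
        spec = pm.GeneratorSpec(n_neurons=6, n_repeats=40, bins_per_repeat=60,
                                modulation_amplitude=2.5,
                                modulation_n_bumps=3, seed=55)
        raster = pm.generate_raster(model, spec)
        out = pm.basin_dynamics(model, raster)
        # repeat-locked control: shuffling kills the per-bin basin locking
        shuffled = pm.shuffle_raster(raster, seed=56)
        out_s = pm.basin_dynamics(model, shuffled)

        def lock_score(o):
            # mean over the most-locked bins of the dominant non-silent
            # basin's across-repeat occupancy
            p = o["prob"]
            sil = o["summary"].silent_basin()
            q = p.copy()
            if sil is not None:
                q[:, sil] = 0
            return float(np.sort(q.max(axis=1))[-5:].mean())

        assert lock_score(out) > lock_score(out_s) + 0.1
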