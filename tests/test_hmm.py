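"""Segmentation HMM: binarization tails, exact small-case oracles,
EM invariants and sparse-state merging."""

import itertools

import numpy as np
import pytest
from scipy.stats import poisson

from chromexpr import hmm
from chromexpr.core_io import BinnedTrackSet
from chromexpr.hmm import (
    BinaryTrackSet, StateModel, binarize, decode, forward_loglik,
    backward_loglik, merge_sparse_states, poisson_threshold, train_hmm,
)


def _random_model(rng, K, M):
    pi = rng.dirichlet(np.ones(K))
    A = rng.dirichlet(np.ones(K), size=K)
    B = rng.uniform(0.05, 0.95, size=(K, M))
    return StateModel(pi, A, B, [f"m{j}" for j in range(M)])


def _random_bits(rng, T, M):
    return BinaryTrackSet(200, [f"m{j}" for j in range(M)],
                          {"chr1": rng.integers(0, 2, size=(T, M))})


def _enumerate_loglik(model, x):
    """Brute-force sum over all K^T hidden paths."""
    K = model.K
    T = len(x)
    Bc = np.clip(model.B, 1e-6, 1 - 1e-6)
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        p = model.pi[path[0]]
        for t in range(1, T):
            p *= model.A[path[t - 1], path[t]]
        for t, k in enumerate(path):
            p *= np.prod(np.where(x[t] == 1, Bc[k], 1 - Bc[k]))
        total += p
    return np.log(total)


def _enumerate_viterbi(model, x):
    K, T = model.K, len(x)
    Bc = np.clip(model.B, 1e-6, 1 - 1e-6)
    best, best_p = None, -np.inf
    for path in itertools.product(range(K), repeat=T):
        p = np.log(model.pi[path[0]])
        for t in range(1, T):
            p += np.log(model.A[path[t - 1], path[t]])
        for t, k in enumerate(path):
            p += np.log(np.where(x[t] == 1, Bc[k], 1 - Bc[k])).sum()
        if p > best_p:
            best, best_p = path, p
    return np.array(best)


class TestBinarize:
    def test_poisson_threshold_examples(self):
        # lambda=1: P(X>=7) ~ 8.3e-5 <= 1e-4 < P(X>=6) ~ 5.9e-4
        assert poisson_threshold(1.0, 1e-4) == 7
        c5 = poisson_threshold(5.0, 1e-4)
        assert poisson.sf(c5 - 1, 5.0) <= 1e-4 < poisson.sf(c5 - 2, 5.0)
        assert c5 > 5  # a count at the mean can never flag

    def test_zero_count_never_flags(self):
        ts = BinnedTrackSet(200, ["m"], {"chr1": np.zeros((100, 1))})
        bits = binarize(ts)
        assert bits.bits["chr1"].sum() == 0

    def test_extreme_count_flags_against_unit_background(self):
        vec = np.ones((100, 1))
        vec[0, 0] = 10  # background mean ~1.09, threshold 7
        bits = binarize(BinnedTrackSet(200, ["m"], {"chr1": vec}))
        assert bits.bits["chr1"][0, 0] == 1
        assert bits.bits["chr1"][1:, 0].sum() == 0

    def test_count_at_the_mean_does_not_flag(self):
        vec = np.full((1000, 1), 5.0)
        bits = binarize(BinnedTrackSet(200, ["m"], {"chr1": vec}))
        assert bits.bits["chr1"].sum() == 0


class TestExactOracles:
    @pytest.mark.parametrize("seed", range(4))
    def test_forward_equals_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        model = _random_model(rng, K=2, M=3)
        bits = _random_bits(rng, T=6, M=3)
        ll = forward_loglik(model, bits)
        assert ll == pytest.approx(
            _enumerate_loglik(model, bits.bits["chr1"]), abs=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_viterbi_attains_enumerated_optimum(self, seed):
        rng = np.random.default_rng(seed + 10)
        model = _random_model(rng, K=2, M=2)
        bits = _random_bits(rng, T=5, M=2)
        got = decode(model, bits).states["chr1"]
        best = _enumerate_viterbi(model, bits.bits["chr1"])

        def lp(path):
            x = bits.bits["chr1"]
            Bc = np.clip(model.B, 1e-6, 1 - 1e-6)
            out = np.log(model.pi[path[0]])
            for t in range(1, len(path)):
                out += np.log(model.A[path[t - 1], path[t]])
            for t, k in enumerate(path):
                out += np.log(np.where(x[t] == 1, Bc[k], 1 - Bc[k])).sum()
            return out

        assert lp(got) == pytest.approx(lp(best), abs=1e-9)

    def test_forward_and_backward_agree(self, rng):
        model = _random_model(rng, K=4, M=3)
        bits = _random_bits(rng, T=400, M=3)
        assert forward_loglik(model, bits) == pytest.approx(
            backward_loglik(model, bits), abs=1e-8)

    def test_permuting_states_preserves_likelihood(self, rng):
        model = _random_model(rng, K=3, M=3)
        bits = _random_bits(rng, T=200, M=3)
        perm = np.array([2, 0, 1])
        permuted = StateModel(model.pi[perm], model.A[np.ix_(perm, perm)],
                              model.B[perm], model.marks)
        assert forward_loglik(model, bits) == pytest.approx(
            forward_loglik(permuted, bits), abs=1e-9)


class TestTraining:
    def test_single_state_closed_form(self, rng):
        bits = _random_bits(rng, T=500, M=3)
        model = train_hmm(bits, K=1, n_restarts=1, seed=0)
        freq = bits.bits["chr1"].mean(axis=0)
        assert model.A.tolist() == [[1.0]]
        assert model.B[0] == pytest.approx(freq, abs=1e-6)

    def test_stochasticity_preserved_and_deterministic(self, rng):
        bits = _random_bits(rng, T=300, M=2)
        m1 = train_hmm(bits, K=3, n_restarts=2, seed=7, max_iter=30)
        m2 = train_hmm(bits, K=3, n_restarts=2, seed=7, max_iter=30)
        assert np.array_equal(m1.B, m2.B)
        assert m1.pi.sum() == pytest.approx(1, abs=1e-10)
        assert np.abs(m1.A.sum(axis=1) - 1).max() < 1e-10

    def test_k_larger_than_data_rejected(self, rng):
        bits = _random_bits(rng, T=5, M=2)
        with pytest.raises(ValueError, match="exceeds"):
            train_hmm(bits, K=10, n_restarts=1, seed=0)

    def test_nonbinary_input_rejected(self):
        with pytest.raises(ValueError, match="non-binary"):
            BinaryTrackSet(200, ["m"], {"chr1": np.full((10, 1), 2)})


class TestDecode:
    def test_single_state_path(self, rng):
        bits = _random_bits(rng, T=50, M=2)
        model = StateModel(np.array([1.0]), np.array([[1.0]]),
                           np.array([[0.5, 0.5]]), ["a", "b"])
        assert (decode(model, bits).states["chr1"] == 0).all()

    def test_deterministic_emissions_recover_unique_path(self):
        # state 0 emits mark0 only, state 1 emits mark1 only
        model = StateModel(np.array([0.5, 0.5]),
                           np.array([[0.8, 0.2], [0.2, 0.8]]),
                           np.array([[1.0, 0.0], [0.0, 1.0]]), ["a", "b"])
        x = np.array([[1, 0], [1, 0], [0, 1], [1, 0]], dtype=np.uint8)
        bits = BinaryTrackSet(200, ["a", "b"], {"chr1": x})
        assert decode(model, bits).states["chr1"].tolist() == [0, 0, 1, 0]

    def test_posterior_decoding_available(self, rng):
        model = _random_model(rng, K=2, M=2)
        bits = _random_bits(rng, T=30, M=2)
        path = decode(model, bits, method="posterior")
        assert path.posterior is not None
        assert np.allclose(path.posterior["chr1"].sum(axis=1), 1)


class TestMerge:
    def _model_and_path(self, occ, B):
        K = len(occ)
        labels = np.repeat(np.arange(K), (np.array(occ) * 1000).astype(int))
        model = StateModel(np.full(K, 1 / K), np.full((K, K), 1 / K),
                           np.asarray(B, float), ["m"])
        return model, hmm.StatePath({"chr1": labels}, K)

    def test_no_sparse_states_only_renumbers(self):
        model, path = self._model_and_path([0.2, 0.8], [[0.9], [0.8]])
        m2, p2 = merge_sparse_states(model, path)
        assert m2.K == 2
        # state with larger occupancy becomes class 0
        assert (p2.states["chr1"][:200] == 1).all()

    def test_two_silent_sparse_states_merge(self):
        model, path = self._model_and_path(
            [0.497, 0.497, 0.003, 0.003],
            [[0.9], [0.8], [0.01], [0.02]])
        m2, p2 = merge_sparse_states(model, path)
        assert m2.K == 3
        occ = p2.occupancy()
        assert occ[2] == pytest.approx(0.006, abs=1e-9)

    def test_merge_preserves_partition_up_to_relabeling(self):
        model, path = self._model_and_path(
            [0.5, 0.494, 0.003, 0.003], [[0.9], [0.8], [0.01], [0.02]])
        _, p2 = merge_sparse_states(model, path)
        old = path.states["chr1"]
        new = p2.states["chr1"]
        for s in np.unique(old):
            assert len(np.unique(new[old == s])) == 1

    def test_high_emission_sparse_state_survives(self):
        model, path = self._model_and_path(
            [0.997, 0.003], [[0.01], [0.99]])
        m2, _ = merge_sparse_states(model, path)
        assert m2.K == 2

    def test_merging_everything_rejected(self):
        model, path = self._model_and_path([0.001, 0.001], [[0.01], [0.02]])
        with pytest.raises(ValueError, match="every state"):
            merge_sparse_states(model, path, occupancy_floor=0.9)


class TestPlantedRecovery:
    def test_em_recovers_well_separated_states(self):
        """Two states with opposite emission signatures and sticky
        transitions are recovered almost exactly from 3000 bins."""
        rng = np.random.default_rng(0)
        Btrue = np.array([[0.9, 0.1], [0.1, 0.9]])
        path = [0]
        for _ in range(2999):
            path.append(path[-1] if rng.random() < 0.95 else 1 - path[-1])
        path = np.array(path)
        x = (rng.random((3000, 2)) < Btrue[path]).astype(np.uint8)
        bits = BinaryTrackSet(200, ["a", "b"], {"chr1": x})
        model = train_hmm(bits, K=2, n_restarts=3, seed=1, max_iter=100)
        dec = decode(model, bits).states["chr1"]
        acc = max((dec == path).mean(), (1 - dec == path).mean())
        assert acc >= 0.9
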