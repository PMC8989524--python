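"""Bernoulli-HMM fitting, decoding, posteriors, model comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest

from chromsig.hmm import (
    BernoulliHMM, decode, fit_hmm, forward_backward, match_states,
    select_state_count, state_similarity, viterbi_states,
)
from chromsig.io_tracks import BinaryMatrix

from conftest import simulate_hmm_sequence


def make_model(emission, transition=None, initial=None):
    emission = np.clip(np.asarray(emission, float), 1e-6, 1 - 1e-6)
    K = emission.shape[0]
    if transition is None:
        transition = np.full((K, K), 1.0 / K)
    if initial is None:
        initial = np.full(K, 1.0 / K)
    return BernoulliHMM(emission=emission, transition=np.asarray(transition, float),
                        initial=np.asarray(initial, float),
                        marks=[f"m{i}" for i in range(emission.shape[1])])


def enumerate_posteriors(model, X):
    """Exhaustive oracle: sum path probabilities over all K^T state paths."""
    T, M = X.shape
    K = model.n_states
    post = np.zeros((T, K))
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        p = model.initial[path[0]]
        for t in range(1, T):
            p *= model.transition[path[t - 1], path[t]]
        for t in range(T):
            e = model.emission[path[t]]
            p *= np.prod(np.where(X[t] == 1, e, 1 - e))
        total += p
        for t in range(T):
            post[t, path[t]] += p
    return post / total, np.log(total)


def bm(X, marks=None):
    marks = marks or [f"m{i}" for i in range(X.shape[1])]
    return BinaryMatrix(marks=marks, data={"chr1": np.asarray(X, np.uint8)})


class TestForwardBackward:
    @pytest.mark.parametrize("K,T,M,seed", [(2, 5, 2, 0), (3, 8, 3, 1), (2, 8, 4, 2),
                                            (3, 6, 2, 3), (1, 4, 2, 4)])
    def test_posteriors_match_exhaustive_enumeration(self, K, T, M, seed):
        rng = np.random.default_rng(seed)
        em = rng.uniform(0.05, 0.95, (K, M))
        A = rng.dirichlet(np.ones(K) * 2, size=K)
        pi = rng.dirichlet(np.ones(K))
        model = make_model(em, A, pi)
        X = rng.integers(0, 2, (T, M)).astype(np.uint8)
        gamma, ll = forward_backward(model, X)
        oracle, oll = enumerate_posteriors(model, X)
        assert np.abs(gamma - oracle).max() < 1e-9
        assert ll == pytest.approx(oll, abs=1e-9)

    def test_posteriors_normalized_per_bin(self):
        rng = np.random.default_rng(5)
        model = make_model(rng.uniform(0.1, 0.9, (4, 3)))
        X = rng.integers(0, 2, (500, 3)).astype(np.uint8)
        gamma, _ = forward_backward(model, X)
        assert np.abs(gamma.sum(axis=1) - 1).max() < 1e-9


class TestFit:
    def test_single_state_closed_form(self):
        rng = np.random.default_rng(0)
        X = (rng.random((2000, 3)) < [0.2, 0.5, 0.8]).astype(np.uint8)
        model = fit_hmm(bm(X), K=1, seed=0)
        assert np.allclose(model.emission[0], X.mean(axis=0), atol=1e-9)
        assert model.transition.tolist() == [[1.0]]

    def test_same_seed_bit_identical(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 2, (800, 3)).astype(np.uint8)
        a = fit_hmm(bm(X), K=3, seed=42, max_iter=20)
        b = fit_hmm(bm(X), K=3, seed=42, max_iter=20)
        assert np.array_equal(a.emission, b.emission)
        assert np.array_equal(a.transition, b.transition)
        assert a.log_likelihood == b.log_likelihood

    def test_loglik_nondecreasing(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 2, (3000, 4)).astype(np.uint8)
        model = fit_hmm(bm(X), K=4, seed=0, max_iter=50)
        assert np.all(np.diff(model.ll_history) >= -1e-8)

    def test_two_state_parameter_recovery(self):
        em = np.array([[0.9, 0.1, 0.9, 0.1], [0.1, 0.9, 0.1, 0.9]])
        A = np.array([[0.95, 0.05], [0.05, 0.95]])
        _, X = simulate_hmm_sequence(em, A, 50_000, seed=3)
        model = fit_hmm(bm(X), K=2, seed=0)
        perm = match_states(em, model.emission)
        assert np.abs(model.emission[perm] - em).mean() <= 0.05

    def test_pooled_sexes_share_one_model(self):
        rng = np.random.default_rng(6)
        em = np.array([[0.9, 0.1], [0.1, 0.9]])
        A = np.array([[0.9, 0.1], [0.1, 0.9]])
        _, Xf = simulate_hmm_sequence(em, A, 5000, seed=7)
        _, Xm = simulate_hmm_sequence(em, A, 5000, seed=8)
        model = fit_hmm([bm(Xf), bm(Xm)], K=2, seed=0)
        assert model.n_states == 2

    def test_mark_order_mismatch_rejected(self):
        X = np.zeros((10, 2), np.uint8)
        with pytest.raises(ValueError, match="mark"):
            fit_hmm([bm(X, ["a", "b"]), bm(X, ["b", "a"])], K=2)

    def test_invalid_state_count_rejected(self):
        with pytest.raises(ValueError):
            fit_hmm(bm(np.zeros((10, 2), np.uint8)), K=0)

    def test_tsv_bundle_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        X = rng.integers(0, 2, (500, 3)).astype(np.uint8)
        model = fit_hmm(bm(X), K=2, seed=1, max_iter=10)
        model.save(tmp_path / "model")
        back = BernoulliHMM.load(tmp_path / "model")
        assert np.allclose(back.emission, model.emission)
        assert np.allclose(back.transition, model.transition)
        assert back.marks == model.marks


class TestDecode:
    def test_single_state_single_tile(self):
        X = np.random.default_rng(0).integers(0, 2, (100, 2)).astype(np.uint8)
        model = fit_hmm(bm(X), K=1, seed=0)
        seg = decode(model, bm(X))
        assert len(seg.tiles) == 1
        assert seg.tiles.iloc[0].tolist() == ["chr1", 0, 100 * 200, "E1"]

    def test_well_separated_states_recovered(self):
        em = np.array([[0.95, 0.05, 0.95], [0.05, 0.95, 0.05]])
        A = np.array([[0.98, 0.02], [0.02, 0.98]])
        states, X = simulate_hmm_sequence(em, A, 20_000, seed=4)
        model = fit_hmm(bm(X), K=2, seed=0)
        seg = decode(model, bm(X))
        dec = np.empty(len(states), dtype=int)
        for r in seg.tiles.itertuples():
            dec[r.start // 200: r.end // 200] = int(r.state[1:]) - 1
        perm = match_states(em, model.emission)
        # map decoded fitted-state indices back to truth indices
        inv = np.empty(2, dtype=int)
        inv[perm] = np.arange(2)
        assert (inv[dec] == states).mean() >= 0.99

    def test_relabeling_permutes_decoded_labels(self):
        rng = np.random.default_rng(10)
        em = rng.uniform(0.1, 0.9, (3, 3))
        A = rng.dirichlet(np.ones(3), size=3)
        pi = rng.dirichlet(np.ones(3))
        model = make_model(em, A, pi)
        X = rng.integers(0, 2, (300, 3)).astype(np.uint8)
        perm = np.array([2, 0, 1])
        permuted = make_model(em[perm], A[perm][:, perm], pi[perm])
        a = decode(model, bm(X)).tiles
        b = decode(permuted, bm(X)).tiles
        relabel = {f"E{k + 1}": f"E{np.flatnonzero(perm == k)[0] + 1}"
                   for k in range(3)}
        assert list(a["state"].map(relabel)) == list(b["state"])

    def test_viterbi_agrees_on_clean_data(self):
        em = np.array([[0.99, 0.01], [0.01, 0.99]])
        A = np.array([[0.95, 0.05], [0.05, 0.95]])
        states, X = simulate_hmm_sequence(em, A, 2000, seed=11)
        model = make_model(em, A, np.array([0.5, 0.5]))
        vit = viterbi_states(model, X)
        assert (vit == states).mean() > 0.98


class TestModelComparison:
    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(12)
        model = make_model(rng.uniform(0.1, 0.9, (4, 5)))
        sim = state_similarity(model, model)
        assert np.allclose(sim["correlation"], 1.0)

    def test_permuted_model_recovers_permutation(self):
        rng = np.random.default_rng(13)
        em = rng.uniform(0.1, 0.9, (5, 4))
        a = make_model(em)
        perm = np.array([3, 0, 4, 1, 2])
        b = make_model(em[perm])
        sim = state_similarity(a, b)
        assert np.allclose(sim["correlation"], 1.0)
        expected = [f"E{np.flatnonzero(perm == k)[0] + 1}" for k in range(5)]
        assert list(sim["best_state_b"]) == expected

    def test_complement_emissions_are_anticorrelated(self):
        em = np.array([[0.9, 0.1], [0.8, 0.3]])
        a = make_model(em)
        b = make_model(np.vstack([em[1], 1 - em[0]]))
        sim = state_similarity(a, b)
        # state with a positive match never picks the complemented state
        assert sim.loc[0, "best_state_b"] == "E1"
        from chromsig.hmm import _emission_correlation
        corr = _emission_correlation(a.emission, b.emission)
        assert corr[0, 1] == pytest.approx(-1.0)

    def test_constant_emission_rows_get_zero_correlation(self):
        a = make_model(np.array([[0.5, 0.5], [0.9, 0.1]]))
        b = make_model(np.array([[0.2, 0.8]]))
        sim = state_similarity(a, b)
        assert sim.loc[0, "correlation"] == 0.0


class TestSelectStateCount:
    def test_degenerate_range_returns_kmax(self):
        rng = np.random.default_rng(14)
        X = rng.integers(0, 2, (1000, 3)).astype(np.uint8)
        chosen, curve = select_state_count(bm(X), k_max=3, k_min=3, seed=0,
                                           max_iter=20)
        assert chosen == 3
        assert len(curve) == 0 or curve["k"].tolist() == []

    def test_curve_covers_requested_range(self):
        rng = np.random.default_rng(15)
        X = rng.integers(0, 2, (2000, 3)).astype(np.uint8)
        chosen, curve = select_state_count(bm(X), k_max=5, k_min=2, seed=0,
                                           max_iter=20)
        assert sorted(curve["k"]) == [2, 3, 4]

    def test_recovers_true_state_count_within_one(self):
        em = np.full((4, 4), 0.05)
        np.fill_diagonal(em, 0.95)
        K = 4
        A = np.full((K, K), 0.1 / (K - 1))
        np.fill_diagonal(A, 0.9)
        _, X = simulate_hmm_sequence(em, A, 30_000, seed=16)
        chosen, _ = select_state_count(bm(X), k_max=7, k_min=2, seed=0,
                                       max_iter=60)
        assert 3 <= chosen <= 5

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            select_state_count(bm(np.zeros((10, 2), np.uint8)), k_max=2, k_min=3)
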