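import numpy as np
import pytest

from dfcstates import (DfcSeries, SignedGraphSet, compare_states, efficiency,
                       global_efficiency, local_efficiency, node_strength,
                       state_mean_dfc, vectorize)
from dfcstates.states import StateModel


def _floyd_warshall(L):
    """Independent brute-force shortest paths (triple loop)."""
    n = L.shape[0]
    D = L.copy()
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def _brute_global_efficiency(W):
    n = W.shape[0]
    with np.errstate(divide="ignore"):
        L = np.where(W > 0, 1.0 / W, np.inf)
    np.fill_diagonal(L, 0.0)
    D = _floyd_warshall(L)
    acc = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(D[i, j]) and D[i, j] > 0:
                acc += 1.0 / D[i, j]
    return acc / (n * (n - 1))


def _brute_local_efficiency(W):
    n = W.shape[0]
    out = np.zeros(n)
    with np.errstate(divide="ignore"):
        L = np.where(W > 0, 1.0 / W, np.inf)
    for i in range(n):
        V = [j for j in range(n) if W[i, j] > 0]
        k = len(V)
        if k < 2:
            continue
        sub = L[np.ix_(V, V)] ** (1 / 3)
        np.fill_diagonal(sub, 0.0)
        D = _floyd_warshall(sub)
        acc = 0.0
        for a in range(k):
            for b in range(k):
                if a != b and np.isfinite(D[a, b]) and D[a, b] > 0:
                    acc += (W[i, V[a]] * W[i, V[b]]) ** (1 / 3) / D[a, b]
        out[i] = acc / (k * (k - 1))
    return out


def _random_graph(rng, n, density=0.7):
    W = rng.uniform(0.1, 1.0, (n, n)) * (rng.random((n, n)) < density)
    W = np.triu(W, 1)
    W = W + W.T
    return W


class TestSignedGraphSet:
    def test_decomposition_reconstructs_fc(self, rng):
        fc = rng.uniform(-1, 1, (6, 6))
        fc = (fc + fc.T) / 2
        g = SignedGraphSet.from_fc(fc)
        off = fc.copy()
        np.fill_diagonal(off, 0.0)
        np.testing.assert_allclose(g.positive - g.negative, off, atol=1e-15)
        assert (g.positive >= 0).all() and (g.negative >= 0).all()
        np.testing.assert_allclose(g.absolute, np.abs(off))
        for v in ("positive", "negative", "absolute"):
            assert np.diag(g.weights(v)).max() == 0.0

    def test_unknown_variant_rejected(self, rng):
        g = SignedGraphSet.from_fc(np.eye(3))
        with pytest.raises(ValueError):
            g.weights("signed")


class TestNodeStrength:
    def test_triangle_half_weights(self):
        fc = np.full((3, 3), 0.5)
        np.fill_diagonal(fc, 1.0)
        g = SignedGraphSet.from_fc(fc)
        np.testing.assert_allclose(node_strength(g, "positive"),
                                   [1.0, 1.0, 1.0])

    def test_empty_graph_zero(self):
        g = SignedGraphSet.from_fc(np.eye(4))
        np.testing.assert_array_equal(node_strength(g, "absolute"),
                                      np.zeros(4))

    def test_matches_hand_summation(self, rng):
        W = _random_graph(rng, 6)
        g = SignedGraphSet(positive=W, negative=np.zeros_like(W),
                           absolute=W)
        expected = np.array([sum(W[i, j] for j in range(6))
                             for i in range(6)])
        np.testing.assert_allclose(node_strength(g, "positive"), expected,
                                   atol=1e-12)


class TestEfficiency:
    def test_complete_unit_graph_global_efficiency_one(self):
        W = np.ones((6, 6)) - np.eye(6)
        assert global_efficiency(W) == pytest.approx(1.0, abs=1e-15)

    def test_two_disconnected_dyads(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        assert global_efficiency(W) == pytest.approx(1.0 / 3.0)

    def test_all_zero_graph(self):
        W = np.zeros((5, 5))
        m = efficiency(SignedGraphSet(W, W, W), "positive")
        assert m.global_efficiency == 0.0
        np.testing.assert_array_equal(m.local_efficiency, np.zeros(5))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        W = _random_graph(rng, 5 + seed)   # 5..8 nodes
        np.testing.assert_allclose(global_efficiency(W),
                                   _brute_global_efficiency(W), atol=1e-12)
        np.testing.assert_allclose(local_efficiency(W),
                                   _brute_local_efficiency(W), atol=1e-12)

    def test_scale_covariance(self, rng):
        W = _random_graph(rng, 7)
        lam = 3.7
        np.testing.assert_allclose(global_efficiency(lam * W),
                                   lam * global_efficiency(W), rtol=1e-10)
        g1 = SignedGraphSet(W, np.zeros_like(W), W)
        g2 = SignedGraphSet(lam * W, np.zeros_like(W), lam * W)
        np.testing.assert_allclose(node_strength(g2, "positive"),
                                   lam * node_strength(g1, "positive"),
                                   rtol=1e-12)


class TestStateMeanDfc:
    def _setup(self, rng, labels):
        P = 6
        vectors = rng.uniform(-1, 1, (len(labels), P))
        series = DfcSeries(vectors=vectors,
                           window_start_tr=np.arange(len(labels)),
                           subject_id="s1", scan_id="sc1")
        model = StateModel(K=3, centroids=np.zeros((3, P)),
                           assignments={("s1", "sc1"): np.array(labels)},
                           inertia=0, seed=0, n_init=1)
        return series, model, vectors

    def test_single_window_mean_is_that_window(self, rng):
        series, model, vectors = self._setup(rng, [0, 1, 1])
        fc = state_mean_dfc([series], model, "s1", 0)
        np.testing.assert_allclose(vectorize(fc), vectors[0])

    def test_two_windows_averaged(self, rng):
        series, model, vectors = self._setup(rng, [1, 0, 1])
        fc = state_mean_dfc([series], model, "s1", 1)
        np.testing.assert_allclose(vectorize(fc),
                                   (vectors[0] + vectors[2]) / 2)

    def test_unvisited_state_returns_missing(self, rng):
        series, model, _ = self._setup(rng, [0, 1, 1])
        assert state_mean_dfc([series], model, "s1", 2) is None


class TestCompareStates:
    def test_identical_metrics_no_rejections(self, rng):
        metrics = {f"s{i}": rng.uniform(0, 2, 8) for i in range(15)}
        table = compare_states(metrics, dict(metrics))
        np.testing.assert_allclose(table["t"], 0.0, atol=1e-12)
        assert not (table["q"] < 0.05).any()
        assert table["zero_variance"].all()

    def test_textbook_paired_t_on_printed_differences(self, rng):
        # paired differences (1, 1, 2, 0, 1): t = dbar / (sd/sqrt(5))
        diffs = np.array([1.0, 1.0, 2.0, 0.0, 1.0])
        base = rng.uniform(0, 1, (5, 1))
        # compare_states needs >= 10 subjects; tile the 5 printed pairs
        # twice and add a second, constant ROI
        a = {f"s{i}": np.array([base[i % 5, 0] + diffs[i % 5], 1.0])
             for i in range(10)}
        b = {f"s{i}": np.array([base[i % 5, 0], 1.0]) for i in range(10)}
        table = compare_states(a, b)
        d2 = np.tile(diffs, 2)
        expected_t = d2.mean() / (d2.std(ddof=1) / np.sqrt(10))
        assert table.loc[0, "t"] == pytest.approx(expected_t, rel=1e-9)
        assert table.loc[0, "direction"] == "A>B"

    def test_planted_difference_localized(self, rng):
        n, R = 60, 12
        base = rng.standard_normal((n, R))
        shift = np.zeros(R)
        shift[:5] = 1.5
        a = {f"s{i}": base[i] + shift for i in range(n)}
        b = {f"s{i}": base[i] + 0.1 * rng.standard_normal(R)
             for i in range(n)}
        table = compare_states(a, b)
        sig = set(table[table["q"] < 0.05]["roi"])
        assert set(range(5)) <= sig
        assert len(sig - set(range(5))) <= 1

    def test_too_few_subjects_rejected(self, rng):
        metrics = {f"s{i}": rng.uniform(0, 1, 4) for i in range(5)}
        with pytest.raises(ValueError):
            compare_states(metrics, dict(metrics))
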