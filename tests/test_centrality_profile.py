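"""Eigencentrality with the uniform 1/N baseline, profile assembly, HITS."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import scnkit as sk
from scnkit.errors import ValidationError

from conftest import make_difference_network

RNG = np.random.default_rng(909)


def _dense_oracle(w):
    """Dominant eigenvector by full eigendecomposition, abs + L1-normalized."""
    vals, vecs = np.linalg.eigh(w)
    v = np.abs(vecs[:, np.argmax(vals)])
    return v / v.sum()


def _random_connected_graph(rng, n, density=0.3):
    while True:
        w = rng.uniform(0, 1, size=(n, n)) * (rng.uniform(size=(n, n)) < density)
        w = np.triu(w, 1)
        w = w + w.T
        from scipy.sparse.csgraph import connected_components
        if connected_components(w > 0, directed=False)[0] == 1:
            return w


class TestEigencentrality:
    def test_empty_graph_uniform_baseline(self):
        out = sk.eigencentrality(np.zeros((61, 61)))
        np.testing.assert_allclose(out, 1 / 61)
        assert round(out[0], 4) == 0.0164

    def test_complete_graph_uniform(self):
        n = 7
        w = np.ones((n, n)) - np.eye(n)
        np.testing.assert_allclose(sk.eigencentrality(w), 1 / n, atol=1e-9)

    def test_star_graph_analytic(self):
        """K_{1,4}: center = sqrt(n) * leaf, so center 1/3 and leaves 1/6 after L1."""
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 1.0
        out = sk.eigencentrality(w)
        np.testing.assert_allclose(out, [1 / 3, 1 / 6, 1 / 6, 1 / 6, 1 / 6], atol=1e-9)
        np.testing.assert_allclose(out, _dense_oracle(w), atol=1e-8)

    @pytest.mark.parametrize("n", [5, 12, 25, 50])
    def test_matches_dense_eigendecomposition(self, n):
        for trial in range(3):
            w = _random_connected_graph(np.random.default_rng(100 * n + trial), n)
            np.testing.assert_allclose(sk.eigencentrality(w), _dense_oracle(w), atol=1e-8)

    def test_disconnected_dominant_component_plus_baseline(self):
        # component {0,1,2} has 3 edges; component {3,4} has 1; nodes 5,6 isolated
        w = np.zeros((7, 7))
        for i, j in [(0, 1), (1, 2), (0, 2), (3, 4)]:
            w[i, j] = w[j, i] = 1.0
        out = sk.eigencentrality(w)
        np.testing.assert_allclose(out[:3], 1 / 3, atol=1e-9)  # triangle, uniform, sums to 1
        np.testing.assert_allclose(out[3:], 1 / 7)  # everything else at baseline

    def test_first_edge_lifts_endpoints_above_baseline(self):
        n = 9
        w = np.zeros((n, n))
        w[2, 5] = w[5, 2] = 0.7
        out = sk.eigencentrality(w)
        assert out[2] == pytest.approx(0.5) and out[5] == pytest.approx(0.5)
        others = np.delete(out, [2, 5])
        np.testing.assert_allclose(others, 1 / n)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(scale=st.floats(1e-6, 1e6))
    def test_scale_invariance(self, scale):
        w = _random_connected_graph(np.random.default_rng(4), 8)
        np.testing.assert_allclose(
            sk.eigencentrality(w * scale), sk.eigencentrality(w), atol=1e-10
        )

    def test_networkx_cross_check(self):
        import networkx as nx

        w = _random_connected_graph(np.random.default_rng(17), 10)
        g = nx.from_numpy_array(w)
        ec = nx.eigenvector_centrality_numpy(g, weight="weight")
        ref = np.array([ec[i] for i in range(10)])
        ref = np.abs(ref) / np.abs(ref).sum()
        np.testing.assert_allclose(sk.eigencentrality(w), ref, atol=1e-7)

    @pytest.mark.parametrize(
        "bad",
        [
            np.array([[0.0, 1.0], [0.5, 0.0]]),   # asymmetric
            np.array([[0.0, -1.0], [-1.0, 0.0]]),  # negative
            np.array([[1.0, 1.0], [1.0, 0.0]]),    # self-edge
        ],
        ids=["asymmetric", "negative", "self-edge"],
    )
    def test_invalid_weights_rejected(self, bad):
        with pytest.raises(ValidationError):
            sk.eigencentrality(bad)


class TestProfileMatrix:
    def _diffs(self, masks, names, dz=None):
        pairs = [("B", "A"), ("C", "A"), ("C", "B")]
        return [
            make_difference_network(m, names, pair=pairs[i % 3], delta_z=None if dz is None else dz[i])
            for i, m in enumerate(masks)
        ]

    def test_all_empty_networks_give_uniform_averages(self):
        names = [f"r{i}" for i in range(6)]
        masks = [np.zeros((6, 6), bool) for _ in range(3)]
        prof = sk.build_profile_matrix(self._diffs(masks, names), names)
        np.testing.assert_allclose(prof.average, 1 / 6)
        np.testing.assert_allclose(prof.values, 1 / 6)

    def test_average_is_row_mean_and_columns_sorted_by_pair(self):
        names = [f"r{i}" for i in range(5)]
        rng = np.random.default_rng(3)
        masks = []
        for _ in range(3):
            m = np.zeros((5, 5), bool)
            i, j = rng.choice(5, 2, replace=False)
            m[i, j] = m[j, i] = True
            masks.append(m)
        prof = sk.build_profile_matrix(self._diffs(masks, names), names)
        assert list(prof.comparisons) == sorted(prof.comparisons)
        np.testing.assert_allclose(prof.average, prof.values.mean(axis=1), atol=1e-12)

    def test_empty_union_rejected(self):
        d = make_difference_network(np.zeros((3, 3), bool), list("abc"))
        with pytest.raises(ValidationError, match="no significant regions"):
            sk.build_profile_matrix([d], [])

    def test_planted_hub_attains_column_maximum(self):
        """A region touching every significant edge of a comparison tops that column."""
        n = 10
        names = [f"r{i}" for i in range(n)]
        wins = 0
        for rep in range(100):
            rng = np.random.default_rng(rep)
            hub = int(rng.integers(n))
            m_hub = np.zeros((n, n), bool)
            spokes = rng.choice([i for i in range(n) if i != hub], size=5, replace=False)
            dz_hub = np.zeros((n, n))
            for s in spokes:
                m_hub[hub, s] = m_hub[s, hub] = True
                dz_hub[hub, s] = dz_hub[s, hub] = rng.uniform(0.8, 1.2)
            m_other = np.zeros((n, n), bool)
            i, j = [int(v) for v in rng.choice(n, 2, replace=False)]
            m_other[i, j] = m_other[j, i] = True
            diffs = self._diffs([m_hub, m_other], names, dz=[dz_hub, m_other.astype(float)])
            prof = sk.build_profile_matrix(diffs, names)
            col = list(prof.comparisons).index("B-A")
            wins += int(np.argmax(prof.values[:, col]) == hub)
        assert wins >= 95


class TestHits:
    def test_symmetric_weights_hubs_equal_authorities(self):
        w = _random_connected_graph(np.random.default_rng(5), 8)
        hubs, auth = sk.hits_scores(w)
        np.testing.assert_allclose(hubs, auth, atol=1e-8)

    def test_directed_chain_pure_roles(self):
        w = np.array([[0.0, 1.0], [0.0, 0.0]])  # a -> b
        hubs, auth = sk.hits_scores(w)
        np.testing.assert_allclose(hubs, [1.0, 0.0], atol=1e-10)
        np.testing.assert_allclose(auth, [0.0, 1.0], atol=1e-10)

    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(99)
        w = rng.uniform(0, 1, size=(6, 6))
        np.fill_diagonal(w, 0.0)
        hubs, auth = sk.hits_scores(w)
        u, s, vt = np.linalg.svd(w)
        hub_ref = np.abs(u[:, 0]) / np.abs(u[:, 0]).sum()
        auth_ref = np.abs(vt[0]) / np.abs(vt[0]).sum()
        np.testing.assert_allclose(hubs, hub_ref, atol=1e-8)
        np.testing.assert_allclose(auth, auth_ref, atol=1e-8)
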