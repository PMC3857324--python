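"""DCeN score bounds, averaging, permutation p-values, switching view."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dcenkit.conet import ConsistencyMask
from dcenkit.dcen import (
    GroupAveragedWeights,
    average_weights,
    dcen_score,
    pooled_permutation_pvalues,
    switching_neighborhood,
)
from dcenkit.model import DCeN
from conftest import build_dataset, oracle_dcen_scores


def _avw(wx, wy, genes=None):
    wx = np.asarray(wx, float)
    genes = genes or [f"g{i}" for i in range(len(wx))]
    return GroupAveragedWeights(
        genes=list(genes),
        x_label="X",
        y_label="Y",
        wbar_x=wx,
        wbar_y=np.asarray(wy, float),
        n_x=2,
        n_y=2,
    )


def _mask(a, genes=None):
    a = np.asarray(a, np.int8)
    genes = genes or [f"g{i}" for i in range(len(a))]
    return ConsistencyMask(
        genes=list(genes), a=a, p_cut=0.05, frac=0.25, min_count=2
    )


def _single_neighbor(wx, wy):
    """Focal gene 0 with one retained neighbor carrying the given weights."""
    z = np.zeros((2, 2))
    mx, my = z.copy(), z.copy()
    mx[0, 1] = mx[1, 0] = wx
    my[0, 1] = my[1, 0] = wy
    return _avw(mx, my), _mask([[0, 1], [1, 0]])


class TestDcenScore:
    @pytest.mark.parametrize(
        "wx,wy,expected",
        [
            (0.8, 0.8, 0.0),     # equal neighborhoods
            (0.8, -0.3, 1.0),    # opposite signs -> the stated maximum
            (0.8, 0.0, 1.0),     # weaker weight zero -> the stated maximum
            (0.6, 0.2, 0.5),     # hand evaluation: 0.4 / 0.8
        ],
    )
    def test_single_neighbor_values(self, wx, wy, expected):
        avw, mask = _single_neighbor(wx, wy)
        assert dcen_score(avw, mask)[0] == pytest.approx(expected)

    def test_empty_neighborhood_scores_zero(self):
        avw, _ = _single_neighbor(0.8, -0.3)
        empty = _mask(np.zeros((2, 2), int))
        assert np.all(dcen_score(avw, empty) == 0.0)

    @given(st.integers(0, 1000))
    def test_bounded_and_group_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 7)
        wx = rng.uniform(-1, 1, (n, n))
        wy = rng.uniform(-1, 1, (n, n))
        wx = (wx + wx.T) / 2
        wy = (wy + wy.T) / 2
        np.fill_diagonal(wx, 0)
        np.fill_diagonal(wy, 0)
        a = rng.integers(0, 2, (n, n))
        a = ((a + a.T) > 0).astype(np.int8)
        np.fill_diagonal(a, 0)
        d = dcen_score(_avw(wx, wy), _mask(a))
        assert np.all((d >= 0) & (d <= 1 + 1e-12))
        d_swapped = dcen_score(_avw(wy, wx), _mask(a))
        assert np.allclose(d, d_swapped, atol=1e-12)


class TestAverageWeights:
    def test_group_means(self, make_dataset):
        ds = make_dataset(n_genes=3, n_per_group=2, m=5, seed=0)
        model = DCeN(ds)
        avw = average_weights(model.networks, ds.group_of)
        nets = {n.individual_id: n for n in model.networks}
        expected = (nets["X1"].w + nets["X2"].w) / 2
        assert np.allclose(avw.wbar_x, expected, atol=1e-12)

    def test_scalar_examples(self):
        # 0.9 and 0.7 average to 0.8; +0.8 and -0.8 cancel
        assert np.mean([0.9, 0.7]) == pytest.approx(0.8)
        from dcenkit.conet import IndividualCorrelationNetwork

        def net(ind, w01):
            r = np.array([[1.0, np.sign(w01)], [np.sign(w01), 1.0]])
            p = np.zeros((2, 2))
            w = np.array([[0.0, w01], [w01, 0.0]])
            return IndividualCorrelationNetwork(ind, ["a", "b"], r, p, w, 5)

        avw = average_weights(
            [net("i1", 0.8), net("i2", -0.8), net("j1", 0.5)],
            {"i1": "X", "i2": "X", "j1": "Y"},
        )
        assert avw.wbar_x[0, 1] == pytest.approx(0.0)
        assert avw.wbar_y[0, 1] == pytest.approx(0.5)  # single individual


class TestOracleEquivalence:
    def test_small_instances_match_scalar_recomputation(self, make_dataset):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            ds = make_dataset(
                n_genes=int(rng.integers(4, 8)),
                n_per_group=int(rng.integers(2, 4)),
                m=5,
                seed=seed + 100,
            )
            res = DCeN(ds).fit()
            expected = oracle_dcen_scores(ds)
            for g, val in expected.items():
                assert res.scores[g] == pytest.approx(val, abs=1e-10)


class TestPermutationPvalues:
    def test_add_one_formula_with_rigged_null(self):
        observed = np.array([2.0, 0.0])
        null = np.random.default_rng(0).uniform(0, 1, size=(100, 50))
        p = pooled_permutation_pvalues(observed, null)
        assert p[0] == pytest.approx(1 / 5001)
        assert p[1] == pytest.approx(1.0)  # d = 0 never beats any null value

    def test_deterministic_given_seed(self, make_dataset):
        ds = make_dataset(n_genes=5, n_per_group=3, m=5, seed=1)
        p1 = DCeN(ds).fit(n_perm=20, seed=9).pvalues
        p2 = DCeN(ds).fit(n_perm=20, seed=9).pvalues
        assert np.array_equal(p1.to_numpy(), p2.to_numpy())

    def test_requires_two_individuals_per_group(self, make_dataset):
        ds = make_dataset(n_genes=4, n_per_group=1, m=5)
        with pytest.raises(ValueError, match="2 individuals"):
            DCeN(ds).fit(n_perm=10, seed=0)

    def test_seed_required(self, make_dataset):
        ds = make_dataset(n_genes=4, n_per_group=2, m=5)
        with pytest.raises(ValueError, match="seed"):
            DCeN(ds).fit(n_perm=10)


class TestSwitchingNeighborhood:
    def _random_avw(self, n, seed=0):
        rng = np.random.default_rng(seed)
        wx = rng.uniform(-1, 1, (n, n))
        wy = rng.uniform(-1, 1, (n, n))
        wx = (wx + wx.T) / 2
        wy = (wy + wy.T) / 2
        np.fill_diagonal(wx, 0)
        np.fill_diagonal(wy, 0)
        genes = [f"g{i:04d}" for i in range(n)]
        return _avw(wx, wy, genes)

    def test_selects_half_percent_of_genes(self):
        avw = self._random_avw(1000)
        ex, ey = switching_neighborhood(avw, "g0000")
        nodes = {g for a, b, _ in ex + ey for g in (a, b)}
        # focal + 5 selected genes at most appear in the edge sets
        assert len(nodes) <= 6
        # count of selected neighbors is ceil(0.005 * 1000) = 5
        diff = np.abs(avw.wbar_x[0] - avw.wbar_y[0])
        top5 = set(np.argsort(-diff[1:])[:5] + 1)
        for a, b, _ in ex + ey:
            for g in (a, b):
                idx = avw.genes.index(g)
                assert idx == 0 or idx in top5

    def test_edges_respect_cut(self):
        avw = self._random_avw(200, seed=3)
        ex, ey = switching_neighborhood(avw, "g0000", diff_fraction=0.05)
        for a, b, w in ex:
            assert abs(w) > 0.95
            i, j = avw.genes.index(a), avw.genes.index(b)
            assert avw.wbar_x[i, j] == pytest.approx(w)
        for _, _, w in ey:
            assert abs(w) > 0.95

    def test_degenerate_ties_lexicographic_and_identical_sets(self):
        n = 10
        wx = np.full((n, n), 0.99)
        np.fill_diagonal(wx, 0)
        genes = [f"g{i}" for i in range(n)]
        avw = _avw(wx, wx.copy(), genes)
        ex, ey = switching_neighborhood(avw, "g0", diff_fraction=0.2)
        assert ex == ey
        nodes = sorted({g for a, b, _ in ex for g in (a, b)})
        # ceil(0.2 * 10) = 2 zero-difference ties resolved lexicographically
        assert nodes == ["g0", "g1", "g2"]

    def test_invalid_fraction_rejected(self):
        avw = self._random_avw(10)
        with pytest.raises(ValueError):
            switching_neighborhood(avw, "g0000", diff_fraction=0.0)
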