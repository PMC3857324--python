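"""Average-profile, concatenation and individual-correlation baselines."""

import numpy as np
import pytest

from dcenkit.baselines import (
    ConnectivityModel,
    average_profile_network,
    concat_network,
    connectivity_rank,
    indcorr_network,
    GroupCorrelationNetwork,
)
from dcenkit.conet import build_all_networks, build_individual_network
from dcenkit.preprocess import center_individuals
from conftest import build_dataset


class TestAverageProfileNetwork:
    def test_single_individual_equals_within_individual_correlation(self):
        ds = build_dataset(n_genes=3, n_per_group=1, m=6, seed=0)
        net = average_profile_network(ds)
        within = build_individual_network(ds, "X1")
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(net.s_x[off], within.r[off], atol=1e-12)

    def test_time_shift_destroys_average_correlation(self):
        """Perfect within-individual pairs lose correlation after averaging.

        Two individuals see the same sharp pulse pair at shifted times; each
        individual's pair correlation is exactly 1, but the mean profiles mix
        the shifts and correlate the pair weakly.
        """
        m = 8
        t = np.linspace(0, 1, m)

        def pulse(c):
            return np.exp(-((t - c) ** 2) / (2 * 0.05**2))

        # genes: pulse at c and its negative (r = -1 within individual)
        rows = []
        values = []
        for group, centers in (("X", (0.25, 0.75)), ("Y", (0.25, 0.75))):
            for k, c in enumerate(centers):
                ind = f"{group}{k + 1}"
                for j in range(m):
                    rows.append((f"{ind}_t{j}", ind, group, float(j)))
                values.append(np.vstack([pulse(c), -pulse(c)]))
        import pandas as pd

        from dcenkit.io import ExpressionDataset

        ds = ExpressionDataset(
            genes=["up", "down"],
            design=pd.DataFrame(
                rows,
                columns=["sample_id", "individual_id", "group", "time"],
            ),
            values=np.concatenate(values, axis=1),
        )
        for ind in ds.individuals:
            within = build_individual_network(ds, ind)
            assert within.r[0, 1] == pytest.approx(-1.0)
        net = average_profile_network(ds)
        assert abs(net.s_x[0, 1]) == pytest.approx(1.0)  # still aligned pair
        # now make one individual's pulses land elsewhere: misaligned means
        shifted = ds.values.copy()
        shifted[:, :m] = np.vstack([pulse(0.5), -pulse(0.9)])
        ds2 = ds.with_values(shifted)
        assert abs(average_profile_network(ds2).s_x[0, 1]) < 0.9

    def test_identical_individuals_preserve_correlation(self):
        ds = build_dataset(n_genes=3, n_per_group=2, m=6, seed=1)
        vals = ds.values.copy()
        vals[:, 6:12] = vals[:, 0:6]  # X2 := X1
        ds = ds.with_values(vals)
        net = average_profile_network(ds)
        within = build_individual_network(ds, "X1")
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(net.s_x[off], within.r[off], atol=1e-12)

    def test_mismatched_time_grids_rejected(self):
        ds = build_dataset(n_genes=3, n_per_group=2, m=5, seed=2)
        design = ds.design.copy()
        design.loc[design["individual_id"] == "X2", "time"] += 0.5
        from dcenkit.io import ExpressionDataset

        ds2 = ExpressionDataset(
            genes=ds.genes, design=design, values=ds.values
        )
        with pytest.raises(ValueError, match="time grid"):
            average_profile_network(ds2)


class TestConcatNetwork:
    def test_single_individual_equals_within_individual(self):
        ds = build_dataset(n_genes=3, n_per_group=1, m=6, seed=3)
        net = concat_network(ds)
        within = build_individual_network(ds, "X1")
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(net.s_x[off], within.r[off], atol=1e-12)

    def test_baseline_offsets_dominate_without_centering(self):
        ds = build_dataset(n_genes=2, n_per_group=2, m=6, seed=4)
        vals = ds.values.copy()
        # individual X2 has huge baseline offsets of opposite sign per gene
        vals[0, 6:12] += 50
        vals[1, 6:12] -= 50
        ds = ds.with_values(vals)
        raw = concat_network(ds, center=False)
        centered = concat_network(ds, center=True)
        assert raw.s_x[0, 1] != pytest.approx(centered.s_x[0, 1], abs=0.05)
        assert raw.s_x[0, 1] < -0.9  # offsets force strong anti-correlation
        assert abs(centered.s_x[0, 1]) < 0.9

    def test_centering_idempotent_on_centered_data(self):
        ds = center_individuals(build_dataset(seed=5))
        a = concat_network(ds, center=False)
        b = concat_network(ds, center=True)
        assert np.allclose(a.s_x, b.s_x, atol=1e-12)
        assert np.allclose(a.s_y, b.s_y, atol=1e-12)


class TestIndcorrNetwork:
    def test_group_mean_of_raw_correlations(self):
        ds = build_dataset(n_genes=3, n_per_group=2, m=6, seed=6)
        nets = build_all_networks(ds)
        net = indcorr_network(nets, ds.group_of)
        by_id = {n.individual_id: n for n in nets}
        expected = (by_id["X1"].r[0, 1] + by_id["X2"].r[0, 1]) / 2
        assert net.s_x[0, 1] == pytest.approx(expected)

    def test_opposite_correlations_cancel(self):
        # arithmetic of the averaging contract: (+1) + (-1) -> 0
        ds = build_dataset(n_genes=2, n_per_group=2, m=5, seed=7)
        vals = ds.values.copy()
        vals[1, 0:5] = vals[0, 0:5]       # X1: r = +1
        vals[1, 5:10] = -vals[0, 5:10]    # X2: r = -1
        ds = ds.with_values(vals)
        net = indcorr_network(build_all_networks(ds), ds.group_of)
        assert net.s_x[0, 1] == pytest.approx(0.0, abs=1e-12)


class TestConnectivityRank:
    def _net(self, sx, sy):
        n = len(sx)
        return GroupCorrelationNetwork(
            method="indcorr",
            genes=[f"g{i}" for i in range(n)],
            x_label="X",
            y_label="Y",
            s_x=np.asarray(sx, float),
            s_y=np.asarray(sy, float),
        )

    def test_equal_networks_score_zero(self):
        s = np.array([[0, 0.5, -0.2], [0.5, 0, 0.8], [-0.2, 0.8, 0]])
        ranked = connectivity_rank(self._net(s, s.copy()))
        assert np.allclose(ranked.table["score"], 0.0)

    def test_unit_edge_scores_one_for_any_beta(self):
        sx = np.array([[0.0, 1.0], [1.0, 0.0]])
        sy = np.zeros((2, 2))
        for beta in (1.0, 3.0, 6.0):
            ranked = connectivity_rank(self._net(sx, sy), beta=beta)
            assert ranked.score_of("g0") == pytest.approx(1.0)

    def test_three_gene_hand_computation(self):
        sx = np.array([[0, 0.9, 0.1], [0.9, 0, 0.5], [0.1, 0.5, 0]])
        sy = np.array([[0, 0.2, 0.6], [0.2, 0, 0.5], [0.6, 0.5, 0]])
        beta = 2.0
        ranked = connectivity_rank(self._net(sx, sy), beta=beta)
        # scalar loop oracle
        for g in range(3):
            expected = sum(
                abs(abs(sx[g, h]) ** beta - abs(sy[g, h]) ** beta)
                for h in range(3)
                if h != g
            )
            assert ranked.score_of(f"g{g}") == pytest.approx(expected)

    def test_beta_below_one_rejected(self):
        with pytest.raises(ValueError):
            connectivity_rank(self._net(np.zeros((2, 2)), np.zeros((2, 2))), 0.5)


class TestConnectivityModel:
    def test_gene_order_permutation_invariance(self):
        ds = build_dataset(n_genes=5, n_per_group=2, m=6, seed=8)
        perm = [3, 0, 4, 1, 2]
        shuffled = ds.subset_genes([ds.genes[i] for i in perm])
        for method in ("average", "concat", "indcorr"):
            a = ConnectivityModel(ds, method).fit().ranking
            b = ConnectivityModel(shuffled, method).fit().ranking
            assert a.genes == b.genes

    def test_summary_mentions_method(self):
        ds = build_dataset(seed=9)
        out = ConnectivityModel(ds, "indcorr").fit().summary()
        assert "indcorr" in out
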