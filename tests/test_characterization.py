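import numpy as np
import pandas as pd
import pytest

from dynsub.characterization import (
    contrast_expression,
    core_periphery_index,
    edge_contrast,
    expression_hierarchy_correlation,
    relative_expression,
    system_core_periphery_test,
    system_interaction_test,
)
from dynsub.networks import SystemPartition, devectorize, edge_list


def _meta(n_subjects=4, tasks=("a", "b"), conditions=("low", "high"), blocks=2):
    rows = []
    for s in range(n_subjects):
        for task in tasks:
            for cond in conditions:
                for block in range(blocks):
                    for sign in ("pos", "neg"):
                        rows.append({"subject": f"s{s}", "task": task,
                                     "condition": cond, "block": block,
                                     "sign": sign})
    return pd.DataFrame(rows)


class TestRelativeExpression:
    def test_subtraction(self):
        meta = _meta(n_subjects=1, tasks=("a",), conditions=("low",), blocks=1)
        H = np.array([[0.7, 0.2]])
        summary = relative_expression(H, meta, exclude_fixation=False)
        assert summary.blocks["relative"].iloc[0] == pytest.approx(0.5)

    def test_equal_channels_zero(self):
        meta = _meta(n_subjects=1, tasks=("a",), conditions=("low",), blocks=1)
        summary = relative_expression(np.array([[0.4, 0.4]]), meta)
        assert summary.blocks["relative"].iloc[0] == pytest.approx(0.0)

    def test_sign_class_labels(self, rng):
        meta = _meta()
        m, T = 3, len(meta)
        H = rng.uniform(0, 1, (m, T))
        pos_cols = (meta["sign"] == "pos").to_numpy()
        H[0, pos_cols] += 2.0  # positively dominant
        H[2, ~pos_cols] += 2.0  # negatively dominant
        summary = relative_expression(H, meta)
        ranking = summary.ranking.set_index("subgraph")
        assert ranking.loc[0, "sign_class"] == "positive"
        assert ranking.loc[0, "label"] == "A"
        assert ranking.loc[2, "sign_class"] == "negative"
        # ranks are a permutation of subgraphs
        assert sorted(summary.ranking["subgraph"]) == [0, 1, 2]

    def test_fixation_excluded_by_default(self):
        meta = _meta(n_subjects=1, tasks=("a",),
                     conditions=("fixation", "low"), blocks=1)
        H = np.ones((1, len(meta)))
        summary = relative_expression(H, meta)
        assert set(summary.blocks["condition"]) == {"low"}

    def test_missing_partner_rejected(self):
        meta = _meta(n_subjects=1, tasks=("a",), conditions=("low",), blocks=1)
        meta = meta[meta["sign"] == "pos"]
        with pytest.raises(ValueError, match="sign-channel partner"):
            relative_expression(np.ones((1, 1)), meta)


class TestCorePeripheryIndex:
    def test_all_within_gives_plus_one(self):
        # block-diagonal: every system internally connected, no cross edges
        labels = np.repeat(["a", "b", "c"], 4)
        w = np.zeros((12, 12))
        for start in (0, 4, 8):
            w[start:start + 4, start:start + 4] = 1.0
        np.fill_diagonal(w, 0.0)
        result = core_periphery_index(w, SystemPartition(labels))
        assert result.index == pytest.approx(1.0)

    def test_all_between_gives_minus_one(self):
        labels = np.repeat(["a", "b"], 5)
        w = np.ones((10, 10))
        w[:5, :5] = 0.0
        w[5:, 5:] = 0.0
        result = core_periphery_index(w, SystemPartition(labels))
        assert result.index == pytest.approx(-1.0)

    def test_uniform_graph_gives_zero(self):
        w = np.ones((4, 4))
        np.fill_diagonal(w, 0.0)
        result = core_periphery_index(w, SystemPartition(["a", "a", "b", "b"]))
        assert result.index == pytest.approx(0.0)

    def test_bounded_on_random_subgraphs(self, rng):
        labels = np.repeat([f"s{i}" for i in range(5)], 6)
        partition = SystemPartition(labels)
        idx = edge_list(30)
        for _ in range(200):
            w = rng.uniform(0, 1, idx.shape[0])
            result = core_periphery_index(w, partition, edge_index=idx)
            assert -1.0 <= result.index <= 1.0

    def test_single_system_rejected(self):
        w = np.ones((4, 4))
        np.fill_diagonal(w, 0.0)
        with pytest.raises(ValueError):
            core_periphery_index(w, SystemPartition(["a"] * 4))

    def test_negative_weights_rejected(self):
        w = -np.ones((4, 4))
        np.fill_diagonal(w, 0.0)
        with pytest.raises(ValueError):
            core_periphery_index(w, SystemPartition(["a", "a", "b", "b"]))


class TestCorePeripheryPermutation:
    def test_constant_weights_nothing_significant(self):
        labels = np.repeat(["a", "b", "c"], 5)
        w = devectorize(np.ones(edge_list(15).shape[0]), 15)
        result = system_core_periphery_test(w, SystemPartition(labels),
                                            n_perm=200, seed=0)
        assert np.all(result.core_p == 1.0)
        assert np.all(result.periphery_p == 1.0)

    def test_planted_system_core_significant(self, rng):
        labels = np.repeat([f"s{i}" for i in range(4)], 5)
        w = devectorize(rng.uniform(0, 0.05, edge_list(20).shape[0]), 20)
        w[:5, :5] += 1.0
        np.fill_diagonal(w, 0.0)
        w = (w + w.T) / 2
        result = system_core_periphery_test(w, SystemPartition(labels),
                                            n_perm=1000, seed=1)
        assert result.core_p_adj[0] <= 0.05
        assert np.all(result.core_p_adj[1:] > 0.05)

    def test_plus_one_bound(self, rng):
        # observed score above every surrogate -> p = 1/(n_perm+1)
        labels = np.repeat(["a", "b"], 5)
        w = np.zeros((10, 10))
        w[:5, :5] = 1.0
        np.fill_diagonal(w, 0.0)
        result = system_core_periphery_test(w, SystemPartition(labels),
                                            n_perm=500, seed=2)
        assert result.core_p[0] == pytest.approx(1.0 / 501.0)


class TestSystemInteractionTest:
    def test_planted_within_block_significant(self, rng):
        labels = np.repeat([f"s{i}" for i in range(4)], 5)
        w = devectorize(rng.uniform(0, 0.05, edge_list(20).shape[0]), 20)
        w[:5, :5] += 1.0
        np.fill_diagonal(w, 0.0)
        w = (w + w.T) / 2
        table = system_interaction_test(w, SystemPartition(labels),
                                        n_perm=1000, seed=3)
        assert table["within_p_adj"].iloc[0] <= 0.05

    def test_uniform_nothing_significant(self):
        labels = np.repeat(["a", "b", "c"], 5)
        w = devectorize(np.ones(edge_list(15).shape[0]), 15)
        table = system_interaction_test(w, SystemPartition(labels),
                                        n_perm=200, seed=4)
        assert np.all(table["within_p"] == 1.0)
        assert np.all(table["between_p"] == 1.0)

    def test_null_subgraph_calibrated_smoke(self, rng):
        # a permuted copy of any subgraph behaves like the null
        labels = np.repeat([f"s{i}" for i in range(3)], 8)
        partition = SystemPartition(labels)
        idx = edge_list(24)
        pvals = []
        for _ in range(20):
            w = rng.uniform(0, 1, idx.shape[0])
            table = system_interaction_test(w, partition, n_perm=200,
                                            seed=int(rng.integers(2**31)),
                                            edge_index=idx)
            pvals.extend(table["within_p"])
        rate = np.mean(np.asarray(pvals) < 0.05)
        assert rate < 0.25  # loose smoke bound; acceptance tightens this


class TestHierarchyCorrelation:
    def _summary(self, H, meta):
        return relative_expression(H, meta, exclude_fixation=False)

    def test_identical_groupings_rho_one(self, rng):
        meta = _meta()
        H = rng.uniform(0, 1, (4, len(meta)))
        summary = self._summary(H, meta)
        rho, _ = expression_hierarchy_correlation(summary, {"task": "a"},
                                                  {"task": "a"})
        assert rho == pytest.approx(1.0)

    def test_reversed_ranks_rho_minus_one(self):
        meta = _meta(n_subjects=2)
        m = 4
        H = np.zeros((m, len(meta)))
        pos = (meta["sign"] == "pos").to_numpy()
        task_a = (meta["task"] == "a").to_numpy()
        for k in range(m):
            H[k, pos & task_a] = k + 1.0
            H[k, pos & ~task_a] = m - k
        summary = self._summary(H, meta)
        rho, _ = expression_hierarchy_correlation(summary, {"task": "a"},
                                                  {"task": "b"})
        assert rho == pytest.approx(-1.0)

    def test_too_few_subgraphs_rejected(self, rng):
        meta = _meta()
        summary = self._summary(rng.uniform(0, 1, (2, len(meta))), meta)
        with pytest.raises(ValueError):
            expression_hierarchy_correlation(summary, {"task": "a"}, {"task": "b"})


class TestContrastExpression:
    def test_identical_groups_nothing_significant(self, rng):
        meta = _meta()
        H = rng.uniform(0, 1, (3, len(meta)))
        # make task b columns identical to task a columns
        a_cols = np.where((meta["task"] == "a"))[0]
        b_cols = np.where((meta["task"] == "b"))[0]
        H[:, b_cols] = H[:, a_cols]
        summary = relative_expression(H, meta, exclude_fixation=False)
        result = contrast_expression(summary, {"task": "a"}, {"task": "b"})
        assert np.all(result.table["t"] == 0.0)
        assert not result.table["significant"].any()

    def test_shifted_subgraph_detected(self, rng):
        meta = _meta(n_subjects=8)
        H = rng.uniform(0, 1, (4, len(meta)))
        shift_cols = ((meta["task"] == "a") & (meta["sign"] == "pos")).to_numpy()
        H[2, shift_cols] += 5.0
        summary = relative_expression(H, meta, exclude_fixation=False)
        result = contrast_expression(summary, {"task": "a"}, {"task": "b"})
        row = result.table.set_index("subgraph").loc[2]
        assert row["significant"]
        assert row["direction"] == "a>b"

    def test_adjusted_dominates_raw(self, rng):
        meta = _meta(n_subjects=6)
        H = rng.uniform(0, 1, (5, len(meta)))
        summary = relative_expression(H, meta, exclude_fixation=False)
        result = contrast_expression(summary, {"condition": "low"},
                                     {"condition": "high"})
        assert np.all(result.table["p_adj"] >= result.table["p"] - 1e-12)


class TestEdgeContrast:
    def test_identical_groups_no_edges(self, small_config):
        results = edge_contrast(small_config, {"condition": "low"},
                                {"condition": "low"})
        for res in results.values():
            assert not res.table["significant"].any()

    def test_shifted_edge_detected(self, rng):
        from dynsub.networks import ConfigurationMatrix

        n_subjects, n_regions = 10, 4
        idx = edge_list(n_regions)
        rows = []
        for s in range(n_subjects):
            for cond in ("low", "high"):
                for block in range(2):
                    for sign in ("pos", "neg"):
                        rows.append({"subject": f"s{s}", "task": "t",
                                     "condition": cond, "block": block,
                                     "sign": sign})
        meta = pd.DataFrame(rows)
        weights = rng.uniform(0.0, 0.2, (idx.shape[0], len(meta)))
        shifted = ((meta["condition"] == "low") & (meta["sign"] == "pos")).to_numpy()
        weights[0, shifted] = rng.uniform(0.85, 0.95, shifted.sum())
        config = ConfigurationMatrix(weights=weights, edge_index=idx, meta=meta)
        results = edge_contrast(config, {"condition": "low"},
                                {"condition": "high"})
        table = results["pos"].table
        assert bool(table.loc[table["edge"] == 0, "significant"].iloc[0])
        assert table.loc[table["edge"] == 0, "mean_dz"].iloc[0] > 0
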