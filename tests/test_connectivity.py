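import numpy as np
import pytest
from hypothesis import given, strategies as st

from netpyramid.connectivity import (edge_budget, extract_node_timecourses,
                                     pearson_connectivity,
                                     proportional_threshold, read_matrix_tsv,
                                     write_matrix_tsv)
from netpyramid.containers import ConnectivityMatrix, SubjectTimeseries
from netpyramid.errors import DegenerateInputError, EmptyNodeError


def _ts(data, labels=None, tr=2.0, scale=None):
    data = np.asarray(data, dtype=float)
    return SubjectTimeseries(
        data=data, tr_seconds=tr, unit_ids=np.arange(data.shape[1]),
        subject_id="s", group="control",
        unit_labels=None if labels is None else np.asarray(labels),
        scale=scale)


def _cm(values, scale=1):
    values = np.asarray(values, dtype=float)
    return ConnectivityMatrix(values=values,
                              node_ids=np.arange(values.shape[0]),
                              scale=scale, subject_id="s")


class TestNodeExtraction:
    def test_identical_voxels_pass_through(self, toy_hierarchy):
        x = np.sin(np.linspace(0, 7, 30))
        data = np.tile(x[:, None], (1, 24))
        ts = _ts(data, labels=np.repeat(np.arange(1, 13), 2))
        node = extract_node_timecourses(ts, ts.unit_labels, toy_hierarchy, 1)
        for j in range(node.n_units):
            np.testing.assert_allclose(node.data[:, j], x)

    def test_arithmetic_mean_of_two_voxels(self):
        from conftest import make_toy_hierarchy

        h = make_toy_hierarchy(2, 1)
        data = np.array([[1.0, 3.0, 5.0, 5.0],
                         [3.0, 5.0, 9.0, 9.0],
                         [5.0, 7.0, 1.0, 1.0]])
        ts = _ts(data, labels=[1, 1, 2, 2])
        node = extract_node_timecourses(ts, ts.unit_labels, h, 1)
        np.testing.assert_allclose(node.data[:, 0], [2.0, 4.0, 6.0])

    def test_coarse_node_is_voxel_weighted_mean_of_children(self, toy_hierarchy):
        """Nested means: a module's series equals the voxel-count-weighted
        mean of its member parcels' node series."""
        rng = np.random.default_rng(5)
        labels = np.concatenate([np.repeat(p, 1 + (p % 3))
                                 for p in range(1, 13)])
        data = rng.normal(size=(40, labels.size))
        ts = _ts(data, labels=labels)
        node1 = extract_node_timecourses(ts, labels, toy_hierarchy, 1)
        node2 = extract_node_timecourses(ts, labels, toy_hierarchy, 2)
        counts = np.array([np.sum(labels == p) for p in range(1, 13)])
        for mi, module in enumerate(toy_hierarchy.node_ids(2)):
            kids = toy_hierarchy.children(2, int(module))
            kid_idx = [int(k) - 1 for k in kids]
            weighted = (node1.data[:, kid_idx] * counts[kid_idx]).sum(axis=1) \
                / counts[kid_idx].sum()
            np.testing.assert_allclose(node2.data[:, mi], weighted, atol=1e-12)

    def test_empty_parcel_raises_with_name(self, toy_hierarchy):
        ts = _ts(np.random.default_rng(0).normal(size=(10, 11)),
                 labels=np.arange(1, 12))     # parcel 12 missing
        with pytest.raises(EmptyNodeError, match="p12"):
            extract_node_timecourses(ts, ts.unit_labels, toy_hierarchy, 1)


class TestPearsonConnectivity:
    def test_affine_copies_fully_correlated(self):
        x = np.random.default_rng(1).normal(size=12)
        ts = _ts(np.column_stack([x, 2 * x + 1]), scale=1)
        m = pearson_connectivity(ts)
        assert m.values[0, 1] == pytest.approx(1.0)
        assert m.values[0, 0] == 0.0            # diagonal zeroed

    def test_sign_flip_anticorrelated(self):
        x = np.random.default_rng(2).normal(size=12)
        m = pearson_connectivity(_ts(np.column_stack([x, -x]), scale=1))
        assert m.values[0, 1] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        data = np.array([[2.0, 7.0, 1.0],
                         [4.0, 5.0, 2.0],
                         [6.0, 6.0, 2.0],
                         [8.0, 2.0, 5.0],
                         [10.0, 1.0, 4.0],
                         [12.0, 3.0, 9.0]])
        m = pearson_connectivity(_ts(data, scale=1))

        def hand_r(x, y):
            xd, yd = x - x.mean(), y - y.mean()
            return (xd * yd).sum() / np.sqrt((xd ** 2).sum() * (yd ** 2).sum())

        for i in range(3):
            for j in range(3):
                expect = 0.0 if i == j else hand_r(data[:, i], data[:, j])
                assert m.values[i, j] == pytest.approx(expect, abs=1e-12)

    def test_zero_variance_node_rejected(self):
        data = np.column_stack([np.arange(5.0), np.ones(5)])
        with pytest.raises(DegenerateInputError):
            pearson_connectivity(_ts(data, scale=1))

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson_connectivity(_ts(np.random.default_rng(0).normal(size=(2, 3)),
                                     scale=1))


class TestProportionalThreshold:
    def test_p_one_complete_graph(self):
        vals = np.random.default_rng(0).uniform(-1, 1, size=(5, 5))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0)
        g = proportional_threshold(_cm(vals), 1.0)
        assert g.n_edges == 10
        assert np.array_equal(g.adjacency,
                              1 - np.eye(5, dtype=np.int8))

    def test_p_zero_empty_graph(self):
        vals = np.random.default_rng(1).uniform(-1, 1, size=(6, 6))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0)
        g = proportional_threshold(_cm(vals), 0.0)
        assert g.n_edges == 0

    def test_top_three_of_six_distinct_values(self):
        vals = np.zeros((4, 4))
        pairs = [(0, 1, 0.9), (0, 2, 0.5), (0, 3, -0.2),
                 (1, 2, 0.7), (1, 3, 0.1), (2, 3, 0.3)]
        for i, j, v in pairs:
            vals[i, j] = vals[j, i] = v
        g = proportional_threshold(_cm(vals), 0.5)
        kept = {(i, j) for i, j in zip(*np.nonzero(np.triu(g.adjacency)))}
        assert kept == {(0, 1), (1, 2), (0, 2)}

    def test_half_up_rounding_for_odd_pair_count(self):
        # 6 nodes -> 15 pairs; P = 0.5 keeps 8 edges
        assert edge_budget(6, 0.5) == 8

    def test_signed_ranking_drops_strong_negatives(self):
        vals = np.zeros((3, 3))
        vals[0, 1] = vals[1, 0] = -0.95
        vals[0, 2] = vals[2, 0] = 0.1
        vals[1, 2] = vals[2, 1] = 0.2
        g = proportional_threshold(_cm(vals), 1 / 3)
        assert g.adjacency[1, 2] == 1 and g.adjacency[0, 1] == 0

    def test_absolute_mode_keeps_strong_negatives(self):
        vals = np.zeros((3, 3))
        vals[0, 1] = vals[1, 0] = -0.95
        vals[0, 2] = vals[2, 0] = 0.1
        vals[1, 2] = vals[2, 1] = 0.2
        g = proportional_threshold(_cm(vals), 1 / 3, mode="absolute")
        assert g.adjacency[0, 1] == 1

    def test_tie_break_deterministic_row_major(self):
        vals = np.full((4, 4), 0.5)
        np.fill_diagonal(vals, 0)
        g = proportional_threshold(_cm(vals), 0.5)
        kept = sorted(zip(*np.nonzero(np.triu(g.adjacency))))
        assert kept == [(0, 1), (0, 2), (0, 3)]
        g2 = proportional_threshold(_cm(vals), 0.5)
        assert np.array_equal(g.adjacency, g2.adjacency)

    @given(st.integers(3, 20), st.floats(0.0, 1.0), st.integers(0, 10_000))
    def test_edge_count_contract(self, n, p, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(-1, 1, size=(n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0)
        g = proportional_threshold(_cm(vals), p)
        assert g.n_edges == edge_budget(n, p)

    @given(st.integers(4, 12), st.integers(0, 10_000))
    def test_invariant_to_monotone_transform(self, n, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(-1, 1, size=(n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0)
        g1 = proportional_threshold(_cm(vals), 0.5)
        warped = np.tanh(1.7 * vals)            # strictly increasing
        np.fill_diagonal(warped, 0)
        g2 = proportional_threshold(_cm(warped), 0.5)
        assert np.array_equal(g1.adjacency, g2.adjacency)


def test_matrix_tsv_roundtrip(tmp_path):
    vals = np.random.default_rng(9).uniform(-1, 1, size=(5, 5))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 0)
    m = ConnectivityMatrix(values=vals, node_ids=np.array([3, 5, 7, 9, 11]),
                           scale=2, subject_id="s1")
    path = tmp_path / "m.tsv"
    write_matrix_tsv(m, path)
    back = read_matrix_tsv(path, scale=2, subject_id="s1")
    np.testing.assert_allclose(back.values, vals, atol=1e-7)
    assert back.node_ids.tolist() == [3, 5, 7, 9, 11]
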