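"""Difference/similarity matrices, module detection, edge export."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diffmet import diffnet
from diffmet.datatypes import UNASSIGNED, CorrelationMatrix
from diffmet.diffnet import (
    DataError,
    correlation_matrix,
    detect_modules,
    difference_matrix,
    differential_modules,
    export_edges,
    preserved_modules,
    similarity_matrix,
)
from conftest import make_table


def random_correlation(n, seed):
    """A valid correlation matrix from random data."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 3 * n))
    R = np.corrcoef(X)
    return CorrelationMatrix(R, [f"F{i:04d}" for i in range(n)], f"rand{seed}", 3 * n)


def naive_d_s(R1, R2, beta):
    """Scalar double-loop oracle for D and S."""
    n = R1.shape[0]
    D = np.zeros((n, n))
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                D[i, j] = abs((R1[i, j] - R2[i, j]) / 2.0) ** (beta / 2.0)
            S[i, j] = (1 - D[i, j]) * abs(R1[i, j]) * abs(R2[i, j])
    return D, S


class TestCorrelationMatrix:
    def _table(self, vals, dev=None):
        vals = np.asarray(vals, float)
        ann = pd.DataFrame({
            "sex": ["male"] * vals.shape[1],
            "dev_temp": dev if dev is not None else [18] * vals.shape[1],
        })
        return make_table(vals, sample_ann=ann)

    def test_duplicated_feature_has_r_one_and_negation_minus_one(self):
        base = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        t = self._table(np.vstack([base, base, -base]))
        C = correlation_matrix(t, {"dev_temp": 18})
        assert C.values[0, 1] == pytest.approx(1.0)
        assert C.values[0, 2] == pytest.approx(-1.0)

    def test_independent_features_nearly_uncorrelated(self):
        rng = np.random.default_rng(0)
        t = self._table(rng.standard_normal((30, 500)))
        C = correlation_matrix(t, {"dev_temp": 18})
        iu, ju = np.triu_indices(30, k=1)
        offdiag = np.abs(C.values[iu, ju])
        assert np.quantile(offdiag, 0.99) < 0.15

    def test_too_few_samples_rejected(self):
        t = self._table(np.random.default_rng(0).normal(size=(3, 3)))
        with pytest.raises(DataError, match="4"):
            correlation_matrix(t, {"dev_temp": 18})

    def test_zero_variance_feature_named(self):
        vals = np.vstack([np.ones(6), np.arange(6.0)])
        t = self._table(vals)
        with pytest.raises(DataError, match="F0001"):
            correlation_matrix(t, {"dev_temp": 18})


class TestDifferenceAndSimilarity:
    def test_identical_conditions_give_zero_d_and_r_squared_s(self):
        for seed in range(5):
            C = random_correlation(15, seed)
            D = difference_matrix(C, C, beta=5)
            S = similarity_matrix(C, C, beta=5)
            assert np.allclose(D.values, 0.0)
            offdiag = ~np.eye(15, dtype=bool)
            assert np.allclose(S.values[offdiag], (C.values**2)[offdiag])

    def test_scalar_examples(self):
        R1 = np.array([[1.0, 0.8], [0.8, 1.0]])
        R2 = np.array([[1.0, 0.2], [0.2, 1.0]])
        C1 = CorrelationMatrix(R1, ["a", "b"], "t1", 10)
        C2 = CorrelationMatrix(R2, ["a", "b"], "t2", 10)
        D = difference_matrix(C1, C2, beta=5)
        S = similarity_matrix(C1, C2, beta=5)
        assert D.values[0, 1] == pytest.approx(0.3**2.5)  # ~0.0493
        assert S.values[0, 1] == pytest.approx((1 - 0.3**2.5) * 0.16)  # ~0.1521

    def test_maximal_disagreement_gives_d_one(self):
        C1 = CorrelationMatrix(np.array([[1.0, 1.0], [1.0, 1.0]]), ["a", "b"], "t1", 9)
        C2 = CorrelationMatrix(np.array([[1.0, -1.0], [-1.0, 1.0]]), ["a", "b"], "t2", 9)
        assert difference_matrix(C1, C2, beta=5).values[0, 1] == pytest.approx(1.0)

    def test_matches_double_loop_oracle(self):
        for seed in range(3):
            C1 = random_correlation(20, seed)
            C2 = random_correlation(20, seed + 100)
            D = difference_matrix(C1, C2, beta=5).values
            S = similarity_matrix(C1, C2, beta=5).values
            Do, So = naive_d_s(C1.values, C2.values, 5)
            offdiag = ~np.eye(20, dtype=bool)
            assert np.abs(D - Do)[offdiag].max() < 1e-12
            assert np.abs(S - So)[offdiag].max() < 1e-12

    def test_entries_bounded_in_unit_interval(self):
        C1 = random_correlation(25, 1)
        C2 = random_correlation(25, 2)
        D = difference_matrix(C1, C2, beta=5).values
        S = similarity_matrix(C1, C2, beta=5).values
        assert ((D >= 0) & (D <= 1)).all()
        assert ((S >= 0) & (S <= 1)).all()
        assert (S <= np.abs(C1.values) * np.abs(C2.values) + 1e-15).all()

    @settings(deadline=None, max_examples=30)
    @given(
        r1=st.floats(-1, 1), r2=st.floats(-1, 1),
        beta=st.integers(min_value=1, max_value=12),
    )
    def test_higher_beta_never_increases_d(self, r1, r2, beta):
        # beta de-emphasises small correlation differences: |dr/2| <= 1 so
        # raising the exponent can only shrink D
        C1 = CorrelationMatrix(np.array([[1.0, r1], [r1, 1.0]]), ["a", "b"], "x", 8)
        C2 = CorrelationMatrix(np.array([[1.0, r2], [r2, 1.0]]), ["a", "b"], "y", 8)
        d_lo = difference_matrix(C1, C2, beta=beta).values[0, 1]
        d_hi = difference_matrix(C1, C2, beta=beta + 1).values[0, 1]
        assert d_hi <= d_lo + 1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            difference_matrix(random_correlation(5, 0), random_correlation(6, 1))

    def test_non_integer_beta_rejected(self):
        with pytest.raises(ValueError):
            difference_matrix(random_correlation(5, 0), random_correlation(5, 1), beta=2.5)


class TestDetectModules:
    def test_all_zero_dissimilarity_one_degenerate_module(self):
        ids = [f"F{i}" for i in range(15)]
        with pytest.warns(UserWarning, match="single module"):
            out = detect_modules(np.zeros((15, 15)), ids, min_size=10)
        assert out.n_modules == 1
        assert set(out.labels) == {"turquoise"}

    def test_fewer_features_than_min_size_all_grey(self):
        ids = [f"F{i}" for i in range(5)]
        with pytest.warns(UserWarning, match="min_size"):
            out = detect_modules(np.ones((5, 5)) - np.eye(5), ids, min_size=10)
        assert set(out.labels) == {UNASSIGNED}

    def test_feature_order_invariance_up_to_renaming(self, planted_network):
        table, plastic, preserved = planted_network
        C1 = correlation_matrix(table, {"dev_temp": 18})
        C2 = correlation_matrix(table, {"dev_temp": 27})
        base = differential_modules(C1, C2)
        rng = np.random.default_rng(4)
        perm = rng.permutation(table.n_features)
        shuffled = table.subset_features([table.feature_ids[i] for i in perm])
        P1 = correlation_matrix(shuffled, {"dev_temp": 18})
        P2 = correlation_matrix(shuffled, {"dev_temp": 27})
        out = differential_modules(P1, P2)
        # same partition of feature ids
        part_a = {frozenset(v) for v in base.modules().values()}
        part_b = {frozenset(v) for v in out.modules().values()}
        assert part_a == part_b

    def test_plastic_block_recovered_from_differential_clustering(self, planted_network):
        table, plastic, _ = planted_network
        C1 = correlation_matrix(table, {"dev_temp": 18})
        C2 = correlation_matrix(table, {"dev_temp": 27})
        label, jac = diffnet.best_match(differential_modules(C1, C2), plastic)
        assert jac >= 0.8

    def test_preserved_block_recovered_from_similarity_clustering(self, planted_network):
        table, _, preserved = planted_network
        C1 = correlation_matrix(table, {"dev_temp": 18})
        C2 = correlation_matrix(table, {"dev_temp": 27})
        label, jac = diffnet.best_match(preserved_modules(C1, C2), preserved)
        assert jac >= 0.8


class TestExportEdges:
    def _corr(self, vals):
        n = len(vals)
        return CorrelationMatrix(np.asarray(vals, float), [f"F{i}" for i in range(n)], "c", 9)

    def test_threshold_inclusive_on_magnitude(self):
        C = self._corr([[1, 0.71, -0.75], [0.71, 1, 0.5], [-0.75, 0.5, 1]])
        edges = export_edges(C, 0.7)
        assert len(edges) == 2
        assert set(edges["sign"]) == {"+", "-"}

    def test_threshold_one_keeps_only_exact_unit_pairs(self):
        C = self._corr([[1, 0.999, 1.0], [0.999, 1, 0.5], [1.0, 0.5, 1]])
        edges = export_edges(C, 1.0)
        assert len(edges) == 1
        assert (edges.loc[0, "source"], edges.loc[0, "target"]) == ("F0", "F2")

    def test_identity_matrix_gives_no_edges(self):
        assert len(export_edges(self._corr(np.eye(4)), 0.7)) == 0

    def test_no_self_edges_and_each_pair_once(self):
        C = random_correlation(10, 3)
        edges = export_edges(C, 0.0001)
        assert len(edges) == 45
        assert (edges["source"] != edges["target"]).all()

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            export_edges(random_correlation(4, 0), 0.0)
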