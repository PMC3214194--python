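import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coexnet import (
    DiscretizationSpec,
    DiscretizedMatrix,
    ExpressionMatrix,
    InvalidDataError,
    InvalidSpecError,
    MIMatrix,
    MrnetResult,
    discretize_equalfreq,
    matrix_to_network,
    mi_matrix,
    mrnet,
    mutual_information,
    normalize_weights,
)
from coexnet.inference import column_entropy

from .oracles import entropy_plugin, mi_plugin, mrmr_exhaustive, mrnet_weights_exhaustive


def expr(cols: dict[str, list[float]]) -> ExpressionMatrix:
    names = list(cols)
    values = np.array(list(cols.values()), dtype=float).T
    return ExpressionMatrix(
        sample_ids=[f"s{i}" for i in range(values.shape[0])],
        probeset_ids=names,
        values=values,
    )


class TestDiscretize:
    def test_rank_based_split_of_six_values(self):
        x = expr({"g1": [5, 1, 3, 2, 6, 4], "g2": [0, 1, 2, 3, 4, 5]})
        d = discretize_equalfreq(x, DiscretizationSpec(nbins=2))
        assert d.values[:, 0].tolist() == [1, 0, 0, 0, 1, 1]
        assert d.values[:, 1].tolist() == [0, 0, 0, 1, 1, 1]

    def test_constant_column_split_by_stable_tie_rule(self):
        x = expr({"g1": [7, 7, 7, 7], "g2": [1, 2, 3, 4]})
        d = discretize_equalfreq(x, DiscretizationSpec(nbins=2))
        assert d.values[:, 0].tolist() == [0, 0, 1, 1]

    def test_default_nbins_is_floor_sqrt_n(self):
        x = expr({"g1": list(range(100)), "g2": list(range(100))})
        d = discretize_equalfreq(x)
        assert d.nbins == 10
        x2 = expr({"g1": list(range(50)), "g2": list(range(50))})
        assert discretize_equalfreq(x2).nbins == 7

    def test_uneven_blocks_first_bins_get_extra(self):
        x = expr({"g1": [10, 20, 30, 40, 50], "g2": [1, 2, 3, 4, 5]})
        d = discretize_equalfreq(x, DiscretizationSpec(nbins=2))
        # 5 = 3 + 2: first bin holds three smallest
        assert d.values[:, 0].tolist() == [0, 0, 0, 1, 1]

    def test_nbins_exceeding_samples_rejected(self):
        x = expr({"g1": [1, 2, 3], "g2": [4, 5, 6]})
        with pytest.raises(InvalidSpecError):
            discretize_equalfreq(x, DiscretizationSpec(nbins=4))

    def test_nonfinite_data_rejected(self):
        with pytest.raises(InvalidDataError):
            expr({"g1": [1, np.nan, 3], "g2": [1, 2, 3]})

    @given(
        values=st.lists(
            st.integers(-1000, 1000), min_size=6, max_size=30, unique=True
        ),
        nbins=st.integers(2, 5),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_transform_invariance_on_tie_free_columns(self, values, nbins):
        """Equal-frequency bins depend only on ranks: a strictly monotone
        transform of a tie-free column yields identical bin labels."""
        other = list(range(len(values)))
        x1 = expr({"g1": values, "g2": other})
        # v -> v^3 is strictly increasing and exact in double precision here
        x2 = expr({"g1": [float(v) ** 3 for v in values], "g2": other})
        spec = DiscretizationSpec(nbins=nbins)
        d1 = discretize_equalfreq(x1, spec)
        d2 = discretize_equalfreq(x2, spec)
        assert d1.values[:, 0].tolist() == d2.values[:, 0].tolist()

    @given(
        values=st.lists(st.integers(0, 6), min_size=4, max_size=40),
        nbins=st.integers(2, 4),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_bin_occupancies_as_equal_as_possible(self, values, nbins):
        n = len(values)
        if nbins > n:
            return
        x = expr({"g1": values, "g2": list(range(n))})
        d = discretize_equalfreq(x, DiscretizationSpec(nbins=nbins))
        counts = np.bincount(d.values[:, 0], minlength=nbins)
        assert counts.min() >= n // nbins
        assert counts.max() <= -(-n // nbins)


class TestMutualInformation:
    def test_independent_empirical_joint_is_zero(self):
        assert mutual_information([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_identical_vectors_give_entropy(self):
        assert mutual_information([0, 0, 1, 1], [0, 0, 1, 1]) == pytest.approx(
            math.log(2), abs=1e-12
        )

    def test_worked_four_sample_example(self):
        # three occupied joint cells; value frozen from the plug-in oracle
        assert mutual_information([0, 0, 0, 1], [0, 1, 0, 1]) == pytest.approx(
            0.21576155433883565, abs=1e-12
        )

    def test_length_one_returns_zero(self):
        assert mutual_information([3], [5]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidDataError):
            mutual_information([0, 1], [0, 1, 2])

    @given(
        st.lists(
            st.tuples(st.integers(0, 4), st.integers(0, 4)), min_size=2, max_size=30
        )
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_plugin_oracle_symmetric_and_nonnegative(self, pairs):
        a = [p[0] for p in pairs]
        b = [p[1] for p in pairs]
        mi = mutual_information(a, b)
        assert mi == pytest.approx(mi_plugin(a, b), abs=1e-12)
        assert mi == pytest.approx(mutual_information(b, a), abs=1e-12)
        assert mi >= -1e-15
        assert mutual_information(a, a) == pytest.approx(entropy_plugin(a), abs=1e-12)


class TestMIMatrix:
    def test_matches_scalar_double_loop(self, rng):
        values = rng.integers(0, 3, size=(25, 4))
        d = DiscretizedMatrix(
            sample_ids=[f"s{i}" for i in range(25)],
            probeset_ids=list("wxyz"),
            values=values,
            nbins=3,
        )
        m = mi_matrix(d)
        for i in range(4):
            assert m.values[i, i] == pytest.approx(entropy_plugin(values[:, i].tolist()))
            for j in range(4):
                if i != j:
                    expected = mutual_information(values[:, i], values[:, j])
                    assert m.values[i, j] == expected
        assert np.allclose(m.values, m.values.T)

    def test_identical_columns_offdiagonal_equals_entropy(self):
        col = [0, 0, 1, 1, 2, 2]
        d = DiscretizedMatrix(
            sample_ids=[f"s{i}" for i in range(6)],
            probeset_ids=["a", "b"],
            values=np.array([col, col]).T,
            nbins=3,
        )
        m = mi_matrix(d)
        assert m.values[0, 1] == pytest.approx(math.log(3), abs=1e-12)

    def test_single_column_rejected(self):
        d = DiscretizedMatrix(
            sample_ids=["s0", "s1"], probeset_ids=["a"],
            values=np.array([[0], [1]]), nbins=2,
        )
        with pytest.raises(InvalidDataError):
            mi_matrix(d)


def random_mim(rng, p):
    """Random valid MI-like matrix: symmetric, nonnegative off-diagonal."""
    m = rng.random((p, p))
    m = (m + m.T) / 2
    np.fill_diagonal(m, rng.random(p) + 1.0)
    return MIMatrix(probeset_ids=[f"g{i}" for i in range(p)], values=m)


class TestMrnet:
    def test_two_variables_weight_is_mi(self):
        m = MIMatrix(probeset_ids=["a", "b"], values=np.array([[0.9, 0.4], [0.4, 0.8]]))
        r = mrnet(m)
        assert r.weights[0, 1] == pytest.approx(0.4, abs=1e-15)
        assert r.weights[1, 0] == pytest.approx(0.4, abs=1e-15)

    def test_all_zero_mi_gives_empty_network(self):
        m = MIMatrix(probeset_ids=list("abc"), values=np.zeros((3, 3)))
        r = mrnet(m)
        assert np.all(r.weights == 0)

    def test_matches_exhaustive_oracle_on_random_matrices(self, rng):
        for _ in range(30):
            p = int(rng.integers(3, 7))
            mim = random_mim(rng, p)
            r = mrnet(mim)
            oracle_scores = np.array(mrmr_exhaustive(mim.values.tolist()))
            oracle_w = np.array(mrnet_weights_exhaustive(mim.values.tolist()))
            assert np.allclose(r.directed_scores, oracle_scores, atol=1e-9)
            assert np.allclose(r.weights, oracle_w, atol=1e-9)

    def test_chain_structure_recovered(self, rng):
        """On a Markov-chain-like MI matrix the adjacent pairs outweigh the
        distant ones."""
        # MI decays with distance along the chain g0-g1-g2-g3
        m = np.array(
            [
                [1.0, 0.60, 0.30, 0.15],
                [0.60, 1.0, 0.60, 0.30],
                [0.30, 0.60, 1.0, 0.60],
                [0.15, 0.30, 0.60, 1.0],
            ]
        )
        r = mrnet(MIMatrix(probeset_ids=list("abcd"), values=m))
        oracle = np.array(mrnet_weights_exhaustive(m.tolist()))
        assert np.allclose(r.weights, oracle, atol=1e-12)
        for i, j in [(0, 1), (1, 2), (2, 3)]:  # chain-adjacent pairs kept
            assert r.weights[i, j] > 0
        for i, j in [(0, 2), (0, 3), (1, 3)]:  # distant pairs pruned away
            assert r.weights[i, j] == 0

    def test_weights_symmetric_zero_diagonal_nonnegative(self, rng):
        r = mrnet(random_mim(rng, 6))
        assert np.allclose(r.weights, r.weights.T)
        assert np.all(np.diag(r.weights) == 0)
        assert np.all(r.weights >= 0)

    def test_argmax_ties_break_to_lowest_index(self):
        # b and c equally relevant to a: the first pick for target a must be b
        m = np.array(
            [
                [1.0, 0.5, 0.5],
                [0.5, 1.0, 0.2],
                [0.5, 0.2, 1.0],
            ]
        )
        r = mrnet(MIMatrix(probeset_ids=list("abc"), values=m))
        # first selected predictor for target 0 is index 1 with score = relevance
        assert r.directed_scores[1, 0] == pytest.approx(0.5)
        # index 2 selected second: u = 0.5 - mean({I(c;b)}) = 0.5 - 0.2
        assert r.directed_scores[2, 0] == pytest.approx(0.3)

    def test_asymmetric_input_rejected(self):
        bad = MIMatrix(probeset_ids=["a", "b"], values=np.array([[1.0, 0.2], [0.5, 1.0]]))
        with pytest.raises(InvalidDataError):
            mrnet(bad)

    def test_negative_offdiagonal_rejected(self):
        bad = MIMatrix(probeset_ids=["a", "b"], values=np.array([[1.0, -0.2], [-0.2, 1.0]]))
        with pytest.raises(InvalidDataError):
            mrnet(bad)


class TestNormalizeAndNetwork:
    def test_scales_max_to_one_preserving_order(self):
        r = MrnetResult(
            probeset_ids=list("abc"),
            weights=np.array([[0, 0.2, 0.4], [0.2, 0, 0], [0.4, 0, 0]]),
        )
        out = normalize_weights(r)
        assert out.weights.max() == 1.0
        assert out.weights[0, 1] == pytest.approx(0.5)

    def test_all_zero_matrix_unchanged(self):
        r = MrnetResult(probeset_ids=["a", "b"], weights=np.zeros((2, 2)))
        assert np.all(normalize_weights(r).weights == 0)

    def test_matrix_to_network_keeps_isolated_nodes(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.8
        g = matrix_to_network(MrnetResult(probeset_ids=list("abc"), weights=w))
        assert set(g.nodes) == {"a", "b", "c"}
        assert g.number_of_edges() == 1
        assert g.edges["a", "b"]["weight"] == 0.8

    def test_edge_count_equals_positive_upper_triangle(self, rng):
        w = rng.random((6, 6)) * (rng.random((6, 6)) > 0.5)
        w = np.triu(w, 1)
        w = w + w.T
        g = matrix_to_network(
            MrnetResult(probeset_ids=[f"g{i}" for i in range(6)], weights=w)
        )
        assert g.number_of_edges() == int((np.triu(w, 1) > 0).sum())
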