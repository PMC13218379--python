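"""Attention correctness against a brute-force dense oracle, exchange
symmetries, and prediction-head contracts."""

import numpy as np
import pytest

from cads._tensor import Tensor
from cads.fusion import (ExchangeBlock, MultiHeadAttention, PredictionHead,
                         cross_attention, drug_cell_exchange,
                         drug_drug_exchange, mlp_fusion,
                         multihead_self_attention, predict_head)


def dense_attention_oracle(X1, X2, mha):
    """Brute-force per-head softmax(Q K^T / sqrt(dk)) V, concatenated and
    output-projected — independent of the Tensor engine."""
    WQ, WK, WV, WO = (m.W.data for m in (mha.WQ, mha.WK, mha.WV, mha.WO))
    Q, K, V = X1 @ WQ, X2 @ WK, X2 @ WV
    heads = []
    for h in range(mha.n_heads):
        sl = slice(h * mha.dk, (h + 1) * mha.dk)
        S = Q[:, sl] @ K[:, sl].T / np.sqrt(mha.dk)
        E = np.exp(S - S.max(axis=1, keepdims=True))
        A = E / E.sum(axis=1, keepdims=True)
        heads.append(A @ V[:, sl])
    return np.concatenate(heads, axis=1) @ WO


@pytest.fixture()
def mha(rng):
    return MultiHeadAttention(d_model=4, n_heads=1,
                              rng=np.random.default_rng(5))


@pytest.fixture()
def mha4(rng):
    return MultiHeadAttention(d_model=8, n_heads=4,
                              rng=np.random.default_rng(6))


class TestCrossAttention:
    def test_matches_dense_oracle_small_instance(self, mha, rng):
        X1 = rng.normal(size=(2, 4))
        X2 = rng.normal(size=(3, 4))
        out = cross_attention(X1, X2, mha).data
        assert np.abs(out - dense_attention_oracle(X1, X2, mha)).max() < 1e-6

    def test_matches_dense_oracle_multihead(self, mha4, rng):
        X1 = rng.normal(size=(4, 8))
        X2 = rng.normal(size=(4, 8))
        out = cross_attention(X1, X2, mha4).data
        assert np.abs(out - dense_attention_oracle(X1, X2, mha4)).max() < 1e-6

    def test_singleton_key_returns_its_value_projection(self, mha, rng):
        X1 = rng.normal(size=(3, 4))
        X2 = rng.normal(size=(1, 4))
        out = cross_attention(X1, X2, mha).data
        expected = np.tile(X2 @ mha.WV.W.data @ mha.WO.W.data, (3, 1))
        assert np.allclose(out, expected, atol=1e-10)

    def test_identical_keys_give_uniform_attention(self, mha, rng):
        X1 = rng.normal(size=(2, 4))
        row = rng.normal(size=(1, 4))
        X2 = np.tile(row, (5, 1))
        _, w = cross_attention(X1, X2, mha, return_weights=True)
        assert np.allclose(w.data, 1 / 5)

    def test_dimension_mismatch_rejected(self, mha, rng):
        with pytest.raises(ValueError):
            cross_attention(rng.normal(size=(2, 3)), rng.normal(size=(2, 4)), mha)


class TestSelfAttention:
    def test_equals_cross_attention_with_itself(self, mha4, rng):
        X = rng.normal(size=(3, 8))
        a = multihead_self_attention(X, mha4).data
        b = cross_attention(X, X, mha4).data
        assert np.array_equal(a, b)

    def test_attention_rows_are_probability_vectors(self, mha4, rng):
        X = rng.normal(size=(5, 8))
        _, w = multihead_self_attention(X, mha4, return_weights=True)
        assert (w.data >= 0).all()
        assert np.abs(w.data.sum(axis=-1) - 1).max() < 1e-6

    def test_length_one_sequence_value_projected(self, mha, rng):
        X = rng.normal(size=(1, 4))
        out = multihead_self_attention(X, mha).data
        assert np.allclose(out, X @ mha.WV.W.data @ mha.WO.W.data, atol=1e-12)


class TestExchanges:
    def test_drug_cell_exchange_shapes_preserved(self, rng):
        block = ExchangeBlock(8, 2, rng)
        G = rng.normal(size=(6, 8))
        DA = rng.normal(size=(3, 8))
        DB = rng.normal(size=(4, 8))
        st = drug_cell_exchange(G, DA, DB, block)
        assert st.Gi_prime.shape == (6, 8)
        assert st.DA_prime.shape == (3, 8) and st.DB_prime.shape == (4, 8)

    def test_missing_drug_rejected(self, rng):
        block = ExchangeBlock(8, 2, rng)
        with pytest.raises(ValueError):
            drug_cell_exchange(rng.normal(size=(2, 8)), None,
                               rng.normal(size=(2, 8)), block)

    def test_drug_drug_identical_inputs_give_identical_outputs(self, rng):
        block = ExchangeBlock(8, 2, rng)
        D = rng.normal(size=(3, 8))
        DA, DB = drug_drug_exchange(D, D.copy(), block)
        assert np.allclose(DA.data, DB.data)

    def test_drug_drug_swap_covariance(self, rng):
        block = ExchangeBlock(8, 2, rng)
        DA_p = rng.normal(size=(3, 8))
        DB_p = rng.normal(size=(2, 8))
        a1, b1 = drug_drug_exchange(DA_p, DB_p, block)
        b2, a2 = drug_drug_exchange(DB_p, DA_p, block)
        assert np.array_equal(a1.data, a2.data)
        assert np.array_equal(b1.data, b2.data)

    def test_exchange_matches_composed_oracle(self, rng):
        """Eq-by-eq composition of the dense attention oracle (without
        residual/norm) reproduces the raw attention outputs."""
        block = ExchangeBlock(8, 2, np.random.default_rng(3))
        G = rng.normal(size=(4, 8))
        DA = rng.normal(size=(2, 8))
        DB = rng.normal(size=(2, 8))
        D = np.concatenate([DA, DB], axis=0)
        att = block.cell_over_drugs.attend(Tensor(G), Tensor(D)).data
        assert np.abs(att - dense_attention_oracle(G, D, block.cell_over_drugs)).max() < 1e-6
        att2 = block.drug_over_cell.attend(Tensor(DA), Tensor(G)).data
        assert np.abs(att2 - dense_attention_oracle(DA, G, block.drug_over_cell)).max() < 1e-6


class TestHeads:
    def test_zero_final_layer_gives_zero_prediction(self, rng):
        head = PredictionHead(4, 4, hidden=(8,), rng=rng)
        head.mlp.layers[-1].W.data[:] = 0.0
        head.mlp.layers[-1].b.data[:] = 0.0
        p = predict_head(rng.normal(size=(3, 4)), rng.normal(size=(2, 4)),
                         rng.normal(size=(2, 4)), head)
        assert p.Yi == 0.0

    def test_tanh_bounds_output(self, rng):
        head = PredictionHead(4, 4, hidden=(8,), rng=rng)
        for _ in range(10):
            p = predict_head(rng.normal(size=(3, 4)) * 100,
                             rng.normal(size=(2, 4)) * 100,
                             rng.normal(size=(2, 4)) * 100, head)
            assert abs(p.Yi) <= 1.0

    def test_concatenation_order_matters(self, rng):
        head = PredictionHead(4, 4, hidden=(8,), rng=rng)
        G = rng.normal(size=(3, 4))
        DA = rng.normal(size=(2, 4))
        DB = rng.normal(size=(2, 4))
        y1 = predict_head(G, DA, DB, head).Yi
        y2 = predict_head(DA, G, DB, head).Yi   # permuted order
        assert y1 != pytest.approx(y2)

    def test_mlp_fusion_equals_predict_head(self, rng):
        head = PredictionHead(4, 4, hidden=(8,), rng=rng)
        G = rng.normal(size=(3, 4))
        DA = rng.normal(size=(2, 4))
        DB = rng.normal(size=(2, 4))
        assert mlp_fusion(G, DA, DB, head).Yi == predict_head(G, DA, DB, head).Yi

    def test_non_finite_input_rejected(self, rng):
        head = PredictionHead(4, 4, hidden=(8,), rng=rng)
        bad = rng.normal(size=(3, 4))
        bad[0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            predict_head(bad, rng.normal(size=(2, 4)),
                         rng.normal(size=(2, 4)), head)
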