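"""Drug graph encoders (GIN/GCN/GAT + pooling) and the cell-line MLP."""

import numpy as np
import pytest

from dgsyn.autodiff import Tensor
from dgsyn.chem import parse_smiles
from dgsyn.encoders import (CellEncoder, DrugEncoder, GATLayer, GCNLayer,
                            GINLayer, SAGPool, graph_readout)


def identity_gin(dim, rng):
    layer = GINLayer(dim, dim, rng, eps=0.0)
    for lin in layer.mlp.layers:
        lin.weight.data[...] = np.eye(dim)
        lin.bias.data[...] = 0.0
    return layer


class TestGIN:
    def test_isolated_node_is_plain_mlp(self, rng):
        layer = GINLayer(5, 7, rng, eps=0.0)
        h = Tensor(rng.random((1, 5)))
        out = layer(h, np.zeros((1, 1)))
        direct = layer.mlp(h)
        assert np.allclose(out.data, direct.data)

    def test_path_graph_hand_oracle(self, rng):
        # 4-node path, identity MLPs, eps=0: one layer = (A + I) h
        adj = np.zeros((4, 4))
        for i in range(3):
            adj[i, i + 1] = adj[i + 1, i] = 1.0
        h0 = np.abs(rng.random((4, 3)))
        layer = identity_gin(3, rng)
        out1 = layer(Tensor(h0), adj)
        expected = (adj + np.eye(4)) @ h0
        assert np.allclose(out1.data, expected, atol=1e-12)
        out2 = layer(out1, adj)
        assert np.allclose(out2.data, (adj + np.eye(4)) @ expected, atol=1e-12)

    def test_permutation_equivariance(self, rng):
        adj = np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]], dtype=float)
        h = rng.random((3, 4))
        layer = GINLayer(4, 6, rng)
        perm = np.array([2, 0, 1])
        p = np.eye(3)[perm]
        out = layer(Tensor(h), adj)
        out_p = layer(Tensor(h[perm]), p @ adj @ p.T)
        assert np.allclose(out_p.data, out.data[perm], atol=1e-10)


class TestSAGPool:
    def test_retention_counts(self, rng):
        pool = SAGPool(4, rng, ratio=0.5)
        h = Tensor(rng.random((5, 4)))
        retained, scores, gated = pool(h, np.zeros((5, 5)))
        assert len(retained) == 3  # ceil(0.5 * 5)
        assert scores.data.shape == (5, 1)
        assert gated.shape == (3, 4)

    def test_ratio_one_keeps_everything(self, rng):
        pool = SAGPool(4, rng, ratio=1.0)
        retained, _, _ = pool(Tensor(rng.random((4, 4))), np.zeros((4, 4)))
        assert list(retained) == [0, 1, 2, 3]

    def test_equal_scores_break_toward_lower_indices(self, rng):
        pool = SAGPool(3, rng, ratio=0.5)
        h = Tensor(np.ones((4, 3)))  # identical rows -> identical scores
        retained, _, _ = pool(h, np.zeros((4, 4)))
        assert list(retained) == [0, 1]

    def test_single_node_always_retained(self, rng):
        pool = SAGPool(3, rng, ratio=0.1)
        retained, _, _ = pool(Tensor(rng.random((1, 3))), np.zeros((1, 1)))
        assert list(retained) == [0]


def test_readout_variants(rng):
    h = Tensor(rng.random((4, 3)))
    assert np.allclose(graph_readout(h, "mean").data, h.data.mean(axis=0))
    assert np.allclose(graph_readout(h, "add").data, h.data.sum(axis=0))
    assert np.allclose(graph_readout(h, "max").data, h.data.max(axis=0))
    with pytest.raises(ValueError):
        graph_readout(h, "median")


class TestDrugEncoder:
    @pytest.fixture
    def encoder(self, rng):
        enc = DrugEncoder(78, (16, 16, 16), rng)
        enc.eval()
        return enc

    def test_shapes_and_token_count(self, encoder):
        enc = encoder(parse_smiles("CCO"))
        assert enc.substructure_tokens.shape == (3, 16)
        assert enc.molecular_embedding.shape == (48,)
        assert len(enc.atom_importance) == 3
        assert all(len(imp) == 3 for imp in enc.atom_importance)

    def test_jk_concat_dimension_before_projection(self, rng):
        enc = DrugEncoder(78, (16, 16, 16), rng, d_mol=24)
        enc.eval()
        assert enc.jk_proj.in_dim == 48  # 3 layers x 16 concatenated
        assert enc(parse_smiles("CCO")).molecular_embedding.shape == (24,)

    def test_zero_tokens_give_zero_projection_without_bias(self, rng):
        enc = DrugEncoder(78, (8, 8, 8), rng, d_mol=6)
        enc.jk_proj.bias.data[...] = 0.0
        out = enc.jk_proj(Tensor(np.zeros((1, 24)))).data
        assert np.allclose(out, 0.0)

    def test_atom_relabeling_invariance(self, rng):
        enc = DrugEncoder(78, (16, 16, 16), rng)
        enc.eval()
        # same molecule, two atom orders
        a = enc(parse_smiles("CCOc1ccncc1"))
        b = enc(parse_smiles("c1cc(OCC)ccn1"))
        assert np.allclose(a.molecular_embedding.data, b.molecular_embedding.data,
                           atol=1e-5)

    @pytest.mark.parametrize("encoder_type,heads", [("gcn", 1), ("gat", 2), ("gat", 4)])
    def test_variant_encoders_run(self, rng, encoder_type, heads):
        enc = DrugEncoder(78, (16, 16, 16), rng, encoder=encoder_type, heads=heads)
        enc.eval()
        out = enc(parse_smiles("NC(=O)CCc1ccncc1"))
        assert out.molecular_embedding.shape == (48,)
        assert np.isfinite(out.molecular_embedding.data).all()

    @pytest.mark.parametrize("readout", ["add", "max", "mean"])
    def test_readout_variants_run(self, rng, readout):
        enc = DrugEncoder(78, (16, 16, 16), rng, readout=readout)
        enc.eval()
        out = enc(parse_smiles("CCO"))
        assert out.substructure_tokens.shape == (3, 16)

    def test_unknown_options_rejected(self, rng):
        with pytest.raises(ValueError):
            DrugEncoder(78, (16,), rng, encoder="transformer")
        with pytest.raises(ValueError):
            DrugEncoder(78, (16,), rng, readout="attention")


class TestVariantLayers:
    def test_gcn_layer_shape(self, rng):
        layer = GCNLayer(4, 6, rng)
        out = layer(Tensor(rng.random((3, 4))), np.ones((3, 3)) - np.eye(3))
        assert out.shape == (3, 6)

    def test_gat_heads_must_divide(self, rng):
        with pytest.raises(ValueError):
            GATLayer(4, 6, rng, heads=4)

    def test_gat_attention_is_local(self, rng):
        # disconnected node only attends to itself: its output depends on it alone
        layer = GATLayer(4, 8, rng, heads=2)
        h = rng.random((3, 4))
        adj = np.zeros((3, 3))
        adj[0, 1] = adj[1, 0] = 1.0
        out1 = layer(Tensor(h), adj).data
        h2 = h.copy()
        h2[0] += 1.0  # perturb a node the isolated one cannot see
        out2 = layer(Tensor(h2), adj).data
        assert np.allclose(out1[2], out2[2])


class TestCellEncoder:
    def test_output_dimension_and_determinism(self, rng):
        enc = CellEncoder(10, (16, 12), rng)
        enc.eval()
        rows = Tensor(rng.random((3, 10)))
        a, b = enc(rows), enc(rows)
        assert a.shape == (3, 12)
        assert np.array_equal(a.data, b.data)

    def test_identical_rows_identical_embeddings(self, rng):
        enc = CellEncoder(6, (8, 5), rng)
        enc.eval()
        row = rng.random(6)
        out = enc(Tensor(np.stack([row, row])))
        assert np.allclose(out.data[0], out.data[1])

    def test_length_mismatch_rejected(self, rng):
        enc = CellEncoder(6, (8, 5), rng)
        with pytest.raises(ValueError):
            enc(Tensor(np.zeros((2, 7))))
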