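"""Incidence construction and hypergraph convolution."""

import numpy as np
import pandas as pd
import pytest

from dgsyn.autodiff import Tensor
from dgsyn.hypergraph import (CoarseHypergraph, HypergraphIncidence,
                              build_incidence, hypergraph_conv,
                              propagation_operator)
from dgsyn.nn import Linear


def frame(rows):
    return pd.DataFrame(rows, columns=["drug1", "drug2", "cell_line", "label"])


class TestBuildIncidence:
    def test_counting_example(self):
        samples = frame([("d1", "d2", "c1", 1), ("d1", "d3", "c1", 0),
                         ("d2", "d3", "c2", 1)])
        inc = build_incidence(samples, ["d1", "d2", "d3"], ["c1", "c2"])
        assert inc.H.shape == (5, 3)
        assert np.all(inc.H.sum(axis=0) == 3)
        assert list(inc.node_degrees) == [2, 2, 2, 2, 1]

    def test_mirrored_duplicates_collapse(self):
        samples = frame([("d1", "d2", "c1", 1), ("d2", "d1", "c1", 1)])
        inc = build_incidence(samples, ["d1", "d2"], ["c1"])
        assert inc.n_hyperedges == 1

    def test_no_repeated_node_in_any_column(self, samples_frame):
        sub = samples_frame.head(200)
        inc = build_incidence(sub, sorted(set(sub.drug1) | set(sub.drug2)),
                              sorted(set(sub.cell_line)))
        assert inc.H.max() == 1.0
        assert np.all(inc.H.sum(axis=0) == 3)

    def test_positive_only_mode(self):
        samples = frame([("d1", "d2", "c1", 1), ("d1", "d3", "c1", 0)])
        inc = build_incidence(samples, ["d1", "d2", "d3"], ["c1"], mode="positive_only")
        assert inc.n_hyperedges == 1
        with pytest.raises(ValueError):
            build_incidence(samples, ["d1", "d2", "d3"], ["c1"], mode="negatives")

    def test_zero_hyperedges_rejected(self):
        samples = frame([("d1", "d2", "c1", 0)])
        with pytest.raises(ValueError):
            build_incidence(samples, ["d1", "d2"], ["c1"], mode="positive_only")


class TestConvolution:
    def test_single_hyperedge_symmetry(self, rng):
        h = np.zeros((3, 1))
        h[:, 0] = 1.0
        op = propagation_operator(h)
        theta = Linear(4, 4, rng)
        theta.weight.data[...] = np.eye(4)
        theta.bias.data[...] = 0.0
        x = Tensor(np.tile(rng.random(4), (3, 1)))  # identical rows
        out = hypergraph_conv(x, op, theta)
        assert np.allclose(out.data[0], out.data[1])
        assert np.allclose(out.data[1], out.data[2])

    def test_isolated_node_self_propagates(self, rng):
        h = np.zeros((4, 1))
        h[:3, 0] = 1.0  # node 3 isolated
        op = propagation_operator(h)
        theta = Linear(5, 5, rng)
        x = rng.random((4, 5))
        out = hypergraph_conv(Tensor(x), op, theta, activation=False)
        expected_row3 = x[3] @ theta.weight.data + theta.bias.data
        assert np.allclose(out.data[3], expected_row3, atol=1e-12)

    def test_matches_dense_brute_force_oracle(self, rng):
        # random 6-node / 3-edge incidence, compared against a from-scratch
        # dense evaluation of D_v^{-1/2} H D_e^{-1} H^T D_v^{-1/2} X W + b
        for _ in range(5):
            H = np.zeros((6, 3))
            for e in range(3):
                members = rng.choice(6, size=3, replace=False)
                H[members, e] = 1.0
            if (H.sum(axis=1) == 0).any():
                H[np.flatnonzero(H.sum(axis=1) == 0), 0] = 1.0
            X = rng.normal(size=(6, 4))
            theta = Linear(4, 4, rng)
            dv = np.diag(1.0 / np.sqrt(H.sum(axis=1)))
            de = np.diag(1.0 / H.sum(axis=0))
            expected = np.maximum(
                dv @ H @ de @ H.T @ dv @ X @ theta.weight.data + theta.bias.data, 0.0)
            out = hypergraph_conv(Tensor(X), propagation_operator(H), theta)
            assert np.abs(out.data - expected).max() < 1e-6

    def test_misaligned_rows_rejected(self, rng):
        theta = Linear(4, 4, rng)
        with pytest.raises(ValueError):
            hypergraph_conv(Tensor(rng.random((5, 4))),
                            propagation_operator(np.ones((6, 2))), theta)


class TestCoarseStack:
    def test_output_width_per_layer(self, rng):
        module = CoarseHypergraph((24, 12, 12, 12), rng)
        module.eval()
        H = np.ones((5, 2))
        H[3:, 1] = 0
        H[:2, 0] = 0
        out = module(Tensor(rng.random((5, 24))), propagation_operator(H))
        assert out.shape == (5, 12)

    def test_residual_uses_projected_input(self, rng):
        module = CoarseHypergraph((6, 4, 4, 4), rng)
        module.eval()
        # zero layers 1-3: layer-4 input must equal the projected input features
        for theta in (module.theta1, module.theta2, module.theta3):
            theta.weight.data[...] = 0.0
            theta.bias.data[...] = 0.0
        H = np.ones((3, 1))
        op = propagation_operator(H)
        X = rng.random((3, 6))
        out = module(Tensor(X), op).data
        projected = X @ module.residual_proj.weight.data
        expected = np.maximum(
            op @ projected @ module.theta4.weight.data + module.theta4.bias.data, 0.0)
        assert np.allclose(out, expected, atol=1e-10)

    def test_disabling_residual_changes_output(self, rng):
        X = rng.random((3, 6))
        op = propagation_operator(np.ones((3, 1)))
        a = CoarseHypergraph((6, 4, 4, 4), np.random.default_rng(0))
        b = CoarseHypergraph((6, 4, 4, 4), np.random.default_rng(0), use_residual=False)
        a.eval(), b.eval()
        assert not np.allclose(a(Tensor(X), op).data, b(Tensor(X), op).data)

    def test_all_zero_input_bias_free_gives_zero(self, rng):
        module = CoarseHypergraph((6, 4, 4, 4), rng)
        module.eval()
        for theta in (module.theta1, module.theta2, module.theta3, module.theta4):
            theta.bias.data[...] = 0.0
        out = module(Tensor(np.zeros((3, 6))), propagation_operator(np.ones((3, 1))))
        assert np.allclose(out.data, 0.0)

    def test_node_permutation_equivariance(self, rng):
        module = CoarseHypergraph((6, 4, 4, 4), rng)
        module.eval()
        H = np.zeros((5, 2))
        H[[0, 1, 3], 0] = 1.0
        H[[1, 2, 4], 1] = 1.0
        X = rng.random((5, 6))
        perm = np.array([3, 0, 4, 1, 2])
        out = module(Tensor(X), propagation_operator(H)).data
        out_p = module(Tensor(X[perm]), propagation_operator(H[perm])).data
        assert np.allclose(out_p, out[perm], atol=1e-10)

    def test_wrong_input_width_rejected(self, rng):
        module = CoarseHypergraph((6, 4, 4, 4), rng)
        with pytest.raises(ValueError):
            module(Tensor(rng.random((3, 5))), propagation_operator(np.ones((3, 1))))
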