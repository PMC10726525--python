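"""Graph layers against dense brute-force oracles of their printed formulas."""

import numpy as np
import pytest

from gpdrp.drug_graph import AtomFeatureSchema, MolecularGraph, smiles_to_graph
from gpdrp.encoders import (
    CellLineEncoder,
    DrugEncoder,
    EncoderConfig,
    GraphBatch,
    GraphTransformerLayer,
    gat_layer,
    gcn_layer,
    gin_layer,
    global_max_pool,
    laplacian_pe,
    normalized_laplacian,
)
from gpdrp.nn import Tensor

from conftest import random_graph


# ---------------------------------------------------------------------------
# dense oracles
# ---------------------------------------------------------------------------


def dense_gcn(H, edges, W):
    n = H.shape[0]
    A = np.zeros((n, n))
    for i, j in edges:
        A[i, j] = A[j, i] = 1.0
    At = A + np.eye(n)
    Dinv = np.diag(At.sum(1) ** -0.5)
    return np.maximum(Dinv @ At @ Dinv @ H @ W, 0.0)


def dense_gin(H, edges, mu=0.0):
    n = H.shape[0]
    A = np.zeros((n, n))
    for i, j in edges:
        A[i, j] = A[j, i] = 1.0
    return (1.0 + mu) * H + A @ H


def dense_gat(H, edges, W, a_src, a_dst, slope=0.2):
    n = H.shape[0]
    z = H @ W
    neigh = {i: {i} for i in range(n)}
    for i, j in edges:
        neigh[i].add(j)
        neigh[j].add(i)
    out = np.zeros_like(z)
    for i in range(n):
        js = sorted(neigh[i])
        logits = np.array(
            [(z[j] @ a_src).item() + (z[i] @ a_dst).item() for j in js]
        )
        logits = np.where(logits > 0, logits, slope * logits)
        e = np.exp(logits - logits.max())
        alpha = e / e.sum()
        out[i] = sum(a * z[j] for a, j in zip(alpha, js))
    return out


@pytest.mark.parametrize("n_nodes", [1, 2, 4, 6, 8])
def test_gcn_layer_matches_dense_oracle(n_nodes):
    rng = np.random.default_rng(n_nodes)
    edges = random_graph(rng, n_nodes)
    H = rng.normal(size=(n_nodes, 5))
    W = rng.normal(size=(5, 3))
    np.testing.assert_allclose(
        gcn_layer(H, edges, W, activation="relu"), dense_gcn(H, edges, W), atol=1e-6
    )


def test_gcn_single_node_identity():
    # Ã = D̃ = 1 so with identity weights and linear activation the row passes through
    H = np.array([[1.5, -2.0]])
    np.testing.assert_allclose(
        gcn_layer(H, [], np.eye(2), activation="none"), H, atol=1e-12
    )


def test_gcn_two_identical_nodes_average_to_input():
    H = np.ones((2, 3))
    np.testing.assert_allclose(
        gcn_layer(H, [(0, 1)], np.eye(3), activation="none"), H, atol=1e-12
    )


@pytest.mark.parametrize("n_nodes", [1, 3, 6, 8])
def test_gin_layer_matches_dense_oracle(n_nodes):
    rng = np.random.default_rng(10 + n_nodes)
    edges = random_graph(rng, n_nodes)
    H = rng.normal(size=(n_nodes, 4))
    np.testing.assert_allclose(
        gin_layer(H, edges, mu=0.3), dense_gin(H, edges, mu=0.3), atol=1e-6
    )


def test_gin_isolated_node_identity():
    H = np.array([[2.0, -1.0]])
    np.testing.assert_allclose(gin_layer(H, [], mu=0.0), H, atol=1e-12)


def test_gin_two_neighbors_direct_sum():
    H = np.array([[1.0, 0.0], [0.0, 2.0], [3.0, 3.0]])
    out = gin_layer(H, [(0, 1), (0, 2)], mu=0.0)
    np.testing.assert_allclose(out[0], H[0] + H[1] + H[2], atol=1e-12)


@pytest.mark.parametrize("n_nodes", [1, 2, 5, 8])
def test_gat_layer_matches_dense_oracle(n_nodes):
    rng = np.random.default_rng(20 + n_nodes)
    edges = random_graph(rng, n_nodes)
    H = rng.normal(size=(n_nodes, 4))
    W = rng.normal(size=(4, 3))
    a_src, a_dst = rng.normal(size=(3, 1)), rng.normal(size=(3, 1))
    np.testing.assert_allclose(
        gat_layer(H, edges, W, a_src, a_dst),
        dense_gat(H, edges, W, a_src, a_dst),
        atol=1e-6,
    )


def test_gat_attention_rows_sum_to_one():
    rng = np.random.default_rng(31)
    n = 6
    edges = random_graph(rng, n)
    H = rng.normal(size=(n, 4))
    _, alpha, _, dst = gat_layer(
        H, edges, rng.normal(size=(4, 3)), rng.normal(size=(3, 1)),
        rng.normal(size=(3, 1)), return_attention=True,
    )
    sums = np.zeros(n)
    np.add.at(sums, dst, alpha.ravel())
    np.testing.assert_allclose(sums, 1.0, atol=1e-6)


def test_gat_two_identical_nodes_equal_attention():
    H = np.ones((2, 3))
    rng = np.random.default_rng(0)
    _, alpha, _, _ = gat_layer(
        H, [(0, 1)], rng.normal(size=(3, 2)), rng.normal(size=(2, 1)),
        rng.normal(size=(2, 1)), return_attention=True,
    )
    np.testing.assert_allclose(alpha.ravel(), 0.5, atol=1e-12)


def test_gat_isolated_node_self_attention_only():
    H = np.array([[1.0, -1.0]])
    rng = np.random.default_rng(1)
    W = rng.normal(size=(2, 2))
    out = gat_layer(H, [], W, rng.normal(size=(2, 1)), rng.normal(size=(2, 1)))
    np.testing.assert_allclose(out, H @ W, atol=1e-12)


# ---------------------------------------------------------------------------
# Laplacian PE
# ---------------------------------------------------------------------------


class TestLaplacianPE:
    def test_two_node_path_closed_form(self, schema):
        g = smiles_to_graph("CC", schema)
        L = normalized_laplacian(2, g.edges)
        np.testing.assert_allclose(L, [[1, -1], [-1, 1]], atol=1e-12)
        np.testing.assert_allclose(np.linalg.eigvalsh(L), [0.0, 2.0], atol=1e-12)

    def test_eigenvalues_bounded_and_zero_smallest(self, fixture_graphs):
        for g in fixture_graphs:
            vals = np.linalg.eigvalsh(normalized_laplacian(g.n_atoms, g.edges))
            assert vals.min() == pytest.approx(0.0, abs=1e-9)
            assert vals.max() <= 2.0 + 1e-9

    def test_disconnected_graph_zero_multiplicity_two(self):
        # two components → block-diagonal Laplacian → eigenvalue 0 twice
        vals = np.linalg.eigvalsh(normalized_laplacian(4, [(0, 1), (2, 3)]))
        assert np.sum(np.abs(vals) < 1e-9) == 2

    def test_columns_are_eigenvectors(self, schema):
        g = smiles_to_graph("CC(=O)Oc1ccccc1C(=O)O", schema)
        L = normalized_laplacian(g.n_atoms, g.edges)
        vals, vecs = np.linalg.eigh(L)
        pe = laplacian_pe(g, 4)
        for col in range(4):
            v = pe[:, col]
            lam = vals[1 + col]
            np.testing.assert_allclose(L @ v, lam * v, atol=1e-8)

    def test_sign_convention_invariant_to_relabeling(self, schema):
        # reversing a path molecule permutes rows without flipping signs
        g = smiles_to_graph("CCCO", schema)
        perm = np.array([3, 2, 1, 0])
        inv = np.argsort(perm)
        gp = MolecularGraph(
            node_features=g.node_features[perm],
            edges=sorted((min(inv[i], inv[j]), max(inv[i], inv[j])) for i, j in g.edges),
            smiles="",
        )
        np.testing.assert_allclose(laplacian_pe(gp, 3), laplacian_pe(g, 3)[perm], atol=1e-9)

    def test_small_graph_zero_padded(self, schema):
        g = smiles_to_graph("CC", schema)
        pe = laplacian_pe(g, 8)  # only 1 nontrivial eigenvector exists
        assert pe.shape == (2, 8)
        np.testing.assert_array_equal(pe[:, 1:], 0.0)

    def test_k_below_one_rejected(self, schema):
        with pytest.raises(ValueError):
            laplacian_pe(smiles_to_graph("CC", schema), 0)


# ---------------------------------------------------------------------------
# transformer layer
# ---------------------------------------------------------------------------


def test_transformer_uniform_attention_degenerate_case(schema):
    """With zeroed query/key weights attention is uniform, so each head's
    output is the graph-mean of its value projection (hand oracle)."""
    g = smiles_to_graph("CCO", schema)
    dim, heads = 8, 2
    rng = np.random.default_rng(3)
    layer = GraphTransformerLayer(dim, heads, rng)
    for h in range(heads):
        layer.q[h].W.data[:] = 0.0
        layer.k[h].W.data[:] = 0.0
    batch = GraphBatch.from_graphs([g])
    x = rng.normal(size=(g.n_atoms, dim))
    out = layer(Tensor(x), batch).data

    # oracle: uniform attention → mean-pooled value projection per head
    head_means = [
        np.repeat((x @ layer.v[h].W.data).mean(axis=0, keepdims=True), g.n_atoms, axis=0)
        for h in range(heads)
    ]
    attn = np.concatenate(head_means, axis=-1) @ layer.out.W.data + layer.out.b.data

    def ln(z, mod):
        mu = z.mean(-1, keepdims=True)
        sd = np.sqrt(((z - mu) ** 2).mean(-1, keepdims=True) + 1e-5)
        return (z - mu) / sd * mod.gamma.data + mod.beta.data

    x1 = ln(x + attn, layer.norm1)
    ff = np.maximum(x1 @ layer.ffn.steps[0].W.data + layer.ffn.steps[0].b.data, 0)
    ff = ff @ layer.ffn.steps[2].W.data + layer.ffn.steps[2].b.data
    expected = ln(x1 + ff, layer.norm2)
    np.testing.assert_allclose(out, expected, atol=1e-8)


def test_transformer_no_cross_molecule_attention(schema):
    """A second molecule in the batch must not change the first's output."""
    g1, g2 = smiles_to_graph("CCO", schema), smiles_to_graph("c1ccccc1", schema)
    rng = np.random.default_rng(4)
    layer = GraphTransformerLayer(8, 2, np.random.default_rng(9))
    x1 = rng.normal(size=(g1.n_atoms, 8))
    x2 = rng.normal(size=(g2.n_atoms, 8))
    solo = layer(Tensor(x1), GraphBatch.from_graphs([g1])).data
    joint = layer(
        Tensor(np.vstack([x1, x2])), GraphBatch.from_graphs([g1, g2])
    ).data[: g1.n_atoms]
    np.testing.assert_allclose(joint, solo, atol=1e-10)


def test_transformer_permutation_equivariant(schema):
    g = smiles_to_graph("CCCO", schema)
    n = g.n_atoms
    rng = np.random.default_rng(5)
    layer = GraphTransformerLayer(8, 2, np.random.default_rng(11))
    x = rng.normal(size=(n, 8))
    perm = np.array([2, 0, 3, 1])
    edges_p = [(int(np.where(perm == i)[0][0]), int(np.where(perm == j)[0][0])) for i, j in g.edges]
    gp = MolecularGraph(node_features=g.node_features[perm], edges=edges_p, smiles="")
    out = layer(Tensor(x), GraphBatch.from_graphs([g])).data
    out_p = layer(Tensor(x[perm]), GraphBatch.from_graphs([gp])).data
    np.testing.assert_allclose(out_p, out[perm], atol=1e-10)


# ---------------------------------------------------------------------------
# pooling and full encoders
# ---------------------------------------------------------------------------


class TestGlobalMaxPool:
    def test_elementwise_maximum(self):
        out = global_max_pool(np.array([[1.0, 5.0], [3.0, 2.0]]))
        np.testing.assert_array_equal(out.data, [[3.0, 5.0]])

    def test_single_node(self):
        out = global_max_pool(np.array([[4.0, -1.0]]))
        np.testing.assert_array_equal(out.data, [[4.0, -1.0]])

    def test_permutation_invariant(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(7, 3))
        a = global_max_pool(x).data
        b = global_max_pool(x[rng.permutation(7)]).data
        np.testing.assert_array_equal(a, b)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            global_max_pool(np.empty((0, 3)))


@pytest.mark.parametrize("variant", ["GCN", "GAT", "GIN", "GIN_TRANSFORMER"])
class TestDrugEncoder:
    def _encode(self, variant, graphs, schema, seed=0):
        cfg = EncoderConfig(variant=variant, hidden_dim=16, embed_dim=128,
                            pe_dim=4, gat_heads=3, transformer_heads=2)
        enc = DrugEncoder(schema.total_dim, cfg, np.random.default_rng(seed)).eval()
        pe = 4 if variant == "GIN_TRANSFORMER" else None
        return enc, enc(GraphBatch.from_graphs(graphs, pe_dim=pe)).data

    def test_output_is_128(self, variant, fixture_graphs, schema):
        _, out = self._encode(variant, fixture_graphs[:3], schema)
        assert out.shape == (3, 128)
        assert np.all(np.isfinite(out))

    def test_atom_relabeling_invariance(self, variant, schema):
        # same molecule with renumbered atoms → identical embedding
        enc, out = self._encode(variant, [smiles_to_graph("CCCO", schema)], schema)
        g = smiles_to_graph("CCCO", schema)
        perm = np.array([3, 1, 0, 2])
        inv = np.argsort(perm)
        gp = MolecularGraph(
            node_features=g.node_features[perm],
            edges=sorted((min(inv[i], inv[j]), max(inv[i], inv[j])) for i, j in g.edges),
            smiles="CCCO",
        )
        pe = 4 if variant == "GIN_TRANSFORMER" else None
        out_p = enc(GraphBatch.from_graphs([gp], pe_dim=pe)).data
        np.testing.assert_allclose(out_p, out, atol=1e-5)

    def test_different_molecules_differ(self, variant, fixture_graphs, schema):
        _, out = self._encode(variant, fixture_graphs[:4], schema)
        for i in range(3):
            assert not np.allclose(out[i], out[i + 1])


def test_unknown_variant_rejected():
    with pytest.raises(ValueError, match="variant"):
        EncoderConfig(variant="MLP")


class TestCellLineEncoder:
    def test_output_is_128(self):
        enc = CellLineEncoder(40, np.random.default_rng(0)).eval()
        out = enc(np.random.default_rng(1).uniform(size=(5, 40))).data
        assert out.shape == (5, 128)

    def test_inference_deterministic(self):
        enc = CellLineEncoder(20, np.random.default_rng(0)).eval()
        x = np.random.default_rng(2).uniform(size=(3, 20))
        np.testing.assert_array_equal(enc(x).data, enc(x).data)

    def test_training_dropout_reproducible_with_seed(self):
        x = np.random.default_rng(3).uniform(size=(4, 20))
        outs = []
        for _ in range(2):
            enc = CellLineEncoder(20, np.random.default_rng(0))
            enc.train(True)
            outs.append(enc(x).data)
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_axis_mismatch_names_dims(self):
        enc = CellLineEncoder(20, np.random.default_rng(0))
        with pytest.raises(ValueError, match="expected 20, got 7"):
            enc(np.ones((1, 7)))
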