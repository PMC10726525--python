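"""Drug-graph encoders and the cell-line DNN branch.

Four graph encoder variants map a molecular graph to a 128-dimensional
embedding:

* ``GCN`` — three spectral convolution layers with the symmetric
  normalisation  H' = σ(D̃^{-1/2} Ã D̃^{-1/2} H W),  Ã = A + I.
* ``GAT`` — three attention layers; the first uses 10 heads with
  concatenation, the later layers emit 128 features.  Attention logits are
  LeakyReLU of a learned linear form and are softmax-normalised over each
  node's first-order neighbourhood (self-loops included).
* ``GIN`` — three layers of  MLP((1+μ)·x_i + Σ_{j∈N(i)} x_j)  with batch
  normalisation after every layer.
* ``GIN_TRANSFORMER`` — two GIN layers combined with one full self-attention
  transformer layer over the nodes of each molecule, with Laplacian
  eigenvector positional encodings injected at the input.  The transformer
  layer sits after the GIN layers by default (configurable), so local
  neighbourhood features are built first and global mixing happens last.

Every variant ends in global max pooling over nodes and a fully connected
layer onto ``embed_dim`` (128).  The cell-line branch is a dense network
512 → 1024 → (dropout 0.2) → 128 with ReLU activations.

All message passing uses gather / segment primitives rather than dense
adjacency matrices, so a batch of molecules is one block-diagonal graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .drug_graph import MolecularGraph
from .nn import (
    BatchNorm1d,
    Dropout,
    LayerNorm,
    Linear,
    Module,
    Sequential,
    Tensor,
    concat,
    gather,
    segment_max,
    segment_softmax,
    segment_sum,
)

VARIANTS = ("GCN", "GAT", "GIN", "GIN_TRANSFORMER")


@dataclass
class EncoderConfig:
    variant: str = "GIN_TRANSFORMER"
    n_graph_layers: int = 3
    hidden_dim: int = 128
    gat_heads: int = 10
    gin_mu_learnable: bool = False
    pe_dim: int = 8
    embed_dim: int = 128
    dropout: float = 0.2
    transformer_heads: int = 4
    transformer_position: str = "last"  # global attention after the GIN layers

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown encoder variant {self.variant!r}; choose from {VARIANTS}")
        if self.variant == "GIN_TRANSFORMER" and self.pe_dim < 1:
            raise ValueError("GIN_TRANSFORMER requires pe_dim >= 1")
        if self.transformer_position not in {"first", "last"}:
            raise ValueError("transformer_position must be 'first' or 'last'")


# ---------------------------------------------------------------------------
# Laplacian positional encoding
# ---------------------------------------------------------------------------


def normalized_laplacian(n_nodes: int, edges) -> np.ndarray:
    """Dense symmetric normalised Laplacian  I − D^{-1/2} A D^{-1/2}."""
    A = np.zeros((n_nodes, n_nodes))
    for i, j in edges:
        A[i, j] = A[j, i] = 1.0
    deg = A.sum(axis=1)
    with np.errstate(divide="ignore"):
        dinv = np.where(deg > 0, deg**-0.5, 0.0)
    return np.eye(n_nodes) - dinv[:, None] * A * dinv[None, :]


_SIGN_SEED = 8237  # fixed weights for the feature-aware sign convention


def laplacian_pe(graph: MolecularGraph, k: int) -> np.ndarray:
    """Node positional encodings from the k smallest nontrivial eigenvectors.

    Eigenvectors are taken in ascending eigenvalue order, skipping the first
    (trivial, eigenvalue 0).  Each eigenvector's sign is fixed by a
    label-invariant convention so that relabelling the atoms of a molecule
    permutes the encoding rows without flipping signs: the sign makes the
    feature-weighted entry sum  Σ_i v_i (1 + f_i·w)  positive (w a fixed
    pseudo-random weight vector), falling back to Σ_i v_i³ and finally to
    making the largest-magnitude entry positive.  Residual ambiguity only
    remains when a sign flip maps the attributed graph onto itself, where
    either choice yields the same graph-level embedding.  Graphs with fewer
    than k+1 nodes are zero-padded on the right.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = graph.n_atoms
    if n == 0:
        raise ValueError("empty graph has no positional encoding")
    L = normalized_laplacian(n, graph.edges)
    eigvals, eigvecs = np.linalg.eigh(L)
    vecs = eigvecs[:, 1 : k + 1]  # drop the trivial eigenvector
    feats = graph.node_features
    w = np.random.default_rng(_SIGN_SEED).normal(size=feats.shape[1])
    node_score = 1.0 + feats @ w
    for col in range(vecs.shape[1]):
        v = vecs[:, col]
        for score in (float(v @ node_score), float((v**3).sum())):
            if abs(score) > 1e-8:
                if score < 0:
                    vecs[:, col] = -v
                break
        else:
            idx = np.argmax(np.round(np.abs(v), 12))  # lowest index on ties
            if v[idx] < 0:
                vecs[:, col] = -v
    out = np.zeros((n, k))
    out[:, : vecs.shape[1]] = vecs
    return out


# ---------------------------------------------------------------------------
# Batched graph container
# ---------------------------------------------------------------------------


@dataclass
class GraphBatch:
    """Block-diagonal batch of molecular graphs with precomputed indexing."""

    x: np.ndarray  # (total_nodes, feat_dim)
    src: np.ndarray  # directed arcs (both orientations), no self-loops
    dst: np.ndarray
    node_graph: np.ndarray  # node → graph index (sorted, contiguous)
    n_graphs: int
    gcn_src: np.ndarray = field(repr=False, default=None)
    gcn_dst: np.ndarray = field(repr=False, default=None)
    gcn_norm: np.ndarray = field(repr=False, default=None)
    loop_src: np.ndarray = field(repr=False, default=None)  # arcs + self-loops
    loop_dst: np.ndarray = field(repr=False, default=None)
    full_src: np.ndarray = field(repr=False, default=None)  # all intra-graph pairs
    full_dst: np.ndarray = field(repr=False, default=None)
    pe: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.x.shape[0]

    @classmethod
    def from_graphs(cls, graphs: list[MolecularGraph], pe_dim: int | None = None) -> "GraphBatch":
        xs, srcs, dsts, node_graph, pes = [], [], [], [], []
        offset = 0
        for gi, g in enumerate(graphs):
            xs.append(g.node_features)
            s, d = g.directed_arcs()
            srcs.append(s + offset)
            dsts.append(d + offset)
            node_graph.append(np.full(g.n_atoms, gi, dtype=np.intp))
            if pe_dim:
                pes.append(laplacian_pe(g, pe_dim))
            offset += g.n_atoms
        x = np.concatenate(xs, axis=0)
        src = np.concatenate(srcs) if srcs else np.empty(0, dtype=np.intp)
        dst = np.concatenate(dsts) if dsts else np.empty(0, dtype=np.intp)
        node_graph = np.concatenate(node_graph)
        n = x.shape[0]
        nodes = np.arange(n, dtype=np.intp)

        # GCN: self-loops + symmetric normalisation on Ã = A + I
        gcn_src = np.concatenate([src, nodes])
        gcn_dst = np.concatenate([dst, nodes])
        deg = np.bincount(gcn_dst, minlength=n).astype(np.float64)
        gcn_norm = (deg[gcn_src] * deg[gcn_dst]) ** -0.5

        # GAT neighbourhoods include self
        loop_src, loop_dst = gcn_src, gcn_dst

        # transformer: complete attention within each molecule (incl. self)
        fs, fd = [], []
        start = 0
        for g in graphs:
            idx = np.arange(start, start + g.n_atoms, dtype=np.intp)
            grid_d, grid_s = np.meshgrid(idx, idx, indexing="ij")
            fs.append(grid_s.ravel())
            fd.append(grid_d.ravel())
            start += g.n_atoms
        return cls(
            x=x,
            src=src,
            dst=dst,
            node_graph=node_graph,
            n_graphs=len(graphs),
            gcn_src=gcn_src,
            gcn_dst=gcn_dst,
            gcn_norm=gcn_norm,
            loop_src=loop_src,
            loop_dst=loop_dst,
            full_src=np.concatenate(fs),
            full_dst=np.concatenate(fd),
            pe=np.concatenate(pes, axis=0) if pes else None,
        )


# ---------------------------------------------------------------------------
# Layer modules
# ---------------------------------------------------------------------------


class GCNConv(Module):
    """H' = σ(D̃^{-1/2} Ã D̃^{-1/2} H W) implemented edge-wise."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.lin = self.add_child("lin", Linear(in_dim, out_dim, rng))

    def __call__(self, x: Tensor, batch: GraphBatch) -> Tensor:
        h = self.lin(x)
        msg = gather(h, batch.gcn_src) * Tensor(batch.gcn_norm[:, None])
        return segment_sum(msg, batch.gcn_dst, batch.n_nodes)


class GATConv(Module):
    """Multi-head attention over first-order neighbourhoods (with self)."""

    def __init__(
        self,
        in_dim: int,
        out_dim: int,
        rng: np.random.Generator,
        heads: int = 1,
        concat_heads: bool = True,
        negative_slope: float = 0.2,
    ):
        super().__init__()
        self.heads = heads
        self.concat_heads = concat_heads
        self.negative_slope = negative_slope
        self.lins = [
            self.add_child(f"lin{h}", Linear(in_dim, out_dim, rng, bias=False))
            for h in range(heads)
        ]
        from .nn.layers import glorot

        self.att_src = [
            self.register(f"a_src{h}", glorot(rng, out_dim, 1)) for h in range(heads)
        ]
        self.att_dst = [
            self.register(f"a_dst{h}", glorot(rng, out_dim, 1)) for h in range(heads)
        ]

    def __call__(self, x: Tensor, batch: GraphBatch, return_attention: bool = False):
        outs, alphas = [], []
        for h in range(self.heads):
            z = self.lins[h](x)
            logits = (
                gather(z @ self.att_src[h], batch.loop_src)
                + gather(z @ self.att_dst[h], batch.loop_dst)
            ).leaky_relu(self.negative_slope)
            alpha = segment_softmax(logits, batch.loop_dst, batch.n_nodes)
            out = segment_sum(alpha * gather(z, batch.loop_src), batch.loop_dst, batch.n_nodes)
            outs.append(out)
            alphas.append(alpha)
        merged = (
            concat(outs, axis=-1)
            if (self.concat_heads and self.heads > 1)
            else (outs[0] if self.heads == 1 else _mean_tensors(outs))
        )
        if return_attention:
            return merged, [a.data for a in alphas]
        return merged


def _mean_tensors(ts: list[Tensor]) -> Tensor:
    out = ts[0]
    for t in ts[1:]:
        out = out + t
    return out * (1.0 / len(ts))


class GINConv(Module):
    """MLP((1+μ)·x_i + Σ_{j∈N(i)} x_j) followed by batch normalisation."""

    def __init__(
        self,
        in_dim: int,
        out_dim: int,
        rng: np.random.Generator,
        mu: float = 0.0,
        mu_learnable: bool = False,
    ):
        super().__init__()
        self.mlp = self.add_child(
            "mlp",
            Sequential(Linear(in_dim, out_dim, rng), _ReLU(), Linear(out_dim, out_dim, rng)),
        )
        self.bn = self.add_child("bn", BatchNorm1d(out_dim))
        if mu_learnable:
            self.mu = self.register("mu", np.array(float(mu)))
        else:
            self.mu = float(mu)

    def aggregate(self, x: Tensor, batch: GraphBatch) -> Tensor:
        neigh = segment_sum(gather(x, batch.src), batch.dst, batch.n_nodes)
        if isinstance(self.mu, Tensor):
            return x * (self.mu + 1.0) + neigh
        return x * (1.0 + self.mu) + neigh

    def __call__(self, x: Tensor, batch: GraphBatch) -> Tensor:
        return self.bn(self.mlp(self.aggregate(x, batch)))


class _ReLU(Module):
    def __call__(self, x: Tensor) -> Tensor:
        return x.relu()


class GraphTransformerLayer(Module):
    """Full self-attention over each molecule's nodes + feed-forward block.

    Pre-computed Laplacian positional encodings enter with the node features
    (handled by the encoder's input projection); this layer applies scaled
    dot-product attention restricted to intra-molecule pairs, a residual
    connection with layer normalisation, and a position-wise feed-forward
    network with a second residual + normalisation.
    """

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % heads != 0:
            raise ValueError("hidden dim must be divisible by number of heads")
        self.heads = heads
        self.head_dim = dim // heads
        self.q = [self.add_child(f"q{h}", Linear(dim, self.head_dim, rng, bias=False)) for h in range(heads)]
        self.k = [self.add_child(f"k{h}", Linear(dim, self.head_dim, rng, bias=False)) for h in range(heads)]
        self.v = [self.add_child(f"v{h}", Linear(dim, self.head_dim, rng, bias=False)) for h in range(heads)]
        self.out = self.add_child("out", Linear(dim, dim, rng))
        self.norm1 = self.add_child("norm1", LayerNorm(dim))
        self.norm2 = self.add_child("norm2", LayerNorm(dim))
        self.ffn = self.add_child(
            "ffn", Sequential(Linear(dim, 2 * dim, rng), _ReLU(), Linear(2 * dim, dim, rng))
        )

    def __call__(self, x: Tensor, batch: GraphBatch) -> Tensor:
        scale = 1.0 / np.sqrt(self.head_dim)
        head_outs = []
        for h in range(self.heads):
            q, k, v = self.q[h](x), self.k[h](x), self.v[h](x)
            logits = (gather(q, batch.full_dst) * gather(k, batch.full_src)).sum(
                axis=1, keepdims=True
            ) * scale
            alpha = segment_softmax(logits, batch.full_dst, batch.n_nodes)
            head_outs.append(
                segment_sum(alpha * gather(v, batch.full_src), batch.full_dst, batch.n_nodes)
            )
        attn = self.out(concat(head_outs, axis=-1))
        x = self.norm1(x + attn)
        return self.norm2(x + self.ffn(x))


def global_max_pool(x: Tensor | np.ndarray, node_graph=None, n_graphs: int = 1):
    """Element-wise maximum over the nodes of each graph."""
    if not isinstance(x, Tensor):
        x = Tensor(x)
    if x.data.shape[0] == 0:
        raise ValueError("cannot pool an empty graph")
    if node_graph is None:
        node_graph = np.zeros(x.data.shape[0], dtype=np.intp)
    return segment_max(x, node_graph, n_graphs)


# ---------------------------------------------------------------------------
# Functional single-graph wrappers (oracle-checkable printed formulas)
# ---------------------------------------------------------------------------


def gcn_layer(H: np.ndarray, edges, W: np.ndarray, activation: str = "relu") -> np.ndarray:
    """One GCN propagation step σ(D̃^{-1/2} Ã D̃^{-1/2} H W) on a single graph."""
    n = H.shape[0]
    g = MolecularGraph(node_features=np.asarray(H, dtype=float), edges=list(edges), smiles="")
    batch = GraphBatch.from_graphs([g])
    h = Tensor(H) @ Tensor(W)
    msg = gather(h, batch.gcn_src) * Tensor(batch.gcn_norm[:, None])
    out = segment_sum(msg, batch.gcn_dst, n)
    return _activate(out, activation).data


def gin_layer(H: np.ndarray, edges, mlp=None, mu: float = 0.0) -> np.ndarray:
    """One GIN aggregation (1+μ)x_i + Σ_{j∈N(i)} x_j, then ``mlp`` if given."""
    g = MolecularGraph(node_features=np.asarray(H, dtype=float), edges=list(edges), smiles="")
    batch = GraphBatch.from_graphs([g])
    x = Tensor(H)
    agg = x * (1.0 + mu) + segment_sum(gather(x, batch.src), batch.dst, batch.n_nodes)
    return mlp(agg.data) if mlp is not None else agg.data


def gat_layer(
    H: np.ndarray,
    edges,
    W: np.ndarray,
    a_src: np.ndarray,
    a_dst: np.ndarray,
    negative_slope: float = 0.2,
    activation: str = "none",
    return_attention: bool = False,
):
    """One single-head GAT step on one graph with explicit parameters."""
    g = MolecularGraph(node_features=np.asarray(H, dtype=float), edges=list(edges), smiles="")
    batch = GraphBatch.from_graphs([g])
    z = Tensor(H) @ Tensor(W)
    logits = (
        gather(z @ Tensor(np.asarray(a_src).reshape(-1, 1)), batch.loop_src)
        + gather(z @ Tensor(np.asarray(a_dst).reshape(-1, 1)), batch.loop_dst)
    ).leaky_relu(negative_slope)
    alpha = segment_softmax(logits, batch.loop_dst, batch.n_nodes)
    out = segment_sum(alpha * gather(z, batch.loop_src), batch.loop_dst, batch.n_nodes)
    out = _activate(out, activation)
    if return_attention:
        return out.data, alpha.data, batch.loop_src.copy(), batch.loop_dst.copy()
    return out.data


def _activate(t: Tensor, name: str) -> Tensor:
    if name in (None, "none", "linear"):
        return t
    if name == "relu":
        return t.relu()
    if name == "sigmoid":
        return t.sigmoid()
    raise ValueError(f"unknown activation {name!r}")


# ---------------------------------------------------------------------------
# Encoders
# ---------------------------------------------------------------------------


class DrugEncoder(Module):
    """Variant-specific graph layer stack → global max pool → FC(embed_dim)."""

    def __init__(self, in_dim: int, config: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        c = config
        self.layers: list = []
        if c.variant == "GCN":
            dims = [in_dim] + [c.hidden_dim] * c.n_graph_layers
            for i in range(c.n_graph_layers):
                self.layers.append(("gcn", self.add_child(f"gcn{i}", GCNConv(dims[i], dims[i + 1], rng))))
            pooled_dim = c.hidden_dim
        elif c.variant == "GAT":
            self.layers.append(
                ("gat", self.add_child("gat0", GATConv(in_dim, c.hidden_dim, rng, heads=c.gat_heads)))
            )
            prev = c.hidden_dim * c.gat_heads
            for i in range(1, c.n_graph_layers):
                self.layers.append(
                    ("gat", self.add_child(f"gat{i}", GATConv(prev, c.embed_dim, rng, heads=1)))
                )
                prev = c.embed_dim
            pooled_dim = prev
        elif c.variant == "GIN":
            dims = [in_dim] + [c.hidden_dim] * c.n_graph_layers
            for i in range(c.n_graph_layers):
                self.layers.append(
                    ("gin", self.add_child(
                        f"gin{i}",
                        GINConv(dims[i], dims[i + 1], rng, mu_learnable=c.gin_mu_learnable),
                    ))
                )
            pooled_dim = c.hidden_dim
        else:  # GIN_TRANSFORMER: input proj over features ⊕ Laplacian PE
            self.proj = self.add_child("proj", Linear(in_dim + c.pe_dim, c.hidden_dim, rng))
            gin_layers = [
                ("gin", self.add_child(
                    f"gin{i}", GINConv(c.hidden_dim, c.hidden_dim, rng, mu_learnable=c.gin_mu_learnable)
                ))
                for i in range(2)
            ]
            tr = ("transformer", self.add_child(
                "transformer", GraphTransformerLayer(c.hidden_dim, c.transformer_heads, rng)
            ))
            self.layers = [tr] + gin_layers if c.transformer_position == "first" else gin_layers + [tr]
            pooled_dim = c.hidden_dim
        self.fc = self.add_child("fc", Linear(pooled_dim, c.embed_dim, rng))

    def __call__(self, batch: GraphBatch) -> Tensor:
        if self.config.variant == "GIN_TRANSFORMER":
            if batch.pe is None:
                raise ValueError("GraphBatch was built without positional encodings")
            x = self.proj(concat([Tensor(batch.x), Tensor(batch.pe)], axis=-1))
        else:
            x = Tensor(batch.x)
        for kind, layer in self.layers:
            x = layer(x, batch)
            if kind in {"gcn", "gat", "gin"}:
                x = x.relu()
        pooled = global_max_pool(x, batch.node_graph, batch.n_graphs)
        return self.fc(pooled).relu()


class CellLineEncoder(Module):
    """Dense 512 → 1024 → dropout(0.2) → 128 branch over pathway scores."""

    def __init__(self, n_pathways: int, rng: np.random.Generator,
                 dims: tuple[int, int, int] = (512, 1024, 128), dropout: float = 0.2):
        super().__init__()
        self.n_pathways = n_pathways
        d1, d2, d3 = dims
        self.fc1 = self.add_child("fc1", Linear(n_pathways, d1, rng))
        self.fc2 = self.add_child("fc2", Linear(d1, d2, rng))
        self.drop = self.add_child("drop", Dropout(dropout, rng))
        self.fc3 = self.add_child("fc3", Linear(d2, d3, rng))

    def __call__(self, features: Tensor | np.ndarray) -> Tensor:
        if not isinstance(features, Tensor):
            features = Tensor(np.atleast_2d(features))
        if features.data.shape[1] != self.n_pathways:
            raise ValueError(
                f"pathway axis mismatch: expected {self.n_pathways}, got {features.data.shape[1]}"
            )
        h = self.fc1(features).relu()
        h = self.fc2(h).relu()
        h = self.drop(h)
        return self.fc3(h).relu()
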