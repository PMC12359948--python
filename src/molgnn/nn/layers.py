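"""The four message-passing layer families.

Each layer maps per-node embeddings H (n x d_in) to H' (n x d_out) over a
fixed :class:`GraphTopology`. The update rules:

* GCN:       h_i' = sum_{j in N(i) u {i}} W h_j / sqrt(dhat_i dhat_j),
             with dhat_i = 1 + sum_{j in N(i)} e_{j,i} the self-loop-augmented
             (optionally edge-weighted) degree.
* GAT:       h_i' = sum_{j in N(i) u {i}} alpha_ij W h_j, with attention
             alpha_ij the softmax over N(i) u {i} of
             LeakyReLU(a^T [W h_i || W h_j]), single head.
* GraphSAGE: h_i' = W1 h_i + W2 mean_{j in N(i)} h_j (neighbour term zero for
             isolated nodes).
* GIN:       h_i' = MLP((1 + eps) h_i + sum_{j in N(i)} h_j) with a fixed
             scalar eps (default 0) and a two-linear-layer rectified MLP.

The surrounding model applies the activation after each convolution, so the
layers themselves return pre-activation outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from molgnn.nn import autodiff as ad
from molgnn.nn.autodiff import Tensor


@dataclass
class GraphTopology:
    """Precomputed arc structure for one (batched) graph.

    ``src``/``dst`` list every directed arc j -> i once (molecular graphs
    store each bond in both directions, so neighbourhoods are symmetric).
    ``edge_weights`` are the optional non-negative e_{j,i} entering the GCN
    degree; they default to 1.
    """

    n_nodes: int
    src: np.ndarray  # (E,) int
    dst: np.ndarray  # (E,) int
    edge_weights: np.ndarray | None = None

    # derived arrays, built lazily
    _gcn: tuple | None = field(default=None, repr=False)

    def __post_init__(self):
        self.src = np.asarray(self.src, dtype=np.int64)
        self.dst = np.asarray(self.dst, dtype=np.int64)
        if self.src.shape != self.dst.shape:
            raise ValueError("src/dst must be aligned")
        if self.src.size and (self.src == self.dst).any():
            raise ValueError("self-arcs are not allowed in the arc list")
        if self.edge_weights is not None:
            self.edge_weights = np.asarray(self.edge_weights, dtype=np.float64)
            if (self.edge_weights < 0).any():
                raise ValueError("edge weights must be non-negative")

    def gcn_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Arcs with self-loops appended and the symmetric-normalisation
        coefficient 1/sqrt(dhat_i dhat_j) per arc."""
        if self._gcn is None:
            w = self.edge_weights if self.edge_weights is not None else np.ones(self.src.size)
            dhat = np.ones(self.n_nodes)
            np.add.at(dhat, self.dst, w)
            loops = np.arange(self.n_nodes)
            src = np.concatenate([self.src, loops])
            dst = np.concatenate([self.dst, loops])
            coeff = 1.0 / np.sqrt(dhat[dst] * dhat[src])
            self._gcn = (src, dst, coeff)
        return self._gcn

    def with_self_loops(self) -> tuple[np.ndarray, np.ndarray]:
        loops = np.arange(self.n_nodes)
        return (
            np.concatenate([self.src, loops]),
            np.concatenate([self.dst, loops]),
        )

    def in_degree(self) -> np.ndarray:
        return np.bincount(self.dst, minlength=self.n_nodes).astype(np.float64)


class GCNConv:
    """Spectral-motivated convolution with symmetric degree normalisation."""

    conv_type = "gcn"

    def __init__(self, in_dim: int, out_dim: int):
        self.in_dim, self.out_dim = in_dim, out_dim
        self.W = Tensor(np.zeros((out_dim, in_dim)), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return [self.W]

    def forward(self, h: Tensor, topo: GraphTopology) -> Tensor:
        src, dst, coeff = topo.gcn_arrays()
        hw = ad.linear(h, self.W)  # (n, out)
        messages = ad.scale(ad.gather_rows(hw, src), coeff[:, None])
        return ad.segment_sum(messages, dst, topo.n_nodes)


class GATConv:
    """Single-head attention convolution; LeakyReLU slope configurable."""

    conv_type = "gat"

    def __init__(self, in_dim: int, out_dim: int, negative_slope: float = 0.2):
        self.in_dim, self.out_dim = in_dim, out_dim
        self.negative_slope = negative_slope
        self.W = Tensor(np.zeros((out_dim, in_dim)), requires_grad=True)
        # attention vector a of length 2*out, split into the halves applied
        # to the target (i) and source (j) transforms
        self.a = Tensor(np.zeros(2 * out_dim), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return [self.W, self.a]

    def forward(
        self, h: Tensor, topo: GraphTopology, return_attention: bool = False
    ):
        src, dst = topo.with_self_loops()
        hw = ad.linear(h, self.W)  # (n, out)
        # split the attention vector into its target/source halves
        a_dst, a_src = _split_vector(self.a, self.out_dim)
        score_dst = ad.matmul(hw, a_dst)  # (n, 1)
        score_src = ad.matmul(hw, a_src)
        logits = ad.add(
            ad.gather_rows(ad.reshape(score_dst, (-1,)), dst),
            ad.gather_rows(ad.reshape(score_src, (-1,)), src),
        )
        logits = ad.leaky_relu(logits, self.negative_slope)
        alpha = ad.segment_softmax(logits, dst, topo.n_nodes)
        messages = ad.mul(ad.gather_rows(hw, src), ad.reshape(alpha, (-1, 1)))
        out = ad.segment_sum(messages, dst, topo.n_nodes)
        if return_attention:
            return out, (alpha.data.copy(), src, dst)
        return out


def _split_vector(vec: Tensor, k: int) -> tuple[Tensor, Tensor]:
    """Split a 1-d parameter into two (k, 1) column views with gradient flow."""

    def make(offset: int) -> Tensor:
        def backward(g):
            if vec.requires_grad:
                grad = np.zeros_like(vec.data)
                grad[offset : offset + k] = g[:, 0]
                vec._accumulate(grad)

        return Tensor(
            vec.data[offset : offset + k].reshape(k, 1),
            parents=(vec,),
            backward=backward,
        )

    return make(0), make(k)


class SAGEConv:
    """Mean-aggregation convolution with separate self and neighbour weights."""

    conv_type = "sage"

    def __init__(self, in_dim: int, out_dim: int):
        self.in_dim, self.out_dim = in_dim, out_dim
        self.W1 = Tensor(np.zeros((out_dim, in_dim)), requires_grad=True)
        self.W2 = Tensor(np.zeros((out_dim, in_dim)), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return [self.W1, self.W2]

    def forward(self, h: Tensor, topo: GraphTopology) -> Tensor:
        neigh_mean = ad.segment_mean(
            ad.gather_rows(h, topo.src), topo.dst, topo.n_nodes
        )
        return ad.add(ad.linear(h, self.W1), ad.linear(neigh_mean, self.W2))


class GINConv:
    """Sum-aggregation convolution with a two-layer rectified MLP."""

    conv_type = "gin"

    def __init__(self, in_dim: int, out_dim: int, eps: float = 0.0):
        self.in_dim, self.out_dim = in_dim, out_dim
        self.eps = float(eps)  # fixed, not trained
        self.W1 = Tensor(np.zeros((out_dim, in_dim)), requires_grad=True)
        self.b1 = Tensor(np.zeros(out_dim), requires_grad=True)
        self.W2 = Tensor(np.zeros((out_dim, out_dim)), requires_grad=True)
        self.b2 = Tensor(np.zeros(out_dim), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return [self.W1, self.b1, self.W2, self.b2]

    def forward(self, h: Tensor, topo: GraphTopology) -> Tensor:
        neigh_sum = ad.segment_sum(ad.gather_rows(h, topo.src), topo.dst, topo.n_nodes)
        agg = ad.add(ad.scale(h, 1.0 + self.eps), neigh_sum)
        hidden = ad.relu(ad.linear(agg, self.W1, self.b1))
        return ad.linear(hidden, self.W2, self.b2)


CONV_CLASSES = {
    "gcn": GCNConv,
    "gat": GATConv,
    "sage": SAGEConv,
    "gin": GINConv,
}
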