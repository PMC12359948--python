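"""Message-passing layers against independent dense/loop oracles."""

import numpy as np
import pytest

from conftest import random_topology
from oracles import dense_gcn, loop_gat, loop_gin, loop_sage

from molgnn.nn.autodiff import Tensor
from molgnn.nn.layers import GATConv, GCNConv, GINConv, GraphTopology, SAGEConv

N_RANDOM_GRAPHS = 100


def random_case(rng):
    n = int(rng.integers(1, 9))
    d = int(rng.integers(1, 5))
    o = int(rng.integers(1, 5))
    adj, src, dst = random_topology(rng, n)
    H = rng.normal(size=(n, d))
    return n, d, o, adj, src, dst, H


@pytest.mark.parametrize("conv_type", ["gcn", "gat", "sage", "gin"])
def test_layer_matches_brute_force_oracle(conv_type):
    rng = np.random.default_rng(20240100 + hash(conv_type) % 1000)
    for _ in range(N_RANDOM_GRAPHS):
        n, d, o, adj, src, dst, H = random_case(rng)
        topo = GraphTopology(n, src, dst)
        if conv_type == "gcn":
            conv = GCNConv(d, o)
            conv.W.data = rng.normal(size=(o, d))
            expect = dense_gcn(H, adj, conv.W.data)
            got = conv.forward(Tensor(H), topo).data
        elif conv_type == "gat":
            conv = GATConv(d, o)
            conv.W.data = rng.normal(size=(o, d))
            conv.a.data = rng.normal(size=2 * o)
            expect, _ = loop_gat(H, adj, conv.W.data, conv.a.data)
            got = conv.forward(Tensor(H), topo).data
        elif conv_type == "sage":
            conv = SAGEConv(d, o)
            conv.W1.data = rng.normal(size=(o, d))
            conv.W2.data = rng.normal(size=(o, d))
            expect = loop_sage(H, adj, conv.W1.data, conv.W2.data)
            got = conv.forward(Tensor(H), topo).data
        else:
            conv = GINConv(d, o, eps=0.0)
            for p, shape in [("W1", (o, d)), ("b1", (o,)), ("W2", (o, o)), ("b2", (o,))]:
                getattr(conv, p).data = rng.normal(size=shape)
            expect = loop_gin(
                H, adj, conv.W1.data, conv.b1.data, conv.W2.data, conv.b2.data
            )
            got = conv.forward(Tensor(H), topo).data
        assert np.abs(got - expect).max() < 1e-6


def test_gcn_isolated_node_identity():
    """With no neighbours and identity weights the update reduces to the
    self term: h' = h (degree 1)."""
    topo = GraphTopology(1, np.zeros(0, int), np.zeros(0, int))
    conv = GCNConv(2, 2)
    conv.W.data = np.eye(2)
    h = np.array([[3.0, -1.0]])
    assert np.allclose(conv.forward(Tensor(h), topo).data, h)


def test_gcn_two_node_hand_expansion():
    """Two connected nodes, identity W, unit weights: both outputs (0.5, 0.5)."""
    topo = GraphTopology(2, np.array([0, 1]), np.array([1, 0]))
    conv = GCNConv(2, 2)
    conv.W.data = np.eye(2)
    h = np.array([[1.0, 0.0], [0.0, 1.0]])
    out = conv.forward(Tensor(h), topo).data
    assert np.allclose(out, [[0.5, 0.5], [0.5, 0.5]])


def test_gat_attention_rows_sum_to_one():
    rng = np.random.default_rng(5)
    for _ in range(20):
        n = int(rng.integers(2, 9))
        adj, src, dst = random_topology(rng, n)
        conv = GATConv(3, 2)
        conv.W.data = rng.normal(size=(2, 3))
        conv.a.data = rng.normal(size=4)
        _, (alpha, _, seg_dst) = conv.forward(
            Tensor(rng.normal(size=(n, 3))), GraphTopology(n, src, dst), True
        )
        sums = np.zeros(n)
        np.add.at(sums, seg_dst, alpha)
        assert np.allclose(sums, 1.0)


def test_gat_zero_attention_vector_uniform():
    rng = np.random.default_rng(6)
    n = 6
    adj, src, dst = random_topology(rng, n)
    conv = GATConv(3, 2)
    conv.W.data = rng.normal(size=(2, 3))
    conv.a.data = np.zeros(4)
    _, (alpha, _, seg_dst) = conv.forward(
        Tensor(rng.normal(size=(n, 3))), GraphTopology(n, src, dst), True
    )
    degree = adj.sum(axis=1)
    for a, i in zip(alpha, seg_dst):
        assert a == pytest.approx(1.0 / (degree[i] + 1))


def test_sage_degenerate_cases():
    conv = SAGEConv(2, 2)
    conv.W1.data = np.array([[1.0, 0], [0, 1]])
    conv.W2.data = np.array([[2.0, 0], [0, 2]])
    # isolated node: neighbour term zero
    topo0 = GraphTopology(1, np.zeros(0, int), np.zeros(0, int))
    h = np.array([[1.0, 2.0]])
    assert np.allclose(conv.forward(Tensor(h), topo0).data, h)
    # single neighbour: mean term is exactly that neighbour
    topo1 = GraphTopology(2, np.array([0, 1]), np.array([1, 0]))
    h2 = np.array([[1.0, 0.0], [0.0, 1.0]])
    out = conv.forward(Tensor(h2), topo1).data
    assert np.allclose(out[0], h2[0] + 2 * h2[1])


def test_gin_degenerate_and_symmetry():
    rng = np.random.default_rng(8)
    conv = GINConv(3, 2, eps=0.0)
    for p, shape in [("W1", (2, 3)), ("b1", (2,)), ("W2", (2, 2)), ("b2", (2,))]:
        getattr(conv, p).data = rng.normal(size=shape)
    # no neighbours: h' = MLP(h)
    h = rng.normal(size=(1, 3))
    out = conv.forward(
        Tensor(h), GraphTopology(1, np.zeros(0, int), np.zeros(0, int))
    ).data
    hidden = np.maximum(conv.W1.data @ h[0] + conv.b1.data, 0)
    assert np.allclose(out[0], conv.W2.data @ hidden + conv.b2.data)
    # two identical connected nodes: identical outputs
    h2 = np.tile(rng.normal(size=(1, 3)), (2, 1))
    out2 = conv.forward(
        Tensor(h2), GraphTopology(2, np.array([0, 1]), np.array([1, 0]))
    ).data
    assert np.allclose(out2[0], out2[1])


@pytest.mark.parametrize("conv_type", ["gcn", "gat", "sage", "gin"])
def test_permutation_equivariance(conv_type):
    """Relabelling nodes permutes layer outputs identically."""
    rng = np.random.default_rng(99)
    for _ in range(20):
        n = int(rng.integers(2, 9))
        adj, src, dst = random_topology(rng, n)
        d, o = 3, 2
        H = rng.normal(size=(n, d))
        if conv_type == "gcn":
            conv = GCNConv(d, o)
            conv.W.data = rng.normal(size=(o, d))
        elif conv_type == "gat":
            conv = GATConv(d, o)
            conv.W.data = rng.normal(size=(o, d))
            conv.a.data = rng.normal(size=2 * o)
        elif conv_type == "sage":
            conv = SAGEConv(d, o)
            conv.W1.data = rng.normal(size=(o, d))
            conv.W2.data = rng.normal(size=(o, d))
        else:
            conv = GINConv(d, o)
            for p, shape in [("W1", (o, d)), ("b1", (o,)), ("W2", (o, o)), ("b2", (o,))]:
                getattr(conv, p).data = rng.normal(size=shape)
        perm = rng.permutation(n)
        inv = np.argsort(perm)
        out = conv.forward(Tensor(H), GraphTopology(n, src, dst)).data
        out_p = conv.forward(
            Tensor(H[perm]), GraphTopology(n, inv[src], inv[dst])
        ).data
        assert np.abs(out_p - out[perm]).max() < 1e-6


def test_gcn_edge_weights_enter_degrees():
    """Non-unit arc weights change the augmented degrees per the update rule."""
    src = np.array([0, 1])
    dst = np.array([1, 0])
    w = np.array([3.0, 3.0])
    topo = GraphTopology(2, src, dst, edge_weights=w)
    conv = GCNConv(1, 1)
    conv.W.data = np.array([[1.0]])
    h = np.array([[1.0], [1.0]])
    out = conv.forward(Tensor(h), topo).data
    # dhat = 1 + 3 = 4 for both nodes: each output = (1/4 + 1/4)
    assert np.allclose(out, 0.5)


def test_topology_rejects_self_arcs_and_negative_weights():
    with pytest.raises(ValueError):
        GraphTopology(2, np.array([0]), np.array([0]))
    with pytest.raises(ValueError):
        GraphTopology(
            2, np.array([0]), np.array([1]), edge_weights=np.array([-1.0])
        )
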