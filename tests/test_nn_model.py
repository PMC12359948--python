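"""Model stack, initialisation, losses and gradients."""

import numpy as np
import pytest

from molgnn.featurize import MolecularGraph
from molgnn.nn.autodiff import Tensor
from molgnn.nn import autodiff as ad
from molgnn.nn.model import (
    GNNModel,
    ModelConfig,
    logit_loss,
    make_batch,
    predict_scores,
    xavier_init,
)


def random_graphs(rng, k=4, d=5):
    graphs = []
    for i in range(k):
        n = int(rng.integers(1, 7))
        adj = (rng.random((n, n)) < 0.5).astype(float)
        adj = np.triu(adj, 1)
        adj = adj + adj.T
        src, dst = np.nonzero(adj)
        arcs = (
            np.stack([src, dst], axis=1) if src.size else np.zeros((0, 2), dtype=int)
        )
        graphs.append(
            MolecularGraph(
                f"g{i}", rng.normal(size=(n, d)), arcs, np.zeros((src.size, 2)), i % 2
            )
        )
    return graphs


@pytest.mark.parametrize("conv_type", ["gcn", "gat", "sage", "gin"])
def test_model_output_shape_and_widths(conv_type):
    rng = np.random.default_rng(1)
    graphs = random_graphs(rng, k=5)
    batch = make_batch(graphs)
    config = ModelConfig(conv_type=conv_type, in_dim=5, hidden_channels=8, dropout=0.0)
    model = xavier_init(GNNModel(config), 0)
    logits = model.forward(batch)
    assert logits.data.shape == (5,)
    # funnel widths 2h -> h -> h/2
    assert [c.out_dim for c in model.convs] == [16, 8, 4]


def test_evaluation_mode_deterministic_despite_dropout_config():
    rng = np.random.default_rng(2)
    graphs = random_graphs(rng)
    batch = make_batch(graphs)
    config = ModelConfig(conv_type="gcn", in_dim=5, hidden_channels=4, dropout=0.5)
    model = xavier_init(GNNModel(config), 3)
    s1 = predict_scores(model, batch)
    s2 = predict_scores(model, batch)
    assert np.array_equal(s1, s2)
    # training mode with a generator perturbs activations
    t1 = model.forward(batch, rng=np.random.default_rng(0)).data
    t2 = model.forward(batch, rng=np.random.default_rng(1)).data
    assert not np.allclose(t1, t2)


def test_model_forward_permutation_invariant():
    """Pooled per-graph outputs are unchanged by node relabelling."""
    rng = np.random.default_rng(3)
    graphs = random_graphs(rng, k=3)
    config = ModelConfig(conv_type="gin", in_dim=5, hidden_channels=4, dropout=0.0)
    model = xavier_init(GNNModel(config), 7)
    base = model.forward(make_batch(graphs)).data
    permuted = []
    for g in graphs:
        perm = rng.permutation(g.n_nodes)
        inv = np.argsort(perm)
        arcs = (
            np.stack([inv[g.arcs[:, 0]], inv[g.arcs[:, 1]]], axis=1)
            if g.n_arcs
            else g.arcs
        )
        permuted.append(
            MolecularGraph(g.graph_id, g.node_matrix[perm], arcs, g.edge_matrix, g.label)
        )
    out = model.forward(make_batch(permuted)).data
    assert np.abs(out - base).max() < 1e-6


def test_xavier_reproducible_and_scaled():
    config = ModelConfig(conv_type="gcn", in_dim=512, hidden_channels=256)
    m1 = xavier_init(GNNModel(config), 11)
    m2 = xavier_init(GNNModel(config), 11)
    assert m1.parameter_hash() == m2.parameter_hash()
    m3 = xavier_init(GNNModel(config), 12)
    assert m3.parameter_hash() != m1.parameter_hash()
    W = m1.convs[0].W.data  # 512 x 512
    expect_var = 2.0 / (W.shape[0] + W.shape[1])
    assert abs(W.var() / expect_var - 1) < 0.2


def test_logit_loss_closed_forms():
    assert logit_loss(Tensor([0.0]), [1]).data == pytest.approx(np.log(2), abs=1e-12)
    assert logit_loss(Tensor([30.0]), [1]).data < 1e-12
    # extreme negative logit: finite, no overflow, matches log-sum-exp form
    val = logit_loss(Tensor([-100.0]), [0]).data
    assert np.isfinite(val)
    assert val == pytest.approx(np.log1p(np.exp(-100.0)), abs=1e-15)
    with pytest.raises(ValueError):
        logit_loss(Tensor([0.0]), [2])


def test_binary_and_two_class_losses_agree():
    """Two-logit cross-entropy with logits (0, z) equals sigmoid loss on z."""
    rng = np.random.default_rng(4)
    z = rng.normal(size=6) * 3
    labels = rng.integers(0, 2, size=6)
    binary = logit_loss(Tensor(z), labels, "binary").data
    two = logit_loss(
        Tensor(np.stack([np.zeros_like(z), z], axis=1)), labels, "two_class"
    ).data
    assert binary == pytest.approx(two, abs=1e-6)


@pytest.mark.parametrize("conv_type", ["gcn", "gat", "sage", "gin"])
def test_gradients_match_finite_differences(conv_type):
    """Analytic gradients of loss(model(batch)) vs central differences on a
    2-graph batch at a random (kink-free) parameter point."""
    rng = np.random.default_rng(17)
    graphs = random_graphs(rng, k=2)
    batch = make_batch(graphs)
    config = ModelConfig(conv_type=conv_type, in_dim=5, hidden_channels=4, dropout=0.0)
    model = GNNModel(config)
    for p in model.parameters():
        p.data = rng.normal(size=p.data.shape) * 0.7

    def loss_value():
        return logit_loss(model.forward(batch), batch.labels).data.item()

    loss = logit_loss(model.forward(batch), batch.labels)
    loss.backward()
    for p in model.parameters():
        flat = p.data.reshape(-1)
        grad = p.grad.reshape(-1) if p.grad is not None else np.zeros(flat.size)
        for idx in range(0, flat.size, max(1, flat.size // 4)):
            eps = 1e-6
            orig = flat[idx]
            flat[idx] = orig + eps
            lp = loss_value()
            flat[idx] = orig - eps
            lm = loss_value()
            flat[idx] = orig
            fd = (lp - lm) / (2 * eps)
            denom = max(abs(fd), abs(grad[idx]), 1e-6)
            assert abs(fd - grad[idx]) / denom < 1e-4


def test_checkpoint_roundtrip_and_schema_guard(tmp_path):
    from molgnn.featurize import FeatureSchema

    rng = np.random.default_rng(5)
    config = ModelConfig(conv_type="sage", in_dim=5, hidden_channels=4)
    model = xavier_init(GNNModel(config), 21)
    header = FeatureSchema("basic").header()
    path = tmp_path / "ckpt.npz"
    model.save_checkpoint(path, schema_header=header)
    back = GNNModel.load_checkpoint(path, schema_header=header)
    assert back.parameter_hash() == model.parameter_hash()
    assert back.config == model.config
    with pytest.raises(ValueError):
        GNNModel.load_checkpoint(path, schema_header=FeatureSchema("custom").header())


def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(conv_type="gcn", in_dim=5, hidden_channels=7)  # odd
    with pytest.raises(ValueError):
        ModelConfig(conv_type="nope", in_dim=5)
    with pytest.raises(ValueError):
        ModelConfig(conv_type="gcn", in_dim=5, dropout=1.0)
    with pytest.raises(ValueError):
        make_batch([])
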