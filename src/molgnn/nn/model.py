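"""Three-layer graph classifier with pooling, dropout and logit losses.

Layer widths follow a 2h -> h -> h/2 funnel for ``hidden_channels = h``, each
convolution followed by a ReLU; dropout acts after the third convolution;
global mean pooling produces one vector per graph which a final linear layer
maps to a single logit (binary mode) or two logits (two-class cross-entropy
mode). The sigmoid/softmax lives inside the loss, not the forward pass.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from molgnn.featurize import MolecularGraph
from molgnn.nn import autodiff as ad
from molgnn.nn.autodiff import Tensor
from molgnn.nn.layers import CONV_CLASSES, GraphTopology


@dataclass
class ModelConfig:
    conv_type: Literal["gcn", "gat", "sage", "gin"]
    in_dim: int
    hidden_channels: int = 64
    dropout: float = 0.1
    learning_rate: float = 1e-3
    batch_size: int = 32
    seed: int = 0
    max_epochs: int = 500
    patience: int = 50
    n_output_logits: int = 1
    gin_eps: float = 0.0
    attn_negative_slope: float = 0.2

    def __post_init__(self):
        if self.conv_type not in CONV_CLASSES:
            raise ValueError(f"unknown conv_type {self.conv_type!r}")
        if self.hidden_channels < 2 or self.hidden_channels % 2:
            raise ValueError("hidden_channels must be an even integer >= 2")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.n_output_logits not in (1, 2):
            raise ValueError("n_output_logits must be 1 or 2")


@dataclass
class GraphBatch:
    """Graphs stacked into one disjoint union for vectorised passes."""

    x: np.ndarray  # (N, d) stacked node features
    topology: GraphTopology
    node_graph: np.ndarray  # (N,) membership: node -> graph index
    labels: np.ndarray  # (k,) int
    n_graphs: int


def make_batch(
    graphs: Sequence[MolecularGraph],
    edge_weight_fn=None,
    label_task: int | None = None,
) -> GraphBatch:
    """Assemble a disjoint-union batch from featurised graphs.

    ``edge_weight_fn`` optionally maps an edge-feature row to a non-negative
    scalar arc weight (consumed by the GCN degree normalisation); default is
    unit weights. ``label_task`` selects one column of multi-task labels.
    """
    if len(graphs) == 0:
        raise ValueError("empty batch")
    xs, srcs, dsts, membership, labels, weights = [], [], [], [], [], []
    offset = 0
    for gi, g in enumerate(graphs):
        xs.append(g.node_matrix)
        if g.n_arcs:
            srcs.append(g.arcs[:, 0] + offset)
            dsts.append(g.arcs[:, 1] + offset)
            if edge_weight_fn is not None:
                weights.append(
                    np.array([edge_weight_fn(row) for row in g.edge_matrix])
                )
        membership.append(np.full(g.n_nodes, gi, dtype=np.int64))
        label = g.label
        if isinstance(label, tuple):
            if label_task is None:
                raise ValueError("multi-task labels need label_task")
            label = label[label_task]
        labels.append(label)
        offset += g.n_nodes
    topo = GraphTopology(
        n_nodes=offset,
        src=np.concatenate(srcs) if srcs else np.zeros(0, dtype=np.int64),
        dst=np.concatenate(dsts) if dsts else np.zeros(0, dtype=np.int64),
        edge_weights=np.concatenate(weights) if weights else None,
    )
    return GraphBatch(
        x=np.concatenate(xs),
        topology=topo,
        node_graph=np.concatenate(membership),
        labels=np.array(labels),
        n_graphs=len(graphs),
    )


class GNNModel:
    """Stack of three convolutions + pooling + linear output head."""

    def __init__(self, config: ModelConfig):
        self.config = config
        h = config.hidden_channels
        widths = [config.in_dim, 2 * h, h, h // 2]
        cls = CONV_CLASSES[config.conv_type]
        kwargs = {}
        if config.conv_type == "gin":
            kwargs["eps"] = config.gin_eps
        elif config.conv_type == "gat":
            kwargs["negative_slope"] = config.attn_negative_slope
        self.convs = [
            cls(widths[i], widths[i + 1], **kwargs) for i in range(3)
        ]
        self.out_W = Tensor(
            np.zeros((config.n_output_logits, h // 2)), requires_grad=True
        )
        self.out_b = Tensor(np.zeros(config.n_output_logits), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        params = []
        for conv in self.convs:
            params.extend(conv.parameters())
        params.extend([self.out_W, self.out_b])
        return params

    def forward(
        self, batch: GraphBatch, rng: np.random.Generator | None = None
    ) -> Tensor:
        """Per-graph logits: (k,) in binary mode, (k, 2) in two-class mode.

        Pass a generator as ``rng`` to enable dropout (training mode);
        ``rng=None`` is deterministic evaluation mode.
        """
        if batch.n_graphs < 1:
            raise ValueError("empty batch")
        h = Tensor(batch.x)
        for conv in self.convs:
            h = ad.relu(conv.forward(h, batch.topology))
        h = ad.dropout(h, self.config.dropout, rng)
        pooled = ad.segment_mean(h, batch.node_graph, batch.n_graphs)
        logits = ad.linear(pooled, self.out_W, self.out_b)
        if self.config.n_output_logits == 1:
            logits = ad.reshape(logits, (-1,))
        return logits

    # -- parameter state ---------------------------------------------------
    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state does not match model parameters")
        for p, arr in zip(params, state):
            if p.data.shape != arr.shape:
                raise ValueError("parameter shape mismatch")
            p.data = arr.copy()

    def parameter_hash(self) -> str:
        digest = hashlib.sha256()
        for p in self.parameters():
            digest.update(np.ascontiguousarray(p.data).tobytes())
        return digest.hexdigest()

    # -- checkpointing -----------------------------------------------------
    def save_checkpoint(self, path: str | Path, schema_header: dict | None = None) -> None:
        """Portable checkpoint: config + parameters + schema hash."""
        path = Path(path)
        schema_hash = (
            hashlib.sha256(
                json.dumps(schema_header, sort_keys=True).encode()
            ).hexdigest()
            if schema_header is not None
            else None
        )
        meta = {"config": asdict(self.config), "schema_hash": schema_hash}
        arrays = {f"p{i}": arr for i, arr in enumerate(self.state_dict())}
        np.savez(path, meta=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load_checkpoint(
        cls, path: str | Path, schema_header: dict | None = None
    ) -> "GNNModel":
        with np.load(path, allow_pickle=False) as npz:
            meta = json.loads(str(npz["meta"]))
            state = [npz[f"p{i}"] for i in range(len(npz.files) - 1)]
        if schema_header is not None and meta["schema_hash"] is not None:
            expect = hashlib.sha256(
                json.dumps(schema_header, sort_keys=True).encode()
            ).hexdigest()
            if expect != meta["schema_hash"]:
                raise ValueError("checkpoint was trained on an incompatible schema")
        model = cls(ModelConfig(**meta["config"]))
        model.load_state(state)
        return model


def xavier_init(model: GNNModel, seed: int) -> GNNModel:
    """Glorot-uniform initialisation of every weight matrix; biases zero.

    Bounds are +/- sqrt(6 / (fan_in + fan_out)), giving variance
    2 / (fan_in + fan_out). Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    for p in model.parameters():
        if p.data.ndim >= 2:
            fan_out, fan_in = p.data.shape[-2], p.data.shape[-1]
            bound = np.sqrt(6.0 / (fan_in + fan_out))
            p.data = rng.uniform(-bound, bound, size=p.data.shape)
        elif p.data.ndim == 1 and p is not model.out_b and p.data.size > 0:
            # attention vectors: treat as (2*out -> 1) maps
            bound = np.sqrt(6.0 / (p.data.size + 1))
            p.data = rng.uniform(-bound, bound, size=p.data.shape)
    # biases (1-d zero-init) are recognisable by being left zero above only
    # for out_b; re-zero all bias-like parameters explicitly:
    for conv in model.convs:
        for name in ("b1", "b2"):
            if hasattr(conv, name):
                getattr(conv, name).data = np.zeros_like(getattr(conv, name).data)
    model.out_b.data = np.zeros_like(model.out_b.data)
    return model


def logit_loss(
    logits: Tensor,
    labels: Sequence[int],
    mode: Literal["binary", "two_class"] = "binary",
) -> Tensor:
    """Classification loss on raw logits.

    ``binary``: numerically stable sigmoid cross-entropy on (k,) logits.
    ``two_class``: softmax cross-entropy on (k, 2) logits.
    """
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    if mode == "binary":
        return ad.bce_with_logits(logits, labels.astype(float))
    if mode == "two_class":
        return ad.softmax_cross_entropy(logits, labels.astype(int))
    raise ValueError(f"unknown loss mode {mode!r}")


def predict_scores(model: GNNModel, batch: GraphBatch) -> np.ndarray:
    """Positive-class probabilities in evaluation mode (deterministic)."""
    logits = model.forward(batch, rng=None).data
    if model.config.n_output_logits == 1:
        return 1.0 / (1.0 + np.exp(-logits))
    shifted = logits - logits.max(axis=1, keepdims=True)
    soft = np.exp(shifted)
    soft /= soft.sum(axis=1, keepdims=True)
    return soft[:, 1]
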