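"""Per-residue binding classifiers: graph attention network (GAT), graph
convolutional network (GCN), and the structure-blind sequence baseline (MLP).

All three end in a dense layer with a two-way softmax per residue; the MLP
sees exactly the same node features but ignores the edge set entirely, which
is what makes GAT-vs-MLP comparisons a measure of the structural signal.

Default hyperparameters: 512 hidden units per layer, ReLU activations,
dropout 0.5 for the graph models (0.1 for the MLP), 4 attention heads with
concatenated head outputs (128 units per head), residual connections for the
graph models and batch normalization for the GCN.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _nn
from .graph_builder import ResidueGraph

__all__ = ["ModelSpec", "PredictionResult", "BindingClassifier", "build_model",
           "forward", "predict", "save_checkpoint", "load_checkpoint"]


@dataclass
class ModelSpec:
    """Architecture hyperparameters.

    ``dropout=None`` resolves to the architecture default (0.5 for gat/gcn,
    0.1 for mlp); ``hidden_units`` is the total layer width — for the GAT it
    is split across ``n_heads`` concatenated heads.
    """

    arch: str = "gat"  # gat | gcn | mlp
    n_layers: int = 1
    hidden_units: int = 512
    n_heads: int = 4
    dropout: float | None = None
    residual: bool = True
    batchnorm: bool | None = None  # None -> on for gcn only

    def __post_init__(self) -> None:
        if self.arch not in {"gat", "gcn", "mlp"}:
            raise ValueError(f"unknown arch {self.arch!r}")
        if self.n_layers < 1 or self.hidden_units < 1 or self.n_heads < 1:
            raise ValueError("n_layers, hidden_units, n_heads must be >= 1")
        if self.dropout is None:
            self.dropout = 0.1 if self.arch == "mlp" else 0.5
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.batchnorm is None:
            self.batchnorm = self.arch == "gcn"


@dataclass
class PredictionResult:
    """Thresholded per-residue predictions for one chain."""

    chain_ref: str
    probs: np.ndarray  # (L,) binding-class probability
    labels_pred: np.ndarray  # (L,) int; 1 iff probs >= threshold
    threshold: float

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if ((self.probs < 0) | (self.probs > 1)).any():
            raise ValueError("probabilities outside [0, 1]")
        self.labels_pred = np.asarray(self.labels_pred, dtype=int)


class BindingClassifier:
    """A ModelSpec instantiated with weights; one forward pass per graph."""

    def __init__(self, spec: ModelSpec, in_dim: int, seed: int = 0):
        self.spec = spec
        self.in_dim = in_dim
        rng = np.random.default_rng(seed)
        self.layers = []
        dim = in_dim
        if spec.arch == "gat":
            for _ in range(spec.n_layers):
                self.layers.append(_nn.GATLayer(
                    rng, dim, spec.hidden_units, spec.n_heads,
                    spec.dropout, spec.residual))
                dim = spec.hidden_units
        elif spec.arch == "gcn":
            for _ in range(spec.n_layers):
                self.layers.append(_nn.GCNLayer(
                    rng, dim, spec.hidden_units, spec.dropout,
                    spec.residual, spec.batchnorm))
                dim = spec.hidden_units
        else:  # mlp: n_layers hidden blocks, edges never consulted
            self.hidden = [_nn.Dense(rng, dim if i == 0 else spec.hidden_units,
                                     spec.hidden_units)
                           for i in range(spec.n_layers)]
            dim = spec.hidden_units
        self.head = _nn.Dense(rng, dim, 2)

    # -- parameters ---------------------------------------------------------
    def parameters(self) -> list:
        ps = []
        if self.spec.arch == "mlp":
            for layer in self.hidden:
                ps += layer.parameters()
        else:
            for layer in self.layers:
                ps += layer.parameters()
        return ps + self.head.parameters()

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state does not match parameter count")
        for p, s in zip(params, state):
            if p.data.shape != s.shape:
                raise ValueError("parameter shape mismatch")
            p.data = s.copy()

    # -- forward ------------------------------------------------------------
    def prepare(self, graph: ResidueGraph):
        """Precompute the per-graph message-passing context."""
        if graph.features is None:
            raise ValueError("graph has no node features attached")
        if graph.features.shape[1] != self.in_dim:
            raise ValueError(
                f"feature dim {graph.features.shape[1]} != model input dim {self.in_dim}"
            )
        x = graph.features
        if self.spec.arch == "gat":
            return x, graph.adjacency(self_loops=True)
        if self.spec.arch == "gcn":
            return x, _nn.Tensor(_nn.normalized_adjacency(graph.adjacency()))
        return x, None

    def logits(self, prepared, training: bool = False,
               rng: np.random.Generator | None = None) -> _nn.Tensor:
        x_np, ctx = prepared
        h = _nn.Tensor(x_np)
        if self.spec.arch == "gat":
            for layer in self.layers:
                h = layer(h, ctx, training, rng)
        elif self.spec.arch == "gcn":
            for layer in self.layers:
                h = layer(h, ctx, training, rng)
        else:
            for layer in self.hidden:
                h = _nn.relu(layer(h))
                if training:
                    h = _nn.dropout(h, self.spec.dropout, rng)
        return self.head(h)

    def predict_proba(self, graph: ResidueGraph) -> np.ndarray:
        """Evaluation-mode class probabilities, rows summing to 1."""
        z = self.logits(self.prepare(graph), training=False)
        return _nn.softmax_rows(z.data)


def build_model(spec: ModelSpec, in_dim: int, seed: int = 0) -> BindingClassifier:
    return BindingClassifier(spec, in_dim, seed)


def forward(model: BindingClassifier, graph: ResidueGraph) -> np.ndarray:
    """(L, 2) class-probability matrix in deterministic evaluation mode."""
    return model.predict_proba(graph)


def predict(model: BindingClassifier, graph: ResidueGraph,
            threshold: float = 0.5) -> PredictionResult:
    probs = model.predict_proba(graph)[:, 1]
    return PredictionResult(
        chain_ref=graph.chain_ref,
        probs=probs,
        labels_pred=(probs >= threshold).astype(int),
        threshold=threshold,
    )


def save_checkpoint(model: BindingClassifier, weights_path, spec_path) -> None:
    """Weights as an NPZ archive plus a JSON ModelSpec sidecar."""
    np.savez(weights_path, **{f"p{i}": w for i, w in enumerate(model.state_dict())})
    with open(spec_path, "w") as fh:
        json.dump({"spec": asdict(model.spec), "in_dim": model.in_dim}, fh)


def load_checkpoint(weights_path, spec_path) -> BindingClassifier:
    with open(spec_path) as fh:
        meta = json.load(fh)
    model = BindingClassifier(ModelSpec(**meta["spec"]), meta["in_dim"])
    with np.load(weights_path) as arc:
        state = [arc[f"p{i}"] for i in range(len(arc.files))]
    model.load_state_dict(state)
    return model
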