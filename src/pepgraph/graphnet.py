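"""Graph node classification over the function-label graph.

Multi-label prediction is recast as node classification: each function
label is a node of a fully connected graph.  A per-node linear encoder
maps the peptide representation ``p`` to node features ``h_i``; stacked
multi-head graph attention (GAT) layers update the node features using
learned attention coefficients γ over the label graph; per-node binary
classifiers turn the updated features into label probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from ._autodiff import Parameter, Tensor
from .seqdata import LabelSpace
from . import encoders as _enc


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class PredictionResult:
    """Per-label probabilities and the thresholded label set."""

    probabilities: np.ndarray
    labels: frozenset[str]
    threshold: float

    @classmethod
    def from_probabilities(cls, probs: np.ndarray, label_space: LabelSpace,
                           threshold: float) -> "PredictionResult":
        labels = frozenset(
            n for n, p in zip(label_space.names, probs) if p >= threshold
        )
        return cls(np.asarray(probs, dtype=np.float64), labels, float(threshold))


@dataclass(frozen=True)
class GraphTopology:
    """Adjacency over the M label nodes (symmetric, with self-loops)."""

    adjacency: np.ndarray

    @classmethod
    def fully_connected(cls, M: int) -> "GraphTopology":
        return cls(np.ones((M, M)))

    def __post_init__(self):
        a = np.asarray(self.adjacency, dtype=np.float64)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ModelError("adjacency must be square")
        if not np.allclose(a, a.T):
            raise ModelError("adjacency must be symmetric")
        if (a.sum(axis=1) == 0).any():
            raise ModelError("isolated node: every node needs a non-empty neighborhood")
        object.__setattr__(self, "adjacency", a)

    @property
    def M(self) -> int:
        return self.adjacency.shape[0]


@dataclass(frozen=True)
class GraphModelConfig:
    """Shapes and knobs of the graph classifier.

    ``d_node`` must equal ``gat_heads * gat_head_dim`` so that the per-node
    classifiers can consume either the GAT output (heads concatenated) or,
    in the GAT-less ablation, the node-encoder output directly with the
    same weight shapes.
    """

    d_node: int = 32
    gat_heads: int = 4
    gat_head_dim: int = 8
    n_gat_layers: int = 2
    leaky_slope: float = 0.2
    node_dropout: float = 0.1
    use_gat: bool = True
    threshold: float = 0.5
    classifier_bias: bool = True

    def __post_init__(self):
        if self.gat_heads * self.gat_head_dim != self.d_node:
            raise ModelError(
                f"gat_heads*gat_head_dim = {self.gat_heads * self.gat_head_dim} "
                f"must equal d_node = {self.d_node} (concatenation contract)"
            )


class GATLayer:
    """One multi-head graph attention layer (concatenating heads)."""

    def __init__(self, d_in: int, n_heads: int, d_head: int,
                 leaky_slope: float = 0.2, activation: str = "elu",
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.n_heads = n_heads
        self.d_head = d_head
        self.leaky_slope = leaky_slope
        self.activation = activation
        scale = np.sqrt(1.0 / d_in)
        self.W = Parameter(rng.normal(0.0, scale, size=(n_heads, d_in, d_head)))
        self.a_src = Parameter(rng.normal(0.0, scale, size=(n_heads, d_head)))
        self.a_dst = Parameter(rng.normal(0.0, scale, size=(n_heads, d_head)))

    def parameters(self) -> list[Parameter]:
        return [self.W, self.a_src, self.a_dst]

    def attention(self, h: Tensor, topology: GraphTopology) -> tuple[Tensor, Tensor]:
        """Attention coefficients γ (B, K, M, M) and projected features Wh."""
        B, M, d_in = h.shape
        K, dh = self.n_heads, self.d_head
        wh = h.reshape(B, 1, M, d_in) @ self.W  # (B,K,M,dh)
        e_src = (wh * self.a_src.reshape(1, K, 1, dh)).sum(axis=-1, keepdims=True)
        e_dst = (wh * self.a_dst.reshape(1, K, 1, dh)).sum(axis=-1, keepdims=True)
        e = (e_src + e_dst.swapaxes(-1, -2)).leaky_relu(self.leaky_slope)  # (B,K,M,M)
        mask = np.where(topology.adjacency > 0, 0.0, -1e9)
        gamma = (e + mask).softmax(axis=-1)
        return gamma, wh

    def forward(self, h: Tensor, topology: GraphTopology) -> tuple[Tensor, Tensor]:
        """Updated node features (B, M, K*d_head) and the γ coefficients."""
        gamma, wh = self.attention(h, topology)
        out = gamma @ wh  # (B,K,M,dh)
        if self.activation == "elu":
            out = out.elu()
        elif self.activation != "identity":
            raise ModelError(f"unknown activation {self.activation!r}")
        B, K, M, dh = out.shape
        return out.swapaxes(1, 2).reshape(B, M, K * dh), gamma


class GraphNodeClassifier:
    """Full model: peptide encoder -> node encoders -> GAT -> classifiers."""

    def __init__(self, encoder, label_space: LabelSpace,
                 config: GraphModelConfig | None = None, seed: int = 0,
                 topology: GraphTopology | None = None):
        self.encoder = encoder
        self.label_space = label_space
        self.config = config or GraphModelConfig()
        self.topology = topology or GraphTopology.fully_connected(label_space.M)
        if self.topology.M != label_space.M:
            raise ModelError("topology size does not match label space")
        cfg = self.config
        M = label_space.M
        rng = np.random.default_rng(seed)
        d_repr = encoder.d_repr
        self.node_W = Parameter(
            rng.normal(0.0, np.sqrt(1.0 / d_repr), size=(M, d_repr, cfg.d_node))
        )
        self.gat_layers: list[GATLayer] = []
        if cfg.use_gat:
            d_in = cfg.d_node
            for li in range(cfg.n_gat_layers):
                act = "elu" if li < cfg.n_gat_layers - 1 else "identity"
                self.gat_layers.append(
                    GATLayer(d_in, cfg.gat_heads, cfg.gat_head_dim,
                             cfg.leaky_slope, act, rng)
                )
                d_in = cfg.gat_heads * cfg.gat_head_dim
        self.clf_W = Parameter(rng.normal(0.0, np.sqrt(1.0 / cfg.d_node), size=(M, cfg.d_node)))
        self.clf_b = Parameter(np.zeros(M)) if cfg.classifier_bias else None

    # -- parameter groups ---------------------------------------------

    def encoder_parameters(self) -> list[Parameter]:
        return self.encoder.parameters()

    def graph_parameters(self) -> list[Parameter]:
        out = [self.node_W, self.clf_W]
        if self.clf_b is not None:
            out.append(self.clf_b)
        for lay in self.gat_layers:
            out.extend(lay.parameters())
        return out

    def parameters(self) -> list[Parameter]:
        return self.encoder_parameters() + self.graph_parameters()

    def perturbation_site(self) -> Parameter | None:
        return self.encoder.perturbation_site()

    # -- stages --------------------------------------------------------

    def node_encode(self, p: Tensor, training: bool = False,
                    rng: np.random.Generator | None = None) -> Tensor:
        """h_i = dropout(W_i · p) for each label node; (B, M, d_node)."""
        B, d_repr = p.shape
        h = (p.reshape(B, 1, 1, d_repr) @ self.node_W).reshape(
            B, self.label_space.M, self.config.d_node
        )
        rate = self.config.node_dropout
        if training and rate > 0.0:
            if rng is None:
                rng = np.random.default_rng()
            keep = (rng.random(h.shape) >= rate).astype(np.float64) / (1.0 - rate)
            h = h * keep
        return h

    def node_classify_tensor(self, h: Tensor) -> Tensor:
        logits = (h * self.clf_W).sum(axis=-1)
        if self.clf_b is not None:
            logits = logits + self.clf_b
        return logits.sigmoid()

    def forward_batch(self, inputs, training: bool = False,
                      rng: np.random.Generator | None = None,
                      trace: bool = False):
        """Probabilities (B, M) plus, when tracing, attention tensors.

        Returns ``(probs, trace_dict)`` where ``trace_dict`` holds
        ``"beta"`` (encoder attention maps, if the encoder produces them)
        and ``"gamma"`` (per-GAT-layer coefficients, each (B, K, M, M)).
        """
        p, betas = self.encoder.encode_batch(inputs, training=training, rng=rng,
                                             trace=trace)
        h = self.node_encode(p, training=training, rng=rng)
        gammas = []
        for lay in self.gat_layers:
            h, gamma = lay.forward(h, self.topology)
            if trace:
                gammas.append(gamma.data)
        probs = self.node_classify_tensor(h)
        return probs, {"beta": betas, "gamma": gammas}

    def predict(self, inputs, threshold: float | None = None,
                trace: bool = False):
        thr = self.config.threshold if threshold is None else threshold
        probs, tr = self.forward_batch(inputs, training=False, trace=trace)
        results = [
            PredictionResult.from_probabilities(row, self.label_space, thr)
            for row in probs.data
        ]
        return (results, tr) if trace else results

    # -- persistence ----------------------------------------------------

    def save(self, path) -> None:
        cfg = asdict(self.config)
        header = {
            "labels": list(self.label_space.names),
            "config": cfg,
            "encoder": _encoder_spec(self.encoder),
        }
        arrays = {"node_W": self.node_W.data, "clf_W": self.clf_W.data,
                  "adjacency": self.topology.adjacency}
        if self.clf_b is not None:
            arrays["clf_b"] = self.clf_b.data
        for i, lay in enumerate(self.gat_layers):
            arrays[f"gat{i}_W"] = lay.W.data
            arrays[f"gat{i}_a_src"] = lay.a_src.data
            arrays[f"gat{i}_a_dst"] = lay.a_dst.data
        for j, p in enumerate(self.encoder.parameters()):
            arrays[f"enc{j}"] = p.data
        if getattr(self.encoder, "scaler_mu", None) is not None:
            arrays["scaler_mu"] = self.encoder.scaler_mu
            arrays["scaler_sd"] = self.encoder.scaler_sd
        np.savez(path, header=json.dumps(header), **arrays)

    @classmethod
    def load(cls, path) -> "GraphNodeClassifier":
        with np.load(path, allow_pickle=False) as z:
            header = json.loads(str(z["header"]))
            arrays = {k: z[k] for k in z.files if k != "header"}
        encoder = _encoder_from_spec(header["encoder"])
        model = cls(
            encoder,
            LabelSpace(tuple(header["labels"])),
            GraphModelConfig(**header["config"]),
            topology=GraphTopology(arrays["adjacency"]),
        )
        model.node_W.data = arrays["node_W"]
        model.clf_W.data = arrays["clf_W"]
        if model.clf_b is not None:
            model.clf_b.data = arrays["clf_b"]
        for i, lay in enumerate(model.gat_layers):
            lay.W.data = arrays[f"gat{i}_W"]
            lay.a_src.data = arrays[f"gat{i}_a_src"]
            lay.a_dst.data = arrays[f"gat{i}_a_dst"]
        for j, p in enumerate(model.encoder.parameters()):
            p.data = arrays[f"enc{j}"]
        if "scaler_mu" in arrays:
            model.encoder.scaler_mu = arrays["scaler_mu"]
            model.encoder.scaler_sd = arrays["scaler_sd"]
        return model


def _encoder_spec(encoder) -> dict:
    if isinstance(encoder, _enc.CompositionEncoder):
        return {
            "kind": "composition",
            "feature": asdict(encoder.config),
            "project_to": None if encoder.W is None else encoder.d_repr,
            "standardize": encoder.standardize,
        }
    if isinstance(encoder, _enc.TransformerEncoder):
        return {"kind": "transformer", "params": asdict(encoder.params)}
    raise ModelError(f"encoder {type(encoder).__name__} is not checkpointable")


def _encoder_from_spec(spec: dict):
    if spec["kind"] == "composition":
        return _enc.CompositionEncoder(
            _enc.CompositionFeatureConfig(**spec["feature"]),
            project_to=spec["project_to"],
            standardize=spec.get("standardize", False),
        )
    if spec["kind"] == "transformer":
        return _enc.TransformerEncoder(_enc.TransformerParams(**spec["params"]))
    raise ModelError(f"unknown encoder kind {spec['kind']!r}")


def build_composition_model(label_space: LabelSpace, feature_kind: str = "DP",
                            project_to: int = 32, standardize: bool = True,
                            use_gat: bool = True, seed: int = 0,
                            config: GraphModelConfig | None = None) -> GraphNodeClassifier:
    """The standard desk-scale model recipe: standardized composition
    features, a learned projection, and the label-graph GAT."""
    if config is None:
        config = GraphModelConfig(use_gat=use_gat)
    encoder = _enc.CompositionEncoder(
        _enc.CompositionFeatureConfig(feature_kind=feature_kind),
        project_to=project_to, standardize=standardize, seed=seed,
    )
    return GraphNodeClassifier(encoder, label_space, config, seed=seed)


# ---------------------------------------------------------------------------
# Spec-level single-sample operations (thin wrappers over the model pieces)
# ---------------------------------------------------------------------------


def node_encode(p: np.ndarray, node_weights: np.ndarray,
                dropout_rate: float = 0.0,
                rng: np.random.Generator | None = None) -> np.ndarray:
    """h_i = dropout(W_i · p); ``node_weights`` is (M, d_node, d_repr)."""
    W = np.asarray(node_weights, dtype=np.float64)
    h = np.einsum("mij,j->mi", W, np.asarray(p, dtype=np.float64))
    if dropout_rate > 0.0:
        if rng is None:
            rng = np.random.default_rng()
        keep = (rng.random(h.shape) >= dropout_rate) / (1.0 - dropout_rate)
        h = h * keep
    return h


def gat_attention(h: np.ndarray, layer: GATLayer, head: int,
                  topology: GraphTopology) -> np.ndarray:
    """The (M, M) attention matrix of one head for a single sample."""
    gamma, _ = layer.attention(Tensor(np.asarray(h)[None, :, :]), topology)
    return gamma.data[0, head]


def gat_layer(h: np.ndarray, layer: GATLayer, topology: GraphTopology) -> np.ndarray:
    """Updated (M, K*d_head) node features for a single sample."""
    out, _ = layer.forward(Tensor(np.asarray(h)[None, :, :]), topology)
    return out.data[0]


def node_classify(h_prime: np.ndarray, weights: np.ndarray,
                  biases: np.ndarray | None, label_space: LabelSpace,
                  threshold: float = 0.5) -> PredictionResult:
    """probabilities[i] = sigmoid(W_i · h'_i + b_i), thresholded."""
    logits = np.einsum("mi,mi->m", np.asarray(weights), np.asarray(h_prime))
    if biases is not None:
        logits = logits + np.asarray(biases)
    probs = 1.0 / (1.0 + np.exp(-logits))
    return PredictionResult.from_probabilities(probs, label_space, threshold)


def model_forward(inputs, model: GraphNodeClassifier, trace: bool = False,
                  threshold: float | None = None):
    """Batch prediction; with ``trace`` also returns attention tensors."""
    return model.predict(inputs, threshold=threshold, trace=trace)
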