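"""Dual-branch subtype classifier.

A graph branch encodes each sample's one-hot gene levels over the shared
static multi-channel graph with two edge-aware graph-attention layers
(explicit self term with its own attention coefficient, softmax-normalized
over the node's closed neighborhood, a learned projection of the 4-channel
edge attribute entering the attention logit).  Layer inputs and outputs are
concatenated (skip connections), globally mean-pooled over nodes, and passed
through a shallow dense block.  A global branch embeds the continuous
(training-standardized) values of the selected genes with a feed-forward
network.  The two embeddings are concatenated and classified with a dense
softmax head, trained jointly with categorical cross-entropy under Adam with
L2 regularization.

All samples share the static graph, so the whole batch is processed as
(samples x nodes x features) tensors; attention coefficients from the final
forward pass are recorded per layer, sample and directed edge for the
biomarker ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor, glorot_uniform
from .graph_build import FinalGraph, SampleGraph

__all__ = [
    "ModelConfig", "AttentionRecord", "TrainedModel", "train",
    "gat_layer_forward", "graph_encoder_forward", "global_encoder_forward",
    "fused_predict", "extract_attention", "predict_proba",
]


@dataclass
class ModelConfig:
    gat_layers: int = 2
    heads: int = 4
    hidden_dim: int = 32
    edge_dim: int = 4
    mlp_dims: tuple[int, ...] = (64,)
    dropout: float = 0.2
    lr: float = 5e-5
    weight_decay: float = 1e-3
    epochs: int = 500
    seed: int = 0
    leaky_slope: float = 0.2
    use_edge_attr: bool = True   # False = literal attention on endpoint states only
    use_gnn: bool = True
    use_dnn: bool = True

    def __post_init__(self):
        if self.hidden_dim % self.heads:
            raise ValueError("hidden_dim must be divisible by heads")
        if not (self.use_gnn or self.use_dnn):
            raise ValueError("at least one branch must be enabled")


@dataclass
class AttentionRecord:
    """Head-averaged attention per layer, sample and directed edge.

    Edge arrays include the explicit self-loops, flagged by `self_mask`.
    For a stored edge (src=nu, dst=mu) the coefficient is alpha_{mu,nu}: the
    weight node mu assigns to nu when aggregating.
    """

    edge_src: np.ndarray
    edge_dst: np.ndarray
    self_mask: np.ndarray
    alpha: dict[int, np.ndarray]  # layer -> (n_samples, n_edges)
    sample_ids: list[str] = field(default_factory=list)

    @property
    def n_layers(self) -> int:
        return len(self.alpha)


@dataclass
class TrainedModel:
    params: dict[str, Tensor]
    config: ModelConfig
    classes: list[str]
    nodes: list[str]
    edge_src: np.ndarray
    edge_dst: np.ndarray
    edge_attr: np.ndarray
    global_mean: np.ndarray
    global_std: np.ndarray
    loss_history: list[float] = field(default_factory=list)
    attention: AttentionRecord | None = None


# ---------------------------------------------------------------------------
# Parameter construction
# ---------------------------------------------------------------------------

def _dense(params, rng, name, d_in, d_out):
    params[f"{name}.W"] = glorot_uniform(rng, d_in, d_out)
    params[f"{name}.b"] = Tensor(np.zeros(d_out), requires_grad=True)


def _init_params(cfg: ModelConfig, m: int, n_classes: int) -> dict[str, Tensor]:
    rng = np.random.default_rng(cfg.seed)
    p: dict[str, Tensor] = {}
    h, H = cfg.hidden_dim, cfg.heads
    dh = h // H
    if cfg.use_gnn:
        _dense(p, rng, "proj", 3, h)
        for layer in range(cfg.gat_layers):
            pre = f"gat{layer}"
            _dense(p, rng, f"{pre}.theta_s", h, h)
            _dense(p, rng, f"{pre}.theta_t", h, h)
            p[f"{pre}.att_src"] = glorot_uniform(rng, dh, 1, shape=(H, dh))
            p[f"{pre}.att_dst"] = glorot_uniform(rng, dh, 1, shape=(H, dh))
            if cfg.use_edge_attr:
                p[f"{pre}.W_e"] = glorot_uniform(rng, cfg.edge_dim, h)
                p[f"{pre}.att_edge"] = glorot_uniform(rng, dh, 1, shape=(H, dh))
        d_cat = h * (cfg.gat_layers + 1)
        _dense(p, rng, "graph_head", d_cat, h)
    if cfg.use_dnn:
        dims = [m, *cfg.mlp_dims, h]
        for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            _dense(p, rng, f"global{i}", a, b)
    d_fuse = h * (int(cfg.use_gnn) + int(cfg.use_dnn))
    _dense(p, rng, "fuse", d_fuse, h)
    _dense(p, rng, "out", h, n_classes)
    return p


def _linear(p, name, x: Tensor) -> Tensor:
    return x @ p[f"{name}.W"] + p[f"{name}.b"]


def _dropout(x: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    if rng is None or rate <= 0:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


# ---------------------------------------------------------------------------
# Forward passes
# ---------------------------------------------------------------------------

def _segment_max(values: np.ndarray, idx: np.ndarray, m: int, axis: int) -> np.ndarray:
    moved = np.moveaxis(values, axis, 0)
    acc = np.full((m,) + moved.shape[1:], -np.inf)
    np.maximum.at(acc, idx, moved)
    return np.moveaxis(acc, 0, axis)


def gat_layer_forward(p: dict[str, Tensor], prefix: str, cfg: ModelConfig,
                      h: Tensor, edge_src: np.ndarray, edge_dst: np.ndarray,
                      edge_attr: np.ndarray) -> tuple[Tensor, np.ndarray]:
    """One edge-aware attention layer over batched node states.

    `h` is (samples, m, d).  Self-loops are appended internally: the update is
    h'_mu = alpha_{mu,mu} Theta_s h_mu + sum_nu alpha_{mu,nu} Theta_t h_nu
    with logits LeakyReLU(a_dst . Theta_s h_mu + a_src . msg_nu + a_e . W_e e)
    softmax-normalized over {mu} u N(mu).  Returns the new states and the
    head-averaged attention matrix (samples, n_edges_with_self).
    """
    S, m, _ = h.shape
    H = cfg.heads
    dh = cfg.hidden_dim // H
    loops = np.arange(m)
    src = np.concatenate([edge_src, loops])
    dst = np.concatenate([edge_dst, loops])
    self_mask = np.concatenate([np.zeros(len(edge_src)), np.ones(m)])[None, :, None]
    attr = np.concatenate([edge_attr, np.zeros((m, edge_attr.shape[1]))], axis=0)
    E = len(src)

    hs = _linear(p, f"{prefix}.theta_s", h)
    ht = _linear(p, f"{prefix}.theta_t", h)
    msg = hs.take(src, axis=1) * Tensor(self_mask) + ht.take(src, axis=1) * Tensor(1.0 - self_mask)
    dst_state = hs.take(dst, axis=1)

    a_src, a_dst = p[f"{prefix}.att_src"], p[f"{prefix}.att_dst"]
    logit = ((msg.reshape(S, E, H, dh) * a_src).sum(axis=3)
             + (dst_state.reshape(S, E, H, dh) * a_dst).sum(axis=3))
    if cfg.use_edge_attr:
        e_proj = (Tensor(attr) @ p[f"{prefix}.W_e"]).reshape(E, H, dh)
        logit = logit + (e_proj * p[f"{prefix}.att_edge"]).sum(axis=2)
    logit = logit.leaky_relu(cfg.leaky_slope)

    shift = _segment_max(logit.data, dst, m, axis=1)[:, dst, :]  # constant, stabilizes exp
    z = (logit - Tensor(shift)).exp()
    denom = z.segment_sum(dst, m, axis=1)
    alpha = z / denom.take(dst, axis=1)

    weighted = alpha.reshape(S, E, H, 1) * msg.reshape(S, E, H, dh)
    out = weighted.segment_sum(dst, m, axis=1).reshape(S, m, H * dh)
    return out, alpha.data.mean(axis=2)


def graph_encoder_forward(p: dict[str, Tensor], cfg: ModelConfig, x_onehot: Tensor,
                          edge_src, edge_dst, edge_attr,
                          rng: np.random.Generator | None = None
                          ) -> tuple[Tensor, dict[int, np.ndarray]]:
    """Attention layers with concat skip connections, mean-pooled over nodes."""
    h0 = _linear(p, "proj", x_onehot)
    states = [h0]
    attention: dict[int, np.ndarray] = {}
    h = h0
    for layer in range(cfg.gat_layers):
        h, att = gat_layer_forward(p, f"gat{layer}", cfg, h, edge_src, edge_dst, edge_attr)
        h = h.elu()
        states.append(h)
        attention[layer] = att
    cat = states[0].concat(states[1:], axis=2)
    pooled = cat.mean(axis=1)
    emb = _dropout(_linear(p, "graph_head", pooled).elu(), cfg.dropout, rng)
    return emb, attention


def global_encoder_forward(p: dict[str, Tensor], cfg: ModelConfig, x: Tensor,
                           rng: np.random.Generator | None = None) -> Tensor:
    """Feed-forward embedding of the continuous selected-gene values."""
    n_layers = len(cfg.mlp_dims) + 1
    h = x
    for i in range(n_layers):
        h = _linear(p, f"global{i}", h).elu()
        if i < n_layers - 1:
            h = _dropout(h, cfg.dropout, rng)
    return h


def fused_predict(p: dict[str, Tensor], cfg: ModelConfig,
                  graph_emb: Tensor | None, global_emb: Tensor | None,
                  rng: np.random.Generator | None = None) -> Tensor:
    """Concatenate available branch embeddings and return class logits."""
    parts = [e for e in (graph_emb, global_emb) if e is not None]
    if not parts:
        raise ValueError("no branch embeddings")
    fused = parts[0] if len(parts) == 1 else parts[0].concat(parts[1:], axis=1)
    h = _dropout(_linear(p, "fuse", fused).elu(), cfg.dropout, rng)
    return _linear(p, "out", h)


def _log_softmax(logits: Tensor) -> Tensor:
    shift = Tensor(logits.data.max(axis=1, keepdims=True))
    z = logits - shift
    return z - z.exp().sum(axis=1, keepdims=True).log()


def cross_entropy(logits: Tensor, y_onehot: np.ndarray) -> Tensor:
    """Categorical cross-entropy, averaged over samples."""
    logp = _log_softmax(logits)
    n = y_onehot.shape[0]
    return -(Tensor(y_onehot) * logp).sum() * (1.0 / n)


def _forward(model_params, cfg, x_onehot, x_global, edge_src, edge_dst, edge_attr,
             rng=None):
    graph_emb = attention = None
    if cfg.use_gnn:
        graph_emb, attention = graph_encoder_forward(
            model_params, cfg, x_onehot, edge_src, edge_dst, edge_attr, rng)
    global_emb = None
    if cfg.use_dnn:
        global_emb = global_encoder_forward(model_params, cfg, x_global, rng)
    logits = fused_predict(model_params, cfg, graph_emb, global_emb, rng)
    return logits, attention


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _stack_features(graphs: list[SampleGraph]) -> np.ndarray:
    return np.stack([g.node_features for g in graphs])


def train(graphs: list[SampleGraph], global_features: np.ndarray,
          labels: list[str], cfg: ModelConfig) -> TrainedModel:
    """Fit the dual-branch classifier with full-batch Adam.

    `global_features` holds the continuous values of the selected genes
    (samples x m); they are standardized with training statistics here.
    Raises on a non-finite loss.  With a fixed config and seed the loss
    history is bit-reproducible on one device.
    """
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("training data must contain at least two classes")
    fg: FinalGraph = graphs[0].graph
    src, dst, attr = fg.directed_edges()
    m = len(fg.nodes)

    mu = global_features.mean(axis=0)
    sd = global_features.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    xg = (global_features - mu) / sd

    y_idx = np.array([classes.index(l) for l in labels])
    y_onehot = np.eye(len(classes))[y_idx]
    x_onehot = _stack_features(graphs)

    params = _init_params(cfg, m, len(classes))
    opt = Adam(list(params.values()), lr=cfg.lr, weight_decay=cfg.weight_decay)
    drop_rng = np.random.default_rng(cfg.seed + 1)
    history = []
    for _ in range(cfg.epochs):
        opt.zero_grad()
        logits, _ = _forward(params, cfg, Tensor(x_onehot), Tensor(xg),
                             src, dst, attr, rng=drop_rng)
        loss = cross_entropy(logits, y_onehot)
        if not np.isfinite(loss.data):
            raise RuntimeError(f"non-finite loss at epoch {len(history)}")
        loss.backward()
        opt.step()
        history.append(float(loss.data))

    model = TrainedModel(params, cfg, classes, list(fg.nodes), src, dst, attr,
                         mu, sd, history)
    if cfg.use_gnn:
        model.attention = extract_attention(model, graphs)
    return model


def predict_proba(model: TrainedModel, graphs: list[SampleGraph],
                  global_features: np.ndarray) -> np.ndarray:
    """Class probabilities (rows sum to 1), dropout disabled."""
    xg = (global_features - model.global_mean) / model.global_std
    logits, _ = _forward(model.params, model.config, Tensor(_stack_features(graphs)),
                         Tensor(xg), model.edge_src, model.edge_dst, model.edge_attr)
    logp = _log_softmax(logits)
    return np.exp(logp.data)


def extract_attention(model: TrainedModel, graphs: list[SampleGraph]) -> AttentionRecord:
    """Head-averaged coefficients for every layer, sample and directed edge."""
    cfg = model.config
    if not cfg.use_gnn:
        raise ValueError("the graph branch is disabled; no attention to extract")
    x = Tensor(_stack_features(graphs))
    _, attention = graph_encoder_forward(model.params, cfg, x, model.edge_src,
                                         model.edge_dst, model.edge_attr)
    m = len(model.nodes)
    loops = np.arange(m)
    return AttentionRecord(
        edge_src=np.concatenate([model.edge_src, loops]),
        edge_dst=np.concatenate([model.edge_dst, loops]),
        self_mask=np.concatenate([np.zeros(len(model.edge_src), dtype=bool),
                                  np.ones(m, dtype=bool)]),
        alpha=attention,
        sample_ids=[g.sample_id for g in graphs],
    )
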