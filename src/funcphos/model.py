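"""The trainable multi-modal core.

Two branches meet in a cross-attention block.  The sequence branch projects
per-residue language-model embeddings to the fusion width C and assembles a
small query token matrix (global context + site context).  The structure
branch runs a graph convolutional encoder over the site-centered residue
subgraph; its per-node outputs serve as attention keys and values, so the
query "reads out" the structural neighbourhood of the site:

    attention(q, k, v) = softmax(q k^T / sqrt(C/d)) v

with embedding width C (default 256) and a single head (d = 1).  A
self-attention block (same formula, q = k = v) refines the fused tokens,
and a three-layer fully connected classifier (256, 256, 512 neurons) maps
their concatenation to a sigmoid probability.  The loss is binary cross
entropy.

Ablation variants are first-class configuration: ``no_gcn`` sends the query
straight to self-attention, ``no_esm`` classifies the mean-pooled graph
vector alone, ``no_cross_attention`` concatenates the two branch outputs,
``no_self_attention`` skips the refinement block.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat
from .graphs import N_NODE_FEATURES, ResidueGraph

VALID_ABLATIONS = ("none", "no_gcn", "no_esm", "no_cross_attention", "no_self_attention")


@dataclass
class FusionConfig:
    embed_dim: int = 256              # C, fusion width
    n_heads: int = 1                  # d; a single head is the validated setting
    gcn_layers: int = 2
    classifier_widths: tuple[int, ...] = (256, 256, 512)
    dropout: float = 0.3
    input_embed_dim: int = 64         # D of the sequence-embedding backend
    node_feature_dim: int = N_NODE_FEATURES
    query_tokens: int = 2             # tokens produced by build_query
    attention_scale: str = "sqrt"     # "sqrt": sqrt(C/d); "linear": C/d
    ablation: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if any(w <= 0 for w in self.classifier_widths):
            raise ValueError("classifier widths must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.attention_scale not in ("sqrt", "linear"):
            raise ValueError(f"bad attention_scale {self.attention_scale!r}")
        if self.ablation not in VALID_ABLATIONS:
            raise ValueError(f"bad ablation {self.ablation!r}")

    @property
    def scale_divisor(self) -> float:
        ratio = self.embed_dim / self.n_heads
        return float(np.sqrt(ratio)) if self.attention_scale == "sqrt" else float(ratio)

    @property
    def classifier_tokens(self) -> int:
        """Number of tokens entering the classifier flattening."""
        if self.ablation == "no_esm":
            return 1
        if self.ablation == "no_cross_attention":
            return self.query_tokens + 1
        return self.query_tokens


@dataclass
class Sample:
    """One site, fully featurized and ready for the model."""

    node_features: np.ndarray    # (n, 35)
    norm_adjacency: np.ndarray   # (n, n) symmetric-normalized, self-loops added
    query: np.ndarray            # (T, D) raw embedding-space query tokens
    label: float
    accession: str = ""
    position: int = 0
    plddt: float = 0.0
    group: int = 0               # protein index, for grouped splits


def normalized_adjacency(graph: ResidueGraph) -> np.ndarray:
    """Symmetric GCN propagation matrix D^{-1/2} (A + I) D^{-1/2}."""
    a = graph.adjacency() + np.eye(graph.n_nodes)
    d = a.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return a * inv_sqrt[:, None] * inv_sqrt[None, :]


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

CLASSIFIER_PREFIX = "classifier."


def init_params(config: FusionConfig) -> dict[str, Tensor]:
    """He-initialized named parameter tensors, reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    params: dict[str, Tensor] = {}

    def dense(name: str, d_in: int, d_out: int) -> None:
        w = rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)
        params[f"{name}.w"] = Tensor(w, requires_grad=True)
        params[f"{name}.b"] = Tensor(np.zeros(d_out), requires_grad=True)

    C = config.embed_dim
    dense("proj", config.input_embed_dim, C)
    d_in = config.node_feature_dim
    for layer in range(config.gcn_layers):
        dense(f"gcn{layer}", d_in, C)
        d_in = C
    for block in ("cross", "self"):
        for mat in ("wq", "wk", "wv", "wo"):
            dense(f"{block}.{mat}", C, C)
    widths = (config.classifier_tokens * C, *config.classifier_widths, 1)
    for layer, (w_in, w_out) in enumerate(zip(widths[:-1], widths[1:])):
        dense(f"{CLASSIFIER_PREFIX}{layer}", w_in, w_out)
    return params


def clone_params(params: dict[str, Tensor]) -> dict[str, Tensor]:
    return {
        k: Tensor(p.data.copy(), requires_grad=p.requires_grad)
        for k, p in params.items()
    }


def _affine(x: Tensor, params: dict[str, Tensor], name: str) -> Tensor:
    return x @ params[f"{name}.w"] + params[f"{name}.b"]


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor, scale: float) -> Tensor:
    """softmax(q k^T / scale) v — the bare attention primitive."""
    if k.shape[0] == 0:
        raise ValueError("attention requires at least one key")
    logits = (q @ k.T) * (1.0 / scale)
    return logits.softmax() @ v


def graph_encode(
    x: Tensor, norm_adj: np.ndarray, params: dict[str, Tensor], config: FusionConfig
) -> tuple[Tensor, Tensor]:
    """GCN over the subgraph; returns per-node vectors and their mean pool."""
    if x.shape[0] == 0:
        raise ValueError("cannot encode an empty graph")
    a = Tensor(norm_adj)
    h = x
    for layer in range(config.gcn_layers):
        h = _affine(a @ h, params, f"gcn{layer}")
        if layer < config.gcn_layers - 1:
            h = h.relu()
    return h, h.mean(axis=0)


def _attention_block(
    q: Tensor, kv: Tensor, params: dict[str, Tensor], block: str, config: FusionConfig
) -> Tensor:
    qp = _affine(q, params, f"{block}.wq")
    kp = _affine(kv, params, f"{block}.wk")
    vp = _affine(kv, params, f"{block}.wv")
    fused = scaled_dot_attention(qp, kp, vp, config.scale_divisor)
    return _affine(fused, params, f"{block}.wo")


def classify(
    tokens: Tensor,
    params: dict[str, Tensor],
    config: FusionConfig,
    train: bool = False,
    rng: np.random.Generator | None = None,
    head: str = CLASSIFIER_PREFIX,
) -> Tensor:
    """Flattened tokens → 256 → 256 → 512 → sigmoid probability.

    Dropout is active only in train mode; eval-mode calls are deterministic.
    """
    h = tokens.reshape(1, -1)
    n_layers = len(config.classifier_widths) + 1
    for layer in range(n_layers):
        h = _affine(h, params, f"{head}{layer}")
        if layer < n_layers - 1:
            h = h.relu()
            if train and config.dropout > 0:
                if rng is None:
                    raise ValueError("training-mode dropout needs an rng")
                mask = (rng.random(h.shape) >= config.dropout) / (1.0 - config.dropout)
                h = h * Tensor(mask)
    return h.reshape(-1).sigmoid()


def forward(
    sample: Sample,
    params: dict[str, Tensor],
    config: FusionConfig,
    train: bool = False,
    rng: np.random.Generator | None = None,
    head: str = CLASSIFIER_PREFIX,
) -> Tensor:
    """Probability that the sample's site is positive (scalar tensor).

    ``head`` selects the classifier parameter group, which lets multi-task
    training attach a second head to the shared trunk.
    """
    q = _affine(Tensor(sample.query), params, "proj")
    if config.ablation != "no_gcn":
        nodes, pooled = graph_encode(
            Tensor(sample.node_features), sample.norm_adjacency, params, config
        )
    if config.ablation == "no_esm":
        tokens = pooled.reshape(1, -1)
    elif config.ablation == "no_gcn":
        tokens = q
    elif config.ablation == "no_cross_attention":
        tokens = concat([q, pooled.reshape(1, -1)], axis=0)
    else:
        tokens = _attention_block(q, nodes, params, "cross", config)
    if config.ablation != "no_self_attention":
        tokens = _attention_block(tokens, tokens, params, "self", config)
    return classify(tokens, params, config, train=train, rng=rng, head=head)


EPSILON = 1e-7


def bce_loss(y: float | np.ndarray, y_hat: Tensor) -> Tensor:
    """Binary cross entropy, probabilities clamped to [eps, 1 - eps]."""
    p = y_hat.clip(EPSILON, 1.0 - EPSILON)
    y = np.asarray(y, dtype=float)
    loss = -(Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log())
    return loss.mean()


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(
    params: dict[str, Tensor],
    config: FusionConfig,
    path: str | Path,
    metadata: dict | None = None,
) -> None:
    """Single-archive checkpoint: config + named tensors + metadata."""
    path = Path(path)
    cfg = asdict(config)
    cfg["classifier_widths"] = list(config.classifier_widths)
    np.savez(
        path,
        __config__=json.dumps(cfg),
        __metadata__=json.dumps(metadata or {}),
        __version__=CHECKPOINT_VERSION,
        **{k: p.data for k, p in params.items()},
    )


def load_checkpoint(path: str | Path) -> tuple[dict[str, Tensor], FusionConfig, dict]:
    with np.load(path, allow_pickle=False) as archive:
        cfg = json.loads(str(archive["__config__"]))
        cfg["classifier_widths"] = tuple(cfg["classifier_widths"])
        metadata = json.loads(str(archive["__metadata__"]))
        params = {
            k: Tensor(archive[k], requires_grad=True)
            for k in archive.files
            if not k.startswith("__")
        }
    return params, FusionConfig(**cfg), metadata
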