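"""The graph-transformer slide classifier.

Pipeline per slide graph:

1. linear projection of the node features into the model width,
2. M graph-convolution layers ``H <- ReLU(A_hat H W)`` over the
   degree-normalised, self-looped adjacency,
3. min-cut pooling: a learned soft assignment ``S`` (rows sum to 1) maps the
   N nodes to a fixed number of clusters, ``X_pool = S^T H``, with two
   auxiliary regularisers from the relaxed normalised-cut objective,
4. a class token is prepended and L pre-norm transformer blocks run multihead
   qkv self-attention over the ``1 + n_clusters`` tokens,
5. the layer-normalised class-token output feeds a linear head and softmax.

Spatial structure enters only through the adjacency matrix (steps 2-3); the
transformer uses no positional encoding, which makes the whole forward pass
invariant to node re-ordering.

Training uses Adam with the step-decay schedule (1e-3, then 1e-4 and 1e-5 at
configurable milestones), batches formed by accumulating gradients over
several graphs, and keeps the state with the best validation loss (earliest
step wins ties).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autograd import Tensor, concat
from .graph_builder import WSIGraph, normalize_adjacency
from .nn import (Adam, LayerNorm, Linear, MLP, Module, cross_entropy,
                 step_decay_lr, trunc_normal, _param)

__all__ = ["GTPConfig", "GraphTransformer", "ForwardTrace", "MinCutPool",
           "gc_layer", "total_loss", "train", "TrainResult"]


@dataclass(frozen=True)
class GTPConfig:
    """Architecture + training hyperparameters of the graph-transformer."""

    n_features: int = 32          # dimension of the extractor's node features
    hidden_dim: int = 64          # token dimension D
    n_gc_layers: int = 1          # M
    n_transformer_blocks: int = 3  # L
    n_heads: int = 8              # k
    head_dim: int | None = None   # D_h; defaults to hidden_dim // n_heads
    mlp_dim: int = 128
    n_clusters: int = 100         # min-cut pooled node count
    n_classes: int = 3
    lambda_cut: float = 1.0
    lambda_ortho: float = 1.0
    lr_milestones: tuple[int, ...] = (30, 100)
    lrs: tuple[float, ...] = (1e-3, 1e-4, 1e-5)
    batch_size: int = 8
    n_steps: int = 150
    seed: int = 0

    def __post_init__(self):
        if self.head_dim is None:
            if self.hidden_dim % self.n_heads:
                raise ValueError("hidden_dim must divide evenly over n_heads")
            object.__setattr__(self, "head_dim", self.hidden_dim // self.n_heads)
        for name in ("hidden_dim", "n_gc_layers", "n_transformer_blocks",
                     "n_heads", "head_dim", "mlp_dim", "n_clusters", "n_classes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def paper_settings(cls, n_features: int, **over) -> "GTPConfig":
        """One GC layer, L=3 blocks, k=8 heads, D=64, MLP 128, 100 clusters."""
        return cls(n_features=n_features, hidden_dim=64, n_gc_layers=1,
                   n_transformer_blocks=3, n_heads=8, mlp_dim=128,
                   n_clusters=100, **over)

    @classmethod
    def table_best(cls, n_features: int, **over) -> "GTPConfig":
        """Hidden 128, 3 GC layers, 3 blocks, 120 clusters."""
        return cls(n_features=n_features, hidden_dim=128, n_gc_layers=3,
                   n_transformer_blocks=3, n_heads=8, mlp_dim=128,
                   n_clusters=120, **over)

    @classmethod
    def desk_scale(cls, n_features: int, **over) -> "GTPConfig":
        """Reduced CPU-friendly profile: hidden 32, M=1, L=2, k=4, 16 clusters."""
        return cls(n_features=n_features, hidden_dim=32, n_gc_layers=1,
                   n_transformer_blocks=2, n_heads=4, mlp_dim=64,
                   n_clusters=16, **over)


@dataclass
class ForwardTrace:
    """Intermediates of one forward pass (kept for saliency mapping)."""

    H_gc: list[Tensor]
    S: Tensor                     # (N, n_clusters) soft assignment
    X_pool: Tensor
    A_pool: np.ndarray
    attn: list[Tensor]            # per block: (heads, T, T), rows sum to 1
    block_inputs: list[np.ndarray]   # detached token matrices entering each block
    tokens_out: Tensor
    logits: Tensor
    probs: np.ndarray
    cut_loss: Tensor
    ortho_loss: Tensor


def gc_layer(H, A_hat, W) -> Tensor:
    """One graph convolution: ReLU(A_hat @ H @ W)."""
    H = H if isinstance(H, Tensor) else Tensor(H)
    A_hat = A_hat if isinstance(A_hat, Tensor) else Tensor(A_hat)
    W = W if isinstance(W, Tensor) else Tensor(W)
    return ((A_hat @ H) @ W).relu()


class MinCutPool(Module):
    """Learnable soft clustering of graph nodes with min-cut regularisation.

    ``S = softmax(H W_s)`` row-wise, ``X_pool = S^T H``.  The cut term
    ``-Tr(S^T A S) / Tr(S^T D S)`` (in [-1, 0]) rewards assignments that keep
    strongly connected nodes together; the orthogonality term
    ``|| S^T S / ||S^T S||_F  -  I/sqrt(n_clusters) ||_F`` (>= 0) pushes
    clusters towards balanced, non-overlapping use.
    """

    def __init__(self, hidden_dim: int, n_clusters: int, rng: np.random.Generator):
        super().__init__()
        if n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        self.assign = Linear(hidden_dim, n_clusters, rng)
        self.n_clusters = n_clusters

    def forward(self, H: Tensor, A: np.ndarray):
        S = self.assign(H).softmax(axis=-1)          # (N, n_clusters)
        X_pool = S.T @ H
        A = np.asarray(A, dtype=H.dtype)
        deg = A.sum(axis=1)
        if deg.sum() > 0:
            A_t = Tensor(A)
            D_t = Tensor(np.diag(deg))
            num = ((S.T @ A_t) * S.T).sum()
            den = ((S.T @ D_t) * S.T).sum()
            cut = -(num / den)
        else:  # edgeless graph: the cut objective is vacuous
            cut = Tensor(np.zeros(()))
        SS = S.T @ S
        frob = (SS * SS).sum().sqrt()
        eye = Tensor(np.eye(self.n_clusters) / np.sqrt(self.n_clusters))
        diff = SS / frob - eye
        ortho = (diff * diff).sum().sqrt()
        A_pool = S.data.T @ A @ S.data
        np.fill_diagonal(A_pool, 0.0)
        A_pool = normalize_adjacency((A_pool + A_pool.T) / 2)
        return X_pool, A_pool, S, (cut, ortho)


class TransformerBlock(Module):
    """Pre-norm block: t' = MSA(LN(t)) + t; t_out = MLP(LN(t')) + t'."""

    def __init__(self, cfg: GTPConfig, rng: np.random.Generator):
        super().__init__()
        D, k, Dh = cfg.hidden_dim, cfg.n_heads, cfg.head_dim
        self.ln1 = LayerNorm(D)
        self.ln2 = LayerNorm(D)
        self.U_qkv = _param(trunc_normal(rng, (D, 3 * k * Dh), std=D ** -0.5))
        self.U_msa = _param(trunc_normal(rng, (k * Dh, D), std=(k * Dh) ** -0.5))
        self.mlp = MLP(D, cfg.mlp_dim, D, rng, activation="gelu")
        self.k, self.Dh = k, Dh

    def attention(self, t_in: Tensor):
        """MSA sub-path; returns (msa_out, attention maps (k, T, T))."""
        x = self.ln1(t_in)
        T = x.shape[0]
        qkv = (x @ self.U_qkv).reshape(T, 3, self.k, self.Dh).transpose(1, 2, 0, 3)
        q, k_, v = qkv[0], qkv[1], qkv[2]            # each (k, T, Dh)
        A = ((q @ k_.transpose(0, 2, 1)) * (self.Dh ** -0.5)).softmax(axis=-1)
        sa = A @ v                                    # (k, T, Dh)
        cat = sa.transpose(1, 0, 2).reshape(T, self.k * self.Dh)
        return cat @ self.U_msa, A

    def forward(self, t_in: Tensor):
        msa_out, A = self.attention(t_in)
        t_mid = msa_out + t_in
        t_out = self.mlp(self.ln2(t_mid)) + t_mid
        return t_out, A, t_mid


class GraphTransformer(Module):
    """Full model: projection → GC stack → min-cut pool → transformer → head."""

    def __init__(self, config: GTPConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        D = config.hidden_dim
        self.input_proj = Linear(config.n_features, D, rng)
        for m in range(config.n_gc_layers):
            setattr(self, f"gc{m}", Linear(D, D, rng, bias=False))
        self.pool = MinCutPool(D, config.n_clusters, rng)
        self.class_token = _param(trunc_normal(rng, (1, D), std=0.02))
        for l in range(config.n_transformer_blocks):
            setattr(self, f"block{l}", TransformerBlock(config, rng))
        self.ln_final = LayerNorm(D)
        self.head = Linear(D, config.n_classes, rng)

    # ------------------------------------------------------------------ forward
    def forward(self, graph: WSIGraph) -> tuple[np.ndarray, ForwardTrace]:
        cfg = self.config
        if graph.n_nodes < 1:
            raise ValueError("empty graph")
        if graph.F.shape[1] != cfg.n_features:
            raise ValueError(
                f"graph features have dim {graph.F.shape[1]}, model expects {cfg.n_features}"
            )
        F = Tensor(np.asarray(graph.F, dtype=np.float32))
        A_hat = Tensor(np.asarray(graph.A_hat, dtype=np.float32))
        H = self.input_proj(F)
        H_gc = []
        for m in range(cfg.n_gc_layers):
            H = gc_layer(H, A_hat, getattr(self, f"gc{m}").weight)
            H_gc.append(H)
        X_pool, A_pool, S, (cut, ortho) = self.pool(H, graph.A)
        tokens = concat([self.class_token, X_pool], axis=0)
        attn_maps, block_inputs = [], []
        for l in range(cfg.n_transformer_blocks):
            block_inputs.append(tokens.data.copy())
            tokens, A, _ = getattr(self, f"block{l}")(tokens)
            attn_maps.append(A)
        y = self.ln_final(tokens[0])
        logits = self.head(y)
        probs = np.exp(logits.log_softmax(axis=-1).data)
        trace = ForwardTrace(
            H_gc=H_gc, S=S, X_pool=X_pool, A_pool=A_pool, attn=attn_maps,
            block_inputs=block_inputs, tokens_out=tokens, logits=logits,
            probs=probs, cut_loss=cut, ortho_loss=ortho,
        )
        return probs, trace

    def predict_proba(self, graph: WSIGraph) -> np.ndarray:
        return self.forward(graph)[0]

    # -------------------------------------------------------------- checkpoints
    def save(self, path: str | Path, meta: dict | None = None):
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.state_dict())
        cfg = {k: v for k, v in self.config.__dict__.items()}
        cfg.update(meta or {})
        path.with_suffix(".json").write_text(json.dumps(cfg, indent=2, default=list))

    @classmethod
    def load(cls, path: str | Path) -> "GraphTransformer":
        path = Path(path)
        cfg_dict = json.loads(path.with_suffix(".json").read_text())
        fields = {f for f in GTPConfig.__dataclass_fields__}
        cfg_dict = {k: (tuple(v) if isinstance(v, list) else v)
                    for k, v in cfg_dict.items() if k in fields}
        model = cls(GTPConfig(**cfg_dict))
        with np.load(path.with_suffix(".npz")) as data:
            model.load_state_dict(dict(data))
        return model


def total_loss(probs, label: int, aux_losses=(0.0, 0.0),
               lambda_cut: float = 1.0, lambda_ortho: float = 1.0) -> Tensor:
    """Cross-entropy + weighted min-cut auxiliaries.

    ``probs`` are class probabilities (Tensor or array).  The auxiliary pair
    is ``(cut_loss, orthogonality_loss)`` as produced by the pooling layer.
    """
    probs_t = probs if isinstance(probs, Tensor) else Tensor(np.asarray(probs, dtype=np.float64))
    n = probs_t.shape[-1]
    if not (0 <= int(label) < n):
        raise ValueError(f"label {label} out of range for {n} classes")
    ce = -(probs_t[int(label)].log())
    cut, ortho = aux_losses
    cut = cut if isinstance(cut, Tensor) else Tensor(np.asarray(float(cut)))
    ortho = ortho if isinstance(ortho, Tensor) else Tensor(np.asarray(float(ortho)))
    return ce + lambda_cut * cut + lambda_ortho * ortho


@dataclass
class TrainResult:
    model: GraphTransformer
    history: dict
    best_step: int
    best_val_loss: float


def _graph_loss(model: GraphTransformer, graph: WSIGraph, label: int) -> tuple[Tensor, bool]:
    cfg = model.config
    probs, trace = model.forward(graph)
    ce = cross_entropy(trace.logits, label)
    loss = ce + cfg.lambda_cut * trace.cut_loss + cfg.lambda_ortho * trace.ortho_loss
    return loss, int(np.argmax(probs)) == int(label)


def train(
    graphs: list[WSIGraph],
    labels: list[int] | np.ndarray,
    config: GTPConfig,
    val_graphs: list[WSIGraph] | None = None,
    val_labels=None,
    val_fraction: float = 0.2,
    eval_every: int = 10,
    verbose: bool = False,
) -> TrainResult:
    """Train a graph-transformer; returns the best-validation-loss state.

    When no explicit validation set is given, a stratified ``val_fraction`` of
    the inputs is held out (reproducibly from ``config.seed``).
    """
    labels = np.asarray(labels, dtype=int)
    if len(graphs) != len(labels):
        raise ValueError("graphs and labels must align")
    if len(np.unique(labels)) < 2:
        raise ValueError("training requires at least two classes")
    rng = np.random.default_rng(config.seed)
    if val_graphs is None:
        tr_idx, va_idx = [], []
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            idx = rng.permutation(idx)
            n_val = max(1, int(round(val_fraction * len(idx))))
            va_idx.extend(idx[:n_val])
            tr_idx.extend(idx[n_val:])
        tr_idx, va_idx = np.array(tr_idx), np.array(va_idx)
        val_graphs = [graphs[i] for i in va_idx]
        val_labels = labels[va_idx]
        graphs = [graphs[i] for i in tr_idx]
        labels = labels[tr_idx]
    else:
        val_labels = np.asarray(val_labels, dtype=int)

    model = GraphTransformer(config)
    opt = Adam(model.parameters(), lr=config.lrs[0])
    history = {"step": [], "loss": [], "lr": [], "val_step": [], "val_loss": [], "val_acc": []}
    best_state, best_val, best_step = model.state_dict(), np.inf, -1

    def validate(step):
        tot, correct = 0.0, 0
        for g, y in zip(val_graphs, val_labels):
            loss, ok = _graph_loss(model, g, y)
            tot += loss.item()
            correct += ok
        vloss = tot / max(1, len(val_graphs))
        history["val_step"].append(step)
        history["val_loss"].append(vloss)
        history["val_acc"].append(correct / max(1, len(val_graphs)))
        return vloss

    n = len(graphs)
    for step in range(config.n_steps):
        opt.lr = step_decay_lr(step, config.lr_milestones, config.lrs)
        batch = rng.integers(0, n, size=min(config.batch_size, n))
        opt.zero_grad()
        batch_loss = 0.0
        for i in batch:
            loss, _ = _graph_loss(model, graphs[i], labels[i])
            (loss * (1.0 / len(batch))).backward()
            batch_loss += loss.item() / len(batch)
        opt.step()
        history["step"].append(step)
        history["loss"].append(batch_loss)
        history["lr"].append(opt.lr)
        if (step + 1) % eval_every == 0 or step == config.n_steps - 1:
            vloss = validate(step)
            if vloss < best_val:  # strict: earliest best step wins ties
                best_val, best_step = vloss, step
                best_state = model.state_dict()
            if verbose:
                print(f"step {step:4d}  loss {batch_loss:.4f}  val {vloss:.4f}")
    model.load_state_dict(best_state)
    return TrainResult(model=model, history=history, best_step=best_step,
                       best_val_loss=best_val)
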