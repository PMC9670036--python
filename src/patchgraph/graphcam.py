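"""GraphCAM: class-specific saliency for the graph-transformer.

For a chosen target class the method

1. runs a forward pass that retains every block's attention maps ``A^(l)``,
2. backpropagates the target-class logit to obtain the attention gradients
   ``grad A^(l)``,
3. propagates *relevance* from a one-hot on the target class back down the
   transformer with a generic epsilon-LRP rule (relevance of an input is
   ``x * VJP(R_out / (out + eps))``, applied module-wise, totals renormalised
   after residual splits), recording the relevance ``R(n_l)`` that lands on
   each attention map,
4. forms the per-block weighted attention ``A_bar^(l) =
   [E_h(grad A^(l) ⊙ R(n_l))]_+ + I`` (mean over heads, positive part, plus
   the identity so no token inhibits itself), and multiplies them in block
   order into the transformer relevance map ``C_t``,
5. takes the class-token row of ``C_t`` over the pooled-node columns, maps it
   back to the original nodes through the soft pooling assignment
   (``C_g = S r_pool``), and
6. paints each patch footprint with its min-max-normalised relevance to form
   the slide heatmap, which can be binarised and scored against an annotation
   mask by intersection-over-union across a threshold sweep.

A forward pass whose attention gradients vanish yields ``C_t = I`` and an
identically zero node relevance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .graph_builder import WSIGraph
from .gtp_model import ForwardTrace, GraphTransformer

__all__ = [
    "RelevanceBundle",
    "capture_attention",
    "transformer_relevance",
    "reverse_pool",
    "reconstruct_heatmap",
    "binarize_and_iou",
    "graphcam",
    "shuffled_relevance_control",
]

_EPS = 1e-9
DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.1, 1.0, 0.1), 10))


@dataclass
class RelevanceBundle:
    target_class: int
    probs: np.ndarray             # per-class probabilities of the forward pass
    attn: list[np.ndarray]        # A^(l), (heads, T, T)
    attn_grad: list[np.ndarray]   # gradient of the target logit w.r.t. A^(l)
    attn_relevance: list[np.ndarray]  # R(n_l), (heads, T, T)
    C_t: np.ndarray               # (T, T) transformer relevance map
    node_relevance: np.ndarray    # C_g, length N (original nodes)
    heatmap: np.ndarray | None = None


def _stab(x: np.ndarray) -> np.ndarray:
    """Stabilised denominator for the epsilon rule."""
    return x + _EPS * np.sign(x) + (x == 0) * _EPS


def _lrp_linear(x: np.ndarray, W: np.ndarray, out: np.ndarray,
                R_out: np.ndarray) -> np.ndarray:
    """Epsilon rule through ``out = x @ W (+ b)``: R_x = x ⊙ (s @ W^T)."""
    s = R_out / _stab(out)
    return x * (s @ W.T)


def _lrp_matmul(A: np.ndarray, B: np.ndarray, out: np.ndarray,
                R_out: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Epsilon rule through the bilinear ``out = A @ B`` (batched ok)."""
    s = R_out / _stab(out)
    R_A = A * (s @ np.swapaxes(B, -1, -2))
    R_B = B * (np.swapaxes(A, -1, -2) @ s)
    return R_A, R_B


def _lrp_add(a: np.ndarray, b: np.ndarray, R_out: np.ndarray
             ) -> tuple[np.ndarray, np.ndarray]:
    s = R_out / _stab(a + b)
    return a * s, b * s


def _renorm(R: np.ndarray, total: float) -> np.ndarray:
    s = R.sum()
    if abs(s) > 1e-12 and abs(total) > 1e-12:
        return R * (total / s)
    return R


def _ln_forward(ln, x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=-1, keepdims=True)
    var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + ln.eps) * ln.weight.data + ln.bias.data


def _gelu(x: np.ndarray) -> np.ndarray:
    c = np.sqrt(2.0 / np.pi)
    return 0.5 * x * (1.0 + np.tanh(c * (x + 0.044715 * x ** 3)))


def capture_attention(
    model: GraphTransformer, graph: WSIGraph, target_class: int,
    trace: ForwardTrace | None = None,
) -> tuple[list[np.ndarray], list[np.ndarray], list[np.ndarray], ForwardTrace]:
    """Attention maps, their target-logit gradients, and relevances per block.

    Returns ``(A, grad_A, R, trace)`` with one (heads, T, T) array per
    transformer block.
    """
    cfg = model.config
    if trace is None:
        _, trace = model.forward(graph)
    if not trace.attn:
        raise ValueError("forward trace holds no attention maps")
    if not (0 <= target_class < cfg.n_classes):
        raise ValueError("invalid target class")

    # gradients of the target logit w.r.t. each attention map
    for A in trace.attn:
        A.zero_grad()
    seed = np.zeros(cfg.n_classes)
    seed[target_class] = 1.0
    trace.logits.backward(seed)
    grads = [np.zeros_like(A.data) if A.grad is None else A.grad.copy()
             for A in trace.attn]
    attns = [A.data.copy() for A in trace.attn]

    # relevance propagation from a one-hot on the target class back through
    # the blocks: epsilon rule on linear/bilinear ops, LayerNorm / GELU /
    # softmax / scalar scalings pass relevance through unchanged, residual
    # adds split it proportionally and block totals are renormalised.
    L = cfg.n_transformer_blocks
    k, Dh = cfg.n_heads, cfg.head_dim
    t_final = trace.tokens_out.data.astype(np.float64)
    y = _ln_forward(model.ln_final, t_final[0])
    Wh = model.head.weight.data.astype(np.float64)
    logits = y @ Wh + model.head.bias.data
    R_logits = np.zeros(cfg.n_classes)
    R_logits[target_class] = 1.0
    R_tokens = np.zeros_like(t_final)
    R_tokens[0] = _lrp_linear(y, Wh, logits, R_logits)

    relevances: list[np.ndarray | None] = [None] * L
    for l in reversed(range(L)):
        block = getattr(model, f"block{l}")
        t_in = trace.block_inputs[l].astype(np.float64)
        T = t_in.shape[0]
        U_qkv = block.U_qkv.data.astype(np.float64)
        U_msa = block.U_msa.data.astype(np.float64)
        W1 = block.mlp.fc1.weight.data.astype(np.float64)
        W2 = block.mlp.fc2.weight.data.astype(np.float64)

        # replay the block in double precision
        x1 = _ln_forward(block.ln1, t_in)
        qkv_flat = x1 @ U_qkv
        qkv = qkv_flat.reshape(T, 3, k, Dh).transpose(1, 2, 0, 3)
        q, k_, v = qkv[0], qkv[1], qkv[2]            # (k, T, Dh)
        scores_raw = q @ np.swapaxes(k_, -1, -2)
        e = np.exp(scores_raw / np.sqrt(Dh)
                   - (scores_raw / np.sqrt(Dh)).max(axis=-1, keepdims=True))
        A = e / e.sum(axis=-1, keepdims=True)
        sa = A @ v
        cat = sa.transpose(1, 0, 2).reshape(T, k * Dh)
        msa_out = cat @ U_msa
        t_mid = msa_out + t_in
        x2 = _ln_forward(block.ln2, t_mid)
        h1 = x2 @ W1 + block.mlp.fc1.bias.data
        g1 = _gelu(h1)
        mlp_out = g1 @ W2 + block.mlp.fc2.bias.data

        total = R_tokens.sum()
        # MLP residual
        R_mlp, R_mid_skip = _lrp_add(mlp_out, t_mid, R_tokens)
        R_g1 = _lrp_linear(g1, W2, mlp_out, R_mlp)
        R_x2 = _lrp_linear(x2, W1, h1, R_g1)         # GELU transparent
        R_mid = _renorm(R_mid_skip + R_x2, total)    # LN transparent
        # MSA residual
        R_msa, R_in_skip = _lrp_add(msa_out, t_in, R_mid)
        R_cat = _lrp_linear(cat, U_msa, msa_out, R_msa)
        R_sa = R_cat.reshape(T, k, Dh).transpose(1, 0, 2)
        R_A, R_v = _lrp_matmul(A, v, sa, R_sa)
        relevances[l] = R_A.copy()                   # relevance at the softmax
        # softmax and the 1/sqrt(Dh) scaling are transparent
        R_q, R_kT = _lrp_matmul(q, np.swapaxes(k_, -1, -2), scores_raw, R_A)
        R_k = np.swapaxes(R_kT, -1, -2)
        R_qkv = np.stack([R_q, R_k, R_v], axis=0).transpose(2, 0, 1, 3)
        R_x1 = _lrp_linear(x1, U_qkv, qkv_flat, R_qkv.reshape(T, 3 * k * Dh))
        R_tokens = _renorm(R_in_skip + R_x1, total)  # LN transparent

    return attns, grads, [np.asarray(r) for r in relevances], trace


def transformer_relevance(attn_grads: list[np.ndarray],
                          attn_relevances: list[np.ndarray]) -> np.ndarray:
    """C_t = ordered product over blocks of [E_h(grad A ⊙ R)]_+ + I."""
    if not attn_grads:
        raise ValueError("need at least one block")
    T = attn_grads[0].shape[-1]
    C = np.eye(T)
    for g, r in zip(attn_grads, attn_relevances):
        if g.shape != r.shape or g.shape[-1] != T:
            raise ValueError("mismatched block shapes")
        A_bar = np.clip((g * r).mean(axis=0), 0.0, None) + np.eye(T)
        C = C @ A_bar
    return C


def reverse_pool(pooled_relevance: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Map pooled-token relevance back to graph nodes: C_g = S @ r_pool."""
    S = np.asarray(S)
    r = np.asarray(pooled_relevance).ravel()
    if S.ndim != 2 or S.shape[1] != r.shape[0]:
        raise ValueError(f"assignment shape {S.shape} does not match relevance {r.shape}")
    return S @ r


def reconstruct_heatmap(
    node_relevance: np.ndarray,
    coords,
    patch_size: int,
    slide_shape: tuple[int, int],
    stride: int | None = None,
) -> np.ndarray:
    """Paint per-node relevance onto patch footprints of the slide raster.

    Relevances are min-max normalised to [0, 1] over the kept nodes (a
    constant relevance vector maps to 0.5 everywhere); background stays 0.
    Overlapping footprints (overlap-tiled slides) take the maximum.
    """
    coords = [tuple(c) for c in coords]
    r = np.asarray(node_relevance, dtype=np.float64).ravel()
    if len(coords) != r.shape[0]:
        raise ValueError("relevance must align with coords")
    stride = stride or patch_size
    H, W = slide_shape
    lo, hi = r.min(), r.max()
    if hi - lo < 1e-12:
        norm = np.full_like(r, 0.5)
    else:
        norm = (r - lo) / (hi - lo)
    heat = np.zeros((H, W))
    for (row, col), val in zip(coords, norm):
        y, x = row * stride, col * stride
        if y + patch_size > H or x + patch_size > W:
            raise ValueError(f"coord {(row, col)} falls outside the slide raster")
        region = heat[y : y + patch_size, x : x + patch_size]
        np.maximum(region, val, out=region)
    return heat


def binarize_and_iou(
    heatmap: np.ndarray,
    annotation_mask: np.ndarray,
    thresholds=DEFAULT_THRESHOLDS,
) -> tuple[list[tuple[float, float]], float, float]:
    """IoU of (heatmap >= t) vs annotation over a threshold sweep.

    Returns ``(curve, best_threshold, max_iou)`` with ``curve`` a list of
    (threshold, IoU) pairs.  An empty annotation yields IoU 0 with a warning.
    """
    heatmap = np.asarray(heatmap)
    annotation = np.asarray(annotation_mask).astype(bool)
    if heatmap.shape != annotation.shape:
        raise ValueError("heatmap and annotation must share a shape")
    if not annotation.any():
        warnings.warn("empty annotation mask: IoU defined as 0", stacklevel=2)
        return [(float(t), 0.0) for t in thresholds], float(thresholds[0]), 0.0
    curve = []
    for t in thresholds:
        pred = heatmap >= t
        union = np.logical_or(pred, annotation).sum()
        inter = np.logical_and(pred, annotation).sum()
        curve.append((float(t), float(inter / union) if union else 0.0))
    best_t, best_iou = max(curve, key=lambda p: p[1])
    return curve, best_t, best_iou


def graphcam(
    model: GraphTransformer,
    graph: WSIGraph,
    target_class: int | str = "auto",
    with_heatmap: bool = True,
) -> RelevanceBundle:
    """End-to-end class-specific saliency for one slide graph."""
    probs, trace = model.forward(graph)
    target = int(np.argmax(probs)) if target_class == "auto" else int(target_class)
    attns, grads, rels, trace = capture_attention(model, graph, target, trace=trace)
    C_t = transformer_relevance(grads, rels)
    r_pool = C_t[0, 1:]  # class-token row, pooled-node columns
    C_g = reverse_pool(r_pool, trace.S.data)
    heat = None
    if with_heatmap and graph.patch_size:
        heat = reconstruct_heatmap(
            C_g, graph.coords, graph.patch_size, graph.slide_shape, graph.stride
        )
    return RelevanceBundle(
        target_class=target, probs=probs, attn=attns, attn_grad=grads,
        attn_relevance=rels, C_t=C_t, node_relevance=C_g, heatmap=heat,
    )


def shuffled_relevance_control(
    bundle: RelevanceBundle, graph: WSIGraph, rng: np.random.Generator
) -> np.ndarray:
    """Heatmap with node relevances randomly permuted (localisation baseline)."""
    perm = rng.permutation(len(bundle.node_relevance))
    return reconstruct_heatmap(
        bundle.node_relevance[perm], graph.coords, graph.patch_size,
        graph.slide_shape, graph.stride,
    )
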