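"""Fine-grained dense-prompt construction from the structural dictionary.

Pipeline: global pooling of the encoder map gives an instance prototype
``p``; matching ``p`` against the dictionary tokens yields a simplex weight
vector; Top-λ selection aggregates the best-matching *structural* tokens
into a foreground vector ``f_fg``; the normalised-entropy confidence ``s``
summarises how peaked the match is; a zero-initialised residual MLP refines
``p`` into ``p_fg``; cosine similarity between ``p_fg`` and every spatial
feature vector gives an activation map; and a 1×1 convolution fuses
``[activation; features; f_fg]`` into the dense prompt embedding.

Top-λ is made differentiable with a soft rank mask: token ``i`` (rank
percentile ``q_i``) receives mask ``logistic((λ − q_i)/temp)``, which
converges to the hard top-k indicator as ``temp → 0``.  Evaluation uses the
exact hard top-k with ``k = max(1, round(λ·(M−1)))`` and ties broken toward
the lower token index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Linear, Module, Parameter, Tensor

__all__ = [
    "SelectionConfig",
    "PromptState",
    "RefinementMLP",
    "pool_prototype",
    "match_dictionary",
    "hard_k",
    "selection_mask",
    "select_top_lambda",
    "select_top_lambda_learnable",
    "confidence_feature",
    "refine_prototype",
    "cosine_map",
    "build_prompt_embedding",
]

_LOGISTIC_CEIL = 1.1  # clipped-logistic headroom so lambda_sel can reach 1.0


@dataclass
class SelectionConfig:
    """Top-λ selection behaviour.

    ``lambda_raw`` maps to the selection ratio through a clipped logistic,
    ``lambda_sel = min(1, 1.1·logistic(lambda_raw)) ∈ (0, 1]``, so λ has a
    gradient everywhere yet can represent "keep everything" exactly.
    """

    lambda_raw: float = 0.0
    relax_temp: float = 0.05
    hard_eval: bool = True

    @property
    def lambda_sel(self) -> float:
        return min(1.0, _LOGISTIC_CEIL / (1.0 + math.exp(-self.lambda_raw)))

    @staticmethod
    def raw_for(lambda_sel: float) -> float:
        """Inverse of the clipped logistic for λ < 1 (used for λ₀ init)."""
        q = min(lambda_sel, 0.999) / _LOGISTIC_CEIL
        return math.log(q / (1.0 - q))


@dataclass
class PromptState:
    """Intermediate products of the prompt branch for one sample."""

    prototype: np.ndarray
    weights: np.ndarray
    fg_vector: np.ndarray
    confidence_feature: float
    refined: np.ndarray
    activation_map: np.ndarray | None = None
    prompt_embedding: np.ndarray | None = None


def pool_prototype(fmap, mode: str = "average"):
    """Per-channel global average (default) or max over a (…, C, H, W) map."""
    if mode == "average":
        return ad.tmean(fmap, axis=(-2, -1))
    if mode == "max":
        return ad.tmax(ad.reshape(fmap, fmap.shape[:-2] + (-1,)), axis=-1)
    raise ValueError(f"pooling mode must be 'average' or 'max', got {mode!r}")


def match_dictionary(prototype, tokens, metric: str = "scaled_dot"):
    """Softmax over token similarities.

    ``metric='scaled_dot'`` uses p·Tᵀ/√C (the printed formula);
    ``metric='cosine'`` is exposed as the textual alternative.
    """
    C = tokens.shape[-1]
    if prototype.shape[-1] != C:
        raise ValueError("prototype/dictionary channel mismatch")
    squeeze = prototype.ndim == 1
    p = ad.reshape(prototype, prototype.shape[:-1] + (1, C)) if squeeze else prototype
    if metric == "scaled_dot":
        logits = ad.mul(ad.matmul(p, _transpose_last(tokens)), 1.0 / math.sqrt(C))
    elif metric == "cosine":
        pn = p / ad.maximum(ad.sqrt(ad.tsum(ad.mul(p, p), axis=-1, keepdims=True)), 1e-12)
        tn = tokens / ad.maximum(ad.sqrt(ad.tsum(ad.mul(tokens, tokens), axis=-1, keepdims=True)), 1e-12)
        logits = ad.matmul(pn, _transpose_last(tn))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    w = ad.softmax(logits, axis=-1)
    return ad.reshape(w, (w.shape[-1],)) if squeeze else w


def _transpose_last(x):
    if isinstance(x, Tensor):
        axes = tuple(range(x.ndim - 2)) + (x.ndim - 1, x.ndim - 2)
        return ad.transpose(x, axes)
    return np.swapaxes(np.asarray(x), -1, -2)


def hard_k(lambda_sel: float, m_struct: int) -> int:
    """Selected-token count: number of rank percentiles below λ, ≥ 1.

    Equivalent to ``max(1, round(λ·m_struct))`` with half-point cases
    resolved consistently with the soft mask's temp→0 limit.
    """
    ranks = np.arange(m_struct)
    return max(1, int(np.sum((ranks + 0.5) / m_struct < lambda_sel)))


def _rank_percentiles(struct_weights: np.ndarray) -> np.ndarray:
    """Percentile of each structural token's rank (0 = best), ties by index."""
    m = struct_weights.shape[-1]
    order = np.argsort(-struct_weights, axis=-1, kind="stable")
    ranks = np.empty_like(order)
    idx = np.arange(m)
    if struct_weights.ndim == 1:
        ranks[order] = idx
    else:
        np.put_along_axis(ranks, order, np.broadcast_to(idx, order.shape), axis=-1)
    return (ranks + 0.5) / m


def selection_mask(struct_weights: np.ndarray, lambda_sel: float,
                   relax_temp: float, hard: bool) -> np.ndarray:
    """Soft (logistic-in-rank-percentile) or hard top-k membership mask."""
    q = _rank_percentiles(np.asarray(struct_weights))
    if hard:
        return (q < max(lambda_sel, 0.5 / struct_weights.shape[-1] + 1e-12)).astype(np.float64)
    with np.errstate(over="ignore"):  # saturated logistic underflows to 0/1
        return 1.0 / (1.0 + np.exp(-(lambda_sel - q) / relax_temp))


def select_top_lambda(weights, tokens, cfg: SelectionConfig, training: bool = False):
    """Aggregate the top-λ structural tokens: ``f_fg = Σ mask·w·t``.

    ``weights`` is the full simplex over all M tokens (silent included);
    only the structural rows 1..M-1 are eligible for selection.  The mask
    multiplies the weights without renormalisation, so λ=1 reduces exactly
    to the full structural weighted sum.
    """
    w_data = weights.data if isinstance(weights, Tensor) else np.asarray(weights)
    struct_w = w_data[..., 1:]
    hard = not training and cfg.hard_eval
    mask = selection_mask(struct_w, cfg.lambda_sel, cfg.relax_temp, hard)
    masked = ad.mul(weights[..., 1:], mask.astype(struct_w.dtype))
    if masked.ndim == 1:
        masked = ad.reshape(masked, (1,) + masked.shape)
        out = ad.matmul(masked, tokens[1:, :])
        return ad.reshape(out, out.shape[1:])
    return ad.matmul(masked, tokens[1:, :])


def select_top_lambda_learnable(weights, tokens, lambda_tensor, relax_temp: float):
    """Training-mode selection where λ itself carries a gradient.

    The rank percentiles are a function of the (detached) weight ordering;
    the logistic mask is differentiable in λ and in the weights' values.
    """
    w_data = weights.data if isinstance(weights, Tensor) else np.asarray(weights)
    q = _rank_percentiles(w_data[..., 1:]).astype(w_data.dtype)
    mask = ad.sigmoid(ad.mul(ad.add(lambda_tensor, -q), 1.0 / relax_temp))
    masked = ad.mul(weights[..., 1:], mask)
    return ad.matmul(masked, tokens[1:, :])


def confidence_feature(weights):
    """Prompt-match confidence ``s = 1 − H(w)/ln M`` ∈ [0, 1].

    1 for a one-hot match distribution, 0 for a uniform one; invariant
    under permutation of the weights.
    """
    m = weights.shape[-1]
    if isinstance(weights, Tensor):
        # training path: softmax outputs are strictly positive
        ent = ad.mul(ad.tsum(ad.mul(weights, ad.log(ad.maximum(weights, 1e-30))),
                             axis=-1, keepdims=True), -1.0)
        return ad.add(1.0, ad.mul(ent, -1.0 / math.log(m)))
    w = np.asarray(weights, dtype=np.float64)
    wl = np.where(w > 0, w * np.log(np.where(w > 0, w, 1.0)), 0.0)
    ent = -wl.sum(axis=-1)
    return 1.0 - ent / math.log(m)


class RefinementMLP(Module):
    """One-hidden-layer residual refinement head, output zero at init."""

    def __init__(self, channels: int, rng: np.random.Generator, activation: str = "gelu"):
        self.hidden = Linear(2 * channels + 1, channels, rng, init="lecun")
        self.out = Linear(channels, channels, rng, init="zero")
        self.activation = activation
        self.channels = channels


def refine_prototype(prototype, fg_vector, s, mlp: RefinementMLP):
    """p_fg = p + MLP([p; f_fg; s]); exact identity for a fresh MLP."""
    s_arr = s if isinstance(s, Tensor) else np.atleast_1d(np.asarray(s, dtype=np.float64))
    if not isinstance(s_arr, Tensor) and s_arr.ndim < np.asarray(prototype).ndim:
        s_arr = s_arr[..., None]
    feats = ad.concatenate([prototype, fg_vector, s_arr], axis=-1)
    if feats.shape[-1] != 2 * mlp.channels + 1:
        raise ValueError("refinement MLP input width mismatch")
    act = ad.ACTIVATIONS[mlp.activation]
    return ad.add(prototype, mlp.out(act(mlp.hidden(feats))))


def cosine_map(vector, fmap):
    """Per-location cosine similarity between a length-C vector and a
    (…, C, H, W) map; all-zero feature vectors map to similarity 0."""
    num = ad.tsum(ad.mul(ad.reshape(vector, vector.shape[:-1] + (vector.shape[-1], 1, 1)), fmap),
                  axis=-3)
    vnorm = ad.sqrt(ad.tsum(ad.mul(vector, vector), axis=-1))
    fnorm = ad.sqrt(ad.tsum(ad.mul(fmap, fmap), axis=-3))
    den = ad.mul(ad.reshape(vnorm, vnorm.shape + (1, 1)), fnorm)
    return num / ad.maximum(den, 1e-12)


def build_prompt_embedding(fmap, p_fg, f_fg, fusion: Linear):
    """Concatenate [activation map; features; broadcast f_fg] channel-wise
    and fuse with a 1×1 convolution (a per-location affine map)."""
    C, H, W = fmap.shape[-3:]
    act_map = cosine_map(p_fg, fmap)
    act_ch = ad.reshape(act_map, act_map.shape[:-2] + (1, H, W))
    fg = ad.reshape(f_fg, f_fg.shape[:-1] + (C, 1, 1))
    ones = np.ones((1, H, W)) if fmap.ndim == 3 else np.ones((1, 1, H, W))
    fg_b = ad.mul(fg, ones)
    stacked = ad.concatenate([act_ch, fmap, fg_b], axis=-3)
    from .dictionary_core import map_to_tokens, tokens_to_map
    tokens = map_to_tokens(stacked)
    fused = fusion(tokens)
    return tokens_to_map(fused, (H, W))


def identity_fusion_conv(channels: int) -> Linear:
    """1×1 fusion conv initialised to pass the feature block through
    unchanged (zero weight on activation-map and f_fg channels)."""
    rng = np.random.default_rng(0)
    lin = Linear(2 * channels + 1, channels, rng, init="zero")
    lin.weight.data[1:channels + 1, :] = np.eye(channels)
    return lin
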