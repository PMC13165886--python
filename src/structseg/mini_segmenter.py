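"""Miniature encoder–decoder segmenter wiring all modules together.

A small vision-transformer backbone (patch embedding + ``L`` pre-norm
blocks) stands in for a large promptable-segmentation encoder: every module
of this package operates on generic token/map features, so the method is
preserved at desk scale.  Layer layout:

* layers 1–2: fine-grained dictionary enhancement (when ``fine_grained``),
  emitting compensations ΔF(1), ΔF(2);
* layers 3..L: residual injection of the structural shortcut built from
  ΔF(1,2) (when ``fine_grained``), then the always-on channel-attention
  filter and residual bottleneck adapter (the adapter-equipped baseline
  that the ablation toggles are measured against);
* prompt branch (when ``prompt_confidence``): dense prompt embedding from
  the shared dictionary, gated by a scalar confidence ``c`` and fused
  softly with the image embedding;
* SCFD (when ``scfd``): one step of learnable frequency-domain diffusion,
  residually re-injected;
* decoder: two linear pixel-shuffle upsampling blocks and a per-class head.

All residual insertions are exactly zero at construction, so a fresh model
with any toggle combination produces bitwise-identical logits — ablation
comparisons start from a common baseline.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from . import autodiff as ad
from .autodiff import AdamW, LayerNorm, Linear, Module, Parameter, Tensor
from .dictionary_core import (AdjustmentMLP, StructuralDictionary,
                              build_dictionary, enhance, map_to_tokens,
                              tokens_to_map)
from .encoder_adaptation import (DeepAdapter, ShortcutProjector, adapter_update,
                                 channel_filter_tokens, fuse_layer,
                                 structural_shortcut)
from .prompt_gating import GatingHead, gate_confidence, matching_score, similarity_map
from .prompt_synthesis import (RefinementMLP, SelectionConfig, confidence_feature,
                               cosine_map, identity_fusion_conv, match_dictionary,
                               refine_prototype, select_top_lambda,
                               select_top_lambda_learnable)
from .scfd import SCFDModule

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "SegmenterNetwork",
    "combined_loss",
    "soft_dice_loss",
    "train_segmenter",
    "predict_masks",
    "MiniSegmenter",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    image_size: int = 96
    patch_size: int = 8
    in_channels: int = 3
    channels: int = 64
    encoder_layers: int = 4
    heads: int = 4
    n_classes: int = 3
    mlp_ratio: float = 2.0
    # module toggles
    fine_grained: bool = True
    prompt_confidence: bool = True
    scfd: bool = True
    # dictionary
    token_count: int = 65
    rank: int = 16
    init_sigma: float = 0.01
    dict_activation: str = "gelu"
    # prompt selection
    lambda0: float = 0.5
    relax_temp: float = 0.05
    hard_eval: bool = True
    prompt_dict_source: str = "concat"  # concat layers 1-2 | layer1 | layer2
    # gating
    gating_variant: str = "as_printed"
    # scfd
    fve_depth: int = 8
    lambda_gate: float = 0.5
    tau0: float = 1.0
    freq_map: str = "discrete"
    # adapters
    bottleneck: int = 16
    adapter_level: int = 4  # opaque depth knob carried in config
    seed: int = 0
    dtype: str = "float32"  # working precision of the trainable stack

    def __post_init__(self):
        if self.encoder_layers < 3:
            raise ValueError("encoder_layers must be >= 3")
        if self.image_size % self.patch_size:
            raise ValueError("image_size must be divisible by patch_size")
        if self.channels % self.heads:
            raise ValueError("channels must be divisible by heads")

    @property
    def grid(self) -> tuple[int, int]:
        g = self.image_size // self.patch_size
        return (g, g)

    @property
    def n_tokens(self) -> int:
        g = self.image_size // self.patch_size
        return g * g


@dataclass
class TrainConfig:
    learning_rate: float = 5e-4
    weight_decay: float = 0.1
    beta: float = 0.8
    warmup_steps: int = 25
    max_epochs: int = 20
    early_stop_epochs: int = 0  # 0 disables early stopping
    batch_size: int = 8
    seed: int = 0
    frozen_backbone: bool = False
    dice_eps: float = 1e-5

    def __post_init__(self):
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")


class _Attention(Module):
    def __init__(self, channels: int, heads: int, rng):
        self.qkv = Linear(channels, 3 * channels, rng)
        self.out = Linear(channels, channels, rng)
        self.heads = heads
        self.dh = channels // heads

    def __call__(self, x):
        B, N, C = x.shape
        h, dh = self.heads, self.dh
        qkv = self.qkv(x)                                   # (B, N, 3C)
        qkv = ad.reshape(qkv, (B, N, 3, h, dh))
        qkv = ad.transpose(qkv, (2, 0, 3, 1, 4))            # (3, B, h, N, dh)
        q, k, v = qkv[0], qkv[1], qkv[2]
        att = ad.mul(ad.matmul(q, ad.transpose(k, (0, 1, 3, 2))), 1.0 / math.sqrt(dh))
        att = ad.softmax(att, axis=-1)
        y = ad.matmul(att, v)                               # (B, h, N, dh)
        y = ad.reshape(ad.transpose(y, (0, 2, 1, 3)), (B, N, C))
        return self.out(y)


class _Block(Module):
    def __init__(self, channels: int, heads: int, mlp_ratio: float, rng):
        hidden = int(channels * mlp_ratio)
        self.norm1 = LayerNorm(channels)
        self.attn = _Attention(channels, heads, rng)
        self.norm2 = LayerNorm(channels)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)

    def __call__(self, x):
        x = ad.add(x, self.attn(self.norm1(x)))
        return ad.add(x, self.fc2(ad.relu(self.fc1(self.norm2(x)))))


class _UpBlock(Module):
    """Linear pixel-shuffle upsampling: C_in → C_out at f× resolution."""

    def __init__(self, c_in: int, c_out: int, factor: int, rng):
        self.proj = Linear(c_in, c_out * factor * factor, rng)
        self.factor = factor
        self.c_out = c_out

    def __call__(self, x, grid):
        B, N, _ = x.shape
        h, w = grid
        f, co = self.factor, self.c_out
        y = self.proj(x)
        y = ad.reshape(y, (B, h, w, f, f, co))
        y = ad.transpose(y, (0, 1, 3, 2, 4, 5))
        y = ad.reshape(y, (B, h * f * w * f, co))
        return ad.relu(y), (h * f, w * f)


class SegmenterNetwork(Module):
    """Full differentiable model; parameters tagged 'backbone' or 'head'."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        C, ps = cfg.channels, cfg.patch_size

        # --- backbone ---
        self.patch_embed = Linear(cfg.in_channels * ps * ps, C, rng)
        self.pos_embed = Parameter(rng.normal(0.0, 0.02, (1, cfg.n_tokens, C)))
        self.blocks = [_Block(C, cfg.heads, cfg.mlp_ratio, rng)
                       for _ in range(cfg.encoder_layers)]
        self.final_norm = LayerNorm(C)
        for m in (self.patch_embed, self.final_norm, *self.blocks):
            m.set_group("backbone")
        self.pos_embed.group = "backbone"

        # --- fine-grained dictionaries, layers 1-2 ---
        self.dicts = [build_dictionary(cfg.token_count, cfg.rank, C,
                                       cfg.init_sigma, seed=cfg.seed * 1000 + i)
                      for i in range(2)]
        self.adj_mlps = [AdjustmentMLP(C, rng, cfg.dict_activation) for _ in range(2)]
        self.shortcut_proj = ShortcutProjector(C, rng)
        # b_p must stay zero at init so the shortcut vanishes with zero ΔF
        # (Linear already zero-inits biases).

        # --- always-on deep adapters (baseline chain) ---
        self.adapters = [DeepAdapter(C, cfg.bottleneck, rng)
                         for _ in range(cfg.encoder_layers - 2)]

        # --- prompt branch ---
        self.selection = SelectionConfig(
            lambda_raw=SelectionConfig.raw_for(cfg.lambda0),
            relax_temp=cfg.relax_temp, hard_eval=cfg.hard_eval)
        self.lambda_raw = Parameter(np.array(self.selection.lambda_raw))
        self.refine_mlp = RefinementMLP(C, rng)
        self.fusion_conv = identity_fusion_conv(C)
        self.gating_head = GatingHead(C, rng, cfg.gating_variant)

        # --- SCFD ---
        g = cfg.image_size // ps
        self.scfd = SCFDModule(g, g, rng, depth=cfg.fve_depth,
                               lambda_gate=cfg.lambda_gate, tau0=cfg.tau0,
                               freq_map=cfg.freq_map)

        # --- decoder ---
        self.up1 = _UpBlock(C, 24, 4 if ps % 4 == 0 else 2, rng)
        f2 = ps // self.up1.factor
        self.up2 = _UpBlock(24, 12, max(f2, 1), rng)
        self.head = Linear(12, cfg.n_classes, rng)
        self.set_group("head")

        dt = np.dtype(cfg.dtype)
        if dt != np.float64:
            for p in self.parameters():
                p.data = p.data.astype(dt)

    # -- plumbing ------------------------------------------------------
    def _patchify(self, images: np.ndarray) -> np.ndarray:
        B, ch, H, W = images.shape
        ps = self.cfg.patch_size
        x = images.reshape(B, ch, H // ps, ps, W // ps, ps)
        x = x.transpose(0, 2, 4, 1, 3, 5).reshape(B, (H // ps) * (W // ps), ch * ps * ps)
        return x

    def prompt_tokens_matrix(self):
        """Dictionary rows the prompt branch matches against:
        [layer-1 silent; layer-1 structural; layer-2 structural]."""
        t1 = self.dicts[0].tokens_tensor()
        t2 = self.dicts[1].tokens_tensor()
        src = self.cfg.prompt_dict_source
        if src == "layer1":
            return t1
        if src == "layer2":
            return t2
        return ad.concatenate([t1, t2[1:, :]], axis=0)

    # -- forward -------------------------------------------------------
    def forward(self, images: np.ndarray, training: bool = False,
                collect_aux: bool = False):
        cfg = self.cfg
        images = np.asarray(images, dtype=cfg.dtype)
        if images.ndim == 3:
            images = images[:, None, :, :]
        if images.shape[-2:] != (cfg.image_size, cfg.image_size) \
                or images.shape[1] != cfg.in_channels:
            raise ValueError(
                f"expected (B,{cfg.in_channels},{cfg.image_size},{cfg.image_size}) "
                f"images, got {images.shape}")
        B = images.shape[0]
        grid = cfg.grid

        x = ad.add(self.patch_embed(Tensor(self._patchify(images))), self.pos_embed)
        deltas = []
        for l, blk in enumerate(self.blocks):
            x = blk(x)
            if l < 2 and cfg.fine_grained:
                x, dF = enhance(x, self.dicts[l], self.adj_mlps[l])
                deltas.append(dF)
            if l >= 2:
                if cfg.fine_grained and len(deltas) == 2:
                    shortcut = structural_shortcut(deltas[0], deltas[1],
                                                   self.shortcut_proj)
                    x = fuse_layer(x, shortcut)
                _, x = channel_filter_tokens(x)
                x = adapter_update(x, self.adapters[l - 2])
        x = self.final_norm(x)
        image_emb = x                                        # (B, N, C)
        aux: dict = {}

        if cfg.prompt_confidence:
            proto = ad.tmean(image_emb, axis=1)              # GAP prototype (B, C)
            tokens = self.prompt_tokens_matrix()
            weights = match_dictionary(proto, tokens)        # (B, M')
            lam = ad.mul(ad.sigmoid(self.lambda_raw), 1.1)
            lam_val = min(1.0, float(lam.data))
            if training:
                lam_c = ad.maximum(ad.mul(lam, -1.0), -1.0)  # min(lam, 1) = -max(-lam, -1)
                lam_c = ad.mul(lam_c, -1.0)
                f_fg = select_top_lambda_learnable(weights, tokens, lam_c,
                                                   cfg.relax_temp)
            else:
                sel = SelectionConfig(lambda_raw=float(self.lambda_raw.data),
                                      relax_temp=cfg.relax_temp,
                                      hard_eval=cfg.hard_eval)
                f_fg = select_top_lambda(weights, tokens, sel, training=False)
            s = confidence_feature(weights)
            if isinstance(s, Tensor):
                s = ad.reshape(s, (B, 1))
            p_fg = refine_prototype(proto, f_fg, s, self.refine_mlp)

            fmap = tokens_to_map(image_emb, grid)            # (B, C, h, w)
            act = cosine_map(p_fg, fmap)                     # (B, h, w)
            act_ch = ad.reshape(act, (B, 1) + grid)
            fg_b = ad.mul(ad.reshape(f_fg, (B, cfg.channels, 1, 1)),
                          np.ones((1, 1) + grid, dtype=cfg.dtype))
            stacked = ad.concatenate([act_ch, fmap, fg_b], axis=1)
            prompt_tokens = self.fusion_conv(map_to_tokens(stacked))  # (B, N, C)

            prompt_map = tokens_to_map(prompt_tokens, grid)
            sim = similarity_map(prompt_map, fmap)
            a = matching_score(sim)                          # (B,)
            a_col = ad.reshape(a, (B, 1))
            pbar = ad.tmean(prompt_tokens, axis=1)
            h_vec = ad.concatenate([pbar, a_col], axis=-1)
            pre = self.gating_head.head(h_vec)
            if self.gating_head.variant == "as_printed":
                pre = ad.relu(pre)
            c = ad.sigmoid(pre)                              # (B, 1)
            c_b = ad.reshape(c, (B, 1, 1))
            # algebraically c·P + (1−c)·X, written residually so the branch
            # is bitwise inert while the fusion conv passes X through
            x = ad.add(image_emb, ad.mul(c_b, ad.add(prompt_tokens,
                                                     ad.mul(image_emb, -1.0))))
            if collect_aux:
                aux["confidence"] = c.data[:, 0].copy()
                aux["match_score"] = a.data.copy()
                aux["selection_ratio"] = lam_val
                aux["prompt_entropy_confidence"] = (
                    s.data[:, 0].copy() if isinstance(s, Tensor) else np.asarray(s))

        if cfg.scfd:
            fmap = tokens_to_map(x, grid)
            fmap = self.scfd(fmap)
            x = map_to_tokens(fmap)

        y, g1 = self.up1(x, grid)
        y, g2 = self.up2(y, g1)
        logits = self.head(y)                                # (B, H*W, K)
        H = g2[0]
        logits = ad.transpose(ad.reshape(logits, (B, H, H, cfg.n_classes)),
                              (0, 3, 1, 2))                  # (B, K, H, W)
        if collect_aux:
            return logits, aux
        return logits

    def trainable_parameters(self, frozen_backbone: bool):
        params = self.parameters()
        if frozen_backbone:
            params = [p for p in params if p.group != "backbone"]
        return params


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def soft_dice_loss(probs, onehot: np.ndarray, eps: float = 1e-5):
    """1 − mean over foreground classes of 2Σpg+ε / (Σp+Σg+ε)."""
    axes = tuple(i for i in range(onehot.ndim) if i != 1)
    inter = ad.tsum(ad.mul(probs, onehot), axis=axes)
    psum = ad.tsum(probs, axis=axes)
    gsum = onehot.sum(axis=axes)
    dice = (2.0 * inter + eps) / (psum + gsum + eps)
    fg = dice[1:]
    return 1.0 - ad.tmean(fg)


def combined_loss(logits, labels: np.ndarray, beta: float = 0.8,
                  eps: float = 1e-5):
    """(1−β)·cross-entropy + β·soft-Dice on per-class probabilities."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    labels = np.asarray(labels)
    K = logits.shape[1]
    if labels.min() < 0 or labels.max() >= K:
        raise ValueError(f"labels must lie in 0..{K - 1}")
    data = logits.data if isinstance(logits, Tensor) else np.asarray(logits)
    shift = data.max(axis=1, keepdims=True)
    z = ad.add(logits, -shift)
    logp = ad.add(z, ad.mul(ad.log(ad.tsum(ad.exp(z), axis=1, keepdims=True)), -1.0))
    dt = data.dtype if data.dtype in (np.float32, np.float64) else np.float64
    onehot = np.moveaxis(np.eye(K, dtype=dt)[labels], -1, 1)  # (B, K, H, W)
    ce = ad.mul(ad.tmean(ad.tsum(ad.mul(logp, onehot), axis=1)), -1.0)
    probs = ad.exp(logp)
    dloss = soft_dice_loss(probs, onehot, eps)
    return ad.add(ad.mul(ce, 1.0 - beta), ad.mul(dloss, beta))


# ---------------------------------------------------------------------------
# training / inference
# ---------------------------------------------------------------------------

def _lr_at(step: int, total: int, cfg: TrainConfig) -> float:
    """Linear warm-up to the base rate, then cosine decay."""
    w = max(cfg.warmup_steps, 1)
    if step < w:
        return cfg.learning_rate * (step + 1) / w
    if total <= w:
        return cfg.learning_rate
    t = (step - w) / max(total - w, 1)
    return cfg.learning_rate * 0.5 * (1.0 + math.cos(math.pi * t))


def train_segmenter(net: SegmenterNetwork, images: np.ndarray, labels: np.ndarray,
                    cfg: TrainConfig, val: tuple | None = None,
                    eval_fn=None):
    """Desk-scale training loop; returns per-epoch history.

    ``val`` is an optional ``(images, labels)`` pair scored after each
    epoch with ``eval_fn(net, images, labels) -> float`` (higher better);
    with ``early_stop_epochs > 0`` training stops after that many epochs
    without improvement and the best state is restored.
    """
    n = len(images)
    if n == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    params = net.trainable_parameters(cfg.frozen_backbone)
    opt = AdamW(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    steps_per_epoch = max(1, math.ceil(n / cfg.batch_size))
    total_steps = steps_per_epoch * cfg.max_epochs
    history: list[dict] = []
    best_score, best_state, since_best = -np.inf, None, 0
    step = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for b in range(steps_per_epoch):
            idx = order[b * cfg.batch_size:(b + 1) * cfg.batch_size]
            logits = net.forward(images[idx], training=True)
            loss = combined_loss(logits, labels[idx], cfg.beta, cfg.dice_eps)
            lv = float(loss.data)
            if not np.isfinite(lv):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {step}: {lv}")
            opt.zero_grad()
            loss.backward()
            opt.step(lr=_lr_at(step, total_steps, cfg))
            epoch_loss += lv
            step += 1
        rec = {"epoch": epoch, "loss": epoch_loss / steps_per_epoch}
        if val is not None and eval_fn is not None:
            score = float(eval_fn(net, val[0], val[1]))
            rec["val_score"] = score
            if score > best_score:
                best_score, since_best = score, 0
                best_state = {k: v.copy() for k, v in net.state_arrays().items()}
            else:
                since_best += 1
            if cfg.early_stop_epochs and since_best >= cfg.early_stop_epochs:
                history.append(rec)
                break
        history.append(rec)
    if best_state is not None:
        net.load_state_arrays(best_state)
    return history


def masks_from_logits(logits: np.ndarray) -> np.ndarray:
    """Argmax over the class axis; ties resolve to the lower class index."""
    return np.argmax(np.asarray(logits), axis=1)


def predict_masks(net: SegmenterNetwork, images: np.ndarray,
                  batch_size: int = 8) -> np.ndarray:
    """Per-pixel class masks for a batch of images."""
    outs = []
    for b in range(0, len(images), batch_size):
        logits = net.forward(images[b:b + batch_size], training=False)
        outs.append(masks_from_logits(logits.data))
    return np.concatenate(outs, axis=0)


# ---------------------------------------------------------------------------
# sklearn estimator
# ---------------------------------------------------------------------------

class MiniSegmenter(BaseEstimator):
    """Sklearn-style facade over the miniature segmenter.

    ``fit(X, y)`` expects images ``X`` of shape (n, H, W[, ch]) with values
    in [0, 1] and integer label masks ``y`` of shape (n, H, W);
    ``predict`` returns label masks.  All architecture and training knobs
    are constructor parameters so the estimator composes with
    ``sklearn.base.clone`` and grid-search tooling.
    """

    def __init__(self, image_size=96, patch_size=8, in_channels=3, channels=64,
                 encoder_layers=4, heads=4, n_classes=3,
                 fine_grained=True, prompt_confidence=True, scfd=True,
                 token_count=65, rank=16, init_sigma=0.01,
                 lambda0=0.5, relax_temp=0.05, gating_variant="as_printed",
                 fve_depth=8, lambda_gate=0.5, tau0=1.0, freq_map="discrete",
                 bottleneck=16, adapter_level=4,
                 learning_rate=5e-4, weight_decay=0.1, beta=0.8,
                 warmup_steps=25, max_epochs=20, early_stop_epochs=0,
                 batch_size=8, frozen_backbone=False, seed=0):
        self.image_size = image_size
        self.patch_size = patch_size
        self.in_channels = in_channels
        self.channels = channels
        self.encoder_layers = encoder_layers
        self.heads = heads
        self.n_classes = n_classes
        self.fine_grained = fine_grained
        self.prompt_confidence = prompt_confidence
        self.scfd = scfd
        self.token_count = token_count
        self.rank = rank
        self.init_sigma = init_sigma
        self.lambda0 = lambda0
        self.relax_temp = relax_temp
        self.gating_variant = gating_variant
        self.fve_depth = fve_depth
        self.lambda_gate = lambda_gate
        self.tau0 = tau0
        self.freq_map = freq_map
        self.bottleneck = bottleneck
        self.adapter_level = adapter_level
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.beta = beta
        self.warmup_steps = warmup_steps
        self.max_epochs = max_epochs
        self.early_stop_epochs = early_stop_epochs
        self.batch_size = batch_size
        self.frozen_backbone = frozen_backbone
        self.seed = seed

    # -- config assembly ----------------------------------------------
    def model_config(self) -> ModelConfig:
        return ModelConfig(
            image_size=self.image_size, patch_size=self.patch_size,
            in_channels=self.in_channels, channels=self.channels,
            encoder_layers=self.encoder_layers, heads=self.heads,
            n_classes=self.n_classes, fine_grained=self.fine_grained,
            prompt_confidence=self.prompt_confidence, scfd=self.scfd,
            token_count=self.token_count, rank=self.rank,
            init_sigma=self.init_sigma, lambda0=self.lambda0,
            relax_temp=self.relax_temp, gating_variant=self.gating_variant,
            fve_depth=self.fve_depth, lambda_gate=self.lambda_gate,
            tau0=self.tau0, freq_map=self.freq_map,
            bottleneck=self.bottleneck, adapter_level=self.adapter_level,
            seed=self.seed)

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate, weight_decay=self.weight_decay,
            beta=self.beta, warmup_steps=self.warmup_steps,
            max_epochs=self.max_epochs, early_stop_epochs=self.early_stop_epochs,
            batch_size=self.batch_size, seed=self.seed,
            frozen_backbone=self.frozen_backbone)

    @staticmethod
    def _to_chw(X: np.ndarray, in_channels: int) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 3:
            X = X[:, None, :, :]
        elif X.ndim == 4 and X.shape[-1] in (1, 3) and X.shape[1] not in (1, 3):
            X = np.moveaxis(X, -1, 1)
        if X.shape[1] != in_channels:
            raise ValueError(f"expected {in_channels} channels, got {X.shape[1]}")
        return X

    # -- estimator API -------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        X = self._to_chw(X, self.in_channels)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.network_ = SegmenterNetwork(self.model_config())
        val = None
        eval_fn = None
        if X_val is not None and y_val is not None:
            X_val = self._to_chw(X_val, self.in_channels)
            val = (X_val, np.asarray(y_val))

            def eval_fn(net, xs, ys):
                from .evaluation import foreground_dice
                preds = predict_masks(net, xs, self.batch_size)
                return float(np.mean([foreground_dice(p, t, self.n_classes)
                                      for p, t in zip(preds, ys)]))

        self.history_ = train_segmenter(self.network_, X, y, self.train_config(),
                                        val=val, eval_fn=eval_fn)
        self.classes_ = np.arange(self.n_classes)
        self.n_features_in_ = X.shape[1] * X.shape[2] * X.shape[3]
        return self

    def _net(self) -> SegmenterNetwork:
        if not hasattr(self, "network_"):
            # an unfitted network is still usable for forward-pass analysis
            self.network_ = SegmenterNetwork(self.model_config())
        return self.network_

    def predict(self, X) -> np.ndarray:
        X = self._to_chw(X, self.in_channels)
        return predict_masks(self._net(), X, self.batch_size)

    def predict_logits(self, X) -> np.ndarray:
        X = self._to_chw(X, self.in_channels)
        outs = []
        for b in range(0, len(X), self.batch_size):
            outs.append(self._net().forward(X[b:b + self.batch_size]).data)
        return np.concatenate(outs, axis=0)

    def confidence_scores(self, X) -> np.ndarray:
        """Per-sample prompt-gating confidence c (empty if toggle is off)."""
        X = self._to_chw(X, self.in_channels)
        scores = []
        for b in range(0, len(X), self.batch_size):
            _, aux = self._net().forward(X[b:b + self.batch_size], collect_aux=True)
            if "confidence" in aux:
                scores.append(aux["confidence"])
        return np.concatenate(scores) if scores else np.empty(0)

    def score(self, X, y) -> float:
        from .evaluation import foreground_dice
        preds = self.predict(X)
        y = np.asarray(y)
        return float(np.mean([foreground_dice(p, t, self.n_classes)
                              for p, t in zip(preds, y)]))


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(net: SegmenterNetwork, path, extra: dict | None = None):
    arrays = net.state_arrays()
    cfg = json.dumps({"model": asdict(net.cfg), "extra": extra or {}})
    np.savez(path, __config__=np.frombuffer(cfg.encode(), dtype=np.uint8),
             **{f"param:{k}": v for k, v in arrays.items()})


def load_checkpoint(path) -> SegmenterNetwork:
    with np.load(path) as z:
        cfg = json.loads(bytes(z["__config__"]).decode())
        net = SegmenterNetwork(ModelConfig(**cfg["model"]))
        arrays = {k[len("param:"):]: z[k] for k in z.files if k.startswith("param:")}
    net.load_state_arrays(arrays)
    return net
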