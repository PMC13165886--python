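"""Deep-layer reuse of shallow structural compensation.

The two shallow dictionary-enhanced layers emit compensations ΔF(1), ΔF(2).
From layer 3 onward these are recombined into a single *structural
shortcut*

    ΔF̄_low = (α·ΔF(1) + (1−α)·ΔF(2))·W_p + b_p ,   α = logistic(α_raw)

which is added residually to each deep layer's features.  The fused
features then pass through parameter-free channel-attention filtering
(logistic of summed global average and max pooling, channel-wise rescale)
and a residual bottleneck adapter whose up-projection is zero at
construction.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Linear, Module, Parameter

__all__ = [
    "ShortcutProjector",
    "DeepAdapter",
    "structural_shortcut",
    "fuse_layer",
    "channel_filter",
    "channel_filter_tokens",
    "adapter_update",
]


class ShortcutProjector(Module):
    """Learnable convex aggregation of the two shallow compensations,
    followed by an affine statistical-alignment projection.

    ``b_p`` is zero at construction so that, with zero compensations, the
    shortcut is exactly zero.
    """

    def __init__(self, channels: int, rng: np.random.Generator, alpha_raw: float = 0.0):
        self.alpha_raw = Parameter(np.array(float(alpha_raw)))
        self.proj = Linear(channels, channels, rng, init="lecun")

    @property
    def alpha_agg(self) -> float:
        return float(ad.sigmoid(np.array(self.alpha_raw.data)))

    def alpha_tensor(self):
        return ad.sigmoid(self.alpha_raw)


class DeepAdapter(Module):
    """Residual bottleneck MLP (Linear–Act–Linear); identity at init."""

    def __init__(self, channels: int, bottleneck: int, rng: np.random.Generator,
                 activation: str = "gelu"):
        if not (0 < bottleneck < channels):
            raise ValueError("bottleneck width must satisfy 0 < d_b < C")
        if activation not in ad.ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        self.down = Linear(channels, bottleneck, rng, init="lecun")
        self.up = Linear(bottleneck, channels, rng, init="zero")
        self.activation = activation


def structural_shortcut(dF1, dF2, proj: ShortcutProjector):
    """(α·ΔF(1) + (1−α)·ΔF(2))·W_p + b_p."""
    if dF1.shape != dF2.shape:
        raise ValueError("shallow compensations must share a shape")
    alpha = proj.alpha_tensor()
    mix = ad.add(ad.mul(alpha, dF1), ad.mul(ad.add(1.0, ad.mul(alpha, -1.0)), dF2))
    return proj.proj(mix)


def fuse_layer(features, shortcut):
    """Residual injection of the structural shortcut (elementwise sum)."""
    if features.shape != shortcut.shape:
        raise ValueError("shape mismatch in layer fusion")
    return ad.add(features, shortcut)


def channel_filter(fmap):
    """Channel attention on a spatial map (…, C, H, W).

    Returns ``(weights, filtered)`` where ``weights_c = logistic(GAP_c +
    GMP_c)`` and the map is rescaled channel-wise.  Weights lie strictly in
    (0,1); a constant-zero channel gets weight exactly 0.5.
    """
    gap = ad.tmean(fmap, axis=(-2, -1))
    gmp = ad.tmax(ad.reshape(fmap, fmap.shape[:-2] + (-1,)), axis=-1)
    w = ad.sigmoid(ad.add(gap, gmp))
    w_b = ad.reshape(w, w.shape + (1, 1))
    return w, ad.mul(w_b, fmap)


def channel_filter_tokens(tokens):
    """Same channel attention on the flattened (…, N, C) token view."""
    gap = ad.tmean(tokens, axis=-2)
    gmp = ad.tmax(tokens, axis=-2)
    w = ad.sigmoid(ad.add(gap, gmp))
    w_b = ad.reshape(w, w.shape[:-1] + (1,) + w.shape[-1:])
    return w, ad.mul(w_b, tokens)


def adapter_update(features, adapter: DeepAdapter):
    """F + up(act(down(F))); exact identity for a fresh adapter."""
    act = ad.ACTIVATIONS[adapter.activation]
    out = ad.add(features, adapter.up(act(adapter.down(features))))
    data = out.data if hasattr(out, "data") else out
    if not np.all(np.isfinite(data)):
        raise FloatingPointError("non-finite output of deep adapter")
    return out
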