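"""Prompt–image consistency gating and soft confidence fusion.

A single scalar confidence ``c`` per image weighs the dense prompt
embedding against the image embedding.  The gate sees (i) the global
average of the prompt features and (ii) the mean per-location cosine
similarity between prompt and image maps, and maps them through a one-layer
head.

The head is provided in two variants.  ``as_printed`` applies
``logistic(ReLU(·))``, which confines ``c`` to [0.5, 1) — a faithful
rendering of the published composition, whose claimed range [0,1] it
contradicts.  ``no_relu`` drops the rectifier and yields the full (0,1)
range.  Neither is "corrected"; the default is the printed form.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Linear, Module, Tensor

__all__ = [
    "GatingHead",
    "similarity_map",
    "matching_score",
    "gate_confidence",
    "fuse_confidence",
]


class GatingHead(Module):
    """One-layer confidence head on ``h = [mean(P); a] ∈ R^{C+1}``."""

    VARIANTS = ("as_printed", "no_relu")

    def __init__(self, channels: int, rng: np.random.Generator,
                 variant: str = "as_printed"):
        if variant not in self.VARIANTS:
            raise ValueError(f"variant must be one of {self.VARIANTS}")
        self.head = Linear(channels + 1, 1, rng, init="lecun")
        self.variant = variant
        self.channels = channels

    @property
    def W1(self):
        return self.head.weight.data[:, 0]

    @property
    def b1(self):
        return float(self.head.bias.data[0])


def similarity_map(P, X):
    """Per-location cosine similarity of two (…, C, H, W) maps ∈ [−1, 1]."""
    if P.shape != X.shape:
        raise ValueError("prompt/image map shape mismatch")
    num = ad.tsum(ad.mul(P, X), axis=-3)
    pn = ad.sqrt(ad.tsum(ad.mul(P, P), axis=-3))
    xn = ad.sqrt(ad.tsum(ad.mul(X, X), axis=-3))
    return num / ad.maximum(ad.mul(pn, xn), 1e-12)


def matching_score(S):
    """Global matching score: arithmetic mean of the similarity map."""
    size = np.prod(S.shape[-2:])
    if size == 0:
        raise ValueError("empty similarity map")
    return ad.tmean(S, axis=(-2, -1))


def gate_confidence(P, a, head: GatingHead):
    """c = logistic(ReLU(W1·[mean(P); a] + b1))  (or without the ReLU)."""
    if P.shape[-3] != head.channels:
        raise ValueError("gating head width mismatch")
    pbar = ad.tmean(P, axis=(-2, -1))
    a_arr = a if isinstance(a, Tensor) else np.atleast_1d(np.asarray(a, dtype=np.float64))
    if not isinstance(a_arr, Tensor) and a_arr.ndim < np.asarray(pbar.data if isinstance(pbar, Tensor) else pbar).ndim:
        a_arr = a_arr[..., None]
    h = ad.concatenate([pbar, a_arr], axis=-1)
    pre = head.head(h)
    if head.variant == "as_printed":
        pre = ad.relu(pre)
    c = ad.sigmoid(pre)
    return ad.reshape(c, c.shape[:-1]) if c.shape[-1] == 1 else c


def fuse_confidence(prompt_emb, image_emb, c):
    """Soft convex fusion ``c·prompt + (1−c)·image`` — no thresholding.

    Endpoints are exact: c=0 returns the image embedding bitwise, c=1 the
    prompt embedding bitwise.
    """
    c_val = c.data if isinstance(c, Tensor) else np.asarray(c, dtype=np.float64)
    if np.any(c_val < 0) or np.any(c_val > 1):
        raise ValueError("confidence c must lie in [0, 1]")
    return ad.add(ad.mul(c, prompt_emb), ad.mul(ad.add(1.0, ad.mul(c, -1.0)), image_emb))
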