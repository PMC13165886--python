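"""Learnable fine-grained structural dictionary and residual enhancement.

A structural dictionary is a bank of ``M`` learnable tokens ``T ∈ R^{M×C}``
stored in low-rank factorised form ``T = A·B`` with ``A ∈ R^{M×r}``,
``B ∈ R^{r×C}`` and ``r ≪ C``.  Row 0 is a *silent* token: it takes part in
the softmax normalisation of the retrieval weights but is excluded from
aggregation, so spatial positions that match nothing in the dictionary
receive (near-)zero compensation instead of a spurious one.

The enhancement pipeline applied to encoder features ``F ∈ R^{N×C}`` is

    weights    = softmax(F·Tᵀ/√C)            (retrieval, all M tokens)
    descriptor = weights[:, 1:] · T[1:, :]   (silent column dropped, no
                                              renormalisation)
    ΔF̄        = descriptor·W_T + b_T
    ΔF         = (act(ΔF̄) + F)·W_f + b_f
    F′         = F + ΔF

``W_f`` and ``b_f`` are zero at construction, so a freshly built adjustment
MLP makes ``enhance`` an exact identity — the compensation "fades in"
during training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Linear, Module, Parameter, Tensor

__all__ = [
    "StructuralDictionary",
    "FeatureTokens",
    "AdjustmentMLP",
    "build_dictionary",
    "correlate",
    "aggregate_local",
    "enhance",
    "save_dictionary",
    "load_dictionary",
    "tokens_to_map",
    "map_to_tokens",
]


@dataclass
class FeatureTokens:
    """Flattened N×C view of a C×H×W feature map (row-major flattening)."""

    values: np.ndarray
    spatial_shape: tuple[int, int]
    layout: str = "row-major"

    def __post_init__(self):
        H, W = self.spatial_shape
        if self.values.shape[-2] != H * W:
            raise ValueError(f"N={self.values.shape[-2]} != H*W={H * W}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")

    @property
    def n(self) -> int:
        return self.values.shape[-2]

    @property
    def channels(self) -> int:
        return self.values.shape[-1]

    def to_map(self):
        return tokens_to_map(self.values, self.spatial_shape)

    @classmethod
    def from_map(cls, fmap: np.ndarray) -> "FeatureTokens":
        return cls(map_to_tokens(fmap), fmap.shape[-2:])


def tokens_to_map(tokens, spatial_shape):
    """(…, N, C) row-major tokens → (…, C, H, W) spatial map."""
    H, W = spatial_shape
    lead = tokens.shape[:-2]
    C = tokens.shape[-1]
    x = ad.reshape(tokens, lead + (H, W, C))
    axes = tuple(range(len(lead))) + (len(lead) + 2, len(lead), len(lead) + 1)
    return ad.transpose(x, axes)


def map_to_tokens(fmap):
    """(…, C, H, W) spatial map → (…, N, C) row-major tokens."""
    lead = fmap.shape[:-3]
    C, H, W = fmap.shape[-3:]
    axes = tuple(range(len(lead))) + (len(lead) + 1, len(lead) + 2, len(lead))
    x = ad.transpose(fmap, axes)
    return ad.reshape(x, lead + (H * W, C))


class StructuralDictionary(Module):
    """Low-rank token bank; row 0 silent, rows 1..M-1 structural."""

    def __init__(self, factor_A: np.ndarray, factor_B: np.ndarray,
                 init_sigma: float, seed: int):
        factor_A = np.asarray(factor_A, dtype=np.float64)
        factor_B = np.asarray(factor_B, dtype=np.float64)
        if factor_A.ndim != 2 or factor_B.ndim != 2 or factor_A.shape[1] != factor_B.shape[0]:
            raise ValueError("inconsistent factor shapes")
        if not (np.all(np.isfinite(factor_A)) and np.all(np.isfinite(factor_B))):
            raise ValueError("non-finite dictionary factors")
        self.factor_A = Parameter(factor_A)
        self.factor_B = Parameter(factor_B)
        self.init_sigma = float(init_sigma)
        self.seed = int(seed)

    @property
    def token_count(self) -> int:
        return self.factor_A.data.shape[0]

    @property
    def rank(self) -> int:
        return self.factor_A.data.shape[1]

    @property
    def channels(self) -> int:
        return self.factor_B.data.shape[1]

    @property
    def tokens(self) -> np.ndarray:
        """Materialised token matrix T = A·B (plain array view)."""
        return self.factor_A.data @ self.factor_B.data

    def tokens_tensor(self) -> Tensor:
        """Differentiable token matrix for use inside the model graph."""
        return ad.matmul(self.factor_A, self.factor_B)


def build_dictionary(token_count: int, rank: int, channels: int,
                     init_sigma: float = 0.01, seed: int = 0) -> StructuralDictionary:
    """Draw both low-rank factors i.i.d. from N(0, init_sigma²), seeded."""
    if token_count < 2:
        raise ValueError("token_count must be >= 2 (silent + >=1 structural)")
    if not (1 <= rank < channels):
        raise ValueError("rank must satisfy 1 <= rank < channels")
    if channels <= 0:
        raise ValueError("channels must be positive")
    rng = np.random.default_rng(seed)
    A = rng.normal(0.0, 1.0, (token_count, rank)) * init_sigma
    B = rng.normal(0.0, 1.0, (rank, channels)) * init_sigma
    return StructuralDictionary(A, B, init_sigma, seed)


def _token_matrix(dictionary):
    if isinstance(dictionary, StructuralDictionary):
        return dictionary.tokens
    return dictionary


def correlate(features, dictionary):
    """Row-wise softmax of scaled dot products F·Tᵀ/√C over all M tokens.

    The silent token participates in the normalisation; rows whose best
    match is the silent token end up with their probability mass parked
    there, which :func:`aggregate_local` then discards.
    """
    T = _token_matrix(dictionary)
    C = T.shape[-1]
    fC = features.shape[-1]
    if fC != C:
        raise ValueError(f"channel mismatch: features C={fC}, dictionary C={C}")
    logits = ad.matmul(features, ad.transpose(T, (1, 0)) if isinstance(T, Tensor)
                       else np.swapaxes(np.asarray(T), -1, -2))
    logits = ad.mul(logits, 1.0 / math.sqrt(C))
    return ad.softmax(logits, axis=-1)


def aggregate_local(weights, dictionary):
    """Compensation descriptor: weights[:, 1:] · T[1:, :].

    The silent column is dropped *without* renormalising, so rows dominated
    by the silent token yield near-zero compensation (the bypass mechanism).
    """
    T = _token_matrix(dictionary)
    M = T.shape[0]
    if weights.shape[-1] != M:
        raise ValueError(f"token-count mismatch: weights M={weights.shape[-1]}, dict M={M}")
    return ad.matmul(weights[..., 1:], T[1:, :])


class AdjustmentMLP(Module):
    """Two-affine nonlinear adjustment; identity at construction.

    ``W_T, b_T`` form the local compensation draft; ``W_f, b_f`` (exactly
    zero at init) combine the activated draft with the original features.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 activation: str = "gelu"):
        if activation not in ad.ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        self.first = Linear(channels, channels, rng, init="lecun")
        self.second = Linear(channels, channels, rng, init="zero")
        self.activation = activation

    @property
    def W_T(self):
        return self.first.weight.data

    @property
    def b_T(self):
        return self.first.bias.data

    @property
    def W_f(self):
        return self.second.weight.data

    @property
    def b_f(self):
        return self.second.bias.data


def enhance(features, dictionary, mlp: AdjustmentMLP):
    """Residual structural enhancement; returns ``(F′, ΔF)``.

    ΔF is returned separately because the deep encoder layers reuse the
    shallow compensations as a structural shortcut.
    """
    weights = correlate(features, dictionary)
    descriptor = aggregate_local(weights, dictionary)
    draft = mlp.first(descriptor)
    act = ad.ACTIVATIONS[mlp.activation]
    delta = mlp.second(ad.add(act(draft), features))
    data = delta.data if isinstance(delta, Tensor) else delta
    if not np.all(np.isfinite(data)):
        raise FloatingPointError("non-finite compensation in dictionary enhancement layer")
    return ad.add(features, delta), delta


def save_dictionary(dictionary: StructuralDictionary, path):
    """Lossless round-trip checkpoint (named-array .npz container)."""
    np.savez(path, factor_A=dictionary.factor_A.data, factor_B=dictionary.factor_B.data,
             meta=np.array([dictionary.token_count, dictionary.rank,
                            dictionary.channels, dictionary.seed], dtype=np.int64),
             init_sigma=np.array(dictionary.init_sigma))


def load_dictionary(path) -> StructuralDictionary:
    with np.load(path) as z:
        meta = z["meta"]
        d = StructuralDictionary(z["factor_A"], z["factor_B"],
                                 float(z["init_sigma"]), int(meta[3]))
    return d
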