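"""Multi-domain synthetic datasets for cross-domain segmentation studies.

Two desk-scale tasks emulate the geometry of common benchmarks without any
downloads:

* ``fundus``: a bright elliptical optic disc with a strictly nested,
  brighter optic cup and a handful of dark curvilinear vessels on a
  reddish textured background (labels 0=background, 1=disc, 2=cup; every
  cup pixel lies inside the disc ellipse by construction);
* ``prostate``: a single smooth star-convex bright blob on a speckled
  grayscale background (labels 0/1).

"Domains" share the anatomy generator and differ only in *style*: gamma,
contrast, additive noise, blur, a smooth multiplicative bias field and (for
fundus) per-channel tints.  Styles are drawn from fixed, disjoint parameter
ranges shipped with the package, so inter-domain shift exceeds intra-domain
variation by construction and suites are reproducible artifacts.  Masks are
rendered before styling, so style never alters labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon

__all__ = [
    "DomainStyle",
    "SampleRecord",
    "DomainSuite",
    "FUNDUS_STYLE_RANGES",
    "PROSTATE_STYLE_RANGES",
    "sample_style",
    "apply_style",
    "generate_fundus_like",
    "generate_prostate_like",
    "make_domain_suite",
    "write_suite",
    "load_suite",
]


@dataclass
class DomainStyle:
    """Appearance transform; label-preserving by construction."""

    gamma: float = 1.0
    contrast: float = 1.0
    noise_sigma: float = 0.0
    blur_sigma: float = 0.0
    bias_amplitude: float = 0.0
    channel_tint: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if self.gamma <= 0 or self.contrast <= 0:
            raise ValueError("gamma and contrast must be positive")
        if self.noise_sigma < 0 or self.blur_sigma < 0 or self.bias_amplitude < 0:
            raise ValueError("noise/blur/bias amplitudes must be non-negative")


@dataclass
class SampleRecord:
    image: np.ndarray           # H×W or H×W×3, float in [0, 1]
    mask: np.ndarray            # H×W uint8 labels
    domain_id: int
    sample_id: int
    seed: int


@dataclass
class DomainSuite:
    task: str
    styles: list
    domains: list               # list of list[SampleRecord]
    manifest: pd.DataFrame
    seed: int

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    def arrays(self, domain: int):
        """(images, masks) stacked arrays for one domain."""
        recs = self.domains[domain]
        return (np.stack([r.image for r in recs]),
                np.stack([r.mask for r in recs]))


# Fixed disjoint per-domain style ranges: (low, high) per field.  Domain 0
# is closest to neutral; later domains drift progressively further.
FUNDUS_STYLE_RANGES = [
    {"gamma": (0.95, 1.05), "contrast": (0.95, 1.05), "noise_sigma": (0.00, 0.01),
     "blur_sigma": (0.0, 0.2), "bias_amplitude": (0.00, 0.03), "tint": (0.98, 1.02)},
    {"gamma": (0.70, 0.80), "contrast": (1.15, 1.30), "noise_sigma": (0.02, 0.03),
     "blur_sigma": (0.4, 0.7), "bias_amplitude": (0.05, 0.09), "tint": (0.90, 1.10)},
    {"gamma": (1.25, 1.40), "contrast": (0.70, 0.82), "noise_sigma": (0.03, 0.05),
     "blur_sigma": (0.8, 1.2), "bias_amplitude": (0.10, 0.16), "tint": (0.82, 1.18)},
    {"gamma": (0.55, 0.65), "contrast": (0.85, 0.95), "noise_sigma": (0.05, 0.07),
     "blur_sigma": (0.1, 0.3), "bias_amplitude": (0.16, 0.22), "tint": (0.75, 1.25)},
    {"gamma": (1.50, 1.70), "contrast": (1.30, 1.45), "noise_sigma": (0.01, 0.02),
     "blur_sigma": (1.3, 1.7), "bias_amplitude": (0.04, 0.08), "tint": (0.85, 1.15)},
    {"gamma": (0.85, 0.92), "contrast": (0.55, 0.68), "noise_sigma": (0.07, 0.09),
     "blur_sigma": (0.5, 0.9), "bias_amplitude": (0.22, 0.28), "tint": (0.70, 1.30)},
]

PROSTATE_STYLE_RANGES = [
    {**r, "tint": (1.0, 1.0)} for r in FUNDUS_STYLE_RANGES
]


def sample_style(task: str, domain: int, rng: np.random.Generator) -> DomainStyle:
    ranges = FUNDUS_STYLE_RANGES if task == "fundus" else PROSTATE_STYLE_RANGES
    if domain >= len(ranges):
        raise ValueError(f"at most {len(ranges)} predefined domains available")
    r = ranges[domain]

    def u(key):
        lo, hi = r[key]
        return float(rng.uniform(lo, hi))

    tint = tuple(float(rng.uniform(*r["tint"])) for _ in range(3))
    return DomainStyle(gamma=u("gamma"), contrast=u("contrast"),
                       noise_sigma=u("noise_sigma"), blur_sigma=u("blur_sigma"),
                       bias_amplitude=u("bias_amplitude"), channel_tint=tint)


def apply_style(image: np.ndarray, style: DomainStyle,
                rng: np.random.Generator) -> np.ndarray:
    """Apply the appearance transform (image only; masks untouched)."""
    img = np.asarray(image, dtype=np.float64)
    color = img.ndim == 3
    if style.blur_sigma > 0:
        sig = (style.blur_sigma, style.blur_sigma, 0) if color else style.blur_sigma
        img = ndi.gaussian_filter(img, sig)
    img = np.clip(img, 0.0, 1.0) ** style.gamma
    img = 0.5 + style.contrast * (img - 0.5)
    if style.bias_amplitude > 0:
        h, w = img.shape[:2]
        yy, xx = np.mgrid[0:h, 0:w]
        cy, cx = rng.uniform(0.2, 0.8, 2)
        bias = np.cos(np.pi * (yy / h - cy)) * np.cos(np.pi * (xx / w - cx))
        bias = 1.0 + style.bias_amplitude * bias
        img = img * (bias[..., None] if color else bias)
    if color:
        img = img * np.asarray(style.channel_tint)
    if style.noise_sigma > 0:
        img = img + rng.normal(0.0, style.noise_sigma, img.shape)
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# anatomy generators
# ---------------------------------------------------------------------------

def _textured_background(size: int, rng, base, variation=0.05, color=True):
    shape = (size, size, 3) if color else (size, size)
    low = ndi.gaussian_filter(rng.normal(0, 1.0, (size, size)), size / 12)
    low = low / (np.abs(low).max() + 1e-9)
    fine = rng.normal(0, 0.015, (size, size))
    tex = variation * low + fine
    img = np.broadcast_to(np.asarray(base), shape).copy() if color else base + np.zeros(shape)
    return np.clip(img + tex[..., None] if color else img + tex, 0, 1)


def _vessel_curve(rng, size, center, n_pts=200):
    """Cubic-curve control points through the disc centre region."""
    t = np.linspace(0, 1, n_pts)
    p = [rng.uniform(0, size, 2) for _ in range(2)]
    mid = center + rng.normal(0, size * 0.08, 2)
    # quadratic Bezier through a disc-adjacent midpoint
    pts = ((1 - t)[:, None] ** 2 * p[0] + 2 * ((1 - t) * t)[:, None] * mid
           + (t ** 2)[:, None] * p[1])
    return np.clip(pts, 0, size - 1)


def generate_fundus_like(n: int, size: int, style: DomainStyle, seed: int,
                         domain_id: int = 0) -> list[SampleRecord]:
    """Nested disc/cup ellipses with vessels; style applied last."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if size < 32:
        raise ValueError("size must be >= 32 to hold the structures")
    records = []
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        img = _textured_background(size, rng, base=(0.55, 0.28, 0.18))
        mask = np.zeros((size, size), dtype=np.uint8)

        # disc ellipse: axis fractions keep the area fraction in ~[0.02, 0.2]
        a = rng.uniform(0.09, 0.22) * size
        b = a * rng.uniform(0.7, 1.3)
        b = min(b, 0.24 * size)
        ang = rng.uniform(0, np.pi)
        margin = max(a, b) + 2
        cy = rng.uniform(margin, size - margin)
        cx = rng.uniform(margin, size - margin)
        rr, cc = draw_ellipse(cy, cx, a, b, shape=(size, size), rotation=ang)
        mask[rr, cc] = 1
        disc_col = np.array([0.93, 0.82, 0.55]) + rng.normal(0, 0.02, 3)
        img[rr, cc] = np.clip(disc_col, 0, 1)

        # strictly nested cup: axes <= 0.6x disc, centre offset bounded
        ratio = rng.uniform(0.35, 0.6)
        ca, cb = a * ratio, b * ratio
        max_off = (1.0 - ratio) * min(a, b) * 0.5
        off = rng.uniform(-max_off, max_off, 2)
        rr2, cc2 = draw_ellipse(cy + off[0], cx + off[1], ca, cb,
                                shape=(size, size), rotation=ang)
        inside = mask[rr2, cc2] == 1          # enforce cup ⊆ disc exactly
        rr2, cc2 = rr2[inside], cc2[inside]
        mask[rr2, cc2] = 2
        cup_col = np.clip(disc_col + np.array([0.05, 0.08, 0.12]), 0, 1)
        img[rr2, cc2] = cup_col

        # vessels: dark curvilinear texture crossing the disc
        vessel = np.zeros((size, size), dtype=bool)
        for _ in range(rng.integers(2, 6)):
            pts = _vessel_curve(rng, size, np.array([cy, cx]))
            ij = np.round(pts).astype(int)
            vessel[ij[:, 0], ij[:, 1]] = True
        vessel = ndi.binary_dilation(vessel, iterations=1)
        img[vessel] = img[vessel] * 0.45

        srng = np.random.default_rng([seed, i, 7])
        img = apply_style(img, style, srng)
        records.append(SampleRecord(img.astype(np.float32), mask, domain_id, i, seed))
    return records


def generate_prostate_like(n: int, size: int, style: DomainStyle, seed: int,
                           domain_id: int = 0) -> list[SampleRecord]:
    """Smooth bright star-convex blob on a speckled background."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if size < 32:
        raise ValueError("size must be >= 32 to hold the structures")
    records = []
    theta = np.linspace(0, 2 * np.pi, 256, endpoint=False)
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        img = np.clip(0.25 + 0.05 * rng.normal(size=(size, size))
                      + 0.08 * ndi.gaussian_filter(rng.normal(size=(size, size)), size / 10),
                      0, 1)
        # multiplicative speckle
        img = np.clip(img * (1.0 + 0.15 * rng.normal(size=(size, size))), 0, 1)

        r0 = rng.uniform(0.15, 0.27) * size
        radius = np.full_like(theta, r0)
        for k in range(2, 6):
            amp = rng.uniform(0, 0.08) * r0
            radius += amp * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
        radius = np.clip(radius, 0.3 * r0, 0.45 * size)
        margin = radius.max() + 2
        cy = rng.uniform(margin, size - margin)
        cx = rng.uniform(margin, size - margin)
        rr, cc = draw_polygon(cy + radius * np.sin(theta),
                              cx + radius * np.cos(theta), shape=(size, size))
        mask = np.zeros((size, size), dtype=np.uint8)
        mask[rr, cc] = 1
        bright = 0.75 + 0.05 * rng.normal(size=(size, size))
        img[mask == 1] = np.clip(bright, 0, 1)[mask == 1]
        img = ndi.gaussian_filter(img, 0.8)

        srng = np.random.default_rng([seed, i, 7])
        img = apply_style(img, style, srng)
        records.append(SampleRecord(img.astype(np.float32), mask, domain_id, i, seed))
    return records


# ---------------------------------------------------------------------------
# suites
# ---------------------------------------------------------------------------

def make_domain_suite(task: str = "fundus", n_domains: int = 3,
                      n_per_domain: int = 48, size: int = 96,
                      seed: int = 0) -> DomainSuite:
    """Draw one style per domain from its disjoint range and render samples.

    All randomness flows from ``seed`` through per-domain and per-sample
    child generators; the same call is bitwise reproducible.
    """
    if n_domains < 2:
        raise ValueError("need at least 2 domains for cross-domain work")
    if task not in ("fundus", "prostate"):
        raise ValueError("task must be 'fundus' or 'prostate'")
    gen = generate_fundus_like if task == "fundus" else generate_prostate_like
    styles, domains, rows = [], [], []
    for d in range(n_domains):
        style = sample_style(task, d, np.random.default_rng([seed, d, 11]))
        styles.append(style)
        recs = gen(n_per_domain, size, style, seed=seed * 100 + d, domain_id=d)
        domains.append(recs)
        for r in recs:
            rows.append({"path": f"domain{d}/images/{r.sample_id:04d}.png",
                         "mask_path": f"domain{d}/masks/{r.sample_id:04d}.png",
                         "domain": d, "split": "all", "seed": r.seed})
    manifest = pd.DataFrame(rows)
    return DomainSuite(task, styles, domains, manifest, seed)


def write_suite(suite: DomainSuite, root) -> Path:
    """Materialise a suite as 8/16-bit PNGs plus a CSV manifest."""
    import imageio.v3 as iio
    root = Path(root)
    for d, recs in enumerate(suite.domains):
        (root / f"domain{d}" / "images").mkdir(parents=True, exist_ok=True)
        (root / f"domain{d}" / "masks").mkdir(parents=True, exist_ok=True)
        for r in recs:
            img8 = np.round(np.clip(r.image, 0, 1) * 255).astype(np.uint8)
            iio.imwrite(root / f"domain{d}" / "images" / f"{r.sample_id:04d}.png", img8)
            iio.imwrite(root / f"domain{d}" / "masks" / f"{r.sample_id:04d}.png", r.mask)
    suite.manifest.to_csv(root / "manifest.csv", index=False)
    return root


def load_suite(root) -> DomainSuite:
    import imageio.v3 as iio
    root = Path(root)
    manifest = pd.read_csv(root / "manifest.csv")
    n_domains = int(manifest["domain"].max()) + 1
    domains = []
    for d in range(n_domains):
        rows = manifest[manifest["domain"] == d]
        recs = []
        for _, row in rows.iterrows():
            img = iio.imread(root / row["path"]).astype(np.float32) / 255.0
            mask = iio.imread(root / row["mask_path"]).astype(np.uint8)
            sid = int(Path(row["path"]).stem)
            recs.append(SampleRecord(img, mask, d, sid, int(row["seed"])))
        domains.append(recs)
    task = "fundus" if domains[0][0].image.ndim == 3 else "prostate"
    return DomainSuite(task, [], domains, manifest, int(manifest["seed"].iloc[0]))
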