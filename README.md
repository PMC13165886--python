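# structseg

Fine-grained structural enhancement for **single-source domain
generalization (SDG)** in medical image segmentation, at desk scale.

Segmentation models trained on one hospital's images degrade on scanners
and protocols they never saw. This package implements a structural
adaptation stack designed to make a segmenter's *fine-grained* anatomy
cues — edges, contours, small structures, which are far more stable across
domains than intensity statistics — explicit and reusable:

* a **low-rank structural dictionary**: learnable tokens `T = A·B ∈ R^{M×C}`
  (rank `r ≪ C`) queried by softmax-normalised similarity
  `softmax(F·Tᵀ/√C)`; a dedicated *silent token* absorbs the probability
  mass of ambiguous regions so they bypass enhancement,
* shallow→deep **structural shortcuts** with channel attention
  `σ(GAP+GMP)` and residual bottleneck adapters,
* dictionary-guided **dense prompt synthesis** with learnable **Top-λ**
  token selection and an entropy-based match confidence,
* **prompt gating**: a scalar confidence `c` softly fuses prompt and image
  embeddings, `src = c·prompt + (1−c)·image`, with no hard threshold,
* **SCFD** — structural-continuity diffusion in the frequency domain: one
  step of heat-equation smoothing `IDCT2(DCT2(src) ⊙ exp(−(K/τ)Λ))` in the
  DCT eigenbasis of the Neumann Laplacian, with learned per-frequency
  coefficients `K = Softplus(Φ(FVE)) ⊙ G`, an edge-protecting boundary gate
  `G`, a global temperature `τ` and a zero-initialised residual gain `γ`,
* training with the combined objective `L = (1−β)·L_CE + β·L_Dice`, β = 0.8.

Everything is wired into a **miniature trainable segmenter** (a small
vision transformer stands in for a foundation-model encoder), a
**synthetic multi-domain generator** (fundus-like disc/cup and
prostate-like blob tasks whose "domains" differ only in style), and a
**leave-one-out cross-domain evaluation harness** — so the full method is
exercisable end-to-end on one CPU with no downloads or pretrained weights.
The trainable stack runs on a small reverse-mode autodiff engine included
in the package; all residual insertions are exactly zero at initialisation,
so every module toggle is behaviour-preserving on a fresh model and
ablations start from a common baseline bitwise.

Intended audience: researchers studying SDG segmentation mechanics
(dictionary retrieval, prompt gating, frequency-domain smoothing) who want
a tested, inspectable, CPU-scale implementation rather than a GPU
benchmark harness.

## Worked example

```python
import numpy as np
from structseg import MiniSegmenter, make_domain_suite
from structseg.evaluation import evaluate_domain

# 3 synthetic fundus-like domains, 48 images each, differing only in style
suite = make_domain_suite("fundus", n_domains=3, n_per_domain=48,
                          size=96, seed=0)
X0, y0 = suite.arrays(0)              # single source domain

model = MiniSegmenter(max_epochs=30, seed=0)   # all modules on
model.fit(X0, y0)

for target in (1, 2):
    Xt, yt = suite.arrays(target)
    print(target, evaluate_domain(model, Xt, yt, "fundus"))
```

Output on this configuration:

```
1 {'disc': 0.7371224888163912, 'cup': 0.11822646216313772}
2 {'disc': 0.8246196271129563, 'cup': 0.121497031624841}
```

i.e. the model trained *only* on domain 0 segments the optic disc of the
two unseen-style domains with Dice ≈ 0.74 and 0.82 (disc = the union
region of disc+cup labels, the clinical convention; the small low-contrast
cup is much harder at this scale). The same run with all three modules
toggled off (`fine_grained=False, prompt_confidence=False, scfd=False`)
reaches 0.49 / 0.83 — the structural stack mainly buys robustness on the
harder style shift. `model.confidence_scores(Xt)` exposes the per-image
prompt-gate confidence, and `structseg.evaluation.leave_one_out` runs the
full every-domain-as-source protocol.

A thin CLI mirrors the library:

```bash
structseg generate --task fundus --domains 3 --n 48 --size 96 --seed 0 --out data/
structseg train   --data data/ --source-domain 0 --out run/
structseg predict --ckpt run/model.npz --image data/domain1/images/0000.png --out mask.png
structseg smooth  --image noisy.png --out smooth.png --kappa 0.8 --tau 1.0
structseg eval    --ckpt run/model.npz --data data/ --out metrics.json
structseg ablate  --data data/ --out ablation.csv
```

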