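# splitthz

Privacy-preserving split learning for pixel-wise tissue classification of
terahertz-style hyperspectral images.

## The problem

Terahertz (THz) reflectance imaging of freshly excised breast-conserving-surgery
specimens can distinguish cancerous from healthy tissue non-invasively: each
pixel carries a reflectance spectrum across tens of bands, and cancer, muscle
and fat have systematically different spectral signatures.  Two practical
obstacles shape the method implemented here.  First, training references are
often formalin-fixed (FFPE) tissue whose dehydrated spectra differ
systematically from fresh tissue, so part of the nominal training data is
unreliable.  Second, patient imagery cannot always be pooled centrally, so the
classifier is trained with a *split learning* protocol in which raw spectra
never leave the client.

`splitthz` is aimed at methods researchers in biomedical image analysis who
want a complete, testable reference implementation of this pipeline.  Because
no public THz tissue cubes are deposited, the package ships a first-class
synthetic phantom generator that emulates the relevant structure of such data.

## The method

The pipeline runs six stages:

1. **Phantom generation** — labeled H×W×B cubes with contiguous cancer /
   muscle / fat regions; class-conditional spectra are isotropic Gaussians in
   band space, and an FFPE-style corruption process adds a constant spectral
   shift to a chosen fraction of labeled pixels.
2. **Preprocessing** — Nyquist guard `T_s ≤ 1/(2 f_max)` for the sampling
   stage, per-band min–max normalization `x_norm = (x − min)/(max − min)`, and
   low-pass FIR smoothing of each pixel spectrum (3-tap binomial kernel by
   default).
3. **PCA features** — `Z = (X − x̄) W`, with `W` the eigenvectors of the sample
   covariance; the classifier and the screening t-test operate on the first
   few components.
4. **EM reliability selection** — per class, a two-component isotropic
   Gaussian mixture separates reliable from corrupted pixels; a pixel's
   reliability score is the posterior responsibility of the majority
   component, and only pixels with score > τ (default 0.8) are used for
   training.
5. **Split training** — a client feature map `F_c(X; θ_c)` (single linear
   layer) sends representations `X^t` to a server head `F_s(X^t; θ_s)`, a
   Bayesian **ordinal probit**: latent `u = βᵀz + ε`, `ε ~ N(0,1)`, cut by
   ordered cutpoints `γ₁ < γ₂` into fat < muscle < cancer, so
   `P(y = c) = Φ(γ_c − βᵀz) − Φ(γ_{c−1} − βᵀz)`.  Both halves take gradient
   steps `θ ← θ − α ∇_θ L` on the ordinal-probit negative log-likelihood; the
   server returns only `∂L/∂X^t`, never raw data, and the recorded transcript
   can be audited for leaks.  The head is deliberately tiny: `d + C − 1`
   parameters (5 for three classes on three components).  A Gibbs sampler
   (truncated-normal data augmentation) provides the full posterior when
   wanted.
6. **Evaluation** — pooled two-sample t-test on PC1 (cancer vs non-cancer
   pixels), one-vs-rest ROC/AUC per tissue region with the operating threshold
   maximizing Youden's J, per-class accuracy / precision / recall / F1 from
   the confusion counts µ (TP), µ₁ (TN), Γ (FP), Γ₁ (FN), and learning
   curves.

## Worked example

```bash
splitthz run --out demo/
```

runs the whole pipeline on the stock phantom (64×64×16 cube, adjacent class
means 5 noise-SDs apart, 10% corrupted training pixels, seed 7) and prints the
evaluation report.  Key numbers from that run:

```
overall_accuracy   0.905
region_auc         cancer 0.966   fat 0.966   muscle 0.895
pc1_ttest          t = 21.56, df = 314, log10(p) = -63.2
privacy            300 rounds, 0 violations
```

Reading: on held-out pixels the classifier separates each tissue region from
the rest with AUC 0.90–0.97 (muscle, squeezed between fat and cancer on the
latent axis, is hardest — consistent with it being the hardest region for
this family of classifiers); the first principal component separates
cancerous from non-cancerous pixels overwhelmingly (t = 21.6 on 314 degrees
of freedom); and no payload crossing the client/server boundary contained a
raw spectrum.  The same artifacts (models, session transcript, report,
manifest with checksums) are written under `demo/`.

Python API equivalent:

```python
from splitthz import PipelineConfig, run_pipeline
report = run_pipeline(PipelineConfig(), "demo/")
print(report.region_auc["cancer"])
```

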