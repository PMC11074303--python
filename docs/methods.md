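# Methods

This note records the models, parameter choices and numerical conventions
behind `splitthz`, and what the synthetic phantoms do and do not establish
about real terahertz tissue data.

## Phantom model

Each phantom is an H×W×B reflectance cube with a label map over
{background, fat, muscle, cancer} (codes 0–3).  Regions are axis-aligned
rectangles and discs, chosen because exact pixel membership is computable in
tests; regions must be disjoint and every non-background pixel carries exactly
one label.  Conditional on its class, a pixel's spectrum is an isotropic
Gaussian in band space: mean `m_c`, covariance `σ_c² I`.  This is the simplest
model under which pixel-wise (texture-free) classification, PCA, the ordinal
probit head and the EM reliability filter are all exercised with known ground
truth.

Default spectra share a smooth base profile and differ by offsets along a
fixed unit direction `u` (a half-sine across bands), with adjacent classes
(fat→muscle, muscle→cancer) separated by `separation × noise_sd` in Euclidean
band distance — 5 noise SDs by default.  Two deliberate consequences:

* the class means are **collinear**, ordered fat < muscle < cancer along `u`.
  This monotone one-dimensional contrast is the regime in which a
  single-index ordinal model is the right classifier, loosely mirroring the
  monotone water-content contrast THz imaging exploits;
* the `separation` parameter is a clean separability dial: the
  Bayes-optimal linear score's AUC grows monotonically with it (tested).

Corruption emulates the fresh-vs-FFPE mismatch as a constant additive
spectral shift (default 5 noise SDs along `u`) applied to exactly
`round(fraction · n_labeled)` labeled pixels; labels are untouched and the
affected pixels are flagged.  Repeated corruption passes draw from
not-yet-flagged pixels, so fractions compose additively.  A constant shift is
detectable by a two-component mixture, which is precisely the capability the
reliability stage is meant to have; FFPE chemistry is not modeled.

What the phantom does **not** emulate: spatial correlation of noise, band-wise
heteroscedasticity, instrument point-spread, partial-volume mixtures at region
boundaries, or any physical wave propagation.  Tests passing on phantoms
establish correctness of the algorithms under their stated assumptions, not
clinical performance on real tissue.

## Preprocessing

* Nyquist guard: `T_s ≤ 1/(2 f_max)`, checked, with equality passing.
* Decimation keeps every k-th sample from index 0 and scales the sampling
  interval; no anti-alias pre-filter beyond the guard.
* Min–max normalization is per feature column; constant columns are an error
  (the map is undefined there), never silently coerced to 0.  Parameters are
  fitted on the training split only and applied to validation data to avoid
  leakage.
* The low-pass stage is a discrete FIR convolution (the discrete analogue of
  a continuous smoothing integral): centre tap at index `len(taps)//2`,
  same-length output, edge-replication padding so normalized kernels leave
  constant spectra untouched end to end (zero padding would create artificial
  dips at spectrum ends).  Default kernel: 3-tap binomial [0.25, 0.5, 0.25].
  High-pass filtering is out of scope.

## PCA

Covariance uses the unbiased 1/(n−1) estimator; eigenpairs come from a dense
symmetric eigendecomposition.  Determinism conventions: eigenvalues sorted
nonincreasing (stable sort for ties), each loading column's sign fixed so its
largest-magnitude entry is positive.  When a retained-variance fraction is
given (default 0.95 when nothing is specified; the pipeline default is k=3),
k is the smallest count whose eigenvalue mass reaches the fraction;
`fraction=1.0` keeps the numerical rank.  The model stores the total variance
so reconstruction error is exactly accountable: the training-data sum of
squared residuals equals (n−1) × (discarded eigenvalue mass).

## EM reliability filtering

The filter operationalizes "reliability" as a posterior responsibility.  Per
class, a two-component isotropic Gaussian mixture is fitted in PCA space by
EM.  Initialization is deterministic: the reliable component starts at the
class median, the unreliable one at the point farthest from it, mixing weight
0.8/0.2 — biased toward the majority being reliable.  A variance floor of
1e-6 × (class total variance) guards against component collapse; in practice,
on homogeneous (uncorrupted) classes the minority component does collapse
onto the farthest outlier at the floor, which is harmless: responsibilities
of typical points remain near 1 and under 5% of clean pixels are lost at the
default threshold.  After fitting, the component with the larger mixing
weight is designated reliable.  Selection keeps rows with score > τ; τ = 0.8
by default and exposed in config.  EM is run per class (not globally) so a
shifted cluster in one class cannot masquerade as another class's reliable
mode.  The EM log-likelihood trace is recorded and is nondecreasing (tested
across seeds).

## Ordinal probit head

`P(y=c|z) = Φ(γ_c − βᵀz) − Φ(γ_{c−1} − βᵀz)` with latent scale fixed at 1
(probit identification) and class order fixed fat < muscle < cancer, exposed
in config.  The "multinomial vs ordinal" choice is resolved as ordinal — a
single β and shared cutpoints — which minimizes parameters (d + C − 1; 5 for
the default configuration) and matches the collinear class geometry; an
unordered per-class-weights head is a non-goal.  Per-observation likelihoods
are floored at 1e-300 with a warning under extreme linear predictors.

MAP fitting is plain gradient descent on NLL + ‖β‖²/(2·10²) (flat prior on
ordered cutpoints), initialized at β = 0 with cutpoints at normal quantiles
of the empirical class frequencies — a standard self-scaling start that
converges faster than fixed constants.  If a raw step crosses the cutpoints,
they are re-sorted with a minimum gap of 1e-6; with the step sizes used in
practice this projection never triggers.  Divergence (loss > 1e10) raises an
error suggesting a smaller learning rate.

The Gibbs sampler uses truncated-normal data augmentation: latents drawn in
their class interval, β from its conjugate normal conditional under the
N(0, 10² I) prior, and each cutpoint uniform between the adjacent classes'
latent order statistics (hence every class must be present).  Draws are
returned after burn-in; seeded, hence reproducible.

## Split learning protocol

The client half is a single linear layer (optional tanh), initialized from a
seeded N(0, 0.01); the server head starts at β = 0 with cutpoints ±0.5.  One
round: client sends representations `X^t` and labels (label-sharing variant —
the confidentiality claim audited is for raw spectra, which never cross);
server computes the NLL loss, steps `θ_s ← θ_s − α∇`, and returns `∂L/∂X^t`;
the client pulls that back through its layer and steps `θ_c`.  Both gradients
come from the same forward pass, so a round is exactly one simultaneous joint
gradient-descent step on the composed model — the split/centralized
equivalence that the tests verify to 1e-9 per round (it is exact in floating
point, since both paths execute the same operations).  The split loss carries
no prior term; the Gaussian prior is a feature of the centralized MAP fitter
only, keeping the equivalence oracle exact.

Multi-client mode is sequential round-robin with θ_c hand-off over a disjoint
(by default IID random) row partition.  Convergence: relative change of the
full-data loss below `tol` (default 1e-6), max 500 rounds.

The transcript records every boundary payload (representations, labels,
representation gradients, loss scalars).  The audit checks each payload wide
enough to hold a raw row for exact bitwise equality with any raw feature row,
including as a contiguous horizontal sub-block, and reports payload counts
and byte volumes per round.

## Evaluation

* t-test: pooled (Student) rather than Welch — the single df = n₁+n₂−2
  convention; "equal means" null, two-sided p, 95% CI for the mean
  difference; log10(p) computed from the log survival function so extreme
  significance is reported without underflow.  Zero pooled variance with
  equal means yields t=0, p=1; with unequal means it is an error.
* AUC: rank-based Mann–Whitney with tie half-credit, computed one-vs-rest per
  tissue region from the class probabilities; undefined with one class
  absent.
* Operating thresholds maximize Youden's J, ties broken toward higher
  sensitivity (missing cancer is the costlier error).
* Per-class metrics from one-vs-rest confusion counts µ/µ₁/Γ/Γ₁; undefined
  ratios surface as NaN with a warning, never as silent zeros.
* Learning curves aggregate the round log per epoch, report the epoch of
  highest validation accuracy and flag a plateau when the monitored metric
  improves by ≤ 1e-4 over the last 10 epochs.

## Pipeline defaults and problem sizes

The stock run uses a 64×64×16 phantom (≈1050 labeled pixels), 5-SD class
separation, 10% corruption, 70/30 train/validation split, k=3 components,
τ=0.8, identity client activation with d_out=3, learning rate 2e-3, up to
300 rounds.  The protocol-level experiments in `scripts/acceptance.py` use a
200-pixel task (preprocessed the same way) with learning rate 5e-3, and the
estimator-recovery experiment uses n=2000 pixels from known parameters
(β = (1.5, −0.7), γ = (−0.5, 0.8)), 800 Gibbs draws with 300 burn-in.  These
sizes were chosen so every experiment runs comfortably on a laptop core in
seconds while keeping Monte-Carlo noise well inside the tolerances tested.

Seed discipline: a single global seed drives each stage through a fixed
counter scheme, so stages are individually reproducible and a rerun of the
same config writes byte-identical reports.

## Known limitations

* The ordinal head assumes classes are ordered along one latent axis; with
  non-collinear class geometry a multinomial head would be needed.
* The EM filter models corruption as a single displaced Gaussian component
  per class; diffuse or multimodal corruption would dilute responsibilities.
* The privacy audit certifies only that raw rows never cross the boundary
  verbatim; it makes no claim about reconstruction attacks on
  representations or gradients (out of scope, as are transport security and
  differential privacy).
* Muscle, the middle ordinal class, is consistently the hardest region —
  its probability mass is squeezed between two cutpoints.
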