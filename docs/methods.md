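# Methods

`taskmo` implements binary signal-detection studies on CT-like images with
four families of model observers — the Hotelling observer (HO), supervised
networks (CNN, SLNN), and a self-supervised two-stage observer (CDAE
features + RBF-SVM) with a PCA baseline — together with the synthetic task
generator and the ROC/AUC evaluation protocol that tie them into
comparable experiments.  This note records the models, the defaults and
why they hold, and the design choices made where the design was genuinely
open.

## The detection task

All tasks are background-known-statistically (BKS): each image is a random
background realization, and signal-present images add a deterministic (SKE)
or orientation-randomized (SKS) signal profile.

**Signals.** The SKE signal is the nodule profile
`A_s (1 − d²/R²)^z` for pixel distance `d ≤ R` and exactly zero outside,
with radius `R` in millimetres converted through the grid's pixel spacing
(default 0.7 mm/pixel, so `R = 4 mm ≈ 5.7 px`); `z = 4` by default.
The SKS signal is a rotated anisotropic Gaussian
`A_s exp(−(R_Φ u)ᵀ D⁻¹ (R_Φ u))` with `D = diag(σ_x², σ_y²)` — the
σ² (covariance-like) convention, with no ½ in the exponent — widths in
pixels (defaults 5 and 1.5), and the orientation Φ drawn per
signal-present image uniformly from {0°, 45°, 90°, 135°}.

**Backgrounds.** Stationary Gaussian random fields synthesized by FFT
spectral filtering on the torus: white noise is filtered by `sqrt(S(f))`
where the target power spectrum is

    S(f) ∝ (1 − φ) · f^α · exp(−f²/f_c²) |_normalized  +  φ,

a radially symmetric structured component plus a white spectral floor of
variance fraction `φ` emulating detector/quantum noise.  The construction
makes the pixel covariance exactly block-circulant with eigenvalue map
`S`, so the Hotelling oracle (`K⁻¹s` via FFT division) and the closed-form
detectability `SNR = √(sᵀK⁻¹s)`, `AUC = Φ(SNR/√2)` are available without
any matrix inversion.  Different `(α, f_c, φ)` triples emulate the noise
textures of different reconstruction regularizations.  An optional lumpy
kind (Poisson count of Gaussian blobs, wrapped on the torus for
stationarity) provides a non-Gaussian texture with no closed-form
covariance.

**Normalization.** Images are generated in HU and mapped to [0, 1] by the
fixed affine window [−1000, 500] HU, clipped; the window is recorded in
the dataset provenance and the mapping is invertible away from the clip
boundary.  Networks and the SVM consume the normalized scale; linear
observers are scale-invariant in AUC.

**Pairing.** By default, signal-present images share the background
realization of their signal-absent sibling ("paired" insertion), which
makes the additive construction exactly verifiable (present minus paired
absent recovers the profile to float precision).  Pairing has two protocol
consequences that are easy to miss.  First, if the two members of a pair
land on opposite sides of a train/test or cross-validation boundary, a
memorizing classifier (notably the RBF-SVM) scores the held-out sibling by
its background similarity and produces systematically anti-correlated
scores; all splits and the SVM cross-validation therefore allocate whole
pairs to one side (`pair_ids` on the dataset; grouped folds in the grid
search).  Second — and more fundamentally — on paired data the
class-mean difference equals the signal profile with *zero* noise, so any
learner that can exploit the empirical mean difference recovers the exact
template from a handful of pairs; measured here, a CNN reached
oracle-level AUC from 200 paired images but only ≈ 0.70 from 200
independent ones.  Real acquisitions are independent, so every learning
experiment in this package trains on unpaired ensembles
(`build_detection_dataset(..., paired=False)`); the paired mode is for
generator verification and variance-reduced evaluation.

**Default difficulty calibration.** The default 64×64 SKE task uses signal
amplitude −60 HU on backgrounds with mean −850 HU and noise SD 56 HU
under a flat spectrum with Gaussian cutoff (α = 0, f_c = 0.35).
The amplitude is deliberately far below the −870 HU of a ground-glass
opacity against air: with the fixed [−1000, 500] window, adding −870 HU to
a −850 HU lung background would saturate the window (every signal pixel
clipped to the lower bound), making detection a trivial nonlinear artifact
of the normalization rather than a statistical task.  The −60 HU default
is instead a faint contrast calibrated analytically (via the spectral
detectability oracle, before any classifier was run) so the
known-covariance HO lands mid-difficulty, AUC ≈ 0.9; the noise SD is the
matching knob for other amplitudes.

## Hotelling observer

`w = (½(K₀+K₁) + λ_r I)⁻¹ Δf̄`, applied as `t = wᵀf`.  The sample form
estimates per-class means and covariances (unbiased, explicitly
symmetrized) and inverts by Cholesky with ridge `λ_r`; the default
`λ_r = 10⁻³·tr(K)/M` reflects that an unregularized estimate would need on
the order of `10·M²` images (M = 4096 on the default grid), far beyond any
ensemble used here.  The known-covariance form exploits the circulant
structure: `K⁻¹s = ifft2(fft2(s)/S)`, exact and O(M log M).  Oracle
validation runs on reduced grids (8×8, 16×16) where the dense covariance
is cheap enough to cross-check the spectral route entry-wise.

## Supervised observers

The CNN stacks `depth` (2–10) size-preserving 3×3 convolutions with
`filters` ∈ {4, 8, 16} channels and LeakyReLU (slope 0.01), no
downscaling anywhere (so no high-frequency content is discarded), ending
in one fully connected sigmoid unit read as the posterior probability of
signal presence.  The SLNN is a single fully connected sigmoid unit over
the vectorized image; its pre-activation weights form an implied linear
template exportable for comparison with the HO.  Training uses Adam
(lr 10⁻³, β = 0.9/0.999), batch size 64, binary cross-entropy, 50 epochs
by default, under a train–validation–test protocol with disjointness
enforced by content hashing.  Batch size, learning rate, slope, and the
uniform fan-in weight initialization are unstated in the source protocol
and are exposed as explicit configuration.  The structure search trains
every (depth, filters) pair `repeats` times and selects the minimum mean
validation cross-entropy.

The networks run on a small numpy layer engine written for this package
(`taskmo.nn`): NHWC layout, convolutions as shifted channel-mixing BLAS
products (with im2col fast paths for single-channel ends), manual
backpropagation verified against float64 loop references and numerical
differentiation, float32 arithmetic throughout, and all randomness through
explicit generators so training is bit-reproducible for a fixed seed and
thread configuration.

## Self-supervised observer

**Pretext.** The convolutional denoising autoencoder corrupts inputs by
independently zeroing each pixel with probability `corruption_rate`,
encodes through `depth` (1–8) conv layers (3×3, LeakyReLU, zero padding)
and a fully connected bottleneck of `latent_units` (2–32), decodes through
the mirror structure, and ends in a sigmoid so reconstructions live on
[0, 1] like the inputs.  The loss is the pixelwise cross-entropy between
the clean image and the reconstruction of its corrupted version — summed
over pixels, averaged over the batch — plus the weight-decay penalty
`λ‖W‖²` over all weight matrices (biases excluded).  The pixel-sum
reduction matters: it keeps the classical λ range [0, 0.1] meaningful
against a whole-image reconstruction term; with a pixel-mean reduction the
penalty would dominate by three orders of magnitude and silently collapse
the encoder.  Early stopping monitors the reconstruction loss of a fixed
corrupted validation set (fixed mask, so the criterion is comparable
across epochs); defaults: patience 5, max 200 epochs.  Labels are never
an argument of the pretext trainer.

The default corruption rate is 0.05.  On this data the window maps lung
backgrounds to ≈ 0.1, so zeroing a pixel is a perturbation of ≈ 3.6
standard deviations of the intrinsic noise; at the textbook masking rate
of 0.2 the corruption variance is about three times the task noise
variance and the denoising objective drowns the faint task-relevant
structure.  Rate 0.05 keeps the corruption variance at the scale of the
intrinsic noise while preserving the denoising pretext.

**Unlabeled pool.** The defining economy of the self-supervised observer
is that the pretext consumes no annotation, so the encoder is trained on
an unlabeled image pool that is larger than — and disjoint from — the
labeled set that the SVM stage uses (`pretext_images` argument).  This
mirrors the intended use on clinical archives, where unlabeled images are
abundant and labels are the scarce resource.  The labeled-set size quoted
in the experiments below refers to the SVM stage.

**Downstream.** Latent features (encoded without corruption) are
standardized per dimension and classified by an RBF-SVM,
`k(x, y) = exp(−‖x−y‖²/(2σ²))` — the width convention under which the
selected σ values are directly interpretable — with C and σ selected by
5-fold cross-validated AUC over log-spaced grids
(C ∈ 10⁻¹…10⁷, σ ∈ 10⁻²…10²), folds grouped by background pair, ties
broken toward the smallest C then the smallest σ (small C means fewer
support vectors and cheaper deployment).  The shipped default architecture
is 1 conv layer, 16 filters, 25 latent units, λ = 10⁻³.

**PCA baseline.** A mean-centered PCA with the same latent dimension
replaces the encoder — the subspace an optimal linear one-layer
autoencoder under squared error converges to, which the test suite
verifies directly by principal angles.

**Architecture search.** `cdae_bayesian_search` performs sequential
model-based optimization over (depth, filters, latent units): a Matérn-5/2
Gaussian process on normalized integer coordinates, expected-improvement
acquisition over the enumerated space, resampled train/validation split
per trial, objective = validation reconstruction loss.  The pretext loss
is optimized rather than downstream AUC because the search must remain
label-free; an AUC objective is available as an explicit option for users
who can afford labels at search time.

## Evaluation

AUC is the Mann–Whitney statistic (ties ½), which equals the trapezoidal
area under the empirical ROC staircase exactly; the suite checks both the
equivalence and brute-force pair counting.  Confidence intervals are
stratified bootstrap percentiles (1000 resamples, 95%).  Splits are
class-stratified, pair-respecting, and disjoint; learning-curve
experiments draw a fresh training subset per (observer, size, repeat),
evaluate on one fixed shared test set, and report the known-covariance HO
as a constant reference line.  Fitting times are logged but never
asserted — wall-clock comparisons are hardware statements, not scientific
ones.

## What the synthetic generator does and does not emulate

The generator reproduces the second-order statistics that drive linear
detectability — controllable correlation structure, stationarity, additive
signal insertion, bounded normalized intensities — and provides exact
oracles for validation.  It does not emulate anatomical structure (vessels,
airways), reconstruction nonlinearity, non-stationary noise, or the
spatial inhomogeneity of real lung texture.  Consequently, passing tests
demonstrate correctness of the observers and protocol and qualitative
reproduction of the method-comparison phenomenology (oracle agreement,
sample-HO convergence, the small-label advantage of the self-supervised
observer, CNN depth overfitting); they do not certify performance numbers
on phantom or patient data.

One structural property deserves emphasis: for stationary Gaussian
backgrounds the Hotelling template concentrates where the
signal-to-noise-spectrum ratio `|ŝ(f)|²/S(f)` is large, which for steep
(very "red") spectra is a mid-frequency band spread over hundreds of
Fourier modes.  A reconstruction-trained bottleneck of 25 units
preferentially spans the top-variance modes and can then not represent the
HO statistic, whatever the training budget — a ceiling one can compute
exactly here by restricting the HO to the top mixture-covariance
eigenmodes.  The default task's flat-spectrum-with-cutoff background is
chosen so this ceiling is negligible (the discriminative direction is
essentially the signal itself and enters the top modes through the class
mixture), which is the regime the structured-texture phantom studies
operate in and the regime where a self-supervised observer can
meaningfully approach the HO.

## Problem sizes used in the shipped experiments

Acceptance-level experiments run at sizes chosen for desk-scale
reproduction: oracle checks on 16×16 grids with 2000 test pairs; sample-HO
convergence on 8×8 with training sizes 200–20000; the observer comparison
on the default 64×64 task with a 7000-image unlabeled (unpaired) pretext
pool, 1000 labeled pairs for the SVM stage (200 images for the
small-label comparison against a 50-epoch CNN), and a 400-pair test set;
the depth-overfitting comparison with 300 training pairs, 4 filters, and
a 12-epoch schedule.  These sizes are the package's own reproduction
conditions; the pretext schedule in particular (24 epochs, learning rate
3×10⁻³, batch 64) was chosen as the point where the latent-space class
separation plateaus on the default task, and one pretext encoder is
shared across the labeled-stage seeds — the same economy the method
offers in practice, where the encoder is trained once on an archive.

## Known limitations

- The numpy engine is CPU-bound and single-threaded through BLAS; wall
  times scale accordingly, and the shipped experiment sizes reflect that.
- The lumpy background kind has no analytic covariance, so oracle-based
  tests are restricted to the Gaussian kinds.
- Clipping at the normalization window edge slightly truncates the lowest
  intensities of signal-present images on the default task (≈ 5% of the
  darkest pixel's distribution, negligible elsewhere); empirical
  comparisons use the same normalized data for all observers, so no
  observer is privileged.
- Bootstrap CIs treat test images as exchangeable; with paired test sets
  the absent/present resamples are drawn independently per class, which is
  slightly conservative.
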