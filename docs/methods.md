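# Methods

This note documents the models implemented in `iqtask`, the numerical
choices behind them, and what the package's simulations do and do not
establish.

## Scientific setting

Single-image super-resolution (SR) networks are usually scored with
full-reference image-quality (IQ) metrics — ensemble MSE, PSNR, SSIM. For
medical images the quantity that matters is *task performance*: how well an
observer (human, linear, or learned) can perform a diagnostic decision on
the processed images. `iqtask` implements a fully simulated test bed for
this question: binary signal-detection tasks on random mammography-like
backgrounds, a configurable degradation/noise model producing low-resolution
(LR) measurements, a small trainable SR network, and a suite of numerical
observers whose ROC performance quantifies the task-relevant information in
high-resolution (HR), LR, and super-resolved (SR) images.

Because SR is a deterministic post-processing of the LR data, the
data-processing inequality applies: an ideal observer cannot do better on
SR images than on the LR images they came from. Any apparent benefit of SR
must therefore come from *suboptimal* observers — limited capacity, limited
training data — and that is exactly what the package's experiment drivers
probe.

## Object models

### Clustered lumpy background (CLB)

Backgrounds are clustered lumpy textures,

    fb(r) = A · Σ_k Σ_n l(r − r_k − r_kn, R_θkn),
    l(r, R_θ) = exp(−α ‖R_θ r‖^β / L(R_θ r)),

with K ~ Poisson(K̄) clusters, N_k ~ Poisson(N̄) blobs per cluster, cluster
centres uniform over the field, blob offsets Gaussian with spread σ, and
per-blob orientations uniform on [0, 2π). L(u) is the radius of the
(Lx, Ly) ellipse along the direction of u,
L = Lx·Ly / sqrt((Ly cos φ)² + (Lx sin φ)²), so β exponentiates the norm and
the ellipse radius rescales the decay anisotropically. Defaults are the
standard mammographic-texture parameter set K̄=150, N̄=20, Lx=5, Ly=2,
α=2.1, β=0.5, σ=12 on a 128×128 field.

Numerical choices:

* **Edge handling.** Cluster centres are sampled over the field extended by
  a margin of 3σ + 3·max(Lx, Ly) per side; blob mass falling outside the
  field is truncated. This removes the edge-intensity deficit of naive
  in-field sampling; the test suite checks mean stationarity across the
  field. Note that K̄ is a count over the extended field, not a density, so
  smaller fields are textured more densely; scaled-down studies that use
  64×64 fields therefore run at a somewhat higher clutter level than the
  128×128 default, which is irrelevant for the ordering claims they test.
* **Blob support.** With β=0.5 the blob has very heavy tails (it falls to
  10⁻³ of its peak only at ~270 px along the long axis), so the blob is
  truncated at a support radius of 127 px (≤1% of peak). The intensity lost
  to truncation is absorbed by the amplitude calibration below.
* **Fast renderer.** The default renderer quantizes blob orientation into
  24 bins over [0, π) (the blob has period π), deposits blob centres onto
  an extended canvas by bilinear splatting, and synthesises the field as a
  sum of FFT convolutions with a precomputed bank of oriented blob kernels.
  The canvas is sized so that circular wrap-around cannot reach the field.
  An exact per-blob renderer (`method="direct"`) serves as the oracle; on
  small fields the two agree to a few percent RMS of the texture contrast,
  the residual being orientation quantization (±3.75°) and sub-pixel splat
  smoothing. All ensemble-level statistics the pipeline consumes are
  insensitive to this at the calibration stage, because the intensity scale
  is calibrated with the same renderer that generates the data.

### Rayleigh discrimination signal

The resolution task discriminates two point-like objects from a single line
of equal extent. For signal length L: hypothesis H0 is two impulses of
height `amplitude` separated by L−2 px; H1 is a horizontal line of L
samples of the same height; both are convolved with a Gaussian of
σ = 1.375 px. Signals are centred so the centroid lies at the image centre
(N−1)/2; sub-pixel positions are deposited by linear interpolation, which
makes every signal exactly mirror-symmetric about the central vertical
axis and keeps the construction well-defined for even and odd L. Signal
height is not normalized across hypotheses: the H1/H0 total-intensity
ratio is L/2 by construction and is asserted in the tests.

### Synthetic microcalcification (MC) clusters

The MC detection task needs 200×200 cluster maps playing the role of
segmented mammogram crops: a sparse cluster of small bright irregular
blobs, values in [0, 1], background exactly zero. Each map draws n
(default 5–12) calcifications of 2–6 px, with irregular shapes produced by
thresholded smoothed noise under a radial envelope, placed uniformly in a
disk of `cluster_radius` (default 40 px) around a centroid near the canvas
centre (`centroid_spread`, default 20 px). The centred centroid mirrors
real segmented crops, where the segmentation window is placed on the
cluster; it also guarantees the cluster survives the random rotation and
central 128×128 crop applied before insertion. Insertion is multiplicative,
f1 = fb(1 + c·sMC), with contrast c uniform in [0.05, 0.06].

These maps emulate the *role* of real segmented clusters (sparse bright
compact signals at statistically known locations), not their exact
morphology; no claim about real mammograms follows from them.

## Degradation and noise

* Rayleigh task: LR = Gaussian blur (σ = 1.5 px, sampled kernel truncated
  at 4σ, mirror boundary) of the object, plus noise; no resampling.
* MC task: blur (σ = 1.5 px), decimation by 2, noise at the LR grid, then
  bilinear upsampling back to the HR grid so HR/LR/SR are comparable
  pixel-wise. Noise-before-upsampling follows the measurement-model
  reading: the SR network sees interpolated, partially correlated noise.
* Noise: n = σp(P − λ0)/√λ0 + σg Z with P ~ Poisson(λ0), Z ~ N(0,1), IID
  per pixel, so the noise is signal-independent with std exactly
  √(σp² + σg²). The internal rate λ0 = 10 only shapes higher moments; the
  published noise parameterization gives only the scales (σp, σg) per task
  (0.013/0.35 for Rayleigh, 10⁻⁴/10⁻³ for MC), which this centred
  construction reproduces exactly. HR and LR ensembles share objects but
  carry independent noise draws.

## Intensity calibration

The texture model is scale-free and the source material fixes no intensity
units; the package pins the free scales once against the published
ensemble-fidelity anchors and freezes them in `iqtask.config`:

* `RAYLEIGH_CLB_AMPLITUDE = 2.6784` — chosen so the Rayleigh-task LR-vs-HR
  ensemble MSE equals 0.4369. The decomposition is
  MSE = E‖f − Gf‖² + 2(σp² + σg²); the second term is 0.2453, and the CLB
  amplitude scales the first.
* `RAYLEIGH_SIGNAL_AMPLITUDE = 8.0` — the signal height, chosen once so
  that linear-observer AUCs sit in the informative mid-range (≈0.6–0.95)
  at desk-scale ensemble sizes, neither at chance nor saturated; its
  contribution to ensemble MSE (≈0.1%) is included in the calibration.
* `MC_CLB_AMPLITUDE = 1.7225` — same construction for the MC chain
  (ensemble MSE 0.1580).
* `MC_PSNR_PEAK = 128.51492` — the PSNR reference implied by the published
  (MSE, PSNR) pair via peak = √(MSE·10^(PSNR/10)); with MSE matched, PSNR
  follows identically and SSIM becomes a genuine prediction of the model
  (it lands within ~5·10⁻⁴ of the published 0.9942).

## Observers

* **HO / RHO.** The Hotelling observer is w = K⁻¹Δf̄ with
  K = (K0 + K1)/2 estimated empirically (1/(n−1) normalization) on
  centrally cropped, vectorized images. Because K is symmetric PSD its SVD
  is computed as an eigendecomposition (symmetrized, eigenvalues clipped at
  zero, sorted descending). The regularized variant uses the truncated
  pseudoinverse keeping modes with σ_i ≥ λσ_1; numerically zero modes are
  never inverted even at λ=0. The threshold is selected by validation AUC
  over the decade grid 10⁻⁹…10⁻⁴, ties resolved toward the larger λ.
* **Gabor CHO.** 60 channels: six octave-wide passbands (ν = 3/256 … 3/8
  cycles/px), five orientations, two phases. The channel width follows the
  1-octave convention: the envelope's frequency-domain FWHM 4 ln2/(π w)
  equals 2ν/3, giving w = 6 ln2/(πν). Channel statistics are estimated in
  the 60-dimensional channel space, so far fewer samples suffice than for
  the RHO.
* **Learned observers.** Residual CNN classifiers (3×3 stem, n residual
  blocks of two 3×3 convolutions with additive skip, global average pool,
  linear head) emit one scalar score per image and are trained with binary
  cross-entropy through a logistic link; AUC is computed on the raw score.
  An optional warm start adds a parallel linear branch initialized from an
  RHO template with trainable gain and a zero-initialized head, so the
  untrained observer scores images exactly like the RHO. "Semionline"
  training re-draws the noise component of every training image each epoch
  from the stored noiseless objects; fourfold flip augmentation is
  available for the MC task.

## SR networks and training

The SR family is a plain feed-forward CNN: 9×9 first layer, 5×5 hidden
layers at constant width (default 32 channels, tests use 8–16), 5×5
single-channel output, rectifiers between layers. All trainable components
run on a compact deterministic numpy engine (same-padded convolutions
evaluated as offset-sums of channel-mixing matmuls, manual backprop, Adam);
gradients are verified against finite differences in the test suite, and
every training run is bit-reproducible from its seed.

Two training parameterizations are used, both minimizing MSE on
standardized images with best-validation checkpoint selection:

* **Direct mapping** (default; `residual=False`): the network predicts the
  HR image. This is the configuration for the depth-spectrum study: how
  aggressively the network suppresses measurement noise is exactly what
  the covariance-spectrum analysis measures, and deeper networks suppress
  more, steepening the singular-value decay of the SR covariance.
* **Residual mode** (`residual=True`, with the output layer
  zero-initialized): the network predicts the HR−LR correction, starting
  at the identity. At the small training budgets used in the test suite
  this reliably yields SR images that improve MSE/PSNR/SSIM over LR, and
  it is the configuration used for the SR-fidelity and observer-benefit
  studies.

## Statistics

Empirical AUC is the Mann–Whitney estimator (ties ½). Confidence intervals
use DeLong's structural-components variance computed via midranks with a
two-sided normal approximation clipped to [0, 1]; a degenerate variance
(perfect separation) collapses the CI to a point and is flagged. The
implementation is cross-checked in the tests against a 2,000-replicate
bootstrap, a coverage study with the analytic Gaussian AUC Φ(SNR/√2), and
the reference R implementation (pROC).

IQ metrics: ensemble MSE is the grand mean of squared pixel differences;
PSNR = 20 log₁₀(peak) − 10 log₁₀(MSE); SSIM uses the standard 11×11
Gaussian window (σ=1.5) with constants (0.01·peak)², (0.03·peak)²,
averaged per image then over the ensemble.

## Problem sizes

The published studies used covariance estimates from 5·10⁵ images per
class and observer training sets up to 10⁵ images. This package's defaults
and test suite run desk-scale versions chosen once: ensemble-fidelity
checks use 300–2,000 image pairs (the acceptance script uses 2,000
Rayleigh and 1,000 MC pairs); sweep studies use 64×64 fields, 32×32
observer crops, 100–600 images per class, and 8–16-channel networks.
Fidelity targets are insensitive to these sizes (they are means over many
pixels); AUC levels are not at published scale — only their *orderings*
(longer signal easier, HR above LR, data-processing inequality,
capacity-dependent SR benefit) are asserted, each within DeLong CIs.

The capacity study needs the LR-image task to be learnable by a CNN at
these training sizes. Calcifications at the default 2–6 px are essentially
erased by the blur/decimation chain at this scale, and at intermediate
sizes LR training exhibits an all-or-nothing optimization transition; the
observer-study fixture therefore draws 6–10 px calcifications (with the
published insertion contrast retained), for which LR learning is smooth.
The capability contrast then reproduces cleanly: a 2-block, 8-channel
observer trained on 150 images gains ~0.3 AUC from SR preprocessing, while
a 4-block, 12-channel observer trained on 600 images reaches AUC ≈ 0.99
on LR and gains nothing from SR.

## Known limitations

* The synthetic MC clusters share only the gross geometry of real
  segmented clusters; morphology-sensitive conclusions are out of reach.
* The CLB emulates second-order mammographic texture, not anatomy; no
  reader-study or clinical claim follows.
* The adversarial-loss hook on the SR trainer exists but is unvalidated;
  only the MSE-trained path is exercised.
* RHO performance at desk-scale sample sizes is covariance-limited and
  sits below the Gabor CHO; at published sample sizes the ordering
  reverses. Comparisons across observers should be read per sample size.
* The FFT renderer's orientation quantization (24 bins) and bilinear
  splatting smooth per-blob detail slightly relative to the exact model;
  the direct renderer is available where exactness matters.
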