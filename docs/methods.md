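# Methods

## Problem setting

Motor imagery (MI) — imagining a hand movement without executing it —
attenuates the sensorimotor mu (8–13 Hz) and beta (13–30 Hz) rhythms
over the hemisphere contralateral to the imagined hand
(event-related desynchronization, ERD). A classifier that detects
which hemisphere shows the attenuation can drive a brain–computer
interface. This package implements a four-stage pipeline for that
task and a synthetic generator that reproduces exactly the signal
structure the pipeline is supposed to exploit, so every stage can be
validated end to end at desk scale.

## Wavelet-packet preprocessing

The packet transform splits both filter-bank branches recursively:
node `(l, m)` has children `(l+1, 2m)` (low-pass) and `(l+1, 2m+1)`
(high-pass), computed as a stride-2 circular correlation
`d_i^{l+1,2m} = Σ_k h(k−2i) d_k^{l,m}` (likewise with `g`).

Choices and their reasons:

- **Quadrature-mirror pair.** `g` is the sign-alternated reversal
  `g(k) = (−1)^k h(L−1−k)` — the QMF relation with the index origin
  placed so both filters share the support `[0, L)`. This placement
  is the one that keeps the stride-2 analysis operator orthogonal;
  the naive "indices mod L" placement destroys orthogonality for any
  filter longer than 2 taps.
- **Periodic (circular) boundaries.** The transform is then exactly
  orthogonal: sub-band energy equals signal energy (Parseval) and
  reconstruction from all nodes is exact to machine precision, which
  makes the energy-based tests sharp. Signals whose length is not a
  multiple of `2^level` are padded by symmetric reflection and
  cropped after reconstruction (band-limiting is then idempotent only
  up to the padding approximation; it is exact for power-of-two
  lengths).
- **Node ordering.** Because down-sampling mirrors the spectrum of
  high-pass branches, tree ("natural") order is not frequency order;
  the frequency-ordered index `f` maps to the natural index through
  the binary-reflected Gray code `m = f ^ (f >> 1)` (verified by
  pure-tone placement tests). Band selection defaults to the four
  lowest frequency-ordered level-4 nodes, covering 0 to fs/8 Hz —
  0–31.25 Hz at the default fs = 250 Hz, i.e. the mu + beta range.
- **Wavelet family.** db4 by default (a common EEG choice with a good
  time–frequency trade-off); Haar is available for hand-checkable
  tests. Both are configurable (`wavelet.name`, `.level`, `.nodes`,
  `.ordering`).

Coefficient thresholding/denoising and artifact rejection are
deliberately out of scope; preprocessing is band reselection only.

## Dense feature extractor

A densely connected convolutional network in plain NumPy: 7×7
stride-2 stem, 3×3 max pool, four dense blocks (each layer a 1×1
bottleneck followed by a padded 3×3 convolution; layer `i` receives
the channel concatenation of the block input and all previous
outputs, so an L-layer block has L(L+1)/2 direct feeds), transitions
of 1×1 convolution (halving channels) plus 2×2 average pooling, a
squeeze-and-excitation (SE) gate after every block, and global
average pooling to a fixed-length vector.

- **Epoch-to-image mapping:** one epoch becomes a single-channel
  `1 × n_channels × n_samples` image, so 2-D kernels slide over the
  channel × time plane. This preserves spatio-temporal structure
  without inventing a spectrogram stage.
- **SE placement:** after each dense block, before the transition —
  one recalibration per resolution stage. The gate is
  squeeze (per-channel global mean) → reduce/expand bottleneck
  (reduction 4 by default) → sigmoid, so every gate value lies
  strictly in (0, 1).
- **Forward-only with seeded He initialization.** Classification is
  delegated to the autoencoder stage and the hyperparameter search
  varies the architecture preset rather than training the extractor,
  so the contract here is *reproducible* random features; a softmax
  head is kept for standalone use. Seeded random convolutional
  features followed by a trained classifier are a recognized
  lightweight regime, and on the synthetic task they are linearly
  separable to ~0.95–1.0 test accuracy.
- **Depth presets.** `d121` = blocks [6,12,24,16] (depth
  2·Σlayers + 5 = 121). Depths 72 and 96 are not exactly attainable
  under that formula (it is always odd); `d72` = [4,8,12,9] (71) and
  `d96` = [5,10,18,13] (97) are the nearest layouts. A deliberately
  small `tiny` preset ([2,2,2,2], growth 8) is the desk-scale
  default; it is also what the test suite uses so runs stay in
  seconds.

## Hawk/shepherd metaheuristic

A Harris-hawks-style population search with three modifications: the
exploration reference is the mean of the best, worst and current
positions; the escape energy `Eg = 2·C·Eg0·(1 − t/t*)` carries a
chaotic multiplier `C` from the logistic map
`Φ_{k+1} = a·Φ_k(1 − Φ_k)` (a = 4, Φ₀ = 0.7 by default, advanced once
per iteration); and each plain hard besiege is followed by a
shepherd-style step `S_best + r·(S_prey − S_i) + Lévy(γ)` accepted
greedily.

Dispatch per hawk per iteration: exploration while `|Eg| ≥ 1`
(`Eg0 ~ U(−1,1)` redrawn per hawk per iteration); otherwise soft
besiege (`|Eg| ≥ 0.5, r ≥ 0.5`), hard besiege (`< 0.5, ≥ 0.5`), or
the corresponding progressive-quick-dive variant for `r < 0.5`, where
candidate `U` (direct dive; mean-position-based in the hard variant)
is accepted if it improves, else `V = U + Q×Lévy` if it improves,
else the hawk stays. Lévy steps use Mantegna's algorithm
(`σ(γ)` from the gamma-function expression; `σ(1.5) ≈ 0.6966`,
`σ(1) = 1`) scaled by 0.01 so jumps stay commensurate with unit
boxes. Numerical conventions: all candidates are clamped to
`[lb, ub]` before evaluation; absolute-value bars are used in the
besiege distances (without them positions diverge on sign-symmetric
landscapes); ties keep the incumbent; non-finite objective values
reject the candidate; minimization is the internal sense and
maximization negates at the boundary. Runs are reproducible from the
seed and the best-so-far history is monotone by construction.

`optimize` accepts optional warm-start positions. The pipeline's
tuner warm-starts at the default configuration whenever it lies
inside the search space: with desk-scale budgets (6 hawks × 5
iterations) a cold-started search can settle below a well-chosen
default, whereas the warm start makes "tuned ≥ default" structural
while leaving room for genuine improvement (observed on roughly half
the seeds).

## Hyperparameter space and fitness

The search space follows the study design: learning rate log-uniform
on [1e−4, 1e−1] (`x = 2/3` decodes to 1e−2), batch size in
{8, 16, 32, 64}, and a depth preset, with the two discrete axes
decoded by equal-width binning of `[0, 1]`. The fitness is macro
validation precision `TP/(TP+FP)` (one-vs-rest); a class with no
positive predictions contributes 0 with a warning, and a diverged
training run is a rejected (non-finite) candidate. Accuracy-based
fitness is available via the same evaluation report. Per-candidate
training uses a short fixed budget (5 epochs); the final model is
retrained at the full configured budget with the winning settings.
Features per preset are cached within a tuning run, so each preset's
extractor runs once.

## Autoencoder classifier

Input vectors are zero-padded to a multiple of the patch length `d`
and cut into non-overlapping `d`-patches (stride configurable). The
encoder applies `m` kernels patch-wise, `o = relu(Wx + b)`; the
decoder is linear, `x̂ = Ŵo + b̂` (linear rather than rectified so
reconstruction targets of either sign are reachable under the MSE
cost). Training is plain minibatch SGD on
`J = (1/p) Σ_i ‖x_i − x̂_i‖² + λ·CE` with λ = 1, where CE is the
cross-entropy of a softmax head on the patch-averaged code. All
gradients are analytic and checked against central finite differences
to 1e−4 relative error. Defaults: m = 32 kernels, d = 4, learning
rate 0.1, batch 8 — sized so the short 5-epoch budget used during
tuning actually converges (both values are members of the search
grid); the head is zero-initialized (uniform initial probabilities),
the standard convention for softmax regression. Divergence (loss
leaving the finite range) aborts with diagnostics. By default the CAE
consumes standardized dense-network feature vectors (standardization
fitted on the training split only); raw preprocessed epochs can be
fed by flattening them instead.

## Synthetic generator

Each channel is unit-variance 1/f^a noise (spectrally shaped white
noise, a = 1 by default; the averaged log-log spectral slope matches
−a within 0.2 over 1–40 Hz) plus one mu-band and one beta-band
sinusoid at random frequency and phase per epoch. Total oscillation
power is set by `snr_db` (10 dB default, split equally between the
bands). For the imagined hand's contralateral lateral channel group
the oscillation amplitude is scaled by `1 − erd_depth`
(`erd_depth = 0.6` default; 0 removes the class signal entirely, 1
suppresses the rhythm fully). The layout is three groups proxying
C3/Cz/C4 — the minimal structure on which "contralateral" is
well-defined. ERD is applied for the whole epoch by default; an
optional 0.25 s onset ramp is available. Defaults: fs = 250 Hz,
3 channels, 2 s epochs (the post-cue ERD window), two classes
(left/right hand), balanced sets, bit-identical regeneration from the
seed.

What the generator deliberately omits: volume conduction and channel
mixing, ocular/muscular artifacts, session/subject nonstationarity,
and trial-to-trial ERD latency variation. Passing tests therefore
show that the pipeline recovers a lateralized band-power contrast
embedded in 1/f noise — not that it reaches any particular accuracy
on real recordings, where these omitted effects dominate the error
budget.

## Splits, determinism and problem sizes

Data are split 60/20/20 (train/validation/test), stratified and
seeded. Every stage draws from `numpy` generators seeded from the
configuration, so a run is reproducible end to end. The test suite
and the acceptance script run the pipeline at deliberately small
sizes — `tiny` extractor preset, 50–200 epochs per class, 5-epoch
candidate training, tuning spaces of three small presets — chosen so
the full suite executes in a couple of minutes on one CPU while still
exercising every code path at the documented operating points.

## Known limitations

- The dense extractor is untrained by design; its features are
  sufficient for the synthetic task but would need supervised
  training (out of scope here) to compete on real EEG.
- The evaluation is a single held-out split, not cross-validation;
  with the small synthetic test sets the reported metrics have wide
  binomial error bars.
- The shepherd component contributes only its position-update step;
  community shuffling into sub-herds is not implemented.
- Real-EEG ingestion (EDF) maps fixed-length windows to epochs with a
  single label; event-based epoching should be done upstream (e.g. in
  MNE) before export.
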