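# Methods

## The model

A contaminated EEG segment is modeled additively: `R = D + N`, where `D` is
the clean brain signal and `N` the artifact. Windowed into a matrix (16
windows of 32 samples for the canonical 512-sample, 256 Hz segment), the
clean part is approximately low rank — resting brain rhythms repeat across
time windows — while ocular (EOG) and myogenic (EMG) artifacts are sparse
in time or frequency. Relaxing rank to the nuclear norm and sparsity to the
l1 norm, and replacing the equality constraint with a quadratic penalty to
avoid Lagrange multipliers, gives the objective

    min_{D,N}  ||D||_* + mu ||N||_1 + (beta/2) ||R - D - N||_F^2 .

### Classical solver (`eegunfold.lowrank`)

Alternating exact proximal steps:

* D-step: `D <- SVT_{1/beta}(R - N)` — singular value thresholding, the
  proximal operator of the nuclear norm;
* N-step: `N <- soft_{mu/beta}(R - D)` — elementwise shrinkage, the
  proximal operator of the l1 norm.

Each step minimizes the objective exactly in its block, so the objective is
monotonically nonincreasing (asserted in tests). Stopping: relative
Frobenius change of `(D, N)` below `tol` (default 1e-7) or `max_iter`
(default 500); non-convergence is reported via a flag, not an exception.
`classical_denoise` returns `x_hat = unembed(D)` and `n_hat = y - x_hat`:
the noise estimate absorbs the small penalty residual so additivity holds
exactly.

A more flexible sparsity prior `S(N)` admits no proximal step in general;
majorizing it by its Lipschitz-gradient quadratic upper bound around the
previous iterate and zeroing the derivative yields the closed form

    N_k = delta N_{k-1} + (1 - delta)(R_{k-1} - D_k) - rho grad_S(N_{k-1}),
    delta = mu ls / (mu ls + beta),   rho = mu / (mu ls + beta),

implemented as `surrogate_update_n` and verified against numerical
minimization of the majorized objective. The constant term of the majorizer
does not affect the argmin and is dropped; `ls` (the Lipschitz constant)
appears only as an explicit parameter here — in the network it is absorbed
into the fixed `delta` and the learned `rho`.

### Unfolded network (`eegunfold.unfolding`)

K stages mirror K solver iterations, with the hand-derived operators
replaced by learnable modules. Starting from `R_0 = y`, `N_0 = 0`:

* **Net-D** (clean estimator): `D_k = (R_{k-1} - N_{k-1}) +
  unet(R_{k-1} - N_{k-1})`. The 1-D U-Net (Conv+BN+ReLU encoder levels with
  max-pool downsampling; zero-stuffed transposed-convolution upsampling
  with skip concatenation) replaces the SVT/approximation operator: its
  multiscale encoder sees the signal at the several window scales in which
  the low-rank structure lives.
* **Net-N** (noise estimator): the surrogate update with `grad_S` replaced
  by a small Conv+ReLU stack `g` and a learnable scalar `rho_k` per stage,
  plus a residual enhancement:
  `N_k = R_{k-1} + N_{k-1} - D_k - rho_k g(N_{k-1}) + (R_{k-1} - D_k)`.
  `delta` is fixed at 0.5 and not learned. A `strict_surrogate` flag
  restores the literal delta-weighted closed form
  `0.5 N_{k-1} + 0.5 (R_{k-1} - D_k) - rho_k g(N_{k-1})` (the residual-
  enhanced form is the default because it is the form the network
  architecture finalizes; the two differ by the 1/2 weights and the extra
  residual). A `use_prev_D` flag feeds `D_{k-1}` instead of `D_k` into the
  noise update (the stage dataflow supports either reading; the current-
  stage estimate is the default since Net-D runs before Net-N within a
  stage).
* **Net-R** (re-synthesis): `R_k = netr(D_k + N_k)`, a small CNN whose
  final convolution is initialized near zero on top of an additive skip, so
  each stage starts as plain addition and training only has to learn the
  correction.

The denoised output is `D_K` by default (`output_mode="R_last"` selects the
re-synthesized signal instead; both readings of "final output" are
defensible and the loss follows the configured choice).

Three structural consequences of this wiring, all asserted in tests:

* **Zero-network identity.** With all weights zero, `D_1 = y` and
  `N_1 = 0`: the K=1 model is exactly the identity.
* **Final half-stage.** With the clean-signal output, the last stage's
  Net-N and Net-R would be dead ends (their outputs feed nothing and could
  never receive gradient), so they are not instantiated; the trajectory
  records the implied residual `N_K = R_{K-1} - D_K`, `R_K = D_K + N_K`.
* **Stage-1 gradient net.** `N_0` is identically zero, so a convolution of
  it is a constant map whose weight could never receive gradient; stage 1's
  `g` therefore starts with a learnable per-channel constant instead of a
  first convolution. Later stages use full convolutions.

### Numerical backend

The network runs on a small reverse-mode automatic-differentiation engine
over NumPy arrays (`eegunfold.nn`): conv1d ('same' padding via im2col),
batch normalization (batch statistics in training, running estimates in
eval), max pooling, zero-stuffed upsampling, ReLU, channel concatenation
and elementwise arithmetic, each with a hand-derived vector-Jacobian
product, plus an own Adam. Everything is float64; all gradients are checked
against central finite differences in the test suite. Initialization is
Kaiming-uniform for convolution weights, uniform +-1/sqrt(fan_in) for
biases, `rho = 0.1`, all drawn from a single seeded generator so builds are
bitwise reproducible.

## Synthetic data (`eegunfold.synth`)

The generators emulate the structure of the public single-channel EEG
denoising benchmarks (thousands of 2 s, 256 Hz clean EEG / EOG / EMG
segments) so the pipeline is testable without any download:

* **Clean EEG**: frequency-domain synthesis — complex Gaussian spectra
  shaped by per-band gains over delta (1-4), theta (4-8), alpha (8-13),
  beta (13-30) and gamma (30-80 Hz), plus a weak 1/f background
  (`pink_gain = 0.05` relative to the largest band gain, exponent 1);
  mean-centered, unit RMS. Defaults emulate a resting-state spectrum
  (delta 1.0, theta 0.8, alpha 1.0, beta 0.4, gamma 0.15).
* **EOG**: raised-cosine bumps (half-width 0.3 s, ~1.5 events/segment,
  mostly one-sided like blinks); >=90% of spectral energy below 5 Hz,
  matching the 0.5-5 Hz band in which ocular artifacts are conventionally
  isolated.
* **EMG**: white noise gated by short Tukey windows (0.05-0.2 s bursts,
  ~3/segment), then band-limited to 20-120 Hz by a hard spectral mask
  (masking after gating keeps the passband energy fraction essentially
  exact).

For positive event rates every segment carries at least one event, so
downstream mixing never sees a zero artifact. Mixing solves
`y = x + lam n` for the scale `lam` that hits a requested SNR. Two
conventions are exposed: `power` (default; SNR = 10 log10(Ps/Pn), so
`lam = RMS(x)/(RMS(n) 10^(s/20))`) and `rms_ratio` (the public benchmark's
mixing dialect, `10^(s/10)`). The power convention is the default because
it is the one the evaluation metric itself defines; neither is claimed to
reproduce published benchmark tables. Standardization divides mixture and
clean target by the mixture's per-segment standard deviation (per segment,
not global — flagged in the API — because it preserves the additive model
and lets metrics be computed in the space the model sees).

What the generators do **not** model: multichannel spatial structure,
nonstationary spectra, line noise, electrode drift, or the correlation
between artifact amplitude and brain state in real recordings. Passing
tests therefore demonstrate that the machinery is correct and that the
architecture can learn this family of spectro-temporal separations — not
performance on real EEG.

## Metrics (`eegunfold.metrics`)

RRMSE_t = RMS(x_hat - x)/RMS(x); RRMSE_s = the same ratio on Welch PSDs
(Hann window, nperseg = min(256, L), 50% overlap, one-sided — the estimator
is unspecified in the usual formulations, so the parameters are recorded in
every `PSDEstimate` and configurable); CC = Pearson correlation; SNR =
10 log10(Ps/Pn) with `Pn` the residual power (zero residual returns `inf`
as a documented sentinel). RRMSE_t and pairwise SNR are deterministically
linked (`snr = -20 log10(rrmse_t)`), which the suite asserts to 1e-9.
Batch aggregation is the unweighted arithmetic mean over pairs; per-SNR
tables pool all segments of a level and the "mean" row averages the level
rows.

## Training protocol (`eegunfold.training`)

Training clean segments are shuffled `n_repeats` times (historically one
shuffle per nominal SNR level, default 10), concatenated, paired with
cyclically reused shuffled artifacts and mixed at SNRs drawn uniformly from
[-7, 2] dB. Validation/test segments are mixed deterministically at each
integer SNR -7..2 dB (10 x |split| pairs, grouped by level). Splits are
80/10/10 by clean-segment identity (proportions are a package choice;
identity-level splitting prevents leakage through the repeat
concatenation). Loss is MSE in standardized space against the configured
output; optimizer Adam (lr 1e-4 default, betas 0.9/0.999); early stopping
on validation loss with patience 10 and restoration of the best epoch.
Batch size 64, epoch cap 200 — all configurable.

## Problem sizes used by the tests and acceptance script

The suite exercises the full-size default model (depth-4 U-Net, channels
16/32/64/128, ~0.3M parameters) for wiring, identity and shape contracts,
and uses a reduced model (depth-3, channels 4/8/16, Net-N 2x8, Net-R 2x8,
~5k parameters) with lr 1e-3 for the training studies: 2000/200/200
segments and 5 epochs for the end-to-end learning check; 300 segments x 3
repeats and 6 epochs per run for the stage-count sweep; and a wider
clean-signal estimator (channels 16/32/64, ~24k parameters, matched by the
plain-CNN twin) with 4 repeats and 7 epochs for the architecture ablation,
which needs runs past the undertrained regime. These sizes are the
package's own
reduced-budget study conditions for CPU execution; the learning check
clears its +3 dB bar by a wide margin (typically +12 dB), and the ablation
directions are stable across seeds at this budget.

## Known limitations

* The ablation comparing the U-Net clean-signal estimator against a plain
  CNN of comparable parameter count is budget-sensitive: at very small
  budgets the full-resolution CNN converges faster on the synthetic task,
  and the U-Net's advantage emerges with capacity/training length (see the
  ablation test's budget).
* The classical solver's (mu, beta) need tuning per signal scale; defaults
  suit unit-RMS standardized segments.
* Hankel embedding is provided but reshape is the default; anti-diagonal
  averaging makes Hankel round trips exact only to ~1e-12.
* No multichannel support; segments are processed independently.
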