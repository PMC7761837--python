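# Methods

This note documents the models, numerical choices, and limitations of the
`synsiggan` pipeline in implementation order: fixture generation, wavelet
denoising, segmentation, the adversarial model, and the evaluation suite.

## Synthetic fixtures

The fixture generator stands in for clinical corpora so that every stage is
testable offline. It emulates the gross morphology of four signal
families, not their physiology:

* **ECG** — each beat is a sum of five Gaussian bumps (P, Q, R, S, T) with
  fixed relative centres/widths on the beat phase; beat-to-beat R-R
  variability comes from drawing each beat length uniformly from
  `segment_length_range` (the default, 324–396 samples at 360 Hz, is ±10%
  around a nominal one-second beat).
* **PPG** — two Gaussian bumps per pulse (systolic peak, dicrotic bump).
* **EEG / EMG** — white noise shaped by a 4th-order Butterworth band-pass
  (EEG 1–30 Hz, EMG 20–150 Hz, upper edge clipped to 0.45·fs), matching
  their band-limited stochastic character.

Distinct class labels scale the template amplitude deterministically so a
multi-class corpus has separable morphology. Additive white Gaussian noise
is rescaled so the realised SNR equals `noise_snr_db` *exactly*; the clean
template and the noise draw use independent child streams of the seed, so
the clean reference is reproducible independently of the noise setting.
One annotation marks each segment start.

What the fixtures do **not** model: baseline wander, electrode motion
artifacts, heart-rate dynamics, pathological beat-to-beat morphology
changes, multi-channel correlation, or 1/f noise. A test passing on
fixtures therefore demonstrates the pipeline's mechanics (conservation,
reproducibility, learnability of a stable template), not clinical fidelity.

## Wavelet denoising

* **Filter bank.** The default analysis pair is db2, the canonical 4-tap
  orthogonal Daubechies pair (taps taken from PyWavelets). Any 4-tap
  orthogonal pair can be supplied.
* **Extension mode.** The cascade is *periodized* (circular convolution
  with stride 2). The resulting transform matrix is orthogonal, which
  gives exact perfect reconstruction and coefficient counts that halve per
  level. Odd-length inputs are edge-padded to even length at each level;
  the pre-pad length is recorded and reconstruction trims back, keeping
  the inversion exact for every length. Energy is preserved to round-off
  (verified against PyWavelets' periodization mode).
* **Adaptive threshold.** Level *i*, window *j* (32 coefficients per
  window): threshold = mean |x₁| over the window × 2^i, computed from the
  **level-1** detail coefficients for all levels. Basing every level's
  statistic on the finest scale is deliberate and implemented literally;
  because each level has half the coefficients, level-i coefficient k is
  assigned to the window containing its level-1 position k·2^(i−1). The
  conventional per-level variant (`per_level_stats=True`) computes window
  means over each level's own coefficients; note the exact ×2 doubling law
  between consecutive levels holds only for the level-1-based rule. Tail
  windows shorter than 32 use the mean over the available coefficients.
* **Mode.** Hard thresholding by default (zero below threshold, survivors
  untouched — preserves sharp QRS amplitudes); soft shrinkage selectable.
  Approximation coefficients are never thresholded.
* **Defaults.** L = 4 levels, window 32. On the default ECG fixture
  (10 beats, 324–396 samples) the median SNR gain is positive for input
  SNR ≤ 15 dB. Because the thresholds scale with the signal's own
  fine-scale detail magnitudes, a noiseless input is *not* a fixed point:
  it loses a small (few percent) fraction of energy; the test suite bounds
  this at 5% relative change rather than claiming exact pass-through.

## Segmentation

* Boundaries are half-open `[start, next_start)`; the trailing segment runs
  to the end of the record, so the annotated region is partitioned exactly.
  Samples before the first annotation (none, for fixtures) belong to no
  segment.
* The R-R alternative takes T = median of successive beat-index
  differences and windows each beat to length T *centred* on the R index
  (centred rather than R-anchored; clipped windows are kept when at least
  T/2 samples survive).
* Z-scoring (mean 0, sample sd 1, ddof = 1) is applied per segment after
  segmentation and **before** resampling; constant segments are rejected.
* Length equalisation: the ratio minL/l is approximated by a
  continued-fraction convergent within `tol` (default 1e-6, shrinking tol
  converges to the exact reduced fraction for rational ratios), then
  `scipy.signal.resample_poly` resamples by p/q. The ±1-sample slack of
  polyphase resampling is resolved by trimming or edge-value padding to
  exactly minL.

## The adversarial model

* **Generator.** A 2-layer bidirectional grid LSTM, hidden size 50 by
  default. Per grid point both the time and the depth block read
  H^dep_{t,l−1} and H^Tm_{t−1,l}; each block keeps its own cell state, all
  four gates carry full-matrix peephole weights D (initialised to zero)
  and a square output projection. Each dimension has its own full
  parameter set (the per-dimension structure standard for grid LSTMs).
  The noise input (i.i.d. standard normal, 8 dims per time step) enters as
  H^dep_{t,0}; C^dep_{t,0} = 0. The reverse grid reads the t+1 states with
  zero states beyond the sequence ends. Per time step the two top-layer
  depth outputs are combined by concatenation + a learned linear map to
  one sample (summation selectable). Swapping the direction stacks
  together with the two halves of the output map and reversing the noise
  time-reverses the output exactly — the symmetry test uses this form.
* **Discriminator.** Conv(8 filters, kernel 5, stride 3) → ReLU →
  max-pool(2) → conv(16 filters, kernel 3) → ReLU → max-pool(2) → fully
  connected → softmax over {real, fake}. First-layer length is
  ⌊(T−H)/P⌋+1.
* **Training.** One discriminator step per generator step; discriminator
  maximises E[log D(x)] + E[log(1−D(G(z)))], generator minimises the
  non-saturating −log D(G(z)) by default (the literal log(1−D(G(z)))
  selectable). Adam (lr 1e-3, β 0.9/0.999), batch 32, global gradient-norm
  clipping at 5 for stability. Weights use Glorot-uniform init with
  forget-gate biases at +1; peepholes start at zero. All arithmetic is
  float64 numpy on an in-package reverse-mode tape (gradients are verified
  against central finite differences in the tests), single-threaded and
  bit-reproducible given the seed.
* **Per-class training.** One model is trained per annotation class (the
  adversarial stage requires same-class, same-length inputs); the pipeline
  loops classes with per-class seed offsets. A trained model always emits
  exactly the requested number of segments, giving per-class count parity
  with the original corpus.
* **Problem sizes.** The reference learning check trains on 64 sinusoid
  segments of length 64 (hidden 16, 200 epochs, ≈3 minutes on one CPU) and
  reaches median Pearson correlation ≈ 0.97 between generated samples and
  the class template; the acceptance threshold is 0.7. These sizes are the
  package's standard smoke-scale conditions; larger corpora and longer
  segments scale linearly in time steps and epochs.

## Evaluation metrics

RMSE is the standard √(1/N·Σ(O−S)²) and PRD the standard
100·√(Σ(O−S)²/ΣO²); a `literal_form` flag provides the squared PRD
variant without the root. PCC is the standard Pearson product-moment
coefficient (anything else could not lie in the [−1, 1] bands used to
interpret it). The discrete Fréchet distance runs the classic O(RS)
dynamic programme over monotone couplings; curves are (index/(N−1),
amplitude) points by default, with a pure-amplitude variant
(`parametrize="values"`). The qualitative correlation bands are
half-open on the left (|r| = 0.9 is already "extensively correlated").

## Known limitations

* The GAN is CPU-bound pure numpy; it is sized for segments of a few
  hundred samples and corpora of hundreds of segments, not for
  GPU-scale training.
* EDF reading recovers samples and sampling rate only (no EDF+ annotation
  channels); WFDB reading supports signal formats 16 and 212 and MIT-format
  annotation files, mapping beat symbols onto the 17-class ECG vocabulary
  with unknown symbols as "UB".
* No beat detection: R peaks must come from annotations.
* Fixture realism limits noted above; clinical-corpus correlation values
  reported for models of this family are not reproducible from fixtures
  and are not claimed by this package's tests.
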