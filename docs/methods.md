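# Methods

`vimsplv` implements an EEG functional-connectivity pipeline for grading
visually induced motion sickness (VIMS): narrowband phase synchrony between
scalp channels, summarized as phase-locking-value (PLV) matrices, classified
by a hybrid CNN-LSTM network.  Because the underlying clinical recordings
are not publicly distributable, the package ships a synthetic phase-coupled
EEG generator with an analytic synchrony oracle, so every stage is testable
end to end.

## The pipeline

1. **Acquisition model.** 64-channel BioSemi 10-20 montage at 2048 Hz.
   Twelve noisy electrodes (PO4, O2, PO8, P10, TP8, F6, Fp2, Fpz, POz, P2,
   P1, PO3) are excluded, leaving 52 analysis channels whose order is frozen
   to the file header; every connectivity matrix is indexed in that order.
   Channels group into five scalp regions (frontal, temporal, central,
   parietal, occipital) by label prefix.
2. **Preprocessing.** 0.5–45 Hz band-pass, 49–51 Hz band-stop (mains),
   downsampling to 1024 Hz (anti-alias low-pass at 0.9x the target Nyquist,
   integer decimation only), whole-brain average re-reference, and an ICA
   artifact-removal hook that is deliberately a no-op here (the generator
   produces no ocular/muscular artifacts; the interface is reserved for real
   data).  All filters are Butterworth applied forward–backward
   (`sosfiltfilt`), hence zero-phase: PLV is a phase statistic and filtering
   must not distort phase.  Order 6 was chosen so that the effective
   (squared) stop-band response suppresses a 60 Hz tone below 5% RMS — a
   4th-order design leaves 8.5% and fails that contract.  Filters always run
   on whole recordings, never on 3-s segments, so segment edges carry no
   transients.  The band-pass plus separate notch is redundant (49–51 Hz lies
   outside 0.5–45 Hz) but both stages are kept for protocol fidelity.
3. **Band decomposition.** delta 0.5–4, theta 4–8, alpha 8–14, beta 15–30,
   gamma 30–45, full 0.5–45 Hz.  The alpha/beta gap at 14–15 Hz is
   reproduced exactly as defined.
4. **State windows.** Three 60-s windows per subject: VIMS_0 = first 60 s of
   rest; VIMS_1 = 30 s either side of the light-sickness report; VIMS_2 =
   the 60 s immediately before the heavy-sickness report (the stimulus stops
   there, so no later data exist).  If the two reports are closer than 30 s
   the windows overlap; this is permitted and logged.
5. **PLV matrices.** Each window is cut into twenty non-overlapping 3-s
   segments (N = 3072 samples at 1024 Hz).  Per segment and channel the
   instantaneous phase is the angle of the analytic (Hilbert) signal; an
   identically-zero channel gets phase 0 plus a logged warning rather than a
   mid-pipeline error.  For channels x, y,

       PLV = | (1/N) Σₙ exp(j(φx(n) − φy(n))) | ∈ [0, 1],

   the modulus of the time-averaged unit phasor of the phase difference
   (the modulus is required for the unit range).  One symmetric,
   unit-diagonal 52×52 matrix per (band, state, subject, segment); the
   default cohort of 25 subjects gives 25·3·20 = 1500 matrices per band.
   PLV is computed over the full 3-s segment with no sub-windowing.
6. **Topology maps.** Per (band, state), matrices are averaged element-wise
   across subjects and segments; edges with average PLV ≥ 0.55 form the
   network topology (exported as edge-list CSV / GraphML).  The 0.55
   "sparsity threshold" is read as an absolute weight cutoff with ≥
   semantics; a proportional (edge-density) reading is available via
   `threshold_topology(..., proportional=True)` since the term is ambiguous.

## The classifier

Input is a raw 52×52 PLV matrix (already in [0, 1]; no further
normalization).  Two convolutional blocks — conv 3×3 (stride 1, padding 1) →
batch-norm → ReLU → 2×2 max-pool → dropout (0.5, then 0.3) — with 64 and 128
feature maps produce (64, 26, 26) and (128, 13, 13) tensors.  The block-2
output is read as a sequence of 13 row-steps of 128·13 = 1664 features
(a spatial scan that preserves row adjacency while matching the stated
hidden sizes), fed through stacked LSTMs with 100 and 50 hidden units; the
final hidden state feeds a single linear softmax layer over 2 or 3 classes.
The binary task merges the two sickness grades against rest.

Training: Adam (lr 1e-3), cross-entropy, batch 32, at most 50 epochs, early
stopping once validation loss has not improved for 10 consecutive epochs,
restoring the best-validation-loss weights.  Evaluation uses 5-fold
cross-validation, stratified by class at the segment level by default.
Segment-level splitting matches the 1500-matrix sample-set protocol but
leaks subject identity across folds; `split_by="subject"` (GroupKFold on
subject ids) is provided for a leakage-free estimate and is the option we
would recommend for real data.

The network is implemented directly in NumPy — im2col convolution,
batch-norm, max-pool, dropout, LSTM with explicit backpropagation through
time, Adam — with every layer verified against central-difference gradients
in the test suite.  Activations use a channels-last memory layout and
float32 GEMMs; training is CPU-only and deterministic given a seed (dropout
draws come from the same seeded generator).

Metrics follow the usual definitions: accuracy = correct/total (the binary
(TP+TN)/(TP+FN+FP+TN) generalized to multiclass), recall = TP/(TP+FN) per
class (NaN with a warning when a class has no true members), and confusion
matrices with true classes on rows, row-normalized so the diagonal holds
recalls.  The cross-validated "average confusion matrix" is the element-wise
mean of per-fold row-normalized matrices.

## Synthetic EEG generator

Each channel is a sum of narrowband oscillators plus white noise:

    x_k(t) = Σ_b A_b (1+a_k) cos(Φ_b(t) + β_kb + ε_kb(t)) + w_k(t)

* Φ_b — a band-specific phase trajectory shared by all channels: carrier at
  the band centre with a slow clipped random-walk frequency wander (±30% of
  the band half-width), so segments are not phase-locked to each other.
* β_kb — fixed per-channel phase offsets, equally spaced on the circle and
  permuted per subject.  Constant offsets leave every pairwise PLV unchanged
  but cancel in the across-channel mean, so the whole-brain average
  reference does not subtract the shared oscillator.  (Without them the
  common mode *is* the synchrony and re-referencing destroys it — a crude
  but instructive stand-in for the spatial phase gradients of real scalp
  EEG.)
* ε_kb — per-channel von Mises phase jitter with concentration
  κ(state, band) × region multiplier.  The von Mises family is chosen
  because its mean resultant R(κ) = I₁(κ)/I₀(κ) gives a closed-form
  population PLV between two channels: R(κ_i)·R(κ_j), i.e. (I₁/I₀)² for an
  equal pair (`expected_plv`).  Jitter is piecewise-constant at 2 Hz knots
  (~1 Hz bandwidth): slow enough to survive band-pass + Hilbert, and
  zero-order hold preserves the von Mises marginal exactly, keeping the
  oracle valid where a linear low-pass of circular samples would not.
* Amplitudes fall off with frequency (delta 20 µV … gamma 4 µV), with ±20%
  per-subject variation that the amplitude-invariant PLV must ignore;
  additive white noise SD 2 µV.  Generation is at the native 2048 Hz so the
  downsampling stage is always exercised.

Default concentrations make synchrony highest in delta and lowest in gamma,
and weaken it as sickness deepens, with the largest relative between-state
contrast in beta/gamma — e.g. gamma κ = (3.0, 1.5, 0.7) across
(rest, light, heavy).  Frontal (×1.25) and temporal (×1.1) channels couple
more strongly than parietal (×0.9) and occipital (×0.8).  A `null` profile
uses state-independent κ everywhere: a negative control on which any
classifier must score at chance.  Each subject's session is one continuous
184-s recording (rest from 0 s, light-sickness report at 92 s, heavy at
184 s, 2-s guard gaps between windows) written as BioSemi 24-bit BDF plus a
plain-text state-timestamp sidecar, so synthetic data flows through the
identical ingestion path as real data.  The BDF writer is implemented here
(no writer library is available); round-trips are validated against the
independent MNE reader to the 24-bit quantization step (~0.004 µV over
±32768 µV).

### Estimator bias, and what the oracle tests mean

The sample PLV |mean phasor| over M effectively independent phase-difference
draws has expectation ≈ sqrt(p² + (1−p²)/M) for population value p — biased
upward, severely so when p² ≲ 1/M.  Two regimes matter here:

* **Phase-domain calibration** (`sample_phase_segments`): one independent
  von Mises draw per sample, M = N = 3072, so the bias is ≤ ~4% even at
  κ = 0.5 and the measured mean PLV matches (I₁/I₀)² within 5% across
  κ ∈ {0.5, 2, 8}.  This is the route used to verify the estimator against
  the closed form.
* **Signal domain through filters**: slow jitter caps M at ≈ 6 knots per 3-s
  segment, so per-segment PLV sits near sqrt(p² + (1−p²)/6) — well above p
  at low synchrony.  Tests of the generated *signals* therefore compare
  against this finite-sample expectation (±15%) and assert strict
  monotonicity in κ through the full preprocessing chain, rather than
  pretending the raw closed form is attainable there.  This bias is a
  well-known property of PLV at short segment lengths, not an artifact of
  this implementation.

What passing tests do and do not show: the synthetic data exercise every
pipeline contract (shapes, counts, invariances, synchrony dial, chance-level
null), but they are far easier to classify than real EEG — no 1/f
background, no volume conduction, no artifacts, no non-stationarity, and a
literal latent oscillator per band.  High synthetic accuracies validate the
machinery, not clinical performance.

## Problem sizes in the test suite

Structural checks run at full scale (25-subject cohort, 1500 matrices).
Classifier-recovery checks run on an 8-subject cohort (480 matrices,
5 folds) with max_epochs 6 / patience 5 — the separable condition converges
by epoch ~3 at this training-set size, and one CPU epoch costs a few
seconds — and the gap-monotonicity check uses 3-subject cohorts with a
single train/validation split per gap level (at 120 training samples and
8 epochs the optimizer converges reliably; much below that, fold-to-fold
convergence becomes the dominant noise source).  Library defaults keep the
published 50-epoch / patience-10 settings.

## Known limitations

* ICA artifact removal is interface-only; real recordings need it filled in.
* Average re-referencing interacts with common-mode synchrony; the generator
  sidesteps this with phase offsets, but on real data reference choice
  materially affects PLV levels.
* Segment-level cross-validation over-estimates subject-level
  generalization; use `split_by="subject"` for honest estimates.
* The 14–15 Hz gap between alpha and beta is reproduced as defined; signals
  there are simply not analysed.
* `expected_plv` describes the population value; finite-segment estimates
  are biased upward as described above.
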