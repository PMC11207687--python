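# vimsplv

Phase-locking-value (PLV) EEG functional connectivity and CNN-LSTM
classification of visually induced motion sickness (VIMS) states.

Users immersed in VR frequently develop motion sickness — nausea, dizziness,
disorientation — from the mismatch between visual and vestibular motion
cues.  The sickness state leaves a signature in the *synchrony structure* of
the EEG: how phase-locked pairs of scalp channels are, band by band.  This
package implements that detection pipeline for researchers working on
EEG-based sickness monitoring:

1. **Preprocess** 64-channel BioSemi recordings: exclude 12 noisy
   electrodes (52 remain), 0.5–45 Hz band-pass, 49–51 Hz notch, downsample
   to 1024 Hz, whole-brain average re-reference, split into six bands
   (delta 0.5–4, theta 4–8, alpha 8–14, beta 15–30, gamma 30–45,
   full 0.5–45 Hz).
2. **Connectivity**: per state (rest `VIMS_0`, light `VIMS_1`, heavy
   `VIMS_2`), extract a 60-s window, cut it into twenty 3-s segments, and
   for each segment compute the 52×52 PLV matrix from Hilbert
   instantaneous phases,

   PLV = | (1/N) Σₙ e^{ j(φₓ(n) − φᵧ(n)) } |  ∈ [0, 1],

   plus per-(band, state) average matrices and network topology maps
   thresholded at PLV ≥ 0.55.
3. **Classify** the matrices with a CNN-LSTM: two conv blocks
   (3×3, stride 1, pad 1; batch-norm; ReLU; 2×2 max-pool; dropout 0.5/0.3)
   giving (64, 26, 26) → (128, 13, 13) features, two stacked LSTMs
   (100 → 50 hidden units), softmax head; Adam (1e-3), cross-entropy,
   batch 32, ≤50 epochs with early stopping (patience 10), 5-fold
   cross-validation with accuracy, per-class recall and row-normalized
   confusion matrices.
4. **Synthesize**: the study's recordings are not public, so a generator
   produces 52-channel, 2048 Hz sessions whose inter-channel synchrony is
   controlled per state and band by von Mises phase jitter with
   concentration κ — giving the analytic ground truth
   PLV = (I₁(κ)/I₀(κ))² against which the whole pipeline is validated.

The classifier follows the Model/Results idiom: construct a
`VIMSClassifier` from data, `fit()` or `cross_validate()`, read results off
the returned object.  The neural network itself is implemented in NumPy
(im2col convolutions, explicit backprop-through-time LSTM, Adam), with every
layer gradient-checked in the test suite.  See `docs/methods.md` for the
model details and design rationale.

## Worked example

Generate a small synthetic cohort, compute gamma-band PLV matrices, and
cross-validate the ternary classifier:

```python
import numpy as np
from vimsplv import (SynthConfig, TrainConfig, VIMSClassifier,
                     build_datasets, expected_plv)

# analytic oracle: population PLV of two channels with kappa = 2
print(expected_plv(2.0))
# 0.4868894732967886

cfg = SynthConfig(n_subjects=3, seed=7)          # 3 subjects, 3 states each
ds = build_datasets(cfg, bands=("gamma",))["gamma"]
print(len(ds), ds.matrices.shape)
# 180 (180, 52, 52)                              # 3 x 3 states x 20 segments

iu = np.triu_indices(52, k=1)
for state in ("VIMS_0", "VIMS_1", "VIMS_2"):
    off = ds.matrices[ds.states == state][:, iu[0], iu[1]]
    print(f"{state}: mean PLV = {off.mean():.3f}")
# VIMS_0: mean PLV = 0.719
# VIMS_1: mean PLV = 0.486
# VIMS_2: mean PLV = 0.368

tc = TrainConfig(max_epochs=8, early_stop_patience=6, seed=0)
clf = VIMSClassifier.from_dataset(ds, n_classes=3, train_config=tc)
print(clf.cross_validate().summary())
# CNN-LSTM 5-fold cross-validation (3-class, split by segment)
# ========================================================
# fold   accuracy
#    0   0.9722
#    1   0.9167
#    2   0.9444
#    3   1.0000
#    4   1.0000
# --------------------------------------------------------
# mean   0.9667  +/- 0.0362 (sd)
# mean confusion (rows = true, cols = predicted):
#    1.000  0.000  0.000
#    0.050  0.900  0.050
#    0.000  0.000  1.000
```

The mean PLV falls as sickness deepens — the generator's gamma-band
concentration κ drops from 3.0 (rest) through 1.5 (light) to 0.7 (heavy),
and the measured synchrony tracks it through filtering, re-referencing and
Hilbert phase extraction.  The summary reports per-fold accuracies, their
mean ± sd, and the average row-normalized confusion matrix (rows = true
state, diagonal = per-class recall); on this easily separable synthetic
cohort the classifier is near-perfect, which validates the machinery, not
clinical performance.

The same pipeline is scriptable from the shell:

```bash
vimsplv synth --subjects 25 --seed 7 --out raw/         # BDF + sidecars
vimsplv plv --in raw/ --bands gamma --threshold 0.55 --out plv/
vimsplv train --data plv/ --band gamma --classes 3 --folds 5 --seed 7 --out run/
vimsplv run-all --subjects 8 --seed 7 --out full_run/   # everything
```

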