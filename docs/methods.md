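# Methods

## Problem and scope

In a motor-imagery brain–computer interface, a subject imagines a
movement (left hand, right hand, …) while EEG is recorded; a classifier
must decode the imagined class from a short epoched trial. Each trial is
a `T × C` block of raw samples — `T` timestamps by `C` electrodes. When
such a trial is fed to a convolutional network the *layout* of those
`T·C` scalars (which axis the kernel slides over, which axis is treated
as feature channels) changes both the inductive bias and the parameter
budget of the network, and with it the attainable accuracy. This package
implements a controlled experiment over eight such layouts on raw
(unpreprocessed, unfiltered) trials, together with everything needed to
run it end to end on synthetic data: the layout transforms, a compact
two-variant CNN, the training protocol, the evaluation statistics, and a
synthetic generator of motor-imagery-like EEG.

## The eight input layouts

The canonical in-memory orientation of a trial is time-major `(T, C)`;
every layout is an exact, invertible rearrangement of it:

`TxC`, `CxT` (rank 2) and `TxCx1`, `CxTx1`, `1xTxC`, `1xCxT`, `Tx1xC`,
`Cx1xT` (rank 3, axes read as height × width × feature-channels). For
rank-2 layouts the network uses one-dimensional convolution with the
second axis as feature channels; for rank-3 layouts two-dimensional
convolution with the third axis as feature channels. Transforms are pure
index rearrangements: bijective, value-preserving, bit-exact — properties
enforced by tests on random tensors.

Parameter counting follows the closed form `W = prod(kernel)·C_in·N`,
`B = N`, `P = W + B`, generalised to rectangular kernels because every
kernel in the architecture has the `[k × 1]` form (the familiar
`K²·C·N` is the square special case). Depthwise-separable layers count
`prod(kernel)·C_in` depthwise weights plus `C_in·N` pointwise weights,
with the bias on the pointwise stage only — the standard factorisation;
whether the original architecture carried a depthwise bias is not
documented, so the conventional bias-free depthwise stage was chosen.

## Network

Both variants share one schedule: an input batch-normalisation, then
three blocks of

    (conv → BN) × 3 → separable conv → BN → ELU → average-pool(½) → dropout(0.7)

followed by flatten → dense(n_classes) → softmax. Kernels/filters per
block: (30×1)/64 with separable (15×1)/64; (15×1)/32 with (7×1)/32;
(15×1)/16 with (7×1)/16. Batch-norm momentum 0.1 and epsilon 1e-5, with
the update convention `running ← 0.9·running + 0.1·batch` (frameworks
disagree about what "momentum" multiplies; this package documents and
tests its convention). ELU has `α` exposed as a user constant in (0, 1];
the default is 1.0, the interval's boundary and the common choice. The
only in-block nonlinearity is the ELU after the separable stage — the
three conv+BN pairs are deliberately linear between normalisations,
mirroring the stated layer order.

Numerical/geometry choices:

* **"Same" zero padding everywhere.** Several layouts put a singleton
  extent under a 30-wide kernel (e.g. `1xTxC`); valid padding would be
  ill-defined there.
* **Pooling** halves the leading spatial axis (floor) and is skipped on
  an axis of extent 1 — required for the 3-channel montage after one
  halving and for every layout with a singleton leading axis.
* The dense head is a single fully connected layer; no hidden dense
  layers.

Starting the network with batch normalisation (and renormalising after
each convolution) is what lets raw, unscaled microvolt data be used
directly: each batch is standardised inside the model, which also damps
the covariate shift that non-stationary EEG exhibits across batches and
sessions.

### Implementation

The network is a self-contained numpy engine (`eegshapes.nn`):
channels-last layers with hand-derived analytic backward passes,
`[k × 1]` convolutions evaluated as a shift-and-sum of batched BLAS
matmuls (genuinely 2-D kernels fall back to im2col + GEMM), and Adam
with bias correction. Every backward pass is verified against central
finite differences at float64 (relative error < 1e-6 asserted; observed
~1e-10), and layer parameter counts are cross-checked against the closed
forms above for every layout. Inference is bit-deterministic; building a
model twice from the same (config, seed) yields identical weights.

## Training protocol

Only training material enters the fit: it is split per class into 80%
train / 20% validation (`round(count·fraction)`, at least 1, per class;
deterministic in the seed). Optimisation is minibatch categorical
cross-entropy. After each epoch the validation loss is recorded; if it
fails to improve its running minimum for 20 consecutive epochs (strict
improvement, no minimum delta), training stops and the weights — and
batch-norm running statistics — of the best epoch are restored. The test
set is touched exactly once, after fitting.

Unspecified hyperparameters were fixed at conventional values and
exposed in `TrainConfig`: Adam, learning rate 1e-3, batch size 64,
epoch cap 500 (50 in the scaled-down experiments below). Per-epoch
wall-clock times are recorded in the history and shown in reports as
informational only — they depend on the host and are never asserted.

## Evaluation statistics

All statistics derive from the integer confusion matrix (rows = true,
columns = predicted): accuracy = trace/total; per-class rates with
percentages rounded half-up to one decimal; macro-F1 = unweighted mean
over classes of the harmonic mean of precision and recall; Cohen's
kappa = (p_o − p_e)/(1 − p_e) with p_e from the marginals. Macro
averaging is used because it is the variant that reproduces the
published summary values from the published pooled counts. Subject-level
summaries report the mean and (population, by default) standard
deviation of per-subject accuracies. Two distinct accuracies exist at
the experiment level — the mean of per-subject accuracies and the
pooled-confusion-matrix accuracy — and reports label both rather than
conflating them (for the best layout on the 22-channel benchmark they
are 89.29 vs 89.35).

Known discrepancies in the published tables, kept out of assertions: the
printed per-layout STD values match neither the population nor the
sample standard deviation of the printed per-subject accuracies (their
provenance is unclear, so STD is reported but never compared), and one
printed F1 entry (3-channel benchmark, `Tx1xC`, 0.830) differs by 0.002
from the value implied by its own printed confusion counts (0.8318); the
consistency test for that single entry uses a 2e-3 tolerance, all other
thirty-one kappa/F1 entries reproduce to the printed three decimals.

## Synthetic motor-imagery generator

Real motor imagery manifests as event-related desynchronisation (ERD):
imagining a hand movement attenuates the 8–12 Hz mu rhythm over the
*contralateral* sensorimotor cortex. The generator reproduces exactly
that discriminative structure: each trial and channel is unit-RMS pink
noise (spectral density ∝ 1/f, shaped in the frequency domain) plus a
mu-band sinusoid (default 10 Hz) with an independent uniform random
phase per trial and channel. The sinusoid's RMS is `snr` times the noise
RMS; on the trial class's contralateral channels the amplitude is
multiplied by `1 − erd_depth`. Contralateral channel sets are inferred
from 10-20 electrode names (odd digits = left hemisphere, suppressed by
right-hand imagery; even = right; midline excluded) and can be
overridden. Defaults: `mu_freq_hz` 10, `erd_depth` 0.6, `snr` 1.0,
`noise_exponent` 1.0 — a moderately separable regime; the class signal
lives in a spatial-by-spectral *power* pattern, never in phase (random
phase prevents phase-locking shortcuts), so a classifier must integrate
power within channels and contrast across channels, the same demands the
real task poses.

What the generator deliberately omits: volume-conduction forward
modelling, ocular/muscular artifacts, inter-subject and inter-session
variability, beta-band dynamics, non-stationarity within a trial.
Passing tests therefore demonstrate that the pipeline can learn and
rank spatial-spectral structure under controlled conditions — not that
the published real-data accuracies are reproduced; those require the
original recordings and GPU-scale training and are out of scope by
design.

Two canned fixtures define the learnability bar on the 3-channel,
2-second (T=500 at 250 Hz) geometry with 200 training and 100 test
trials: **easy** (`erd_depth` 0.8, `snr` 2.0), which the `TxC` model
must classify above 85% held-out accuracy within 50 epochs, and
**hard** (`erd_depth` 0.1, `snr` 0.25), which must stay near chance
(accuracy in [0.4, 0.6], |kappa| ≤ 0.15). At these sizes a full fit runs
in roughly two to three minutes on one CPU core; T=1000 and the
22-channel montage remain available through `SynthConfig`.

## Problem sizes used in checks

The automated checks scale the experiment down, as the package's own
choice of desk-scale conditions: metric re-derivations use the published
nine-subject accuracy rows and pooled binary counts (593/590 and
1118/1123 trials per class) as fixed inputs; transform bijectivity runs
1000 random round-trips; the learnability runs use the fixture sizes
above with fixed seeds; synthetic-validity statistics use 50–100 trials
per class and five-seed ensembles for the ERD monotonicity check. The
acceptance script (`scripts/acceptance.py`) recomputes all of these from
scratch at run time.

## Design decisions that were genuinely open

* **Trial window**: the benchmark's epoch window is not pinned down by
  the published description; window length is configurable with a 4 s
  default (T=1000 at 250 Hz) for dataset-shaped configs, and the
  fixtures use 2 s to keep training fast.
* **Canonical orientation**: both `(T, C)` and `(C, T)` appear in the
  layout list; time-major `(T, C)` was fixed as the single source of
  truth from which all eight layouts derive.
* **Rank-2 vs rank-3 reading**: `TxC` and `TxCx1` would be the same
  tensor up to a trailing axis, yet they are distinct experimental arms;
  the only reading that distinguishes them — 1-D convolution with
  channels-as-features for rank 2, 2-D convolution over the first two
  axes for rank 3 — is the one implemented.
* **Early stopping "does not decrease"**: interpreted as strict
  improvement of the running minimum, with no tolerance delta.
* **Single-run reporting**: per-subject results are single runs with
  disclosed seeds, not averages over restarts.

## Known limitations

* CPU-only, float32; no GPU path. Large geometries (22 channels,
  T=1000) train slowly at desk scale.
* The generator's simplicity means layout rankings on synthetic data
  need not mirror rankings on real recordings.
* GDF import of the original competition recordings is out of scope; the
  HDF5 trial archive is the interchange point for anyone who converts
  them externally.
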