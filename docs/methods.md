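# Methods

## The decoding problem

A subject performing motor imagery (MI) produces event-related
desynchronization (ERD): imagining a specific movement attenuates the
band-limited mu (~8–12 Hz) and beta (~12.5–30 Hz) rhythms over a
class-specific subset of sensorimotor electrodes.  Given segmented trials
{(x_i, y_i)}, x_i ∈ R^{E×T} (E electrodes, T samples, microvolts), the task
is to predict the imagery class y_i ∈ {0, …, M−1}.  Decoding is
subject-dependent: train and test sessions come from the same subject.

## Architecture

The classifier is a compact three-stage CNN of the EEGNet family operating
on raw trials:

| stage | operation | output (time, space, maps) |
|---|---|---|
| 1 | temporal conv, F1 filters, kernel (K1, 1), same padding + BN | (T, E, F1) |
| 2 | depthwise spatial conv, kernel (1, E), multiplier D + BN + ELU + avg-pool (P1, 1) | (T/P1, 1, F1·D) |
| 3 | separable conv (per-channel K2 temporal + pointwise to F2) + BN + ELU + avg-pool (P2, 1) | (T/(P1·P2), 1, F2) |
| 4 | flatten → dense → softmax | M |

The flatten output — the *deep feature*, length T·F2/(P1·P2) — is both the
classifier input and the object of the center loss.  The temporal kernel is
kept short (K1 = 32 samples ≈ 8 Hz at 250 Hz) so stage 1 concentrates on
the mu/beta band.  Default hyperparameters: F1=8, F2=16, K1=32, K2=16, D=2,
P1=P2=8.

Numerical choices the architecture tables leave open: ELU α = 1; batch-norm
momentum 0.99 and ε = 1e-3; convolutions carry no bias (each is followed by
batch norm); "same" zero padding on the temporal and separable convolutions
(the only assignment consistent with the published length-preserving output
shapes); no dropout and no weight-norm constraints (the architecture table
lists neither).  Ties in the arg-max prediction resolve to the lowest class
index.  Weight initialization is Glorot-uniform from a seed.

Pooled lengths must be exact: building the network requires P1 | T and
P2 | (T/P1).  Note the standard configuration T=1000, P1=P2=8 has an
integral flatten length (250) but a non-integral second pooled length
(125/8); it is accepted as a config, reports feature length 250, and is
rejected at build time.  Benchmark configs use pooling that divides T.

### Why NumPy

The network, its backward pass, and the Adam optimizer are implemented
directly in NumPy.  The model is small (tens of thousands of parameters)
and the exactness of every gradient is verified against central finite
differences in the test suite, which also makes the training loop bitwise
reproducible from a seed with no framework-specific nondeterminism.

## Objective

With softmax probabilities q(y|x) and one-hot targets p, the combined
objective is

    L = L_cl + α_lsr · L_lsr + α_ct · L_ct

* **L_cl** — standard cross-entropy Σ_i H(p_i, q_i).
* **L_lsr** — label-smoothing regularization Σ_i H(u, q_i), u = 1/M.
  Equivalently one may train against smoothed targets
  p′ = (1−ε)p + εu with ε = α_lsr/(1+α_lsr); the identity
  H(p′, q) = (1−ε)H(p, q) + εH(u, q) ties the two parameterizations
  together and is enforced by tests to 1e-10.  ε is always derived from
  α_lsr so the two forms cannot disagree.
* **L_ct** — center loss ½ Σ_i ‖f_i − c_{y_i}‖², f_i the deep feature.
  Centers are model state, not parameters: gradients flow into features
  only, and after each optimizer step the centers of classes present in the
  batch take a damped step toward their batch mean,
  c_j ← c_j − λ · Σ_{i:y_i=j}(c_j − f_i)/(1+n_j), step λ = 0.5 by default
  (an update-per-epoch mode is also provided).  Centers start at zero.

Defaults α_lsr = α_ct = 0.5.  Losses reduce by batch mean by default (so
magnitudes are batch-size independent); a sum mode exists for checking the
printed per-trial identities.  Probabilities are floored at 1e-12 inside
logarithms.

Training: Adam (0.9/0.999, ε=1e-8), learning rate 1e-3, batch 64, 750
epochs by default; per-epoch records of every loss term and of train/test
accuracy (test metrics in inference mode, used for monitoring only — no
early stopping or model selection; the final-epoch model is reported).
Batch size 1 is rejected because batch statistics need two samples; a final
short batch is kept unless it has a single trial.

## Synthetic ERD generator

Trials are simulated as class-modulated rhythms over noise, per channel e:

    x_e(t) = (1 − ρ·P[y, e]) · A · [sin(2π f_mu t + φ_e) + 0.5 sin(2π f_beta t + ψ_e)]
             + pink noise + white noise

* P is an M×E spatial-pattern matrix in [0,1]: each class attenuates a
  distinct channel subset (affected weights in [0.6, 1], rest in [0, 0.2]).
  The pattern matrix is the simulated subject's identity — train and test
  sessions of one subject share `pattern_seed` while drawing independent
  phases and noise.
* ρ ∈ [0,1] is the ERD depth and the single separability dial; ρ = 0 makes
  trials class-independent by construction (chance-level decodable).
* ERD is multiplicative amplitude attenuation, not an additive template, so
  the class signal lives in band power, matching MI physiology.
* Pink noise is generated by inverse-FFT spectral shaping (power ∝ 1/f),
  normalized to unit variance per channel; white sensor noise is added
  independently per sample.
* Defaults: 250 Hz, f_mu = 10 Hz, f_beta = 20 Hz, rhythm amplitude 10 µV
  over a 5 µV pink + 2 µV white floor — a realistic sensorimotor-rhythm to
  background ratio.
* Optional label noise reassigns exactly round(frac·n) labels (chosen
  without replacement) to a different class *after* signal generation, so
  the signals still reflect the original class: mislabeled data.
* One shared generator per dataset, consumed in trial order; everything is
  determined by the seed.

What the generator does **not** emulate: volume conduction / electrode
leakage, ocular and muscular artifacts, session-to-session nonstationarity,
and within-class amplitude variability beyond phase and noise.  Passing the
synthetic benchmarks therefore demonstrates that the pipeline recovers
band-power class structure and that the regularizers act as designed — not
that recorded-EEG accuracies would be matched.

## Benchmark conditions

The end-to-end benchmark (in `erdnet.benchmarks`) is one simulated subject:
2 classes, 8 channels, T = 500 samples at 250 Hz, 100 training and 50 test
trials per class, ρ = 0.8, trained 60 epochs with Adam 1e-3, batch 32.  The
matching architecture keeps the default filters/kernels with pooling
(P1, P2) = (10, 5) (divides 500; feature length 160).  These sizes keep a
full training run under a minute on one CPU while leaving the task
unambiguous: the decoder reaches ≥ 90% test accuracy, and the same pipeline
on a ρ = 0 subject stays inside the 95% binomial band around chance.

The generalization (label-smoothing) benchmark injects 10% label noise into
the same training session and trains both a plain-cross-entropy and a
smoothed (α_lsr = 0.5) model for 200 epochs — long enough for the baseline
to fully memorize the mislabeled trials (training accuracy reaches 1.0 by
roughly epoch 150).

A caveat the package measures rather than hides: under this *stationary*
generator with a clean test session, memorizing mislabeled trials does not
make the baseline confidently wrong on test data — its test cross-entropy
stays near the calibration it had before memorization, while the smoothed
model's test cross-entropy is bounded below by the confidence cap smoothing
itself imposes (≈ −log[(1−ε) + ε/M] per correct trial, ≈ 0.18 at
α_lsr = 0.5, M = 2).  The learning-curve pathology that label smoothing
repairs on recorded EEG — test loss rising over training while training
loss falls — depends on test trials that are ambiguous or shifted relative
to training (session nonstationarity, low SNR), which this generator
excludes by design.  The corresponding end-to-end assertion in the test
suite encodes the expected contrast and is expected to fail under the
synthetic conditions; the acceptance script reports both cross-entropies so
the comparison is always visible.

## Evaluation machinery

* `accuracy` — percent agreement.
* `paired_ttest` — classical paired t on per-subject accuracy vectors,
  n−1 df, two-sided p; zero-variance differences are a degenerate-input
  error.
* `pca_project` — covariance PCA (centered, unstandardized) of the deep
  features to 2-D for display; component signs fixed so each axis's
  largest-magnitude loading is positive.
* `class_dispersion` — the quantitative form of the "compact and
  separated" feature-geometry claim: intra-class variance (mean over
  classes of mean squared distance to the class centroid) and mean pairwise
  centroid distance.  Computed on raw features, never on the PCA
  projection, which discards variance and would bias the comparison.

## Known limitations

* The GDF reader for competition recordings is a thin optional path,
  exercised only when local files exist; epoch counts follow the event
  table rather than asserted session sizes.
* The generator's stationarity means cross-session effects (the main
  challenge of real subject-dependent decoding) are out of scope.
* Training is single-threaded NumPy: ~0.5 s/epoch on the benchmark — fine
  for the benchmark scale, not intended for 1000-sample, 22-channel,
  750-epoch runs, which the same code performs correctly but slowly.
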