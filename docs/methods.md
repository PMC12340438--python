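# Methods

## Model

The network classifies fixed-length single-channel EEG segments
`X ∈ R^{B×L}` as seizure / non-seizure through three stages.

**Dynamic frequency selection.**  `F = rfft(X)` gives the one-sided
spectrum with `N = L/2 + 1` unique bins (bin `k` is `k·fs/L` Hz).  The
amplitude spectrum `A = |F|` feeds a two-layer perceptron
`S = W2·ReLU(W1·A + b1) + b2` (hidden width 64 by default) whose logits are
relaxed into a per-sample probabilistic mask by the Gumbel-SoftMax,

    w_{b,k} = exp((s_{b,k} + g_k)/τ) / Σ_j exp((s_{b,j} + g_j)/τ),

with `g ~ Gumbel(0,1)` redrawn every training step and set to zero at
inference (a plain softmax), and fixed temperature τ (default 1.0).  The
mask multiplies the complex coefficients elementwise — phase is untouched —
and the inverse real FFT returns a filtered signal of the original length.
Soft relaxation is the default; a straight-through hard (one-hot) mode
exists behind `hard_mask`.  Noise is drawn independently per batch row by
default; `shared_noise` draws one vector per frequency bin instead.

**Multi-scale temperature-controlled attention.**  The filtered signal is
average-pooled (non-overlapping windows, kernel `k_i = L/s_i`) to the scale
list (default full/half/quarter length), each scalar timestep is embedded to
width `D` by a per-scale affine map, and each scale runs multi-head
self-attention sharing one QKV projection across scales.  Head `h` divides
its scores by a learnable temperature `τ_h = exp(λ_h)`; `λ_h` starts at
`ln(D/H)` so the initial divisor equals the head width, playing the role of
the conventional `√d_k` factor, which is otherwise absent.  No positional
encoding, residual path, normalisation layer or dropout is used — the
architecture is exactly attention over embedded pooled amplitudes.
Scales must divide `L`; `allow_interpolation` switches to adaptive
(variable-window) pooling for scales that do not.

**Phase-aware fusion and head.**  A hybrid kernel
`K = softmax(α·tanh(W_b) + (1−α)·K₀)` (length 15, `K₀` a centre impulse,
α learnable in [0,1] via clamping, init 0.5) is slid over the
replicate-padded filtered signal; the similarity profile, softmaxed over
time, re-weights the signal.  This enhanced signal is pooled and embedded to
each scale (the subtraction in the phase estimator requires matching
shapes), a two-layer tanh network maps the difference between attended
features and aligned enhanced signal to a signed per-timestep offset `ΔP`,
and `Γ = sigmoid(ΔP)` convexly blends the two streams.  Per-scale fused
features are mean-pooled over time, concatenated, affinely projected to two
logits and softmaxed.  `head_reduction: flatten` keeps every timestep
instead of the temporal mean.

**Ablation variants.**  `AB1` removes the spectral-selection stage (raw
signal enters the pyramid), `AB2` removes the multi-scale stage (one
attention branch at full resolution), `AB3` removes the fusion stage
(attended features go straight to the head).  At most one stage may be
ablated at a time; each variant has strictly fewer parameters than the full
model.

## Training

Cross-entropy with Adam (lr 1e-3, batch 32); epochs default to 30, the
benchmark uses 20.  Splits are stratified 80/20 by label.  The benchmark
enables inverse-frequency class weights: at 10 % seizure prevalence an
unweighted objective tolerates false negatives that are unacceptable for a
sensitivity-critical detector.  All randomness (splits, shuffling, Gumbel
noise, parameter init) flows from one integer seed; identical seeds give
bitwise-identical histories.

Two rescaling options exist for numerical comfort and are enabled in the
benchmark configuration: `mask_gain` multiplies the mask by `N` and
`scale_preserving` multiplies the time-attention by `L`.  Both are global
scalar factors — the literal normalisations (mask rows and attention rows
each summing to 1) shrink activations by `1/N` and `1/L` respectively, which
downstream affine maps must otherwise absorb.  Neither changes the
normalised form of any mask or attention distribution.  The frequency
scorer's output layer is initialised near zero so the initial mask is
near-uniform; amplitude-scaled logits would otherwise saturate the softmax
at an arbitrary bin and stall its gradients.

## Autodiff engine

The package includes a small tape-based reverse-mode engine on numpy
(`seiznet.autograd`): elementwise arithmetic with broadcasting, batched
matmul, reductions, shape ops, activations, fused softmax/log-softmax, a
real-FFT pair whose adjoints are expressed through the inverse transform
(`dx = L·irfft(g/w)` with `w` the two-sided bin multiplicity), and a
replicate-padded sliding correlation.  Every operation is verified against
central finite differences in the test suite.  Tensors preserve dtype; the
model runs float32 by default (float64 via `ModelConfig.dtype`).

## Synthetic benchmark

The generator produces pink-noise (`1/f^β`, β=1) backgrounds with a weak
10 Hz rhythm; seizure segments add Hann-windowed oscillatory bursts drawn
uniformly from a configurable band (default 3–8 Hz, amplitude `snr` × the
background sd) and, optionally, sparse biphasic spike transients
(~40 ms derivative-of-Gaussian).  Labels are allocated exactly
(`round(prevalence·n)` positives) and the manifest (config + seed)
regenerates a dataset bit for bit.

The benchmark geometry is a scaled-down mirror of the study conditions so a
multi-seed experiment fits in CPU minutes: half-second segments (L=128 at
256 Hz), scale pyramid 128/64/32 (identity kernel at the top scale,
mirroring the full/half/quarter structure of 1228/614/307), embedding width
32, four heads, n=480 segments at 10 % prevalence, 20 epochs.  Two
signatures serve different experiments:

* **band** — bursts only at high snr (4.0).  The planted band carries the
  whole class signal, giving the learned mask a ground truth and making
  classification a pure band-detection task.
* **mixed** — bursts plus spikes at moderate amplitudes (snr 2.0, spike
  amplitude 2.0).  The difficulty is calibrated so a trivial band-power
  threshold classifier scores ≈ 0.89 rather than 1.0: ablations can only
  show visible degradations on a benchmark that is not already at ceiling.

What passing tests on this data do and do not show: the generator matches
the *statistical* structure the architecture targets (class-dependent band
power and transients over a 1/f background) but not real EEG's
nonstationarity, inter-patient variability, channel montage effects or
artifacts, so synthetic results demonstrate mechanism correctness, not
clinical performance.

## Evaluation protocols

Metrics come from the confusion counts (`Acc`, `Sens`, `Spec`,
`F1 = 2TP/(2TP+FP+FN)`); the positive class is an explicit argument
(default: seizure).  Repeated train/test cycles form run sets compared by a
two-sided paired t-test (`t = d̄/(s_d/√R)`, Student t with R−1 df;
zero-variance nonzero-mean differences report an infinite statistic with
p=0).  The mixed-split protocol merges datasets, reshuffles globally 20
times at an 8:2 ratio and reports per-repeat metrics with mean ± sd.  The
sensitivity sweep varies one parameter at a time over the study grids
(τ ∈ {0.1, 0.5, 1, 2}; coarse/baseline/fine scale lists; heads {2, 4, 8};
α ∈ {0.3, 0.5, 0.7}), records invalid configurations as failed rows (the
fine scale list deliberately contains scales that do not divide L), and
stamps every row with the hash of the non-swept keys.

## Known limitations

* **The per-sample mask admits an "energy coding" optimum.**  Because the
  frequency scorer sees the amplitude spectrum of the very sample it masks,
  gradient descent can make the scorer itself act as the classifier: it
  routes high-energy bins for one class and near-empty bins for the other,
  encoding the label in downstream signal energy instead of statically
  selecting the seizure band.  On synthetic data whose amplitude spectra are
  cleanly separable this solution dominates — freezing a static in-band mask
  reaches slightly lower accuracy than the learned code — so the trained
  mask need not concentrate on the planted band even when classification is
  near-perfect.  Interpretability claims about the mask therefore require
  checking it against a band-restricted control, which the benchmark's
  band-recovery measurement automates.
* On clean synthetic backgrounds the spectral-selection stage has little to
  suppress, so removing it (AB1) can cost nothing or even help slightly;
  its value shows on data with nuisance spectral content.
* Attention is O(s²) per scale; the full study geometry (L=1228) trains,
  but slowly on one CPU — the benchmark geometry exists precisely to keep
  multi-seed experiments affordable.
* Single-channel only; no positional encoding (literal architecture); the
  "phase" is a learned scalar offset, not an analytic instantaneous phase.
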