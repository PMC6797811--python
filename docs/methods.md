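# Methods

`pulsecnn` implements a complete pulse-wave-pattern classification (PWPC)
study on synthetic data: cohort simulation, signal preprocessing into
cycle images, rule-based subject screening under two classification
criteria, a small convolutional classifier, and confusion-matrix
evaluation. This note records the models, the parameters that matter, and
the design decisions taken where the procedure was genuinely open.

## Synthetic pulse model

A single arterial pulse cycle is modelled as a superposition of three
Gaussian bumps on the unit interval — the classical decomposition of a
radial pressure pulse into a **percussion wave** (main systolic peak), a
**tidal wave** (late-systolic reflection) and a **dicrotic wave**
(diastolic rebound):

    p(t) = Σ_k a_k · exp( −(t − c_k)² / (2 w_k²) ),   t ∈ [0, 1)

Each pattern class fixes mean `(a_k, c_k, w_k)` triples; per-cycle jitter
multiplies amplitude, center and width by independent `1 + σ·N(0,1)`
factors, reproducing the within-class "local time shifting" that defeats
template matching. Two structural constraints keep the model
physiological:

* **Onset alignment.** A pulse cycle starts, by definition, at the foot of
  the systolic upstroke. Every percussion component therefore satisfies
  `c = 0.02 + 2.3 w` (the rise of a Gaussian becomes detectable about 2.3
  widths before its center), and the percussion jitter re-ties the center
  to this onset after the width draw. Beat-to-beat variability widens or
  delays the peak but never moves the start of the rise; without this the
  nominal cycle boundary is not recoverable from the waveform to within a
  few samples, for any detector.
* **Edge decay.** All components decay to near zero at both cycle edges so
  concatenated cycles join continuously.

Records concatenate `n` jittered cycles (duration 0.8 ± 0.08 s at
fs = 100 Hz, so a raw cycle has ~80 samples and the 200-point resampling
genuinely interpolates), then add white Gaussian noise with standard
deviation expressed as a fraction of the clean signal's RMS
(`noise_sd = 10^(−SNR/20)` targets an SNR in dB) and a 0.3 Hz sinusoidal
baseline wander scaled to the clean peak. Cohort defaults are
`noise_sd = 0.05` (26 dB) and wander 0.05.

Two class families are provided. The six disease-based patterns (H1
healthy, Hn hypertension, At atherosclerosis, Ha hyperlipidaemia, Td type 2
diabetes, HCA hypertension complicated by atherosclerosis) have clearly
distinct mean morphologies with modest jitter (5%/3%/5% on
amplitude/center/width). The five parameter-based patterns (H2 healthy,
BP, CAVI, baPWV, BV) deliberately share a near-common stiffened morphology
whose between-class differences are comparable to the within-class jitter
(12%/5%/10%): a single out-of-range physiological parameter perturbs local
waveform features only, so these classes interfere. The class means are
design defaults of this generator — qualitative morphology, not
measurements — and the expected experimental signature is *relative*:
disease-based classification should be easy, parameter-based classification
measurably harder.

Cohort subjects carry disease labels and four physiological parameters
(blood pressure mmHg, CAVI, baPWV cm/s, blood viscosity) drawn uniformly
from in-range or out-of-range bands consistent with their intended pattern
(e.g. a BP-pattern subject is out of range in blood pressure only).
Comorbid subjects ("Td+Hn", "diabetic foot", ...) exist to be excluded by
screening.

### What the generator does not emulate

No Windkessel or transmission-line hemodynamics, no device-specific
artefacts, no age/height/weight covariates, no intra-subject drift. Cycles
within a subject are exchangeable draws. A classifier accuracy obtained on
these data therefore validates the *pipeline* (preprocessing geometry,
training loop, evaluation arithmetic) and the relative difficulty of the
two class families; it says nothing about accuracy on clinical recordings.

## Preprocessing

1. **Denoising.** Wavelet thresholding: `db4` decomposition at level
   `ceil(log2(fs/8))` (4 at 100 Hz), soft universal threshold
   `σ·sqrt(2 ln n)` on all detail bands, σ estimated from the
   finest-band median absolute deviation. The approximation band is left
   untouched; slow drift is removed later by per-cycle normalization.
2. **Segmentation.** The cycle period is estimated from the first
   prominent autocorrelation peak in the 0.3–2.5 s lag band (taking the
   first peak ≥ 50% of the best avoids locking onto 2× / 3× harmonics).
   Systolic upstrokes are slope maxima at least 15% of the global maximum
   slope, with closer-than-0.6-period candidates suppressed in favour of
   the steeper one — this discards dicrotic upslopes, which sit within
   0.6 period of a percussion upslope on at least one side. Each foot is
   then the point, on a Savitzky–Golay(9, 2)-smoothed trace, where the
   signal last crosses 10% of the local pulse height above the preceding
   valley baseline (10th percentile of the look-back window), with
   sub-sample interpolation; when the record starts inside the first
   upstroke the window minimum is used instead. Measured against generator
   ground truth at 20 dB SNR, ~99% of feet land within ±3 samples. A
   simpler "window argmin before the upstroke" rule was tried first and
   biased feet 5–10 samples early, because the diastolic valley is flat
   and its minimum under noise is essentially uniform over the flat span.
3. **Resampling.** Piecewise-linear interpolation of each foot-to-foot
   cycle onto exactly 200 uniform points (monotone, exact on ramps, no
   ringing; endpoints preserved exactly).
4. **Normalization.** Affine map of each cycle onto [0, 200]
   (min → 0, max → 200, pinned exactly against float rounding); constant
   cycles are rejected as degenerate.
5. **Rasterization.** 200×200 8-bit image, background 0, curve 255, row 0
   at the top: column `x` carries the curve at row `199 − round(v_x)`
   (round half-up; rows clipped to the grid since 201 amplitude levels map
   onto 200 rows). Connectivity fills run strictly *downward* from each
   column's own pixel toward the lower neighbour, so the trace is
   8-connected, every column holds one contiguous run, and the topmost
   foreground row of every column encodes that column's value exactly —
   extracting it inverts the rasterizer to within the ±1 rounding bound.
   Grayscale connected-curve rendering is a declared convention, not a
   claim about how any particular device renders pulse images.

## Screening

Criterion 1 (diseases): exactly one study disease → its pattern
(Hn/At/Ha/Td); hypertension+atherosclerosis and nothing else → HCA; no
diseases → H1; anything else (other comorbidity, out-of-vocabulary
disease) → excluded. HCA subjects must have no third condition.

Criterion 2 (parameters): out-of-range means systolic > 140 **or**
diastolic > 90 mmHg (the standard hypertension reading of ">90/140"),
CAVI > 9.0, baPWV > 1400 cm/s, viscosity > 5.0 — all strict inequalities.
Exactly one out → that parameter's pattern; none → H2; two or more →
excluded.

After per-subject decisions, any pattern with ≤ 20 kept subjects ("more
than 20" read strictly) is dropped wholesale, its subjects re-marked with
reason `class_too_small`. A pluggable quality gate can reject subjects
whose records fail basic integrity before pattern assignment; the default
pipeline applies none because the generator does not produce corrupted
records.

## Dataset assembly

Exactly 210 distinct cycles per pattern, drawn uniformly without
replacement when more are available, split 140 training / 70 test
uniformly at random per pattern with a fixed seed. The split is by
*cycle*: a subject may contribute to both halves, and the resulting
subject-leakage fraction is computed and logged. This mirrors the study
design being reproduced; a subject-wise split would be the stricter
protocol and the builder's pools make it easy to implement, but it is not
the default because the contract is per-cycle.

## Classifier

A 10-layer CNN: three convolution layers (ReLU), each followed by 2×2/2
max pooling, dropout between the third pool and the first fully connected
layer, two fully connected layers, softmax output on 1×200×200 inputs.
Loss is categorical cross-entropy (implied by the softmax output);
activations are ReLU; both are standard for this family and exposed in
the architecture config. Reference hyperparameters: conv 5×5 stride 1
same-padding with 16/32/64 channels, hidden width 128, dropout 0.5. A
LeNet-style baseline (6/16/32 channels, hidden 84, no dropout) is
expressible in the same schema.

Training: mini-batch Adam with learning rate 0.001, ρ1 = 0.9, ρ2 = 0.999,
stability constant δ = 1e−8, batch 64, reference budget 100 epochs. The
source procedure lists both an ε = 0.001 and δ = 1e−8 although Adam has a
single stability constant; δ is used in the update and ε is stored
verbatim as `epsilon_reported` without guessing its role. Each epoch
records the mean training loss ("cost"), the training error and the test
error, both measured by a dedicated evaluation-mode pass (dropout off), and
the weights minimising test error are checkpointed. Selecting the model on
the test set conflates model selection with evaluation — there is no
separate validation split in this protocol; the reproduction keeps the
procedure as specified and flags it here.

Everything is numpy: convolution as im2col + GEMM (backward via 25
strided accumulations per 5×5 kernel), non-overlapping max pooling with an
argmax scatter, inverted dropout, explicit Adam moments. All randomness
(He-init, shuffling, dropout) flows from `numpy` generators spawned from
one seed, so runs are bit-reproducible; ties in `argmax` predictions break
toward the lowest class index.

## Evaluation

Rows of the confusion matrix are true classes, columns predictions. Per
class: precision TP/(TP+FP), recall TP/(TP+FN), F = 2PR/(P+R). Overall
accuracy is trace/total; overall precision/recall/F are reported both as
unweighted class means (macro) and in micro form — on the balanced test
sets used here macro recall equals accuracy, so the two conventions are
indistinguishable, and both are written to the machine-readable output.
Division by zero (a class never predicted or absent) yields 0 with an
explicit flag. Human-readable tables round half-up to two decimals;
machine-readable files keep full precision.

## Experiment sizes and defaults

The packaged experiment (`pipeline.run_experiment`, also behind the CLI
`run` command) uses 22 subjects per pattern × 12 cycles each (≥ 210 cycles
per pattern with margin), the criterion-1 comorbid mix (4+3+5+8 subjects)
for the disease data set, and a compact instance of the 10-layer
architecture (channels 6/12/24, first conv stride 2, hidden 48, dropout
0.5) trained for 10–30 epochs. The compact instance keeps a full
six-class run in the minutes range on a single CPU core; the experimental
conclusions (disease-based patterns learned to ≥ 0.9 test accuracy within
a few epochs, parameter-based patterns scoring far lower under the same
budget, with the healthy class nearly perfect and the four parameter
classes confusing each other) are insensitive to the channel widths, which
remain configurable up to the 16/32/64 reference.

## Known limitations

* Synthetic waveforms only; see the generator caveats above.
* Best-on-test checkpointing inherits the protocol's selection bias.
* The binarised curve image discards everything but shape; amplitude and
  rate information is lost by design, as in the study being reproduced.
* Non-overlapping pooling and odd-size clipping are the only pooling
  variants implemented.
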