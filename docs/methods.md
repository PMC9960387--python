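# Methods

This note documents the models and procedures implemented in `edapain`, the
assumptions behind the synthetic electrodermal activity (EDA) generator, the
parameters that matter, and the numerical choices made where the design was
genuinely open.

## Problem setting

Heat-pain studies record skin conductance (µS) in short stimulus-locked
windows and ask whether a window belongs to a "no pain" or "high pain"
condition. Two acquisition geometries are emulated throughout:

* 87 subjects x 5 intensity labels x 20 repetitions, 5.5 s windows at
  512 Hz (2816 samples);
* 52 subjects x 6 labels x 8 repetitions, 10 s windows at 250 Hz
  (2500 samples).

All evaluation is subject-independent: leave-one-subject-out (LOSO)
cross-validation, with headline accuracy reported as the unweighted mean
± SD over subjects and the pooled accuracy (cumulative confusion matrix)
alongside. The pooled accuracy equals the window-weighted mean of the
per-subject accuracies — an identity the test suite asserts.

## Synthetic EDA generator

No generative model for EDA is fixed by the analysis itself; the generator
is a stand-in whose obligations are the qualitative contrasts the analysis
relies on, not a biophysical simulation. Each window is

```
x(t) = SCL + drift * t + wander(t) + evoked(t) + spontaneous(t) + noise(t)
```

clipped to a 0.01 µS conductance floor.

* **Tonic level and drift.** Baseline SCL ~ U(2, 12) µS per subject; resting
  drift ~ N(-0.005, 0.003) µS/s — resting skin conductance declines slowly.
* **Slow wander.** A partial arc of a 20-50 s oscillation with amplitude
  ~|N(0, 0.05 µS)|, anchored at zero at window start. Without it, synthetic
  no-pain windows are implausibly clean and any variance-type feature
  separates the classes perfectly, which real recordings do not support.
* **Evoked response.** A unit-peak Bateman (difference of exponentials)
  pulse, tau_rise 0.75 s, tau_decay 4 s, scaled by an amplitude drawn per
  window (mean per label: 0 to 0.5 µS monotone across intensities, CV 0.25)
  and by a per-subject amplitude scale ~ lognormal(0, 0.7). The pulse peak
  lands 3-6 s post-stimulus when the window permits, otherwise within
  [0.3, 0.6] of the window. Alongside the pulse, an evoked window adds a
  saturating tonic recruitment ramp, `2.5 * amplitude * (1 - exp(-dt/6 s))`,
  which does not recover within the window: sustained noxious stimulation
  raises the skin conductance *level*, and stimulus-locked pain windows keep
  rising rather than returning to baseline. Setting `tonic_gain = 0` gives a
  pure-pulse response.
* **Spontaneous SCRs.** Poisson count per window (rate 0.2, identical in
  every label — SCRs are not specific to pain) with amplitudes
  U(0.05, 0.3) µS, pure pulses. These double as data augmentation: forests
  trained with them learn that the mere presence of an SCR is not pain.
* **Non-responders.** With probability 0.1 a subject's amplitude scale is 0:
  no evoked or spontaneous phasic activity at all.
* **Noise.** White Gaussian, SD 0.01 µS.

What the generator does **not** emulate: motion artifacts, electrode drift
or detachment, multi-peaked compound SCRs, habituation across repetitions,
inter-channel physiology (ECG/EMG/respiration), and any dependence of the
spontaneous rate on arousal. Passing tests therefore show that the pipeline
recovers the intended structure *under these conditions*; they do not certify
performance numbers on real recordings.

### Desk-scale study conditions

The default benchmark is 50 subjects x 2 labels (no pain / high pain) x 4
repetitions at 32 Hz and 10 s windows (400 windows). These sizes keep the
full pipeline — feature extraction, LOSO forests, full recursive feature
elimination and CNN training — at single-CPU desk scale while leaving all
qualitative contrasts assertable.

## Hand-crafted features

Features are computed on the **raw** trace (no resampling or smoothing).
The registry covers plain statistics (extrema and their 1-based first-
occurrence indices, first/second-difference statistics, IQR, RMS, last-minus-
first difference, statistics of the min-max-normalised trace), tonic/phasic
summaries, SCR event statistics, a 20-point resampled derivative of the
phasic component (dPhEDA), and a 5-point band-limited sympathetic-tone
envelope (TVSymp) plus a variant computed on the final half-window
(MTVSymp).

Numerical choices:

* **Tonic/phasic decomposition** is a moving minimum over 4 s followed by a
  centered moving average over the same span; phasic is the residual, so
  additivity is exact by construction. The estimator is deliberately simple
  and pluggable; the convex-optimisation decompositions used in parts of the
  literature are not required for any contract here.
* **SCR detection**: strict local maxima of the phasic trace; onset is the
  nearest preceding strict local minimum (or the first sample); events under
  0.01 µS are discarded. Half-recovery (recovery) is the time from peak
  until the trace falls below onset + amplitude/2 (x 0.37), left missing
  when the window ends first. Event statistics over an empty list impute 0
  so the feature matrix is dense.
* **TVSymp** z-scores the input, band-passes 0.08-0.24 Hz (2nd-order
  Butterworth, zero-phase) and takes the analytic-signal envelope, resampled
  to 5 points. This is a band-limited-envelope surrogate for variable-
  frequency complex demodulation; it preserves the band-selectivity contract
  (an in-band sinusoid scores higher than an out-of-band one) but is not the
  published estimator. The input is z-scored (rather than the envelope)
  so the mean of the index reflects in-band energy.
* **"Variation of the first and second moment"** is interpreted as the
  variance of the first and second differences.
* Tie-breaks: argmax/argmin take the first occurrence, 1-based.

## Boolean pain rules

Four training-free, single-feature classifiers decide high pain by strict
inequalities: `x_1 < x_l`; 1-based argmax beyond 7/10 of the window;
argmax - argmin (signed) beyond l/4; positive sum of the discrete
derivative (x'_1 = 0, x'_i = x_i - x_{i-1}). The derivative telescopes to
`x_l - x_1`, so the first and fourth rules are the same classifier — the
test suite asserts the identity on a thousand random windows (away from
exact start == end ties, where only floating-point rounding decides the
derivative sum's sign). All four rules depend only on the ordering of
values, hence are invariant under strictly increasing transforms; they are
evaluated on raw windows, and boundary cases reject pain.

## Random forest, importance, RFE

The binary task is pair-encoded as two regression outputs, (1,0) and (0,1);
a 100-tree random-forest regressor (MSE impurity, min_samples_split 2,
unlimited depth, bootstrap) is fit and a window is classified by the larger
of the two averaged outputs, with exact ties going to "no pain".

Impurity importance is mean decrease in impurity: per internal node j,
`n_j = w_j C_j - w_left C_left - w_right C_right` with C the node MSE and w
the weighted sample fraction; per feature, the sum of n_j over its split
nodes, normalised to sum to one per tree and averaged over trees. Fitting
and prediction are delegated to scikit-learn; the importance is computed by
this package's own traversal of the fitted trees and is cross-checked
against scikit-learn's `feature_importances_` in the tests.

Recursive feature elimination runs inside the LOSO loop: per iteration the
forest is fit on every fold, importances are averaged across folds, the
least important feature is dropped (ties break toward the earlier registry
column) and the pooled LOSO accuracy is recorded, down to one feature. The
RFE forest defaults to 40 trees to keep the full curve (66 features x 50
folds per iteration) tractable; the comparison between full-feature and
best-subset accuracy is internal to one configuration, so the tree count
cancels out of the conclusion.

## Neural classifiers

Implemented in plain numpy with explicit backpropagation:

* **MLP**: flatten -> dropout + dense(250, ReLU) -> dropout + dense(100,
  ReLU) -> dense(2) + softmax.
* **CNN**: three blocks of same-padded temporal convolution (32/64/128
  filters, kernel 8), ReLU, max pooling (8), dropout (0.2); then flatten ->
  dense(2) + softmax. Inputs are resampled to 256 Hz, min-max normalised
  per window and smoothed with a 1 s moving average, in that order.

Training: softmax cross-entropy, Adam, batch 32, learning rate 1e-4,
seeded shuffling and dropout; 100 epochs in the full profile, 20 in the
desk profile. He-initialised weights; training is bit-reproducible for a
fixed seed in single-threaded execution.

Design notes on parameters that were genuinely open:

* The appendix-level layer tables of the original architectures are not
  available; filter counts (32/64/128), pool size 8 and dropout 0.2 are
  declared defaults. The temporal kernel defaults to 8: with kernel 16 the
  receptive field at the last convolution spans roughly 4 s of signal and
  Grad-CAM attribution smears well past the rising segment it should credit;
  kernel 8 halves the receptive field and localises attribution without any
  measurable accuracy cost.
* The pipeline keeps the 256 Hz resample rate even at desk scale: at lower
  rates the third pooling collapses the time axis to a single position, the
  classification head becomes position-blind, and class-conditional
  attribution degenerates.
* The hybrid pathway exports the activations feeding the softmax (the
  flatten output for the CNN, the 100-unit layer for the MLP) as a feature
  matrix for the forest/RFE machinery.

## Grad-CAM and slope-masked class importance

For window x and class c, the channel weights are the time-averaged
gradients of the pre-softmax class score with respect to the last
convolutional feature maps, `a_k = mean_t dy_c/df_k(t)`; the saliency map is
`ReLU(sum_k a_k f_k)`, linearly upsampled to the input length (endpoints
pinned). The averaging constant is the global mean over the feature-map
axes; the normalised slope scores below are provably invariant to this
constant, so the choice cannot affect results. Gradients are exact
backpropagation and are verified against central finite differences in the
tests (away from max-pooling ties, where only subgradients exist).

The slope masks come from the discrete derivative of the model-input trace:
g+ flags positions with x' > 0, g- the complement (position 1 is always
falling since x'_1 = 0). Per window, the saliency mass over rising and
falling positions is `w+ = L_c . g+` and `w- = L_c . g-`; masses are summed
over windows and normalised per class, `w+_norm = w+ / (w+ + w-)`.

Aggregation follows the classification outcome: a window contributes to
class c's score only if the model assigns it class c (modes aggregating all
windows, or only correctly classified ones, are available). Aggregating
saliency toward a class over windows the model assigns to the *other* class
dilutes both scores toward 0.5 — on synthetic data the toward-no-pain maps
on pain windows carry mass comparable to the no-pain windows themselves —
so outcome-bucketed aggregation is the default. If a class's total saliency
is exactly zero the normalised weights are reported as missing, with a
warning.

## Known limitations

* The generator's distributional choices are stand-ins; effect sizes were
  chosen so the documented qualitative contrasts hold, and absolute
  accuracies on synthetic data should not be read as predictions for real
  recordings.
* The TVSymp/MTVSymp implementation is a surrogate (see above), and the
  "modified" variant (final half-window) is a declared placeholder.
* The numpy CNN is adequate for desk-scale experiments but makes no claim
  to GPU-scale performance.
* Grad-CAM attribution at the last convolution has coarse temporal
  resolution (one raw saliency point per pooled position) and inherits the
  usual caveats of gradient-based attribution near ReLU/max-pool
  nondifferentiabilities.
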