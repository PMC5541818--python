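# Methods

## The problem

In a rapid serial visual presentation (RSVP) target-detection task, images
flash at a fixed screen location at 4 Hz while EEG is recorded; a rare
*target* image elicits a P300 — a positive event-related deflection over
centro-parietal electrodes roughly 300–500 ms after onset. Detecting targets
from a *single* trial is noisy. The multi-RSVP idea trades screen space for
repetitions: the same image sequence is replayed on a second (and third)
stream after a fixed delay, the observer's gaze follows a detected target
from stream to stream, each viewing elicits its own P300, and the per-stream
interest scores of one image are averaged. This package implements the full
framework — scheduling, gaze protocol, synthetic EEG, preprocessing, two
single-trial classifiers, score fusion, evaluation, and the analytic model
of targets lost while the gaze is in transit — so that every claim can be
tested end to end on simulated data.

## Stimulus schedules and the gaze protocol

A session is 10 blocks of 200 images (2000 images, 200 targets; target
probability 0.1). Stream delays default to 750 ms steps — 3 frames at 4 Hz —
so the right stream lags the base (left) stream by 3 frames and the bottom
stream by 6. Targets are placed uniformly at random within each block
subject to a minimum frame gap between consecutive targets; the draw uses
the standard combination bijection onto gap-feasible placements, so it is
exactly uniform and needs no rejection loop. The gap constraint also binds
across block boundaries.

The gaze model is deterministic: the observer fixates the left stream;
an attended target triggers a dwell on the right stream until the same
image reappears there (3 frames), then — triple-RSVP — on the bottom stream
(3 more frames), then a refixation travel of `refixation_frames` (default 3)
back to the left stream during which nothing is perceived. An image is
*missed* when none of its presentations falls on an attended stream. Per
isolated diversion this skips `delay span + refixation` base images: 5–6
(dual) and 8–9 (triple) for refixation 2–3, which is why the default
minimum target gap is `span + refixation + 1` (7 dual, 10 triple) — the
smallest gap that makes every missed image a nontarget by construction.
Two subtleties the simple accounting hides, both reproduced by the model:
images flashed on the left just before a *later* target can be re-seen on
the right/bottom during that target's dwell ("rescue"), so the long-run
missed count per target is slightly below span + refixation; and a target
inside a diversion window triggers no dwell of its own.

## Target-miss model

If targets occur independently with probability p and each diversion
ignores N images, the probability that a diversion skips at least one
target is

    P_miss = 1 − (1 − p)^N .

This is a *per-diversion* probability. The long-run *fraction of target
images* missed is a different quantity: each cycle holds one attended
target plus N ignored frames carrying N·p further targets in expectation,
giving N·p / (1 + N·p) (0.375 vs 0.469 at p = 0.1, N = 6). The package
exposes both, plus schedule-level empirical estimators; the Monte-Carlo and
schedule estimates agree with the respective closed forms to within
simulation error, with the rescue effect depressing the target-fraction
estimate by a few percent.

## Synthetic EEG

The generator writes continuous 16-channel data (10–20 labels, µV):

- **Background**: AR(1) noise (coefficient 0.95) with stationary standard
  deviation 10 µV per channel. 80% of each channel's noise variance comes
  from 6 latent AR(1) sources mixed linearly across channels; 20% is
  independent sensor noise. The mixing is a minimal surrogate for volume
  conduction: real EEG background is strongly correlated between
  electrodes, and without that correlation a spatial filter has nothing to
  cancel and single-trial detection saturates near AUC 0.77 (matched-filter
  ceiling) instead of the ~0.9 regime real recordings reach.
  `spatial_noise_frac=0` restores independent noise — used when testing
  topography recovery, because against correlated noise the discriminant
  weight is the *whitened* topography rather than the topography itself.
- **Mains**: a 50 Hz sinusoid (2 µV, random phase per channel), so the
  acquisition notch stage has something to remove.
- **Evoked response**: for every target presentation attended under the
  gaze trace, a Gaussian bump (FWHM 200 ms) scaled by a per-repetition
  amplitude and centred at onset + per-repetition latency is projected
  through a fixed unit-norm topography maximal at Pz. `amplitude_uV` is the
  deflection on the peak channel. Defaults per repetition: 6 µV / 300 ms,
  5.5 µV / 300 ms, 4 µV / 400 ms — the third viewing is smaller and later,
  reflecting the observer's reduced surprise once a target is known to
  reappear. Missed presentations contribute nothing.

The simulator does **not** model ocular or muscle artifacts, amplitude
drift, habituation across blocks, alpha rhythms, or latency jitter between
trials. Passing tests therefore demonstrate the correctness and internal
consistency of the pipeline under a controlled ERP model, not performance
on real recordings.

Recordings can be exported as 16-bit EDF plus a BIDS-style events TSV; the
EDF reader goes through MNE, so synthetic and real files share one loader.

## Preprocessing

Band-pass 0.5–60 Hz (4th-order Butterworth, zero phase), polyphase
resampling to 600 Hz, extraction of 1000 ms post-onset epochs for every
stimulus event on every stream, and per-epoch per-channel baseline
subtraction of the mean over the 200 ms before onset (a whole-epoch-mean
mode exists for data without pre-stimulus context). A 200 Hz low-pass and
50 Hz notch emulate the amplifier and are applied at the acquisition stage,
not in this chain. At 4 Hz with 1 s epochs neighbouring epochs overlap by
construction; no epochs are rejected for overlap. Events whose epoch would
run past the end of the recording are dropped with a warning.

## Classifiers

**HDCA.** Epochs are divided into K windows of T = 25 ms (N = T·Fs = 15
samples at 600 Hz, K = 40). Per window, a spatial weight vector over
electrodes is fitted by Fisher's linear discriminant on the window-mean
features, giving per-window scores y_k; a logistic regression over the
z-scored y_k yields temporal weights v_k, and the interest score is
y_IS = Σ_k v_k y_k. The within-class covariance uses Ledoit–Wolf shrinkage
(16 channels, 15-sample window means: the raw pooled covariance can be
ill-conditioned); the logistic stage carries a fixed mild ridge (C = 1).
Window scores are oriented so the target mean exceeds the nontarget mean.
Epoch lengths that do not divide into whole windows drop the trailing
partial window with a warning; a window that is not a whole number of
samples is an error.

**SWLDA.** Each epoch becomes an 840-point vector (14 of the 16 channels —
the frontopolar pair is excluded as the most ocular-contaminated — times 60
points per channel, non-overlapping block means). Class labels are
regressed on a stepwise-selected feature subset: forward entry by the
smallest partial-F p-value below p_enter = 0.10, backward removal of any
retained feature above p_remove = 0.15, at most 60 features — the
long-standing P300-speller convention. Ties break toward the lowest feature
index, making fits bit-for-bit reproducible. The forward step residualises
the labels and all candidates against the current selection with an
incrementally grown orthonormal basis, which is algebraically identical to
refitting the full regression per candidate (a brute-force oracle asserts
this in the tests).

## Fusion and evaluation

Cross-validation assigns *images* (not epochs) to 10 stratified folds, so
all stream presentations of an image stay together and every stream subset
is evaluated on the same partition. Within each training fold one
classifier is fitted per stream: each stream carries one repetition with
its own amplitude and latency, so per-stream models stay
latency-homogeneous (pooled training is available and costs a little
accuracy and stability in the triple-versus-dual comparison). Held-out
epochs get out-of-fold scores; fusion averages the scores of an image over
the streams in the evaluated subset (single = left, dual = left + right,
triple = all). Images missing a stream's score (gaze-missed) use the mean
of the available streams by default; a strict mode drops them. Performance
is the fold-mean AUC (Mann–Whitney rank statistic, mid-ranks on ties);
paradigms are compared with the exact two-sided Wilcoxon signed-rank test
on paired fold AUCs. Thresholded decisions are available (default
threshold: midpoint of the class medians of fused training scores), but all
headline evaluation is threshold-free.

On default synthetic sessions this yields mean CV AUCs around 0.90 / 0.93 /
0.95 for single / dual / triple HDCA fusion (SWLDA slightly lower), with
the triple-over-dual increment smaller than the dual-over-single one once
the third repetition is attenuated — the diminishing return that bounds the
usefulness of quadruple-or-more RSVP.

## Problem sizes and numerical choices

The simulation-heavy checks run single sessions of 2000 images at a 600 Hz
generation rate (the preprocessed rate; the 2400 Hz acquisition path with
4:1 downsampling is exercised separately), 20 replicates for the fusion
direction study, 20 seeds for topography recovery, 10^6 trials per point
for the Monte-Carlo miss curve. Epoch tensors are float32; model fitting is
float64. All randomness flows from explicit integer seeds; two runs with
one config are bitwise identical.

## Known limitations

- The gaze protocol is idealised: fixed dwell equal to the stream delay, a
  fixed integer refixation time, no lapses, blinks, or anticipatory shifts.
- The noise model is stationary and Gaussian; there is no artifact module,
  so artifact-removal stages cannot be meaningfully tested here.
- The closed-form miss probabilities assume independent target placement; the
  schedule's gap constraint deliberately violates that, and the empirical
  estimators quantify the (small) difference once the constraint is
  relaxed.
- The 14-channel SWLDA subset is a documented assumption (the montage
  records 16); it is configurable.
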