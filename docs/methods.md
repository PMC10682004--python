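# Methods

## Problem setting

A driver is monitored by redundant cardiac sensors: a clean chest-electrode
reference ECG, a steering-wheel contact ECG, a contact PPG on the wheel rim,
and an image-based PPG (iPPG) taken as the green-channel time series of a
cheek face segment filmed at the video frame rate.  Driving degrades the
wheel-contact and camera channels — baseline wander from body and vehicle
motion, high-amplitude motion-artifact bursts, contact-loss dropouts — while
the chest reference stays high-SNR.  The task is to decide, sample by
sample, where heartbeats occur in the degraded channels, and to quantify how
much of the driving time yields beat positions that agree with the
reference.

## Synthetic recordings

The simulator (`drivebeat.sigsim`) stands in for road recordings so the
whole pipeline is buildable and testable without the original data.

* **Beat train.** RR intervals are i.i.d. Gaussian with mean `60/hr_mean`
  and the first-order spread `60·hr_sd/hr_mean²`, clipped at the 0.25 s
  refractory floor.  HRV autocorrelation structure is deliberately absent:
  the pipeline never exploits rhythm regularity, so i.i.d. intervals
  exercise it equally well.
* **ECG.** Each beat renders five Gaussian bumps (P, Q, R, S, T) with fixed
  offsets/widths; the R amplitude (1 mV) is at least 3× every other wave, so
  the per-beat global maximum is the R wave to within one sample.  A
  dynamical-system ECG model would look prettier but adds nothing a QRS
  detector needs.
* **PPG.** One systolic Gaussian pulse plus a smaller dicrotic hump per
  beat, onset delayed by the pulse-transit time (default 0.25 s).  The
  template peak sits `PPG_TEMPLATE_PEAK_OFFSET` = 0.15 s after onset.
* **iPPG.** The same pulse shape at 2% amplitude riding on a constant
  illumination level, sampled at 10 Hz (the camera frame rate).  Frame rates
  below twice the pulse rate are rejected (Nyquist).
* **Artifacts.** Baseline wander is a sinusoid (default 0.25 Hz) plus a
  normalized random walk, both scaled by `baseline_amp`.  Bursts are
  Poisson-scheduled windows of zero-mean Gaussian noise with amplitude
  `burst_amp` (default 20× the modality's white-noise sd); dropouts are
  Poisson-scheduled constant-hold intervals.  A boolean mask of
  burst/dropout-covered samples rides along on the returned channel.
* **Synchronization.** All channels carry the acquisition counter of a
  master 500 Hz clock; the 10 Hz channel holds every 50th value, so equal
  counters mean simultaneous samples.  Channels are rendered 0.5 s past the
  nominal duration so the final beat's full waveform is present.

Every operation is a pure function of its arguments including the seed; one
`SeedSequence` per recording spawns independent child streams per modality.

What the simulator does **not** emulate: waveform morphology variation
between and within subjects (bundle-branch shapes, ectopy), HRV structure,
illumination changes and skin-tone effects on iPPG, correlated multi-channel
artifacts from a shared road event, and electrode-impedance drift.  Passing
the clean-limit and monotonicity checks therefore shows the pipeline's
machinery is correct, not that its real-road performance equals the
simulated numbers.

## Ground truth by detector consensus

Reference-ECG R peaks come from a majority vote over three diverse
detectors: a Pan–Tompkins-style detector (band-pass 5–15 Hz, derivative,
squaring, 150 ms integration, adaptive threshold), a slope-threshold
detector with an adaptive amplitude gate, and a detrended local-maximum
picker with a percentile threshold.  Candidates pooled across detectors are
single-linkage clustered within 100 ms; a cluster supported by a strict
majority of distinct detectors (⌈k/2⌉, default 2 of 3) emits one beat at the
cluster median position (half-integer medians floor toward the earlier
sample).  Three detectors suffice because the reference channel is high-SNR
by construction; the registry is pluggable if more diversity is wanted.  The
consensus tolerance and quorum are package choices — they are exposed as
parameters rather than fixed constants.

## Conditioning and snippets

The chain is fixed: (i) upsample to the master 500 Hz clock (linear
interpolation by default — it preserves sample values at grid positions and
peak locations at these rates; a polyphase FIR resampler is selectable),
(ii) subtract a 100-sample running median, (iii) affine-normalize to
[−1, 1] over the processed segment (a constant segment maps to zeros).

The running median is interpreted as a baseline estimator whose output is
*subtracted* (detrending); the alternative reading — keep the median-filtered
signal as a smoothed output — is available behind a flag.  Edges replicate;
the even default window (100 samples = 0.2 s) uses the lower-median
convention, implemented via `scipy.ndimage.rank_filter` with rank
`(w−1)//2`.  Normalization is per channel over the whole segment, not per
snippet: per-snippet scaling would erase the amplitude contrast between
beat-bearing and empty windows.

Snippets are 501 samples long, stepping 11 samples for training (overlap
490; thins the training set) and 1 sample for testing (overlap 500).  A
snippet is labeled 1 iff a reference R peak lies within ±25 samples (50 ms)
of its center.  With test step 1 this puts each beat at the center of a
contiguous run of ~51 positive snippets — the property that makes decoding
labels back into positions well-posed.  The half-width is configurable; 25
samples is half the refractory floor's sample count at the lowest legal RR,
so runs from neighbouring beats cannot merge.

## Fusion classifiers

Each architecture ends in a single sigmoid unit classifying a snippet as
heartbeat/no-heartbeat:

| approach | branches | merge point |
|---|---|---|
| early | 1 conv over the stacked n-signal input | convolutional layer |
| sensor-based late | 1 conv branch per signal | dense layer |
| signal-based late | 2 identical-input conv branches per signal | dense layer |

Every branch is conv (2 filters, kernel 20, linear activation) → dropout
(0.5, training only) → max-pool (2) → flatten; concatenated features feed
the dense sigmoid.  Training is Adam (lr 0.001) on binary cross-entropy,
batch size 32, 10 epochs by default.  For the same inputs, the signal-based
late network always carries more parameters than the sensor-based one (twice
the branches).  The sigmoid nonlinearity sits at the output; the
convolution itself is linear (the framework-default choice for a conv layer
with no stated activation), and max-pooling supplies the only hidden
nonlinearity — ample for a task that amounts to matched filtering plus
position readout.

The network is implemented directly in NumPy (im2col convolution as a BLAS
matmul, explicit backprop, hand-rolled Adam).  Initialisation, epoch
shuffling and dropout masks all flow from one seeded generator, so training
is bit-reproducible single-threaded.

The **hybrid** approach votes per snippet over the three architectures'
binary labels: label 1 iff ≥ 2 of 3 vote 1.  The vote is independent of the
networks, permutation-invariant, and monotone (upgrading any member vote
0→1 never flips the result 1→0).

Class imbalance and calibration: positives are ~10% of snippets at 70 bpm.
Two opt-in remedies exist, both off by default (the unweighted 0.5-threshold
classifier is the baseline condition):

* `class_weight=True` — inverse-frequency weighting of the cross-entropy;
* `calibrate=True` — prevalence-matched thresholding: instead of a fixed
  0.5 cut, each sufficiently large prediction batch is thresholded at its
  own quantile so that the predicted positive rate equals the training
  prevalence (labels of the scored data are never consulted; small batches
  fall back to a threshold fitted the same way on the training outputs).

The calibration matters for two reasons.  First, dropout sits before
max-pooling, so training-time pooled features (inverted-dropout-scaled
survivors) run systematically larger than inference-time ones and the
dense layer's 0.5 operating point under-calls positives — occasionally to
the point where no positive run reaches the decoder's minimum length and a
fold collapses to zero detections.  Second, min/max amplitude
normalization makes the conv feature scale a per-recording quantity, so
sigmoid outputs shift wholesale between subjects; a threshold fitted on
training subjects (or fixed at 0.5) does not transfer, whereas pinning the
positive *rate* is invariant to any monotone shift of the output
distribution.  The SNR-sweep experiment and the noisy-cohort examples
enable both remedies so that signal quality, not operating-point drift,
drives their comparisons.

## Decoding and evaluation

Test-mode labels (step 1) are decoded by run-length analysis: each maximal
run of ≥ `min_run` consecutive positive labels (default 25, tied to the
labeling half-width) emits one beat at the center sample of its center
snippet; runs closer than the 250 ms refractory interval to the previous
emitted beat are suppressed (earlier kept).

Detected and reference beats are matched greedily, one-to-one: references
in temporal order each claim their nearest unmatched detection within 50 ms
(configurable; common beat-matching windows span 50–150 ms).  At
physiological spacing (≥ 250 ms between beats, tolerance ≤ 50 ms) a
detection can be within tolerance of at most one reference, so greedy
matching is optimal; a brute-force assignment oracle in the tests guards
this.  Then

    PPV = TP/(TP+FP),  S = TP/(TP+FN),  P = (PPV+S)/2.

P is symmetric in FP↔FN and equals 1 iff there are no spurious and no
missed beats.  A zero denominator reports the statistic as 0 with a
`degenerate` flag rather than dropping the fold, keeping averages defined.

Leave-one-subject-out: one fold per subject; the held-out subject's
test-mode snippets are scored by models trained on all other subjects'
train-mode snippets; per-fold P is averaged per (approach, signal set,
scenario) cell.  Subjects missing a required modality are skipped for that
cell with a logged warning.

## Canonical experiments and problem sizes

`experiments.clean_cohort_performance` runs hybrid ECG+PPG LOSO on an
artifact-free cohort — 3 subjects × 120 s by default, chosen as the smallest
cohort where LOSO is meaningful and every fold still contains ~130 beats.
The expected outcome is mean P ≈ 1: with no artifacts, every architecture
localizes beats almost perfectly, and the vote cannot do worse than its
majority.

`experiments.noise_sweep` degrades single-signal ECG across three
severities that raise white noise (sd 0.05 → 0.18 → 0.45 against a 1 mV R
wave) with baseline wander kept fixed — a controlled SNR sweep.  Poisson
bursts and dropouts are excluded from the sweep by design: whether a given
60 s recording happens to contain a burst decides whether its min/max
normalization scale is burst- or R-wave-dominated (a ~5× bimodal scale
lottery), which couples multiplicatively into the linear conv features and
swamps the severity effect the sweep is meant to measure.  Burst/dropout
machinery is exercised by its own unit tests instead.  Five replicates per
severity, 2 training subjects (64 and 74 bpm) + 1 test subject (69 bpm,
inside the training range so the test prevalence matches the calibrated
operating point) × 60 s each, 8 epochs, class-weighted and
prevalence-calibrated.  Mean P is expected non-increasing
in severity; replicates are paired across severities (same subjects and
artifact draws, only the noise amplitude changes).

## Numerical choices and degenerate inputs

* Ties in max-pooling go to the first element (NumPy argmax convention);
  consensus cluster medians floor toward the earlier sample; even-length
  positive runs decode at the earlier center snippet.
* Matching uses a 1 ns epsilon so distances exactly at tolerance match.
* Constant channels normalize to zeros; flat signals yield empty candidate
  sets; single-class training data and empty beat trains raise errors
  rather than degenerate silently.
* Counter columns must be strictly increasing with a uniform stride; the
  first offending data row is named in the error.

## Known limitations

* The simulator's artifact statistics are package choices, not calibrated
  to any road dataset; absolute P values under noise are not comparable to
  road numbers.
* Real multi-subject morphology variation is absent, so cross-subject
  generalization here is easier than in practice.
* The greedy matcher's optimality guarantee holds only while the matching
  tolerance is below half the minimum beat spacing; widening it past 125 ms
  voids the oracle argument.
* The hybrid vote needs all three member networks trained; it triples
  training cost relative to a single architecture.
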