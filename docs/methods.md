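# Methods

`standscore` characterizes lower-limb surface-EMG activity promoted by
spinal cord epidural stimulation (scES) during standing, classifies
assisted vs independent standing from time- and wavelet-derived features,
and ranks the effectiveness of each muscle's activation with a
distance-weighted KNN posterior. This note documents the models, the
numerical conventions, and the design choices where the design was open.

## Signal model and the synthetic generator

No patient recordings ship with the package; every quantitative claim in
the tests is made on synthetic data whose construction is described here.

A single-muscle scES-EMG trace is modeled as a train of stimulus-locked
evoked responses plus noise:

    x(t) = G * env(t) * sum_k a_k g(t - t_k) + n(t)

* `g` — the evoked-response kernel, a Gaussian-windowed cosine
  (Morlet-like). Its **duration** defaults to 40 ms (sigma = duration/6),
  the length of the window between successive pulses at typical rates, so
  responses are temporally compact the way stimulus-locked compound
  responses are. Its **central frequency** f_c sets the oscillation under
  the window and is the peak-sharpness control: raising f_c moves power
  into higher bins and increases both the level and the frame-to-frame
  modulation of the instantaneous median frequency (IMDF). We deliberately
  did not tie the window width to 1/f_c: with 15-60 Hz stimulation a
  1/f_c-wide window makes low-frequency kernels overlap many inter-pulse
  intervals, and the summed train then gains or loses power with the
  commensurability of f_c and the stimulation rate — an interference
  artifact, not a physiological effect.
* `t_k` — pulse onsets at the stimulation rate (10-60 Hz supported;
  defaults follow the acquisition conditions the package targets: 2000 Hz
  sampling, 25 Hz stimulation, 40-70 s standing events).
* `a_k` — per-pulse amplitudes, lognormal with unit median and a preset
  coefficient of variation (positivity guaranteed).
* `env` — constant, or raised-cosine bursts (default 1 Hz, duty 0.5, 5%
  baseline) for the burst-and-near-silence activation pattern.
* `n` — Gaussian noise band-limited to 10-500 Hz (standard surface-EMG
  band), RMS in µV.

Three **class presets** (fictional calibrations, not estimates of any
participant's data) encode the qualitative contrasts between standing
classes: `independent_like` (f_c 20 Hz, amplitude CV 0.1, constant
envelope, gain 1.2), `assisted_continuous` (f_c 40 Hz, CV 0.35, constant,
gain 0.8), `assisted_bursting` (as continuous but burst-gated, CV 0.6).
These directions give independent-like activity higher total power, lower
pattern variability, lower maximum-power CV, lower IMDF mean and lower
IMDF SD — the orderings reported for real standing data.

A **heterogeneity model** perturbs the presets per event and per muscle
trace (lognormal multipliers; relative SDs: central frequency 0.2,
amplitude CV 0.5, shared event gain 0.4, per-muscle gain 0.3, noise 0.3),
emulating between-event differences in activation strength and
between-muscle differences in evoked-response shape and electrode
coupling. Without it, every (event, muscle) row is an i.i.d. draw from
its preset and all feature sets classify at 100%; with it, the feature
sets separate realistically (time-only and FFT-only land in the low 90s,
combined time+CWT near 98 on the bundled benchmark).

What the generator does **not** model: motor-unit recruitment and
conduction, volume conduction and electrode cross-talk, movement and
powerline artifacts, nonstationary fatigue drift, and the fine-wire
iliopsoas idiosyncrasies. Passing tests therefore demonstrate the
*pipeline's* correctness and the *internal* consistency of the feature
mechanisms, not performance on patient data.

## Features

* **Linear envelope** — rectified EMG through a 4th-order zero-phase
  (forward-backward) Butterworth low-pass at 4 Hz. Zero phase avoids
  envelope lag; 0.5 s is dropped at each end before statistics to remove
  filter transients. **Pattern variability** is the envelope's SD/mean.
* **Total power** — mean squared amplitude (µV²), the discrete realization
  of the time-averaged squared signal; normalized per participant and
  muscle by the maximum across that participant's events.
* **FFT PSD** — one-sided, of the full trimmed window (no segment
  averaging), normalized so the bin sum equals total power (discrete
  Parseval; asserted to 1e-6 relative). Summary features: mean, median,
  dominant frequency, maximum power.
* **STFT spectrogram** — 0.3 s Hann window, 50% overlap,
  magnitude-squared.
* **CWT scalogram** — analytic Morlet (omega0 = 6, the standard
  admissibility choice), scale s = omega0/(2 pi f), evaluated in the
  frequency domain: one FFT of the padded signal, then a per-scale
  multiply and inverse FFT. This is mathematically the convolution
  definition; it is cross-checked against PyWavelets' `cmor2.0-0.955` in
  the tests and is about an order of magnitude faster on dense grids.
  Wavelets are L2-normalized so white noise has flat expected power
  across rows. Default grid: 4-500 Hz, 120 log-spaced bins, clipped below
  Nyquist; results are robust to ±25% grid-density changes (tested).
  Frames within 3 time-widths of the lowest-frequency wavelet from either
  edge are excluded from summaries (cone of influence).
* **Instantaneous features** — per frame: IMNF (spectral centroid), IMDF
  (smallest grid frequency at which cumulative power reaches half the
  frame total — discrete convention, no interpolation; the test oracle
  uses the same convention), F_max and P_max. Summaries are mean and
  population SD over valid frames; maximum-power variability is
  SD/mean of P_max. All-zero frames are excluded.
* The scalogram's per-sample time axis may be strided (default stride 4
  in the extraction configuration) before summaries; the scalogram is
  smooth at these scales and the summaries are insensitive to the stride.

## Reduction pipeline

Fixed order, enforced by stage tags: (1) each feature column is divided
by its maximum (unit removal); (2) the spectral block is reduced by NNMF
(multiplicative updates, 10 random restarts keeping the best
reconstruction, rank 5 by default, clipped to the block width); row
coefficients are the reduced features and the basis is frozen for
projecting unseen events; (3) log(x + eps) with eps = 1e-6 x the training
column maximum guards NNMF's exact zeros and stabilizes variance. The two
time-domain features, already unit-free after normalization, are
concatenated after reduction (configurable via `reduce_block`). All
fitted statistics (maxima, basis, eps) are frozen at fit time so held-out
events go through the identical transform.

## Classification

KNN with four tuned dimensions — neighbors (1-30, log-scaled), metric
(euclidean, cityblock, chebyshev, cosine, mahalanobis), weighting
(uniform, inverse, squared-inverse distance), standardization — optimized
by a Gaussian-process expected-improvement loop (in-package; Matern-5/2
surrogate over one-hot-encoded categoricals, random candidate pool,
random-search fallback behind the same interface) against
log(1 + CV loss), the loss being the misclassification ratio under
stratified 10-fold CV. Accuracy = 100(1 - loss). The optimize+validate
cycle is repeated 10 times with fresh fold shuffles and reported as mean
with a t-distribution 95% CI. Folds are row-level (an event's muscles may
split across folds), which matches the classification design being
reproduced; an event-grouped split would be stricter and is trivial to
add via scikit-learn's grouped splitters.

## Prediction / ranking

Per muscle pair (left+right of one muscle), a K=5 nearest-neighbor model
is trained on one of three assistance regimes (fully assisted vs fully
independent; one knee assisted vs independent; hips-assisted/knees-
independent vs independent). A new event's score is the weighted
posterior of the independent class over the 5 nearest training rows with
weight W = (1/distance) / prior(neighbor's class). The inverse-distance,
prior-normalized reading makes the score a calibrated posterior under
class imbalance; the raw-distance reading is available behind
`weight_mode="raw_distance"` for sensitivity checks. A zero-distance
neighbor dominates (ties averaged). Scores ≤ 0.5 label the muscle's
activation "assisted" (boundary inclusive), > 0.5 "independent".
Left/right/total aggregates are arithmetic means of member-muscle scores;
stimulation parameter sets are ranked by descending total aggregate with
stable ties.

## Bundled benchmark and problem sizes

The seeded benchmark used by the acceptance tests and
`scripts/acceptance.py`: 300 events (150 independent-like; 150 assisted,
split between continuous and bursting) x 16 muscle channels, 10 s events
at 1 kHz with 25 Hz stimulation, 1 s trimmed per end, CWT grid 4-450 Hz
with 90 bins, stride 4. These sizes keep a full
generate-extract-reduce-classify-predict cycle in the minutes range on a
single CPU; the generator's own defaults remain the study-scale
conditions (2 kHz, 40-70 s events, 5 s trims). Feature-direction
replicates use 16 events per class of a single muscle; the
evoked-sharpness grid covers 40-120 Hz at matched total power — below
~40 Hz the oscillation is shorter than one cycle of the 40 ms response
window, the central frequency is not identifiable from the waveform, and
the mechanism has no room to act (a genuine property of short windowed
oscillations, documented rather than hidden).

## Numerical conventions and degenerate inputs

Event windows are half-open `[start+trim, end-trim)` with `floor(t*fs)`
sample conversion, 0-based. Onset detection thresholds the rectified
artifact at median + 8 MAD with a refractory period of 0.4 nominal
periods; pure Gaussian noise yields no detections at this threshold, and
an empty train is returned with a warning rather than an error. CV of an
all-zero envelope is NaN with a warning. Zero-maximum feature columns and
missing classes raise with the offending column/pair named. Single seeds
fan out to per-event substreams via `SeedSequence.spawn`, so datasets are
reproducible event by event.

## Known limitations

* Synthetic-only validation; the class presets are conventions, and
  absolute accuracies on the benchmark say nothing about patient data.
* The MU solver for NNMF converges slowly in the exact-factorization
  regime; the default tolerance targets the reduction use case, and the
  tests use a tighter budget where near-exactness is the point.
* PyWavelets agreement is high (r > 0.985 per scale) but not exact, since
  pywt discretizes the integrated wavelet; the frequency-domain
  evaluation used here is the analytic reference.
* Hip-assistance contrasts (regime iii) are intrinsically harder and show
  lower training CV accuracy; the package reports this rather than
  claiming discrimination.
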