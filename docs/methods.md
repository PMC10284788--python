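# Methods

This note documents the models and procedures implemented in `arousalkit`,
the parameter choices that matter, what the synthetic generator does and
does not emulate, and the package's known limitations.

## Windowing

All analysis operates on contiguous, non-overlapping fixed-length windows
(default 5 s; at the default 128 Hz sampling rate, 640 samples). A trailing
partial window is dropped rather than padded: every feature formula assumes
a full N-sample block, and padding would bias amplitude and spectral
statistics. A stride parameter allows sliding-window analysis at extra
compute cost; the default stride equals the window length. Internally
indexing is 0-based, but reported peak locations (`lpk`, `argminim`,
`argmaxim`) are 1-based sample indices, the convention of the feature
catalogue; index differences are basis-independent and convert to seconds
by dividing by `fs`.

## Time-domain features

`TimeFeatureSet` implements the catalogue exactly as defined, including two
deliberate oddities:

* `std_raw`/`var_raw` are the *uncentred* second moment, `sqrt(Σx²/(N−1))`
  and `Σx²/(N−1)`, with no mean subtraction. They are named `_raw` to avoid
  confusion with the conventional centred `sigma` (which is also computed,
  with the 1/(N−1) sample denominator); `channel_stats(..., centred=True)`
  swaps in the centred variants.
* The normalised difference statistics are defined through the identities
  `delta_norm = delta/sigma` and `gamma_norm = gamma_diff/sigma`, i.e. the
  mean absolute first/second difference of the standardised signal.
* `pp` is the index difference between the largest and second-largest
  sample — a sample-domain quantity, not a time interval.
* `kurt` is the plain fourth-moment ratio m₄/m₂² (non-excess; a Gaussian
  scores 3). The epoch statistics (`EpochStats`) instead follow scipy
  conventions — population std/var, biased skewness, Fisher *excess*
  kurtosis — since they feed scikit-learn feature tables where those are
  the ecosystem defaults. The two kurtosis conventions coexist
  intentionally and are named differently.

Ties in argmax/argmin resolve to the earliest index for determinism.
Statistics undefined on degenerate windows (zero variance → normalised
differences, skewness, kurtosis; zero RMS → `prms`) return NaN with a
warning instead of raising, so batch extraction over long recordings never
aborts; `build_feature_table` then drops (default) or retains such rows.

The moving-median window size `k` has no principled default; `k=5` is
exposed as an argument.

## Spectral features

PSDs are estimated with Welch's method: Hann taper, segment length
`min(N, fs)` samples (1-s segments on the standard window), 50% overlap,
constant detrend. Band power is the trapezoidal integral of the density
with linear interpolation at band edges, which makes power exactly additive
over adjacent bands and the full-range integral equal to total power by
construction. Per-window agreement between integrated density and
time-domain variance is approximate (within a few percent) because the
Hann taper under-weights segment edges; tests hold it at 5%.

Two band presets ship. The default `"eq23"` uses α 8–15 Hz, β 16–31 Hz,
δ 0–4 Hz, θ 4–7 Hz — the edges over which the valence/arousal indices are
defined. The `"bandlist"` preset carries the conventional clinical edges
(δ 0.5–4, θ 4–8, α 8–12, β 12–30 Hz). The two alpha definitions differ
materially (8–15 vs 8–12 Hz); users comparing against other software should
check which preset they need. Gamma spans from the beta edge to
min(45, fs/2) Hz, since acquisition chains commonly low-pass at 45 Hz.

Median frequency is the linearly interpolated half-power crossing of the
cumulative band-limited spectrum, with the upper limit defaulting to the
Nyquist frequency so the definition generalises across sampling rates. On
white noise at 128 Hz it sits at ~32 Hz, the flat-spectrum half-point.

Whether "band power" should be absolute or density-normalised was an open
choice; absolute integrated power is used, and every ratio-valued index
(valence, arousal, laterality) is invariant to that choice anyway.

## Valence, arousal and the calm/stress rules

V and A are alpha/beta band-power ratios over the frontal channels (see
README for the formulas). The four-channel aggregate in A is implemented as
the ratio of summed per-channel band powers — summing powers is robust to
inter-channel phase cancellation — with `affect_report(...,
aggregate="signal_mean")` offering the alternative reading (average the
four time series before the PSD).

The calm/stress thresholds (4/5/6/3) live on a 1–9 self-assessment-style
scale, not on the unbounded ratio scale of V and A. A monotone calibration
is therefore required before classification: `LinearCalibration` maps a
chosen input range linearly onto [1, 9], and
`LinearCalibration.from_samples` fits that range to the empirical [p5, p95]
of a calibration recording. This calibration is a package design choice —
nothing in the underlying index definitions fixes the mapping — and all
thresholds are configurable. Both rules use strict inequalities, so the
calm and stress regions are disjoint by construction and boundary
equalities fall to "undetermined", as do NaN indices.

Because A is an alpha/beta ratio, *rest* windows score high and *stress*
windows low; any downstream use that expects "arousal increases under
stress" must either invert the index or calibrate with a decreasing map.

## Heart rate from the FT9–FT10 derivation

Processing chain per window (≥ 5 s required):

1. **Baseline correction**: subtract a 1-s moving-median track. The median
   is robust to the sparse cardiac pulses, so drift is removed without
   flattening beats (a planted 50 µV/s drift leaves < 0.5 µV/s residual).
2. **Band-pass 12–30 Hz**, zero-phase Butterworth order 3. The band was
   chosen by measurement: the cardiac transient is broadband while the
   dominant contaminant is the 8–12 Hz alpha rhythm, and excluding alpha
   improved planted-rate recovery at SNR 3 from a median error of ~15 bpm
   to ~0.15 bpm. The band is configurable.
3. **Bipolar difference** FT9 − FT10: the artifact arrives with opposite
   polarity on the two electrodes and roughly doubles, while common-mode
   EEG cancels.
4. **Peak detection** on a 100-ms moving-average energy envelope (squared
   signal — the classic QRS integration step): envelope maxima above
   κ × rolling-median envelope (κ = 4, 2-s median window), each refined to
   the nearby maximum of |d|. A 0.25-s guard band at each end discards
   zero-phase filter transients.
5. **False-peak rejection**, in order: (i) refractory — of any pair closer
   than 300 ms the smaller peak is dropped; (ii) rate gate — intervals
   implying > 180 bpm drop the smaller peak (intervals implying < 40 bpm
   indicate a missed beat and cannot be fixed by rejection); (iii)
   amplitude — peaks below 30% of the median surviving amplitude are
   dropped. Every rejection is recorded with its reason.
6. **BPM** = 60·(n−1)/Δt over the accepted peak train; fewer than two
   accepted peaks gives NaN.

A full-amplitude spurious spike exactly mid-interval cannot be rejected by
these rules (it violates neither the refractory period nor the rate gate);
the amplitude gate handles the realistic case of noise spikes well below
beat amplitude.

## Laterality index and biofeedback frames

LI = (right − left)/(right + left) over frontal alpha power, with
left = α(F3)+α(AF3) and right = α(F4)+α(AF4). Only the input electrodes are
fixed by the acquisition protocol; the normalised-difference form is this
package's choice of the standard frontal-asymmetry statistic. LI ∈ [−1, 1]
and is antisymmetric under hemisphere swap.

A biofeedback frame maps BPM through breakpoints (default 60/80/100/120) to
a discrete `heart_level` (0 = "normal condition") and |LI| through
breakpoints (default 0.2/0.4/0.6/0.8) to `brain_level`. The breakpoints are
presentation defaults, not physiology. Frames are stamped at window *end*:
feedback for data in [t, t+w) is available at t+w, a constant one-window
delay; processing time itself is not modelled. Frames with NaN inputs are
flagged invalid rather than dropped, so the frame log stays aligned with
the window sequence.

## Model-selection harness

Eight families with a small default sweep (14 settings): QDA, GNB, SVM
(RBF, C=1), MLP (one 50-unit layer, 500 iterations), AdaBoost (50
estimators), KNN (k ∈ {3,5,7}), DT (depth ∈ {5,10,∞}), RF
({50,100,200} trees). Stratified k-fold CV (default 10 folds, reduced with
a warning when the smallest class is smaller); features standardised inside
each training fold only; metrics macro-averaged (appropriate for
multi-class tables) and then averaged over folds. A setting that fails to
fit (e.g. QDA's per-class covariance is singular when a class has fewer
training rows than features) is reported with NaN metrics and skipped by
`select_best` rather than aborting the sweep. Selection is by accuracy,
ties broken by F1 then alphabetical family name. Stratified window-level
folds are the default; a `groups` column switches to subject-grouped folds,
which should be preferred on multi-subject EEG since window-level splits
let windows from the same subject straddle the train/test boundary and
inflate scores.

All randomness (fold shuffling, stochastic learners) is derived from one
seed; identical (table, seed, grid) reproduces reports bit-for-bit.

## Synthetic data: what it emulates, and what it does not

Each channel is a weighted sum of band-filtered Gaussian noise components
(one per canonical band) plus 1/f background. The rest state is
alpha-dominant (gains δ 1.0, θ 0.8, α 2.0, β 0.6, γ 0.2, overall scale
10 µV RMS); the stress state divides the alpha gain and multiplies the beta
gain by a factor (default 2) — the alpha-suppression/beta-activation
signature of cognitive load. A configurable fraction of background variance
(default 0.7) is shared across channels, emulating volume conduction; this
is what makes the bipolar derivation informative. F4/AF4 alpha is scaled by
an asymmetry ratio for laterality tests. FT9/FT10 carry opposite-polarity
Gaussian pulses (40 ms width) at a configured BPM — constant or linearly
ramped — with Gaussian inter-beat jitter (default SD 20 ms); pulse
amplitude is set via an SNR relative to the channels' background RMS.
Optional spurious spikes (default 25% of beat amplitude, placed ≥ 200 ms
from any true beat) exercise the false-peak rejection. A pure-tone mode
replaces band noise with sinusoids for closed-form spectral tests.

The generator does **not** model real ECG morphology (P/T waves),
eye-blink/EMG artifacts, electrode pops, non-stationary drift within a
state, inter-subject variability, or realistic spatial covariance beyond
the single common-mode factor. Tests passing on this generator therefore
demonstrate algorithmic correctness under the assumed signal structure, not
clinical performance on recorded EEG: in particular the perfect rest/stress
separation reflects the generator's clean two-state construction, and
results on real multi-subject data will be worse and must use grouped CV.

The IBI generator draws per-state AR(1) Gaussian interval series (innovation
variance scaled so the stationary SD matches the configured SD). HRV
features per beat window: MEAN_RR, MEDIAN_RR, SDRR (sample SD), RMSSD,
SDRR/RMSSD, relative-RR variants (each interval divided by the rolling mean
of the previous 10 beats), and VLF power over 0.0033–0.04 Hz with its
percentage of total spectral power, computed with a Lomb–Scargle
periodogram since the tachogram is sampled irregularly (one point per
beat). Short windows (< 10 beats) are skipped. VLF power on windows much
shorter than ~5 minutes is poorly resolved and should be treated as a
relative, not absolute, measure.

## Problem sizes and numerical choices

The verification battery (`scripts/acceptance.py` and the end-to-end test
module) uses: 1,000 random 640-sample windows for feature-oracle
equivalence at 1e-9 relative tolerance; 200 windows for spectral partition
consistency; a 101×101 grid for the decision rules; 100 ten-second
recordings (BPM ~ U[55,140], SNR 3) for heart-rate recovery; and the
300-s/60-window rest–stress preset for state discrimination. These sizes
give stable statistics while keeping the full battery under a minute of
compute; all are arguments, not constants.

EDF files are written with 16-bit quantisation against per-channel physical
ranges (the format's native resolution), so EDF round-trips are exact only
to that step; CSV round-trips are exact to 10 significant digits.
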