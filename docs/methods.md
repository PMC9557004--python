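# Methods

This note documents the models, conventions and numerical choices behind
`hfopipe`, in the order the pipeline runs them.

## Detection model

The detector is two-stage and runs independently per bipolar channel, per
frequency band (ripples 80–250 Hz, fast ripples 250–500 Hz), per 5-min NREM
interval.

**Band-pass filter.** Zero-phase Butterworth (order 5, applied forward and
backward with `sosfiltfilt`, so effectively 10th order). Order 5 keeps the
passband maximally flat while attenuating a tone one octave outside the
band to below 5% amplitude (order 4 leaves ~6%, enough for strong FR to
leak into the ripple band).

**Baseline threshold.** The core idea is that the amplitude threshold
separating events from background must be estimated from background only,
even on channels where events are frequent. The filtered interval is cut
into non-overlapping windows (`entropy_window_ms`, default 50 ms). For each
window the time-averaged Stockwell power spectrum over the in-band bins is
computed — using the identity that the S-transform power averaged over the
window's time axis equals (1/N)·Σₙ|X[k+n]|²·G_k[n]², with X the window FFT
and G_k(n)=exp(−2π²n²/k²) the Gaussian voice, so one FFT per window
suffices — and its Shannon entropy taken. A flat spectrum (high entropy)
means no sustained oscillation: windows at or above the `entropy_quantile`
(default 0.9) of the entropy distribution are declared background. The
threshold is then the `envelope_cdf_quantile` of the Hilbert-envelope
samples within those windows.

`envelope_cdf_quantile` defaults to 0.99. This was chosen by examining the
detector's operating point on pink-noise synthetics: at 0.95 roughly 5% of
background samples sit above threshold by construction, producing a false
candidate load several times the true event count (pair precision ~0.2);
at 0.99 precision and recall are both ≈ 1.0 across burst peak amplitudes
of 10–25 µV (ripple band) and 5–15 µV (FR band) over 5 µV-RMS pink noise,
without losing the smallest bursts. The baseline is computed per interval
(matching the interval-wise test-retest design); a per-recording scope is
available via `baseline_scope`.

**Segmentation.** Candidate events are contiguous runs where the envelope
exceeds the threshold; runs closer than `merge_gap_ms` (10 ms) merge. A run
is kept only if the rectified band signal has at least `min_peaks` (4)
local maxima above the threshold — a sustained oscillation, not a filter
response to a transient. Onset/offset sit at the threshold crossings; the
event's peak amplitude is max |filtered| within the run.

**Morphology rejection.** Accepted ripples must have peak amplitude ≤ 30 µV
and duration ≤ 150 ms; FR ≤ 20 µV and ≤ 50 ms. These are artifact bounds:
sharp transients reach the high bands with far larger amplitude than
physiological HFO. "Peak amplitude" here is max |band-filtered signal|
within the event — distinct from the morphology module's peak-to-peak
feature.

**Co-occurrence.** A ripple and an FR on the same channel with ≥ 1 sample
of temporal overlap form one HFO event. Each ripple/FR joins at most one
pair; candidate pairs are taken greedily by decreasing overlap, ties broken
by earlier onset. The paired event spans the union of its members (the
intersection convention is available via `pair_extent`).

## Rates, area, reliability

Rates are counts per minute over the pooled NREM intervals (the
per-interval variant divides by each interval's minutes). The HFO area is
{channel : rate ≥ 1/min and rate > P95} where P95 is the
linear-interpolation 95th percentile of the patient's full channel-rate
distribution; "exceeding" is strict, so an all-equal (degenerate) rate
distribution yields an empty area.

Test–retest reliability of the spatial profile is the normalized scalar
product between per-interval rate vectors, averaged over all unordered
interval pairs and reported in percent. Significance per pair: the channel
order of one vector is permuted (default N = 5000) and the observed product
must exceed the 97.5th percentile of the permuted products. Constant
vectors make the null degenerate (every permutation is identical); such
pairs are flagged and never significant. All permutation draws are seeded.

## Outcome validation

Per patient: the HFO area is "fully resected" iff every area channel is
resected. Crossing that flag with the dichotomized ILAE outcome (1 vs 2–6)
gives the exhaustive, mutually exclusive rule {fully ∧ ILAE=1 → TN, fully ∧
ILAE>1 → FN, not-fully ∧ ILAE=1 → FP, not-fully ∧ ILAE>1 → TP}. A patient
with an empty HFO area cannot be classified and is excluded with a log
entry. The bipolar channel's resected flag requires both member contacts
resected (conservative; the either-contact rule is a config option).

Metrics use the standard definitions (sensitivity TP/(TP+FN), specificity
TN/(TN+FP), PPV TP/(TP+FP), NPV TN/(TN+FN), accuracy (TP+TN)/N) with exact
Clopper–Pearson 95% intervals from beta quantiles; this interval choice
reproduces the printed intervals of the reference cohort exactly after
integer rounding (e.g. lower bound 0.025^(1/6) ≈ 54% for 6/6), which
normal-approximation and Wilson intervals do not. Display values round
half-up to integer percent; full precision is retained in JSON. 0/0 ratios
are reported as not-applicable.

## Morphology features

Per paired event: Am-ripples/Am-FR are the peak-to-peak voltage of the
band-filtered signal over the ripple/FR sub-event window; Fr-ripples/Fr-FR
are the inverse mean spacing of consecutive positive local maxima of the
band-filtered signal (for a sinusoid, exactly the oscillation frequency);
D-HFO is the paired event's onset-to-offset duration in ms. Events with
fewer than two peaks or zero amplitude are dropped with a logged count.

Only true-negative patients enter the feature dataset: their resected
HFO-area channels are operationally epileptogenic (Class-1) and their
non-resected channels non-epileptogenic (Class-2); events on resected
channels outside the area are ambiguous and excluded, and TP/FP/FN
patients contribute nothing because their tissue labels cannot be
established.

## Statistics and classification

**Mood's median test.** 2×2 table of counts above vs at-or-below the
pooled grand median; Pearson chi-square n(ad−bc)²/(r1·r2·c1·c2) with 1 df,
no continuity correction; ties count in the "at or below" cell. All pooled
values identical is degenerate (chi2 = 0, p = 1). The 25 tests (5 features
× 5 contrasts) share Bonferroni α = 0.05/25 = 0.002. With these
conventions the empirical type-I error at nominal 5% is ≈ 4.9% for samples
of a few hundred per group; at small n the hypergeometric lattice makes the
chi-square approximation slightly anti-conservative (e.g. ≈ 6.7% at
100 + 100), which is inherent to the test, not to this implementation.

**Outlier removal and scaling.** Within each (patient, class) group an
Isolation Forest on the five features removes anomalous events
(contamination bound 0.05; groups under 10 events pass through). Features
are then z-scored with mean/SD over the full TN event set — deliberately
before cross-validation, matching the reference procedure despite the mild
leakage; a strictly fold-nested scaler is available (`apply_scaler` with
per-fold statistics).

**SMOTE.** Implemented in-package: synthetic minority points are drawn
uniformly on segments between a minority sample and one of its k = 5
nearest minority neighbours, appended until classes balance. It is applied
to training folds only — never to evaluation folds — in both CV schemes.

**Nested CV Random Forest.** Outer stratified 5-fold for evaluation; inside
each outer training set an inner stratified 5-fold grid search selects
{n_estimators ∈ {100, 300}, max_depth ∈ {3, None}, max_features ∈ {√p,
all}, bootstrap fraction 0.8} by mean inner AUC. The default grid spans
the forest-size, depth, feature-subsampling and bootstrap axes with two
points each where it matters; a denser grid can be passed via
`param_grid`, but at the package's test scale (~10³ events) the nested
search cost grows linearly with grid size while AUC changes marginally.
Reports mean/SD AUC over outer test folds (percent) and Gini importances
averaged over outer models, normalized to sum to 1. The
leave-one-patient-out variant uses patients as outer folds; held-out
patients with a single class have no defined AUC and are excluded with a
logged count. All stochastic steps derive from one master seed recorded in
every report.

## Synthetic data: what it emulates and what it does not

Background is 1/f (pink) noise at 5 µV RMS broadband — chosen once as a
realistic filtered-band background level for depth-EEG (the in-band RMS is
then ~1–4 µV, so the entropy baseline operates on a sloped, not flat,
spectrum). Events are hann-windowed sinusoidal bursts placed by independent
Poisson processes per channel and interval, with non-overlap enforced by
rejection sampling (bounded retries; a `PlacementError` signals infeasible
rates). Co-occurring pairs share a centre time with the FR burst (default
0.45× the ripple duration, capped at 40 ms) inside the ripple burst.
Anatomy (MTL/Neocortex), resection flags, interval lists (4–14 × 5 min) and
ILAE outcomes are channel/patient metadata; `generate_cohort` constructs
patients whose ground-truth rates realize an exact TP/TN/FP/FN table under
the HFO-area rule. Optional 50 Hz mains contamination is off by default.
`generate_feature_table` synthesizes morphology-feature tables directly
(Gaussian at realistic locations/scales) for classifier-stage studies.

Not emulated: physiological waveform diversity (spikes, sharp transients,
spindles), amplitude/frequency jitter within a channel, state transitions
within NREM, inter-channel correlation, or real artifact structure.
Passing tests therefore demonstrate correctness of the pipeline's
computations and its behaviour under controlled SNR — not clinical
detector performance, which depends on artifact and spike content absent
here.

## Known limitations and numerical notes

- **Duration bias.** With onset/offset at threshold crossings, tapered
  bursts are systematically shortened: the hann tails sit below any
  noise-level threshold, so end-to-end detected durations run ~20–30%
  below the injected window length at realistic SNR. Amplitude and
  frequency are unbiased (≈ 5% and ≈ 1% median error end-to-end). Feature
  recovery is therefore assessed over ground-truth event windows, where
  all five features are genuine measurements from the filtered signal.
- Burst injection aligns the carrier peak with the envelope maximum, so
  the injected waveform's peak equals the requested amplitude exactly;
  peak-to-peak is 2× that up to filter ripple.
- Percentile conventions are linear interpolation throughout (rates
  threshold, permutation null); alternative conventions move results only
  in degenerate ties.
- The cohort-level mean test-retest reliability averages per-pair products
  with equal weight per pair (patients with more intervals weigh more);
  per-patient weighting is a one-line change on the report.
- Recordings travel as float64 flat binary + JSON sidecar + TSV contact
  tables; round-trips are exact. EDF export is out of scope.
- Event times are seconds from recording start, samples 0-based, intervals
  half-open [start, stop); burst onsets are rounded to the sample grid so
  truth lists and rendered signals agree exactly.
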