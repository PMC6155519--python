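# Methods

This note documents the models and procedures implemented in
`hrvseizure`, the parameters that matter, and the choices made where the
design was genuinely open. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Signal model and scope

The pipeline assumes multi-channel surface ECG sampled at ≥ 256 Hz
(512 Hz typical), with seizure annotations (electro-clinical onset and
offset) on the same clock. All analysis is of the RR-interval series —
the autonomic nervous system is read through the sinus node — so
everything upstream of the tachogram exists to produce accurate,
sinus-only beat timings, and everything downstream treats the seizure
problem as binary preictal-vs-interictal classification per patient.

## Preprocessing

*Impulsive artifacts.* Per channel, d = |x − median₆₀ₘₛ(x)|; contiguous
segments where d exceeds `k_thresh` (default 0.35) times max(d) — with
an absolute floor of 1 mV so that clean channels, whose largest
deviations are their own QRS complexes, are never mutilated — are
replaced by the mean of the neighboring samples.

*Power line.* A second-order IIR notch (default 50 Hz, −3 dB width 1 Hz)
applied forward–backward. The padding length is set to ~3/bandwidth
seconds because a high-Q notch has a transient far longer than the
filtfilt default.

*Baseline wander.* The baseline estimate is a first-order Butterworth
low-pass run forward and backward, with the per-pass cutoff chosen so
the composite −3 dB point is 3.1 Hz, subtracted from the signal. When
the estimate itself shows fast residual excursions (above 5 MADs for
longer than 0.5 s) a 0.26 s median filter replaces it over those spans.
Two consequences of the first-order choice are documented by the tests
rather than idealized away: R-peak amplitudes are uniformly reduced by
roughly a quarter (harmless for detection, which normalizes amplitude),
and a 20 Hz tone changes by ~5%, not 0. The stage is not idempotent for
the same reason; idempotence holds for the other two stages.

Stage order is impulse removal → notch → baseline; the order of the
first two is not critical and was fixed once.

## QRS detection

Each channel is band-passed to 5–15 Hz (order-2 Butterworth sections,
zero phase), differentiated with the comb x(n) − x(n−k), k = 13 ms,
smoothed by an 8 ms moving average and rectified; the comb's k/2 delay
is compensated so the envelope is beat-aligned.

*Channel selection.* Candidate peaks are envelope maxima above 0.3 of
the envelope's 99th percentile (minimum spacing 50 ms). The quality
score multiplies: the median over 2 s windows of the envelope maximum
(the typical QRS-scale deflection — deliberately a windowed median so
rare large artifacts cannot inflate it); the fraction of 2 s windows
containing a candidate (a real rhythm fills them); one minus the
fraction of 0.2 s windows containing ≥ 2 candidates (dense noise peaks);
and one minus the fraction of candidate-bearing 8 s windows whose
candidates fall within a single 2 s subwindow (sporadic artifacts).
Channels within 0.9 of the best quality are selected. An earlier variant
using the median *candidate* amplitude as the amplitude term mis-ordered
channels on fixtures — large in-band artifacts reward it — which is why
the windowed-median form is used.

*Detection.* The selected channels' envelopes are summed and band-passed
at 6.3–16 Hz. First-order sections are used here: zero-phase filtering
squares the response, and higher orders crush the rectified-envelope
bump relative to in-band noise (measured contrast 5× vs 2.5× at 20 dB
SNR). The threshold initializes at 0.4 × the 99th percentile of the
first 10 s, updates as thr ← 0.85·thr + 0.15·(0.4·peak) at each
detection, and is doubled immediately after a detection, decaying
linearly over 360 ms — this is what rejects tall T waves. A 200 ms
refractory period is enforced.

*Fiducials.* The envelope locates the beat; the reported fiducial is the
signed extremum of the zero-phase 5–15 Hz band-passed channel sum within
±50 ms, with the polarity fixed from the initial 10 s. The extremum of
the derivative itself sits on the R flank rather than the apex, so
refining on the band-passed waveform is what makes ±10 ms accuracy
against ground-truth R times possible.

For precise timing the record is first interpolated to 1024 Hz
(polyphase resampling).

## RR correction

Step 1 — rules with a running expectation ê = median of the last 7
accepted intervals: an interval pair (r, r_next) with r ≤ 0.75ê,
r_next ≥ 1.25ê and r + r_next within 20% of 2ê is an ectopic
(short coupling interval plus compensatory pause) and both are replaced
by their mean; r < 0.6ê with r + r_next within 20% of ê is a spurious
detection and the pair is merged; r > 1.8ê is a pause from missed
detections and is split into round(r/ê) equal sub-intervals. All
multipliers are configuration, defaulted as above.

Step 2 — an order-8 linear predictor initialized by least squares on the
first 30 intervals. An interval within 30% of its prediction is accepted
(normalized-gradient coefficient update, gain 0.05); otherwise it is
replaced by the prediction pulled 25% toward the observation, with a
quarter-gain update. A zero-variance initialization span degrades to a
running-mean predictor. Every altered interval carries a flag naming the
stage that changed it.

The corrected series is resampled at 4 Hz by linear interpolation with
each interval anchored at its terminating beat (the convention matters:
it is also how the synthetic generator defines its modulation, so
parameter-recovery tests are exact). Closed form puts the linear
interpolation error of a 0.1 Hz modulation at ~3% of its amplitude for a
75 bpm rhythm; tests that assert a 2% tracking bound therefore use a
faster rhythm where that bound is attainable.

## Features

Windows are 180 intervals with 60 of overlap (step 120); a trailing
remainder is dropped. Time-domain features use population SDs;
pNN50 = 100·NN50/(n−1) over the n−1 successive differences; SD1 =
RMSSD/√2 and SD2 = √(2·SDNN² − SD1²) (the lag-1 Poincaré identities, in
place of an eigendecomposition they equal); CSI = SD2/SD1 and
CSV = log₁₀(SD1·SD2) are undefined (NaN, window flagged) for a constant
window.

*Normalization scope.* The whole-recording z-scored series feeds the
shape-sensitive features — the recurrence measures and the Katz fractal
dimension — to damp inter-individual scale differences. Features whose
definitions need physical milliseconds (meanNN, SDNN, pNN50, CoSEn with
its ln(meanNN) term, the spectral bands) use raw values; scale is
removed for the classifier anyway by per-feature standardization at
training time.

*CoSEn.* SampEn with m = 1, Chebyshev distance, self-matches excluded,
both template lengths counted over the same n−m starting indices;
tolerance r = 0.03 × window SD with a 3 ms floor; CoSEn = SampEn +
ln(2r) − ln(meanNN). The entropy is computed on the physical series —
on a z-scored series meanNN ≈ 0 and the correction term is undefined;
the ln(meanNN) term *is* the heart-rate normalization of this measure.

*KFD.* log₁₀(n)/(log₁₀(n) + log₁₀(d/L)) with unit abscissa steps, L the
total ordinate path length and d the maximum excursion from the first
point; defined as 1 for monotone or constant windows.

*Recurrence.* Delay embedding with m = 3, τ = 1; Euclidean distances;
ε = 0.2 × the window's SD by default (a fixed value or a target
recurrence rate are also supported). Conventions, fixed once and
mirrored exactly by the brute-force oracle in the tests: diagonal lines
are maximal runs on every off-LOI diagonal, and %DET divides by the
off-LOI recurrent points (this keeps DET ≤ 100; note the two corner
cells of the matrix are length-1 diagonals, so even an all-ones matrix
gives DET marginally below 100). Vertical lines are counted on the full
matrix including the LOI and LAM divides by all recurrent points, which
keeps LAM ≤ 100 while preserving the natural reading of a vertical
structure. ENT uses the natural log over diagonal lines of length ≥ 2;
TT is the mean vertical line length (≥ 2). When no line reaches the
minimum length, TT and ENT are undefined at the measure level; the
feature matrix codes them as 0 ("no trapping, no line diversity")
because on sparse noise-like windows this is the common case and
dropping such windows would discard most interictal data.

*Spectra.* The 4 Hz tachogram is analyzed with a Gaussian-window STFT
whose window SD follows σ(f) = σ_min + (σ_max − σ_min)/(1 + exp((f −
f_c)/s)) with σ_max = 12.5 s, σ_min = 2.5 s, f_c = 0.15 Hz, s = 0.04 Hz,
on a 0.01–0.5 Hz grid (step 0.005 Hz): long windows where LF resolution
is needed, short windows where HF tracking is needed. Each frequency's
output is normalized by its window's equivalent noise bandwidth so the
map is a power *density*; without this the frequency-dependent window
width tilts a white-noise spectrum toward the short-window end. LF and
HF are the band-integrated densities averaged over the window's time
span from a single whole-recording map; the normalizing "total" is
LF + HF (so LFn + HFn = 1 and the VLF band, heavily window-dependent at
these durations, never enters).

The classifier's feature vector has exactly 20 entries (NN50 is computed
but is an intermediate; pNN50 represents it).

## Labeling and classification

A window is ictal if it overlaps a seizure, preictal if it lies entirely
within the 15 minutes before an onset, interictal only if its whole span
is at least 50 minutes from every onset and offset, and excluded
otherwise — boundary-straddling windows are dropped rather than assigned
by majority, and the postictal hour falls out of training automatically.

Stepwise regression on the 0/1 response over standardized features: add
the candidate with the smallest partial-F p-value while it is below
0.05, then drop the worst in-model term while its p-value exceeds 0.10,
until stable. Constant columns are dropped up front; an exactly
collinear duplicate can never enter second. If nothing passes the entry
threshold the single best candidate is used so the classifier always has
an input.

The SVM uses an RBF kernel with per-class weights {interictal: 1,
preictal: n_inter/n_pre} recomputed on each training set. (C, γ) are
selected from the log grid C ∈ 2^(−5..15), γ ∈ 2^(−15..3) (step 2²) by
minimizing the class-weighted stratified five-fold cross-validation
misclassification loss; the fold shuffling is seeded, making training
bit-reproducible. Scaling, selection and the grid search are functions
of the training rows only — a mutation test asserts the trained model is
identical when test rows are altered.

*Experiment 1* is a stratified 80/20 holdout. FP/h divides test-split
false positives by the union length (hours) of the test split's
interictal window spans — windows overlap by a third, so summing spans
would double-count time.

*Experiment 2* (for ≥ 3 seizures) splits the recording into one block
per seizure at seizure offsets, each block carrying its interictal share
and its preictal span. For k = 3..N the model is fitted on blocks
1..k−1 and tested on block k, so training strictly precedes testing;
per-block reports, their average, and per-seizure prediction times (the
gap from the first preictal-classified window inside the true preictal
span to onset; earlier alarms count as false positives, not predictions)
are returned.

## Synthetic data

RR series are built by direct interval modulation: each interval is the
base (60000/HR ms) plus an LF sinusoid (default 0.1 Hz, 20 ms), an HF
sinusoid (default 0.25 Hz, 30 ms) and white noise (5 ms), clamped to
[300, 2000] ms, each modulator evaluated at the running beat time. This
is not an integral-pulse-frequency-modulation model; it was chosen
because the fixtures need exactly controllable spectra, and the
terminating-beat convention makes the modulation recoverable to
interpolation accuracy.

Preictal spans (the 15 min before each onset, continuing through the
3-min ictal span) apply a configured shift: mean RR × 0.9, HF amplitude
× 0.4, LF amplitude × 1.8, beat noise × 0.4, plus a 15 ms
4-beat-period oscillation that raises determinism and laminarity. The
directions follow the autonomic signature described above; the
magnitudes are free parameters of the generator, chosen once as a
"strong, clearly detectable" preictal state — real preictal shifts are
weaker and far more variable, so classifier performance on these
fixtures is an upper bound and a correctness check, not a clinical
claim. Recordings are laid out so every seizure has a 50-min margin on
both sides of its block's interictal stretch (about 2.2 h per seizure
with the default 1 h of interictal data per block).

ECG is rendered as five Gaussian bumps per beat (P, Q, R, S, T at
−200/−30/0/+30/+250 ms with 25/8/10/8/60 ms widths; T amplitude
configurable to stress T-wave rejection), per-channel gain scaling, plus
baseline and mains sinusoids, Poisson-scheduled 20 ms impulses shared
across channels, and white noise. No 12-lead geometry, respiration
coupling, morphology change or electrode-motion modeling is attempted —
the fixtures validate timing, artifact handling and spectral placement,
not morphological analysis.

Every generator threads an explicit seed and is bit-reproducible.

## Numerical conventions and degenerate inputs

Flat channels score quality 0; an all-flat record yields an empty beat
sequence with a warning. Series shorter than 3 intervals skip rule
correction; shorter than the predictor order skip the predictive pass.
Windows with undefined features carry `valid=False` and never reach
training. Zero-SD normalization returns zeros with a degenerate flag.
Confusion-matrix metrics with empty denominators are NaN, never 0.

## Problem sizes

Test and benchmark recordings are sized for completeness at interactive
runtimes: 10-minute detection benchmarks (~750 beats), a ~8 h
3-seizure recording (~37k beats, 309 windows) for the end-to-end
protocols, and a ~20 h 8-seizure recording for the fold-structure check.
The chain is linear in recording length; day-scale recordings pose no
algorithmic issue.

## Known limitations

- The preictal effect sizes are inventions with the right signs; no
  claim about real-data sensitivity follows from the synthetic
  benchmarks.
- The detector assumes QRS-dominant channels after preprocessing; it
  performs no beat-morphology classification, so atrial fibrillation or
  bundle-branch morphologies would degrade the correction stage's
  assumptions.
- FP/h counts false-positive windows, not merged alarm episodes; an
  alarm-refractory post-processing would lower it and is intentionally
  not applied by default.
- EDF files can be read (via mne) but not written; the interchange
  formats are CSV/JSON.
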