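# Methods

This note records the models implemented in `sacsyn`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the package's design decisions where the procedure left
genuine freedom.

## White-noise stimulus and session structure

The stimulus is a sequence of standard-normal draws at the recording
sample rate (default 10 kHz; every operation accepts any uniform dt),
ideally low-pass filtered at 30 Hz by hard-zeroing FFT bins above the
cutoff. A session comprises 10 consecutive 10-s trials, each 7.5 s of a
unique sequence followed by the same 2.5-s repeated sequence. Unique
segments build models; repeat segments assess them.

Filtering order is underdetermined: filtering each trial independently
would create discontinuities at trial boundaries, so the full 100-s
concatenation is filtered once. Consequently the repeated segment is
bitwise identical across trials only in the pre-filter domain; after
filtering, repeat segments differ negligibly near segment edges. All
repeat-segment comparisons (reliability, model accuracy, repeat means)
therefore drop a leading edge band of 3/cutoff s (100 ms at 30 Hz),
three "memory" time constants of the band-limited signal.

Trial-to-trial reliability is the mean over trials of the Pearson
correlation between each trial's repeat response and the mean of all
other trials' repeat responses; sessions must exceed 0.7 to enter LN
analysis. Reliability is computed on raw (unsmoothed) responses.

## LN cascade estimation

The linear filter is the plain cross-correlation
`taps[k] ∝ mean_t s(t) r(t + k dt)` over lags 0–200 ms, accumulated
across the unique segment of every trial. No whitening by the stimulus
autocorrelation is applied; for a 30-Hz band-limited stimulus the
estimate equals the true cascade kernel smoothed by that band-limit, and
the recovery tests compare against exactly this smoothed ground truth.
The filter is rescaled to unit L2 norm — the LN cascade has a scale
degeneracy, and the gain is absorbed into the nonlinearity; the raw gain
is retained on the filter object. All shape metrics are scale-invariant,
so normalization does not affect them.

Metrics: peak time and the extrema f_max, f_min are measured over
0 < t ≤ 60 ms; width is the full width at 25 % of the maximum with
sub-sample linear interpolation, taking the outermost crossings flanking
the peak when several exist; `b_φ = 2 f_min/(f_max + f_min)` is clipped
to [0, 1] (a negative lobe larger than the peak would otherwise exceed
the formula's intended range).

The static nonlinearity is fit to 100 equal-count bin means of the
(linear prediction, response) scatter — stable sort, `np.array_split`
for ties — by bounded least squares on
`N(x) = β + α Φ((x−μ)/σ)` with α > 0 enforced (monotone increasing).
Initialization: β = min bin mean, α = range, μ = prediction at the
half-range response, σ = quarter of the prediction span. Burn-in (the
first filter-length of samples of the session) is excluded from the
scatter. `i_rect` is evaluated from the fitted N at the bin-prediction
extrema and 0, clipped to [0, 1].

Model accuracy is the squared Pearson correlation between the model's
repeat-segment output (averaged across trials) and the mean recorded
repeat response, burn-in and edge band excluded.

## emIPSC analysis

Detection operationalizes "filtered and thresholded": each trial is
zero-phase low-pass filtered at 500 Hz and differenced over a fixed 1-ms
step; the threshold is 4.5 baseline SDs of that difference signal, with
re-arming at half threshold, inside a 100-ms post-pulse window. A
one-sample first difference was rejected during development: at 10 kHz
it carries almost none of a ~1.5-ms rising phase and missed a quarter of
SNR-7 events. With the time-based step the detector achieves ≥ 95 %
sensitivity at ≤ 5 % false positives for events ≥ 5 noise SDs, and is
sampling-rate independent. Parameters are exposed in `DetectionParams`.

Exactly one suprathreshold rising phase classifies a trial as
monophasic, none as failure, more as multiphasic. The mean failure trace
isolates the stimulus-locked photocurrent and is subtracted from every
event. Amplitude is the post-alignment segment maximum; τ_decay is a
single-exponential fit from the peak to the segment end (150 ms), τ
bounded at 500 ms (a pinned fit raises). The fit window is deliberately
of fixed extent: an amplitude-adaptive window keyed to the noisy 1/e
crossing truncates the slow tail of small events and induces a spurious
positive amplitude–τ association; with the fixed window the Kendall τ of
a fixed-kernel ensemble is ≈ 0, the premise behind treating compound
IPSCs as linear sums of unitary events.

Averages are aligned at the first threshold crossing and fit with the
product forms (three starts on the time constants, bounded least
squares); the DSGC decay pair is reported fast-to-slow.

## Wiener deconvolution and hybrids

`H(f) = K̄S/(|K|²S + N)` with K the transfer function of the unit-peak
average emIPSC (zero-padded to the recording length; the kernel starts
at its onset so release is causally placed), N the Welch spectrum
(0.5-s Hann segments) of a ≥ 1-s pre-stimulus baseline, and S the
recording's periodogram smoothed over 2 Hz, minus N, floored at a small
positive value. The exact regularization is a package choice; the
governing contract is the round trip: reconvolving the train with the
matched kernel reproduces the input with r² > 0.99 at amplitude SNR 10,
degrading monotonically at lower SNR. Trains are left unrectified and
unsmoothed for downstream analysis. A fixed `signal_psd` may be supplied,
making the operator exactly linear in the recording.

Hybrid IPSCs are causal convolutions of a release train with the other
cell type's unit-peak kernel, truncated to the train length. Presynaptic
LN analysis substitutes the release train for the session's responses;
presynaptic spectra are Welch spectra (2-s Hann segments, 50 % overlap
— resolving 2.5 Hz while averaging the full 100 s) normalized to the
power at the bin nearest 2.5 Hz.

## Contamination simulation

The contaminant family is the mean photocurrent template × 0.146 (the
conservative mean + 3 SEM bound derived from the E_cation/E_Cl amplitude
ratio 0.088 ± 0.019), optionally convolved with exponential filters
(τ = 10, 31.6, 100, 316 ms) truncated at 10 τ and renormalized so the
tap sum is exactly 1 — the discrete reading of "integral of 1", which
keeps a constant template's amplitude scale-controlled only. For each
(SAC, DSGC) pair of repeat-segment means on a common time base the DSGC
trace is downscaled by the SD ratio, each variant added, and
Δr² = r²(contaminated) − r²(downscaled) computed; the grid is averaged
over SAC cells. Only linear interaction is modeled.

## Desensitization estimator

`v(t) = [ipsc ⊛ e^(−t/τ)](t)·dt / (q N)` with τ = 35 ms (fast GABA_A
desensitization), q = 1.4 pC per vesicle, N = 500 synapses; the
exponential is peak-normalized (first tap exactly 1) and truncated at
10 τ. The dt factor converts the discrete convolution into a charge
integral, so a constant current I settles at I τ/(q N) to first order in
dt (0.1 % at 10 kHz). Median and IQR summarize the raw time series;
the reported distribution is a right-open histogram (default 0.001-wide
bins over [0, 0.1], out-of-range samples clipped into the edge bins).
Cell-averaged histograms carry per-bin SEM; pooled quantiles are read
from the averaged histogram by cumulative interpolation.

## Synthetic-data generator

Forward model: stimulus → presynaptic filter (unit-L2 gamma-bump
difference) → drive standardized to unit variance → rate
`floor + rate_max Φ((z − θ)/s)` → inhomogeneous Poisson event times by
thinning → unit-peak unitary kernel scaled by lognormal amplitudes
(CV 0.3) → additive Gaussian noise (4 pA). Release events, not
Gaussian-rate currents, are the noise backbone because deconvolution and
the vesicle estimator assume delta-like release. The rate floor
(0.5 events/s) keeps baseline content in the trains.

Reference archetypes (constants documented here; all in
`reference_models`):

* **DSGC-like** — monophasic presynaptic filter (positive lobe peaking
  at 12 ms, order-3 gamma bump), strong rectification (θ = 0.9,
  s = 0.7), rate_max 400 Hz, biexponential kernel τ = 11.9/54.2 ms with
  a 0.3-amplitude slow term and 1.5-ms rise.
* **SAC-like** — biphasic presynaptic filter (positive lobe at 12 ms,
  negative lobe 40 % of peak at 24 ms; b_φ of the taps ≈ 0.46), mild
  rectification (θ = 0, s = 1), rate_max 900 Hz, monoexponential kernel
  τ = 18.1 ms with 1.5-ms rise.

The shared 12-ms positive-lobe timing keeps the recorded filter peak
latencies of the two types within a few milliseconds, which in turn
keeps responses of different cell types to a common stimulus
substantially correlated — both properties of the real measurements this
generator emulates, and both essential for the contamination comparison
to be meaningful. The rate maxima are set so that Poisson shot noise
leaves repeat reliability in the 0.7–0.9 range (at low rates shot noise
alone pushes reliability below the 0.7 gate); they can be read as
aggregate release over the convergent presynaptic population. Event
amplitude statistics in the real data are unknown; CV 0.3 is a
documented free parameter chosen to keep the amplitude–τ association
near zero.

What the generator does **not** emulate: dendritic (cable) filtering and
space-clamp error beyond the explicit contaminant; correlated or
history-dependent release (depression/facilitation, refractoriness
beyond the rate floor); amplitude–kinetics covariation of unitary
events; drift, series-resistance changes, or line noise. Passing tests
therefore demonstrate that the analyses recover what they assume — not
that real recordings satisfy those assumptions.

## Problem sizes and determinism

Recovery and ordering checks use the full 10 × 10-s protocol at 10 kHz
with five paired seeds; the contamination comparison uses three cells
per type on a common stimulus; event analyses use 60–180 pulse trials.
These sizes make every stochastic contrast reproducible across seeds
while keeping the whole suite and the acceptance script fast. All
randomness flows from `numpy.random.default_rng` seeded per component;
equal seeds give bitwise-equal data.

## Known limitations

* The cross-correlation filter estimate is band-limited by the stimulus;
  structure above 30 Hz in the true kernel is unrecoverable by design.
* The Wiener train is a linear estimate: it resolves release bursts, not
  individual vesicles, and its amplitude scale inherits any error in the
  unit-peak kernel normalization.
* `b_φ` and `i_rect` are point summaries of band-limited estimates;
  clipping at [0, 1] hides pathological filters rather than flagging
  them (the raw extrema remain available on the filter object).
* The contamination analysis assumes linear summation of the photocurrent
  with the IPSC; conductance interactions are out of scope.
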