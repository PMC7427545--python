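# Methods

This note documents the models, defaults, and numerical choices behind
`dualeeg`, and what the synthetic validation loop does and does not show
about real recordings.

## The validation problem

Two EEG systems record the same scalp potential simultaneously. The
question is whether the consumer system — lower amplitude resolution,
slower and slightly drifting sampling clock, fixed hardware band —
captures the same event-related potentials, steady-state responses, and
band power as the research system. The package frames this as a
simulation study with known ground truth: a master scalp signal is
synthesized, both virtual devices record it, both streams pass through an
identical analysis chain, and agreement statistics quantify how close the
two sets of measurements are — and how close each is to the injected
truth.

## Paradigm generators

The oddball generator parameterizes the tone stream as runs of standards
around each deviant: a leading run (≥ 3 standards), 99 inter-deviant runs
(5–35 standards, a stricter minimum at block boundaries so every block
opens with its leading standards), and a trailing run. Surplus standards
above the per-run minima (68 of 566 under the default design) are spread
by a multinomial draw with cap repair. The resulting distribution over
valid sequences is not exactly uniform — runs near the cap are slightly
disfavoured — which is acceptable here because all published constraints
are hard-checked per sequence (the test suite re-validates every emitted
sequence with an independent scanner). SOAs are i.i.d. uniform on
900–1,100 ms; uniform is the minimal-assumption reading of "randomly
jittered", and the distribution is configurable. Total duration is the
sum of all SOAs, hence 666 s in expectation for 666 tones.

The image task pairs each unique face/watch image with one upright and
one inverted presentation and permutes the order per seed; the simulated
self-paced response interval is uniform on 500–1,000 ms. Flicker
schedules emit one event per complete stimulus cycle. Resting blocks are
two labelled contiguous intervals with boundary events.

## Source model

Brains are abstracted to per-channel weight maps; there is no head
geometry or dipole solution. ERP components are Gaussian envelopes
(latency, FWHM, amplitude, polarity) with topographies typical of each
component: a frontocentral N1/P2 to every tone, a −2 µV deviant-only
negativity at 150 ms (FWHM 80 ms), a +5 µV parietal positivity at 330 ms
for attended deviants, occipito-temporal face negativities at 170 ms
(−4 µV, right-biased) with a +7 ms latency shift and 20% amplitude gain
for inverted faces (the qualitative inversion effect; magnitudes are
config defaults, not published values), and smaller watch responses.
Oscillations are condition-gated sinusoids: a 1 µV occipital 14.36 Hz
flicker response, and occipital alpha of 1.5 µV (eyes open) vs 5 µV
(eyes closed).

All source weight maps are centred to zero mean across the 16-channel
montage, so common-average re-referencing downstream is truth-preserving
and injected amplitudes can be compared to recovered ones exactly. Blink
topographies are *not* centred: ocular artifacts genuinely violate the
zero-mean assumption, which is what makes them removable by reference
regression.

Background noise is per-channel 1/f-amplitude ("pink") noise at 4 µV RMS
plus 1 µV RMS white noise. These defaults were chosen to land the
simulated ERP signal-to-noise ratios in the mid single digits, the range
typical of averaged scalp ERPs; they are deliberately not a best case.
Blinks are a homogeneous Poisson process (12/min) of 400 ms raised-cosine
bumps, +120 µV at the frontal pole with weights decaying toward posterior
channels.

What the generator does **not** emulate: non-stationary noise, muscle and
movement artifact, electrode drift/pops, alpha waxing-and-waning,
latency jitter of components across trials, overlapping responses at
short SOAs, or inter-participant topography differences. Passing the
recovery tests therefore shows the *analysis chain* is correct and the
device model's degradations are tolerable — not that any real headset
performs equivalently.

## Acquisition model

Each virtual device applies, in order: its hardware band (4th-order
Butterworth, applied forward–backward), polyphase rational resampling to
its *true* rate, uniform mid-tread quantization over its input range with
saturation clipping, additive Gaussian sensor noise, and event-marker
re-indexing with Gaussian timing jitter. The two presets are a
research-grade amplifier (1,000 Hz, 24 bits over ±200,000 µV → 0.024 µV
steps, 0.2 µV noise, 0.1 ms jitter) and a consumer headset (true rate
129.05 Hz despite a 128 Hz nominal, 14 bits over ±4,096 µV → 0.5 µV
steps, 0.2–45 Hz hardware band, 1 µV noise, 1 ms jitter).

Zero-phase hardware filtering is a deliberate idealization: real analog
front ends are causal and introduce group delay, which would shift both
devices' latencies; modelling that faithfully would confound the
agreement statistics with a removable constant offset. This is a known
limitation.

The default master grid is 8,192 Hz. Full-study runs and the acceptance
checks synthesize at 1,024 Hz — still ≥ 4× every oscillation frequency
and above the faster device's rate — because the higher grid buys nothing
for signals band-limited below 45 Hz. The demo study configuration also
shortens paradigms (132-tone oddball in 2 blocks, 10+10 images, 60 s
flicker, 30 s resting conditions) so a complete multi-participant study
stays in the minutes range; effect sizes, noise levels, and device
parameters are never scaled.

## Preprocessing

The canonical order — bandpass (0.1–30 Hz, 4th-order Butterworth,
forward–backward so the response is zero-phase), resample, common-average
re-reference, ocular removal — is enforced by `preprocess_recording`.
Resampling targets the slower device's *measured* rate (samples divided
by elapsed seconds), not its nominal rate; a hair of upsampling is
permitted there because the measured rate can sit just above nominal.
Events are re-indexed to the nearest output sample.

Default ocular removal is windowed reference regression: the blink-band
(0.5–8 Hz) mean of Fp1/Fp2 is thresholded at 4 robust (MAD) z-units,
detections are dilated by ±150 ms, and each channel's least-squares
projection onto the reference is subtracted *within detected windows
only*. Away from blinks the data is untouched, so clean recordings pass
through essentially unchanged — a property plain full-record regression
lacks. An ICA route (FastICA, fixed seed; components correlating with a
frontal channel at |r| > 0.8 are zeroed) is provided because component
selection criteria for ICA-based blink removal vary between labs; the
regression default is preferred here for transparency and determinism.

## ERP quantification

Epochs run −100…700 ms with the −100…0 ms mean subtracted per channel.
The epoch grid's left edge is floored (not rounded) onto the sample grid
so the baseline window is always inside the epoch at non-integer rates.
Rejection is |amplitude| > 150 µV on any channel/sample (exactly 150 µV
is retained), evaluated after ocular removal; the cross-system rule ANDs
the two accept masks, and a participant is flagged for exclusion when
either single system rejects more than 50% of trials. Measurement windows
are closed intervals on the nearest-sample grid; extremum ties resolve to
the earliest latency. The SNR's signal term is the RMS of the raw samples
in the window (not the absolute mean), and the baseline SD uses the
unbiased n−1 estimator; multi-channel SNR is the mean of per-channel
ratios.

## Spectral analysis

Spectra average non-overlapping 5 s Hanning-tapered FFT segments,
discarding any partial trailing segment. Two unit conventions are carried
explicitly: *amplitude* spectra are coherent-gain corrected (a pure tone
of amplitude A reads A at its bin — the convention the neighbor-bin SNR
needs), while *power* spectra are energy-normalized so bins sum to the
time-domain variance (Parseval), making band power an integral: a tone
contributes A²/2 to its band regardless of bin step or zero-padding. Bin
steps finer than 1/window (e.g. 0.004 Hz for the alpha analysis) are
reached by zero-padding, which interpolates the spectrum without adding
information; coarser steps aggregate natural bins (mean for amplitude,
sum for power).

The neighbor-bin SNR divides each bin by the mean of the 20 surrounding
bins (10 per side, skipping the immediately adjacent bin so the tested
bin's own leakage cannot contaminate its baseline); z-scores use the
neighborhood's n−1 SD. Edge bins with incomplete neighborhoods are
returned as NaN rather than computed from a shrunken neighborhood. On
featureless noise the SNR is ~1 by construction; note that because the z
denominator is estimated from only 20 bins, the z > 1.96 exceedance rate
on noise runs a little above the Gaussian 2.5% (a t-type inflation) —
the calibration test accepts chance level within a factor of two.

## Agreement statistics

**Waveform ICC.** Time points are treated as rated targets and the two
systems as raters. The default model is two-way, single-measure,
absolute-agreement — ICC(A,1) — because a systematic amplitude offset
between systems *should* count against agreement in a validation setting;
the consistency variant ICC(C,1) is exposed. CIs use the McGraw–Wong
F-distribution construction, cross-checked against pingouin. Waveform
samples are serially correlated, so these CIs are optimistic as
inferential statements; they are used here as the conventional
descriptive summary.

**JZS Bayes factor.** The default Bayesian paired t-test: Cauchy prior
with scale r = √2/2 on the standardized effect, computed by adaptive
quadrature of the g-mixture representation on a log-stable integrand,
with the reported relative integration error from the quadrature bound.
Verified three ways: against pingouin, against a 10⁶-draw Monte-Carlo
prior-predictive estimate, and against fixed-grid Simpson integration on
a compactified axis. The paired form is used throughout because the
design is within-participant (both systems measure every participant).

**Sequential stopping.** The BF is evaluated at n = 20 and after each
additional unit, stopping below 0.33 (equivalence) or above 3.00
(difference). Under a true null the rule lands on the equivalence bound
in the large majority of decided runs; with a standardized effect of 0.8
it decides "different" well before n = 60.

**Bayesian 2×2.** Implemented as JZS paired tests on the within-unit
marginal contrasts (each main effect) and the difference-of-differences
(interaction) — a transparent, oracle-checkable approximation to a full
mixture-of-g-priors ANOVA that is adequate for a 2×2 within design; the
approximation is recorded in the result metadata by construction (each
output is a labelled contrast BF).

**Wilcoxon signed-rank.** Zero differences dropped, average ranks for
ties with the usual variance correction, normal approximation for the Z
statistic; for n ≤ 12 the p-value comes from exhaustive enumeration of
all sign assignments.

## Degenerate inputs and tie-breaks

Zero-variance difference vectors raise (t undefined); the study runner
reports a null BF instead of crashing in the exact-identity limit.
Extremum ties take the earliest sample. Epochs extending past either
recording edge are dropped with a warning. An all-standard oddball
(deviant fraction 0) is a valid degenerate sequence; infeasible
constraint sets raise an explicit error rather than silently relaxing.

## File formats

Recordings are written as plain text: a TSV sample matrix (one column per
channel, µV), a JSON sidecar (rate, labels), and a TSV event table
(onset_s, sample, label). EDF files can be read through MNE when it is
installed; output stays textual.
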