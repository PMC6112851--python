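# Methods

This note documents the models, estimators and numerical choices behind
`songcircuit`: what the synthetic generators emulate, how the evoked-response
and song analyses are defined, which parameters matter, and what the
package's tests do and do not demonstrate about real recordings.

## 1. Evoked-response analysis (PSTH)

### Model of the data

A single-pulse electrical stimulation (1 ms pulse, 1.6 s inter-stimulation
interval by default) is delivered repeatedly while one unit is recorded
extracellularly. Spike times are binned into a peri-stimulus time histogram
(PSTH): trial-aligned counts averaged over trials and converted to Hz. Bin
width is 2 ms for high-rate (pallidal-like) units and 10 ms for low-rate
structures, where fine bins would fluctuate too strongly. Baseline mean and
SD are computed from the bins fully inside the pre-stimulation baseline
window (50 ms for high-rate structures, 100 ms for low-rate ones).

Units are classified by spontaneous rate: above 25 Hz, pallidal-like
(the spontaneously active projection neurons of the song basal ganglia);
below 10 Hz, excluded from response analysis; in between, unclassified.

### Detection rule

A response starts at the first of at least two consecutive bins strictly
beyond baseline mean ± k·SD (k = 2.5), and ends on the return of two
consecutive bins inside that band; the event offset is the end of the last
beyond-threshold bin. Polarity (excitation/inhibition) is the side of the
band crossed. Three conventions close gaps the rule leaves open:

* **Strict inequality.** Bins exactly at mean ± k·SD are non-responsive.
* **Single interrupting bins.** One in-band (or opposite-polarity) bin inside
  a response does not split it — the end rule demands *two* consecutive
  in-band bins. Two consecutive opposite-polarity bins end the current event
  and start a new one immediately.
* **Artifact blanking.** The first 2 ms after stimulation onset (the
  stimulation-artifact "blind" period) are excluded from detection;
  configurable, since the true artifact length depends on the hardware.

**SD floor.** The empirical baseline SD comes from a few tens of bins and is
noisy; when it happens to be underestimated, the band narrows and isolated
noise runs leak through as spurious events. Spike counts are not materially
under-dispersed relative to a Poisson process, so by default the detector
floors the SD estimate at the Poisson counting SD, sqrt(mean / (n_trials ×
bin_s)). The raw empirical band is available with `sd_floor="none"`. A
digitally silent baseline falls back to a one-spike floor so the band never
collapses.

### Response measures

* **Latency**: time from stimulation onset to the onset of the first
  (excitatory or inhibitory) event.
* **Strength**: sum over response bins of (rate − baseline mean) × bin
  width, in excess spikes per stimulation. For pallidal-like and premotor
  units the convention is the first excitatory peak only
  (`mode="first_excitation"`); for cortical nuclei with bimodal responses,
  all excitatory peaks (`mode="total"`).
* **Peak rate**: maximal PSTH value within the excitatory events.
* **Profile label**: `[exc]` → excitation_only, `[exc, inh]` → biphasic,
  `[inh, exc, inh]` → triphasic, `[]` → none, anything else → other.
  Inhibition-only responses are measured but labelled `other`.
* **Percent of resting response**: 100 × strength(condition) /
  strength(baseline), for pharmacology conditions.

The default response search window is 0–300 ms post-stimulus, covering
latencies up to the late (~125 ms) cortical second peak plus offsets.

### Pharmacology comparisons

Condition contrasts (baseline vs drug vs washout) on strengths, peak rates
or spontaneous rates use the Wilcoxon signed-rank test when the same units
are measured in both conditions, and the rank-sum test otherwise. All-zero
paired differences return p = 1 with a warning: identical measurements carry
no evidence, and failing would be wrong for control analyses.

## 2. Song segmentation and features

### Envelope and spectrogram

The amplitude envelope is the sliding-window RMS of the waveform (default
5 ms window) evaluated on a 1 kHz grid. 5 ms resolves 10 ms inter-syllable
gaps while averaging out carrier ripple for fundamentals ≥ 400 Hz.
Spectrograms are magnitude STFTs with a 256-point Hanning window and
128-point hop.

### Motif detection and similarity

Putative motifs are local maxima of the sliding Pearson correlation between
the recording envelope and a clean template-motif envelope, above a
threshold (default 0.6), with non-maximum suppression over one template
length. Candidates are then scored by spectrogram similarity — the peak
over time lag of the normalized cross-correlation between log-magnitude
spectrograms with per-column mean removal (shape, not loudness) — and
accepted at or above a configurable threshold (default 0.5). Both scores
are gain-invariant by construction. Bouts group accepted motifs separated
by less than 500 ms of silence.

### Syllable segmentation

Within each accepted motif window (padded by 40 ms on both sides so a
template-length window does not clip a rendition sung slightly longer), a
per-motif threshold is set at

```
max(min envelope within the motif × 1.1, background RMS × 3)
```

The minimum envelope inside a motif sits in its quietest gap; the 1.1 margin
and 3× noise floor make the crossing robust. Background defaults to the
10th percentile of the recording envelope, floored at 0.2% of the envelope
peak so digitally silent stretches cannot drive the threshold to zero.
Maximal runs above threshold become segments after closing dips shorter
than 5 ms and dropping blips shorter than 10 ms. Because the RMS window
spreads a near-floor crossing outward by about half the window on each
side, boundaries are pulled back in by that amount; residual duration bias
on synthetic ground truth is under 1 ms (tolerance 5 ms). All times are
seconds from recording start; segments are half-open [onset, offset).

Relative amplitude is the peak envelope in the syllable over the peak
envelope of the motif (in (0, 1]). Syllable types are matched positionally
within accepted motifs; no acoustic clustering is attempted.

### Fundamental frequency

For harmonic stacks, F0 comes from the normalized biased autocorrelation of
a 40 ms window centered in the segment (configurable multi-window placement
for syllables with distinct sub-element fundamentals): lags spanning
[1/f_max, 1/f_min] (defaults 1500 / 300 Hz, the zebra-finch harmonic-stack
band) are scanned, the highest peak refined by parabolic interpolation, and
the estimate declared undefined when the peak correlation (harmonicity)
falls below 0.5. The biased estimator decays with lag, which breaks the tie
between the true period and its multiples in favour of the true period. The
estimate is invariant to polarity flips and gain.

## 3. Learning statistics

Features are grouped into periods: *pre* (the two days before surgery),
*post 1–2 / 3–4 / 5–6* (day offsets from surgery), and *crystallization*
(90–91 dph). Per syllable type and period the module computes mean, SD, CV
(sample SD / mean) and n.

* **Relative change** = 100 × |post mean / pre mean − 1|. Reported changes
  are small percentages, so the "ratio" is interpreted as a percent change;
  the raw sign-preserving ratio is emitted alongside.
* **Learning trajectory** = relative change at crystallization − relative
  change at post days 5–6 (signed, percentage points).
* **Group contrasts** (sham vs lesion) use the unpaired rank-sum test —
  the groups contain different birds, so a paired test is not applicable.
* **Pooling check**: before pooling syllable types within a group,
  Kruskal–Wallis verifies that pre-period CVs are homogeneous between birds
  and between syllable types (pre only, so surgery-related drift cannot
  masquerade as heterogeneity).
* **Imitation**: a pluggable scorer interface; the built-in score is the
  spectrogram cross-correlation similarity against the tutor motif, averaged
  over a seeded random sample of clean bouts (convention: 50–100 per
  condition). The normalized imitation score is crystallization / pre
  (> 1 = improvement). Its dependence on lesion size (percent of the
  lateral deep cerebellar nucleus left intact; 100% for shams) is tested
  with Pearson correlation and the classic no-correlation p-value.
* **Multiple testing**: Holm step-down across a declared test family
  (default), monotone and never below the raw p-values.

Rank tests use the exact small-sample null (n ≤ 25, no ties) and a
tie-corrected normal approximation otherwise.

## 4. Synthetic data generators

The generators exist so every analysis stage can be tested by parameter
recovery; their defaults are the study conditions.

### Spike trains

Firing rate = baseline + a sum of rectangular kernels aligned to each
stimulation onset. Rectangles make the expected strength closed-form
(amplitude × duration) for analytic tests. Spikes are drawn by thinning a
homogeneous Poisson process at the peak rate — exact for piecewise-constant
rates. Configurations whose instantaneous rate would go negative (inhibition
deeper than baseline) are rejected at construction, checked exactly at the
kernel breakpoints. Pharmacology series scale kernel amplitudes by factors
in [0, 1] with baseline unchanged (baseline / drug / washout).

### Song audio

Harmonic syllables are 1/k-weighted sums of harmonics of an F0 in the
400–800 Hz band; noise syllables are 1–8 kHz band-limited noise bursts.
Both sit under trapezoidal envelopes with 5 ms ramps — sharp, unambiguous
threshold crossings for ground truth. Motifs are 4–6 syllables
(30–200 ms) with 10–100 ms gaps over a small additive noise floor; bouts
contain 1–3 motifs with inter-motif silence drawn from (100, 450) ms and
more than 500 ms of framing silence, exercising the bout rule on both
sides. Imperfect imitation is emulated by blending band noise into
harmonic syllables (`noise_mix`); rendition-to-rendition variability by
multiplicative duration jitter (default CV 2%) and F0 jitter (0.5%) —
realistic orders for adult zebra-finch song.

### Cohorts and the drift model

A cohort is n lesion + n sham birds (defaults 10 + 6), surgery at 57 dph,
recordings on the two pre days, post days 1–6, and 90–91 dph, with
lesioned birds' intact fraction drawn uniformly from 30–95%. No
quantitative map from lesion size to song drift exists, so the drift model
is a deliberately simple, explicit choice:

* **Duration.** Each syllable carries a random drift sign and per-syllable
  magnitudes drawn around group means: an acute change (default 2%) in
  post days 1–6 and an additional learning-related change by
  crystallization — defaults 12% (sham) vs 4% (lesion), the study-condition
  trajectory magnitudes. Factors are multiplicative and piecewise-constant
  per period, so the recovered trajectory equals the configured one by
  construction.
* **Imitation.** The spectral noise mix starts at 0.5 (immature song) and
  relaxes toward 0.08 at crystallization by an amount proportional to the
  intact fraction (plus per-bird noise, SD 0.06), making the normalized
  imitation score increase with intact fraction — a positive lesion-size /
  imitation dependence by construction.

`simulate_cohort_features` draws the same duration/F0 model directly as a
feature table without audio — the fast path for statistical power studies
where the acoustic front end is not under test; `generate_cohort` renders
the full audio.

All generators are deterministic: one seed flows through
`numpy.random.default_rng`, and identical configurations are byte-identical.

## 5. What the tests show — and what they do not

Passing parameter-recovery tests on this synthetic data shows that the
estimators are unbiased and correctly calibrated *under the generative
model*: Poisson spiking with rectangular kernels, clean trapezoidal
syllables, stationary noise floors, a drift model with known functional
form. Real recordings add spike-sorting errors, non-Poisson firing
statistics, anesthesia-state drift, cage noise, overlapping calls, singing
rate changes, and syllable-type confusions — none of which the generators
model (biophysical neuron models and realistic vocal-tract synthesis are
out of scope). Recovery tolerances (duration 5 ms, F0 1%, latency one bin)
should therefore be read as the method's floor under favourable conditions,
not as field accuracy.

## 6. Problem sizes used in the shipped checks

The test suite and the acceptance script run scaled problem sizes chosen to
exercise every stage at meaningful statistical power: 500-trial sessions
(20 seeds) for strength/latency recovery; 400-trial sessions (100 runs) for
profile classification; a 200-rendition, 6-syllable corpus plus 10
noise-only files for song recovery; 50 cohort seeds at the study's
21-vs-24-syllable sample sizes for trajectory discrimination (25
renditions/day); 100 audio cohorts at n = 10 for correlation recovery
(2 bouts/day on 4 scored days, 22.05 kHz); and 10,000 null simulations for
rank-test calibration. The acceptance script uses smaller seed counts for
the same quantities where the Monte-Carlo spread is already far from the
decision boundaries.

## 7. Known limitations

* Syllable types are matched positionally within a motif; swapped or
  dropped syllables would mis-pair types.
* The envelope threshold rule assumes the quietest motif gap is quieter
  than every syllable; breathy or continuous song would need the
  configurable margin/floor retuned.
* The F0 estimator reports a single fundamental per window; biphonation is
  not modelled.
* The drift model's linear intact-fraction maps are a modelling choice, not
  a measured dose–response curve; only the qualitative direction (larger
  lesions, less learning) is anchored.
* Exact rank tests require untied data; heavy ties silently shift to the
  tie-corrected normal approximation.
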