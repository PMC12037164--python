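# Methods

This note documents the models, parameters and numerical choices behind
`silenttrack`, and what the synthetic-data tests do and do not establish
about real recordings.

## Stimulus features

**Cochlear filterbank.** Band edges are equidistant on the Liberman cat
cochlear frequency–position map rescaled so that the full position
interval [0, 1] spans up to 20 kHz: f(x) = A·(10^{2.1x} − 0.8) with
A = 20000/(10^{2.1} − 0.8). The range endpoints are inverted, n+1 equally
spaced positions taken, and mapped back. For nine bands over
100–10,000 Hz the rounded edges are 100, 220, 402, 679, 1103, 1748,
2731, 4231, 6516, 10000 Hz — within 1 Hz of the published cutoff table
everywhere except the first edge (100 vs 101, a 1% endpoint-convention
difference we report rather than tune away).

**Envelope.** Per band: zero-phase (forward–backward) 4th-order
Butterworth band-pass, magnitude of the Hilbert analytic signal; equal-
weight average across bands; FFT resampling to 150 Hz. Zero-phase
filtering is chosen because phase alignment across bands matters when
averaging band envelopes. FFT ringing can push isolated output samples a
few ulp below zero; envelopes are clipped at 0 to preserve
non-negativity. One resampling convention (Fourier zero-pad/truncate) is
used throughout, including the 50→150 Hz lip upsampling.

## Preprocessing

Broadband 0.1–12 Hz band-pass with a symmetric Hamming-window FIR kernel
applied by overlap-add; kernel length = 6.6/(shortest transition band) ×
rate, forced odd, group delay compensated by centred alignment. Default
transitions: min(hp, 2 Hz) at the high-pass edge, 25% of the low-pass
frequency at the low-pass edge — common MEG-toolbox defaults; the length
rule applied to the shortest transition gives a 9901-tap (66 s) kernel
at 150 Hz, so recordings must exceed ~66 s. The continuous data are
filtered first (reflect-padded by one kernel length), then cut into
non-overlapping 6-s epochs; stimulus features ride along as extra matrix
rows so epoch alignment is structural. No detrending beyond the
high-pass.

## Spectral estimation and connectivity

6-s epochs, DPSS tapers with time-halfbandwidth NW = T·W = 3 (spectral
smoothing ±0.5 Hz), hence K = ⌊2NW⌋ − 1 = 5 tapers, each with
concentration > 0.9. The "smoothing 0.5" parameter is read as ±0.5 Hz
(the tapsmofrq convention); reading it as NW would give K = 0, which is
impossible. Fourier coefficients are evaluated at exactly the grid
frequencies 1/6…5 Hz (the grid step equals the Rayleigh spacing, so this
coincides with zero-padded DFT bins). Epochs and tapers pool as equally
weighted estimates of the cross-spectral density; coherence is
magnitude-squared; for independent signals E[Ĉ] = 1/n_est. Partial
coherence applies the Schur complement to all of S_aa, S_bb, S_ab before
the ratio; a zero-power partial channel degrades to a warned no-op, and
degenerate denominators yield NaN bins that are excluded from band
averages and cluster statistics rather than zero-filled.

A consequence worth knowing: with ±0.5 Hz smoothing, coherence carried
by a band only 0.5 Hz wide (the 0.33–0.83 Hz coupling band) is diluted
by out-of-band noise inside the smoothing window — a true in-band
coupling of 0.6 yields measured coherence of order 0.1. Partialization
is only clean when the transfer from the partialized channel is roughly
constant across the smoothing window; the partial-coherence validation
fixture therefore uses a band (0.5–2 Hz) wider than the smoothing.

## Cluster permutation statistics

Dependent-samples t: per-bin paired t over forward−backward differences,
cluster-forming threshold = two-sided critical t at p = 0.01, clusters
formed separately per sign under a declared adjacency (1-D frequency
chain by default; frequency×channel analyses use the graph product of
the frequency chain with a channel chain). Cluster mass = summed t; the
null is the maximal |mass| over random within-subject sign flips, the
observed labelling included, so min p = 1/(1+n_perm); a cluster is
called significant at level α when p ≤ α/2 (the two-sided convention of
the major cluster toolboxes). On one bin this reduces exactly to a
paired permutation t-test (verified by full 2^n enumeration), and the
implementation matches an independent toolbox oracle on shared data.

Mixed 2×k ANOVA (split-plot): between-subject group F from subject
means, within-subject modality and interaction F from per-subject
modality differences; verified against a hand-computed worked dataset
and against `pingouin.mixed_anova` on balanced designs (unbalanced
designs use weighted-means sums of squares inside the permutation
scheme, which calibrates the reference distribution regardless).
Permutation schemes: group → permute group labels; modality → flip
modality within subjects; interaction → modality flips under fixed
groups (an approximate scheme — no exact interaction permutation
exists). F clusters are one-sided at the critical F for p = 0.01. The
three effects are reported jointly without cross-effect correction.
Post hoc: paired t within subjects, Welch t (Satterthwaite fractional
df) between groups, two-sided, uncorrected.

## Synthetic cohort generator

The generator's job is to produce data with the statistical structure
the analysis assumes, at effect sizes that give comfortable power at
desk scale (tens of subjects, minutes of data). Defaults:

| parameter | default | meaning |
|---|---|---|
| syllable_rate | 3.3 Hz | modulation peak of the envelope |
| sentence_rate | 0.25 Hz | mean sentence gating rate |
| coupling_band | 0.33–0.83 Hz | where channels couple to the envelope |
| coupling_strength | hearing 0.6 / DHH 0.75 / congenital 0, forward only | target in-band driver coherence |
| ocular_gain | 0.8 | ocular coupling relative to neural |
| blink_rate | 0.2 Hz | Poisson blink rate |
| blink_envelope_coupling | 0.3, forward only | blink timing bias to envelope troughs |
| noise_exponent | 1 | 1/f background slope |
| duration | 120 s per condition | 20 epochs ⇒ n_est = 100 |
| lip_corr | 0.6 | corr(lip trace, composite envelope) |
| n_per_group | 49 / 18 / 7 | the study's group sizes (tests use smaller) |

**Envelope.** Syllable events on a jittered lattice (event i at i·T +
N(0, (0.2T)²)): a renewal (cumulative-interval) process was rejected
because its spectral peak sits several percent above the nominal rate,
violating the generator's own 3.3 ± 0.3 Hz contract; the lattice pins
the peak exactly while the jitter broadens it. Pulses are 100-ms Hann
kernels, gated by a smoothed on/off sentence wave with gamma-jittered
sentence durations (CV ≈ 0.3, duty cycle 0.8) — deterministic gating
periods would concentrate all sub-1-Hz power into single Fourier lines —
plus a small positive noise floor.

**Two-component stimulus model.** The composite envelope is
ρ·(lip-visible component) + √(1−ρ²)·(acoustic-only component), both
independent envelope realizations; the lip trace follows the
lip-visible component, and channels couple *only* to the band-filtered
acoustic-only component. This encodes the claim under test — tracking is
specific to unheard acoustic features — and makes channel–lip coherence
exactly chance by construction. (Regression-based orthogonalization of
the driver against the lip was tried and rejected: it biases lip
coherence slightly off chance, enough to create spurious lip clusters
at n = 15.)

**Coupling calibration.** Channel = g·driver + 1/f noise with g set so
the in-band SNR is s/(1−s), i.e. expected in-band coherence with the
driver ≈ s. Realized channel–envelope coherence is several-fold smaller
(smoothing dilution plus the √(1−ρ²) mixing weight), which is why the
default strengths sit high in [0, 1). The backward condition couples to
the time-reversed driver with strength 0 by default: coherence with
either stimulus ordering is at chance, the intelligibility-dependence
assumption in its sharpest form.

**Ocular channel.** Same coupling scaled by `ocular_gain`, plus a blink
train: Poisson events (400-ms minimum separation so pulses do not fuse),
300-ms biphasic kernels (positive Hann lobe, 25% undershoot), amplitude
8× the noise SD. With `blink_envelope_coupling` > 0 (forward condition
only), events are thinned preferentially at high values of the *slow*
(<1 Hz) envelope — gating on the instantaneous envelope fails because
the detected pulse peak lags blink onset by ~0.1 s, beyond the fast
envelope's correlation time.

**What the generator does not emulate:** volume conduction and sensor
mixing, realistic source geometry, non-stationarity, saccades or gaze
shifts, subject-specific spectra, or any nonlinear stimulus–response
coupling. Passing tests establish that the estimators and inference
machinery behave correctly under the assumed linear band-limited
coupling model — not that real MEG effects of a given size would be
detected.

## Blink detection

Robust z-score (median/MAD, Gaussian consistency factor 1.4826) so the
blinks themselves do not inflate the threshold; peaks above z = 3
separated by ≥ 0.5 s. Blink rate = count/duration. The envelope-at-blink
statistic z-scores the envelope over the recording and samples it at
event centres; condition comparisons are paired t-tests over subjects.
False-alarm behaviour is scale-invariant (the robust z normalizes any
noise level), so the threshold, not the noise amplitude, controls
specificity.

## Problem sizes

Test and analysis runs use scaled-down cohorts chosen as the package's
desk-scale defaults: 120-s recordings (20 epochs × 5 tapers = 100
estimates per condition), 2–15 subjects per group, 300–500 permutations;
the type-I calibration uses 200 replicates of a 15-subject no-effect
simulation. Full-study group sizes (49/18/7) remain the generator
default and run in a few minutes if requested.

## Known limitations

* The interaction permutation scheme is approximate; its calibration is
  checked empirically, not guaranteed.
* Unbalanced mixed ANOVA uses weighted-means sums of squares; parametric
  p-values for strongly unbalanced designs should be taken from the
  permutation path.
* The ROI "strongest source" is selected on the forward−backward
  contrast (not raw forward coherence); with the selection applied
  before a condition test, the ROI condition effect is mildly
  selection-biased, as in any peak-picking analysis.
* Whether the original analysis filtered before or after epoch boundary
  definition is unknown; this implementation filters continuous data,
  then epochs.
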