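# Methods

This note documents the models, estimators and design choices behind
`erp2ch`, and what the synthetic-data tests do and do not establish about
real recordings.

## Setting

Two monopolar prefrontal channels (Fp1, Fp2), 250 Hz, 15-bit resolution
over a ±393 μV input range, recorded during an active auditory oddball
task: 256 frequent standard tones and 64 rare targets (4:1) at a 1,000 ms
onset-to-onset asynchrony, 50 ms tone duration, subjects pressing a key
for targets. With a 1 s lead-in this yields a 321 s session. (Reading the
stated 1,000 ms inter-stimulus interval as offset-to-onset would give
5 min 36 s instead; the onset-to-onset reading reproduces the stated
5 min 21 s recording and is the one implemented.)

Conventions: μV, ms, Hz; epoch windows half-open `[start, end)` with
stimulus onset at 0; sample k of an epoch at `start + 4k` ms.

## Synthetic sessions

The generator is first-class, tested code: its role is to produce data
with the statistical structure the analysis assumes, so each estimator
can be validated against known ground truth.

Per channel, the signal is the sum of:

1. **1/f background** — white Gaussian noise shaped to a 1/f power
   spectrum, RMS `noise_scale` (default 5 μV). A fraction
   `shared_noise_frac` (default 0.72, in power) is common to both
   channels; this sets the broadband baseline coherence (~0.5–0.6 across
   4–30 Hz, matching the overall coherence level typical of neighbouring
   prefrontal sites) without affecting band-specific group contrasts.
2. **Beta oscillation** — amplitude `beta_amp_rel × noise_scale`, laid
   down in per-stimulus segments covering (−200, 800) ms around each
   onset (segments tile the session exactly at the default SOA). Each
   segment draws a frequency uniformly from 16–22 Hz, a random phase, and
   an inter-channel phase offset from von Mises(0, κ). κ
   (`beta_coupling_kappa`) therefore directly controls the expected beta
   PLV across epochs — the mean resultant I₁(κ)/I₀(κ) — and the beta-band
   coherence. A multiplicative envelope `beta_erd_gain` (50 ms
   raised-cosine ramps) over 300–500 ms post-stimulus produces
   event-related desynchronization when < 1.
3. **Evoked components** — Gaussian bumps (SD 25/35/60 ms for
   N100/P200/P300), identical on both channels, at per-trial jittered
   latencies. The standard-epoch P200 amplitude decays by
   `p200_habituation` per standard trial (habituation). Component base
   amplitudes are *calibrated*: the configured amplitude is divided by
   the measured single-pass retention of the full linear chain
   (acquisition filters + analysis bandpass + baseline correction:
   0.766/0.683/0.538 for the three widths) and by the closed-form
   jitter-smear factor σ/√(σ²+jitter²), so the *measured*
   averaged-waveform amplitudes land at the intended values (e.g. target
   N100 ≈ −4, P200 ≈ +6, P300 ≈ +7.6 μV) rather than drifting with every
   filter choice.
4. **Acquisition filters** — the device's Butterworth cascade (2nd-order
   55–65 Hz band-stop, 1st-order 2.6 Hz high-pass, 8th-order 43 Hz
   low-pass) is emulated by a linear-phase FIR matched to the cascade's
   single-pass *magnitude* response. Matching magnitude while discarding
   phase keeps configured latencies recoverable within one sample, which
   the component-recovery tests rely on; a causal IIR emulation would
   shift slow components by several samples. Signals are then quantized
   to the device's 0.024 μV step and checked against the ±393 μV range.

**Behaviour**: each target is answered with probability 1 − `miss_rate`
at onset + RT, RT ~ Normal(`rt_mean`, `rt_sd`) truncated to (100 ms,
SOA); standards draw false alarms with probability `false_alarm_rate`.

**Cohorts**: one profile per subgroup (CN, SCD, aMCI, naMCI; HC = CN∪SCD,
MCI = aMCI∪naMCI). The default profiles are synthetic encodings of a
qualitative effect structure, not estimates: beta coupling ordered
CN > SCD > naMCI > aMCI (κ = 2.10/1.95/1.65/1.45); `beta_erd_gain` 0.7 in
HC vs 1.0 (no ERD) in MCI; target P300 latency jitter 42/46/53/56 ms;
RT SD 68/76/90/84 ms; miss and false-alarm rates worst in naMCI; P200
habituation fastest in aMCI. Evoked amplitudes and mean latencies are
identical across subgroups, so plain component measures carry no group
signal by construction. Group effect sizes are deliberately larger than
a real elderly cohort would show, so that the pattern is decidable at the
cohort sizes practical for simulation (100 per main group) rather than
the thousands of participants a clinical study would use.

Each participant individualizes the profile with lognormal scatter:
σ = 0.15 on κ, RT SD and target P300 jitter, and σ = 0.35 on a global
evoked-amplitude gain. The amplitude scatter matches the large
between-subject amplitude SDs seen in elderly ERP cohorts and is also
statistically necessary: without it, microscopic deterministic couplings
(e.g. the P300 filter undershoot beneath the N100 window differing
between groups because jitter-smear compensation differs) would be
declared significant at cohort scale, which no real cohort would show.
Covariates (age, sex, education) are drawn per subgroup from
distributions resembling an elderly memory-clinic cohort.

All randomness flows from named seeds through `numpy` `SeedSequence`
spawning; identical master seeds give byte-identical cohorts.

What the generator does *not* emulate: eye-blink/EMG artifact morphology
(only amplitude outliers via `inject_artifacts`), volume conduction,
electrode impedance drift, non-stationary background power, or
participant-level correlations between behaviour and physiology. Passing
tests therefore demonstrate estimator correctness and pipeline
sensitivity under the assumed signal model, not clinical validity.

## Preprocessing

0.1–30 Hz Hamming-window FIR (8 s of taps, so the 0.1 Hz edge is
feasible) applied to the *continuous* recording as a zero-net-delay
convolution, with explicit mean removal first (the 0.1 Hz edge lies
inside the transition band, so the filter alone leaves a DC residue).
Epochs (−200, 800) ms — the analysis range extends to 700 ms and the
P300 window to 600 ms; the 800 ms tail gives margin for time-frequency
edge effects. Baseline correction subtracts the per-epoch, per-channel
(−200, 0) ms mean. Artifact rejection removes epochs exceeding ±100 μV
on either channel (an automated, reproducible stand-in for manual
inspection; threshold configurable); a participant with no surviving
epochs is excluded. Random selection (default 64 of the 256 standard
epochs, seeded, order-preserving) equates standard and target trial
counts so that across-trial variability measures and Welch segment counts
are comparable between epoch kinds.

## Components and behaviour

Peaks are strict local extrema inside their windows (N100 most negative
in [60, 200); P200/P300 most positive in [180, 300)/[300, 600) ms), at
least 2 μV in magnitude, not on a window edge; ties resolve to the
earliest latency. Absence is a value, not an error — analysis proceeds
when the P300 is missing (common for standard epochs prefrontally).
Participant-level values come from the two-channel mean trace;
per-channel detections are retained. Single-trial P300 latency/amplitude
use the windowed maximum of each epoch's channel-mean trace low-passed at
10 Hz (4th-order Butterworth, zero-phase) — the simplest robust
estimator; SDs use the n−1 denominator everywhere. The response window is
(100, 1000) ms with first-press assignment; RT statistics use correct
target responses only.

## Connectivity

PLV: per epoch, both channels are band-passed (zero-phase Hamming FIR,
taps ≈ 3.3·fs/transition, capped at 251 given 250-sample epochs) and
Hilbert-transformed after mirror-padding 200 ms per side (pad discarded),
then `PLV(t) = |Σ exp(jΔφ)|/N`. A single epoch is rejected (PLV ≡ 1
identically). Features per band: max and its time (earliest tie), means
over the P200 (180–300), P300 (300–600) and positive (0–700 ms) windows.
The "positive window" is the post-stimulus analysis range 0–700 ms.

Coherence: magnitude-squared, with the Welch averaging running *over
epochs* — each epoch's post-stimulus span (200 samples) is one
Hann-tapered segment, FFT length 256 (~0.98 Hz bins); cross- and
auto-spectra are averaged before forming the ratio. Band features: max
and its frequency, mean, and SD across bins, the SDs reported ×100
(`COH_std` is the percentile of the SD of a [0, 1] quantity, giving the
8–12 range conventionally tabulated); the all-band mean/SD covers
4–30 Hz. Band-limited coherence is read from the full spectrum, not from
band-passed signals — the estimator is already frequency-resolved.

Known estimator biases, verified by the calibration tests: independent
channels give E[C] ≈ 1/N for N segments; finite-N PLV of uniform phases
is ~√π/2·N^(−1/2), not 0. Group comparisons are unaffected since N is
equated across participants.

## Time-frequency

Sliding 64-sample Hann FFT, hop 1 sample (3.90625 Hz bins; analyses crop
to 2–30 Hz), frame timestamped at its center. ERSP is
`10·log10(P(f,t)/P̄_baseline(f))` with the baseline mean taken over
frames centered in (−200, 0) ms — note that with 256 ms windows those
frames unavoidably overlap early post-stimulus samples; ERS/ERD
classification is by sign. ITC is the magnitude of the trial-mean unit
phasor, averaged over the two channels.

Significance: pointwise two-sided permutation test, p < 0.01, no cluster
correction (masks are exploratory). Each of the 200 seeded surrogates
bootstraps trials with replacement and draws one baseline frame per drawn
trial; for ERSP each surrogate also bootstraps its own dB reference.
Both resampling layers are necessary for calibration: frame-only
resampling freezes the between-trial variance (adjacent baseline frames
overlap almost completely at hop 1) and a fixed reference hides the
baseline anchor's sampling error — either omission inflates the empirical
false-positive rate several-fold, while the implemented scheme measures
~1% on stationary noise.

Time-trial maps: channel-mean trace per epoch in presentation order,
10-epoch boxcar along the trial axis, valid convolution (n − 9 rows), so
no edge rows are fabricated.

## Group statistics

Two-group comparisons: Shapiro-Wilk per group at α = 0.05; if either
rejects and all values are positive, both groups are log-transformed
(flagged), otherwise the comparison proceeds untransformed with a flag;
Levene's test then chooses Student's t (equal variances) or Welch's t.
ANCOVA fits `value ~ group + age + sex + education` with no
group×covariate interactions (parallel lines); sex is a binary indicator;
constant covariate columns are dropped (which makes the model collapse
exactly to the t test, a tested identity). Four-subgroup models report
the omnibus F and all six pairwise contrasts Bonferroni-adjusted
(p_adj = min(1, 6p)). Grand-average PLV curves are compared over seven
100 ms intervals (0–700 ms) and coherence spectra over seven named bands
(theta, low/high alpha, low/middle/high/very-high beta); pointwise
per-sample masks are uncorrected and exploratory.

## Replication experiment

`replication_experiment(seed)` simulates 50 participants per subgroup
(100 per main group), extracts all features, and evaluates the finding
pattern: significant (α = 0.05) RT_std and target P300_lat_std,
standard-epoch COH_std and beta PLV_P_B; null N100/P200 latency and
amplitude; null alpha/theta PLV (beta-specificity); and the ERD
contrast — on pooled target epochs of 6 participants per group, an "ERD
cluster" is ≥ 20% of the beta × 300–500 ms bins significantly negative
with a region mean below −0.5 dB, present in HC and absent in MCI. The
acceptance suite requires each finding to reproduce in ≥ 80% of 20 master
seeds; per-finding counting is used because the null findings alone have
a joint chance success rate below 80% under exact α = 0.05 calibration.
The problem size (50/subgroup, 6 participants for the ERD pool, 200
permutations) keeps one replication near 15 s while leaving all effects
clearly decidable.

## Numerical notes and limitations

* Epochs are only 250 samples; all per-epoch filtering uses mirror
  padding and capped FIR lengths, so theta-band phase estimates are
  smoother than a long-FIR implementation would give.
* The EDF writer is minimal (1 s records, 15-bit mapping over ±393 μV)
  and pads the final record with zeros; round trips are exact to the
  quantization step for whole-second recordings.
* Latency resolution is one sample (4 ms); all recovery guarantees are
  stated at that resolution.
* The pipeline analyzes standard and target epochs separately throughout;
  difference waves, directed connectivity, wavelet/multitaper variants
  and cluster-corrected permutation statistics are out of scope.
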