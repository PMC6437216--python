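# Methods

`seizkit` implements an EEG analysis chain for optogenetic kindling
experiments — automated electrographic-seizure detection by baseline
z-scored spectral power, per-session seizure metrics, seizure-onset
time–frequency dynamics, postictal depression, paired-pulse evoked-response
plasticity, and the cohort statistics that summarize kindling — together
with a seeded synthetic-EEG generator that provides ground truth for every
stage. This note records the models, the defaults and why they were
chosen, and the limits of what the synthetic validation can show.

## Session model

A stimulation session is: a pre-induction baseline (default 600 s), a
3-minute induction, and a post-induction baseline (default 1200 s) —
~33 minutes in total. During both baselines, pairs of 10-ms laser pulses
33.3 ms apart (a 30-Hz pair) are delivered every 10 s to probe the evoked
EEG response. The induction delivers 15 bouts of 3-s, 50-Hz stimulation at
50% duty cycle (five bouts per sweep, three sweeps, one sweep per minute).
All timing is configurable through `StimProtocol`. One reported variant
uses 5-ms induction pulses; the 50%-duty convention (10 ms at 50 Hz) is
the default and the width is a protocol field.

Cohort-scale computations in the test suite, the analysis drivers and the
acceptance script use a shortened session (120 s pre, 180 s induction,
300 s post) so that hundreds of sessions run in minutes; the detector
contract is validated on the full-length session.

## Synthetic EEG generator

The generator emulates the statistical structure the analyses assume — it
is not a biophysical simulation.

* **Background**: 1/f^α Gaussian noise (α = 1) at 50 µV RMS, with a
  first-order high-pass at 0.5 Hz emulating the AC coupling of an EEG
  amplifier. Without that corner, roughly half the 1/f power lies below
  0.5 Hz and wanders on minute time scales, which no recording rig passes;
  with it, 60-s broadband power estimates are stable to a few percent.
* **Evoked responses**: negative alpha-function deflections (5-ms rise,
  8-ms latency, ~15-ms width), amplitudes A1 = 100 µV and A2 = 120 µV for
  the two pulses of a pair. After the induction, the second response is
  multiplied by `potentiation_factor2` (default 1.4) while the first is
  unchanged — the dissociation the plasticity stage must resolve. During
  50-Hz induction bouts each pulse evokes a response at 0.3 × A1:
  synaptic transmission depresses strongly under sustained 50-Hz drive,
  so the tetanic steady-state response sits well below the paired-pulse
  amplitude. (An early design without this depression produced
  physiologically implausible tetanic oscillations that dominated the
  induction-epoch spectrum.)
* **Seizure occurrence** follows a logistic in session number
  (midpoint s₀ = 10, slope k = 2): seizures are absent early and nearly
  certain after session ~12, matching the observation that kindling needs
  more than ten sessions before the first seizure. Onset latency from
  induction start falls linearly (160 − 5·s seconds, floor 5 s, SD 5 s)
  and duration grows linearly (5 + 1·s seconds, ceiling 120 s, SD 2 s);
  both are clipped so the event fits in the induction + post window.
* **Seizure morphology**: the event is gated to its interval by a Tukey
  window (abrupt electrographic onset/offset) and is the sum of two
  components with tonic-plus-phasic envelopes — ripple-band (80–250 Hz)
  filtered noise at 250 µV whose phasic Gaussian bump (σ ≤ 2 s) sits near
  onset, and a ~5-Hz sawtooth spike-wave component at 300 µV whose bump
  (σ ≤ 2.5 s) peaks `hfo_lead_s` seconds later (default 6.4 s). The low
  tonic plateaus (25% / 35% of peak envelope) keep the whole event
  supra-threshold so detected edges track the true interval, while the
  phasic peaks carry the programmed high-frequency-before-low-frequency
  lead. Pure-Gaussian envelopes were tried first and rejected: they make
  events quiet at the edges (detected durations shrink) and their flat
  tops make envelope peak times poorly defined.
* **Postictal depression**: background amplitude is scaled by
  √(1 − d) for `postictal_dur_s` (90 s) after seizure end, so broadband
  *power* is suppressed by the fraction d (default 0.34).
* **Behavioural score**: a Racine-style severity score
  clip(round-to-half(r₀ + r₁·s + ε), 0, 6) with r₀ = 0.5, r₁ = 0.18,
  ε ~ N(0, 0.5) — a gradual climb from ~0.5 to ~5 over 25 sessions,
  scored in half-steps as behavioural scoring between two stages is.
* **Cohorts**: `stim-ChR2` animals get everything; `no-stim-ChR2`
  controls get paired pulses but no induction and no seizures;
  `stim-no-ChR2` controls get light but no responses and no seizures.
  Per-animal/session seeds are spawned deterministically from one master
  seed (`SeedSequence(seed, spawn_key=(animal, session))`), so cohorts
  are bit-reproducible.

What the generator does **not** emulate: real inter-animal variability in
spectra, artifacts (movement, chewing, electrical), interictal discharges,
seizure propagation across channels, and any biophysics. Passing tests
therefore demonstrate that the analysis chain is *correct and calibrated
under its stated assumptions*, not that it is robust to every failure mode
of real recordings.

## Spectral analysis

Spectrograms use 1-s Hann windows with 0.25-s steps (1-Hz resolution — the
delta band needs it — and 13+ windows across the shortest legal event).
Power is one-sided PSD normalized so that band-summed power × Δf equals
the windowed mean square (Parseval within taper leakage, verified to
<2%). Band power is the *mean* PSD over the bins of a half-open band
[f_low, f_high), so z-scores are comparable across unequal band widths.
The canonical seven bands tile 0–500 Hz: delta 0–4, theta 4–8, alpha 8–12,
beta 12–30, gamma 30–80, ripples 80–250, fast ripples 250–500 Hz. For
onset dynamics a figure-style convention is also exposed
(`ONSET_LOW_BAND` = 4–8 Hz, labelled "delta" in some onset figures, vs
ripples 80–250 Hz) because the spike-wave fundamental (~5 Hz) falls in
4–8 Hz.

**Baseline z-scoring.** Per-band statistics come from the pre-induction
baseline with windows overlapping the 200 ms after any stimulus pulse
excised (evoked deflections otherwise inflate σ). Statistics are taken on
**log10 band power** by default: raw band power is right-skewed
(χ²-like, with few effective degrees of freedom in the narrow low bands),
which makes linear z-scores heavy-tailed — sustained z > 7 excursions
appear in pure pink-noise delta power. On the log scale the baseline is
close to Gaussian and z-scores are exactly invariant to recording gain.
A linear-scale option is retained.

**Wigner–Ville.** The plain discrete Wigner transform of the analytic
signal satisfies the time marginal identity exactly (frequency-summed
transform = |analytic signal|², verified to <1%); the default
smoothed-pseudo variant applies independent Gaussian time and lag
smoothing to attenuate cross terms and is used for display and peak work.
Cost is O(N·M) memory with M lags, so long seizures are decimated before
transforming.

## Seizure detection

Per-band z-traces are combined by taking the **maximum over bands** at
each window (a seizure dominated by any single band — ripple early, delta
late — stays supra-threshold throughout; mean-over-bands is available).
Runs of windows with combined z ≥ threshold are merged across gaps
≤ 1 s and kept if they last ≥ 4 s. Stimulation epochs are *not* excised
from the detection trace (seizures begin during induction; latency is
measured from induction start); evoked windows are excised only from the
baseline statistics.

Event edges are reported at the stride-cell edges of the contributing
windows (first center − step/2 … last center + step/2), so a run of n
windows has duration exactly n × step and the ≥ 4 s rule is exact. Full
window-support edges would over-cover a sharp event by up to one window
length.

**Threshold calibration.** The z-threshold is determined from baseline
noise: on seeded null sessions (paired pulses, no induction, no seizures)
the largest combined log-z excursion sustained for 4 s was ~2.4 across
dozens of full-length sessions, while synthetic seizures hold z ≥ 10
throughout and peak at z ≈ 30–100. The default threshold is **z = 4**:
comfortably above everything baseline noise sustains, far below any
seizure. At this default, 100 full-length null sessions produce 0
detections and injected seizures are recalled at 100% with onset errors
~0.1 s. A threshold of 3 also yields zero false positives but with less
margin.

## Session metrics

* **Latency** (seizure-threshold proxy): first detected onset minus
  induction start. Events before induction are flagged, not dropped.
* **Band peak lag**: within the event ± 5 s, each band-power trace is
  smoothed with a 1-s centered moving average; the peak time is the
  power-weighted centroid of the contiguous region above half the
  smoothed maximum (a raw argmax on the 0.25-s grid has ~0.7 s jitter for
  a noisy ripple envelope; the half-maximum centroid is unbiased for
  symmetric envelopes and cuts the error to ~0.2 s). The lag is
  t_peak(low band) − t_peak(high band): positive means the
  high-frequency envelope peaked first.
* **Postictal depression**: 1 − (post/pre) broadband (0–500 Hz) power,
  with 60-s windows separated from the event by a 1-s guard gap and
  stimulus windows excised from both sides. Bounded above by 1,
  gain-invariant, undefined when preictal power is ~0.

## Plasticity

Trials are epoched at each first pulse (−50…+100 ms), baseline-subtracted
(mean of the 50 ms before the pulse), and averaged; trials overlapping
detected seizures or supplied exclusion intervals are dropped. Amplitudes
are peak absolute deflections 3–30 ms after each pulse onset. With the
alpha-function kernel the first response decays to <5% of its peak by the
second-response window, so kernel subtraction is off by default (an
alpha-kernel fit-and-subtract is available). Within-session plasticity is
R = A_post/A_pre per response; cross-session series are normalized to the
mean of sessions 1–2. Single-session amplitude estimates scatter ~8% at
60 trials under the default background, so calibration statements are made
on seed averages.

## Statistics

The incidence test is an exact Fisher–Freeman–Halton test for r × 2
tables, enumerated over all tables with the observed margins; the
two-sided p sums the probabilities of tables no more probable than the
observed one (the point-probability convention of standard exact-test
software). On the reported incidence table (9/12 vs 0/4 vs 0/5) it gives
p = 0.00112, rounding to the printed 0.001, and it agrees with an
independent enumeration oracle and (on 2 × 2 tables) with
`scipy.stats.fisher_exact` to machine precision.

Spearman trend tests use mid-ranks with an exhaustive permutation p for
n ≤ 8 and the t-approximation above. Group tests (paired t, one-sample t,
Mann–Whitney U, Kruskal–Wallis, one-way ANOVA, Friedman) wrap scipy behind
one result type; the rank tests optionally compute exhaustive permutation
p-values at small n, which the test suite checks against independent
brute-force oracles. Identical paired vectors return t = 0, p = 1 rather
than 0/0. Circadian association offers a linear correlation against clock
hour and a circular-aware option (regression on sin/cos of the clock
angle, F-test on the multiple R). Reported p-values are unadjusted, as is
conventional for per-figure tests; a Holm adjustment helper is provided
but off by default.

**Type-I-error audit.** Null p-values are checked for uniformity
(KS test, 500 seeded nulls) for the tests whose null p-value distribution
is effectively continuous: t tests, Pearson, Spearman (n = 30),
Mann–Whitney (exact, 25 vs 25), Kruskal–Wallis (3 × 12), Friedman
(20 × 4). Sample sizes were chosen so the discrete lattice of the rank
statistics is fine enough for the KS check to be meaningful. The exact
Fisher test on small discrete tables is *provably* non-uniform
(conservative, with few support atoms), so no correct implementation can
pass a uniformity test; it is audited for validity instead:
P(p ≤ α) ≤ α under the null.

## Degenerate inputs and numerical conventions

Zero-variance baselines raise a degenerate-baseline error; constant
score vectors flag an undefined ρ; empty groups are dropped from the
incidence table with a flag and p = 1 if fewer than two groups remain;
flat peak-lag traces break ties to the earliest peak with a warning;
sampling rates below 1 kHz disable the bands above Nyquist with a
warning. Times in outputs are seconds from recording start; clock
time-of-day is carried separately in hours. Every pipeline output table
carries a SHA-256 hash (12 hex digits) of the fully resolved
configuration.

## File formats

Recordings travel as HDF5 bundles (samples, sampling rate, channel
labels, annotation times) or plain CSV with a JSON annotation sidecar;
EDF files can be read through `mne` when it is installed. EDF *writing*
is not supported — no EDF writer library is available in the supported
dependency set — so HDF5/CSV is the canonical interchange. Events,
metrics, plasticity and statistics tables are CSV with fixed column
order; rekindling is a manifest convention (a `phase` column with
sessions renumbered from one), not a separate code path.

## Known limitations

* The detector is calibrated on the generator's stationary background; real
  EEG has artifacts and state changes (sleep/wake) that would require
  artifact rejection the package deliberately does not include.
* Multi-channel support is per-channel detection only; no cross-channel
  event reconciliation.
* The peak-lag estimator assumes a unimodal band-power envelope within the
  event window; multi-burst seizures would need a different summary.
* The Wigner transform is quadratic in segment length and meant for
  single-event portraits, not whole-session scans.
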