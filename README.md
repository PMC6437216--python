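# seizkit

EEG analysis chain for **optogenetic kindling** experiments, paired with a
seeded synthetic-EEG generator so every stage is verifiable without animal
data.

In a kindling experiment, brief high-frequency stimulation of a defined
neuronal population is repeated every few days. Initially inert, the
stimulus eventually evokes electrographic seizures that grow in number,
duration and behavioural severity while the onset latency (a seizure
threshold proxy) falls. `seizkit` implements the analyses such a study
needs:

* **Detection** — EEG spectral power in seven canonical bands (delta 0–4,
  theta 4–8, alpha 8–12, beta 12–30, gamma 30–80, ripples 80–250, fast
  ripples 250–500 Hz) is z-scored against pre-induction baseline noise
  (log-power scale, stimulus-evoked windows excised); runs where the
  combined statistic max_b z_b(t) stays ≥ z* (default 4) for at least
  4 s, after closing ≤ 1 s gaps, are electrographic seizures.
* **Session metrics** — onset latency from induction start, duration,
  ripple-vs-spike-wave envelope peak lag (positive ⇒ high frequencies
  peak first), and postictal depression
  1 − P_post/P_pre of broadband (0–500 Hz) power.
* **Time–frequency** — plain (exact time marginal) and smoothed-pseudo
  Wigner–Ville transforms for seizure portraits.
* **Plasticity** — paired-pulse evoked responses (pulses 33.3 ms apart
  every 10 s in both baselines): amplitudes A1, A2, within-session ratios
  R_i = A_i^post/A_i^pre, and cross-session series normalized to the mean
  of sessions 1–2.
* **Statistics** — an exact Fisher–Freeman–Halton r × 2 incidence test
  (implemented from the hypergeometric enumeration), Spearman/Pearson
  trend tests, paired/one-sample t, Mann–Whitney U, Kruskal–Wallis,
  ANOVA, Friedman, and a circadian-association test, all behind one
  result type with exhaustive permutation oracles at small n.
* **Synthetic data** — `seizkit.synth` generates whole sessions and
  cohorts (pink-noise background with AC-coupling corner, evoked pulse
  responses, logistic seizure emergence across sessions, programmed
  ripple-before-delta onset dynamics, postictal suppression, half-step
  Racine-style scores) with exact ground truth and bit-reproducible
  seeding.

## Worked example

```python
from seizkit import (SimConfig, StimProtocol, simulate_session,
                     detect_seizures, seizure_latency, band_peak_lag,
                     postictal_depression)

proto = StimProtocol()                      # 10 min + 3 min + 20 min session
cfg = SimConfig(seed=11)
rec, truth = simulate_session(cfg, proto, session_index=20)

events = detect_seizures(rec, proto)
ev = events[0]
print(f"seizure {ev.start_s:.2f}-{ev.end_s:.2f} s "
      f"(truth {truth.seizure_intervals[0][0]:.2f}-"
      f"{truth.seizure_intervals[0][1]:.2f} s)")
print(f"latency from induction start: {seizure_latency(ev, proto):.1f} s")
print(f"ripple-before-spike-wave lag: {band_peak_lag(rec, ev):.2f} s")
print(f"postictal suppression: {postictal_depression(rec, ev, proto):.2f}")
```

prints (seed 11):

```
seizure 656.12-680.88 s (truth 656.11-681.00 s)
latency from induction start: 56.1 s
ripple-before-spike-wave lag: 6.48 s
postictal suppression: 0.32
```

i.e. the detector recovers the programmed event to within a fraction of a
second, the high-frequency envelope peaks ~6.4 s before the slow
spike-wave envelope (the programmed lead), and broadband power after the
seizure is suppressed by ~34% relative to the preictal minute.

The numbered drivers under `analysis/` run the cohort-scale analyses
(simulate three cohorts, detect and test the kindling trends, onset and
postictal recovery sweeps, plasticity ratios, incidence and circadian
statistics) and write their tables under `results/`. A `seizkit` CLI
(`simulate`, `detect`, `run`, `stats`, `report`) wraps the same library
for shell use.

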