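"""Cohort-scale validation experiments.

These functions recompute the headline quantities of the analysis chain
from scratch on synthetic data — detector specificity/sensitivity, HFO-lead
recovery, postictal-suppression recovery, paired-pulse plasticity
dissociation, kindling trend statistics, and the spectral identities — so
that the acceptance script and the test suite share one implementation.

Problem sizes: the mass experiments use a shortened session (2-minute pre
baseline, 3-minute induction, 5-minute post baseline) so that hundreds of
sessions fit in a routine run; the detector contract runs on the full
~33-minute session.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .detection import DetectionConfig, SeizureEvent, detect_seizures
from .metrics import band_peak_lag, postictal_depression, seizure_latency
from .plasticity import extract_evoked, session_plasticity
from .protocol import StimProtocol
from .spectral import (BAND_TABLE, compute_baseline_stats,
                       compute_spectrogram, wigner_transform, zscore_bands)
from .stats import ContingencyTable, fisher_freeman_halton, group_tests, \
    linear_corr, rank_trend
from .synth import SimConfig, iter_cohort_sessions, simulate_session

__all__ = [
    "SHORT_PROTOCOL", "incidence_test", "detector_null_false_positives",
    "detector_recall", "peak_lag_recovery", "postictal_recovery",
    "plasticity_ratios", "kindling_trends", "spectral_identities",
    "null_pvalues",
]

#: Shortened session used for cohort-scale sweeps.
SHORT_PROTOCOL = StimProtocol(baseline_pre_s=120.0, baseline_post_s=300.0)

#: Reported incidence of seizure-positive animals per cohort:
#: stimulated ChR2 9/12, unstimulated ChR2 0/4, stimulated no-ChR2 0/5.
INCIDENCE_COUNTS = np.array([[9, 3], [0, 4], [0, 5]])
INCIDENCE_GROUPS = ["stim-ChR2", "no-stim-ChR2", "stim-no-ChR2"]


def incidence_test():
    """Exact Fisher-Freeman-Halton test on the cohort incidence table."""
    return fisher_freeman_halton(
        ContingencyTable(INCIDENCE_GROUPS, INCIDENCE_COUNTS))


# ---------------------------------------------------------------------------
# detector contract

def detector_null_false_positives(n_sessions: int = 100, *, seed: int = 0,
                                  protocol: StimProtocol | None = None,
                                  det_cfg: DetectionConfig | None = None,
                                  ) -> int:
    """Total detections over seeded control sessions with no seizures.

    Null sessions are unstimulated-induction controls: paired-pulse evoked
    responses are present, the induction and seizures are absent.
    """
    protocol = protocol or StimProtocol()
    det_cfg = det_cfg or DetectionConfig()
    total = 0
    for i in range(n_sessions):
        cfg = SimConfig(seed=seed)
        rec, truth = simulate_session(cfg, protocol, 1, animal_index=1000 + i,
                                      with_induction=False)
        assert not truth.seizure_intervals
        total += len(detect_seizures(rec, protocol, det_cfg))
    return total


def detector_recall(n_sessions: int = 100, *, seed: int = 0,
                    session_index: int = 20,
                    protocol: StimProtocol | None = None,
                    det_cfg: DetectionConfig | None = None) -> dict:
    """Recall of injected seizures, plus the duration-rule audit.

    Every simulated session carries one programmed seizure (the logistic
    occurrence probability is ~1 at the chosen session index); a hit is a
    detected event overlapping the true interval.
    """
    protocol = protocol or StimProtocol()
    det_cfg = det_cfg or DetectionConfig()
    hits = n_true = 0
    min_dur = np.inf
    start_err, dur_err = [], []
    for i in range(n_sessions):
        cfg = SimConfig(seed=seed)
        rec, truth = simulate_session(cfg, protocol, session_index,
                                      animal_index=2000 + i)
        events = detect_seizures(rec, protocol, det_cfg)
        for e in events:
            min_dur = min(min_dur, e.duration_s)
        for (a, b) in truth.seizure_intervals:
            n_true += 1
            matches = [e for e in events if e.overlaps(a, b)]
            if matches:
                hits += 1
                start_err.append(abs(matches[0].start_s - a))
                dur_err.append(abs(sum(e.duration_s for e in matches)
                                   - (b - a)))
    return {
        "n_true": n_true,
        "recall": hits / n_true if n_true else float("nan"),
        "min_detected_duration_s": float(min_dur),
        "mean_abs_start_error_s": float(np.mean(start_err)) if start_err
        else float("nan"),
        "mean_abs_duration_error_s": float(np.mean(dur_err)) if dur_err
        else float("nan"),
    }


# ---------------------------------------------------------------------------
# generator-recovery sweeps

def _truth_event(truth) -> SeizureEvent:
    a, b = truth.seizure_intervals[0]
    return SeizureEvent(start_s=a, end_s=b, duration_s=b - a,
                        peak_z=float("nan"))


def peak_lag_recovery(taus=(2.0, 4.0, 6.4, 8.0), n_seeds: int = 20, *,
                      seed: int = 0, session_index: int = 15,
                      protocol: StimProtocol | None = None) -> dict:
    """Recover the programmed ripple-before-spike-wave lead time.

    Returns per-tau mean recovered lag and the overall mean absolute error.
    """
    protocol = protocol or SHORT_PROTOCOL
    per_tau = {}
    all_err = []
    for tau in taus:
        lags = []
        for i in range(n_seeds):
            cfg = SimConfig(seed=seed, hfo_lead_s=float(tau))
            rec, truth = simulate_session(cfg, protocol, session_index,
                                          animal_index=3000 + i)
            if not truth.seizure_intervals:
                continue
            lag = band_peak_lag(rec, _truth_event(truth))
            lags.append(lag)
            all_err.append(abs(lag - tau))
        per_tau[float(tau)] = float(np.mean(lags))
    return {"per_tau_mean_lag_s": per_tau,
            "mean_abs_error_s": float(np.mean(all_err))}


def postictal_recovery(fractions=(0.0, 0.15, 0.34, 0.5), n_seeds: int = 20,
                       *, seed: int = 0, session_index: int = 15,
                       protocol: StimProtocol | None = None) -> dict:
    """Recover programmed postictal power-suppression fractions."""
    protocol = protocol or SHORT_PROTOCOL
    out = {}
    for d in fractions:
        vals = []
        for i in range(n_seeds):
            cfg = SimConfig(seed=seed, postictal_fraction=float(d))
            rec, truth = simulate_session(cfg, protocol, session_index,
                                          animal_index=4000 + i)
            if not truth.seizure_intervals:
                continue
            vals.append(postictal_depression(rec, _truth_event(truth),
                                             protocol))
        out[float(d)] = float(np.mean(vals))
    return out


def plasticity_ratios(n_seeds: int = 50, *, potentiation: float = 1.4,
                      seed: int = 0,
                      protocol: StimProtocol | None = None) -> dict:
    """Mean within-session plasticity ratios R1, R2 over seeded sessions.

    Sessions run the full protocol with induction but without seizures, so
    that every paired-pulse trial is usable.
    """
    protocol = protocol or SHORT_PROTOCOL
    r1s, r2s = [], []
    for i in range(n_seeds):
        cfg = SimConfig(seed=seed, potentiation_factor2=float(potentiation),
                        seizure_prob_midpoint=1e9)
        rec, _ = simulate_session(cfg, protocol, 1, animal_index=5000 + i)
        pre = extract_evoked(rec, protocol, "pre")
        post = extract_evoked(rec, protocol, "post")
        res = session_plasticity(pre, post)
        r1s.append(res.r1)
        r2s.append(res.r2)
    return {"R1_mean": float(np.mean(r1s)), "R2_mean": float(np.mean(r2s)),
            "R1_sd": float(np.std(r1s, ddof=1)),
            "R2_sd": float(np.std(r2s, ddof=1))}


# ---------------------------------------------------------------------------
# kindling hallmark trends

def kindling_trends(n_animals: int = 12, n_sessions: int = 25, *,
                    seed: int = 0,
                    protocol: StimProtocol | None = None,
                    det_cfg: DetectionConfig | None = None) -> dict:
    """End-to-end cohort: simulate, detect, and test the hallmark trends.

    Returns the Racine-vs-session rank correlation, the detected-seizure
    duration-vs-session and latency-vs-session Pearson correlations, and
    the per-group incidence of seizure-positive animals.
    """
    protocol = protocol or SHORT_PROTOCOL
    det_cfg = det_cfg or DetectionConfig()
    cfg = SimConfig(seed=seed)
    sessions, racines = [], []
    ev_sessions, durations, latencies = [], [], []
    positive = set()
    for aid, s, rec, truth in iter_cohort_sessions(cfg, n_animals,
                                                   n_sessions, "stim-ChR2",
                                                   protocol):
        sessions.append(s)
        racines.append(truth.racine_score)
        events = detect_seizures(rec, protocol, det_cfg)
        if events:
            positive.add(aid)
            ev_sessions.append(s)
            durations.append(events[0].duration_s)
            latencies.append(seizure_latency(events[0], protocol))
    racine_res = rank_trend(sessions, racines)
    dur_res = linear_corr(ev_sessions, durations)
    lat_res = linear_corr(ev_sessions, latencies)
    return {
        "n_seizure_positive": len(positive),
        "n_animals": n_animals,
        "n_detected_seizures": len(ev_sessions),
        "racine_rho": racine_res.statistic, "racine_p": racine_res.p_value,
        "duration_r": dur_res.statistic, "duration_p": dur_res.p_value,
        "latency_r": lat_res.statistic, "latency_p": lat_res.p_value,
    }


# ---------------------------------------------------------------------------
# spectral identities

def spectral_identities(*, seed: int = 0) -> dict:
    """Numerical identities of the spectral layer on synthetic signals."""
    rng = np.random.default_rng(seed)
    fs = 2000.0
    # Parseval: white noise, total band-partition power vs signal power
    x = rng.standard_normal(int(20 * fs))
    spec = compute_spectrogram(x, fs)
    summed = (spec.power.sum(axis=1) * spec.df).mean()
    parseval_err = abs(summed - np.mean(x ** 2)) / np.mean(x ** 2)
    # band table tiling of [0, 500)
    edges_ok = (BAND_TABLE[0].f_low == 0.0
                and BAND_TABLE[-1].f_high == 500.0
                and all(a.f_high == b.f_low
                        for a, b in zip(BAND_TABLE[:-1], BAND_TABLE[1:])))
    # plain Wigner time marginal vs |analytic signal|^2
    t = np.arange(int(0.5 * fs)) / fs
    chirp = np.cos(2 * np.pi * (50 * t + 200 * t ** 2))
    times, freqs, w = wigner_transform(chirp, fs, mode="plain")
    from scipy.signal import hilbert
    inst = np.abs(hilbert(chirp)) ** 2
    marg = w.sum(axis=1)
    sl = slice(50, -50)  # edges suffer from lag truncation
    marginal_err = float(np.max(np.abs(marg[sl] - inst[sl]))
                         / np.max(inst))
    # baseline z self-normalization: apply the baseline statistics back to
    # the (stimulus-excised) baseline windows they were computed from
    from .spectral import _window_mask
    proto = SHORT_PROTOCOL
    rec, _ = simulate_session(SimConfig(seed=seed), proto, 1,
                              animal_index=6000, with_induction=False)
    spec2 = compute_spectrogram(rec)
    baseline = compute_baseline_stats(spec2, proto)
    zs = zscore_bands(spec2, baseline)
    half = spec2.window_s / 2
    keep = _window_mask(spec2, baseline.excised)
    keep &= ((spec2.window_centers - half >= 0)
             & (spec2.window_centers + half <= proto.baseline_pre_s))
    zmeans = [float(np.mean(s.z[keep])) for s in zs]
    zsds = [float(np.std(s.z[keep], ddof=1)) for s in zs]
    return {
        "parseval_rel_err": float(parseval_err),
        "band_table_tiles": bool(edges_ok),
        "wigner_marginal_rel_err": marginal_err,
        "baseline_z_mean_max_abs": float(np.max(np.abs(zmeans))),
        "baseline_z_sd_max_abs_dev": float(np.max(np.abs(np.array(zsds) - 1))),
    }


# ---------------------------------------------------------------------------
# null p-value sampling for the type-I-error audit

def null_pvalues(test: str, n_draws: int = 500, *, seed: int = 0,
                 ) -> np.ndarray:
    """Sample p-values of a named test under its null hypothesis."""
    rng = np.random.default_rng(seed)
    ps = np.empty(n_draws)
    for i in range(n_draws):
        if test == "paired_t":
            ps[i] = group_tests((rng.normal(size=12), rng.normal(size=12)),
                                "paired_t").p_value
        elif test == "one_sample_t":
            ps[i] = group_tests(rng.normal(size=12), "one_sample_t").p_value
        elif test == "pearson":
            ps[i] = linear_corr(rng.normal(size=20),
                                rng.normal(size=20)).p_value
        elif test == "spearman":
            ps[i] = rank_trend(rng.normal(size=30),
                               rng.normal(size=30)).p_value
        elif test == "mann_whitney":
            ps[i] = group_tests((rng.normal(size=25), rng.normal(size=25)),
                                "mann_whitney", method="exact").p_value
        elif test == "kruskal":
            ps[i] = group_tests([rng.normal(size=12) for _ in range(3)],
                                "kruskal").p_value
        elif test == "friedman":
            ps[i] = group_tests(rng.normal(size=(20, 4)),
                                "friedman").p_value
        else:
            raise ValueError(f"unknown test {test!r}")
    return ps


def ks_uniformity_p(pvals: np.ndarray) -> float:
    """KS p-value of a sample of p-values against U(0, 1)."""
    return float(sps.kstest(pvals, "uniform").pvalue)
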