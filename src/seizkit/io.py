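"""File formats, manifests, configuration resolution, and the end-to-end
pipeline.

Recordings travel as HDF5 bundles (samples + sampling rate + annotations)
or plain CSV; EDF files can be *read* through :mod:`mne` when it is
installed.  Events, metrics, plasticity and statistics tables are CSV with
fixed column order so downstream users need no custom parser.  Every output
table carries a hash of the fully resolved configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from typing import Any

import h5py
import numpy as np
import pandas as pd

from .detection import DetectionConfig, SeizureEvent, detect_seizures
from .metrics import cohort_metrics_table, session_metrics
from .plasticity import extract_evoked, session_plasticity
from .protocol import StimProtocol, build_protocol
from .recording import EEGRecording
from .stats import ContingencyTable, fisher_freeman_halton, linear_corr, rank_trend
from .synth import SimConfig, simulate_session, _group_flags

logger = logging.getLogger("seizkit")

EVENT_COLUMNS = ["animal_id", "session", "channel", "start_s", "end_s",
                 "duration_s", "peak_z"]
MANIFEST_COLUMNS = ["animal_id", "group", "session", "recording_path",
                    "racine", "clock_h", "phase"]

__all__ = ["save_recording", "load_recording", "read_recording",
           "save_recording_csv", "load_recording_csv", "events_to_frame",
           "write_manifest", "read_manifest", "resolve_config",
           "config_hash", "run_pipeline", "EVENT_COLUMNS", "MANIFEST_COLUMNS"]


# ---------------------------------------------------------------------------
# recordings

def save_recording(rec: EEGRecording, path: str) -> None:
    """Write an HDF5 bundle: /data (n_ch x n), attrs, /annotations/<name>."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data, compression="gzip",
                         compression_opts=1)
        f.attrs["fs"] = rec.fs
        f.attrs["channels"] = [str(c) for c in rec.channels]
        f.attrs["start_clock_h"] = rec.start_clock_h
        g = f.create_group("annotations")
        for name, times in rec.annotations.items():
            g.create_dataset(name, data=np.asarray(times, dtype=float))


def load_recording(path: str) -> EEGRecording:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        fs = float(f.attrs["fs"])
        channels = [str(c) for c in f.attrs["channels"]]
        clock = float(f.attrs.get("start_clock_h", 0.0))
        ann = {name: f["annotations"][name][()]
               for name in f.get("annotations", {})}
    return EEGRecording(data=data, fs=fs, channels=channels,
                        annotations=ann, start_clock_h=clock)


def save_recording_csv(rec: EEGRecording, path: str) -> None:
    """CSV with a time column and one column per channel; annotations go in
    a JSON sidecar ``<path>.ann.json``."""
    df = pd.DataFrame({"time_s": rec.times()})
    for i, ch in enumerate(rec.channels):
        df[ch] = rec.data[i]
    df.to_csv(path, index=False)
    side = {"fs": rec.fs, "start_clock_h": rec.start_clock_h,
            "annotations": {k: list(map(float, v))
                            for k, v in rec.annotations.items()}}
    with open(path + ".ann.json", "w") as fh:
        json.dump(side, fh)


def load_recording_csv(path: str) -> EEGRecording:
    df = pd.read_csv(path)
    side_path = path + ".ann.json"
    if os.path.exists(side_path):
        with open(side_path) as fh:
            side = json.load(fh)
        fs = float(side["fs"])
        ann = {k: np.asarray(v) for k, v in side["annotations"].items()}
        clock = float(side.get("start_clock_h", 0.0))
    else:
        dt = np.diff(df["time_s"].to_numpy()[:2])[0]
        fs, ann, clock = 1.0 / dt, {}, 0.0
    channels = [c for c in df.columns if c != "time_s"]
    data = df[channels].to_numpy().T
    return EEGRecording(data=data, fs=fs, channels=channels,
                        annotations=ann, start_clock_h=clock)


def _read_edf(path: str) -> EEGRecording:
    try:
        import mne
    except ImportError as exc:                      # pragma: no cover
        raise RuntimeError("reading EDF requires the optional 'mne' "
                           "package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    ann = {}
    for desc in set(raw.annotations.description):
        sel = raw.annotations.description == desc
        ann[str(desc)] = np.asarray(raw.annotations.onset[sel], dtype=float)
    return EEGRecording(data=raw.get_data(), fs=float(raw.info["sfreq"]),
                        channels=list(raw.ch_names), annotations=ann)


def read_recording(path: str, format: str | None = None) -> EEGRecording:
    """Dispatch on ``format`` or the file extension (h5/hdf5, csv, edf)."""
    fmt = (format or os.path.splitext(path)[1].lstrip(".")).lower()
    if fmt in ("h5", "hdf5"):
        rec = load_recording(path)
    elif fmt == "csv":
        rec = load_recording_csv(path)
    elif fmt == "edf":
        rec = _read_edf(path)
    else:
        raise ValueError(f"unsupported recording format {fmt!r}")
    if rec.fs < 1000.0:
        import warnings
        warnings.warn(f"sampling rate {rec.fs} Hz cannot resolve the "
                      "fast-ripple band; it will be disabled", stacklevel=2)
    return rec


# ---------------------------------------------------------------------------
# tables and configuration

def events_to_frame(events: list[SeizureEvent], animal_id: str,
                    session: int) -> pd.DataFrame:
    rows = [{"animal_id": animal_id, "session": session, "channel": e.channel,
             "start_s": round(e.start_s, 3), "end_s": round(e.end_s, 3),
             "duration_s": round(e.duration_s, 3),
             "peak_z": round(e.peak_z, 3)} for e in events]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_manifest(entries: list[dict], path: str) -> None:
    df = pd.DataFrame(entries)
    if "phase" not in df.columns:
        df["phase"] = "kindling"
    df[MANIFEST_COLUMNS].to_csv(path, index=False)


def read_manifest(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - {"phase"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if "phase" not in df.columns:
        df["phase"] = "kindling"
    dup = df.duplicated(subset=["animal_id", "session"])
    if dup.any():
        raise ValueError("(animal_id, session) pairs must be unique")
    for aid, sub in df.groupby("animal_id"):
        if sub["group"].nunique() != 1:
            raise ValueError(f"group changes within animal {aid}")
        sess = sorted(sub["session"])
        if sess != list(range(1, len(sess) + 1)):
            raise ValueError(f"sessions of {aid} not contiguous from 1")
    return df


def resolve_config(defaults: dict, config_file: str | None = None,
                   overrides: dict | None = None) -> dict:
    """Layered configuration: defaults <- file <- CLI overrides."""
    cfg = dict(defaults)
    if config_file:
        with open(config_file) as fh:
            cfg.update(json.load(fh))
    cfg.update(overrides or {})
    return cfg


def config_hash(cfg: Any) -> str:
    if dataclasses.is_dataclass(cfg) and not isinstance(cfg, type):
        cfg = dataclasses.asdict(cfg)
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# pipeline

def _default_run_config() -> dict:
    return {
        "sim": dataclasses.asdict(SimConfig()),
        "detection": {f.name: getattr(DetectionConfig(), f.name)
                      for f in dataclasses.fields(DetectionConfig)
                      if f.name != "bands"},
        "protocol": dataclasses.asdict(StimProtocol()),
        "seed": 0,
    }


def run_pipeline(manifest: pd.DataFrame, out_dir: str, *,
                 detection_cfg: DetectionConfig | None = None,
                 protocol: StimProtocol | None = None,
                 sim_cfg: SimConfig | None = None,
                 compute_lags: bool = False,
                 compute_postictal: bool = False) -> int:
    """Run detect -> metrics -> plasticity -> stats over every manifest row.

    Rows with a ``recording_path`` are loaded from disk; rows without one
    are re-synthesized deterministically from ``sim_cfg`` (animal order in
    the manifest defines the per-animal seed stream).  A failing session is
    logged and skipped; the return value is the number of failures (also
    the suggested process exit status).
    """
    os.makedirs(out_dir, exist_ok=True)
    detection_cfg = detection_cfg or DetectionConfig()
    protocol = protocol or StimProtocol()
    sim_cfg = sim_cfg or SimConfig()
    resolved = {
        "sim": dataclasses.asdict(sim_cfg),
        "detection": {f.name: getattr(detection_cfg, f.name)
                      for f in dataclasses.fields(DetectionConfig)
                      if f.name != "bands"},
        "protocol": dataclasses.asdict(protocol),
    }
    h = config_hash(resolved)
    resolved["config_hash"] = h
    with open(os.path.join(out_dir, "resolved_config.json"), "w") as fh:
        json.dump(resolved, fh, indent=2)

    animal_order = {aid: i for i, aid in
                    enumerate(dict.fromkeys(manifest["animal_id"]))}
    event_frames, metric_rows, plasticity_rows = [], [], []
    seizure_positive: dict[str, tuple[str, bool]] = {}
    failures = 0
    for _, row in manifest.sort_values(["animal_id", "session"]).iterrows():
        aid, session = row["animal_id"], int(row["session"])
        try:
            if isinstance(row.get("recording_path"), str) and row["recording_path"]:
                rec = read_recording(row["recording_path"])
            else:
                flags = _group_flags(row["group"])
                rec, _ = simulate_session(sim_cfg, protocol, session,
                                          animal_index=animal_order[aid],
                                          **flags)
            events = detect_seizures(rec, protocol, detection_cfg)
            event_frames.append(events_to_frame(events, aid, session))
            racine = float(row["racine"]) if "racine" in row and \
                pd.notna(row["racine"]) else None
            m = session_metrics(events, rec, protocol, racine,
                                compute_lags=compute_lags,
                                compute_postictal=compute_postictal)
            metric_rows.append({"animal_id": aid, "session": session,
                                "metrics": m})
            group, prev = seizure_positive.get(aid, (row["group"], False))
            seizure_positive[aid] = (group, prev or bool(events))
            if row["group"] != "stim-no-ChR2":
                guard = [(e.start_s - 5, e.end_s + 60) for e in events]
                pre = extract_evoked(rec, protocol, "pre",
                                     exclude_intervals=guard)
                post = extract_evoked(rec, protocol, "post",
                                      exclude_intervals=guard)
                pl = session_plasticity(pre, post)
                plasticity_rows.append({
                    "animal_id": aid, "session": session,
                    "R1": pl.r1, "R2": pl.r2,
                    "A1_pre": pre.a1, "A2_pre": pre.a2})
            logger.info("session %s/%s: %d event(s)", aid, session,
                        len(events))
        except Exception:
            failures += 1
            logger.exception("session %s/%s failed; continuing", aid, session)

    events_df = (pd.concat(event_frames, ignore_index=True)
                 if event_frames else pd.DataFrame(columns=EVENT_COLUMNS))
    events_df["config_hash"] = h
    events_df.to_csv(os.path.join(out_dir, "events.csv"), index=False)

    metrics_df = cohort_metrics_table(metric_rows)
    metrics_df["config_hash"] = h
    metrics_df.to_csv(os.path.join(out_dir, "metrics.csv"), index=False)
    with open(os.path.join(out_dir, "metrics.json"), "w") as fh:
        json.dump([{"animal_id": r["animal_id"], "session": r["session"],
                    **r["metrics"].to_dict()} for r in metric_rows], fh,
                  indent=2)

    plast_df = pd.DataFrame(plasticity_rows)
    plast_df["config_hash"] = h
    plast_df.to_csv(os.path.join(out_dir, "plasticity.csv"), index=False)

    stats_rows = _cohort_stats(manifest, metrics_df, seizure_positive)
    stats_df = pd.DataFrame(stats_rows)
    stats_df["config_hash"] = h
    stats_df.to_csv(os.path.join(out_dir, "stats.csv"), index=False)

    _write_report(out_dir, manifest, events_df, stats_df, h, failures)
    return failures


def _cohort_stats(manifest, metrics_df, seizure_positive) -> list[dict]:
    rows = []
    by_group: dict[str, list[bool]] = {}
    for _, (group, pos) in seizure_positive.items():
        by_group.setdefault(group, []).append(pos)
    if by_group:
        groups = sorted(by_group)
        counts = [[sum(by_group[g]), len(by_group[g]) - sum(by_group[g])]
                  for g in groups]
        res = fisher_freeman_halton(ContingencyTable(groups, np.array(counts)))
        rows.append({"test": "incidence_fisher_freeman_halton",
                     "groups": "|".join(f"{g}:{sum(by_group[g])}/"
                                        f"{len(by_group[g])}" for g in groups),
                     "statistic": res.statistic, "p": res.p_value,
                     "n": sum(len(v) for v in by_group.values()),
                     "method": res.method})
    if "racine" in metrics_df and metrics_df["racine"].notna().sum() >= 3:
        sub = metrics_df.dropna(subset=["racine"])
        res = rank_trend(sub["session"], sub["racine"])
        rows.append({"test": "racine_vs_session_spearman", "groups": "all",
                     "statistic": res.statistic, "p": res.p_value,
                     "n": len(sub), "method": res.method})
    sub = metrics_df.dropna(subset=["mean_duration_s"])
    if len(sub) >= 3 and sub["session"].nunique() > 1:
        res = linear_corr(sub["session"], sub["mean_duration_s"])
        rows.append({"test": "duration_vs_session_pearson", "groups": "all",
                     "statistic": res.statistic, "p": res.p_value,
                     "n": len(sub), "method": res.method})
    sub = metrics_df.dropna(subset=["latency_s"])
    if len(sub) >= 3 and sub["session"].nunique() > 1:
        res = linear_corr(sub["session"], sub["latency_s"])
        rows.append({"test": "latency_vs_session_pearson", "groups": "all",
                     "statistic": res.statistic, "p": res.p_value,
                     "n": len(sub), "method": res.method})
    return rows


def _write_report(out_dir, manifest, events_df, stats_df, h, failures):
    lines = [
        "seizkit pipeline report",
        f"config hash: {h}",
        f"sessions: {len(manifest)}  failures: {failures}",
        f"detected events: {len(events_df)}",
        "",
        "cohort statistics:",
    ]
    for _, r in stats_df.iterrows():
        lines.append(f"  {r['test']}: stat={r['statistic']:.4g} "
                     f"p={r['p']:.4g} (n={r['n']}, {r['method']})")
    with open(os.path.join(out_dir, "report.txt"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
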