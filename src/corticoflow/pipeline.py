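"""End-to-end pipeline: simulate → preprocess → detect → metrics → stats.

Each stage reads the previous stage's directory and writes its own, so the
stages can be run separately (via the ``corticoflow`` CLI) or together with
:func:`run_pipeline`.  A manifest records the configuration, seeds, and row
counts; re-running with the same configuration reproduces all outputs.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cfio
from .config import RunConfig
from .detection import analyze_connection
from .metrics import (
    build_sr_curve,
    classify_connection,
    directionality_index,
    excitability_index,
    excitability_significance,
    response_magnitude,
    signaling_probability,
)
from .preprocess import epoch_trials, preprocess_recording
from .stats import class_contrasts, fit_probability_model
from .synthetic_data import (
    STATE_CLASS,
    VigilanceTrack,
    baseline_windows,
    build_schedule,
    demo_network,
    simulate_session,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "detect", "metrics", "stats")


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained with a marker."""


# ---------------------------------------------------------------------------
# stage: simulate
# ---------------------------------------------------------------------------

def stage_simulate(
    out_dir: Path,
    config: RunConfig,
    duration_h: float = 1.0,
    mapping_reps: int = 5,
    sr_electrodes: tuple[str, ...] = ("e0",),
    sleep_fraction: float = 0.35,
    block_interval_s: float = 3600.0,
) -> Path:
    """Generate the demo session: two-region network, block-wise schedule,
    wake followed by an NREM episode covering ``sleep_fraction`` of the end."""
    out = Path(out_dir) / "session"
    network = demo_network(seed=config.seed)
    schedule = build_schedule(
        duration_h,
        network.names,
        mapping_reps=mapping_reps,
        sr_electrodes=sr_electrodes,
        block_interval_s=block_interval_s,
        seed=config.seed + 1,
    )
    duration_s = max(e.onset_s for e in schedule) + 2.0
    split = duration_s * (1.0 - sleep_fraction)
    vigilance = VigilanceTrack([(0.0, split, "W"), (split, duration_s + 1.0, "N2")])
    recording, truth = simulate_session(
        network, schedule, vigilance, seed=config.seed + 2, duration_s=duration_s + 1.0
    )
    cfio.write_session(out, recording, schedule, vigilance, network=network, truth_table=truth)
    bwin = [
        (s, e)
        for s, e in baseline_windows(max(duration_h, 1.0), block_interval_s=block_interval_s)
        if s < duration_s
    ]
    (out / "baseline_windows.json").write_text(json.dumps(bwin))
    return out


# ---------------------------------------------------------------------------
# stage: preprocess
# ---------------------------------------------------------------------------

def stage_preprocess(in_dir: Path, out_dir: Path, config: RunConfig) -> Path:
    session = Path(in_dir) / "session"
    out = Path(out_dir) / "preprocessed"
    out.mkdir(parents=True, exist_ok=True)
    recording, events, _ = cfio.read_session(session)
    bwin = json.loads((session / "baseline_windows.json").read_text())
    bwin = [(s, min(e, recording.duration_s)) for s, e in bwin if s < recording.duration_s]
    clean, info = preprocess_recording(recording, events, bwin, config)
    cfio.write_signal(out / "signal", clean)
    clean.channel_table[cfio.ELECTRODE_COLUMNS].to_csv(out / "electrodes.tsv", sep="\t", index=False)
    (out / "preprocess_info.json").write_text(json.dumps(info, indent=2))
    (out / "baseline_windows.json").write_text(json.dumps(bwin))
    return out


# ---------------------------------------------------------------------------
# stage: detect
# ---------------------------------------------------------------------------

def _baseline_slice(signal: np.ndarray, fs: float, windows: list) -> np.ndarray:
    parts = []
    for start, end in windows:
        parts.append(signal[int(start * fs) : int(end * fs)])
    return np.concatenate(parts) if parts else signal[: int(5 * fs)]


def stage_detect(in_dir: Path, out_dir: Path, config: RunConfig) -> Path:
    base = Path(in_dir)
    out = Path(out_dir) / "detection"
    out.mkdir(parents=True, exist_ok=True)
    electrodes = pd.read_csv(base / "preprocessed" / "electrodes.tsv", sep="\t")
    recording = cfio.read_signal(base / "preprocessed" / "signal", electrodes)
    events = cfio.read_events(base / "session" / "events.tsv")
    vigilance = cfio.read_vigilance(base / "session" / "vigilance.tsv")
    bwin = json.loads((base / "preprocessed" / "baseline_windows.json").read_text())

    trials, n_dropped = epoch_trials(recording, events, vigilance, config)
    by_conn: dict[tuple[str, str], list] = {}
    for t in trials:
        by_conn.setdefault(t.connection, []).append(t)

    ch_index = {name: i for i, name in enumerate(recording.channel_names)}
    seed_seq = np.random.SeedSequence(config.seed)
    conn_rows = []
    score_rows = []
    for (stim, ch), conn_trials in sorted(by_conn.items()):
        mapping = [t for t in conn_trials if t.block_kind == "mapping"]
        if len(mapping) < 2:
            continue
        rng = np.random.default_rng(seed_seq.spawn(1)[0])
        baseline = _baseline_slice(
            recording.signal[ch_index[ch]], recording.sampling_rate, bwin
        )
        post = np.stack([t.post for t in mapping])
        pre = np.stack([t.pre for t in mapping])
        result = analyze_connection(
            post, baseline, recording.sampling_rate, rng, config, pre=pre, connection=(stim, ch)
        )
        conn_rows.append(
            {
                "stim_pair": stim,
                "channel": ch,
                "effective": result.effective,
                "p_value": result.p_value,
                "latency_ms": result.latency_ms,
                "latency_reason": result.latency_reason,
                "n_trials": result.n_trials,
                "trial_threshold": result.trial_threshold,
            }
        )
        sc = result.scores.copy()
        sc.insert(0, "stim_pair", stim)
        sc.insert(1, "channel", ch)
        sc.insert(2, "state", [t.state for t in mapping])
        sc.insert(3, "event_idx", [t.event_idx for t in mapping])
        sc.insert(4, "intensity_ma", [t.intensity_ma for t in mapping])
        sc.insert(5, "block_kind", "mapping")
        score_rows.append(sc)
        # score stimulation-response trials against the same centroids/null
        sr = [t for t in conn_trials if t.block_kind == "sr_curve"]
        if sr:
            from .detection import score_trials

            offset = config.artifact_offset_samples(recording.sampling_rate)
            m = config.n_ll_samples(recording.sampling_rate)
            windows = np.stack([t.post[offset : offset + m] for t in sr])
            sc2 = score_trials(windows, result.centroids, recording.sampling_rate, config)
            sc2["significant"] = sc2["score"] >= result.trial_threshold
            sc2["outlier"] = False
            sc2["response"] = sc2["significant"]
            sc2.insert(0, "stim_pair", stim)
            sc2.insert(1, "channel", ch)
            sc2.insert(2, "state", [t.state for t in sr])
            sc2.insert(3, "event_idx", [t.event_idx for t in sr])
            sc2.insert(4, "intensity_ma", [t.intensity_ma for t in sr])
            sc2.insert(5, "block_kind", "sr_curve")
            score_rows.append(sc2)

    pd.DataFrame(conn_rows).to_csv(out / "connections_detection.csv", index=False)
    pd.concat(score_rows, ignore_index=True).to_csv(out / "trial_scores.csv", index=False)
    (out / "detect_info.json").write_text(
        json.dumps(
            {
                "n_trials": len(trials),
                "n_dropped_edge": n_dropped,
                "n_connections": len(conn_rows),
                "centroid_surrogates": f"2 x {config.n_centroid_surrogates} "
                "(200 shuffled baseline re-computations per centroid, pooled)",
                "trial_surrogates": config.n_trial_surrogates,
            },
            indent=2,
        )
    )
    return out


# ---------------------------------------------------------------------------
# stage: metrics
# ---------------------------------------------------------------------------

def stage_metrics(in_dir: Path, out_dir: Path, config: RunConfig) -> Path:
    base = Path(in_dir)
    out = Path(out_dir) / "metrics"
    out.mkdir(parents=True, exist_ok=True)
    detection = pd.read_csv(base / "detection" / "connections_detection.csv")
    scores = pd.read_csv(base / "detection" / "trial_scores.csv")
    electrodes = pd.read_csv(base / "preprocessed" / "electrodes.tsv", sep="\t").set_index("name")
    bwin = json.loads((base / "preprocessed" / "baseline_windows.json").read_text())
    recording = cfio.read_signal(base / "preprocessed" / "signal", electrodes.reset_index())
    ch_index = {name: i for i, name in enumerate(recording.channel_names)}
    fs = recording.sampling_rate
    offset = config.artifact_offset_samples(fs)
    m = config.n_ll_samples(fs)
    events = cfio.read_events(base / "session" / "events.tsv")
    vigilance = cfio.read_vigilance(base / "session" / "vigilance.tsv")
    trials, _ = epoch_trials(recording, events, vigilance, config)
    twin = {
        (t.stim_pair, t.channel, t.event_idx): t.post[offset : offset + m] for t in trials
    }

    def _xyz(name):
        return electrodes.loc[name, ["x_mm", "y_mm", "z_mm"]].to_numpy(float)

    scores["state_class"] = scores["state"].map(lambda s: STATE_CLASS.get(s, "unknown"))
    conn_rows = []
    curve_rows = []
    exi_rows = []
    for (stim, ch), det in detection.groupby(["stim_pair", "channel"]):
        det = det.iloc[0]
        grp = scores[(scores.stim_pair == stim) & (scores.channel == ch)]
        mapping = grp[grp.block_kind == "mapping"]
        distance = float(np.linalg.norm(_xyz(stim) - _xyz(ch)))
        same_region = electrodes.loc[stim, "region"] == electrodes.loc[ch, "region"]
        same_hemi = electrodes.loc[stim, "hemisphere"] == electrodes.loc[ch, "hemisphere"]
        cls = classify_connection(distance, det.latency_ms, same_region, same_hemi, config)
        for state, sub in [("pooled", mapping)] + [
            (s, mapping[mapping.state_class == s]) for s in ("W", "NREM", "REM")
        ]:
            if len(sub) == 0:
                continue
            keep = sub[~sub.outlier] if config.outlier_mode == "both" else sub
            if len(keep) == 0:
                continue
            p, n_sig, n_stims = signaling_probability(keep["response"].to_numpy())
            sig_windows = [
                twin[(stim, ch, e)]
                for e, r in zip(keep["event_idx"], keep["response"])
                if r and (stim, ch, e) in twin
            ]
            mag = (
                response_magnitude(np.stack(sig_windows), fs, config.min_trials)
                if len(sig_windows) >= config.min_trials
                else float("nan")
            )
            conn_rows.append(
                {
                    "stim_pair": stim,
                    "channel": ch,
                    "state": state,
                    "n_stims": n_stims,
                    "n_significant": n_sig,
                    "probability": p,
                    "latency_ms": det.latency_ms,
                    "magnitude": mag,
                    "distance_mm": distance,
                    "stim_region": electrodes.loc[stim, "region"],
                    "resp_region": electrodes.loc[ch, "region"],
                    "connection_class": cls,
                    "effective": bool(det.effective),
                    "p_value": det.p_value,
                    "n_outliers": int(sub["outlier"].sum()),
                }
            )
        # stimulation-response curves per state class
        sr = grp[grp.block_kind == "sr_curve"]
        if len(sr) == 0:
            continue
        state_curves = {}
        for state in ("W", "NREM", "REM"):
            sub = sr[sr.state_class == state]
            if len(sub) == 0:
                continue
            lv_int, lv_mag, lv_n = [], [], []
            for inten, lv in sub.groupby("intensity_ma"):
                wins = [
                    twin[(stim, ch, e)]
                    for e, r in zip(lv["event_idx"], lv["response"])
                    if r and (stim, ch, e) in twin
                ]
                lv_int.append(float(inten))
                lv_n.append(len(lv))
                lv_mag.append(
                    response_magnitude(np.stack(wins), fs, config.min_trials)
                    if len(wins) >= config.min_trials
                    else float("nan")
                )
            state_curves[state] = (lv_int, lv_mag, lv_n)
        wake_max = float("nan")
        if "W" in state_curves:
            finite = [
                mg
                for mg, n in zip(state_curves["W"][1], state_curves["W"][2])
                if np.isfinite(mg) and n >= config.min_trials
            ]
            if finite:
                wake_max = max(finite)
        for state, (lv_int, lv_mag, lv_n) in state_curves.items():
            curve = build_sr_curve(lv_int, lv_mag, lv_n, state, wake_max, config.min_trials)
            exi = excitability_index(curve)
            exi_sig, exi_thr = False, float("nan")
            if np.isfinite(exi):
                baseline = _baseline_slice(recording.signal[ch_index[ch]], fs, bwin)
                exi_sig, exi_thr = excitability_significance(
                    curve, baseline, fs, np.random.default_rng(config.seed + 7), config
                )
            for i in range(len(lv_int)):
                curve_rows.append(
                    {
                        "stim_pair": stim,
                        "channel": ch,
                        "state": state,
                        "intensity_ma": lv_int[i],
                        "n_trials": lv_n[i],
                        "magnitude": lv_mag[i],
                    }
                )
            exi_rows.append(
                {
                    "stim_pair": stim,
                    "channel": ch,
                    "state": state,
                    "exi": exi,
                    "exi_significant": exi_sig,
                    "exi_threshold": exi_thr,
                    "wake_max_ll": wake_max,
                }
            )

    connections = pd.DataFrame(conn_rows)
    # FDR-correct connection-level decisions across all probed pairs
    if len(connections):
        from .stats import fdr_bh

        pooled_mask = connections.state == "pooled"
        reject, p_adj = fdr_bh(
            connections.loc[pooled_mask, "p_value"].to_numpy(), config.fdr_alpha
        )
        adj = dict(
            zip(
                zip(
                    connections.loc[pooled_mask, "stim_pair"],
                    connections.loc[pooled_mask, "channel"],
                ),
                zip(p_adj, reject & connections.loc[pooled_mask, "effective"].to_numpy()),
            )
        )
        keys = list(zip(connections["stim_pair"], connections["channel"]))
        connections["p_value_fdr"] = [adj[k][0] for k in keys]
        connections["effective_fdr"] = [bool(adj[k][1]) for k in keys]
    connections.to_csv(out / "connections.csv", index=False)

    # undirected pairs with DI (pooled state)
    pair_rows = []
    pooled = connections[connections.state == "pooled"].set_index(["stim_pair", "channel"])
    seen = set()
    for (a, b) in pooled.index:
        if (b, a) in seen or (a, b) in seen:
            continue
        seen.add((a, b))
        p_ab = float(pooled.loc[(a, b), "probability"])
        p_ba = float(pooled.loc[(b, a), "probability"]) if (b, a) in pooled.index else 0.0
        pair_rows.append(
            {
                "a": a,
                "b": b,
                "p_ab": p_ab,
                "p_ba": p_ba,
                "di_ab": directionality_index(p_ab, p_ba),
                "distance_mm": float(pooled.loc[(a, b), "distance_mm"]),
                "connection_class": pooled.loc[(a, b), "connection_class"],
            }
        )
    pd.DataFrame(pair_rows).to_csv(out / "pairs.csv", index=False)
    pd.DataFrame(curve_rows).to_csv(out / "sr_curves.csv", index=False)
    pd.DataFrame(exi_rows).to_csv(out / "excitability.csv", index=False)
    (out / "metrics_info.json").write_text(
        json.dumps(
            {
                "distance_threshold_mm": config.distance_threshold_mm,
                "latency_threshold_ms": config.latency_threshold_ms,
                "fdr_alpha": config.fdr_alpha,
                "min_trials": config.min_trials,
                "outlier_mode": config.outlier_mode,
            },
            indent=2,
        )
    )
    return out


# ---------------------------------------------------------------------------
# stage: stats
# ---------------------------------------------------------------------------

def stage_stats(in_dir: Path, out_dir: Path, config: RunConfig) -> Path:
    base = Path(in_dir)
    out = Path(out_dir) / "stats"
    out.mkdir(parents=True, exist_ok=True)
    connections = pd.read_csv(base / "metrics" / "connections.csv")
    pooled = connections[connections.state == "pooled"].copy()
    pairs = pd.read_csv(base / "metrics" / "pairs.csv")

    ct = class_contrasts(
        pooled.rename(columns={"probability": "probability"}).assign(
            di=pooled.merge(
                pairs[["a", "b", "di_ab"]],
                left_on=["stim_pair", "channel"],
                right_on=["a", "b"],
                how="left",
            )["di_ab"].to_numpy()
        ),
        config.fdr_alpha,
    )
    ct.to_csv(out / "contrasts.csv", index=False)

    coef_path = out / "model_coefficients.csv"
    effective = pooled[pooled.effective & (pooled.n_stims > 0)]
    report: dict = {"alpha": config.fdr_alpha, "fdr_method": "benjamini-hochberg"}
    if effective["stim_region"].nunique() >= 1 and len(effective) >= 4 and (
        effective["stim_region"] + ":" + effective["resp_region"]
    ).nunique() >= 2:
        model = fit_probability_model(effective)
        pd.DataFrame(
            {"coef": model.params, "se": model.bse, "p": model.pvalues}
        ).to_csv(coef_path)
        report["pseudo_r2_mcfadden"] = model.pseudo_r2
        report["n_model_observations"] = model.n_observations
    else:
        report["model"] = "skipped: too few effective connections/region pairs"
    (out / "stats_report.json").write_text(json.dumps(report, indent=2))
    return out


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_pipeline(
    config: RunConfig,
    out_dir: Path,
    duration_h: float = 1.0,
    block_interval_s: float = 3600.0,
) -> dict:
    """Run all five stages into ``out_dir``; returns the manifest."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "version": __version__,
        "stages": [],
    }
    stage_fns = {
        "simulate": lambda: stage_simulate(
            out, config, duration_h=duration_h, block_interval_s=block_interval_s
        ),
        "preprocess": lambda: stage_preprocess(out, out, config),
        "detect": lambda: stage_detect(out, out, config),
        "metrics": lambda: stage_metrics(out, out, config),
        "stats": lambda: stage_stats(out, out, config),
    }
    for name in STAGES:
        try:
            stage_fns[name]()
            manifest["stages"].append({"stage": name, "status": "completed"})
        except Exception as exc:
            manifest["stages"].append({"stage": name, "status": "failed", "error": str(exc)})
            (out / "FAILED").write_text(f"stage {name}: {exc}\n")
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise StageError(f"stage {name!r} failed: {exc}") from exc
    conn_path = out / "metrics" / "connections.csv"
    if conn_path.exists():
        manifest["n_connection_rows"] = int(len(pd.read_csv(conn_path)))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
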