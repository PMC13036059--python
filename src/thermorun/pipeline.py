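"""Orchestration: simulate -> segment -> select -> metrics -> fuse -> physio -> stats.

A session run produces a synchronized long table (selected-frame metrics +
resampled sensors), per-stage summaries, phase deltas and a JSON manifest
recording seeds and parameter hashes, so a rerun with the same config is
bit-identical.  The reproducibility driver runs T1/T2/T3 per participant
(sharing the participant's physiology seed across sessions, with
independent measurement-noise seeds) and computes section-wise ICC tables,
cohort median series and repeated-measures correlation panels.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from thermorun import fuse, frameselect, metrics, physio, segment, stats, synthdata
from thermorun.physio import Participant
from thermorun.synthdata import SceneConfig, PhysioParams

__all__ = [
    "SessionConfig",
    "SessionResult",
    "run_session_analysis",
    "run_reproducibility",
    "StageError",
    "SECTIONS",
]

PIPELINE_STAGES = ("synthdata", "segment", "frameselect", "metrics",
                   "fuse", "physio", "stats")

#: exercise sections compared across sessions: name -> (sessions, (start, end) s)
SECTIONS = {
    "WU": (("T1", "T2", "T3"), (0.0, 600.0)),
    "CON_T1-T2": (("T1", "T2"), (600.0, 1680.0)),       # first half, both continuous
    "CON_T1-T3": (("T1", "T3"), (1680.0, 2760.0)),      # second half, both continuous
    "CON_T2-T3": (("T2", "T3"), None),                  # T2 FH vs T3 SH (aligned per session)
    "INT_T2-T3": (("T2", "T3"), None),                  # T2 SH vs T3 FH
    "REC": (("T1", "T2", "T3"), (2760.0, 2940.0)),
}
_HALVES = {"CON_T2-T3": {"T2": (600.0, 1680.0), "T3": (1680.0, 2760.0)},
           "INT_T2-T3": {"T2": (1680.0, 2760.0), "T3": (600.0, 1680.0)}}


class StageError(RuntimeError):
    """A pipeline stage violated its contract; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage={stage}: {original}")
        self.stage = stage
        self.original = original


@dataclass
class SessionConfig:
    session_id: str = "T1"
    participant: Participant = field(default_factory=lambda: Participant(id="SYN"))
    scene: SceneConfig = field(default_factory=SceneConfig)
    params: PhysioParams = field(default_factory=PhysioParams)
    seed: int = 0
    physio_seed: int | None = None   # share across sessions of one runner
    duration: float | None = None
    segmentation: str = "oracle"            # oracle | classical | external
    external_masks: list | None = None
    segment_params: segment.SegmentParams = field(default_factory=segment.SegmentParams)
    min_area_fraction: float = 0.5
    bin_width: float = 0.1
    min_pixels: int = 25
    savgol_window_s: float = 54.0           # physical smoothing window (151 samples at full rate)
    savgol_polyorder: int = 3

    def params_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class SessionResult:
    config: SessionConfig
    session: synthdata.SyntheticSession
    selected: np.ndarray
    metric_table: pd.DataFrame      # raw per-selected-frame metrics
    fused: pd.DataFrame             # smoothed metrics + resampled sensors
    stages: pd.DataFrame            # per-stage 5-s aggregates
    deltas: dict
    derived: dict
    manifest: dict


def _odd_window(n_samples: float, series_len: int, polyorder: int) -> int:
    w = int(round(n_samples))
    w = max(w | 1, polyorder + 2 if (polyorder + 2) % 2 == 1 else polyorder + 3)
    if w > series_len:
        w = series_len if series_len % 2 == 1 else series_len - 1
    return w


def run_session_analysis(config: SessionConfig, out_dir: str | None = None) -> SessionResult:
    """Run the full analysis chain for one (synthetic) session."""
    cfg = config

    def _stage(name):
        def wrap(exc):
            raise StageError(name, exc) from exc
        return wrap

    # --- synthdata -------------------------------------------------------
    try:
        session = synthdata.generate_session(cfg.session_id, cfg.participant,
                                             cfg.scene, cfg.params, seed=cfg.seed,
                                             duration=cfg.duration,
                                             physio_seed=cfg.physio_seed)
    except Exception as exc:   # pragma: no cover - passthrough
        _stage("synthdata")(exc)

    # --- segment ---------------------------------------------------------
    try:
        if cfg.segmentation == "oracle":
            masks = [segment.oracle_segment(m) for m in session.truth_masks]
            areas = np.array([m.body.sum() for m in masks], dtype=float)
        elif cfg.segmentation == "classical":
            # fast body-only pass for areas; vessel classes only on selected frames
            bodies = []
            areas = np.empty(len(session.frames))
            for i, fr in enumerate(session.frames):
                body = segment.segment_body(fr, cfg.segment_params)
                bodies.append(body)
                areas[i] = body.sum()
            masks = None
        elif cfg.segmentation == "external":
            if cfg.external_masks is None or len(cfg.external_masks) != len(session.frames):
                raise ValueError("external mode requires one mask per frame")
            masks = [segment.SegmentationMask(np.asarray(m), source="external")
                     for m in cfg.external_masks]
            areas = np.array([m.body.sum() for m in masks], dtype=float)
        else:
            raise ValueError(f"unknown segmentation mode {cfg.segmentation!r}")
    except StageError:
        raise
    except Exception as exc:
        _stage("segment")(exc)

    # --- frameselect -----------------------------------------------------
    try:
        selected = frameselect.select_stance_frames(
            areas, fps=session.frames.fps,
            step_frequency=cfg.scene.gait_frequency,
            min_area_fraction=cfg.min_area_fraction)
    except Exception as exc:
        _stage("frameselect")(exc)

    # --- metrics ---------------------------------------------------------
    try:
        if cfg.segmentation == "classical":
            masks = {}
            for i in selected:
                resp = segment.enhance_vessels(session.frames[i], bodies[i], cfg.segment_params)
                masks[i] = segment.classify_vessels(resp, bodies[i], cfg.segment_params)
            mask_list = [masks.get(i) for i in range(len(session.frames))]
        else:
            mask_list = masks
        table = metrics.metric_timeseries(session.frames, mask_list, selected,
                                          bin_width=cfg.bin_width,
                                          min_pixels=cfg.min_pixels)
    except StageError:
        raise
    except Exception as exc:
        _stage("metrics")(exc)

    # --- fuse ------------------------------------------------------------
    try:
        t = table["timestamp"].to_numpy()
        rate = 1.0 / np.median(np.diff(t)) if t.size > 1 else 1.0
        window = _odd_window(cfg.savgol_window_s * rate, t.size, cfg.savgol_polyorder)
        fused = pd.DataFrame({"time": t})
        for col in ("t_mean", "t_nv", "t_v", "t_p", "h_mean", "h_nv", "h_v", "h_p"):
            filled = fuse.interpolate_missing(table[col].to_numpy())
            fused[col] = fuse.savgol_smooth(filled, window=window,
                                            polyorder=cfg.savgol_polyorder)
        sens = session.sensors
        for col in ("hr", "vo2", "tcore_pill", "tcore_ant", "ambient_temp", "humidity"):
            fused[col] = fuse.resample_to_timeline(sens.time, getattr(sens, col), t)
        fused["load_pct"] = session.protocol.load_series(t)
    except Exception as exc:
        _stage("fuse")(exc)

    # --- physio ----------------------------------------------------------
    try:
        series = {c: fused[c].to_numpy() for c in fused.columns if c != "time"}
        summaries = fuse.aggregate_stage(t, series, session.protocol)
        stage_df = fuse.stage_table(summaries)
        deltas = {}
        t_max = float(t[-1])
        for var in ("t_nv", "t_p", "t_mean", "t_v"):
            for a, b in (("Pre", "WU-end"), ("WU-end", "FH-end"), ("FH-end", "SH-end"),
                         ("SH-end", "REC-end"), ("Pre", "FH-end")):
                if physio.ANCHORS[b] - 5.0 > t_max + 1e-9:   # truncated session
                    continue
                deltas[f"d_{var}_{a}_to_{b}"] = physio.delta_metric(
                    t, fused[var].to_numpy(), a, b)
        part = cfg.participant
        vo2_end = stage_df.iloc[-2]["vo2"] if len(stage_df) >= 2 else float("nan")
        m_rate = physio.metabolic_rate(float(vo2_end)) if np.isfinite(vo2_end) else float("nan")
        v_end = session.protocol.phases[-2].velocity
        w_ext = physio.external_work_rate(part.mass_pre, v_end, session.protocol.incline)
        derived = {
            "bsa": part.bsa,
            "bmi": part.bmi,
            "mhp_end": physio.mhp(m_rate, w_ext, part.bsa) if np.isfinite(m_rate) else float("nan"),
            "core_skin_gradient_end": physio.core_skin_gradient(
                float(fused["tcore_ant"].iloc[-1]), float(fused["t_nv"].iloc[-1])),
        }
        if part.mass_post is not None:
            derived["sweat_loss_g"] = physio.sweat_loss(part.mass_pre, part.mass_post)
    except Exception as exc:
        _stage("physio")(exc)

    # --- stats -----------------------------------------------------------
    try:
        wu = fused[fused["time"] <= 600.0]
        corr_panel = {}
        if len(wu) >= 3:
            corr_panel["wu_tnv_vs_tcore"] = stats.correlate(
                wu["t_nv"], wu["tcore_ant"]).r
        rec = fused[fused["time"] >= session.protocol.phases[-1].start]
        if len(rec) >= 3:
            corr_panel["rec_tp_vs_hr"] = stats.correlate(rec["t_p"], rec["hr"]).r
    except Exception as exc:
        _stage("stats")(exc)

    manifest = {
        "session_id": cfg.session_id,
        "participant": cfg.participant.id,
        "seed": cfg.seed,
        "params_hash": cfg.params_hash(),
        "stages": [{"name": s, "params_hash": cfg.params_hash()} for s in PIPELINE_STAGES],
        "n_frames": len(session.frames),
        "n_selected": int(len(selected)),
        "savgol_window_samples": int(window),
        "corr_panel": corr_panel,
    }
    result = SessionResult(config=cfg, session=session, selected=selected,
                           metric_table=table, fused=fused, stages=stage_df,
                           deltas=deltas, derived=derived, manifest=manifest)
    if out_dir is not None:
        _write_outputs(result, out_dir)
    return result


def _write_outputs(result: SessionResult, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    result.metric_table.to_csv(os.path.join(out_dir, "metrics.csv"), index=False)
    result.fused.to_csv(os.path.join(out_dir, "fused.csv"), index=False)
    result.stages.to_csv(os.path.join(out_dir, "stages.csv"), index=False)
    sess = result.session
    frameselect.selection_table(
        np.array([m.body.sum() for m in sess.truth_masks], dtype=float),
        sess.frames.timestamps, result.selected
    ).to_csv(os.path.join(out_dir, "selection.csv"), index=False)
    sess.sensors.to_frame().to_csv(os.path.join(out_dir, "sensors.csv"), index=False)
    sess.truth_metrics.to_csv(os.path.join(out_dir, "truth_metrics.csv"), index=False)
    with open(os.path.join(out_dir, "deltas.json"), "w") as fh:
        json.dump({**result.deltas, **result.derived}, fh, indent=1)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(result.manifest, fh, indent=1)


def _section_matrix(results: dict[str, SessionResult], section: str,
                    grid_step: float = 5.0) -> np.ndarray | None:
    """Aligned (n_time x k_sessions) matrix of fused T_NV for one section."""
    sessions, interval = SECTIONS[section]
    cols = []
    for sid in sessions:
        res = results.get(sid)
        if res is None:
            return None
        lo, hi = interval if interval is not None else _HALVES[section][sid]
        t = res.fused["time"].to_numpy()
        grid = np.arange(0.0, hi - lo + 1e-9, grid_step)
        sel = (t >= lo) & (t <= hi)
        if sel.sum() < 2:
            return None
        cols.append(np.interp(grid, t[sel] - lo, res.fused["t_nv"].to_numpy()[sel]))
    return np.column_stack(cols)


def run_reproducibility(participants: list[Participant],
                        scene: SceneConfig | None = None,
                        params: PhysioParams | None = None,
                        seed: int = 0,
                        sessions: tuple[str, ...] = ("T1", "T2", "T3"),
                        shared_physiology: bool = True,
                        rmcorr_sample_step: float = 15.0,
                        session_kwargs: dict | None = None) -> dict:
    """Run T1/T2/T3 for each participant and compute the reliability report.

    Each participant keeps one physiology seed across their sessions
    (``shared_physiology=True``, the repeated-measures design) while frame
    and sensor noise seeds differ per session.  Returns a dict with the
    section ICC table, cohort median T_NV series, and rmcorr panels
    (T_P vs HR and VO2 over the intermittent section; entropy of T_P vs
    T_CORE over the warm-up).
    """
    scene = scene or SceneConfig()
    params = params or PhysioParams()
    session_kwargs = session_kwargs or {}
    root = np.random.SeedSequence([int(seed), 0xC0DE])
    per_part = root.spawn(len(participants))

    all_results: dict[str, dict[str, SessionResult]] = {}
    for p_index, (part, pseq) in enumerate(zip(participants, per_part)):
        child = pseq.generate_state(len(sessions) + 2) % (2 ** 31)
        # one calf/vessel geometry per runner, stable across their sessions
        part_scene = dataclasses.replace(scene, seed=int(child[-1]))
        res_by_session = {}
        for j, sid in enumerate(sessions):
            cfg = SessionConfig(
                session_id=sid, participant=part, scene=part_scene, params=params,
                seed=int(child[j]),
                physio_seed=int(child[-2]) if shared_physiology else None,
                **session_kwargs)
            res = run_session_analysis(cfg)
            # free the frame/mask payload; the report only needs the tables
            res.session.frames.frames = []
            res.session.truth_masks = []
            res_by_session[sid] = res
        all_results[part.id] = res_by_session

    section_matrices = {pid: {sec: _section_matrix(r, sec) for sec in SECTIONS}
                        for pid, r in all_results.items()}
    icc_table = stats.section_icc_report(section_matrices)

    # cohort median T_NV on a common 1-s grid, then rolling-median smoothed
    grid = np.arange(0.0, 2941.0, 1.0)
    panel = []
    for pid, r in all_results.items():
        for sid, res in r.items():
            panel.append(np.interp(grid, res.fused["time"], res.fused["t_nv"]))
    cohort_median = fuse.rolling_median(fuse.cohort_median_series(np.array(panel)),
                                        window=350)

    def _rm_panel(sid: str, var_x: str, var_y: str, lo: float, hi: float):
        subs, xs, ys = [], [], []
        for pid, r in all_results.items():
            res = r.get(sid)
            if res is None:
                continue
            t = res.fused["time"].to_numpy()
            grid_s = np.arange(lo, hi + 1e-9, rmcorr_sample_step)
            sel = (t >= lo) & (t <= hi)
            if sel.sum() < 2:
                continue
            xs.append(np.interp(grid_s, t[sel], res.fused[var_x].to_numpy()[sel]))
            ys.append(np.interp(grid_s, t[sel], res.fused[var_y].to_numpy()[sel]))
            subs.append(np.full(grid_s.size, pid))
        if len(subs) < 2:
            return None
        return stats.rmcorr(np.concatenate(subs), np.concatenate(xs),
                            np.concatenate(ys), n_boot=500, seed=seed)

    rm_panels = {}
    for sid in sessions:
        if sid not in ("T2", "T3"):
            continue
        lo, hi = _HALVES["INT_T2-T3"][sid]
        rm_panels[f"{sid}_INT_tp_vs_hr"] = _rm_panel(sid, "hr", "t_p", lo, hi)
        rm_panels[f"{sid}_INT_tp_vs_vo2"] = _rm_panel(sid, "vo2", "t_p", lo, hi)
    for sid in sessions:
        rm_panels[f"{sid}_WU_htp_vs_tcore"] = _rm_panel(sid, "tcore_ant", "h_p", 0.0, 600.0)
        lo_r, hi_r = SECTIONS["REC"][1]
        rm_panels[f"{sid}_REC_tp_vs_hr"] = _rm_panel(sid, "hr", "t_p", lo_r, hi_r)

    return {
        "icc_table": icc_table,
        "cohort_median_tnv": pd.DataFrame({"time": grid, "t_nv": cohort_median}),
        "rmcorr_panels": rm_panels,
        "results": all_results,
    }
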