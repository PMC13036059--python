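"""Synthetic thermogram sessions and sensor traces with ground truth.

The generator emulates the measurement setting of a treadmill running
session viewed by a fixed radiometric camera: two elliptical calves on an
ambient background, superficial veins as warm curvilinear strokes,
cutaneous arterial perforators as compact warm blobs, gait-driven area
reduction and motion blur during the swing phase, and pixel noise at the
camera's thermal-resolution scale.

Physiology follows first-order linear dynamics toward load-proportional
targets: HR and VO2 lag the commanded external load (% of the velocity at
the individual anaerobic threshold, vIAT); core temperature is a
saturating ramp driven by relative load; non-vessel skin temperature
combines a fast sympathetic vasoconstriction component, slow heat storage
coupled to the core-temperature rise, and a cutaneous vasodilation rebound
once the load drops to walking at the end of the session.  With default
parameters the warm-up non-vessel drop is ~-1.2 degC and the post-exercise
rebound ~+1.4 degC within 3 min, and the rendered metric ordering
T_V > T_P > T_MEAN > T_NV holds in every frame.

All states are advanced with the exact exponential step for
piecewise-constant inputs, so noise-free step responses match the
closed-form first-order solution to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from thermorun.thermio import CalibrationInfo, RadiometricFrame, FrameSequence
from thermorun.segment import (SegmentationMask, LABEL_CALF, LABEL_VEIN,
                               LABEL_PERFORATOR)
from thermorun.fuse import SensorTrace
from thermorun.physio import Participant, Protocol, build_protocol

__all__ = [
    "SceneConfig",
    "PhysioParams",
    "SyntheticSession",
    "simulate_physiology",
    "render_frame",
    "generate_session",
    "scene_templates",
]

#: normalising load for the fast/slow thermal drives (the CON load, % vIAT)
_REFERENCE_LOAD_PCT = 85.0
#: swing phase occupies gait phases in (pi/2, 3*pi/2)
_SWING_LO, _SWING_HI = np.pi / 2, 3 * np.pi / 2


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, optics and noise of the synthetic thermogram scene.

    Defaults are desk scale: a 96x128 grid at 2 fps with the gait slowed to
    0.4 Hz so one gait cycle spans several frames at the reduced rate; the
    full-rate acquisition (30 fps, ~2.8 Hz cadence, 1024x768) is available
    by configuration.
    """

    image_height: int = 96
    image_width: int = 128
    ambient_temp: float = 20.2          # degC, thermoneutral laboratory
    base_skin_temp: float = 31.0        # degC, resting non-vessel calf skin
    vein_delta: float = 1.2             # degC above non-vessel skin
    perforator_delta: float = 0.7       # degC above non-vessel skin
    vein_count: int = 2                 # per calf
    perforator_count: int = 3           # per calf
    vessel_profile_sigma: float = 1.2   # px, cross-profile scale
    noise_sigma: float = 0.05           # degC per pixel, i.i.d. Gaussian
    fps: float = 2.0
    gait_frequency: float = 0.4         # Hz
    swing_area_reduction: float = 0.35
    swing_blur_sigma: float = 3.0       # px
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.vein_delta > self.perforator_delta > 0:
            raise ValueError("need vein_delta > perforator_delta > 0")
        if not self.ambient_temp < self.base_skin_temp:
            raise ValueError("ambient_temp must be below base_skin_temp")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not 0 < self.gait_frequency < self.fps / 2:
            raise ValueError("gait_frequency must lie in (0, fps/2)")


@dataclass(frozen=True)
class PhysioParams:
    """First-order physiological dynamics and their noise scales.

    Gains are per %vIAT of commanded load; time constants in seconds.
    Defaults reproduce a warm-up non-vessel temperature drop of -1.1 to
    -1.3 degC within 3 min and a post-exercise rebound of ~+1.4 degC.
    """

    hr_rest: float = 55.0               # bpm
    hr_gain: float = 1.30               # bpm per %vIAT
    tau_hr: float = 40.0
    vo2_rest: float = 0.35              # L/min
    vo2_gain: float = 0.0325            # L/min per %vIAT
    tau_vo2: float = 45.0
    tcore_baseline: float = 37.1        # degC
    tcore_rise: float = 1.2             # degC asymptotic session rise
    tau_core: float = 2400.0
    tnv_baseline: float = 31.0          # degC
    vasoconstriction_amp: float = 1.8   # degC at reference load
    tau_fast: float = 60.0
    storage_gain: float = 0.5           # degC skin per degC core rise
    rebound_amp: float = 0.5            # degC extra vasodilation after exercise
    tau_rebound: float = 90.0
    noise_hr: float = 1.0               # bpm
    noise_vo2: float = 0.05             # L/min
    noise_tcore: float = 0.02           # degC
    pill_ant_offset: float = 0.15       # degC systematic pill-vs-ANT+ offset
    ou_sigma: float = 0.02              # degC stationary sd of vasomotor fluctuation
    ou_tau: float = 240.0               # s, its correlation time

    def __post_init__(self) -> None:
        for name in ("tau_hr", "tau_vo2", "tau_core", "tau_fast", "tau_rebound"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _exp_step(state: float, target: float, dt: float, tau: float) -> float:
    """Exact update of dy/dt = (target - y)/tau over dt with constant target."""
    return target + (state - target) * np.exp(-dt / tau)


def simulate_physiology(protocol: Protocol, params: PhysioParams | None = None,
                        dt: float = 1.0, seed: int = 0,
                        vein_delta: float = 1.2, perforator_delta: float = 0.7,
                        vessel_fractions: tuple[float, float] = (0.12, 0.03),
                        sensor_seed: int | None = None,
                        ) -> tuple[SensorTrace, pd.DataFrame]:
    """Integrate sensor and skin-temperature dynamics over a protocol.

    Returns the noisy sensor trace (1/dt Hz) and a noise-free ground-truth
    DataFrame of the four skin-temperature metrics plus internal states.
    T_MEAN truth is the vessel-fraction-weighted mean of the three regions.
    """
    params = params or PhysioParams()
    if dt <= 0 or dt > 1.0:
        raise ValueError("dt must be in (0, 1] s")
    if not protocol.phases:
        raise ValueError("empty protocol")
    ss = np.random.SeedSequence([int(seed), 0x5EB5])
    truth_ss, sensor_ss = ss.spawn(2)
    rng_truth = np.random.default_rng(truth_ss)
    # sensor (measurement) noise can be re-seeded independently of the
    # physiological truth, e.g. for repeated sessions of the same runner
    rng = np.random.default_rng(sensor_ss if sensor_seed is None
                                else np.random.SeedSequence([int(sensor_seed), 0x5E50]))

    n = int(round(protocol.total_duration / dt)) + 1
    times = np.arange(n) * dt
    load = protocol.load_series(times)                       # % vIAT
    walking = np.array([protocol.phase_at(t).mode == "WALK" for t in times])

    hr = np.empty(n)
    vo2 = np.empty(n)
    tcore = np.empty(n)
    x_fast = np.empty(n)
    rebound = np.empty(n)
    hr[0], vo2[0], tcore[0] = params.hr_rest, params.vo2_rest, params.tcore_baseline
    x_fast[0], rebound[0] = 0.0, 0.0

    for k in range(1, n):
        u_pct = load[k - 1]
        u_rel = u_pct / _REFERENCE_LOAD_PCT
        hr[k] = _exp_step(hr[k - 1], params.hr_rest + params.hr_gain * u_pct, dt, params.tau_hr)
        vo2[k] = _exp_step(vo2[k - 1], params.vo2_rest + params.vo2_gain * u_pct, dt, params.tau_vo2)
        # saturating core ramp: dTc/dt = (u/tau)*(Tmax - Tc); monotone for u >= 0
        t_max = params.tcore_baseline + params.tcore_rise
        if u_rel > 0:
            tcore[k] = t_max + (tcore[k - 1] - t_max) * np.exp(-u_rel * dt / params.tau_core)
        else:
            tcore[k] = tcore[k - 1]
        x_fast[k] = _exp_step(x_fast[k - 1], u_rel, dt, params.tau_fast)
        r_target = params.rebound_amp if walking[k - 1] else 0.0
        rebound[k] = _exp_step(rebound[k - 1], r_target, dt, params.tau_rebound)

    # slow vasomotor fluctuation (OU process): the day-to-day physiological
    # variability of skin temperature, part of the ground truth itself
    ou = np.zeros(n)
    if params.ou_sigma > 0:
        rho = np.exp(-dt / params.ou_tau)
        innov = params.ou_sigma * np.sqrt(1 - rho ** 2) * rng_truth.standard_normal(n)
        for k in range(1, n):
            ou[k] = rho * ou[k - 1] + innov[k]

    t_nv = (params.tnv_baseline
            - params.vasoconstriction_amp * x_fast
            + params.storage_gain * (tcore - params.tcore_baseline)
            + rebound
            + ou)
    t_v = t_nv + vein_delta
    t_p = t_nv + perforator_delta
    f_v, f_p = vessel_fractions
    t_mean = (1.0 - f_v - f_p) * t_nv + f_v * t_v + f_p * t_p

    truth = pd.DataFrame({
        "time": times, "load_pct": load,
        "t_nv": t_nv, "t_v": t_v, "t_p": t_p, "t_mean": t_mean,
        "tcore": tcore, "hr": hr, "vo2": vo2,
        "x_fast": x_fast, "rebound": rebound, "ou": ou,
    })

    # sparse RPE: one Borg rating at the end of each stage
    rpe = np.full(n, np.nan)
    for ph in protocol.phases:
        k = min(int(round(ph.end / dt)) - 1, n - 1)
        rating = 6.0 + 0.105 * ph.pct_viat + 0.055 * (ph.end / 60.0)
        rpe[k] = float(np.clip(np.round(rating), 6, 20))

    sensors = SensorTrace(
        time=times,
        hr=hr + params.noise_hr * rng.standard_normal(n),
        vo2=np.maximum(vo2 + params.noise_vo2 * rng.standard_normal(n), 0.0),
        tcore_pill=tcore + params.noise_tcore * rng.standard_normal(n),
        tcore_ant=tcore - params.pill_ant_offset + params.noise_tcore * rng.standard_normal(n),
        rpe=rpe,
        ambient_temp=20.2 + 0.3 * times / max(times[-1], 1.0)
        + 0.05 * rng.standard_normal(n),
        humidity=44.0 + 0.5 * rng.standard_normal(n),
    )
    return sensors, truth


# ---------------------------------------------------------------------------
# scene rendering
# ---------------------------------------------------------------------------

class DrawableAreaError(ValueError):
    """Requested vessel counts cannot be placed in the calf area."""


@dataclass
class _Template:
    """Static per-gait-state geometry: unit fields and labels."""

    body: np.ndarray          # float {0,1}: calf support
    vein: np.ndarray          # float [0,1]: unit vein profile
    perf: np.ndarray          # float [0,1]: unit perforator profile
    labels: np.ndarray        # uint8 ground-truth labels
    coeffs: dict[str, tuple[float, float]]  # region -> (mean vein, mean perf)


@dataclass
class _SceneTemplates:
    stance: _Template
    swing: _Template          # reduced-area geometry, component fields pre-blurred
    swing_labels: np.ndarray


def _ellipse_params(scene: SceneConfig, scale: float = 1.0):
    h, w = scene.image_height, scene.image_width
    a_row = 0.40 * h * scale
    a_col = 0.13 * w * scale
    centers = [(0.5 * h, 0.28 * w), (0.5 * h, 0.72 * w)]
    return a_row, a_col, centers


def _build_template(scene: SceneConfig, geometry: list[dict], scale: float) -> _Template:
    h, w = scene.image_height, scene.image_width
    rows, cols = np.mgrid[0:h, 0:w]
    sigma = scene.vessel_profile_sigma
    a_row, a_col, centers = _ellipse_params(scene, scale)

    body = np.zeros((h, w), dtype=bool)
    vein_marks = np.zeros((h, w), dtype=bool)
    perf_marks = np.zeros((h, w), dtype=bool)
    for (cr, cc), geo in zip(centers, geometry):
        body |= ((rows - cr) / a_row) ** 2 + ((cols - cc) / a_col) ** 2 <= 1.0
        for coeff in geo["veins"]:
            s = np.linspace(-1.0, 1.0, 600)
            r = cr + s * geo["vein_extent"] * a_row
            c = cc + (coeff[0] + coeff[1] * s + coeff[2] * s ** 2) * a_col
            ri = np.clip(np.rint(r).astype(int), 0, h - 1)
            ci = np.clip(np.rint(c).astype(int), 0, w - 1)
            inside = ((ri - cr) / a_row) ** 2 + ((ci - cc) / a_col) ** 2 <= 0.92
            vein_marks[ri[inside], ci[inside]] = True
        for (pr, pc) in geo["perforators"]:
            rr = cr + pr * a_row
            pc_ = cc + pc * a_col
            perf_marks[int(round(rr)), int(round(pc_))] = True

    def unit_field(marks: np.ndarray, core_radius: float) -> np.ndarray:
        if not marks.any():
            return np.zeros((h, w))
        d = ndimage.distance_transform_edt(~marks)
        fld = np.where(d <= core_radius, 1.0,
                       np.exp(-((d - core_radius) ** 2) / (2.0 * sigma ** 2)))
        return np.where(body, fld, 0.0)

    vein_field = unit_field(vein_marks, sigma)
    perf_field = unit_field(perf_marks, 2.0 * sigma)

    labels = np.where(body, LABEL_CALF, 0).astype(np.uint8)
    vein_core = (vein_field >= 1.0) & body
    perf_core = (perf_field >= 1.0) & body & ~vein_core
    labels[vein_core] = LABEL_VEIN
    labels[perf_core] = LABEL_PERFORATOR

    coeffs = {}
    for name, sel in (("nv", labels == LABEL_CALF), ("v", labels == LABEL_VEIN),
                      ("p", labels == LABEL_PERFORATOR), ("mean", labels > 0)):
        if sel.any():
            coeffs[name] = (float(vein_field[sel].mean()), float(perf_field[sel].mean()))
        else:
            coeffs[name] = (float("nan"), float("nan"))
    return _Template(body.astype(float), vein_field, perf_field, labels, coeffs)


def scene_templates(scene: SceneConfig) -> _SceneTemplates:
    """Build (and cache per config) the static stance/swing scene geometry."""
    rng = np.random.default_rng(np.random.SeedSequence([int(scene.seed), 0x6E0]))
    a_row, a_col, centers = _ellipse_params(scene)
    geometry = []
    for _ in centers:
        veins = []
        for _ in range(scene.vein_count):
            veins.append((rng.uniform(-0.45, 0.45), rng.uniform(-0.25, 0.25),
                          rng.uniform(-0.35, 0.35)))
        perfs: list[tuple[float, float]] = []
        attempts = 0
        min_sep = (4.0 * scene.vessel_profile_sigma + 2.0)
        # dense vein polylines in pixel units for distance checks
        s_dense = np.linspace(-1.0, 1.0, 200)
        vein_pts = [np.column_stack([s_dense * 0.6 * a_row,
                                     (c0 + c1 * s_dense + c2 * s_dense ** 2) * a_col])
                    for (c0, c1, c2) in veins]
        while len(perfs) < scene.perforator_count:
            attempts += 1
            if attempts > 600:
                raise DrawableAreaError("vessel counts exceed drawable area")
            pr = rng.uniform(-0.75, 0.75)
            pc = rng.uniform(-0.7, 0.7)
            if pr ** 2 + pc ** 2 > 0.8:
                continue
            # keep blobs away from vein curves and from each other
            pt = np.array([pr * a_row, pc * a_col])
            ok = all(np.min(np.hypot(v[:, 0] - pt[0], v[:, 1] - pt[1])) >= min_sep
                     for v in vein_pts)
            ok = ok and all(np.hypot((pr - qr) * a_row, (pc - qc) * a_col) >= min_sep
                            for (qr, qc) in perfs)
            if ok:
                perfs.append((pr, pc))
        geometry.append({"veins": veins, "perforators": perfs, "vein_extent": 0.6})

    stance = _build_template(scene, geometry, scale=1.0)
    swing_scale = float(np.sqrt(1.0 - scene.swing_area_reduction))
    swing = _build_template(scene, geometry, scale=swing_scale)
    swing_labels = swing.labels.copy()
    # pre-blur swing component fields so motion blur is a linear map of them
    b = scene.swing_blur_sigma
    swing = _Template(
        body=ndimage.gaussian_filter(swing.body, b),
        vein=ndimage.gaussian_filter(swing.vein, b),
        perf=ndimage.gaussian_filter(swing.perf, b),
        labels=swing_labels,
        coeffs=swing.coeffs,
    )
    return _SceneTemplates(stance=stance, swing=swing, swing_labels=swing_labels)


def is_swing(gait_phase: float) -> bool:
    """Swing (flight) phase: gait phase in (pi/2, 3*pi/2) modulo 2*pi."""
    ph = float(np.mod(gait_phase, 2 * np.pi))
    return _SWING_LO < ph < _SWING_HI


def render_frame(scene: SceneConfig, t_nv: float, t_v: float | None = None,
                 t_p: float | None = None, gait_phase: float = 0.0,
                 seed: int | None = None, templates: _SceneTemplates | None = None,
                 timestamp: float = 0.0, frame_index: int = 0,
                 calibration: CalibrationInfo | None = None,
                 ) -> tuple[RadiometricFrame, SegmentationMask]:
    """Render one radiometric frame and its ground-truth mask.

    The frame is a linear combination of static unit fields:
    ``ambient + (t_nv - ambient)*body + dv*vein + dp*perf`` (+ noise), with
    the swing-phase variant using area-reduced, motion-blurred fields.
    """
    templates = templates or scene_templates(scene)
    cal = calibration or CalibrationInfo()
    dv = (t_v - t_nv) if t_v is not None else scene.vein_delta
    dp = (t_p - t_nv) if t_p is not None else scene.perforator_delta
    if dv <= 0 or dp <= 0 or dv <= dp:
        raise ValueError("need t_v > t_p > t_nv (vein offset above perforator offset)")
    lo, hi = cal.offset, cal.offset + cal.scale * 65535
    if not (lo <= t_nv and t_nv + dv <= hi):
        raise ValueError("metric targets outside the representable camera range")

    swing = is_swing(gait_phase)
    tpl = templates.swing if swing else templates.stance
    temps = (scene.ambient_temp
             + (t_nv - scene.ambient_temp) * tpl.body
             + dv * tpl.vein + dp * tpl.perf)
    if scene.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        temps = temps + scene.noise_sigma * rng.standard_normal(temps.shape)
    frame = RadiometricFrame(temps, timestamp=timestamp, frame_index=frame_index,
                             calibration=cal)
    labels = templates.swing_labels if swing else templates.stance.labels
    return frame, SegmentationMask(labels.copy(), source="oracle")


@dataclass
class SyntheticSession:
    """A complete synthetic running session with full ground truth."""

    session_id: str
    frames: FrameSequence
    truth_masks: list[SegmentationMask]
    truth_metrics: pd.DataFrame     # per-frame rendered-region ground truth
    sensors: SensorTrace
    truth_physiology: pd.DataFrame  # 1 Hz noise-free state series
    protocol: Protocol
    participant: Participant
    scene: SceneConfig
    params: PhysioParams

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.truth_masks):
            raise ValueError("frames and truth_masks must have equal length")


def generate_session(session_id: str, participant: Participant | None = None,
                     scene: SceneConfig | None = None,
                     params: PhysioParams | None = None,
                     seed: int = 0, duration: float | None = None,
                     physio_seed: int | None = None) -> SyntheticSession:
    """Generate a full synthetic session (frames + masks + sensors + truth).

    ``duration`` truncates the timeline (seconds) for desk-scale tests; the
    default is the full 49-min protocol.  Reproducible bit-for-bit given
    (configs, seed); the protocol depends only on session_id and the
    participant's vIAT, never on the seed.
    """
    participant = participant or Participant(id="SYN")
    scene = scene or SceneConfig()
    params = params or PhysioParams()
    protocol = build_protocol(session_id, participant.viat)

    root = np.random.SeedSequence([int(seed), 0x7AE])
    physio_ss, frame_seed, sensor_ss = root.spawn(3)
    if physio_seed is None:
        physio_seed = int(physio_ss.generate_state(1)[0] % (2 ** 31))
    sensors, truth = simulate_physiology(
        protocol, params, dt=1.0, seed=physio_seed,
        sensor_seed=int(sensor_ss.generate_state(1)[0] % (2 ** 31)),
        vein_delta=scene.vein_delta, perforator_delta=scene.perforator_delta)

    total = protocol.total_duration if duration is None else min(duration, protocol.total_duration)
    n_frames = int(np.floor(total * scene.fps)) + 1
    frame_times = np.arange(n_frames) / scene.fps
    t_nv_t = np.interp(frame_times, truth["time"], truth["t_nv"])
    gait_phase = 2 * np.pi * scene.gait_frequency * frame_times

    templates = scene_templates(scene)
    cal = CalibrationInfo()
    rng = np.random.default_rng(frame_seed)
    frames: list[RadiometricFrame] = []
    masks: list[SegmentationMask] = []
    rows = []
    for k in range(n_frames):
        swing = is_swing(gait_phase[k])
        tpl = templates.swing if swing else templates.stance
        temps = (scene.ambient_temp
                 + (t_nv_t[k] - scene.ambient_temp) * tpl.body
                 + scene.vein_delta * tpl.vein + scene.perforator_delta * tpl.perf)
        if scene.noise_sigma > 0:
            temps = temps + scene.noise_sigma * rng.standard_normal(temps.shape)
        frames.append(RadiometricFrame(temps, timestamp=frame_times[k],
                                       frame_index=k, calibration=cal))
        labels = templates.swing_labels if swing else templates.stance.labels
        masks.append(SegmentationMask(labels, source="oracle"))

        c = templates.stance.coeffs if not swing else templates.swing.coeffs
        rows.append({
            "time": frame_times[k], "is_swing": swing, "gait_phase": gait_phase[k],
            "t_nv": t_nv_t[k] + scene.vein_delta * c["nv"][0] + scene.perforator_delta * c["nv"][1],
            "t_v": t_nv_t[k] + scene.vein_delta * c["v"][0] + scene.perforator_delta * c["v"][1],
            "t_p": t_nv_t[k] + scene.vein_delta * c["p"][0] + scene.perforator_delta * c["p"][1],
            "t_mean": t_nv_t[k] + scene.vein_delta * c["mean"][0] + scene.perforator_delta * c["mean"][1],
            "t_nv_target": t_nv_t[k],
        })

    seq = FrameSequence(frames, fps=scene.fps,
                        metadata={"session_id": session_id, "seed": seed,
                                  "participant": participant.id})
    return SyntheticSession(
        session_id=session_id, frames=seq, truth_masks=masks,
        truth_metrics=pd.DataFrame(rows), sensors=sensors,
        truth_physiology=truth, protocol=protocol, participant=participant,
        scene=scene, params=params)
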