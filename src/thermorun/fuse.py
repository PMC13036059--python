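"""Sensor/IRT fusion: resampling, gap interpolation, smoothing, low-pass
filtering, phase labelling, per-stage aggregation and cohort medians.

Conventions: low-frequency sensor traces are linearly resampled onto the
(higher-rate) selected-frame timeline; each treadmill stage is summarised
by the mean over its final five seconds with the treadmill acceleration/
deceleration ramps excluded; cohort series are per-timepoint medians
across participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter, butter, sosfiltfilt, sosfilt

from thermorun.physio import Protocol, Phase

__all__ = [
    "SensorTrace",
    "StageSummary",
    "resample_to_timeline",
    "interpolate_missing",
    "savgol_smooth",
    "butterworth_lowpass",
    "rolling_median",
    "label_phases",
    "ramp_exclusions",
    "aggregate_stage",
    "cohort_median_series",
]

#: treadmill velocity ramp rate [km/h per s] and safety margin [s] used to
#: exclude acceleration/deceleration samples around commanded speed changes
RAMP_RATE_KMH_PER_S = 1.0
RAMP_MARGIN_S = 2.0


@dataclass
class SensorTrace:
    """Raw sensor series on a common session clock (seconds from warm-up onset)."""

    time: np.ndarray
    hr: np.ndarray                  # bpm
    vo2: np.ndarray                 # L/min
    tcore_pill: np.ndarray          # degC
    tcore_ant: np.ndarray           # degC
    rpe: np.ndarray                 # Borg 6-20, sparse (NaN between ratings)
    ambient_temp: np.ndarray        # degC
    humidity: np.ndarray            # % RH

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        rated = self.rpe[np.isfinite(self.rpe)]
        if rated.size and (rated.min() < 6 or rated.max() > 20):
            raise ValueError("RPE values must lie in [6, 20]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.time, "hr": self.hr, "vo2": self.vo2,
            "tcore_pill": self.tcore_pill, "tcore_ant": self.tcore_ant,
            "rpe": self.rpe, "ambient_temp": self.ambient_temp,
            "humidity": self.humidity,
        })


@dataclass
class StageSummary:
    """Per-stage aggregate: mean of each variable over the final 5 s of the stage."""

    stage_id: str
    phase: str                    # WU | FH | SH | REC
    load_pct_viat: float
    start: float
    end: float
    values: dict[str, float] = field(default_factory=dict)
    valid: bool = True


def resample_to_timeline(trace_times: np.ndarray, trace_values: np.ndarray,
                         target_times: np.ndarray) -> np.ndarray:
    """Linear interpolation onto a target timeline; endpoints held outside the span."""
    trace_times = np.asarray(trace_times, dtype=float)
    trace_values = np.asarray(trace_values, dtype=float)
    if trace_times.size < 2:
        raise ValueError("need at least 2 trace points to resample")
    if np.any(np.diff(trace_times) <= 0):
        raise ValueError("trace times must be strictly increasing")
    return np.interp(np.asarray(target_times, dtype=float), trace_times, trace_values)


def interpolate_missing(series: np.ndarray) -> np.ndarray:
    """Fill NaN gaps: linear in the interior, nearest defined value at the ends."""
    s = pd.Series(np.asarray(series, dtype=float))
    if s.notna().sum() == 0:
        return s.to_numpy()
    return s.interpolate(method="linear", limit_direction="both").to_numpy()


def savgol_smooth(series: np.ndarray, window: int = 151, polyorder: int = 3) -> np.ndarray:
    """Savitzky-Golay least-squares polynomial smoothing (length preserving)."""
    series = np.asarray(series, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if window > series.size:
        raise ValueError(f"window {window} longer than series ({series.size})")
    return savgol_filter(series, window_length=window, polyorder=polyorder)


def butterworth_lowpass(series: np.ndarray, order: int = 3,
                        cutoff_normalized: float = 0.04,
                        zero_phase: bool = True) -> np.ndarray:
    """Low-pass Butterworth filter, cutoff as a fraction of Nyquist.

    Zero-phase (forward-backward) by default so filtered series stay
    time-aligned with the raw ones; set ``zero_phase=False`` for a causal
    single pass.
    """
    series = np.asarray(series, dtype=float)
    if not 0.0 < cutoff_normalized < 1.0:
        raise ValueError("cutoff_normalized must be in (0, 1)")
    sos = butter(order, cutoff_normalized, btype="low", output="sos")
    if zero_phase:
        return sosfiltfilt(sos, series)
    return sosfilt(sos, series)


def rolling_median(series: np.ndarray, window: int = 350) -> np.ndarray:
    """Centred rolling median; truncated windows at the edges."""
    s = pd.Series(np.asarray(series, dtype=float))
    return s.rolling(window, center=True, min_periods=1).median().to_numpy()


def label_phases(protocol: Protocol) -> dict[str, tuple[float, float]]:
    """Session phase intervals: WU, FH/SH (equal halves of the main block), REC."""
    wu = next(ph for ph in protocol.phases if ph.mode == "WU")
    rec = next(ph for ph in protocol.phases if ph.mode == "WALK")
    main_start, main_end = wu.end, rec.start
    mid = 0.5 * (main_start + main_end)
    return {
        "WU": (wu.start, wu.end),
        "FH": (main_start, mid),
        "SH": (mid, main_end),
        "REC": (rec.start, rec.end),
    }


def ramp_exclusions(protocol: Protocol,
                    ramp_rate: float = RAMP_RATE_KMH_PER_S,
                    margin: float = RAMP_MARGIN_S) -> list[tuple[float, float]]:
    """Excluded intervals around each commanded treadmill velocity change.

    Ramp duration is |dv| / ramp_rate plus a margin on both sides; the
    session start (initial acceleration) and end (final deceleration) are
    also excluded.
    """
    edges: list[tuple[float, float]] = []
    v_prev = 0.0
    for ph in protocol.phases:
        dv = abs(ph.velocity - v_prev)
        if dv > 1e-9 or ph is protocol.phases[0]:
            dur = dv / ramp_rate + margin
            edges.append((ph.start - margin, ph.start + dur))
        v_prev = ph.velocity
    # final deceleration to stop
    last = protocol.phases[-1]
    edges.append((last.end - RAMP_MARGIN_S, last.end + last.velocity / ramp_rate + margin))
    return edges


def _phase_of(stage: Phase, phases: dict[str, tuple[float, float]]) -> str:
    mid = 0.5 * (stage.start + stage.end)
    for name, (a, b) in phases.items():
        if a <= mid < b:
            return name
    return "REC"


def aggregate_stage(times: np.ndarray, series: dict[str, np.ndarray],
                    protocol: Protocol, window: float = 5.0) -> list[StageSummary]:
    """One summary row per protocol stage: mean over its final ``window``
    seconds, excluding treadmill ramp samples; flagged invalid when fewer
    than 50% of the window samples are defined."""
    times = np.asarray(times, dtype=float)
    phases = label_phases(protocol)
    excl = ramp_exclusions(protocol)
    in_ramp = np.zeros_like(times, dtype=bool)
    for a, b in excl:
        in_ramp |= (times >= a) & (times <= b)

    out: list[StageSummary] = []
    for ph in protocol.phases:
        sel = (times > ph.end - window) & (times <= ph.end) & ~in_ramp
        n_window = int(np.sum((times > ph.end - window) & (times <= ph.end)))
        summary = StageSummary(stage_id=ph.name, phase=_phase_of(ph, phases),
                               load_pct_viat=ph.pct_viat, start=ph.start, end=ph.end)
        for name, vals in series.items():
            vals = np.asarray(vals, dtype=float)
            good = sel & np.isfinite(vals)
            summary.values[name] = float(vals[good].mean()) if good.any() else float("nan")
            if n_window == 0 or good.sum() < 0.5 * n_window:
                summary.valid = False
        out.append(summary)
    return out


def stage_table(summaries: list[StageSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"stage_id": s.stage_id, "phase": s.phase, "load_pct_viat": s.load_pct_viat,
               "start": s.start, "end": s.end, "valid": s.valid}
        row.update(s.values)
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_median_series(panel: np.ndarray) -> np.ndarray:
    """Per-timepoint median across participants (rows), ignoring NaNs.

    ``panel`` is (n_participants, n_timepoints); the result is NaN where
    every participant is missing.
    """
    panel = np.asarray(panel, dtype=float)
    with np.errstate(all="ignore"):
        out = np.nanmedian(panel, axis=0)
    return out
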