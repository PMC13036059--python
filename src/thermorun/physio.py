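"""Protocol construction and derived physiological quantities.

Covers the load structure of the three 49-min running sessions (10-min
warm-up at 60% vIAT, a 36-min main block averaging 85% vIAT, 3-min walking
recovery at 4 km/h, treadmill incline 1.5%), body surface area (Mosteller),
BMI, metabolic heat production by partitional calorimetry, sweat loss,
core-to-skin gradient, the Dickhuth individual anaerobic threshold from a
lactate-velocity table, and phase-delta extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Participant",
    "Phase",
    "Protocol",
    "LactateStage",
    "build_protocol",
    "bsa_mosteller",
    "bmi",
    "metabolic_rate",
    "external_work_rate",
    "mhp",
    "sweat_loss",
    "core_skin_gradient",
    "iat_dickhuth",
    "delta_metric",
    "ANCHORS",
    "IATRangeError",
]

#: kJ of heat released per litre O2 when oxidising pure carbohydrate / pure fat
_E_CHO_KJ_PER_L = 21.13
_E_FAT_KJ_PER_L = 19.62

WALK_VELOCITY_KMH = 4.0
TREADMILL_INCLINE = 0.015
WARMUP_S = 600.0
MAIN_S = 36 * 60.0
RECOVERY_S = 180.0
SESSION_S = WARMUP_S + MAIN_S + RECOVERY_S  # 49 min


@dataclass(frozen=True)
class Participant:
    """Anthropometric and fitness attributes of one runner."""

    id: str
    sex: str = "m"
    age: float = 25.0
    height: float = 175.0        # cm
    mass_pre: float = 70.0       # kg
    mass_post: float | None = None
    body_fat: float = 15.0       # %
    lean_mass: float = 55.0      # kg
    pa_r: float = 8.0            # physical activity rating 1-10
    viat: float = 12.2           # km/h, velocity at individual anaerobic threshold
    vo2max: float = 51.3         # mL/min/kg
    fev1: float = 100.0          # % predicted

    def __post_init__(self) -> None:
        if self.height <= 0 or self.mass_pre <= 0:
            raise ValueError("height and mass must be positive")
        if self.viat <= 0:
            raise ValueError("viat must be positive")

    @property
    def bsa(self) -> float:
        return bsa_mosteller(self.height, self.mass_pre)

    @property
    def bmi(self) -> float:
        return bmi(self.mass_pre, self.height)


@dataclass(frozen=True)
class Phase:
    """One constant-velocity treadmill stage."""

    name: str
    start: float          # s from session start (= warm-up onset)
    end: float
    pct_viat: float       # commanded load, % of vIAT
    velocity: float       # km/h
    mode: str             # WU | CON | INT | WALK

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class Protocol:
    """Load structure of one running session (T1/T2/T3)."""

    session_id: str
    phases: tuple[Phase, ...]
    incline: float = TREADMILL_INCLINE
    total_duration: float = SESSION_S

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("protocol must have at least one phase")
        t = 0.0
        for ph in self.phases:
            if abs(ph.start - t) > 1e-9:
                raise ValueError("phases must be contiguous and non-overlapping")
            t = ph.end
        if abs(t - self.total_duration) > 1e-9:
            raise ValueError("phases must tile [0, total_duration]")

    def phase_at(self, t: float) -> Phase:
        for ph in self.phases:
            if ph.start <= t < ph.end:
                return ph
        return self.phases[-1]

    def load_series(self, times: np.ndarray) -> np.ndarray:
        """Commanded %vIAT at each time (piecewise constant)."""
        times = np.asarray(times, dtype=float)
        out = np.empty_like(times)
        for ph in self.phases:
            sel = (times >= ph.start) & (times < ph.end)
            out[sel] = ph.pct_viat
        out[times >= self.phases[-1].end - 1e-12] = self.phases[-1].pct_viat
        return out

    def velocity_series(self, times: np.ndarray) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        out = np.empty_like(times)
        for ph in self.phases:
            sel = (times >= ph.start) & (times < ph.end)
            out[sel] = ph.velocity
        out[times >= self.phases[-1].end - 1e-12] = self.phases[-1].velocity
        return out


@dataclass(frozen=True)
class LactateStage:
    velocity: float       # km/h
    lactate: float        # mmol/L

    def __post_init__(self) -> None:
        if self.lactate <= 0:
            raise ValueError("lactate must be positive")


class IATRangeError(ValueError):
    """Lactate never reaches threshold within the tested velocity range."""


def _int_block(start: float, viat: float) -> list[Phase]:
    """Three 3-min 105% / 3-min 65% alternations (18 min total)."""
    phases = []
    t = start
    for rep in range(3):
        for pct in (105.0, 65.0):
            phases.append(Phase(f"INT{rep + 1}_{int(pct)}", t, t + 180.0, pct,
                                pct / 100.0 * viat, "INT"))
            t += 180.0
    return phases


def build_protocol(session_id: str, viat: float) -> Protocol:
    """Construct the T1/T2/T3 session load structure for a given vIAT.

    T1: WU + 36 min continuous at 85% vIAT + recovery walk.
    T2: WU + 18 min continuous (85%) + 18 min intermittent (3 x [3 min 105% +
    3 min 65%]) + recovery.  T3: same blocks as T2 in reverse order.  All
    sessions share the same 85% mean load over the main block.
    """
    if viat <= 0:
        raise ValueError("viat must be positive")
    wu = Phase("WU", 0.0, WARMUP_S, 60.0, 0.60 * viat, "WU")
    phases: list[Phase] = [wu]
    t = WARMUP_S
    if session_id == "T1":
        phases.append(Phase("CON", t, t + MAIN_S, 85.0, 0.85 * viat, "CON"))
        t += MAIN_S
    elif session_id == "T2":
        phases.append(Phase("CON", t, t + MAIN_S / 2, 85.0, 0.85 * viat, "CON"))
        t += MAIN_S / 2
        phases.extend(_int_block(t, viat))
        t += MAIN_S / 2
    elif session_id == "T3":
        phases.extend(_int_block(t, viat))
        t += MAIN_S / 2
        phases.append(Phase("CON", t, t + MAIN_S / 2, 85.0, 0.85 * viat, "CON"))
        t += MAIN_S / 2
    else:
        raise ValueError(f"unknown session_id {session_id!r} (expected T1, T2 or T3)")
    phases.append(Phase("REC", t, t + RECOVERY_S, WALK_VELOCITY_KMH / viat * 100.0,
                        WALK_VELOCITY_KMH, "WALK"))
    return Protocol(session_id, tuple(phases))


def bsa_mosteller(height_cm: float, mass_kg: float) -> float:
    """Body surface area [m^2] by Mosteller: sqrt(height_cm * mass_kg / 3600)."""
    if height_cm <= 0 or mass_kg <= 0:
        raise ValueError("height and mass must be positive")
    return float(np.sqrt(height_cm * mass_kg / 3600.0))


def bmi(mass_kg: float, height_cm: float) -> float:
    """Body mass index [kg/m^2]."""
    if height_cm <= 0 or mass_kg <= 0:
        raise ValueError("height and mass must be positive")
    return mass_kg / (height_cm / 100.0) ** 2


def metabolic_rate(vo2_l_min: float, rer: float = 0.85) -> float:
    """Metabolic rate [W] from VO2 [L/min] by partitional calorimetry.

    The energy equivalent of oxygen is interpolated between the fat
    (RER 0.7, 19.62 kJ/L) and carbohydrate (RER 1.0, 21.13 kJ/L) endpoints;
    RER outside [0.7, 1.0] (non-steady-state breaths) is clamped with a
    warning.
    """
    if vo2_l_min < 0:
        raise ValueError("vo2 must be non-negative")
    if not 0.7 <= rer <= 1.0:
        warnings.warn(f"RER {rer} outside [0.7, 1.0]; clamped", stacklevel=2)
        rer = min(max(rer, 0.7), 1.0)
    w = (rer - 0.7) / 0.3
    e_kj_per_l = w * _E_CHO_KJ_PER_L + (1.0 - w) * _E_FAT_KJ_PER_L
    return vo2_l_min / 60.0 * e_kj_per_l * 1000.0


def external_work_rate(mass_kg: float, velocity_kmh: float, grade: float = TREADMILL_INCLINE) -> float:
    """External work rate [W] on an inclined treadmill (vertical lifting power)."""
    return mass_kg * 9.81 * (velocity_kmh / 3.6) * grade


def mhp(metabolic_rate_w: float, external_work_w: float, bsa_m2: float) -> float:
    """Metabolic heat production rate [W/m^2]: (M - W_ext) / BSA."""
    if bsa_m2 <= 0:
        raise ValueError("bsa must be positive")
    return (metabolic_rate_w - external_work_w) / bsa_m2


def sweat_loss(mass_pre_kg: float, mass_post_kg: float) -> float:
    """Sweat loss [g] as pre-post body-mass difference; negative values flagged."""
    loss = (mass_pre_kg - mass_post_kg) * 1000.0
    if loss < 0:
        warnings.warn("negative sweat loss (mass gain); check scale readings", stacklevel=2)
    return loss


def core_skin_gradient(tcore: float, tnv: float) -> float:
    """Core-to-skin temperature gradient [degC]: T_CORE - T_NV."""
    return tcore - tnv


def iat_dickhuth(stages: list[LactateStage], threshold_delta: float = 1.5) -> float:
    """Individual anaerobic threshold velocity [km/h], Dickhuth's model.

    The lactate equivalent l(v) = lactate/velocity is minimised over stages
    (parabolic refinement through the three stages around the discrete
    minimum); the IAT is the velocity at which lactate exceeds the
    lactate-threshold value by ``threshold_delta`` mmol/L, located by
    piecewise-linear interpolation of the lactate-velocity curve above LT.
    """
    if len(stages) < 4:
        raise ValueError("need at least 4 lactate stages")
    v = np.array([s.velocity for s in stages], dtype=float)
    lac = np.array([s.lactate for s in stages], dtype=float)
    if np.any(np.diff(v) <= 0):
        raise ValueError("stage velocities must be strictly increasing")
    leq = lac / v
    i = int(np.argmin(leq))
    # parabolic refinement of the lactate-equivalent minimum
    if 0 < i < len(v) - 1:
        x0, x1, x2 = v[i - 1:i + 2]
        y0, y1, y2 = leq[i - 1:i + 2]
        denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
        a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
        b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
        v_lt = -b / (2 * a) if a > 0 else v[i]
        v_lt = float(np.clip(v_lt, x0, x2))
    else:
        v_lt = float(v[i])
    lac_lt = float(np.interp(v_lt, v, lac))
    target = lac_lt + threshold_delta
    # walk the curve above LT for the upward crossing
    vv = np.concatenate([[v_lt], v[v > v_lt]])
    ll = np.concatenate([[lac_lt], lac[v > v_lt]])
    for j in range(len(vv) - 1):
        if (ll[j] - target) * (ll[j + 1] - target) <= 0 and ll[j + 1] >= ll[j]:
            frac = (target - ll[j]) / (ll[j + 1] - ll[j])
            return float(vv[j] + frac * (vv[j + 1] - vv[j]))
    raise IATRangeError("IAT beyond test range: lactate never reaches LT + "
                        f"{threshold_delta} mmol/L")


#: canonical phase anchors for delta metrics (seconds from warm-up onset)
ANCHORS = {
    "Pre": 0.0,
    "WU-end": WARMUP_S,
    "FH-end": WARMUP_S + MAIN_S / 2,
    "SH-end": WARMUP_S + MAIN_S,
    "REC-end": SESSION_S,
}


def delta_metric(times: np.ndarray, values: np.ndarray,
                 anchor_a: str | float, anchor_b: str | float,
                 window: float = 5.0) -> float:
    """Delta of a series between two anchors (mean over the window seconds
    ending at each anchor), value(b) - value(a).

    Anchors may be named (``Pre``, ``WU-end``, ``FH-end``, ``SH-end``,
    ``REC-end``) or given in seconds.  The ``Pre`` anchor uses the first
    ``window`` seconds of the series instead of the preceding ones.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)

    def anchor_value(a: str | float) -> float:
        t = ANCHORS[a] if isinstance(a, str) else float(a)
        if t <= times[0] + window:
            sel = (times >= t) & (times <= t + window)
        else:
            sel = (times >= t - window) & (times <= t)
        if not np.any(sel & np.isfinite(values)):
            raise ValueError(f"no defined samples in the window at anchor {a!r}")
        return float(np.nanmean(values[sel]))

    return anchor_value(anchor_b) - anchor_value(anchor_a)
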