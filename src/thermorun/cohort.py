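"""Reference cohort: printed anthropometric and fitness characteristics of
the 11 endurance-trained runners (sex, age [y], height [cm], mass [kg],
body fat [%], lean mass [kg], PA-R [1-10], vIAT [km/h], VO2max [mL/min/kg]).

Used as the default participant pool for synthetic sessions and as the
worked-example input for BSA/BMI computations.
"""

from __future__ import annotations

import pandas as pd

from thermorun.physio import Participant

__all__ = ["reference_cohort", "cohort_frame", "PRINTED_SUMMARY"]

# id, sex, age, height_cm, mass_kg, body_fat_pct, lean_mass_kg, pa_r, viat_kmh, vo2max
_ROWS = [
    ("P1", "m", 25, 178, 76.3, 15.1, 60.8, 10, 16.5, 65.9),
    ("P2", "f", 27, 179, 68.4, 15.8, 53.9, 10, 13.3, 47.5),
    ("P3", "m", 27, 178, 67.6, 11.6, 56.0, 8, 12.2, 48.8),
    ("P4", "m", 29, 181, 83.6, 10.2, 66.6, 7, 12.2, 59.2),
    ("P5", "f", 22, 167, 57.1, 20.3, 42.5, 9, 12.5, 50.0),
    ("P6", "m", 22, 170, 70.4, 18.1, 54.0, 9, 13.3, 57.9),
    ("P7", "f", 23, 160, 60.5, 21.3, 44.5, 10, 10.7, 45.9),
    ("P8", "m", 23, 177, 72.6, 14.1, 58.4, 6, 11.2, 56.9),
    ("P9", "f", 26, 166, 58.9, 25.3, 41.1, 7, 9.9, 41.0),
    ("P10", "f", 24, 175, 65.2, 13.6, 52.8, 7, 10.4, 41.8),
    ("P11", "f", 24, 177, 72.2, 18.1, 54.7, 9, 12.5, 49.2),
]

#: published per-column BMI and BSA values (rounded as printed), plus the
#: printed cohort summary row (mean, sd) — used as worked-example expectations
PRINTED_BMI = [24.1, 21.3, 21.3, 24.1, 20.5, 24.3, 23.6, 23.1, 21.4, 21.3, 22.8]
PRINTED_BSA = [1.94, 1.84, 1.83, 2.05, 1.63, 1.82, 1.64, 1.89, 1.65, 1.78, 1.88]
PRINTED_SUMMARY = {
    "age": (24.7, 2.3),
    "height": (173.5, 6.7),
    "mass": (68.4, 7.9),
    "bmi": (22.5, 1.4),
    "body_fat": (16.7, 4.5),
    "lean_mass": (53.2, 7.8),
    "bsa": (1.8, 0.1),
    "pa_r": (8.4, 1.4),
    "viat": (12.2, 1.8),
    "vo2max": (51.3, 7.8),
}


def reference_cohort() -> list[Participant]:
    """The 11-runner reference cohort as Participant objects."""
    return [
        Participant(id=r[0], sex=r[1], age=r[2], height=r[3], mass_pre=r[4],
                    body_fat=r[5], lean_mass=r[6], pa_r=r[7], viat=r[8], vo2max=r[9])
        for r in _ROWS
    ]


def cohort_frame() -> pd.DataFrame:
    """Cohort as a DataFrame with derived BMI and BSA columns."""
    df = pd.DataFrame(_ROWS, columns=["id", "sex", "age", "height", "mass",
                                      "body_fat", "lean_mass", "pa_r", "viat", "vo2max"])
    df["bmi"] = df["mass"] / (df["height"] / 100.0) ** 2
    df["bsa"] = (df["height"] * df["mass"] / 3600.0) ** 0.5
    return df
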