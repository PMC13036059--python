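"""Stance-phase frame selection.

Running thermograms are only analysable when the leg is extended and still
(stance); swing frames suffer motion blur and occlusion.  The selector
partitions the frame timeline into windows of one gait cycle and keeps the
frame with the largest segmented calf in each window, then rejects windows
whose best area falls below a fraction of the running median of selected
areas (occlusions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["select_stance_frames", "selection_table"]


def select_stance_frames(areas: np.ndarray, fps: float,
                         step_frequency: float = 2.8,
                         min_area_fraction: float = 0.5,
                         median_window: int = 31) -> np.ndarray:
    """Indices of per-gait-cycle largest-calf frames.

    Windows have length round(fps / step_frequency) frames; within each the
    argmax of area is taken (ties toward the earlier frame).  A selection is
    dropped when its area is below ``min_area_fraction`` times the running
    median (window ``median_window``, truncated at edges) of the selected
    areas.  Requires ``step_frequency < fps / 2``.
    """
    areas = np.asarray(areas, dtype=float)
    if areas.size == 0:
        raise ValueError("empty area sequence")
    if not 0 < step_frequency < fps / 2:
        raise ValueError("step_frequency must be in (0, fps/2)")
    wlen = int(round(fps / step_frequency))
    if wlen < 1:
        raise ValueError("window length < 1 frame; lower step_frequency")
    if areas.size < wlen:
        raise ValueError("need at least one gait cycle of frames")

    n_windows = areas.size // wlen
    cand = np.array([w * wlen + int(np.argmax(areas[w * wlen:(w + 1) * wlen]))
                     for w in range(n_windows)])
    cand_areas = areas[cand]
    running_med = (pd.Series(cand_areas)
                   .rolling(median_window, center=True, min_periods=1)
                   .median().to_numpy())
    keep = cand_areas >= min_area_fraction * running_med
    return cand[keep]


def selection_table(areas: np.ndarray, timestamps: np.ndarray,
                    selected: np.ndarray) -> pd.DataFrame:
    """Per-frame table: frame_index, timestamp, area, selected flag."""
    sel = np.zeros(len(areas), dtype=int)
    sel[np.asarray(selected, dtype=int)] = 1
    return pd.DataFrame({"frame_index": np.arange(len(areas)),
                         "timestamp": np.asarray(timestamps, dtype=float),
                         "area": np.asarray(areas, dtype=float),
                         "selected": sel})
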