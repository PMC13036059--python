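"""Data model and I/O for calibrated radiometric frame sequences and label masks.

A sequence on disk is an open container: a multi-page 16-bit TIFF stack of
digital numbers plus a ``sequence.json`` sidecar holding the linear
calibration (T = offset + scale * DN), frame rate and per-frame timestamps.
Label masks travel as 8-bit multi-page PNG/TIFF stacks with the palette
{0 background, 1 non-vessel calf, 2 vein, 3 perforator}.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import tifffile
import imageio.v3 as iio

__all__ = [
    "CalibrationInfo",
    "RadiometricFrame",
    "FrameSequence",
    "apply_two_point_calibration",
    "read_sequence",
    "write_sequence",
    "read_masks",
    "write_masks",
    "SequenceError",
]

SIDECAR_NAME = "sequence.json"


class SequenceError(ValueError):
    """Malformed or missing on-disk frame sequence."""


@dataclass(frozen=True)
class CalibrationInfo:
    """Linear radiometric calibration T[degC] = offset + scale * DN.

    ``range_low``/``range_high`` is the camera measurement range; pixels
    outside it are retained (never clamped, clamping would bias entropy)
    but counted in each frame's ``out_of_range_fraction``.
    """

    emissivity: float = 0.98
    range_low: float = 25.0
    range_high: float = 35.0
    scale: float = 0.001
    offset: float = 15.0

    def __post_init__(self) -> None:
        if not 0.0 < self.emissivity <= 1.0:
            raise ValueError(f"emissivity must be in (0, 1], got {self.emissivity}")
        if not self.range_low < self.range_high:
            raise ValueError("range_low must be < range_high")
        if self.scale == 0:
            raise ValueError("calibration scale must be nonzero")


@dataclass
class RadiometricFrame:
    """One calibrated 2-D temperature field [degC] with acquisition metadata."""

    temperatures: np.ndarray
    timestamp: float
    frame_index: int = 0
    calibration: CalibrationInfo = field(default_factory=CalibrationInfo)

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if self.temperatures.ndim != 2:
            raise ValueError("temperatures must be a 2-D grid")
        if not np.all(np.isfinite(self.temperatures)):
            raise ValueError("temperatures must be finite")
        if self.timestamp < 0:
            raise ValueError("timestamp must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.temperatures.shape

    @property
    def out_of_range_fraction(self) -> float:
        """Fraction of pixels outside the calibrated measurement range."""
        t = self.temperatures
        cal = self.calibration
        bad = (t < cal.range_low) | (t > cal.range_high)
        return float(bad.mean())


@dataclass
class FrameSequence:
    """Ordered radiometric frames at a nominally uniform rate."""

    frames: list[RadiometricFrame]
    fps: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ts = self.timestamps
        if len(ts) > 1:
            dt = np.diff(ts)
            if np.any(dt <= 0):
                raise SequenceError("timestamps must be strictly increasing")
            if np.max(np.abs(dt - 1.0 / self.fps)) > 1e-6:
                raise SequenceError("timestamps must be uniformly spaced at 1/fps")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> RadiometricFrame:
        return self.frames[i]

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([f.timestamp for f in self.frames])


def apply_two_point_calibration(raw_dn: np.ndarray, cal: CalibrationInfo,
                                timestamp: float = 0.0, frame_index: int = 0) -> RadiometricFrame:
    """Map raw digital numbers to temperature, T = offset + scale * DN.

    Out-of-range pixels are retained; inspect ``out_of_range_fraction`` on
    the returned frame.
    """
    raw_dn = np.asarray(raw_dn)
    if np.any(raw_dn < 0):
        raise ValueError("raw digital numbers must be non-negative")
    temps = cal.offset + cal.scale * raw_dn.astype(float)
    return RadiometricFrame(temps, timestamp=timestamp, frame_index=frame_index, calibration=cal)


def _dn_from_temperature(temps: np.ndarray, cal: CalibrationInfo) -> np.ndarray:
    dn = np.rint((temps - cal.offset) / cal.scale)
    return np.clip(dn, 0, 65535).astype(np.uint16)


def write_sequence(seq: FrameSequence, path: str | os.PathLike) -> None:
    """Write a sequence as frames.tif (16-bit multi-page) + sequence.json sidecar."""
    os.makedirs(path, exist_ok=True)
    cal = seq.frames[0].calibration
    stack = np.stack([_dn_from_temperature(f.temperatures, cal) for f in seq.frames])
    tifffile.imwrite(os.path.join(path, "frames.tif"), stack)
    sidecar = {
        "n_frames": len(seq.frames),
        "fps": seq.fps,
        "timestamps": [f.timestamp for f in seq.frames],
        "calibration": asdict(cal),
        "metadata": seq.metadata,
    }
    with open(os.path.join(path, SIDECAR_NAME), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_sequence(path: str | os.PathLike) -> FrameSequence:
    """Read a TIFF stack + JSON sidecar written by :func:`write_sequence`."""
    tif_path = os.path.join(path, "frames.tif")
    sidecar_path = os.path.join(path, SIDECAR_NAME)
    if not os.path.exists(tif_path) or not os.path.exists(sidecar_path):
        raise SequenceError(f"no sequence found in {path!r}")
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    stack = tifffile.imread(tif_path)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[0] != sidecar["n_frames"]:
        raise SequenceError(
            f"sidecar lists {sidecar['n_frames']} frames but stack has {stack.shape[0]}")
    ts = sidecar["timestamps"]
    if len(ts) != stack.shape[0]:
        raise SequenceError("timestamp count does not match frame count")
    if np.any(np.diff(ts) <= 0):
        raise SequenceError("non-monotone timestamps in sidecar")
    cal = CalibrationInfo(**sidecar["calibration"])
    frames = [
        apply_two_point_calibration(stack[i], cal, timestamp=ts[i], frame_index=i)
        for i in range(stack.shape[0])
    ]
    return FrameSequence(frames, fps=sidecar["fps"], metadata=sidecar.get("metadata", {}))


def write_masks(masks: list[np.ndarray], path: str | os.PathLike) -> None:
    """Write label masks as an 8-bit multi-page TIFF stack (palette {0,1,2,3})."""
    os.makedirs(os.path.dirname(str(path)) or ".", exist_ok=True)
    stack = np.stack([np.asarray(m, dtype=np.uint8) for m in masks])
    if stack.max() > 3:
        raise ValueError("mask labels must be in {0,1,2,3}")
    str_path = str(path)
    if str_path.endswith(".png"):
        iio.imwrite(str_path, stack[0] if stack.shape[0] == 1 else stack)
    else:
        tifffile.imwrite(str_path, stack)


def read_masks(path: str | os.PathLike) -> list[np.ndarray]:
    str_path = str(path)
    if str_path.endswith(".png"):
        stack = np.asarray(iio.imread(str_path))
    else:
        stack = tifffile.imread(str_path)
    if stack.ndim == 2:
        stack = stack[None]
    return [stack[i].astype(np.uint8) for i in range(stack.shape[0])]
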