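"""Calf and vessel segmentation of radiometric frames.

The contract of this stage is frame -> 4-label mask {0 background,
1 non-vessel calf, 2 vein, 3 perforator}.  Two implementations are
shipped: a classical one (Otsu body threshold + morphology, multiscale
Hessian ridge enhancement, shape-based vein/perforator classification)
and an oracle passthrough for synthetic ground-truth masks, which
isolates downstream stages from segmentation error.  External mask
stacks can be injected to plug in any learned model honouring the same
contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology

from thermorun.thermio import RadiometricFrame

__all__ = [
    "SegmentationMask",
    "SegmentParams",
    "segment_body",
    "enhance_vessels",
    "vessel_candidates",
    "classify_vessels",
    "segment_frame",
    "oracle_segment",
    "NoCalfFoundError",
    "LABEL_BACKGROUND",
    "LABEL_CALF",
    "LABEL_VEIN",
    "LABEL_PERFORATOR",
]

LABEL_BACKGROUND = 0
LABEL_CALF = 1
LABEL_VEIN = 2
LABEL_PERFORATOR = 3


class NoCalfFoundError(ValueError):
    """No connected component passes the minimum body-area threshold."""


@dataclass
class SegmentationMask:
    """Per-pixel labels {0 background, 1 non-vessel calf, 2 vein, 3 perforator}."""

    labels: np.ndarray
    source: str = "classical"   # oracle | classical | external

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D grid")
        if not np.isin(np.unique(self.labels), [0, 1, 2, 3]).all():
            raise ValueError("labels must be a subset of {0,1,2,3}")

    @property
    def body(self) -> np.ndarray:
        """Whole-calf mask (non-vessel + vein + perforator)."""
        return self.labels > 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def region(self, which: str) -> np.ndarray:
        sel = {"mean": self.labels > 0,
               "nv": self.labels == LABEL_CALF,
               "v": self.labels == LABEL_VEIN,
               "p": self.labels == LABEL_PERFORATOR}
        return sel[which]


@dataclass
class SegmentParams:
    body_threshold_mode: str = "otsu"      # "otsu" or "fixed"
    fixed_threshold: float = 26.0          # degC, used when mode == "fixed"
    opening_radius: int = 2
    min_body_area: int = 200
    ridge_scales: tuple[float, ...] = (1.0, 1.5, 2.5)
    vessel_quantile: float = 0.78
    min_response: float = 0.3              # absolute floor on the normalised response
    elongation_threshold: float = 3.0
    perforator_area_range: tuple[int, int] = (6, 200)
    boundary_margin: int = 3               # px eroded off the body before vessel search

    def __post_init__(self) -> None:
        if not 0.0 < self.vessel_quantile < 1.0:
            raise ValueError("vessel_quantile must be in (0,1)")
        if self.elongation_threshold <= 1.0:
            raise ValueError("elongation_threshold must be > 1")


def segment_body(frame: RadiometricFrame, params: SegmentParams | None = None) -> np.ndarray:
    """Binary calf mask: threshold, opening, hole fill, keep <=2 largest components."""
    params = params or SegmentParams()
    t = frame.temperatures
    if params.body_threshold_mode == "otsu":
        if np.ptp(t) < 1e-9:
            raise NoCalfFoundError("no calf found: uniform image")
        thr = filters.threshold_otsu(t)
    elif params.body_threshold_mode == "fixed":
        thr = params.fixed_threshold
    else:
        raise ValueError(f"unknown body_threshold_mode {params.body_threshold_mode!r}")
    mask = t > thr
    if params.opening_radius > 0:
        mask = ndimage.binary_opening(mask, structure=morphology.disk(params.opening_radius))
    mask = ndimage.binary_fill_holes(mask)
    lab, n = ndimage.label(mask)
    if n == 0:
        raise NoCalfFoundError("no calf found: empty mask after morphology")
    areas = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    order = np.argsort(areas)[::-1]
    keep = [order[i] + 1 for i in range(min(2, n)) if areas[order[i]] >= params.min_body_area]
    if not keep:
        raise NoCalfFoundError(f"no calf found: largest component {int(areas.max())} px "
                               f"< min_body_area {params.min_body_area}")
    return np.isin(lab, keep)


def enhance_vessels(frame: RadiometricFrame, body_mask: np.ndarray,
                    params: SegmentParams | None = None) -> np.ndarray:
    """Ridge/blob response in [0,1] inside the body, 0 outside.

    Vessels are warm curvilinear or punctate structures a few pixels wide
    riding on the smooth calf background.  The background outside the body
    is first replaced by the median body temperature so the calf outline
    itself produces no spurious edge response; the response is then the
    pixelwise max of multiscale Hessian tubeness (Sato, bright ridges) and
    a white top-hat (bright structures smaller than the structuring disk),
    each max-normalised within the (slightly eroded) body interior.
    """
    params = params or SegmentParams()
    body_mask = np.asarray(body_mask, dtype=bool)
    if not body_mask.any():
        raise ValueError("empty body mask")
    t = frame.temperatures
    filled = np.where(body_mask, t, np.median(t[body_mask]))

    interior = ndimage.binary_erosion(body_mask, iterations=params.boundary_margin) \
        if params.boundary_margin > 0 else body_mask

    def _norm(resp: np.ndarray) -> np.ndarray:
        resp = np.where(interior, resp, 0.0)
        resp[resp < 0] = 0.0
        peak = resp.max()
        return resp / peak if peak > 1e-9 else np.zeros_like(resp)

    ridge = filters.sato(filled, sigmas=params.ridge_scales,
                         black_ridges=False, mode="reflect")
    radius = int(np.ceil(2.0 * max(params.ridge_scales))) + 1
    tophat = ndimage.white_tophat(filled, structure=morphology.disk(radius))
    return np.maximum(_norm(ridge), _norm(tophat))


def vessel_candidates(response: np.ndarray, body_mask: np.ndarray,
                      vessel_quantile: float, min_response: float = 0.3) -> np.ndarray:
    """Binary candidate-vessel mask: response above the within-body quantile
    (and above an absolute floor, so structure-poor frames do not promote
    background texture).

    Monotone in the quantile: lowering it never shrinks the candidate set.
    """
    body_mask = np.asarray(body_mask, dtype=bool)
    vals = response[body_mask]
    thr = max(np.quantile(vals, vessel_quantile), min_response)
    return (response > thr) & body_mask


def classify_vessels(response: np.ndarray, body_mask: np.ndarray,
                     params: SegmentParams | None = None) -> SegmentationMask:
    """Label candidate components as vein (elongated) or perforator (compact).

    Components with major/minor axis ratio >= elongation_threshold become
    veins; otherwise components whose area lies in perforator_area_range
    become perforators; the rest are merged back into non-vessel calf.
    """
    params = params or SegmentParams()
    body_mask = np.asarray(body_mask, dtype=bool)
    labels = np.where(body_mask, LABEL_CALF, LABEL_BACKGROUND).astype(np.uint8)
    cand = vessel_candidates(response, body_mask, params.vessel_quantile,
                             params.min_response)
    comp, n = ndimage.label(cand)
    lo, hi = params.perforator_area_range
    for rp in measure.regionprops(comp):
        minor = max(rp.axis_minor_length, 1.0)
        elongation = rp.axis_major_length / minor
        rows, cols = rp.coords[:, 0], rp.coords[:, 1]
        if elongation >= params.elongation_threshold:
            labels[rows, cols] = LABEL_VEIN
        elif lo <= rp.area <= hi:
            labels[rows, cols] = LABEL_PERFORATOR
        # else: stays non-vessel calf
    return SegmentationMask(labels, source="classical")


def segment_frame(frame: RadiometricFrame, params: SegmentParams | None = None) -> SegmentationMask:
    """Full classical pipeline: body -> ridge response -> vessel classes."""
    params = params or SegmentParams()
    body = segment_body(frame, params)
    resp = enhance_vessels(frame, body, params)
    return classify_vessels(resp, body, params)


def oracle_segment(truth: SegmentationMask | np.ndarray) -> SegmentationMask:
    """Passthrough of a ground-truth mask, tagged source='oracle'."""
    labels = truth.labels if isinstance(truth, SegmentationMask) else truth
    return SegmentationMask(np.array(labels, copy=True), source="oracle")


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient of two binary masks (1.0 when both empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
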