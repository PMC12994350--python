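"""Hot-spot geometry and tumor-stroma ratio computation.

The stroma hot-spot is a circle marked by a pathologist in physical slide
coordinates (default diameter 1.8 mm, the specimen-level field of view at
x100 magnification; at 0.455 um/pixel that is ~4000 pixels). TSR is the
stroma area as a percentage of tumor + stroma area inside the circle; every
other tissue type, plus lumen/background, is excluded from the denominator,
mirroring the visual scoring protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .classes import TissueClass
from .errors import OutOfBoundsError, ParameterError, UndefinedTSRError

STROMA_LOW = "stroma-low"
STROMA_HIGH = "stroma-high"


@dataclass(frozen=True)
class HotspotSpec:
    """A hot-spot circle in slide coordinates (millimetres)."""

    center_x_mm: float
    center_y_mm: float
    diameter_mm: float = 1.8

    def __post_init__(self):
        if self.diameter_mm <= 0:
            raise ParameterError("diameter_mm must be positive")


@dataclass(frozen=True)
class TsrResult:
    """Pixel bookkeeping and TSR for one hot-spot circle.

    ``excluded_px`` counts every in-circle pixel that is neither tumor nor
    intratumoral stroma (other tissue classes and background/lumen).
    """

    stroma_px: int
    tumor_px: int
    excluded_px: int
    tsr_percent: float
    label: str | None = None
    cutoff_used: float | None = None

    @property
    def circle_px(self) -> int:
        return self.stroma_px + self.tumor_px + self.excluded_px


def mm_to_px(length_mm: float, spacing_um: float) -> float:
    """Convert a physical length in mm to pixels at ``spacing_um`` µm/pixel."""
    if spacing_um <= 0:
        raise ParameterError("spacing_um must be positive")
    return length_mm * 1000.0 / spacing_um


def circle_mask(shape: tuple[int, int], center_px: tuple[float, float],
                diameter_px: float) -> np.ndarray:
    """Boolean in-circle mask using the pixel-center rule.

    Pixel (i, j) is inside iff its center (i+0.5, j+0.5) lies within
    ``diameter_px/2`` of ``center_px`` (y, x), boundary inclusive. Circles
    may clip the raster edge.
    """
    if diameter_px <= 0:
        raise ParameterError("diameter_px must be positive")
    h, w = shape
    cy, cx = center_px
    yy = np.arange(h) + 0.5
    xx = np.arange(w) + 0.5
    d2 = (yy[:, None] - cy) ** 2 + (xx[None, :] - cx) ** 2
    return d2 <= (diameter_px / 2.0) ** 2


def extract_hotspot(image: np.ndarray, spacing_um: float, spec: HotspotSpec):
    """Crop the bounding square of a hot-spot circle given in mm.

    Returns ``(crop, mask, (y0, x0))`` where ``crop`` is the (edge-clipped)
    bounding-square image crop, ``mask`` the in-circle mask on the crop, and
    ``(y0, x0)`` the crop origin in the source raster.
    """
    h, w = image.shape[:2]
    d_px = mm_to_px(spec.diameter_mm, spacing_um)
    cy = mm_to_px(spec.center_y_mm, spacing_um)
    cx = mm_to_px(spec.center_x_mm, spacing_um)
    r = d_px / 2.0
    if cy + r <= 0 or cx + r <= 0 or cy - r >= h or cx - r >= w:
        raise OutOfBoundsError("hot-spot circle lies entirely outside the raster")
    side = math.ceil(d_px)
    y0 = max(0, int(math.floor(cy - r)))
    x0 = max(0, int(math.floor(cx - r)))
    y1 = min(h, y0 + side)
    x1 = min(w, x0 + side)
    crop = image[y0:y1, x0:x1]
    mask = circle_mask(crop.shape[:2], (cy - y0, cx - x0), d_px)
    return crop, mask, (y0, x0)


def compute_tsr(labels: np.ndarray, circle: np.ndarray) -> TsrResult:
    """Compute the TSR inside a circle of a class-code raster.

    TSR = 100 x stroma / (tumor + stroma), counting pixels inside the
    circle; all other classes and background are tallied as excluded. A
    circle containing no tumor and no stroma raises ``UndefinedTSRError``
    (the hot-spot protocol requires tumor at the borders, so an empty
    denominator marks an invalid hot-spot rather than a ratio of 0 or 100).
    """
    labels = np.asarray(labels)
    circle = np.asarray(circle, bool)
    if labels.shape != circle.shape:
        raise ParameterError("labels and circle mask shapes disagree")
    if not circle.any():
        raise ParameterError("circle mask is empty")
    inside = labels[circle]
    stroma = int(np.count_nonzero(inside == TissueClass.STROMA))
    tumor = int(np.count_nonzero(inside == TissueClass.TUMOR))
    excluded = int(inside.size - stroma - tumor)
    if stroma + tumor == 0:
        raise UndefinedTSRError(
            "no tumor or stroma pixels inside the circle; TSR undefined")
    tsr = 100.0 * stroma / (stroma + tumor)
    return TsrResult(stroma_px=stroma, tumor_px=tumor, excluded_px=excluded,
                     tsr_percent=tsr)


def dichotomize(tsr_percent: float, cutoff: float) -> str:
    """Map a TSR percentage to 'stroma-low' (<= cutoff) or 'stroma-high'."""
    if not 0 < cutoff < 100:
        raise ParameterError("cutoff must lie strictly inside (0, 100)")
    if not 0 <= tsr_percent <= 100:
        raise ParameterError("tsr_percent must be in [0, 100]")
    return STROMA_LOW if tsr_percent <= cutoff else STROMA_HIGH


def dichotomize_array(values, cutoff: float) -> np.ndarray:
    """Vectorized :func:`dichotomize` returning an object array of labels."""
    if not 0 < cutoff < 100:
        raise ParameterError("cutoff must lie strictly inside (0, 100)")
    values = np.asarray(values, float)
    return np.where(values <= cutoff, STROMA_LOW, STROMA_HIGH)


def median_cutoff(tsr_values) -> float:
    """Sample median of TSR values, used as the data-driven cutoff.

    For even n this is the mean of the two middle order statistics; with the
    inclusive-low rule the resulting groups are balanced up to ties.
    """
    values = np.asarray(tsr_values, float)
    if values.size == 0:
        raise ParameterError("tsr_values must be non-empty")
    return float(np.median(values))


def attach_label(result: TsrResult, cutoff: float) -> TsrResult:
    """Return a copy of ``result`` with its dichotomized label filled in."""
    return TsrResult(result.stroma_px, result.tumor_px, result.excluded_px,
                     result.tsr_percent,
                     label=dichotomize(result.tsr_percent, cutoff),
                     cutoff_used=float(cutoff))
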