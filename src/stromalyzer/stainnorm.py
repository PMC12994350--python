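"""Stain normalization for H&E rasters.

Staining intensity varies between labs, batches and scanners; normalizing
color to a reference slide before classification removes most of that
variation. Two standard families are offered behind one interface:

* ``"reinhard"`` — channel statistics in the perceptual CIELAB space: tissue
  pixels are shifted/scaled so their per-channel mean and standard
  deviation match the reference's.
* ``"macenko"`` — stain-vector deconvolution: the two dominant stain
  directions (hematoxylin, eosin) are estimated from the optical-density
  cloud by SVD plus angular percentiles, concentrations are rescaled to the
  reference's robust maxima, and the image is recomposed with the
  reference's stain vectors.

Near-white background pixels (unstained glass, lumen) are left untouched by
both methods, so glass never acquires stain. A fitted normalizer is
serializable to JSON and is idempotent up to 8-bit quantization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from skimage import color as skcolor

from .errors import DegenerateReferenceError, ParameterError

#: pixels with luminance >= this fraction of full scale count as background
BACKGROUND_LUMINANCE = 0.9

METHODS = ("reinhard", "macenko")


def background_mask(image: np.ndarray) -> np.ndarray:
    """True where a pixel is near-white glass/lumen (luminance >= 90%)."""
    img = np.asarray(image, float) / 255.0
    lum = 0.2126 * img[..., 0] + 0.7152 * img[..., 1] + 0.0722 * img[..., 2]
    return lum >= BACKGROUND_LUMINANCE


def _tissue_pixels(image: np.ndarray) -> np.ndarray:
    tissue = ~background_mask(image)
    if not tissue.any():
        raise DegenerateReferenceError(
            "reference raster contains no tissue pixels (all near-white)")
    return tissue


# -- Reinhard: LAB channel statistics ---------------------------------------

def _lab_stats(image: np.ndarray, tissue: np.ndarray):
    lab = skcolor.rgb2lab(np.asarray(image, np.uint8))
    px = lab[tissue]
    return px.mean(axis=0), px.std(axis=0) + 1e-8


# -- Macenko: stain-vector estimation ---------------------------------------

_OD_FLOOR = 0.15  # optical-density threshold excluding near-transparent pixels


def _macenko_stains(image: np.ndarray, tissue: np.ndarray,
                    angle_pct: float = 1.0, conc_pct: float = 99.0):
    od = -np.log10(np.maximum(np.asarray(image, float), 1.0) / 255.0)
    pts = od[tissue]
    pts = pts[(pts > _OD_FLOOR).any(axis=1)]
    if pts.shape[0] < 10:
        raise DegenerateReferenceError("too few stained pixels to fit stains")
    _, _, vt = np.linalg.svd(pts - pts.mean(0), full_matrices=False)
    plane = vt[:2]  # the two dominant OD directions
    proj = pts @ plane.T
    ang = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(ang, [angle_pct, 100 - angle_pct])
    v1 = plane.T @ [np.cos(lo), np.sin(lo)]
    v2 = plane.T @ [np.cos(hi), np.sin(hi)]
    stains = np.stack([v1, v2])
    stains = np.abs(stains)
    stains /= np.linalg.norm(stains, axis=1, keepdims=True)
    # hematoxylin (blue-heavy) first, eosin second, for a stable order
    if stains[0, 2] < stains[1, 2]:
        stains = stains[::-1]
    conc = np.linalg.lstsq(stains.T, pts.T, rcond=None)[0]
    maxima = np.percentile(conc, conc_pct, axis=1)
    return stains, np.maximum(maxima, 1e-8)


@dataclass
class StainNormalizer:
    """A fitted stain normalizer (see module docstring for the methods)."""

    method_name: str
    reference_statistics: dict

    def apply(self, image: np.ndarray) -> np.ndarray:
        return apply_normalizer(self, image)

    def to_json(self) -> str:
        stats = {k: np.asarray(v).tolist()
                 for k, v in self.reference_statistics.items()}
        return json.dumps({"method": self.method_name, "statistics": stats})

    @classmethod
    def from_json(cls, text: str) -> "StainNormalizer":
        obj = json.loads(text)
        stats = {k: np.asarray(v) for k, v in obj["statistics"].items()}
        return cls(method_name=obj["method"], reference_statistics=stats)


def fit_normalizer(reference: np.ndarray, method: str = "macenko") -> StainNormalizer:
    """Fit a normalizer to a reference raster's color statistics."""
    if method not in METHODS:
        raise ParameterError(f"unknown stain-normalization method {method!r}; "
                             f"available: {METHODS}")
    tissue = _tissue_pixels(reference)
    if method == "reinhard":
        mean, std = _lab_stats(reference, tissue)
        stats = {"mean": mean, "std": std}
    else:
        stains, maxima = _macenko_stains(reference, tissue)
        stats = {"stains": stains, "maxima": maxima}
    return StainNormalizer(method_name=method, reference_statistics=stats)


def apply_normalizer(normalizer: StainNormalizer, image: np.ndarray) -> np.ndarray:
    """Map an RGB raster to the normalizer's reference color distribution.

    Background (near-white) pixels are passed through unchanged; output has
    the input's shape and dtype uint8.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ParameterError("expected an H×W×3 RGB raster")
    bg = background_mask(image)
    tissue = ~bg
    out = image.astype(np.uint8).copy()
    if not tissue.any():
        return out
    stats = normalizer.reference_statistics
    if normalizer.method_name == "reinhard":
        lab = skcolor.rgb2lab(image.astype(np.uint8))
        mean, std = lab[tissue].mean(0), lab[tissue].std(0) + 1e-8
        lab[tissue] = (lab[tissue] - mean) / std * stats["std"] + stats["mean"]
        rgb = np.clip(skcolor.lab2rgb(lab) * 255.0, 0, 255)
        out[tissue] = np.round(rgb[tissue]).astype(np.uint8)
    elif normalizer.method_name == "macenko":
        stains_src, maxima_src = _macenko_stains(image, tissue)
        od = -np.log10(np.maximum(image[tissue].astype(float), 1.0) / 255.0)
        conc = np.linalg.lstsq(stains_src.T, od.T, rcond=None)[0]
        residual = od - (stains_src.T @ conc).T  # color outside the stain plane
        conc *= (np.asarray(stats["maxima"]) / maxima_src)[:, None]
        od_new = (np.asarray(stats["stains"]).T @ conc).T + residual
        rgb = np.clip(255.0 * 10.0 ** (-od_new), 0, 255)
        out[tissue] = np.round(rgb).astype(np.uint8)
    else:  # pragma: no cover - method validated at fit time
        raise ParameterError(f"unknown method {normalizer.method_name!r}")
    return out
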