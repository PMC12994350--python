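"""Synthetic pseudo-histology fixtures.

Everything downstream — stain normalization, the patch classifier, hot-spot
geometry, agreement and survival statistics — is testable against data made
here, with known ground truth and no external downloads.

Three generators:

* :func:`generate_tile` — labelled RGB tiles where each tissue class is
  rendered by a fixed procedural texture recipe (base hue + noise field +
  structural elements). The recipes are *not* photorealistic; they are
  designed so a compact patch classifier can separate the nine classes.
* :func:`generate_hotspot_scene` — a square tile with an inscribed circular
  hot-spot filled with tumor + stroma (plus optional other tissue), whose
  true tumor-stroma ratio is known exactly from the emitted mask.
* :func:`simulate_cohort` — a patient cohort whose observer TSR scores are
  the true TSR plus rounding/noise, and whose right-censored survival times
  follow a proportional-hazards model in which the stroma-high group's
  hazard is multiplied by a configurable hazard ratio.

All generators are bit-reproducible given their parameters and seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .classes import CLASS_LEGEND, TissueClass, validate_class_codes
from .errors import InfeasibleSceneError, ParameterError, SizeError


@dataclass
class LabeledTile:
    """An RGB raster with a congruent class-code mask.

    ``image`` is H×W×3 uint8; ``mask`` is H×W uint8 of tissue class codes;
    ``spacing_um`` is the physical pixel size in µm/pixel.
    """

    image: np.ndarray
    mask: np.ndarray
    spacing_um: float
    seed: int
    provenance: str = ""

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ParameterError(
                f"image {self.image.shape[:2]} and mask {self.mask.shape} disagree"
            )
        validate_class_codes(np.unique(self.mask))


# ---------------------------------------------------------------------------
# Procedural textures
# ---------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, shape, sigma) -> np.ndarray:
    """Zero-mean unit-variance smoothed Gaussian noise field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    s = f.std()
    return f / s if s > 0 else f


def _paint(img, region, color, jitter, rng):
    base = np.asarray(color, float) + rng.uniform(-jitter, jitter, 3)
    img[region] = np.clip(base, 0, 255)


# Each recipe fills ``img[region]`` for one class. Shapes of the noise
# fields are drawn on the full tile so textures are stationary across
# region boundaries; only the region's pixels are written.
def _render_class(img: np.ndarray, region: np.ndarray, code: int,
                  rng: np.random.Generator) -> None:
    h, w = region.shape
    if not region.any():
        return
    if code == TissueClass.TUMOR:
        _paint(img, region, (125, 75, 160), 8, rng)
        nuclei = _smooth_field(rng, (h, w), 1.5) > 0.9
        img[region & nuclei] = (55, 25, 95)
    elif code == TissueClass.STROMA:
        _paint(img, region, (238, 185, 210), 8, rng)
        fibres = ndimage.gaussian_filter(rng.standard_normal((h, w)), (0.6, 9.0))
        fibres = fibres / (fibres.std() + 1e-9)
        dark = region & (fibres > 0.8)
        img[dark] = np.clip(img[dark].astype(float) - 45, 0, 255)
    elif code == TissueClass.NECROSIS:
        _paint(img, region, (205, 175, 175), 6, rng)
        speck = rng.random((h, w)) < 0.04
        img[region & speck] = (150, 120, 120)
    elif code == TissueClass.MUSCLE:
        _paint(img, region, (198, 105, 135), 8, rng)
        fibres = ndimage.gaussian_filter(rng.standard_normal((h, w)), (12.0, 1.0))
        fibres = fibres / (fibres.std() + 1e-9)
        img[region & (fibres > 0.6)] = (150, 55, 90)
    elif code == TissueClass.HEALTHY_EPITHELIUM:
        _paint(img, region, (185, 125, 185), 8, rng)
        rings = np.sin(6.0 * _smooth_field(rng, (h, w), 6.0))
        img[region & (np.abs(rings) < 0.25)] = (120, 60, 140)
    elif code == TissueClass.FAT:
        # pale, but kept under the background threshold so fat is not masked
        _paint(img, region, (222, 212, 219), 3, rng)
        membranes = np.abs(_smooth_field(rng, (h, w), 5.0)) < 0.12
        img[region & membranes] = (180, 172, 182)
    elif code == TissueClass.MUCUS:
        _paint(img, region, (198, 214, 232), 4, rng)
        wisp = _smooth_field(rng, (h, w), 8.0) > 1.0
        img[region & wisp] = (178, 198, 224)
    elif code == TissueClass.LYMPHOCYTES:
        _paint(img, region, (185, 185, 220), 6, rng)
        dots = _smooth_field(rng, (h, w), 1.0) > 0.55
        img[region & dots] = (45, 45, 125)
    elif code == TissueClass.BLOOD:
        _paint(img, region, (198, 45, 55), 8, rng)
        cells = _smooth_field(rng, (h, w), 1.2) > 0.8
        img[region & cells] = (160, 20, 35)
    elif code == TissueClass.BACKGROUND:
        img[region] = (248, 248, 250)
    # small stationary shot noise over everything in the region
    noise = rng.normal(0, 3.0, (h, w, 3))
    sel = region
    img[sel] = np.clip(img[sel].astype(float) + noise[sel], 0, 255)


def render_mask(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Render an RGB image from a class-code mask using the texture recipes."""
    img = np.zeros(mask.shape + (3,), float)
    for code in np.unique(mask):
        _render_class(img, mask == code, int(code), rng)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Tile generation
# ---------------------------------------------------------------------------

def _voronoi_partition(codes, size_px, rng, min_fraction=0.02,
                       points_per_class=2, max_tries=50):
    """Partition the raster into contiguous nearest-seed cells per class.

    Retries the seed-point draw until every class holds at least
    ``min_fraction`` of the raster; falls back to equal-width stripes.
    """
    n = len(codes)
    if n == 1:
        return np.full((size_px, size_px), codes[0], np.uint8)
    yy, xx = np.mgrid[0:size_px, 0:size_px]
    for _ in range(max_tries):
        pts = rng.uniform(0, size_px, (n * points_per_class, 2))
        owner = np.repeat(np.asarray(codes, np.uint8), points_per_class)
        d = (yy[..., None] - pts[:, 0]) ** 2 + (xx[..., None] - pts[:, 1]) ** 2
        mask = owner[np.argmin(d, axis=-1)]
        counts = np.bincount(mask.ravel(), minlength=10)
        if all(counts[c] >= min_fraction * size_px ** 2 for c in codes):
            return mask
    # deterministic fallback: horizontal stripes of equal height
    stripe = np.linspace(0, n, size_px, endpoint=False).astype(int)
    return np.asarray(codes, np.uint8)[stripe][:, None].repeat(size_px, 1)


def generate_tile(class_list, size_px: int, spacing_um: float,
                  seed: int) -> LabeledTile:
    """Generate a labelled tile covering the requested tissue classes.

    The mask partitions the raster into contiguous regions (one or more per
    class, each at least 2% of the raster); the image renders each class
    with its procedural texture. Same arguments → bit-identical output.
    """
    codes = sorted(int(c) for c in class_list)
    if not codes:
        raise ParameterError("class_list must be non-empty")
    validate_class_codes(codes)
    if size_px < 64:
        raise SizeError(f"size_px must be >= 64, got {size_px}")
    if spacing_um <= 0:
        raise ParameterError("spacing_um must be positive")
    rng = np.random.default_rng(seed)
    mask = _voronoi_partition(codes, size_px, rng)
    image = render_mask(mask, rng)
    return LabeledTile(image=image, mask=mask, spacing_um=float(spacing_um),
                       seed=int(seed),
                       provenance=f"generate_tile(classes={codes}, size={size_px})")


# ---------------------------------------------------------------------------
# Hot-spot scenes
# ---------------------------------------------------------------------------

#: classes used to fill the "other tissue" share of a hot-spot scene
_OTHER_FILL = (TissueClass.MUSCLE, TissueClass.NECROSIS, TissueClass.MUCUS,
               TissueClass.BACKGROUND)


def generate_hotspot_scene(target_tsr: float, diameter_px: int,
                           other_tissue_fraction: float, seed: int):
    """Build a circular hot-spot scene with a known tumor-stroma ratio.

    Returns ``(tile, true_tsr)`` where ``true_tsr`` is recomputed from the
    emitted mask restricted to the inscribed circle (stroma as a percentage
    of tumor + stroma). By construction it is within 2 percentage points of
    ``target_tsr`` (typically well under 0.1).
    """
    if not 0 <= target_tsr <= 100:
        raise ParameterError("target_tsr must be in [0, 100]")
    if not 0 <= other_tissue_fraction <= 0.5:
        raise ParameterError("other_tissue_fraction must be in [0, 0.5]")
    if diameter_px < 64:
        raise SizeError("diameter_px must be >= 64")
    from .hotspot import circle_mask  # local import keeps modules acyclic

    rng = np.random.default_rng(seed)
    size = int(diameter_px)
    circle = circle_mask((size, size), (size / 2, size / 2), float(diameter_px))
    mask = np.full((size, size), int(TissueClass.BACKGROUND), np.uint8)

    inside = np.flatnonzero(circle.ravel())
    n_in = inside.size
    # region scale tracks the scene size: tumor/stroma territories in a
    # hot-spot are large contiguous areas, not pixel-level salt
    other_sigma = max(12.0, size / 5.0)
    ts_sigma = max(9.0, size / 5.0)
    other_field = _smooth_field(rng, (size, size), other_sigma).ravel()[inside]
    n_other = int(round(other_tissue_fraction * n_in))
    order = np.argsort(other_field, kind="stable")
    other_idx = inside[order[:n_other]]
    ts_idx = inside[order[n_other:]]
    if ts_idx.size == 0:
        raise InfeasibleSceneError(
            "no tumor+stroma pixels remain inside the circle")

    # split the "other" share among a few classes by value bands
    if n_other:
        bands = np.array_split(np.arange(n_other), len(_OTHER_FILL))
        for band, cls in zip(bands, _OTHER_FILL):
            mask.ravel()[other_idx[band]] = int(cls)

    # split tumor/stroma on a smooth field at the exact quantile
    ts_field = _smooth_field(rng, (size, size), ts_sigma).ravel()[ts_idx]
    n_stroma = int(round(target_tsr / 100.0 * ts_idx.size))
    ts_order = np.argsort(ts_field, kind="stable")
    mask.ravel()[ts_idx[ts_order[:n_stroma]]] = int(TissueClass.STROMA)
    mask.ravel()[ts_idx[ts_order[n_stroma:]]] = int(TissueClass.TUMOR)

    image = render_mask(mask, rng)
    tile = LabeledTile(image=image, mask=mask, spacing_um=0.455, seed=int(seed),
                       provenance=f"generate_hotspot_scene(target={target_tsr})")
    stroma_px = int(np.count_nonzero(mask[circle] == TissueClass.STROMA))
    tumor_px = int(np.count_nonzero(mask[circle] == TissueClass.TUMOR))
    true_tsr = 100.0 * stroma_px / (stroma_px + tumor_px)
    return tile, true_tsr


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohortParams:
    """Parameters of the simulated patient cohort.

    Observer scores are the true TSR plus independent Gaussian noise,
    rounded to ``visual_rounding_increment`` (visual scoring is done in 10%
    steps); the automated score adds small unrounded noise. Survival times
    are exponential with the stroma-high group's hazard multiplied by
    ``hr_stroma_high``; censoring is independent exponential plus an
    administrative cap at ``max_followup_years``.
    """

    n_patients: int = 129
    true_tsr_distribution: dict = field(
        default_factory=lambda: {"kind": "normal", "mean": 55.0, "sd": 20.0})
    observer_noise_sd: float = 10.0
    auto_noise_sd: float = 2.0
    visual_rounding_increment: float = 10.0
    cutoff: float = 50.0
    hr_stroma_high: float = 2.5
    baseline_hazard: float = 0.06
    baseline_hazard_dfs: float = 0.09
    censoring_rate: float = 0.05
    max_followup_years: float = 12.0
    seed: int = 0

    def validate(self):
        if self.n_patients < 1:
            raise ParameterError("n_patients must be >= 1")
        if self.hr_stroma_high <= 0:
            raise ParameterError("hr_stroma_high must be > 0")
        for name in ("baseline_hazard", "baseline_hazard_dfs",
                     "censoring_rate", "observer_noise_sd", "auto_noise_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not 0 < self.cutoff < 100:
            raise ParameterError("cutoff must be in (0, 100)")
        if self.visual_rounding_increment <= 0:
            raise ParameterError("visual_rounding_increment must be > 0")


# Marginal frequencies of the clinicopathological covariates emulated by the
# cohort generator (129-patient rectal-cancer cohort structure).
_COVARIATE_FREQS = {
    "gender": (["female", "male"], [43, 86]),
    "pT": ([1, 2, 3, 4], [4, 40, 79, 6]),
    "pN": ([0, 1, 2], [78, 33, 18]),
    "stage": (["I", "II", "III"], [33, 45, 51]),
    "grade": (["well", "moderate", "poor"], [3, 112, 14]),
    "adjuvant": (["none", "radiotherapy", "chemoradiotherapy"], [86, 43, 5]),
}


def _draw_true_tsr(spec: dict, n: int, rng) -> np.ndarray:
    kind = spec.get("kind", "normal")
    if kind == "normal":
        x = rng.normal(spec.get("mean", 55.0), spec.get("sd", 20.0), n)
    elif kind == "uniform":
        x = rng.uniform(spec.get("low", 0.0), spec.get("high", 100.0), n)
    else:
        raise ParameterError(f"unknown TSR distribution kind: {kind!r}")
    return np.clip(x, 0.0, 100.0)


def _round_to(x, inc):
    return np.clip(np.round(x / inc) * inc, 0.0, 100.0)


def _exp_times(rng, rate, n):
    if rate <= 0:
        return np.full(n, np.inf)
    return rng.exponential(1.0 / rate, n)


def simulate_cohort(params: SyntheticCohortParams) -> pd.DataFrame:
    """Simulate a cohort table with observer scores and survival outcomes.

    Returns one row per patient with clinicopathological covariates, a
    hidden true TSR, two rounded visual scores, an unrounded automated
    score, dichotomized labels, and right-censored disease-specific (DSS)
    and disease-free (DFS) times. Same params → identical table.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_patients

    true_tsr = _draw_true_tsr(params.true_tsr_distribution, n, rng)
    v1 = _round_to(true_tsr + rng.normal(0, params.observer_noise_sd, n),
                   params.visual_rounding_increment)
    v2 = _round_to(true_tsr + rng.normal(0, params.observer_noise_sd, n),
                   params.visual_rounding_increment)
    auto = np.clip(true_tsr + rng.normal(0, params.auto_noise_sd, n), 0, 100)

    high = true_tsr > params.cutoff
    haz_dss = params.baseline_hazard * np.where(high, params.hr_stroma_high, 1.0)
    haz_dfs = params.baseline_hazard_dfs * np.where(high, params.hr_stroma_high, 1.0)

    t_dss = rng.exponential(1.0, n) / np.maximum(haz_dss, 1e-300)
    t_dfs = rng.exponential(1.0, n) / np.maximum(haz_dfs, 1e-300)
    censor = np.minimum(_exp_times(rng, params.censoring_rate, n),
                        params.max_followup_years)

    dss_years = np.minimum(t_dss, censor)
    dss_event = (t_dss <= censor).astype(int)
    # recurrence cannot be observed past the end of disease-specific follow-up
    dfs_years = np.minimum(t_dfs, dss_years)
    dfs_event = (t_dfs <= dss_years).astype(int)

    cov = {}
    for name, (levels, weights) in _COVARIATE_FREQS.items():
        p = np.asarray(weights, float) / np.sum(weights)
        cov[name] = rng.choice(levels, size=n, p=p)

    from .hotspot import dichotomize_array, median_cutoff

    consensus = (v1 + v2) / 2.0
    med = median_cutoff(auto)
    df = pd.DataFrame({
        "patient_id": np.arange(1, n + 1),
        "age": np.clip(np.round(rng.normal(67, 10, n), 1), 35, 95),
        **cov,
        "true_tsr": np.round(true_tsr, 3),
        "tsr_visual_1": v1,
        "tsr_visual_2": v2,
        "tsr_auto": np.round(auto, 3),
        "true_label": dichotomize_array(true_tsr, params.cutoff),
        "consensus_label": dichotomize_array(consensus, params.cutoff),
        "auto_label_50": dichotomize_array(auto, 50.0),
        "auto_label_median": dichotomize_array(auto, med),
        "dss_years": np.round(dss_years, 4),
        "dss_event": dss_event,
        "dfs_years": np.round(dfs_years, 4),
        "dfs_event": dfs_event,
    })
    return df


def simulate_projected_cohort(n_projected: int = 154,
                              n_mucinous: int = 12,
                              n_unavailable: int = 12,
                              n_no_invasive: int = 1,
                              params: SyntheticCohortParams | None = None,
                              seed: int = 0) -> pd.DataFrame:
    """Simulate the *projected* cohort before eligibility screening.

    Adds an ``excluded_reason`` column: mucinous carcinoma, missing slide or
    data, or no invasive carcinoma on the slide; all other rows are
    ``none``. :func:`filter_eligible` removes the flagged rows.
    """
    total_excl = n_mucinous + n_unavailable + n_no_invasive
    if total_excl > n_projected:
        raise ParameterError("more exclusions than projected cases")
    p = params or SyntheticCohortParams(seed=seed)
    p = dataclasses.replace(p, n_patients=n_projected, seed=seed)
    df = simulate_cohort(p)
    rng = np.random.default_rng(seed + 1)
    reasons = np.array(["none"] * n_projected, dtype=object)
    flagged = rng.choice(n_projected, size=total_excl, replace=False)
    reasons[flagged[:n_mucinous]] = "mucinous"
    reasons[flagged[n_mucinous:n_mucinous + n_unavailable]] = "slide_unavailable"
    reasons[flagged[n_mucinous + n_unavailable:]] = "no_invasive_carcinoma"
    df["excluded_reason"] = reasons
    return df


def filter_eligible(cohort: pd.DataFrame) -> pd.DataFrame:
    """Drop patients flagged for exclusion (mucinous tumors, missing slides
    or data, slides without invasive carcinoma)."""
    if "excluded_reason" not in cohort.columns:
        return cohort
    return cohort[cohort["excluded_reason"] == "none"].drop(
        columns="excluded_reason").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Tile / cohort I/O
# ---------------------------------------------------------------------------

def write_tile(tile: LabeledTile, prefix: str | Path) -> None:
    """Write ``<prefix>.png`` (image), ``<prefix>_mask.png`` (class codes)
    and ``<prefix>.json`` (spacing, seed, legend)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(tile.image).save(prefix.with_suffix(".png"))
    Image.fromarray(tile.mask, mode="L").save(
        prefix.parent / f"{prefix.name}_mask.png")
    meta = {"spacing_um": tile.spacing_um, "seed": tile.seed,
            "provenance": tile.provenance, "class_legend": CLASS_LEGEND}
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_tile(prefix: str | Path) -> LabeledTile:
    prefix = Path(prefix)
    image = np.asarray(Image.open(prefix.with_suffix(".png")).convert("RGB"))
    mask = np.asarray(Image.open(prefix.parent / f"{prefix.name}_mask.png"))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return LabeledTile(image=image, mask=mask.astype(np.uint8),
                       spacing_um=float(meta["spacing_um"]),
                       seed=int(meta["seed"]),
                       provenance=meta.get("provenance", ""))
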