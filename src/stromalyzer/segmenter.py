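"""Patch-based multi-class tissue segmentation.

An H&E raster is segmented into the nine tissue classes by classifying
256×256-pixel patches and painting each patch's predicted class onto its
central 16×16 block (sliding with stride 16), which yields a dense map
with smooth block-level boundaries. Pixels flagged by the tissue/background mask
(near-white glass or lumen) are forced to the background code regardless of
the classifier's output, since background is not a prediction target.

The classifier itself is a compact multilayer perceptron over engineered
per-patch color and texture statistics (channel moments, dark/white pixel
fractions, gradient energy, orientation anisotropy). Training supports
per-class balanced sampling, a held-out split with a per-epoch training
curve, and slide-level k-fold cross-validation that never lets a slide
contribute to both training and evaluation of the same fold.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field

import joblib
import numpy as np
from scipy import ndimage
from sklearn.neural_network import MLPClassifier

from .classes import CLASS_LEGEND, TISSUE_CLASSES, TissueClass
from .errors import (EmptyEvaluationError, FoldError, MissingClassError,
                     ParameterError)
from .fixtures import LabeledTile

PATCH_SIZE = 256
BLOCK = 16  # central block painted during dense inference
#: after stain normalization a pixel with min channel >= this is background
BACKGROUND_MIN_CHANNEL = 220


@dataclass
class SegmentationMap:
    """Dense class-code raster with physical pixel spacing."""

    labels: np.ndarray
    spacing_um: float
    class_legend: dict = field(default_factory=lambda: dict(CLASS_LEGEND))

    def __post_init__(self):
        if self.spacing_um <= 0:
            raise ParameterError("spacing_um must be positive")


@dataclass
class TrainConfig:
    """Training hyperparameters for the patch classifier."""

    epochs: int = 30
    learning_rate: float = 0.01
    hidden_layers: tuple = (64, 32)
    batch_size: int = 128
    stride: int = 64
    purity_threshold: float = 0.9
    val_fraction: float = 0.2
    max_patches_per_class: int = 2000

    def validate(self):
        if self.epochs < 1 or self.learning_rate <= 0:
            raise ParameterError("epochs >= 1 and learning_rate > 0 required")
        if not 0 < self.purity_threshold <= 1:
            raise ParameterError("purity_threshold must be in (0, 1]")


# ---------------------------------------------------------------------------
# Patch features
# ---------------------------------------------------------------------------

def patch_features(patch: np.ndarray) -> np.ndarray:
    """Color/texture feature vector of one RGB patch.

    Statistics are computed over the patch's central block — the same
    region the patch's training label describes — so mixed surroundings do
    not dilute the signal.
    """
    h, w = patch.shape[:2]
    if h > BLOCK and w > BLOCK:
        y0, x0 = (h - BLOCK) // 2, (w - BLOCK) // 2
        patch = patch[y0:y0 + BLOCK, x0:x0 + BLOCK]
    p = patch[::2, ::2].astype(float)  # 2x decimation; statistics survive
    flat = p.reshape(-1, 3)
    mean = flat.mean(0)
    std = flat.std(0)
    med = np.median(flat, axis=0)
    mn = flat.min(1)
    dark_frac = float((mn < 100).mean())
    white_frac = float((mn >= BACKGROUND_MIN_CHANNEL).mean())
    lum = p @ np.array([0.2126, 0.7152, 0.0722])
    gy, gx = np.gradient(lum)
    grad = np.hypot(gy, gx)
    aniso = float(np.abs(gy).mean() - np.abs(gx).mean())
    rb = float((flat[:, 0] - flat[:, 2]).mean())
    rg = float((flat[:, 0] - flat[:, 1]).mean())
    return np.concatenate([mean, std, med,
                           [dark_frac, white_frac, grad.mean(), grad.std(),
                            aniso, rb, rg]])


N_FEATURES = 16


# ---------------------------------------------------------------------------
# Patch extraction
# ---------------------------------------------------------------------------

def extract_patches(tile: LabeledTile, patch_size: int = PATCH_SIZE,
                    stride: int = 64, purity_threshold: float = 0.9):
    """Slide a patch grid over a labelled tile and emit pure patches.

    A patch is kept when the majority class of its central block region
    covers at least ``purity_threshold`` of that region; the patch is
    labelled with that class. Grid positions use 0-based, half-open
    indexing; a tile smaller than the patch yields an empty list.
    """
    if stride < 1:
        raise ParameterError("stride must be >= 1")
    if not 0 < purity_threshold <= 1:
        raise ParameterError("purity_threshold must be in (0, 1]")
    h, w = tile.mask.shape
    out = []
    if h < patch_size or w < patch_size:
        return out
    off = (patch_size - BLOCK) // 2
    for y in range(0, h - patch_size + 1, stride):
        for x in range(0, w - patch_size + 1, stride):
            centre = tile.mask[y + off:y + off + BLOCK, x + off:x + off + BLOCK]
            counts = np.bincount(centre.ravel(), minlength=10)
            label = int(counts.argmax())
            if counts[label] / centre.size < purity_threshold:
                continue
            if label == TissueClass.BACKGROUND:
                continue
            out.append((tile.image[y:y + patch_size, x:x + patch_size], label))
    return out


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class SegmenterModel:
    """A fitted patch classifier plus everything needed to reapply it."""

    mlp: MLPClassifier
    feature_mean: np.ndarray
    feature_std: np.ndarray
    class_codes: tuple
    config: TrainConfig
    seed: int
    history: list = field(default_factory=list)  # per-epoch (loss, val_acc)
    patch_size: int = PATCH_SIZE

    @property
    def fingerprint(self) -> str:
        buf = io.BytesIO()
        for w in self.mlp.coefs_ + self.mlp.intercepts_:
            buf.write(np.ascontiguousarray(w).tobytes())
        return hashlib.sha256(buf.getvalue()).hexdigest()[:16]

    def predict_features(self, feats: np.ndarray) -> np.ndarray:
        return self.mlp.predict(_standardize(feats, self.feature_mean,
                                             self.feature_std))


def save_model(model: SegmenterModel, path) -> None:
    joblib.dump({"model": model, "class_legend": CLASS_LEGEND}, path)


def load_model(path) -> SegmenterModel:
    return joblib.load(path)["model"]


def _standardize(feats, mean, std):
    # the std floor and z-clip keep features that are near-constant in
    # training (e.g. white fraction) from exploding on unseen mixed blocks
    z = (feats - mean) / np.maximum(std, 1e-2)
    return np.clip(z, -8.0, 8.0)


def _collect_training_set(tiles, config: TrainConfig, rng):
    feats, labels = [], []
    for tile in tiles:
        for patch, label in extract_patches(tile, stride=config.stride,
                                            purity_threshold=config.purity_threshold):
            feats.append(patch_features(patch))
            labels.append(label)
    feats = np.asarray(feats)
    labels = np.asarray(labels)
    present = set(labels.tolist())
    missing = [CLASS_LEGEND[int(c)] for c in TISSUE_CLASSES
               if int(c) not in present]
    if missing:
        raise MissingClassError(
            f"training data lacks class(es): {', '.join(missing)}")
    # balanced per-class subsampling prevents majority-class collapse
    keep = []
    for c in sorted(present):
        idx = np.flatnonzero(labels == c)
        n = min(idx.size, config.max_patches_per_class)
        keep.append(rng.choice(idx, size=n, replace=False))
    keep = np.concatenate(keep)
    return feats[keep], labels[keep]


def train_segmenter(training_tiles, config: TrainConfig | None = None,
                    seed: int = 0) -> SegmenterModel:
    """Train the patch classifier on labelled tiles.

    All nine tissue classes must be present. Training runs a fixed number
    of epochs over shuffled minibatches, recording per-epoch training loss
    and held-out accuracy; with a fixed seed the result is reproducible.
    """
    config = config or TrainConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    feats, labels = _collect_training_set(training_tiles, config, rng)

    n = feats.shape[0]
    perm = rng.permutation(n)
    n_val = max(1, int(round(config.val_fraction * n)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    mean = feats[tr_idx].mean(0)
    std = feats[tr_idx].std(0)
    z = _standardize(feats, mean, std)

    mlp = MLPClassifier(hidden_layer_sizes=config.hidden_layers,
                        learning_rate_init=config.learning_rate,
                        batch_size=min(config.batch_size, tr_idx.size),
                        random_state=int(rng.integers(2 ** 31)),
                        max_iter=1, warm_start=False)
    classes = np.array(sorted(int(c) for c in TISSUE_CLASSES))
    history = []
    for _ in range(config.epochs):
        order = rng.permutation(tr_idx)
        mlp.partial_fit(z[order], labels[order], classes=classes)
        val_acc = float((mlp.predict(z[val_idx]) == labels[val_idx]).mean())
        history.append({"loss": float(mlp.loss_), "val_accuracy": val_acc})

    return SegmenterModel(mlp=mlp, feature_mean=mean, feature_std=std,
                          class_codes=tuple(classes.tolist()), config=config,
                          seed=int(seed), history=history)


# ---------------------------------------------------------------------------
# Dense inference
# ---------------------------------------------------------------------------

def tissue_background_mask(image: np.ndarray) -> np.ndarray:
    """Background rule for dense maps: min channel >= 220, majority-cleaned."""
    bg = np.asarray(image).min(axis=2) >= BACKGROUND_MIN_CHANNEL
    # 3x3 median filter = majority vote on a boolean raster
    return ndimage.median_filter(bg.astype(np.uint8), size=3).astype(bool)


def segment_raster(model: SegmenterModel, image: np.ndarray,
                   spacing_um: float) -> SegmentationMap:
    """Produce a dense 9-class + background map the same size as the input.

    The patch classifier slides with stride 16; each patch's class is
    painted on its central 16×16 block. Inputs smaller than a patch are
    reflectively padded. Background-masked pixels are forced to the
    background code.
    """
    if spacing_um <= 0:
        raise ParameterError("spacing_um must be positive")
    image = np.asarray(image)
    h, w = image.shape[:2]
    margin = (model.patch_size - BLOCK) // 2
    nby, nbx = -(-h // BLOCK), -(-w // BLOCK)
    pad_b = margin + nby * BLOCK - h
    pad_r = margin + nbx * BLOCK - w
    mode = ("reflect" if min(h, w) > max(margin, pad_b, pad_r) else "edge")
    padded = np.pad(image, ((margin, pad_b), (margin, pad_r), (0, 0)), mode=mode)

    feats = np.empty((nby * nbx, N_FEATURES))
    k = 0
    for by in range(nby):
        for bx in range(nbx):
            y, x = by * BLOCK, bx * BLOCK
            feats[k] = patch_features(
                padded[y:y + model.patch_size, x:x + model.patch_size])
            k += 1
    pred = model.predict_features(feats).reshape(nby, nbx)
    labels = np.kron(pred, np.ones((BLOCK, BLOCK), np.uint8))[:h, :w]
    labels = labels.astype(np.uint8)
    labels[tissue_background_mask(image)] = int(TissueClass.BACKGROUND)
    return SegmentationMap(labels=labels, spacing_um=float(spacing_um))


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class SegMetrics:
    """Pixel-wise one-vs-rest metrics over an evaluation region.

    ``confusion`` has one row per tissue class (truth) and one column per
    tissue class plus a final predicted-background column: a pixel the map
    coded background inside an annotated tissue region is a miss for its
    true class but a false positive for none.
    """

    confusion: np.ndarray  # 9 x 10, rows = truth, cols = predicted (+bg)
    per_class_sensitivity: dict
    per_class_specificity: dict
    overall_accuracy: float


def metrics_from_confusion(confusion: np.ndarray) -> SegMetrics:
    k = len(TISSUE_CLASSES)
    confusion = np.asarray(confusion)
    if confusion.shape[1] == k:  # accept a plain 9x9 table too
        confusion = np.hstack([confusion, np.zeros((k, 1), confusion.dtype)])
    total = confusion.sum()
    if total == 0:
        raise EmptyEvaluationError("confusion table is empty")
    sens, spec = {}, {}
    for i, c in enumerate(TISSUE_CLASSES):
        name = CLASS_LEGEND[int(c)]
        tp = confusion[i, i]
        fn = confusion[i].sum() - tp
        fp = confusion[:k, i].sum() - tp
        tn = total - tp - fn - fp
        sens[name] = float(tp / (tp + fn)) if tp + fn else float("nan")
        spec[name] = float(tn / (tn + fp)) if tn + fp else float("nan")
    acc = float(np.trace(confusion[:, :k]) / total)
    return SegMetrics(confusion=confusion, per_class_sensitivity=sens,
                      per_class_specificity=spec, overall_accuracy=acc)


def evaluate_segmentation(predicted: SegmentationMap | np.ndarray,
                          truth: np.ndarray,
                          evaluate_on: np.ndarray) -> SegMetrics:
    """Score a predicted map against ground truth inside a region mask.

    Only pixels marked by ``evaluate_on`` are scored; background truth
    pixels are excluded (the classifier never predicts background as a
    tissue class).
    """
    pred = predicted.labels if isinstance(predicted, SegmentationMap) else predicted
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    region = np.asarray(evaluate_on, bool)
    if not (pred.shape == truth.shape == region.shape):
        raise ParameterError("shape mismatch between prediction/truth/region")
    region = region & (truth != TissueClass.BACKGROUND)
    if not region.any():
        raise EmptyEvaluationError("evaluation region selects no pixels")
    t = truth[region].astype(int)
    p = pred[region].astype(int)
    k = len(TISSUE_CLASSES)
    p = np.where(p >= k, k, p)  # predicted background -> last column
    conf = np.zeros((k, k + 1), np.int64)
    np.add.at(conf, (t, p), 1)
    return metrics_from_confusion(conf)


# ---------------------------------------------------------------------------
# Slide-level cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CrossValResult:
    fold_assignment: dict          # slide_id -> fold index
    per_fold: list                 # SegMetrics per fold
    pooled: SegMetrics             # from the summed confusion tables
    mean_fold_accuracy: float


def crossvalidate(tiles_by_slide: dict, k: int = 5, seed: int = 0,
                  config: TrainConfig | None = None) -> CrossValResult:
    """k-fold cross-validation with folds that partition slide ids.

    No slide ever contributes tiles to both the training and held-out side
    of the same fold, preventing within-slide texture leakage. Pooled
    metrics concatenate all held-out pixels (i.e. sum the per-fold
    confusion tables).
    """
    slide_ids = sorted(tiles_by_slide)
    if len(slide_ids) < k:
        raise FoldError(f"{len(slide_ids)} slides cannot form {k} folds")
    rng = np.random.default_rng(seed)
    order = [slide_ids[i] for i in rng.permutation(len(slide_ids))]
    folds = [list(f) for f in np.array_split(np.asarray(order, object), k)]
    assignment = {sid: fi for fi, fold in enumerate(folds) for sid in fold}

    per_fold = []
    pooled_conf = np.zeros((len(TISSUE_CLASSES), len(TISSUE_CLASSES) + 1),
                           np.int64)
    for fi, fold in enumerate(folds):
        train_tiles = [t for sid in slide_ids if sid not in fold
                       for t in tiles_by_slide[sid]]
        model = train_segmenter(train_tiles, config, seed=seed + fi)
        conf = np.zeros_like(pooled_conf)
        for sid in fold:
            for tile in tiles_by_slide[sid]:
                seg = segment_raster(model, tile.image, tile.spacing_um)
                region = tile.mask != TissueClass.BACKGROUND
                m = evaluate_segmentation(seg, tile.mask, region)
                conf += m.confusion
        per_fold.append(metrics_from_confusion(conf))
        pooled_conf += conf
    pooled = metrics_from_confusion(pooled_conf)
    mean_acc = float(np.mean([m.overall_accuracy for m in per_fold]))
    return CrossValResult(fold_assignment=assignment, per_fold=per_fold,
                          pooled=pooled, mean_fold_accuracy=mean_acc)
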