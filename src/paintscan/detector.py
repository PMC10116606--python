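"""Detection of selected variants on ancestry-painted images.

The detector follows the standard two-stage object-detection contract:
candidate regions are proposed across the image, each proposal is scored
with a probability that it contains a selected variant, overlapping
proposals are suppressed, and only detections whose score clears the
detection threshold are returned.

The built-in backbone is a sliding-window detector: every x-axis pixel is a
candidate box center; a gradient-boosted classifier scores each candidate
from the local shape of the image's column-mean (ancestry-1 fraction per
column) profile, centered by the image-wide mean so the peak shape rather
than the absolute ancestry level drives the score; score-profile local
maxima are kept (one proposal per candidate peak, minimum separation of one
box width) and non-maximum suppression on box overlap guards against
duplicates.  Any other backbone implementing ``fit(examples, config)`` /
``score_profile(pixels)`` can be plugged in.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import log_loss

from .painting import BBox, Detection

__all__ = [
    "DetectorConfig",
    "DetectorModel",
    "Detection",
    "fit_detector",
    "train",
    "predict",
    "predict_batch",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Training and inference settings.

    ``epochs``/``frozen_epochs``/``base_lr``/``weight_decay`` are part of
    the backbone contract (a neural backbone consumes them directly); the
    gradient-boosted backbone maps ``epochs`` to boosting stages
    (``epochs * stages_per_epoch``) and uses its own ``gbm_*`` settings,
    while ``frozen_epochs``, ``base_lr`` and ``weight_decay`` are recorded
    in the artifact but have no boosted-tree equivalent.
    """

    epochs: int = 30
    frozen_epochs: int = 1
    base_lr: float = 3e-3
    weight_decay: float = 1e-2
    threshold: float = 0.5
    nms_iou: float = 0.5
    half_width: int = 5
    seed: int = 0
    backbone: str = "boosted-windows"
    feature_radius: int = 25
    stages_per_epoch: int = 5
    gbm_learning_rate: float = 0.1
    gbm_max_depth: int = 3
    neg_per_image: int = 8
    neutral_neg_per_image: int = 10

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 <= self.threshold <= 1:
            raise ValueError("threshold must be in [0, 1]")

    @property
    def box_width(self) -> int:
        return 2 * self.half_width + 1


def _column_profile(pixels: np.ndarray) -> np.ndarray:
    return pixels.mean(axis=0)


def _features_for_centers(pixels: np.ndarray, centers: np.ndarray, radius: int) -> np.ndarray:
    """Feature matrix for candidate box centers of one image.

    Per center: the column-mean profile in a +/- radius window (edge-padded),
    centered by the image-wide mean, followed by the image-wide mean and SD.
    """
    col = _column_profile(pixels)
    padded = np.pad(col, radius, mode="edge")
    idx = centers[:, None] + np.arange(2 * radius + 1)[None, :]
    window = padded[idx]
    g_mean = col.mean()
    g_std = col.std()
    n = len(centers)
    return np.hstack(
        [window - g_mean, np.full((n, 1), g_mean), np.full((n, 1), g_std)]
    )


@dataclass
class DetectorModel:
    """Trained detector artifact: classifier, config and training metadata."""

    clf: GradientBoostingClassifier
    config: DetectorConfig
    image_shape: tuple[int, int]
    training_log: list[float] = field(default_factory=list)
    config_hash: str = ""

    def score_profile(self, pixels: np.ndarray) -> np.ndarray:
        """Per-center probability that a box there contains a selected variant."""
        if pixels.shape != self.image_shape:
            raise ValueError(
                f"image shape {pixels.shape} does not match training shape {self.image_shape}"
            )
        centers = np.arange(pixels.shape[1])
        X = _features_for_centers(pixels, centers, self.config.feature_radius)
        return self.clf.predict_proba(X)[:, 1]


def _config_hash(config: DetectorConfig) -> str:
    import hashlib

    payload = json.dumps(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _training_matrix(examples, config: DetectorConfig, rng: np.random.Generator):
    """Stack positive/negative candidate-center features over a training set.

    ``examples`` is a sequence of ``(pixels, variant_pixel_or_None)``.
    Positives: the target center and its two neighbors.  Negatives: random
    centers well clear of the target, plus (for neutral images) the highest
    column-contrast centers as hard negatives.
    """
    feats, labels = [], []
    for pixels, vpix in examples:
        W = pixels.shape[1]
        if vpix is not None:
            pos = np.clip(np.array([vpix - 1, vpix, vpix + 1]), 0, W - 1)
            far = np.abs(np.arange(W) - vpix) > config.half_width + 5
            candidates = np.flatnonzero(far)
            neg = rng.choice(candidates, size=min(config.neg_per_image, len(candidates)),
                             replace=False)
            centers = np.concatenate([pos, neg])
            y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
        else:
            col = _column_profile(pixels)
            hard = np.argsort(np.abs(col - col.mean()))[-3:]
            rand = rng.integers(0, W, size=config.neutral_neg_per_image - 3)
            centers = np.concatenate([hard, rand])
            y = np.zeros(len(centers))
        feats.append(_features_for_centers(pixels, centers.astype(int), config.feature_radius))
        labels.append(y)
    return np.vstack(feats), np.concatenate(labels)


def fit_detector(examples, config: DetectorConfig | None = None) -> DetectorModel:
    """Fit the detector on in-memory examples ``(pixels, variant_pixel|None)``.

    Emits a per-stage training-loss log; aborts with a diagnostic if the
    loss ever becomes non-finite.
    """
    if config is None:
        config = DetectorConfig()
    rng = np.random.default_rng(config.seed)
    X, y = _training_matrix(examples, config, rng)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both positive and negative examples")
    n_stages = config.epochs * config.stages_per_epoch
    clf = GradientBoostingClassifier(
        n_estimators=n_stages,
        learning_rate=config.gbm_learning_rate,
        max_depth=config.gbm_max_depth,
        random_state=config.seed,
    )
    clf.fit(X, y)
    log = []
    for proba in clf.staged_predict_proba(X):
        loss = log_loss(y, proba[:, 1], labels=[0.0, 1.0])
        if not np.isfinite(loss):
            raise RuntimeError(f"training diverged: non-finite loss at stage {len(log) + 1}")
        log.append(float(loss))
    shape = examples[0][0].shape
    return DetectorModel(clf, config, shape, log, _config_hash(config))


def _local_maxima(scores: np.ndarray, min_separation: int) -> np.ndarray:
    """One proposal center per score peak.

    A candidate must maximize the score within +/- min_separation (leftmost
    on exact ties); confident classifiers produce near-flat score plateaus
    across the selected region, so each peak is then refined to the
    score-weighted centroid of its contiguous near-peak plateau (score
    within 5% of the peak), which centers the box on the signal rather than
    on the plateau edge.
    """
    W = len(scores)
    peaks = []
    for c in range(W):
        lo = max(c - min_separation, 0)
        hi = min(c + min_separation + 1, W)
        window = scores[lo:hi]
        if scores[c] == window.max() and (c - lo) == int(np.argmax(window)):
            peaks.append(c)
    refined = []
    for c in peaks:
        cut = scores[c] * 0.95
        lo = c
        while lo > 0 and scores[lo - 1] >= cut:
            lo -= 1
        hi = c
        while hi < W - 1 and scores[hi + 1] >= cut:
            hi += 1
        idx = np.arange(lo, hi + 1)
        center = int(round(np.average(idx, weights=scores[lo : hi + 1])))
        refined.append(center)
    # plateau refinement can merge neighbouring peaks onto one center
    out = sorted(set(refined), key=lambda c: -scores[c])
    return np.array(out, dtype=int)


def _nms(boxes: list[BBox], iou_threshold: float) -> list[BBox]:
    kept: list[BBox] = []
    for box in sorted(boxes, key=lambda b: -b.score):
        ok = True
        for other in kept:
            inter = max(0, min(box.x_max, other.x_max) - max(box.x_min, other.x_min))
            union = box.width + other.width - inter
            if union > 0 and inter / union > iou_threshold:
                ok = False
                break
        if ok:
            kept.append(box)
    return kept


def predict(
    model: DetectorModel, pixels: np.ndarray, threshold: float | None = None
) -> list[Detection]:
    """Scored detections on one image, sorted by descending score.

    Only boxes with score strictly above the threshold are returned, so a
    threshold of 1.0 always yields an empty list.
    """
    config = model.config
    if threshold is None:
        threshold = config.threshold
    scores = model.score_profile(pixels)
    H, W = pixels.shape
    hw = config.half_width
    peaks = _local_maxima(scores, config.box_width)
    boxes = [
        BBox(max(int(c) - hw, 0), 0, min(int(c) + hw + 1, W), H, float(scores[c]))
        for c in peaks
        if scores[c] > threshold
    ]
    boxes = _nms(boxes, config.nms_iou)
    return sorted(boxes, key=lambda b: -b.score)


def predict_batch(
    model: DetectorModel, images, threshold: float | None = None
) -> list[list[Detection]]:
    return [predict(model, np.asarray(img), threshold) for img in images]


def save_model(model: DetectorModel, path) -> None:
    joblib.dump(model, path)


def load_model(path) -> DetectorModel:
    model = joblib.load(path)
    if not isinstance(model, DetectorModel):
        raise ValueError(f"{path} is not a detector artifact")
    return model


def train(training_dir, config: DetectorConfig | None = None, split: str = "train") -> DetectorModel:
    """Train from an assembled on-disk training set (see
    :func:`paintscan.pipeline.assemble_training_set`)."""
    from . import tractio  # local import: keeps detector importable without PIL use

    training_dir = Path(training_dir)
    manifest = json.loads((training_dir / split / "manifest.json").read_text())
    examples = []
    for rec in manifest["images"]:
        img = tractio.read_image(training_dir / split / "images" / rec["file_name"])
        examples.append((img.pixels, rec["variant_pixel"]))
    return fit_detector(examples, config)
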