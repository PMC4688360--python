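"""Trainable pixel classification of vessels vs. tissue.

Mirrors the interactive trainable-segmentation workflow: multi-scale image
features per pixel, a random-forest classifier fitted on sparse user (or
auto-generated) scribbles, a per-pixel vessel probability map, and a binary
vessel mask thresholded at 60% probability.

The 17 features per pixel are the raw intensity, Gaussian blur at scales
{1, 2, 4, 8} px, gradient magnitude at each scale, and the smallest and
largest Hessian eigenvalue (ridge detector) at each scale; each feature is
standardized to zero mean and unit variance over the image (a zero-variance
feature standardizes to all zeros).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import hessian_matrix, hessian_matrix_eigvals
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "UNLABELED",
    "VESSEL",
    "TISSUE",
    "FEATURE_SCALES",
    "VesselProbabilityMap",
    "LabelMask",
    "VesselClassifier",
    "extract_pixel_features",
    "feature_names",
    "train_classifier",
    "predict_probability",
    "threshold_vessels",
    "auto_scribbles",
    "michelson_contrast",
]

UNLABELED, VESSEL, TISSUE = 0, 1, 2
FEATURE_SCALES = (1, 2, 4, 8)
MIN_LABELED_PER_CLASS = 20


@dataclass
class VesselProbabilityMap:
    prob: np.ndarray  # per-pixel P(vessel), in [0, 1]
    feature_spec: tuple[str, ...]


@dataclass
class LabelMask:
    """Sparse training scribbles: 0 unlabeled, 1 vessel, 2 tissue."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        extra = set(np.unique(self.labels)) - {UNLABELED, VESSEL, TISSUE}
        if extra:
            raise ValueError(f"unexpected label values: {sorted(extra)}")

    def count(self, value: int) -> int:
        return int((self.labels == value).sum())


@dataclass
class VesselClassifier:
    model: RandomForestClassifier
    feature_spec: tuple[str, ...]


def feature_names() -> tuple[str, ...]:
    names = ["intensity"]
    names += [f"gaussian_s{s}" for s in FEATURE_SCALES]
    names += [f"gradmag_s{s}" for s in FEATURE_SCALES]
    for s in FEATURE_SCALES:
        names += [f"hessian_min_s{s}", f"hessian_max_s{s}"]
    return tuple(names)


def _standardize(stack: np.ndarray) -> np.ndarray:
    mean = stack.mean(axis=(0, 1))
    sd = stack.std(axis=(0, 1))
    out = stack - mean
    # zero-variance features (up to float round-off) define as 0
    nonzero = sd > 1e-9 * np.maximum(1.0, np.abs(mean))
    out[..., nonzero] /= sd[nonzero]
    out[..., ~nonzero] = 0.0
    return out


def extract_pixel_features(image: np.ndarray) -> np.ndarray:
    """Per-pixel feature stack, shape (rows, cols, 17), standardized."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    feats = [image]
    for s in FEATURE_SCALES:
        feats.append(ndimage.gaussian_filter(image, s))
    for s in FEATURE_SCALES:
        feats.append(ndimage.gaussian_gradient_magnitude(image, s))
    for s in FEATURE_SCALES:
        H = hessian_matrix(
            image, sigma=s, order="rc", mode="reflect", use_gaussian_derivatives=False
        )
        lo, hi = hessian_matrix_eigvals(H)[::-1]  # eigvals sorted descending
        feats += [lo, hi]
    stack = np.stack(feats, axis=-1)
    return _standardize(stack)


def train_classifier(
    features: np.ndarray,
    labels: LabelMask | np.ndarray,
    rng_seed: int = 0,
    n_trees: int = 100,
) -> VesselClassifier:
    """Fit a random forest on the labeled pixels only.

    Requires at least 20 labeled pixels of each class; deterministic for a
    fixed ``rng_seed``.
    """
    if not isinstance(labels, LabelMask):
        labels = LabelMask(labels)
    for cls, name in ((VESSEL, "vessel"), (TISSUE, "tissue")):
        if labels.count(cls) < MIN_LABELED_PER_CLASS:
            raise ValueError(
                f"need >= {MIN_LABELED_PER_CLASS} labeled {name} pixels, "
                f"got {labels.count(cls)}"
            )
    sel = labels.labels != UNLABELED
    X = features[sel]
    y = labels.labels[sel]
    model = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",  # per-tree feature subsampling
        random_state=int(rng_seed),
        n_jobs=1,
    )
    model.fit(X, y)
    return VesselClassifier(model=model, feature_spec=feature_names())


def predict_probability(clf: VesselClassifier, image: np.ndarray) -> VesselProbabilityMap:
    """Vessel-class probability (tree-vote fraction) for every pixel."""
    if clf.feature_spec != feature_names():
        raise ValueError("classifier feature_spec does not match this feature set")
    feats = extract_pixel_features(image)
    X = feats.reshape(-1, feats.shape[-1])
    proba = clf.model.predict_proba(X)
    vessel_col = list(clf.model.classes_).index(VESSEL)
    prob = proba[:, vessel_col].reshape(image.shape)
    return VesselProbabilityMap(prob=prob, feature_spec=clf.feature_spec)


def threshold_vessels(prob_map: VesselProbabilityMap, threshold: float = 0.6) -> np.ndarray:
    """Binary vessel mask: probability strictly above the threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return prob_map.prob > threshold


def auto_scribbles(
    vessel_mask: np.ndarray,
    n_per_class: int = 800,
    margin_px: int = 1,
    rng: np.random.Generator | int | None = 0,
) -> LabelMask:
    """Training scribbles sampled from ground truth, away from the boundary.

    Erodes the vessel mask and its complement by ``margin_px`` so no label
    sits on the ambiguous rim, then samples up to ``n_per_class`` pixels of
    each class.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    structure = np.ones((3, 3), dtype=bool)
    core_vessel = ndimage.binary_erosion(vessel_mask, structure, iterations=margin_px)
    core_tissue = ndimage.binary_erosion(~vessel_mask, structure, iterations=margin_px)
    labels = np.zeros(vessel_mask.shape, dtype=np.uint8)
    for cls, core in ((VESSEL, core_vessel), (TISSUE, core_tissue)):
        idx = np.flatnonzero(core)
        if idx.size == 0:
            raise ValueError("mask leaves no core pixels for a class")
        take = min(n_per_class, idx.size)
        chosen = rng.choice(idx, size=take, replace=False)
        labels.flat[chosen] = cls
    return LabelMask(labels)


def michelson_contrast(image: np.ndarray, labels: LabelMask) -> float:
    """Vessel/tissue Michelson contrast on the labeled pixels.

    Quality gate for recordings: low values flag poor vessel/tissue contrast
    (the field's usual reason to exclude an animal), reported rather than
    silently dropped.
    """
    image = np.asarray(image, dtype=float)
    v = image[labels.labels == VESSEL].mean()
    t = image[labels.labels == TISSUE].mean()
    if v + t == 0:
        return 0.0
    return float(abs(t - v) / (t + v))
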