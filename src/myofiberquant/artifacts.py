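"""Random-forest pixel classification for artifact removal.

Segmenters happily produce masks over folds, bubbles, dust and tears. A
binary random-forest pixel classifier over simple color/texture features —
Gaussian smoothing, Laplacian of Gaussian and Gaussian-weighted local
standard deviation ("weighted deviation"), on each of the R, G and B
channels at a physical scale of 1.0 um — labels each pixel tissue or
artifact; a mask is removed when the artifact fraction of its pixels
exceeds a threshold (majority by default).
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from .errors import ConsistencyError, ParameterError, TrainingError
from .imaging import CalibratedImage, LabelImage

__all__ = [
    "FeatureParams",
    "PixelClassifierModel",
    "MaskFilterParams",
    "compute_pixel_features",
    "train_pixel_classifier",
    "filter_masks",
    "save_model",
    "load_model",
    "FEATURE_NAMES",
]

_CHANNELS = ("red", "green", "blue")
_FEATURES = ("gaussian", "laplacian_of_gaussian", "weighted_deviation")
# fixed feature order: channel-major, feature-minor
FEATURE_NAMES = tuple(f"{c}_{f}" for c in _CHANNELS for f in _FEATURES)


@dataclass
class FeatureParams:
    """Feature scale in physical units (converted to pixels per image)."""

    scale_um: float = 1.0

    def __post_init__(self) -> None:
        if self.scale_um <= 0:
            raise ParameterError("scale_um must be > 0")


@dataclass
class MaskFilterParams:
    """A mask is removed iff its artifact pixel fraction exceeds the threshold."""

    artifact_fraction_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.artifact_fraction_threshold <= 1.0:
            raise ParameterError("artifact_fraction_threshold must be in [0, 1]")


@dataclass
class PixelClassifierModel:
    """Trained tissue/artifact pixel classifier with its training metadata."""

    classifier: RandomForestClassifier
    feature_params: FeatureParams
    metadata: dict = field(default_factory=dict)

    def predict_artifact(self, features: np.ndarray) -> np.ndarray:
        """Boolean per-pixel artifact map from an (H, W, 9) feature stack."""
        h, w, k = features.shape
        pred = self.classifier.predict(features.reshape(-1, k))
        return pred.reshape(h, w).astype(bool)


def compute_pixel_features(img: CalibratedImage, p: FeatureParams | None = None) -> np.ndarray:
    """Per-pixel feature stack of shape (H, W, 9).

    For each channel c at sigma = scale_um / pixel_size_um (pixels):

    * G   = Gaussian-smoothed c,
    * LoG = Laplacian of G (sign convention of the discrete Laplacian:
      a bright spot on dark background gives a negative extremum at the
      spot, positive ring around it),
    * WD  = sqrt(max(0, G(c^2) - G(c)^2)), the Gaussian-weighted local
      standard deviation.

    Feature order is fixed channel-major: see :data:`FEATURE_NAMES`.
    """
    p = p or FeatureParams()
    sigma = p.scale_um / img.pixel_size_um
    planes = [img.pixels[..., i].astype(np.float64) for i in range(3)]
    feats = []
    for c in planes:
        g = ndimage.gaussian_filter(c, sigma)
        log = ndimage.laplace(g)
        g2 = ndimage.gaussian_filter(c * c, sigma)
        wd = np.sqrt(np.maximum(0.0, g2 - g * g))
        feats.extend([g, log, wd])
    return np.stack(feats, axis=-1)


def train_pixel_classifier(
    feature_stacks: list[np.ndarray],
    label_masks: list[np.ndarray],
    n_trees: int = 100,
    seed: int = 0,
    max_pixels_per_class: int = 50_000,
) -> PixelClassifierModel:
    """Train the tissue/artifact random forest.

    Parameters
    ----------
    feature_stacks : list of (H, W, 9) arrays
        From :func:`compute_pixel_features`.
    label_masks : list of (H, W) integer arrays
        0 = unlabeled, 1 = tissue, 2 = artifact.
    """
    xs, ys = [], []
    for stack, lab in zip(feature_stacks, label_masks):
        if stack.shape[:2] != lab.shape:
            raise ConsistencyError("feature stack and label mask shapes differ")
        sel = lab > 0
        xs.append(stack[sel])
        ys.append(lab[sel])
    X = np.concatenate(xs)
    y = np.concatenate(ys)
    classes = np.unique(y)
    if classes.size < 2:
        raise TrainingError(
            f"training requires both classes; got only {classes.tolist()}"
        )
    rng = np.random.default_rng(seed)
    # balance and cap the training set for speed
    keep = []
    for cls in classes:
        idx = np.nonzero(y == cls)[0]
        if idx.size > max_pixels_per_class:
            idx = rng.choice(idx, max_pixels_per_class, replace=False)
        keep.append(idx)
    keep = np.concatenate(keep)
    X, y = X[keep], y[keep] == 2  # True = artifact
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    clf.fit(X, y)
    return PixelClassifierModel(
        classifier=clf,
        feature_params=FeatureParams(),
        metadata={
            "n_trees": n_trees,
            "seed": seed,
            "n_training_pixels": int(len(y)),
            "class_priors": {"tissue": float((~y).mean()), "artifact": float(y.mean())},
            "training_accuracy": float(clf.score(X, y)),
            "feature_names": list(FEATURE_NAMES),
        },
    )


def filter_masks(
    labels: LabelImage,
    img: CalibratedImage,
    model: PixelClassifierModel,
    p: MaskFilterParams | None = None,
) -> tuple[LabelImage, list[dict]]:
    """Remove masks whose artifact pixel fraction exceeds the threshold.

    Returns the filtered label image (surviving masks untouched) and a
    removal report listing each removed label with its artifact fraction.
    """
    p = p or MaskFilterParams()
    if labels.shape != img.shape:
        raise ConsistencyError(
            f"labels shape {labels.shape} != image shape {img.shape}"
        )
    features = compute_pixel_features(img, model.feature_params)
    artifact = model.predict_artifact(features)
    out = labels.labels.copy()
    report = []
    for lab, sl in enumerate(ndimage.find_objects(out), start=1):
        if sl is None:
            continue
        mask = out[sl] == lab
        frac = float(artifact[sl][mask].mean())
        if frac > p.artifact_fraction_threshold:
            sub = out[sl]
            sub[mask] = 0
            report.append({"label": lab, "artifact_fraction": frac})
    return LabelImage(out), report


def save_model(model: PixelClassifierModel, path) -> None:
    """Serialize a trained classifier with its feature parameters."""
    with open(path, "wb") as f:
        pickle.dump(
            {"version": 1, "feature_params": model.feature_params,
             "metadata": model.metadata, "classifier": model.classifier},
            f,
        )


def load_model(path, expected_params: FeatureParams | None = None) -> PixelClassifierModel:
    """Load a serialized classifier; refuse on feature-parameter mismatch."""
    with open(path, "rb") as f:
        blob = pickle.load(f)
    model = PixelClassifierModel(blob["classifier"], blob["feature_params"], blob["metadata"])
    if expected_params is not None and expected_params != model.feature_params:
        raise ConsistencyError(
            f"model feature params {model.feature_params} do not match "
            f"expected {expected_params}"
        )
    return model
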