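"""Pixel classification into background/cell/neurite and neurite length.

A fixed bank of per-pixel filter responses (intensity plus Gaussian
smoothing, gradient magnitude, Laplacian, Hessian eigenvalues and
structure-tensor eigenvalues at scales σ ∈ {1, 2, 4, 8} px) feeds a
seeded random-forest classifier trained on ground-truth label maps
from the synthetic generator.  The arg-max labelling is cleaned up
morphologically, the neurite class is skeletonised to 1-px
centrelines, and mean neurite length per cell is the skeleton length
(orthogonal steps count 1, diagonal steps √2, times the pixel size)
divided by the number of DAPI-detected nuclei.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import feature as skfeature
from skimage import morphology
from sklearn.ensemble import RandomForestClassifier

from .wavelet import NucleiParams, detect_nuclei_spots

__all__ = [
    "PixelFeatureStack",
    "SegmentationMap",
    "PixelClassifier",
    "MissingDenominatorError",
    "compute_pixel_features",
    "train_pixel_classifier",
    "segment",
    "neurite_length_per_cell",
    "skeleton_length",
    "FEATURE_NAMES",
    "FEATURE_VERSION",
    "LABEL_BACKGROUND",
    "LABEL_CELL",
    "LABEL_NEURITE",
]

LABEL_BACKGROUND, LABEL_CELL, LABEL_NEURITE = 0, 1, 2

_SCALES = (1.0, 2.0, 4.0, 8.0)
_FAMILIES = ("gauss", "gradmag", "laplace", "hess_max", "hess_min",
             "st_max", "st_min")

#: Stable, versioned feature order: raw intensity followed by the seven
#: filter responses at each scale.
FEATURE_NAMES: tuple[str, ...] = ("intensity",) + tuple(
    f"{fam}_s{int(s)}" for s in _SCALES for fam in _FAMILIES)
FEATURE_VERSION = 1

# morphological cleanup constants (px)
MIN_NEURITE_COMPONENT = 5
MAX_CELL_HOLE = 25


class MissingDenominatorError(ValueError):
    """Per-cell normalisation requested with no nuclei available."""


@dataclass
class PixelFeatureStack:
    """(H, W, n_features) float32 stack with named, versioned channels."""

    data: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES
    version: int = FEATURE_VERSION


@dataclass
class SegmentationMap:
    """Per-pixel 3-class labelling plus derived skeleton and cell count."""

    labels: np.ndarray            # uint8: 0 background, 1 cell, 2 neurite
    nucleus_count: int | None     # None when no DAPI channel was given
    skeleton: np.ndarray          # bool, subset of neurite pixels
    pixel_size: float             # µm/px

    @property
    def neurite_mask(self) -> np.ndarray:
        return self.labels == LABEL_NEURITE

    @property
    def cell_mask(self) -> np.ndarray:
        return self.labels == LABEL_CELL


def compute_pixel_features(image: np.ndarray) -> PixelFeatureStack:
    """Fixed filter-bank features for one single-channel image."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    feats = [image]
    for s in _SCALES:
        sm = ndi.gaussian_filter(image, s)
        grad = ndi.gaussian_gradient_magnitude(image, s)
        lap = ndi.gaussian_laplace(image, s)
        H = skfeature.hessian_matrix(image, sigma=s, order="rc",
                                     mode="mirror",
                                     use_gaussian_derivatives=False)
        h_max, h_min = skfeature.hessian_matrix_eigvals(H)
        A = skfeature.structure_tensor(image, sigma=s, order="rc",
                                       mode="mirror")
        st_max, st_min = skfeature.structure_tensor_eigenvalues(A)
        feats.extend([sm, grad, lap, h_max, h_min, st_max, st_min])
    data = np.stack(feats, axis=-1).astype(np.float32)
    return PixelFeatureStack(data=data)


@dataclass
class PixelClassifier:
    """Random-forest pixel classifier with the feature contract recorded.

    Any estimator exposing ``predict_proba`` over the same feature
    stack can stand in; the persisted container carries a format
    version so stored models fail loudly rather than silently when the
    feature definition changes.
    """

    model: RandomForestClassifier
    feature_names: tuple[str, ...]
    feature_version: int = FEATURE_VERSION
    format_version: int = 1

    def predict_proba_image(self, stack: PixelFeatureStack,
                            chunk: int = 1 << 18) -> np.ndarray:
        if stack.version != self.feature_version:
            raise ValueError(
                f"feature version mismatch: stack v{stack.version}, "
                f"classifier v{self.feature_version}")
        h, w, f = stack.data.shape
        flat = stack.data.reshape(-1, f)
        out = np.empty((flat.shape[0], len(self.model.classes_)),
                       dtype=np.float32)
        for i in range(0, flat.shape[0], chunk):
            out[i:i + chunk] = self.model.predict_proba(flat[i:i + chunk])
        return out.reshape(h, w, -1)

    def save(self, path) -> None:
        payload = {"format_version": self.format_version,
                   "feature_version": self.feature_version,
                   "feature_names": self.feature_names,
                   "model": self.model}
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "PixelClassifier":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("format_version") != 1:
            raise ValueError("unsupported classifier container version")
        return cls(model=payload["model"],
                   feature_names=tuple(payload["feature_names"]),
                   feature_version=payload["feature_version"])


def train_pixel_classifier(stacks: Sequence[PixelFeatureStack],
                           label_maps: Sequence[np.ndarray],
                           seed: int = 0, n_trees: int = 100,
                           max_pixels: int = 200_000) -> PixelClassifier:
    """Train the 3-class pixel classifier on ground-truth label maps.

    Pixels are subsampled (stratified, seeded) to at most ``max_pixels``
    to keep training tractable; raises on single-class training data.
    """
    xs, ys = [], []
    for stack, labels in zip(stacks, label_maps):
        xs.append(stack.data.reshape(-1, stack.data.shape[-1]))
        ys.append(np.asarray(labels).ravel())
    X = np.concatenate(xs)
    y = np.concatenate(ys)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data contains a single class")
    rng = np.random.default_rng(seed)
    per_class = max_pixels // classes.size
    keep = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        if idx.size > per_class:
            idx = rng.choice(idx, per_class, replace=False)
        keep.append(idx)
    keep = np.concatenate(keep)
    model = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                   n_jobs=1, min_samples_leaf=2)
    model.fit(X[keep], y[keep])
    return PixelClassifier(model=model, feature_names=FEATURE_NAMES)


def segment(image: np.ndarray, classifier: PixelClassifier,
            dapi: np.ndarray | None = None,
            pixel_size: float = 0.65,
            nuclei_params: NucleiParams = NucleiParams(),
            ) -> SegmentationMap:
    """Classify pixels, clean up, skeletonise, count nuclei.

    ``dapi=None`` leaves ``nucleus_count`` unavailable (``None``);
    downstream per-cell metrics then raise rather than divide.
    """
    stack = compute_pixel_features(image)
    proba = classifier.predict_proba_image(stack)
    labels = classifier.model.classes_[np.argmax(proba, axis=-1)]
    labels = labels.astype(np.uint8)

    neurite = labels == LABEL_NEURITE
    neurite = morphology.remove_small_objects(
        neurite, max_size=MIN_NEURITE_COMPONENT - 1)
    cell = labels == LABEL_CELL
    cell = morphology.remove_small_holes(cell, max_size=MAX_CELL_HOLE)

    clean = np.zeros_like(labels)
    clean[cell] = LABEL_CELL
    clean[neurite] = LABEL_NEURITE

    skeleton = morphology.skeletonize(clean == LABEL_NEURITE)
    nucleus_count = None
    if dapi is not None:
        _, nucleus_count = detect_nuclei_spots(dapi, nuclei_params)
    return SegmentationMap(labels=clean, nucleus_count=nucleus_count,
                           skeleton=skeleton, pixel_size=pixel_size)


def skeleton_length(skeleton: np.ndarray, pixel_size: float = 1.0) -> float:
    """Polyline-style length of a 1-px skeleton.

    Counts 4-neighbour (orthogonal) adjacent pixel pairs as one step
    and diagonal pairs as √2 steps, each pair once, then scales by the
    pixel size.  For a straight n-pixel segment this gives n-1 steps.
    """
    sk = np.asarray(skeleton, dtype=bool)
    n_orth = (np.count_nonzero(sk[:, :-1] & sk[:, 1:])
              + np.count_nonzero(sk[:-1, :] & sk[1:, :]))
    n_diag = (np.count_nonzero(sk[:-1, :-1] & sk[1:, 1:])
              + np.count_nonzero(sk[:-1, 1:] & sk[1:, :-1]))
    return (n_orth + np.sqrt(2.0) * n_diag) * pixel_size


def neurite_length_per_cell(segmap: SegmentationMap) -> float:
    """Total skeleton length (µm) divided by the nucleus count."""
    if segmap.nucleus_count is None:
        raise MissingDenominatorError(
            "nucleus count unavailable (scene had no DAPI channel)")
    if segmap.nucleus_count == 0:
        raise MissingDenominatorError("no nuclei detected")
    total = skeleton_length(segmap.skeleton, segmap.pixel_size)
    return total / segmap.nucleus_count
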