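"""Segmentation and morphology primitives shared by all pipelines.

A trainable multiscale random-forest pixel classifier (the in-repo
replacement for the Ilastik / Arivis classifiers the original assays
used), rolling-ball background subtraction, Euclidean mask erosion, and
connected-component labeling with physical-volume filtering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure
from sklearn.ensemble import RandomForestClassifier

# ---------------------------------------------------------------------------
# Pixel classification


DEFAULT_FEATURE_SCALES = (1.0, 2.0, 4.0)
_FEATURE_VERSION = 1


def _feature_stack(image: np.ndarray, scales: Sequence[float]) -> np.ndarray:
    """Per-pixel feature bank: raw, Gaussian, gradient magnitude, Laplacian
    at each scale. Returns (n_pixels, n_features)."""
    image = np.asarray(image, dtype=np.float32)
    feats = [image.ravel()]
    for s in scales:
        smooth = ndimage.gaussian_filter(image, s)
        feats.append(smooth.ravel())
        feats.append(ndimage.gaussian_gradient_magnitude(image, s).ravel())
        feats.append(ndimage.gaussian_laplace(image, s).ravel())
    return np.stack(feats, axis=1)


@dataclass
class PixelClassifier:
    """Random-forest pixel classifier over a fixed multiscale feature bank.

    Features per pixel: raw intensity plus Gaussian smoothing, gradient
    magnitude and Laplacian of Gaussian at each scale (default scales
    1, 2, 4 px). Single pass — no AutoContext second stage.
    """

    model: RandomForestClassifier
    scales: tuple[float, ...]
    classes: tuple[int, ...]
    version: int = _FEATURE_VERSION

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        """Class probabilities, shape image.shape + (n_classes,)."""
        X = _feature_stack(image, self.scales)
        proba = self.model.predict_proba(X)
        return proba.reshape(image.shape + (len(self.classes),))

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Argmax class label per pixel."""
        proba = self.predict_proba(image)
        idx = np.argmax(proba, axis=-1)
        return np.asarray(self.classes)[idx]

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "model": self.model,
                "scales": self.scales,
                "classes": self.classes,
                "version": self.version,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "PixelClassifier":
        bundle = joblib.load(path)
        if bundle.get("version") != _FEATURE_VERSION:
            raise ValueError(
                f"classifier bundle version {bundle.get('version')} unsupported"
            )
        return cls(
            model=bundle["model"],
            scales=tuple(bundle["scales"]),
            classes=tuple(bundle["classes"]),
        )


def train_pixel_classifier(
    images: Sequence[np.ndarray],
    label_masks: Sequence[np.ndarray],
    scales: Sequence[float] = DEFAULT_FEATURE_SCALES,
    n_estimators: int = 50,
    seed: int = 0,
) -> PixelClassifier:
    """Train a pixel classifier from sparse annotations.

    ``label_masks`` use 0 for unlabeled pixels and positive integers for
    class labels; at least two classes must be annotated. Deterministic
    for a given seed.
    """
    if len(images) != len(label_masks):
        raise ValueError("one label mask per image required")
    Xs, ys = [], []
    for image, labels in zip(images, label_masks):
        labels = np.asarray(labels)
        if labels.shape != np.asarray(image).shape:
            raise ValueError("label mask shape must match image shape")
        annotated = labels > 0
        if annotated.any():
            Xs.append(_feature_stack(image, scales)[annotated.ravel()])
            ys.append(labels[annotated])
    if not Xs:
        raise ValueError("no annotated pixels")
    X = np.concatenate(Xs)
    y = np.concatenate(ys)
    classes = tuple(int(c) for c in np.unique(y))
    if len(classes) < 2:
        raise ValueError(f"need >=2 annotated classes, got {classes}")
    model = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )
    model.fit(X, y)
    return PixelClassifier(model=model, scales=tuple(scales), classes=classes)


def predict_mask(
    clf: PixelClassifier, image: np.ndarray, target_class: int
) -> np.ndarray:
    """Binary mask of pixels whose argmax class equals ``target_class``."""
    if target_class not in clf.classes:
        raise ValueError(f"class {target_class} not in classifier classes {clf.classes}")
    return clf.predict(image) == target_class


# ---------------------------------------------------------------------------
# Background subtraction


def _disk_footprint(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (yy * yy + xx * xx) <= radius * radius


def rolling_ball_subtract(
    image: np.ndarray, radius_px: int, presmooth_sigma: float = 0.0
) -> np.ndarray:
    """Rolling-ball background subtraction on a 2D image.

    Background is estimated by grayscale morphological opening with a
    flat disk of the given radius (peaks narrower than the ball survive
    subtraction; plateaus wider than the ball are removed), optionally
    after a light Gaussian smooth. Output = image − background, clipped
    at 0, in float.
    """
    if radius_px < 1:
        raise ValueError("radius must be >= 1")
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("rolling-ball subtraction operates on a single 2D channel")
    work = ndimage.gaussian_filter(image, presmooth_sigma) if presmooth_sigma > 0 else image
    background = ndimage.grey_opening(work, footprint=_disk_footprint(radius_px))
    return np.clip(image - background, 0.0, None)


# ---------------------------------------------------------------------------
# Mask morphology


def erode_mask(mask: np.ndarray, radius_px: int) -> np.ndarray:
    """Euclidean erosion: keep pixels strictly farther than ``radius_px``
    from the nearest background pixel. radius 0 is the identity."""
    mask = np.asarray(mask, dtype=bool)
    if radius_px < 0:
        raise ValueError("erosion radius must be >= 0")
    if radius_px == 0:
        return mask.copy()
    dist = ndimage.distance_transform_edt(mask)
    return dist > radius_px


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Largest connected component of a mask.

    The automated counterpart of the manual false-positive removal step
    for reference structures: stray noise voxels that clear a global
    threshold would otherwise seed spurious distance shells.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = measure.label(mask, connectivity=mask.ndim)
    if labels.max() == 0:
        return mask.copy()
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


# ---------------------------------------------------------------------------
# Connected components


@dataclass
class LabeledObjects:
    """Connected components with per-object geometry and intensity summaries.

    ``labels`` holds dense labels 1..n assigned in raster-scan order of
    each component's first voxel; ``table`` has one row per object with
    voxel_count, volume_um3 (voxel count × voxel volume), centroid and
    bounding box, plus mean/total intensity per measured channel.
    """

    labels: np.ndarray
    spacing: tuple[float, ...] | None
    table: pd.DataFrame

    @property
    def n_objects(self) -> int:
        return len(self.table)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing)) if self.spacing else 1.0

    def mask(self) -> np.ndarray:
        return self.labels > 0

    def subset(self, keep_labels: Sequence[int]) -> "LabeledObjects":
        """Retain the given labels and re-densify to 1..k (order preserved
        by first-voxel raster order, i.e. ascending old label)."""
        keep = sorted(int(l) for l in keep_labels)
        lut = np.zeros(int(self.labels.max()) + 1, dtype=self.labels.dtype)
        for new, old in enumerate(keep, start=1):
            lut[old] = new
        new_labels = lut[self.labels]
        new_table = self.table[self.table["label"].isin(keep)].copy()
        new_table["label"] = new_table["label"].map({old: i + 1 for i, old in enumerate(keep)})
        new_table = new_table.sort_values("label").reset_index(drop=True)
        return LabeledObjects(labels=new_labels, spacing=self.spacing, table=new_table)


def label_and_filter(
    mask: np.ndarray,
    spacing: Sequence[float] | None = None,
    min_size_px: int | None = None,
    min_volume_um3: float | None = None,
    intensity_channels: dict[str, np.ndarray] | None = None,
) -> LabeledObjects:
    """Label connected components and drop small ones.

    Connectivity is full (8-connectivity in 2D, 26 in 3D). Components
    below ``min_size_px`` voxels or ``min_volume_um3`` physical volume
    are removed and the surviving labels re-densified in raster-scan
    order of first voxel.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = measure.label(mask, connectivity=mask.ndim)
    voxel_volume = float(np.prod(spacing)) if spacing is not None else 1.0

    counts = np.bincount(labels.ravel())
    # deterministic ordering: raster-scan position of each component's
    # first voxel (skimage usually already yields this; enforce it)
    uniq, first_idx = np.unique(labels.ravel(), return_index=True)
    order = [int(l) for _, l in sorted(zip(first_idx, uniq)) if l > 0]
    rows = []
    keep_ids = []
    for obj_id in order:
        n_vox = int(counts[obj_id])
        volume = n_vox * voxel_volume
        if min_size_px is not None and n_vox < min_size_px:
            continue
        if min_volume_um3 is not None and volume < min_volume_um3:
            continue
        keep_ids.append(obj_id)
        rows.append({"old_label": obj_id, "voxel_count": n_vox, "volume_um3": volume})

    lut = np.zeros(len(counts), dtype=np.int32)
    for new, old in enumerate(keep_ids, start=1):
        lut[old] = new
    dense = lut[labels]

    if rows:
        table = pd.DataFrame(rows)
        table["label"] = np.arange(1, len(rows) + 1)
        # geometry
        com = ndimage.center_of_mass(np.ones_like(dense), dense, table["label"].to_list())
        table["centroid"] = [tuple(float(c) for c in cc) for cc in com]
        slices = ndimage.find_objects(dense)
        table["bbox"] = [
            tuple((s.start, s.stop) for s in slices[l - 1]) for l in table["label"]
        ]
        if intensity_channels:
            for name, channel in intensity_channels.items():
                channel = np.asarray(channel, dtype=np.float64)
                sums = ndimage.sum_labels(channel, dense, table["label"].to_list())
                table[f"mean_{name}"] = np.asarray(sums) / table["voxel_count"]
                table[f"total_{name}"] = np.asarray(sums)
        table = table.drop(columns=["old_label"])
        cols = ["label"] + [c for c in table.columns if c != "label"]
        table = table[cols]
    else:
        cols = ["label", "voxel_count", "volume_um3", "centroid", "bbox"]
        if intensity_channels:
            for name in intensity_channels:
                cols += [f"mean_{name}", f"total_{name}"]
        table = pd.DataFrame(columns=cols)

    sp = tuple(float(s) for s in spacing) if spacing is not None else None
    return LabeledObjects(labels=dense, spacing=sp, table=table)
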