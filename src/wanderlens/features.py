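"""Shape and visual-word features of trajectory images.

Two complementary descriptor families summarise each rendered episode:

* **Connected-region features (CRF)** — 15 shape and intensity properties of
  the trajectory's principal connected pixel region in the binarized image
  (area, fitted-ellipse axes, eccentricity, orientation, perimeter,
  circularity, filled area, Euler number, equivalent diameter, solidity,
  extent, and max/mean/min grayscale intensity).
* **Bag of visual words (BoVW)** — local keypoint descriptors detected on
  the RGB image are quantised against a k-means vocabulary into a K-bin,
  L2-normalised histogram.  The descriptor layer is pluggable; the default
  is ORB (oriented FAST keypoints + rotated BRIEF descriptors), a free,
  deterministic scale/rotation-robust detector-descriptor.

The concatenation (15 CRF values, then K histogram bins) plus subject id and
class label forms the per-episode feature vector consumed by the
classification stage.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import measure
from skimage.feature import ORB
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

#: CRF field order used everywhere a vector is assembled.
CRF_FIELDS = (
    "area",
    "major_axis_length",
    "minor_axis_length",
    "eccentricity",
    "orientation",
    "perimeter",
    "circularity",
    "filled_area",
    "euler_number",
    "equiv_diameter",
    "solidity",
    "extent",
    "max_intensity",
    "mean_intensity",
    "min_intensity",
)


class EmptyRegionError(ValueError):
    """Raised when a binary image contains no foreground pixels."""


@dataclass(frozen=True)
class RegionFeatures:
    area: float
    major_axis_length: float
    minor_axis_length: float
    eccentricity: float
    orientation: float  # degrees in (-90, 90], x-axis convention, y-up
    perimeter: float
    circularity: float
    filled_area: float
    euler_number: int
    equiv_diameter: float
    solidity: float
    extent: float
    max_intensity: float
    mean_intensity: float
    min_intensity: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in CRF_FIELDS], dtype=float)


def circularity(area: float, perimeter: float) -> float:
    """Roundness of a region from its area and perimeter.

    Uses the boundary-corrected form ``(4*pi*A / P^2) * (1 - 0.5/r)^2`` with
    ``r = P/(2*pi) + 0.5``, which compensates for the half-pixel bias of
    discrete perimeters (a rasterized disk scores close to 1).
    """
    if perimeter <= 0:
        return 0.0
    r = perimeter / (2.0 * math.pi) + 0.5
    return (4.0 * math.pi * area / perimeter**2) * (1.0 - 0.5 / r) ** 2


def _largest_region(props):
    """Largest region; ties resolved by the smaller top-left bbox corner."""
    return max(props, key=lambda p: (p.area, (-p.bbox[0], -p.bbox[1])))


def region_features(binary: np.ndarray, gray: np.ndarray) -> RegionFeatures:
    """The 15 connected-region features of a binary + grayscale image pair.

    Connected components use 8-connectivity; features describe the largest
    component (the principal trajectory blob), except the Euler number,
    which is objects minus holes (4-connected holes) over the whole image.
    Intensity statistics are taken over the component's pixels in ``gray``.
    Raises :class:`EmptyRegionError` when there is no foreground.
    """
    binary = np.asarray(binary).astype(bool)
    gray = np.asarray(gray, dtype=float)
    if binary.shape != gray.shape:
        raise ValueError("binary and grayscale images must share dimensions")
    if not binary.any():
        raise EmptyRegionError("binary image has no foreground pixels")

    labels = measure.label(binary, connectivity=2)
    props = measure.regionprops(labels, intensity_image=gray)
    p = _largest_region(props)

    # skimage orientation is measured from the row axis; convert to the
    # x-axis/y-up convention, wrapped to (-90, 90]
    orient = math.degrees(p.orientation) - 90.0
    if orient <= -90.0:
        orient += 180.0
    elif orient > 90.0:
        orient -= 180.0

    euler = measure.euler_number(binary, connectivity=2)

    return RegionFeatures(
        area=float(p.area),
        major_axis_length=float(p.axis_major_length),
        minor_axis_length=float(p.axis_minor_length),
        eccentricity=float(p.eccentricity),
        orientation=float(orient),
        perimeter=float(p.perimeter),
        circularity=circularity(float(p.area), float(p.perimeter)),
        filled_area=float(p.area_filled),
        euler_number=int(euler),
        equiv_diameter=math.sqrt(4.0 * float(p.area) / math.pi),
        solidity=float(p.solidity),
        extent=float(p.extent),
        max_intensity=float(p.intensity_max),
        mean_intensity=float(p.intensity_mean),
        min_intensity=float(p.intensity_min),
    )


def region_feature_vector(binary: np.ndarray, gray: np.ndarray) -> np.ndarray:
    """CRF vector; an empty image yields all zeros with a logged warning."""
    try:
        return region_features(binary, gray).as_array()
    except EmptyRegionError:
        logger.warning("empty trajectory region: substituting an all-zero CRF block")
        return np.zeros(len(CRF_FIELDS))


# --------------------------------------------------------------------------
# bag of visual words


@dataclass
class VisualVocabulary:
    """K visual words: cluster centers in descriptor space."""

    K: int
    centers: np.ndarray  # (K, d)
    descriptor_kind: str = "orb"
    seed: int = 0

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "K": self.K,
                    "descriptor_kind": self.descriptor_kind,
                    "seed": self.seed,
                    "centers": self.centers.tolist(),
                },
                fh,
            )

    @classmethod
    def load(cls, path) -> "VisualVocabulary":
        with open(path, "r", encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            K=d["K"],
            centers=np.asarray(d["centers"], dtype=float),
            descriptor_kind=d["descriptor_kind"],
            seed=d["seed"],
        )


def _as_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim == 3:
        from .movement import to_grayscale

        return to_grayscale(img)
    return img.astype(float)


def extract_descriptors(
    img: np.ndarray, n_keypoints: int = 200, fast_threshold: float = 0.02
) -> np.ndarray:
    """ORB keypoint descriptors of one image as an (n, 256) float array.

    The FAST threshold is set low because trajectory images are sparse line
    drawings with weak local contrast compared to natural photographs.
    Deterministic for a given image.  Returns an empty (0, 256) array when
    the detector finds no keypoints (featureless images).
    """
    gray = _as_gray(img)
    orb = ORB(n_keypoints=n_keypoints, fast_threshold=fast_threshold)
    try:
        orb.detect_and_extract(gray)
    except (RuntimeError, IndexError, ValueError):
        return np.empty((0, 256), dtype=float)
    if orb.descriptors is None or len(orb.descriptors) == 0:
        return np.empty((0, 256), dtype=float)
    return orb.descriptors.astype(float)


def build_vocabulary(
    images: list[np.ndarray] | None,
    K: int = 500,
    seed: int = 0,
    descriptors: list[np.ndarray] | None = None,
    max_descriptors: int = 5000,
    n_init: int = 1,
) -> VisualVocabulary:
    """Learn a K-word vocabulary by k-means over pooled descriptors.

    Either raw ``images`` or precomputed per-image ``descriptors`` may be
    given (the latter avoids re-detection when vocabularies are refit per
    cross-validation fold).  If fewer than K descriptors are pooled, K is
    clamped with a warning; zero descriptors overall is fatal.  The pooled
    set is subsampled to ``max_descriptors`` (seeded) before clustering to
    bound runtime.
    """
    if K < 2:
        raise ValueError("vocabulary size K must be >= 2")
    if descriptors is None:
        if not images:
            raise ValueError("no images given")
        descriptors = [extract_descriptors(im) for im in images]
    pool = np.vstack([d for d in descriptors if len(d)]) if any(len(d) for d in descriptors) else None
    if pool is None or len(pool) == 0:
        raise RuntimeError(
            "no keypoints detected in any image; lower the detector threshold"
        )
    rng = np.random.default_rng(seed)
    if len(pool) > max_descriptors:
        idx = rng.choice(len(pool), size=max_descriptors, replace=False)
        pool = pool[idx]
    k = K
    if len(pool) < K:
        k = max(2, len(pool))
        logger.warning("only %d descriptors pooled; clamping K from %d to %d", len(pool), K, k)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # k-means duplicate-point warnings on tiny pools
        km = KMeans(n_clusters=k, random_state=seed, n_init=n_init).fit(pool)
    return VisualVocabulary(K=k, centers=km.cluster_centers_, seed=seed)


def assign_words(descriptors: np.ndarray, vocab: VisualVocabulary) -> np.ndarray:
    """Nearest-center index per descriptor (Euclidean; ties -> lowest index)."""
    if len(descriptors) == 0:
        return np.empty(0, dtype=int)
    d2 = (
        (descriptors**2).sum(axis=1)[:, None]
        - 2.0 * descriptors @ vocab.centers.T
        + (vocab.centers**2).sum(axis=1)[None, :]
    )
    return np.argmin(d2, axis=1)


def encode_bovw(
    img: np.ndarray | None,
    vocab: VisualVocabulary,
    descriptors: np.ndarray | None = None,
    norm: str = "l2",
) -> np.ndarray:
    """K-bin visual-word histogram of one image.

    ``norm`` is ``l2`` (default), ``l1`` or ``none``.  An image with no
    detectable keypoints yields an all-zero histogram with a warning.
    """
    if descriptors is None:
        descriptors = extract_descriptors(img)
    hist = np.zeros(vocab.K, dtype=float)
    if len(descriptors) == 0:
        logger.warning("no keypoints detected; emitting a zero histogram")
        return hist
    words = assign_words(descriptors, vocab)
    np.add.at(hist, words, 1.0)
    if norm == "l2":
        hist /= np.linalg.norm(hist)
    elif norm == "l1":
        hist /= hist.sum()
    elif norm != "none":
        raise ValueError(f"unknown normalization {norm!r}")
    return hist


# --------------------------------------------------------------------------
# feature vectors


@dataclass
class FeatureVector:
    """Per-episode feature vector: 15 CRF values then K histogram bins."""

    crf: np.ndarray
    bovw: np.ndarray
    subject_id: str
    label: str

    def as_array(self) -> np.ndarray:
        return np.concatenate([self.crf, self.bovw])

    def __len__(self) -> int:
        return len(self.crf) + len(self.bovw)


def assemble_feature_vector(
    crf: RegionFeatures | np.ndarray, bovw: np.ndarray, subject_id: str, label: str
) -> FeatureVector:
    crf_arr = crf.as_array() if isinstance(crf, RegionFeatures) else np.asarray(crf, dtype=float)
    if crf_arr.shape != (len(CRF_FIELDS),):
        raise ValueError(f"CRF block must have {len(CRF_FIELDS)} entries")
    return FeatureVector(
        crf=crf_arr, bovw=np.asarray(bovw, dtype=float), subject_id=subject_id, label=label
    )


def feature_column_names(K: int) -> list[str]:
    return list(CRF_FIELDS) + [f"bovw_{i:03d}" for i in range(K)]


def feature_frame(vectors: list[FeatureVector]):
    """Feature vectors as a pandas DataFrame (subject_id, label, features...)."""
    import pandas as pd

    if not vectors:
        raise ValueError("no feature vectors")
    k = len(vectors[0].bovw)
    for v in vectors:
        if len(v.bovw) != k:
            raise ValueError("inconsistent BoVW length across dataset")
    rows = [v.as_array() for v in vectors]
    df = pd.DataFrame(rows, columns=feature_column_names(k))
    df.insert(0, "label", [v.label for v in vectors])
    df.insert(0, "subject_id", [v.subject_id for v in vectors])
    return df
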