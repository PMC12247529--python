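"""Preprocessing: spatial resampling, skull stripping, intensity normalization
and mask binarization.

The pipeline standardizes heterogeneous clinical FLAIR scans before lesion
segmentation: voxel spacing is harmonized by spline interpolation (labels by
nearest neighbour, so masks stay binary), non-brain voxels are removed with a
deterministic Otsu + largest-connected-component stripper, and intensities are
z-scored within the brain so that scanner units cancel across subjects.

Masks are binary after every stage; normalization is idempotent and invariant
under positive affine intensity transforms.
"""

from __future__ import annotations

import logging
from contextlib import contextmanager
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import DegenerateInputError
from .io import LesionMask, Volume

__all__ = [
    "PreprocessConfig",
    "Preprocessor",
    "resample",
    "resample_mask",
    "skull_strip",
    "normalize_intensity",
    "binarize_mask",
    "preprocess_case",
]

log = logging.getLogger(__name__)

_FACE_CONNECTIVITY = ndimage.generate_binary_structure(3, 1)


@dataclass
class PreprocessConfig:
    """Configuration of the preprocessing pipeline.

    ``target_spacing=None`` keeps the native grid (no resampling). The
    default 1 mm isotropic target is a convention, configurable per study.
    """

    target_spacing: tuple[float, float, float] | None = (1.0, 1.0, 1.0)
    image_interp_order: int = 3
    mask_interp: str = "nearest"
    normalization: str = "zscore_brain"  # zscore_brain | zscore_global | none
    skullstrip_method: str = "otsu_cc"  # otsu_cc | none
    binarize_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.target_spacing is not None:
            ts = np.asarray(self.target_spacing, dtype=float)
            if ts.shape != (3,) or np.any(ts <= 0):
                raise ValueError(f"target_spacing must be three positive values, got {self.target_spacing}")
        if self.image_interp_order not in (0, 1, 2, 3):
            raise ValueError(f"image_interp_order must be in 0..3, got {self.image_interp_order}")
        if self.mask_interp != "nearest":
            raise ValueError("only nearest-neighbour mask interpolation preserves labels")
        if self.normalization not in ("zscore_brain", "zscore_global", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.skullstrip_method not in ("otsu_cc", "none"):
            raise ValueError(f"unknown skullstrip_method {self.skullstrip_method!r}")
        if not 0.0 < float(self.binarize_threshold) < 1.0:
            raise ValueError("binarize_threshold must lie in (0, 1)")


def _resampled_shape(shape: Sequence[int], spacing: np.ndarray, target: np.ndarray) -> np.ndarray:
    """round(old_shape * old_spacing / new_spacing), at least 1 per axis."""
    new = np.rint(np.asarray(shape) * np.asarray(spacing) / np.asarray(target))
    return np.maximum(1, new.astype(int))


def _zoom_to(data: np.ndarray, new_shape: np.ndarray, order: int) -> np.ndarray:
    factors = new_shape / np.asarray(data.shape)
    return ndimage.zoom(data, factors, order=order, mode="nearest", grid_mode=True)


def _rescaled_affine(v: Volume, target: np.ndarray) -> np.ndarray:
    affine = v.affine.copy()
    affine[:3, :3] = v.affine[:3, :3] / v.spacing[np.newaxis, :] * target[np.newaxis, :]
    return affine


def resample(v: Volume, target_spacing, order: int = 3) -> Volume:
    """Resample a volume to ``target_spacing`` (mm) with spline order ``order``.

    The new shape per axis is round(old_shape * old_spacing / new_spacing),
    never below 1; direction cosines are preserved and the origin is kept, so
    the world extent is preserved to within a voxel.
    """
    target = np.asarray(target_spacing, dtype=float)
    if target.shape != (3,) or np.any(target <= 0):
        raise ValueError(f"target spacing must be three positive values, got {target_spacing}")
    if order not in (0, 1, 2, 3):
        raise ValueError(f"interpolation order must be in 0..3, got {order}")
    new_shape = _resampled_shape(v.shape, v.spacing, target)
    if tuple(new_shape) == v.shape and np.allclose(target, v.spacing):
        return Volume(v.data.copy(), v.affine.copy(), axial_axis=v.axial_axis)
    data = _zoom_to(np.asarray(v.data, dtype=float), new_shape, order)
    out = Volume(data, _rescaled_affine(v, target), axial_axis=v.axial_axis)
    log.debug("resample: %s @ %s mm -> %s @ %s mm", v.shape, v.spacing, out.shape, out.spacing)
    return out


def resample_mask(m: LesionMask, target_spacing) -> LesionMask:
    """Nearest-neighbour resampling of a binary mask (labels preserved)."""
    target = np.asarray(target_spacing, dtype=float)
    if np.any(target <= 0):
        raise ValueError("target spacing must be strictly positive")
    new_shape = _resampled_shape(m.shape, m.spacing, target)
    if tuple(new_shape) == m.shape and np.allclose(target, m.spacing):
        return LesionMask(m.data.copy(), m.affine.copy(), axial_axis=m.axial_axis)
    data = _zoom_to(m.data, new_shape, order=0)
    geom = _rescaled_affine(Volume(m.data, m.affine, axial_axis=m.axial_axis), target)
    return LesionMask(data, geom, axial_axis=m.axial_axis)


def skull_strip(v: Volume) -> tuple[Volume, np.ndarray]:
    """Remove non-brain voxels.

    Otsu threshold on intensities, morphological closing (radius-1
    structuring element), largest face-connected component, hole filling.
    Returns the stripped volume (outside-brain voxels set to 0) and the
    boolean brain mask, which is a single connected component.
    """
    data = np.asarray(v.data, dtype=float)
    if data.max() == data.min():
        raise DegenerateInputError("constant image: no threshold separates brain from background")
    fg = data > threshold_otsu(data)
    fg = ndimage.binary_closing(fg, structure=_FACE_CONNECTIVITY)
    labels, n = ndimage.label(fg, structure=_FACE_CONNECTIVITY)
    if n == 0:
        raise DegenerateInputError("no foreground component found above the Otsu threshold")
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    brain = ndimage.binary_fill_holes(labels == largest)
    stripped = np.where(brain, v.data, 0)
    return v.with_data(stripped), brain


def normalize_intensity(v: Volume, brain_mask: np.ndarray) -> Volume:
    """Z-score intensities within the brain mask; zero elsewhere.

    After normalization the in-mask mean is 0 and the standard deviation 1.
    Idempotent, and invariant under x -> a*x + b with a > 0.
    """
    mask = np.asarray(brain_mask).astype(bool)
    if mask.shape != v.shape:
        raise DegenerateInputError(f"brain mask shape {mask.shape} != volume shape {v.shape}")
    if not mask.any():
        raise DegenerateInputError("empty brain mask")
    vals = np.asarray(v.data, dtype=float)[mask]
    sd = vals.std()
    if sd == 0:
        raise DegenerateInputError("zero intensity variance within the brain mask")
    out = np.zeros(v.shape, dtype=float)
    out[mask] = (vals - vals.mean()) / sd
    return v.with_data(out)


def binarize_mask(raw: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary mask: 1 where ``raw > threshold``, else 0 (uint8)."""
    raw = np.asarray(raw)
    if not np.isfinite(raw).all():
        raise ValueError("mask contains non-finite values")
    return (raw > threshold).astype(np.uint8)


@contextmanager
def _stage(name: str):
    # annotate propagated errors with the failing pipeline stage
    try:
        yield
    except Exception as exc:
        exc.args = (f"[{name}] {exc.args[0] if exc.args else ''}",) + exc.args[1:]
        raise


def preprocess_case(
    v: Volume, m: LesionMask, cfg: PreprocessConfig | None = None
) -> tuple[Volume, LesionMask]:
    """Run the full preprocessing pipeline on a voxel-aligned image/mask pair.

    Stages, in order: resample (image with ``cfg.image_interp_order``, mask
    with nearest neighbour) -> skull strip -> intensity normalization ->
    mask binarization. Errors from a stage are re-raised with the stage name
    prepended.
    """
    cfg = cfg or PreprocessConfig()
    m.check_aligned(v)

    with _stage("resample"):
        if cfg.target_spacing is not None:
            v = resample(v, cfg.target_spacing, cfg.image_interp_order)
            m = resample_mask(m, cfg.target_spacing)

    with _stage("skull_strip"):
        if cfg.skullstrip_method == "otsu_cc":
            v, brain = skull_strip(v)
        else:
            brain = np.ones(v.shape, dtype=bool)

    with _stage("normalize"):
        if cfg.normalization == "zscore_brain":
            v = normalize_intensity(v, brain)
        elif cfg.normalization == "zscore_global":
            v = normalize_intensity(v, np.ones(v.shape, dtype=bool))

    with _stage("binarize"):
        m = LesionMask(
            binarize_mask(m.data, cfg.binarize_threshold),
            v.affine.copy(),
            axial_axis=v.axial_axis,
        )
    return v, m


class Preprocessor(TransformerMixin, BaseEstimator):
    """Stateless sklearn-style transformer over (Volume, LesionMask) pairs.

    ``transform`` maps a sequence of voxel-aligned pairs through
    :func:`preprocess_case` with this transformer's parameters.
    """

    def __init__(
        self,
        target_spacing=(1.0, 1.0, 1.0),
        image_interp_order: int = 3,
        normalization: str = "zscore_brain",
        skullstrip_method: str = "otsu_cc",
        binarize_threshold: float = 0.5,
    ):
        self.target_spacing = target_spacing
        self.image_interp_order = image_interp_order
        self.normalization = normalization
        self.skullstrip_method = skullstrip_method
        self.binarize_threshold = binarize_threshold

    def _config(self) -> PreprocessConfig:
        return PreprocessConfig(
            target_spacing=self.target_spacing,
            image_interp_order=self.image_interp_order,
            normalization=self.normalization,
            skullstrip_method=self.skullstrip_method,
            binarize_threshold=self.binarize_threshold,
        )

    def fit(self, X, y=None):
        self._config()  # validate parameters
        self.n_features_in_ = 0
        return self

    def transform(self, X):
        cfg = self._config()
        return [preprocess_case(v, m, cfg) for v, m in X]
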