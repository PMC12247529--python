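"""Lesion-focused axial slice selection and slab compilation.

A 3D scan contains many axial slices but only a few carry visible lesion;
training a segmenter on everything dilutes the signal. This module scores
each axial slice, keeps the top-k (five by default), and compiles the kept
slices into a new, smaller 3D volume ("slab") that is enriched in lesion.

Two scoring criteria are provided, because both readings are defensible:

``lesion_area``
    per-slice count of mask-positive voxels (the default whenever a
    ground-truth mask is available). An intensity-weighted variant,
    ``visibility="intensity"``, sums the masked image intensity instead.
``peak_intensity``
    per-slice maximum image intensity; usable mask-free at inference time
    (FLAIR lesions are hyperintense).

Ties rank the lower slice index first; selected slices are kept in
anatomical (ascending-index) order in the slab.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ConfigurationError
from .io import LesionMask, Volume

__all__ = [
    "SliceRanking",
    "SliceSelector",
    "score_slices",
    "select_top_k",
    "extract_slab",
    "select_case",
]


@dataclass
class SliceRanking:
    """Per-slice scores and (once selected) the kept slice indices.

    ``scores[z]`` is the score of axial slice ``z``; ``selected`` is an
    ascending array of the top-``k`` slice indices, ties broken toward the
    lower index.
    """

    scores: np.ndarray
    criterion: str
    k: int | None = None
    selected: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1 or self.scores.size == 0:
            raise ValueError("scores must be a non-empty 1-D sequence")
        if self.selected is not None:
            self.selected = np.asarray(self.selected, dtype=int)

    def to_frame(self) -> pd.DataFrame:
        """Per-case report: one row per slice, with score and selection flag."""
        sel = set() if self.selected is None else set(self.selected.tolist())
        return pd.DataFrame(
            {
                "slice": np.arange(self.scores.size),
                "score": self.scores,
                "selected": [int(z in sel) for z in range(self.scores.size)],
            }
        )


def _per_slice(data: np.ndarray, axial_axis: int) -> np.ndarray:
    return np.moveaxis(data, axial_axis, 0).reshape(data.shape[axial_axis], -1)


def score_slices(
    v: Volume,
    m: LesionMask | None = None,
    criterion: str = "lesion_area",
    visibility: str = "count",
) -> SliceRanking:
    """Score every axial slice.

    ``lesion_area``: number of mask-1 voxels per slice (``visibility="count"``)
    or sum of masked image intensity (``visibility="intensity"``).
    ``peak_intensity``: maximum intensity per slice; no mask needed.
    """
    if criterion == "peak_intensity":
        scores = _per_slice(np.asarray(v.data, dtype=float), v.axial_axis).max(axis=1)
    elif criterion == "lesion_area":
        if m is None:
            raise ConfigurationError("lesion_area scoring requires a lesion mask")
        m.check_aligned(v)
        if visibility == "count":
            scores = _per_slice(m.data, v.axial_axis).sum(axis=1).astype(float)
        elif visibility == "intensity":
            weighted = np.asarray(v.data, dtype=float) * m.data
            scores = _per_slice(weighted, v.axial_axis).sum(axis=1)
        else:
            raise ConfigurationError(f"unknown visibility measure {visibility!r}")
    else:
        raise ConfigurationError(f"unknown slice criterion {criterion!r}")
    return SliceRanking(scores=scores, criterion=criterion)


def select_top_k(ranking: SliceRanking, k: int) -> SliceRanking:
    """Indices of the k largest scores, ties toward the lower index,
    returned in ascending slice order. k beyond the slice count selects all.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    # stable sort on descending score keeps lower indices first among ties
    order = np.argsort(-ranking.scores, kind="stable")
    selected = np.sort(order[: min(k, ranking.scores.size)])
    return replace(ranking, k=int(k), selected=selected)


def extract_slab(
    v: Volume, m: LesionMask | None, selected
) -> tuple[Volume, LesionMask | None]:
    """Compile the selected axial slices into a new 3D volume (and mask).

    Slice ``j`` of the slab equals slice ``selected[j]`` of the input.
    In-plane geometry is unchanged; the axial translation is moved to the
    first selected slice's world position, and the nominal axial spacing is
    retained even when the selected slices are non-adjacent (true inter-slice
    gaps belong in the per-case selection report).
    """
    selected = np.asarray(selected, dtype=int)
    if selected.size == 0:
        raise ValueError("no slices selected")
    if np.any(np.diff(selected) <= 0):
        raise ValueError(f"selected indices must be strictly ascending, got {selected}")
    if selected.min() < 0 or selected.max() >= v.n_slices:
        raise IndexError(
            f"selected indices {selected} out of bounds for {v.n_slices} axial slices"
        )
    affine = v.affine.copy()
    affine[:3, 3] += v.affine[:3, v.axial_axis] * selected[0]
    slab_v = Volume(
        np.take(v.data, selected, axis=v.axial_axis), affine, axial_axis=v.axial_axis
    )
    slab_m = None
    if m is not None:
        m.check_aligned(v)
        slab_m = LesionMask(
            np.take(m.data, selected, axis=v.axial_axis),
            affine.copy(),
            axial_axis=v.axial_axis,
        )
    return slab_v, slab_m


def select_case(
    v: Volume,
    m: LesionMask | None,
    criterion: str = "lesion_area",
    k: int = 5,
    visibility: str = "count",
) -> tuple[Volume, LesionMask | None, SliceRanking]:
    """score_slices -> select_top_k -> extract_slab, returning the ranking too."""
    ranking = select_top_k(score_slices(v, m, criterion, visibility), k)
    slab_v, slab_m = extract_slab(v, m, ranking.selected)
    return slab_v, slab_m, ranking


class SliceSelector(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer: (Volume, LesionMask) pairs -> lesion-rich slabs.

    After ``transform``, ``rankings_`` holds one :class:`SliceRanking` per case.
    """

    def __init__(self, criterion: str = "lesion_area", k: int = 5, visibility: str = "count"):
        self.criterion = criterion
        self.k = k
        self.visibility = visibility

    def fit(self, X, y=None):
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        self.n_features_in_ = 0
        return self

    def transform(self, X):
        out, rankings = [], []
        for v, m in X:
            slab_v, slab_m, ranking = select_case(
                v, m, criterion=self.criterion, k=self.k, visibility=self.visibility
            )
            out.append((slab_v, slab_m))
            rankings.append(ranking)
        self.rankings_ = rankings
        return out
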