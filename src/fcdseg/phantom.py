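"""FLAIR-like 3D brain phantoms with ground-truth lesion masks.

The generator emulates the statistical structure the pipeline assumes of a
clinical FLAIR cohort, at desk scale: a bright ellipsoidal "brain" in a dark
background; one or more hyperintense cortically-placed lesion blobs spanning
a few axial slices and occupying a small fraction of the volume; per-case
variation in field of view, voxel spacing and brain size; and a frontal
placement bias (lesion centers fall in the anterior half with probability
0.624, matching the frontal-lobe prevalence reported for FCD type II
cohorts). Anatomy, MRI physics (bias fields, partial volume) and healthy
controls are deliberately out of scope: the phantoms exist to exercise
skull stripping, normalization, slice ranking, segmentation baselines and
the metrics, not to look like a brain.

Everything is reproducible bitwise from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cases import Case, CaseCollection
from .exceptions import LesionPlacementError
from .io import LesionMask, Volume, write_volume

__all__ = ["PhantomSpec", "CohortSpec", "PhantomInfo", "generate_phantom", "generate_cohort"]


@dataclass
class PhantomSpec:
    """Geometry and intensity model of one phantom, in voxel units.

    ``lesion_slab_extent`` is the number of axial slices a lesion spans;
    ``lesion_contrast`` is the multiplicative hyperintensity factor (> 1,
    FLAIR-like); ``frontal_bias`` is the probability that a lesion center
    falls in the anterior half of the first in-plane axis.
    """

    shape: tuple[int, int, int] = (48, 56, 36)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_axes: tuple[float, float, float] = (16.5, 20.5, 13.0)
    tissue_mean: float = 100.0
    tissue_sd: float = 5.0
    lesion_count: int = 1
    lesion_radius_range: tuple[float, float] = (4.0, 5.0)
    lesion_contrast: float = 1.5
    lesion_slab_extent: int = 5
    frontal_bias: float = 0.624
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lesion_contrast <= 1:
            raise ValueError("lesion_contrast must exceed 1 (FLAIR hyperintensity)")
        if not 0.0 <= self.frontal_bias <= 1.0:
            raise ValueError("frontal_bias must lie in [0, 1]")
        if self.lesion_count < 0:
            raise ValueError("lesion_count must be >= 0")
        lo, hi = self.lesion_radius_range
        if not 0 < lo <= hi:
            raise ValueError("lesion_radius_range must be positive and ordered")
        if hi >= min(self.brain_axes[:2]) / 2:
            raise ValueError("lesion radius too large to fit inside the brain ellipsoid")
        if self.lesion_slab_extent < 1:
            raise ValueError("lesion_slab_extent must be >= 1")


@dataclass
class PhantomInfo:
    """Generator-side ground truth beyond the mask itself."""

    brain_mask: np.ndarray
    lesion_centers: list[tuple[float, float, float]]
    lesion_radii: list[float]
    lesion_axial_semi: float
    lesion_voxels: int


def _ellipsoid_field(shape, center, axes) -> np.ndarray:
    """Normalized squared ellipsoid distance; <= 1 is inside."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center, axes):
        acc = acc + ((g - c) / a) ** 2
    return acc


def generate_phantom(
    spec: PhantomSpec, with_info: bool = False
) -> tuple[Volume, LesionMask] | tuple[Volume, LesionMask, PhantomInfo]:
    """Generate one phantom volume and its paired ground-truth mask.

    Lesions are axis-aligned ellipsoidal blobs of brain tissue scaled by
    ``lesion_contrast``: in-plane radius drawn from ``lesion_radius_range``,
    axial semi-axis set so the blob spans ``lesion_slab_extent`` slices,
    center placed at 40-70% of the brain's in-plane radius ("cortical")
    with the anterior/posterior side drawn from ``frontal_bias``. Placement
    is rejected (bounded retries) if any lesion voxel leaves the brain or
    touches another lesion.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.shape)
    center = tuple((s - 1) / 2.0 for s in shape)
    a, b, c = spec.brain_axes

    brain = _ellipsoid_field(shape, center, spec.brain_axes) <= 1.0
    data = np.zeros(shape, dtype=float)
    data[brain] = spec.tissue_mean + rng.normal(0.0, spec.tissue_sd, int(brain.sum()))

    mask = np.zeros(shape, dtype=np.uint8)
    zsemi = (spec.lesion_slab_extent - 1) / 2.0 + 0.49
    centers: list[tuple[float, float, float]] = []
    radii: list[float] = []
    for _ in range(spec.lesion_count):
        placed = False
        for _try in range(200):
            dz = rng.uniform(-0.30, 0.30) * c
            z0 = center[2] + dz
            scale = math.sqrt(max(0.0, 1.0 - (dz / c) ** 2))
            r = rng.uniform(*spec.lesion_radius_range)
            anterior = rng.random() < spec.frontal_bias
            theta = rng.uniform(math.pi / 2, 3 * math.pi / 2) if anterior else rng.uniform(-math.pi / 2, math.pi / 2)
            rho = rng.uniform(0.40, 0.70)
            x0 = center[0] + rho * a * scale * math.cos(theta)
            y0 = center[1] + rho * b * scale * math.sin(theta)
            blob = _ellipsoid_field(shape, (x0, y0, z0), (r, r, zsemi)) <= 1.0
            # keep the lesion strictly interior to the brain, non-overlapping
            inside = _ellipsoid_field(shape, center, spec.brain_axes)[blob] <= 0.97
            if blob.any() and inside.all() and not (mask[blob] == 1).any():
                mask[blob] = 1
                data[blob] *= spec.lesion_contrast
                centers.append((x0, y0, z0))
                radii.append(r)
                placed = True
                break
        if not placed:
            raise LesionPlacementError(
                f"could not place a lesion of radius <= {spec.lesion_radius_range[1]} "
                "inside the brain after 200 attempts"
            )

    data += rng.normal(0.0, spec.noise_sd, shape)
    affine = np.diag((*spec.spacing, 1.0))
    vol = Volume(data, affine)
    les = LesionMask(mask, affine.copy())
    if with_info:
        info = PhantomInfo(
            brain_mask=brain,
            lesion_centers=centers,
            lesion_radii=radii,
            lesion_axial_semi=zsemi,
            lesion_voxels=int(mask.sum()),
        )
        return vol, les, info
    return vol, les


@dataclass
class CohortSpec:
    """Per-case sampling ranges for a heterogeneous cohort, in physical units.

    Fields of view and voxel spacings vary per case (scans "vary in size")
    while the physical brain size stays nearly constant, as it does across
    adult subjects. Lesions have a 4-5 mm in-plane radius and span about
    5 mm axially.
    """

    fov_mm: tuple[tuple[float, float], ...] = ((44.0, 52.0), (52.0, 60.0), (32.0, 40.0))
    spacing_choices: tuple[tuple[float, float, float], ...] = (
        (1.0, 1.0, 1.0),
        (0.9, 0.9, 1.1),
        (1.1, 1.1, 0.9),
    )
    brain_semi_axes_mm: tuple[tuple[float, float], ...] = (
        (15.9, 17.1),
        (19.8, 21.2),
        (12.5, 13.5),
    )
    lesion_radius_mm: tuple[float, float] = (4.0, 5.0)
    lesion_extent_mm: float = 5.0
    lesion_count: int = 1
    lesion_contrast: float = 1.5
    frontal_bias: float = 0.624
    tissue_mean: float = 100.0
    tissue_sd: float = 5.0
    noise_sd: float = 5.0

    def draw_spec(self, rng: np.random.Generator) -> PhantomSpec:
        spacing = self.spacing_choices[rng.integers(len(self.spacing_choices))]
        fov = [rng.uniform(lo, hi) for lo, hi in self.fov_mm]
        shape = tuple(int(round(f / s)) for f, s in zip(fov, spacing))
        brain = tuple(
            rng.uniform(lo, hi) / s for (lo, hi), s in zip(self.brain_semi_axes_mm, spacing)
        )
        r_lo, r_hi = (r / spacing[0] for r in self.lesion_radius_mm)
        return PhantomSpec(
            shape=shape,
            spacing=spacing,
            brain_axes=brain,
            tissue_mean=self.tissue_mean,
            tissue_sd=self.tissue_sd,
            lesion_count=self.lesion_count,
            lesion_radius_range=(r_lo, r_hi),
            lesion_contrast=self.lesion_contrast,
            lesion_slab_extent=max(3, int(round(self.lesion_extent_mm / spacing[2]))),
            frontal_bias=self.frontal_bias,
            noise_sd=self.noise_sd,
            seed=int(rng.integers(2**31)),
        )


def generate_cohort(
    n: int, out_dir, seed: int = 0, cohort: CohortSpec | None = None
) -> CaseCollection:
    """Generate ``n`` phantom cases, write NIfTI pairs plus a TSV manifest.

    The manifest records, per case, the true lesion voxel count and lesion
    center indices alongside the file paths. Reproducible from ``seed``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    cohort = cohort or CohortSpec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(int(seed))

    cases, extra_rows = [], []
    for i in range(n):
        spec = cohort.draw_spec(rng)
        vol, mask, info = generate_phantom(spec, with_info=True)
        case_id = f"case_{i:03d}"
        img_path = out_dir / f"{case_id}_flair.nii.gz"
        msk_path = out_dir / f"{case_id}_mask.nii.gz"
        write_volume(vol, img_path)
        write_volume(mask, msk_path)
        cases.append(Case(case_id, img_path, msk_path))
        extra_rows.append(
            {
                "case_id": case_id,
                "lesion_voxels": info.lesion_voxels,
                "lesion_centers": ";".join(
                    ",".join(f"{x:.2f}" for x in ctr) for ctr in info.lesion_centers
                ),
            }
        )

    collection = CaseCollection(
        cases=tuple(cases), provenance="synthetic", extra=pd.DataFrame(extra_rows)
    )
    collection.to_manifest(out_dir / "manifest.tsv")
    return collection
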