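"""Shared grid primitives.

All volumes in the pipeline live on a single voxel grid with physical
spacing in millimetres; physical position of voxel ``(i, j, k)`` is
``(i * sx, j * sy, k * sz)``. Nothing in the package resamples: stages
that consume pairs of volumes assert grid equality and fail hard on
mismatch.

Label codes for the tissue/lobe label volume:

======================  ====
background              0
lateral ventricle       1
white matter, frontal   2
white matter, parietal  3
white matter, occipital 4
white matter, temporal  5
cortical gray matter    6
======================  ====

Axis convention: axis 0 = left-right, axis 1 = posterior-anterior
(larger index is more anterior), axis 2 = inferior-superior. Axial
slices are planes of constant axis-2 index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BACKGROUND = 0
VENTRICLE = 1
WM_FRONTAL = 2
WM_PARIETAL = 3
WM_OCCIPITAL = 4
WM_TEMPORAL = 5
CORTICAL_GM = 6

WM_LABELS = (WM_FRONTAL, WM_PARIETAL, WM_OCCIPITAL, WM_TEMPORAL)

LABEL_NAMES = {
    BACKGROUND: "background",
    VENTRICLE: "ventricle",
    WM_FRONTAL: "wm-frontal",
    WM_PARIETAL: "wm-parietal",
    WM_OCCIPITAL: "wm-occipital",
    WM_TEMPORAL: "wm-temporal",
    CORTICAL_GM: "cortical-gm",
}

# integer codes used when a ZoneSet is flattened to a single labelmap
ZONE_PV = 1
ZONE_DEEP = 2
ZONE_IC = 3


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


@dataclass
class Volume:
    """A 3-D scalar/label/mask volume with physical voxel spacing (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3:
            raise ValueError("spacing must have three components")
        if not all(np.isfinite(s) and s > 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive and finite, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def same_grid(self, other: "Volume") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)

    def astype_bool(self) -> "Volume":
        return Volume(self.data.astype(bool), self.spacing)


def require_same_grid(*volumes: Volume, context: str = "") -> None:
    """Raise :class:`GridMismatchError` unless all volumes share one grid."""
    first = volumes[0]
    for v in volumes[1:]:
        if not first.same_grid(v):
            where = f" in {context}" if context else ""
            raise GridMismatchError(
                f"grid mismatch{where}: shape/spacing {first.shape}/{first.spacing} "
                f"vs {v.shape}/{v.spacing}"
            )


def wm_mask(labels: Volume) -> np.ndarray:
    """Boolean array of all white-matter voxels (any lobe)."""
    return np.isin(labels.data, WM_LABELS)


def label_histogram(labels: Volume) -> dict[int, int]:
    """Voxel count per label code present in the volume."""
    codes, counts = np.unique(labels.data, return_counts=True)
    return {int(c): int(n) for c, n in zip(codes, counts)}


def physical_coords(shape: tuple[int, int, int], spacing: tuple[float, float, float]):
    """Per-axis physical coordinate grids (mm), broadcastable to ``shape``."""
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)
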