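"""Depth zoning of white matter and the anterior/posterior partition.

White matter is split into three a-priori depth zones:

* **periventricular** — within ``pv_width_mm`` (default 5 mm) of the
  lateral-ventricle wall, the ventricle itself excluded;
* **infracortical** — within ``ic_width_mm`` (default 5 mm, 2 mm
  selectable) of the internal cortical gray-matter edge, where U-fibers
  run;
* **deep** — all remaining white matter, housing the long association
  fasciculi.

Distances are Euclidean in physical millimetres via a spacing-aware
distance transform, so anisotropic grids behave correctly. Band
membership is inclusive (``distance <= width``). Where the two border
bands overlap (thin white matter), precedence decides; the default gives
the contested voxels to the periventricular band.

The anterior/posterior partition assigns frontal white matter to the
anterior compartment and parietal + occipital white matter to the
posterior compartment; temporal white matter belongs to neither.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import (
    CORTICAL_GM,
    VENTRICLE,
    WM_FRONTAL,
    WM_OCCIPITAL,
    WM_PARIETAL,
    ZONE_DEEP,
    ZONE_IC,
    ZONE_PV,
    Volume,
    wm_mask,
)

ZONE_NAMES = ("periventricular", "deep", "infracortical")


@dataclass
class ZoneParams:
    """Widths (mm) of the border bands and their overlap precedence."""

    pv_width_mm: float = 5.0
    ic_width_mm: float = 5.0
    precedence: str = "periventricular"  # or "infracortical"

    def __post_init__(self) -> None:
        if self.pv_width_mm < 0 or self.ic_width_mm < 0:
            raise ValueError("band widths must be >= 0")
        if self.precedence not in ("periventricular", "infracortical"):
            raise ValueError(f"unknown precedence {self.precedence!r}")


@dataclass
class ZoneSet:
    """Disjoint depth-zone masks partitioning white matter, plus the
    anterior/posterior lobe partition. All masks share one grid."""

    periventricular: Volume
    deep: Volume
    infracortical: Volume
    anterior: Volume
    posterior: Volume
    wm: Volume

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.wm.spacing

    def by_name(self, name: str) -> Volume:
        return {
            "periventricular": self.periventricular,
            "deep": self.deep,
            "infracortical": self.infracortical,
            "anterior": self.anterior,
            "posterior": self.posterior,
        }[name]

    def labelmap(self) -> Volume:
        """Single integer labelmap: 1 = PV, 2 = deep, 3 = infracortical."""
        out = np.zeros(self.wm.shape, dtype=np.int8)
        out[self.periventricular.data] = ZONE_PV
        out[self.deep.data] = ZONE_DEEP
        out[self.infracortical.data] = ZONE_IC
        return Volume(out, self.spacing)

    def validate(self) -> None:
        """Assert the partition invariants (disjoint, exhaustive over WM)."""
        pv, dp, ic = (self.periventricular.data, self.deep.data, self.infracortical.data)
        if (pv & dp).any() or (pv & ic).any() or (dp & ic).any():
            raise AssertionError("depth zones overlap")
        if not ((pv | dp | ic) == self.wm.data).all():
            raise AssertionError("depth zones do not cover white matter")
        if (self.anterior.data & self.posterior.data).any():
            raise AssertionError("anterior and posterior masks overlap")


def _distance_to(target: np.ndarray, spacing) -> np.ndarray:
    """mm distance from every voxel to the nearest True voxel of ``target``."""
    if not target.any():
        return np.full(target.shape, np.inf)
    return ndimage.distance_transform_edt(~target, sampling=spacing)


def periventricular_mask(labels: Volume, width_mm: float = 5.0) -> Volume:
    """White matter within ``width_mm`` of the lateral-ventricle wall.

    The ventricle voxels themselves are excluded; an empty ventricle
    (or zero width) yields an empty mask.
    """
    vent = labels.data == VENTRICLE
    dist = _distance_to(vent, labels.spacing)
    mask = wm_mask(labels) & ~vent & (dist <= width_mm)
    return Volume(mask, labels.spacing)


def infracortical_mask(labels: Volume, width_mm: float = 5.0) -> Volume:
    """White matter within ``width_mm`` of the cortical gray-matter edge."""
    gm = labels.data == CORTICAL_GM
    if not gm.any():
        raise ValueError("no cortical gray matter present: cannot build the infracortical band")
    dist = _distance_to(gm, labels.spacing)
    mask = wm_mask(labels) & (dist <= width_mm)
    return Volume(mask, labels.spacing)


def anterior_posterior_masks(labels: Volume) -> tuple[Volume, Volume]:
    """Anterior (frontal WM) and posterior (parietal + occipital WM) masks.

    Temporal white matter is deliberately excluded from both.
    """
    anterior = labels.data == WM_FRONTAL
    posterior = (labels.data == WM_PARIETAL) | (labels.data == WM_OCCIPITAL)
    return Volume(anterior, labels.spacing), Volume(posterior, labels.spacing)


def zone_partition(labels: Volume, params: ZoneParams | None = None) -> ZoneSet:
    """Partition white matter into the three depth zones.

    ``deep`` is defined by subtraction: white matter minus both border
    bands. Overlap between the bands is resolved by ``params.precedence``.
    """
    params = params or ZoneParams()
    pv = periventricular_mask(labels, params.pv_width_mm)
    ic = infracortical_mask(labels, params.ic_width_mm)
    if params.precedence == "periventricular":
        ic = Volume(ic.data & ~pv.data, labels.spacing)
    else:
        pv = Volume(pv.data & ~ic.data, labels.spacing)
    wm = wm_mask(labels)
    deep = Volume(wm & ~pv.data & ~ic.data, labels.spacing)
    anterior, posterior = anterior_posterior_masks(labels)
    zones = ZoneSet(
        periventricular=pv,
        deep=deep,
        infracortical=ic,
        anterior=anterior,
        posterior=posterior,
        wm=Volume(wm, labels.spacing),
    )
    zones.validate()
    return zones
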