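"""Lesion volumetrics: zonal leukoaraiosis fractions, lacunae, stroke.

Leukoaraiosis load is expressed as a percentage of regional white
matter: 100 * volume(LA ∩ region) / volume(region). Lacunae are small
cavitated infarcts gated to equivalent diameter >= 2 mm and < 15 mm and
required to persist across a minimum number of axial slices; each
retained lacuna is volumetrized with the sphere formula (4/3)π r³ on its
equivalent diameter. Stroke volume follows the two-diameter caliper
convention: d1 * d2 * (number of slices * slice thickness), with an
optional correction factor (0.5 reproduces the ABC/2 convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import ZONE_DEEP, ZONE_IC, ZONE_PV, Volume, require_same_grid
from .segment import STRUCT_26
from .zoning import ZoneSet

LACUNA_MIN_DIAMETER_MM = 2.0
LACUNA_MAX_DIAMETER_MM = 15.0

_ZONE_TAGS = {ZONE_PV: "periventricular", ZONE_DEEP: "deep", ZONE_IC: "infracortical"}


@dataclass
class LAProfile:
    """Leukoaraiosis load of one subject, total and by region (%)."""

    total_pct: float
    pv_pct: float
    deep_pct: float
    ic_pct: float
    anterior_pct: float
    posterior_pct: float
    la_volume_mm3: float
    wm_volume_mm3: float

    def as_dict(self) -> dict[str, float]:
        return {
            "total_pct": self.total_pct,
            "pv_pct": self.pv_pct,
            "deep_pct": self.deep_pct,
            "ic_pct": self.ic_pct,
            "anterior_pct": self.anterior_pct,
            "posterior_pct": self.posterior_pct,
            "la_volume_mm3": self.la_volume_mm3,
            "wm_volume_mm3": self.wm_volume_mm3,
        }


@dataclass
class Lacuna:
    """One retained lacunar lesion."""

    centroid_mm: tuple[float, float, float]
    equivalent_diameter_mm: float
    slice_extent: int
    zone: str
    volume_mm3: float


@dataclass
class LesionSet:
    """Detected lacunae with their summed sphere-formula volume."""

    lacunae: list[Lacuna] = field(default_factory=list)

    @property
    def summed_volume_mm3(self) -> float:
        return float(sum(l.volume_mm3 for l in self.lacunae))

    def __len__(self) -> int:
        return len(self.lacunae)


class DiameterGateError(ValueError):
    """A diameter outside the lacunar gate [2, 15) mm."""


def la_fraction(la: Volume, region: Volume, spacing=None) -> float:
    """LA volume as a percentage of a region's white-matter volume."""
    require_same_grid(la, region, context="la_fraction")
    n_region = int(region.data.astype(bool).sum())
    if n_region == 0:
        raise ValueError("empty region: fraction undefined")
    n_la = int((la.data.astype(bool) & region.data.astype(bool)).sum())
    return 100.0 * n_la / n_region


def la_profile(la: Volume, zones: ZoneSet) -> LAProfile:
    """Fractions for the three depth zones, the anterior/posterior
    partition and the whole white matter; absolute volumes in mm³."""
    vox = la.voxel_volume_mm3
    la_in_wm = Volume(la.data.astype(bool) & zones.wm.data, la.spacing)
    return LAProfile(
        total_pct=la_fraction(la_in_wm, zones.wm),
        pv_pct=la_fraction(la_in_wm, zones.periventricular),
        deep_pct=la_fraction(la_in_wm, zones.deep),
        ic_pct=la_fraction(la_in_wm, zones.infracortical),
        anterior_pct=la_fraction(la_in_wm, zones.anterior),
        posterior_pct=la_fraction(la_in_wm, zones.posterior),
        la_volume_mm3=float(la_in_wm.data.sum()) * vox,
        wm_volume_mm3=float(zones.wm.data.sum()) * vox,
    )


def lacuna_volume(diameter_mm: float) -> float:
    """Sphere volume (4/3)π(d/2)³ for a gated lacunar diameter (mm³)."""
    if diameter_mm < LACUNA_MIN_DIAMETER_MM:
        raise DiameterGateError(f"diameter {diameter_mm} mm below the {LACUNA_MIN_DIAMETER_MM} mm gate")
    if diameter_mm >= LACUNA_MAX_DIAMETER_MM:
        raise DiameterGateError(f"diameter {diameter_mm} mm at/above the {LACUNA_MAX_DIAMETER_MM} mm gate")
    return (4.0 / 3.0) * math.pi * (diameter_mm / 2.0) ** 3


def detect_lacunae(
    dark_lesion_mask: Volume,
    min_slices: int = 2,
    zones: ZoneSet | None = None,
) -> LesionSet:
    """Detect lacunae as 26-connected components of a dark-lesion mask.

    A component is retained when its equivalent-sphere diameter lies in
    the [2, 15) mm gate and it spans at least ``min_slices`` axial
    slices (the "stationary between slices" rule). Each lacuna is tagged
    with the depth zone at its centroid ("deep-gray" outside the zoned
    white matter) and volumetrized via :func:`lacuna_volume`.
    """
    mask = dark_lesion_mask.data.astype(bool)
    out = LesionSet()
    if not mask.any():
        return out
    vox = dark_lesion_mask.voxel_volume_mm3
    spacing = dark_lesion_mask.spacing
    zone_labels = zones.labelmap().data if zones is not None else None
    comp, n = ndimage.label(mask, structure=STRUCT_26)
    for lab in range(1, n + 1):
        idx = np.nonzero(comp == lab)
        n_vox = idx[0].size
        volume = n_vox * vox
        d_eq = (6.0 * volume / math.pi) ** (1.0 / 3.0)
        if not (LACUNA_MIN_DIAMETER_MM <= d_eq < LACUNA_MAX_DIAMETER_MM):
            continue
        slice_extent = int(np.unique(idx[2]).size)
        if slice_extent < min_slices:
            continue
        centroid_idx = tuple(float(c.mean()) for c in idx)
        centroid_mm = tuple(centroid_idx[i] * spacing[i] for i in range(3))
        tag = "deep-gray"
        if zone_labels is not None:
            at = tuple(int(round(c)) for c in centroid_idx)
            tag = _ZONE_TAGS.get(int(zone_labels[at]), "deep-gray")
        out.lacunae.append(
            Lacuna(
                centroid_mm=centroid_mm,
                equivalent_diameter_mm=d_eq,
                slice_extent=slice_extent,
                zone=tag,
                volume_mm3=lacuna_volume(d_eq),
            )
        )
    return out


def stroke_volume(
    d1_mm: float,
    d2_mm: float,
    n_slices: int,
    slice_thickness_mm: float,
    correction: float = 1.0,
) -> float:
    """Two-diameter stroke volume in mL.

    ``correction * d1 * d2 * n_slices * slice_thickness / 1000``; the
    default correction 1.0 is the literal product, 0.5 reproduces ABC/2.
    """
    for name, v in (("d1_mm", d1_mm), ("d2_mm", d2_mm), ("n_slices", n_slices),
                    ("slice_thickness_mm", slice_thickness_mm), ("correction", correction)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    return correction * d1_mm * d2_mm * n_slices * slice_thickness_mm / 1000.0
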