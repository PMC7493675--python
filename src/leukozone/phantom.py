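"""Synthetic brain phantoms with planted hyperintense lesions.

The phantom is a deliberately simple parametric head: an ellipsoidal
brain whose outer shell is a cortical gray-matter ribbon, two
ellipsoidal lateral ventricles at its core, and white matter in between,
split into frontal/parietal/occipital/temporal compartments by
axis-aligned planes. Simple as it is, it yields all three depth zones
(periventricular, deep, infracortical) and the anterior/posterior
partition with controllable sizes, which is all the downstream
quantification needs.

Lesions are planted as compact sphere-derived blobs fully inside a
requested depth zone until the zone's leukoaraiosis fraction (% of zonal
white matter) hits its target voxel count exactly, so ground truth is
recoverable by plain voxel counting. A FLAIR-like intensity volume is
rendered from per-tissue means (CSF dark, lesions bright) plus Gaussian
noise; with a fixed seed every output is byte-identical across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .grid import (
    BACKGROUND,
    CORTICAL_GM,
    VENTRICLE,
    WM_FRONTAL,
    WM_OCCIPITAL,
    WM_PARIETAL,
    WM_TEMPORAL,
    Volume,
    physical_coords,
)
from .zoning import ZoneSet

#: default FLAIR-like tissue mean intensities (arbitrary units);
#: CSF is suppressed (dark), lesions are hyperintense relative to WM
DEFAULT_TISSUE_MEANS = {
    BACKGROUND: 0.0,
    VENTRICLE: 30.0,
    WM_FRONTAL: 100.0,
    WM_PARIETAL: 100.0,
    WM_OCCIPITAL: 100.0,
    WM_TEMPORAL: 100.0,
    CORTICAL_GM: 120.0,
}
DEFAULT_LESION_MEAN = 180.0


@dataclass
class EllipsoidSpec:
    """An axis-aligned ellipsoid: center offset from brain center (mm)
    and semi-axes (mm). A zero semi-axis makes the ellipsoid empty."""

    center_mm: tuple[float, float, float]
    semiaxes_mm: tuple[float, float, float]


@dataclass
class PhantomSpec:
    """Full parametric description of one phantom.

    ``zone_targets`` are planted lesion loads in % of zonal white
    matter. ``lacunae_plan`` entries are ``(center_offset_mm, diameter_mm)``
    dark spherical cavities; ``stroke_plan`` entries are
    ``(d1_mm, d2_mm, n_slices)`` caliper-style measurements (tabular
    only, not rendered).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_semiaxes_mm: tuple[float, float, float] = (26.0, 29.0, 24.0)
    ribbon_thickness_mm: float = 3.0
    ventricles: tuple[EllipsoidSpec, ...] = (
        EllipsoidSpec((-4.5, 2.0, 0.0), (1.8, 4.5, 1.8)),
        EllipsoidSpec((4.5, 2.0, 0.0), (1.8, 4.5, 1.8)),
    )
    #: lobe boundary planes, offsets from brain center (mm):
    #: frontal is anterior of ``frontal_y_mm``; occipital posterior of
    #: ``occipital_y_mm``; temporal is the inferior part (below
    #: ``temporal_z_mm``) of the middle band; parietal is the rest.
    frontal_y_mm: float = 8.0
    occipital_y_mm: float = -16.0
    temporal_z_mm: float = -12.0
    zone_targets: dict[str, float] = field(
        default_factory=lambda: {"periventricular": 0.0, "deep": 0.0, "infracortical": 0.0}
    )
    lacunae_plan: tuple[tuple[tuple[float, float, float], float], ...] = ()
    stroke_plan: tuple[tuple[float, float, int], ...] = ()
    tissue_means: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_TISSUE_MEANS))
    lesion_mean: float = DEFAULT_LESION_MEAN
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        for name, pct in self.zone_targets.items():
            if not 0.0 <= pct <= 100.0:
                raise ValueError(f"zone target {name}={pct} outside [0, 100]")


@dataclass
class GroundTruth:
    """Planted truth for one phantom, recoverable by voxel counting."""

    lesion_mask: Volume
    per_zone_fraction: dict[str, float]  # achieved % of zonal WM
    per_zone_target: dict[str, float]
    lacunae_true_volume_mm3: float = 0.0
    stroke_true_volume_ml: float = 0.0


def _ellipsoid_mask(shape, spacing, center_mm, semiaxes_mm) -> np.ndarray:
    if any(a <= 0 for a in semiaxes_mm):
        return np.zeros(shape, dtype=bool)
    xs, ys, zs = physical_coords(shape, spacing)
    q = (
        ((xs - center_mm[0]) / semiaxes_mm[0]) ** 2
        + ((ys - center_mm[1]) / semiaxes_mm[1]) ** 2
        + ((zs - center_mm[2]) / semiaxes_mm[2]) ** 2
    )
    return q <= 1.0


def make_label_volume(spec: PhantomSpec) -> Volume:
    """Build the tissue/lobe label volume for ``spec``.

    Every voxel carries exactly one label; white matter surrounds the
    ventricles and is capped by a closed cortical ribbon. Geometry that
    does not fit the grid is rejected.
    """
    shape, spacing = spec.grid_shape, spec.spacing
    extent = tuple((n - 1) * s for n, s in zip(shape, spacing))
    center = tuple(e / 2.0 for e in extent)
    for ax in range(3):
        if center[ax] - spec.brain_semiaxes_mm[ax] < 0 or center[ax] + spec.brain_semiaxes_mm[ax] > extent[ax]:
            raise ValueError(
                f"brain semi-axis {spec.brain_semiaxes_mm[ax]} mm exceeds grid bounds on axis {ax} "
                f"(grid extent {extent[ax]:.1f} mm)"
            )

    brain = _ellipsoid_mask(shape, spacing, center, spec.brain_semiaxes_mm)
    # cortical ribbon: brain voxels within ribbon_thickness of the outside
    from scipy import ndimage

    dist_inside = ndimage.distance_transform_edt(brain, sampling=spacing)
    ribbon = brain & (dist_inside <= spec.ribbon_thickness_mm)

    vent = np.zeros(shape, dtype=bool)
    for v in spec.ventricles:
        c = tuple(center[i] + v.center_mm[i] for i in range(3))
        vent |= _ellipsoid_mask(shape, spacing, c, v.semiaxes_mm)
    if (vent & ~(brain & ~ribbon)).any():
        raise ValueError("ventricle geometry extends outside the white-matter interior")

    wm = brain & ~ribbon & ~vent

    xs, ys, zs = physical_coords(shape, spacing)
    y_rel = ys - center[1]
    z_rel = zs - center[2]
    frontal = np.broadcast_to(y_rel >= spec.frontal_y_mm, shape)
    occipital = np.broadcast_to(y_rel <= spec.occipital_y_mm, shape)
    middle = ~frontal & ~occipital
    temporal = middle & np.broadcast_to(z_rel <= spec.temporal_z_mm, shape)
    parietal = middle & ~temporal

    labels = np.zeros(shape, dtype=np.int8)
    labels[ribbon] = CORTICAL_GM
    labels[vent] = VENTRICLE
    labels[wm & frontal] = WM_FRONTAL
    labels[wm & parietal] = WM_PARIETAL
    labels[wm & occipital] = WM_OCCIPITAL
    labels[wm & temporal] = WM_TEMPORAL
    return Volume(labels, spacing)


def _ball_indices(center_idx, radius_mm, shape, spacing):
    """Voxel indices within ``radius_mm`` of a voxel center, with their
    distances, restricted to a local bounding box."""
    lo, hi, axes = [], [], []
    for ax in range(3):
        half = int(math.ceil(radius_mm / spacing[ax]))
        a = max(0, center_idx[ax] - half)
        b = min(shape[ax], center_idx[ax] + half + 1)
        lo.append(a)
        hi.append(b)
        axes.append((np.arange(a, b) - center_idx[ax]) * spacing[ax])
    dx, dy, dz = np.meshgrid(*axes, indexing="ij", sparse=True)
    dist = np.sqrt(dx**2 + dy**2 + dz**2)
    inside = dist <= radius_mm
    ii, jj, kk = np.nonzero(inside)
    d = dist[inside]
    return ii + lo[0], jj + lo[1], kk + lo[2], d


class ZoneTooSmallError(ValueError):
    """A planted lesion target cannot be met inside the named zone."""


def plant_lesions(
    labels: Volume,
    zones: ZoneSet,
    zone_targets: dict[str, float],
    rng_seed: int | np.random.Generator = 0,
    radius_range_mm: tuple[float, float] = (1.2, 3.0),
    max_iter: int = 20000,
) -> GroundTruth:
    """Plant lesions per depth zone until each zone's fraction of
    lesioned white matter matches its target.

    Lesion seeds are random zone voxels; each lesion is the intersection
    of a random-radius ball with the zone (so it lies wholly inside),
    trimmed to the nearest-to-center voxels when it would overshoot the
    target count. The achieved fraction therefore equals
    ``round(target% * |zone|) / |zone|`` exactly.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    shape, spacing = labels.shape, labels.spacing
    lesion = np.zeros(shape, dtype=bool)
    achieved: dict[str, float] = {}

    for zone_name, pct in zone_targets.items():
        zone = zones.by_name(zone_name).data
        n_zone = int(zone.sum())
        if pct == 0.0:
            achieved[zone_name] = 0.0
            continue
        if n_zone == 0:
            raise ZoneTooSmallError(f"zone {zone_name!r} is empty; cannot plant {pct}%")
        n_target = int(round(pct / 100.0 * n_zone))
        tol_vox = max(0.10 * pct, 0.05) / 100.0 * n_zone  # ±10% rel or ±0.05 pp
        if n_target == 0 and pct / 100.0 * n_zone > tol_vox:
            raise ZoneTooSmallError(
                f"zone {zone_name!r} ({n_zone} voxels) too small for target {pct}%"
            )
        placed = 0
        it = 0
        free = zone & ~lesion
        while placed < n_target:
            it += 1
            if it > max_iter:
                raise ZoneTooSmallError(
                    f"could not reach {pct}% in zone {zone_name!r} "
                    f"({placed}/{n_target} voxels after {max_iter} attempts)"
                )
            idx_flat = np.flatnonzero(free)
            if idx_flat.size == 0:
                raise ZoneTooSmallError(f"zone {zone_name!r} saturated before reaching {pct}%")
            c_flat = int(rng.choice(idx_flat))
            c = np.unravel_index(c_flat, shape)
            r = float(rng.uniform(*radius_range_mm))
            ii, jj, kk, d = _ball_indices(c, r, shape, spacing)
            keep = free[ii, jj, kk]
            ii, jj, kk, d = ii[keep], jj[keep], kk[keep], d[keep]
            deficit = n_target - placed
            if ii.size > deficit:
                order = np.argsort(d, kind="stable")[:deficit]
                ii, jj, kk = ii[order], jj[order], kk[order]
            lesion[ii, jj, kk] = True
            free[ii, jj, kk] = False
            placed += int(ii.size)
        achieved[zone_name] = 100.0 * placed / n_zone

    return GroundTruth(
        lesion_mask=Volume(lesion, spacing),
        per_zone_fraction=achieved,
        per_zone_target=dict(zone_targets),
    )


def lacunae_mask(labels: Volume, plan) -> tuple[Volume, float]:
    """Voxelize a plan of spherical cavities; returns the mask and the
    analytic (4/3)πr³ true volume summed over the plan (mm³)."""
    shape, spacing = labels.shape, labels.spacing
    extent = tuple((n - 1) * s for n, s in zip(shape, spacing))
    center = tuple(e / 2.0 for e in extent)
    mask = np.zeros(shape, dtype=bool)
    true_vol = 0.0
    for offset, diameter in plan:
        c_mm = tuple(center[i] + offset[i] for i in range(3))
        c_idx = tuple(int(round(c_mm[i] / spacing[i])) for i in range(3))
        ii, jj, kk, _ = _ball_indices(c_idx, diameter / 2.0, shape, spacing)
        mask[ii, jj, kk] = True
        true_vol += (4.0 / 3.0) * math.pi * (diameter / 2.0) ** 3
    return Volume(mask, spacing), true_vol


def render_flair(
    labels: Volume,
    lesions: Volume | None = None,
    tissue_means: dict[int, float] | None = None,
    lesion_mean: float = DEFAULT_LESION_MEAN,
    noise_sd: float = 0.0,
    rng_seed: int | np.random.Generator = 0,
) -> Volume:
    """Render a FLAIR-like intensity volume: per-tissue means, lesion
    voxels overridden by the (hyperintense) lesion mean, plus i.i.d.
    Gaussian noise. Deterministic for a fixed seed."""
    means = tissue_means or DEFAULT_TISSUE_MEANS
    present = np.unique(labels.data)
    missing = [int(c) for c in present if int(c) not in means]
    if missing:
        raise ValueError(f"tissue_means missing labels {missing}")
    wm_means = [means[c] for c in present if c in (WM_FRONTAL, WM_PARIETAL, WM_OCCIPITAL, WM_TEMPORAL)]
    if wm_means and lesion_mean <= max(wm_means):
        raise ValueError("lesion mean must be strictly above the white-matter mean")
    lut = np.zeros(int(present.max()) + 1, dtype=np.float64)
    for code in present:
        lut[int(code)] = means[int(code)]
    img = lut[labels.data]
    if lesions is not None:
        if not labels.same_grid(lesions):
            raise ValueError("lesion mask grid does not match label grid")
        img = np.where(lesions.data, lesion_mean, img)
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd > 0:
        rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return Volume(img.astype(np.float32), labels.spacing)
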