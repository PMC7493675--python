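"""Threshold-based leukoaraiosis segmentation on FLAIR-like volumes.

The workflow mirrors manual hyperintensity tracing: each axial slice is
thresholded independently against statistics of a reference region
(normal-appearing white matter by default), the 2-D binary masks are
stacked into a 3-D mask, and optionally components smaller than a voxel
count are discarded.

Two threshold statistics are available:

* ``"robust"`` (default): median + k * 1.4826 * MAD. Robust to the
  lesions themselves contaminating the reference region, which on
  lesion-rich slices inflates mean and SD enough to swallow the lesions.
* ``"moments"``: mean + k * SD, the textbook hyperintensity heuristic.

A slice whose reference region is empty falls back to whole-volume
reference statistics (logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import WM_LABELS, Volume, require_same_grid

log = logging.getLogger("leukozone.segment")

#: consistency constant making MAD unbiased for the SD under normality
MAD_TO_SD = 1.4826

#: 26-connectivity structuring element for 3-D components
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SegmentationParams:
    """Threshold-rule parameters.

    ``k`` is the multiplier on the spread statistic; raising it can only
    shrink the mask. ``smooth_sigma_mm`` optionally pre-smooths the
    intensity volume with a Gaussian (0 disables), useful at high noise.
    """

    reference_labels: tuple[int, ...] = WM_LABELS
    k: float = 3.0
    min_component_voxels: int = 0
    mode: str = "per-slice"  # or "global"
    statistic: str = "robust"  # or "moments"
    smooth_sigma_mm: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.k):
            raise ValueError("k must be finite")
        if self.min_component_voxels < 0:
            raise ValueError("min_component_voxels must be >= 0")
        if self.mode not in ("per-slice", "global"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.statistic not in ("robust", "moments"):
            raise ValueError(f"unknown statistic {self.statistic!r}")


def _threshold(values: np.ndarray, k: float, statistic: str) -> float:
    if statistic == "moments":
        return float(values.mean() + k * values.std())
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    return med + k * MAD_TO_SD * mad


def segment_la(intensity: Volume, labels: Volume, params: SegmentationParams | None = None) -> Volume:
    """Segment hyperintense white-matter voxels.

    Returns a binary mask restricted to the reference tissue. In
    per-slice mode each axial slice (axis 2) is thresholded
    independently then stacked, mirroring 2-D tracing workflows.
    """
    params = params or SegmentationParams()
    require_same_grid(intensity, labels, context="segment_la")
    img = intensity.data.astype(np.float64)
    if params.smooth_sigma_mm > 0:
        sigmas = [params.smooth_sigma_mm / s for s in intensity.spacing]
        img = ndimage.gaussian_filter(img, sigma=sigmas)
    ref = np.isin(labels.data, params.reference_labels)
    if not ref.any():
        raise ValueError("reference region is empty in the label volume")
    global_thr = _threshold(img[ref], params.k, params.statistic)

    mask = np.zeros(img.shape, dtype=bool)
    if params.mode == "global":
        mask = ref & (img > global_thr)
    else:
        for z in range(img.shape[2]):
            ref_z = ref[:, :, z]
            if not ref_z.any():
                continue
            vals = img[:, :, z][ref_z]
            if vals.size < 2:
                thr = global_thr
                log.debug("slice %d: reference too small, global threshold fallback", z)
            else:
                thr = _threshold(vals, params.k, params.statistic)
            mask[:, :, z] = ref_z & (img[:, :, z] > thr)

    if params.min_component_voxels > 0 and mask.any():
        comp, n = ndimage.label(mask, structure=STRUCT_26)
        sizes = np.bincount(comp.ravel())
        small = np.flatnonzero(sizes < params.min_component_voxels)
        mask[np.isin(comp, small[small > 0])] = False
    return Volume(mask, intensity.spacing)


def dice(a: Volume, b: Volume) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|).

    Two empty masks agree perfectly by convention (returns 1.0).
    """
    require_same_grid(a, b, context="dice")
    am = a.data.astype(bool)
    bm = b.data.astype(bool)
    denom = int(am.sum()) + int(bm.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((am & bm).sum()) / denom
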