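"""Measurement-mask refinement: erosion and Otsu blood-pool separation.

Raw contours become the masks actually measured: the myocardial ring
(epicardial minus endocardial) is shrunk by a 3x3 binary erosion to pull
away from both borders; the blood pool is separated from papillary muscles
by Otsu's threshold computed over cavity voxels, then eroded the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import RefinementError
from .io import T1Map
from .segmentation import SegMasks

OTSU_BINS = 256
# if the best between-class variance explains less than this share of the
# total variance the cavity histogram is treated as unimodal
UNIMODAL_TOLERANCE = 0.01


@dataclass(frozen=True)
class MeasurementMasks:
    myocardium_refined: np.ndarray
    blood_refined: np.ndarray
    otsu_threshold_ms: float      # NaN when the unimodal fallback fired
    counts: dict = field(default_factory=dict)
    phase: str = ""


def erode_mask(mask: np.ndarray, kernel_size: int = 3) -> np.ndarray:
    """Binary erosion with a square structuring element.

    A voxel is retained iff itself and its full neighbourhood lie inside the
    mask; voxels beyond the raster edge count as outside. The default 3x3
    kernel removes exactly one voxel from alongside every margin.
    """
    if kernel_size < 1 or kernel_size % 2 != 1:
        raise RefinementError("erosion kernel must be odd-sized")
    mask = np.asarray(mask, bool)
    if kernel_size == 1 or not mask.any():
        return mask.copy()
    structure = np.ones((kernel_size, kernel_size), bool)
    return ndimage.binary_erosion(mask, structure=structure, border_value=0)


def myocardium_from_contours(masks: SegMasks) -> np.ndarray:
    """Myocardial ring = epicardial mask minus endocardial mask."""
    ring = np.asarray(masks.epicardial, bool) & ~np.asarray(
        masks.endocardial, bool)
    if not ring.any():
        raise RefinementError("no myocardium: epicardial and endocardial "
                              "contours coincide")
    return ring


def otsu_threshold(values: np.ndarray, bins: int = OTSU_BINS,
                   unimodal_tolerance: float = UNIMODAL_TOLERANCE):
    """Otsu's threshold over a 1D sample.

    Builds a ``bins``-bin histogram over the observed range and returns the
    bin-edge threshold maximizing the between-class variance (ties broken
    toward the lower threshold). Returns ``(threshold, is_bimodal)``;
    ``is_bimodal`` is False when the best between-class variance is below
    ``unimodal_tolerance`` times the total variance (effectively unimodal),
    in which case the threshold is NaN.
    """
    values = np.asarray(values, float).ravel()
    if values.size == 0:
        raise RefinementError("cannot threshold an empty sample")
    total_var = values.var()
    if total_var == 0:
        return float("nan"), False
    counts, edges = np.histogram(values, bins=bins)
    # candidate thresholds: interior bin edges; classes split as < t / >= t
    w0 = np.cumsum(counts)[:-1].astype(float)
    w1 = values.size - w0
    centers = 0.5 * (edges[:-1] + edges[1:])
    csum = np.cumsum(counts * centers)[:-1]
    total_sum = np.sum(counts * centers)
    valid = (w0 > 0) & (w1 > 0)
    between = np.zeros_like(w0)
    mu0 = np.divide(csum, w0, out=np.zeros_like(w0), where=valid)
    mu1 = np.divide(total_sum - csum, w1, out=np.zeros_like(w1), where=valid)
    between[valid] = (w0[valid] * w1[valid] * (mu0[valid] - mu1[valid]) ** 2
                      / values.size ** 2)
    best = int(np.argmax(between))   # argmax takes the first (lowest) tie
    if between[best] < unimodal_tolerance * total_var:
        return float("nan"), False
    return float(edges[best + 1]), True


def separate_blood_pool(endocardial: np.ndarray, t1map: T1Map,
                        bins: int = OTSU_BINS,
                        unimodal_tolerance: float = UNIMODAL_TOLERANCE):
    """Split the cavity into blood pool vs papillary muscle by Otsu.

    The threshold is computed over map values inside the endocardial mask
    only. Which side is blood follows the contrast physics: native blood T1
    exceeds myocardial T1, post-contrast the ordering flips. Returns
    ``(blood_mask, threshold_ms)``; an effectively unimodal cavity is
    returned whole with a NaN threshold.
    """
    endocardial = np.asarray(endocardial, bool)
    if not endocardial.any():
        raise RefinementError("empty endocardial mask")
    inside = t1map.values[endocardial]
    thr, bimodal = otsu_threshold(inside, bins=bins,
                                  unimodal_tolerance=unimodal_tolerance)
    if not bimodal:
        return endocardial.copy(), float("nan")
    if t1map.phase == "native":
        blood = endocardial & (t1map.values >= thr)
    else:
        blood = endocardial & (t1map.values < thr)
    return blood, thr


def refine_masks(masks: SegMasks, t1map: T1Map,
                 kernel_size: int = 3, bins: int = OTSU_BINS,
                 unimodal_tolerance: float = UNIMODAL_TOLERANCE
                 ) -> MeasurementMasks:
    """Refine one phase: erode the ring, Otsu-split then erode the cavity."""
    counts = {}
    ring = myocardium_from_contours(masks)
    counts["myocardium_raw"] = int(ring.sum())
    myo = erode_mask(ring, kernel_size)
    counts["myocardium_eroded"] = int(myo.sum())
    if not myo.any():
        raise RefinementError(
            "empty myocardium after erosion (wall too thin for the "
            f"{kernel_size}x{kernel_size} kernel)")
    counts["cavity_raw"] = int(np.asarray(masks.endocardial, bool).sum())
    blood_raw, thr = separate_blood_pool(
        masks.endocardial, t1map, bins=bins,
        unimodal_tolerance=unimodal_tolerance)
    counts["blood_after_otsu"] = int(blood_raw.sum())
    blood = erode_mask(blood_raw, kernel_size)
    counts["blood_eroded"] = int(blood.sum())
    if not blood.any():
        raise RefinementError("empty blood pool after erosion (cavity too "
                              "small)")
    return MeasurementMasks(myocardium_refined=myo, blood_refined=blood,
                            otsu_threshold_ms=thr, counts=counts,
                            phase=t1map.phase)


def refine_all(masks: SegMasks, native: T1Map, post: T1Map,
               kernel_size: int = 3, bins: int = OTSU_BINS,
               unimodal_tolerance: float = UNIMODAL_TOLERANCE):
    """Refine both phases; Otsu runs independently per phase on its own map.

    Returns ``(native_masks, post_masks)``.
    """
    if native.values.shape != masks.shape or post.values.shape != masks.shape:
        raise RefinementError("masks and maps must share the raster shape")
    out = []
    for t1map in (native, post):
        try:
            out.append(refine_masks(masks, t1map, kernel_size=kernel_size,
                                    bins=bins,
                                    unimodal_tolerance=unimodal_tolerance))
        except RefinementError as exc:
            raise RefinementError(f"{t1map.phase} phase: {exc}") from exc
    return out[0], out[1]
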