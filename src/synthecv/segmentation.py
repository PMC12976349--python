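"""Segmentation backends producing epicardial / endocardial / RV masks.

Conventions (shared by every backend):

* ``epicardial`` — full LV disc out to the epicardial border;
* ``endocardial`` — LV cavity *including* papillary muscles (their removal
  happens later, in the refinement stage);
* ``rv`` — RV cavity blood.

Backends: ``oracle`` (ground-truth labels), ``classical`` (three-class Otsu
on the native map), and an optional trainable backend in
:mod:`synthecv.learned`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label

from .errors import SegmentationError
from .io import T1Map
from .phantom import (LBL_LV_BLOOD, LBL_MYOCARDIUM, LBL_PAPILLARY,
                      LBL_RV_BLOOD, LabelRaster)

STRUCTURES = ("epicardial", "endocardial", "rv")


@dataclass(frozen=True)
class SegMasks:
    epicardial: np.ndarray
    endocardial: np.ndarray
    rv: np.ndarray
    spacing_mm: float
    provenance: str = "unknown"

    def __post_init__(self):
        epi, endo, rv = (np.asarray(self.epicardial, bool),
                         np.asarray(self.endocardial, bool),
                         np.asarray(self.rv, bool))
        if not (epi.shape == endo.shape == rv.shape):
            raise SegmentationError("mask shapes differ")
        if np.any(endo & ~epi):
            raise SegmentationError("endocardial mask not contained in "
                                    "epicardial mask")
        if np.any(rv & epi):
            raise SegmentationError("RV mask overlaps the epicardial disc")

    @property
    def shape(self):
        return self.epicardial.shape


def segment_oracle(labels: LabelRaster) -> SegMasks:
    """Ground-truth masks from a phantom label raster (stands in for expert
    contours)."""
    labels.validate()
    arr = labels.labels
    epi = np.isin(arr, (LBL_LV_BLOOD, LBL_MYOCARDIUM, LBL_PAPILLARY))
    endo = np.isin(arr, (LBL_LV_BLOOD, LBL_PAPILLARY))
    rv = arr == LBL_RV_BLOOD
    return SegMasks(epicardial=epi, endocardial=endo, rv=rv,
                    spacing_mm=labels.spacing_mm, provenance="oracle")


def segment_classical(native: T1Map) -> SegMasks:
    """Model-free backend: hierarchical Otsu on a native-phase map.

    On native maps blood has the highest T1, myocardium intermediate and
    background the lowest, so the raster is split into three intensity
    classes: an Otsu threshold over the whole raster separates foreground
    from background, a second Otsu threshold within the foreground
    separates blood (high class) from myocardium (intermediate class).
    (A joint three-class Otsu is unreliable here: the dominant background
    mode can pull a threshold into the tissue range.) The LV cavity is the
    largest high-class connected component (hole-filled to re-include
    papillaries), the RV the next largest, and the myocardial ring the
    intermediate class adjacent to the cavity. 8-connectivity throughout.
    """
    from .refinement import otsu_threshold

    if native.phase != "native":
        raise SegmentationError("classical backend requires a native-phase "
                                "map (blood/myocardium T1 ordering)")
    values = native.values
    t_fg, split_fg = otsu_threshold(values, unimodal_tolerance=1e-6)
    if not split_fg:
        raise SegmentationError("degenerate intensity histogram: cannot "
                                "separate foreground from background")
    foreground = values >= t_fg
    if foreground.sum() < 16:
        raise SegmentationError("foreground too small to segment")
    # sample the second threshold from the twice-eroded foreground: the
    # background-adjacent partial-volume band (which can be two voxels deep,
    # one on each side of the tissue border) would otherwise offer a
    # spuriously attractive split below the myocardium
    interior = ndimage.binary_erosion(foreground, np.ones((3, 3), bool),
                                      border_value=0, iterations=2)
    sample = values[interior] if interior.sum() >= 16 else values[foreground]
    t_bm, split_bm = otsu_threshold(sample, unimodal_tolerance=1e-6)
    if not split_bm:
        raise SegmentationError("degenerate foreground histogram: cannot "
                                "separate blood from myocardium")
    high = foreground & (values >= t_bm)
    mid = foreground & ~high

    high_cc = cc_label(high, connectivity=2)
    sizes = np.bincount(high_cc.ravel())
    sizes[0] = 0
    if np.count_nonzero(sizes) < 1:
        raise SegmentationError("no blood-pool component found")
    # The LV cavity is the blood component *enclosed by myocardium*: among
    # the largest high-class components, take the one whose border touches
    # the intermediate class the most. (Pure size ranking misidentifies the
    # cavity when the RV happens to be larger.)
    candidates = [c for c in np.argsort(sizes)[::-1][:4] if sizes[c] > 0]
    structure = np.ones((3, 3), bool)

    def ring_contact(component: np.ndarray) -> float:
        # 3-voxel shell: myocardium fills it around the cavity, while a
        # stray blood component sees mostly background there
        shell = ndimage.binary_dilation(component, structure,
                                        iterations=3) & ~component
        return float(mid[shell].mean()) if shell.any() else 0.0

    lv_label = max(candidates,
                   key=lambda c: (ring_contact(high_cc == c), sizes[c]))
    lv_component = high_cc == lv_label
    endo = ndimage.binary_fill_holes(lv_component)

    # ring = intermediate-class components touching the cavity
    mid_cc = cc_label(mid, connectivity=2)
    touching = np.unique(mid_cc[ndimage.binary_dilation(
        endo, structure=np.ones((3, 3), bool)) & (mid_cc > 0)])
    ring = np.isin(mid_cc, touching[touching > 0])
    if not ring.any():
        raise SegmentationError("no myocardial ring found enclosing the "
                                "blood-pool cavity")
    epi = ndimage.binary_fill_holes(endo | ring)
    if not np.any(epi & ~endo):
        raise SegmentationError("no myocardial ring found enclosing the "
                                "blood-pool cavity")

    remaining = [c for c in candidates if c != lv_label]
    rv = np.zeros_like(endo)
    if remaining:
        rv_label = max(remaining, key=lambda c: sizes[c])
        rv = (high_cc == rv_label) & ~epi
        # reclaim the crescent's partial-volume rim (mixed-value voxels drop
        # below the blood threshold but stay well above background)
        rv = (ndimage.binary_dilation(rv, structure) & foreground & ~epi)
    if not rv.any():
        raise SegmentationError("no RV blood-pool component found")

    return SegMasks(epicardial=epi, endocardial=endo, rv=rv,
                    spacing_mm=native.spacing_mm, provenance="classical")


def clean_structure(mask: np.ndarray) -> np.ndarray:
    """Largest 8-connected component, hole-filled (prediction cleanup)."""
    if not mask.any():
        return mask
    cc = cc_label(mask, connectivity=2)
    sizes = np.bincount(cc.ravel())
    sizes[0] = 0
    return ndimage.binary_fill_holes(cc == np.argmax(sizes))
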