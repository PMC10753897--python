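"""Gray-level segmentation of reconstructed tomograms.

Implements the "holes" extraction as a four-step mask pipeline — (1) select a
gray-level band that contains both the dark features and the background,
(2) invert it (mostly mineralized matter), (3) fill enclosed 2D regions
slice-wise in x, then y, then z, (4) intersect with the step-1 mask — followed
by small-island removal, plus a coarse one-threshold mineral segmentation and
6-connected component labelling. Thresholds default to an automated choice
(lo = volume minimum, hi = Otsu) since interactive gray-level picking is not
reproducible.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu

from .volume import BinaryMask, LabelVolume, Volume3D

__all__ = [
    "define_range",
    "invert",
    "fill_inner_areas",
    "boolean_intersect",
    "process_islands",
    "connected_components_6",
    "segment_holes",
    "segment_mineral",
    "auto_thresholds",
]

_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # face connectivity


def define_range(volume: Volume3D, lo: float, hi: float) -> BinaryMask:
    """Mask of voxels with lo <= value <= hi (both ends inclusive)."""
    if lo > hi:
        raise ValueError(f"invalid gray-level range: lo={lo} > hi={hi}")
    data = (volume.data >= lo) & (volume.data <= hi)
    return BinaryMask(data, volume.voxel_size, [f"define_range[{lo},{hi}]"])


def invert(mask: BinaryMask) -> BinaryMask:
    return mask.derived(~mask.data, "invert")


def fill_inner_areas(mask: BinaryMask, axes: Tuple[str, ...] = ("x", "y", "z")) -> BinaryMask:
    """Fill enclosed zero-regions of every 2D slice, one axis at a time.

    For each axis in order, every slice perpendicular to it has its zero
    regions not connected to the slice border set to 1; each pass operates on
    the result of the previous one (the order is therefore significant and
    fixed to x, y, z by default).
    """
    axis_index = {"x": 0, "y": 1, "z": 2}
    data = mask.data.copy()
    for ax in axes:
        a = axis_index[ax]
        moved = np.moveaxis(data, a, 0)
        for i in range(moved.shape[0]):
            moved[i] = ndimage.binary_fill_holes(moved[i])
        data = np.moveaxis(moved, 0, a)
    return mask.derived(data, f"fill_inner_areas[{','.join(axes)}]")


def boolean_intersect(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    return BinaryMask(
        a.data & b.data,
        a.voxel_size,
        a.provenance + b.provenance + ["boolean_intersect"],
    )


def process_islands(mask: BinaryMask, min_island: int = 27) -> BinaryMask:
    """Remove 6-connected components smaller than ``min_island`` voxels."""
    if min_island <= 1:
        return mask.derived(mask.data.copy(), f"process_islands[{min_island}]")
    labels, n = ndimage.label(mask.data, structure=_STRUCT6)
    if n == 0:
        return mask.derived(mask.data.copy(), f"process_islands[{min_island}]")
    counts = np.bincount(labels.ravel())
    keep = counts >= min_island
    keep[0] = False
    return mask.derived(keep[labels], f"process_islands[{min_island}]")


def connected_components_6(mask: BinaryMask) -> LabelVolume:
    """6-connected labelling with labels sorted by decreasing component size."""
    labels, n = ndimage.label(mask.data, structure=_STRUCT6)
    if n == 0:
        return LabelVolume(labels.astype(np.int32), mask.voxel_size)
    counts = np.bincount(labels.ravel())[1:]
    order = np.argsort(-counts, kind="stable")  # old label order-1 -> rank
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[order + 1] = np.arange(1, n + 1, dtype=np.int32)
    return LabelVolume(remap[labels], mask.voxel_size)


def _material_threshold(data: np.ndarray) -> float:
    """Gray level separating unmineralized/organic material from the bright
    mineral phase.

    A reconstructed rod has (at least) three histogram modes: the background
    outside the sample, the dark fibril material and the bright mineralized
    matrix. A two-class Otsu threshold tends to land inside the fibril gray
    band (pulled down by the large background mode), so the fibril/matrix
    boundary is taken as the upper threshold of a three-class Otsu split;
    when the histogram has too few distinct levels for that, fall back to the
    two-class threshold.
    """
    try:
        return float(threshold_multiotsu(data, classes=3)[-1])
    except ValueError:
        return float(threshold_otsu(data))


def auto_thresholds(volume: Volume3D) -> Tuple[float, float]:
    """Automated (lo, hi) for the dark band: lo = volume minimum, hi = the
    material/mineral histogram threshold (see ``_material_threshold``)."""
    data = np.asarray(volume.data, dtype=np.float64)
    return float(data.min()), _material_threshold(data)


def segment_holes(
    volume: Volume3D,
    lo: Optional[float] = None,
    hi: Optional[float] = None,
    min_island: int = 27,
) -> BinaryMask:
    """Extract the dark "holes" strictly inside the sample envelope.

    Composition: define_range -> invert -> fill_inner_areas(x, y, z) ->
    intersect with the step-1 mask -> remove islands below ``min_island``
    voxels. The background around the sample is in the step-1 band too, but it
    is never enclosed in any slice, so the fill/intersect combination removes
    it: the result can only contain low-gray voxels inside the sample.
    """
    if lo is None or hi is None:
        auto_lo, auto_hi = auto_thresholds(volume)
        lo = auto_lo if lo is None else lo
        hi = auto_hi if hi is None else hi
    step1 = define_range(volume, lo, hi)
    step2 = invert(step1)
    step3 = fill_inner_areas(step2)
    step4 = boolean_intersect(step1, step3)
    return process_islands(step4, min_island)


def segment_mineral(volume: Volume3D, lo: Optional[float] = None, hi: Optional[float] = None) -> BinaryMask:
    """Coarse gray-level segmentation of the (bright) mineral phase.

    When ``hi`` is left at its default (the volume maximum) and no voxel
    reaches ``lo``, the result is simply empty (no mineral present)."""
    if lo is None:
        lo = _material_threshold(np.asarray(volume.data, dtype=np.float64))
    if hi is None:
        hi = float(np.asarray(volume.data).max())
        if hi < lo:
            out = BinaryMask(np.zeros(volume.shape, dtype=bool), volume.voxel_size)
            out.provenance.append("define_range(empty: lo above volume maximum)")
            return out
    return define_range(volume, lo, hi)
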