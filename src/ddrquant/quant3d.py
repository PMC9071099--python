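"""Spheroid quantification from confocal z-stacks.

Spheroid cultures are reduced to 2D by a maximum-intensity projection
across the z-stack; spheroids are segmented by thresholding the projected
Hoechst signal, and GFP intensity and the PI-positive area fraction are
measured inside each projected spheroid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .errors import GeometryError, InvalidStackError
from .images import ChannelImage, LabelMap, ZStack, relabel_consecutive

__all__ = ["SpheroidRecord", "max_project", "segment_spheroids", "measure_spheroids"]


@dataclass
class SpheroidRecord:
    """Per-spheroid measurements on the 2D projection."""

    label: int
    area: int
    mean_gfp: float
    pi_area_fraction: float


def max_project(stack: ZStack) -> ChannelImage:
    """Per-pixel maximum across planes; channel and pixel size preserved."""
    if len(stack.planes) < 1:
        raise InvalidStackError("cannot project an empty stack")
    proj = stack.as_array().max(axis=0)
    return ChannelImage(proj, stack.channel, stack.planes[0].pixel_size)


def segment_spheroids(
    projection: ChannelImage,
    threshold: Optional[float] = None,
    min_area: int = 200,
) -> LabelMap:
    """Connected components of the supra-threshold Hoechst projection.

    ``threshold=None`` selects the Otsu level.  Holes are filled (spheroid
    cores can project dim) and components below ``min_area`` pixels are
    dropped; labels are consecutive.
    """
    if projection.channel != "hoechst":
        raise ValueError(f"expected a hoechst projection, got {projection.channel!r}")
    img = projection.pixels.astype(np.float64)
    if threshold is None:
        if np.ptp(img) == 0:
            return LabelMap(np.zeros(img.shape, dtype=np.int32), kind="spheroid")
        threshold = threshold_otsu(img)
    mask = img >= threshold
    mask = ndi.binary_fill_holes(mask)
    labels, _ = ndi.label(mask)
    sizes = np.bincount(labels.ravel())
    labels[np.isin(labels, np.flatnonzero(sizes < min_area))] = 0
    return LabelMap(relabel_consecutive(labels), kind="spheroid")


def measure_spheroids(
    spheroids: LabelMap,
    gfp_projection: ChannelImage,
    pi_projection: ChannelImage,
    pi_threshold: Optional[float] = None,
) -> List[SpheroidRecord]:
    """Mean GFP and PI-positive area fraction per projected spheroid.

    ``pi_area_fraction`` = supra-threshold PI pixels inside the spheroid /
    spheroid area.  ``pi_threshold=None`` uses Otsu on the PI projection
    (empty mask when the PI channel is constant).
    """
    shape = spheroids.shape
    if gfp_projection.shape != shape or pi_projection.shape != shape:
        raise GeometryError("projections must share the spheroid map's shape")
    n = spheroids.n_objects
    if n == 0:
        return []
    pi_img = pi_projection.pixels.astype(np.float64)
    if pi_threshold is None:
        pi_mask = (
            np.zeros(shape, dtype=bool) if np.ptp(pi_img) == 0 else pi_img >= threshold_otsu(pi_img)
        )
    else:
        pi_mask = pi_img >= pi_threshold
    idx = np.arange(1, n + 1)
    areas = ndi.sum_labels(np.ones(shape), labels=spheroids.labels, index=idx)
    mean_gfp = ndi.mean(gfp_projection.pixels.astype(np.float64), labels=spheroids.labels, index=idx)
    pi_px = ndi.sum_labels(pi_mask.astype(np.float64), labels=spheroids.labels, index=idx)
    return [
        SpheroidRecord(
            label=int(lab),
            area=int(areas[i]),
            mean_gfp=float(mean_gfp[i]),
            pi_area_fraction=float(pi_px[i] / areas[i]),
        )
        for i, lab in enumerate(idx)
    ]
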