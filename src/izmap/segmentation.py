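"""Circumscription of DCP telangiectasia and SCP large-vessel artifact
exclusion.

The telangiectatic zone is an operator-marked region of interest; within
it, local adaptive thresholding isolates the dilated vessels and hole
filling turns the binarized loops into a circumscribed area.  Large
superficial (SCP) vessels project into the deeper angiogram and can mimic
telangiectasia, so they are segmented from the SCP image and subtracted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import polygon2mask
from skimage.morphology import disk

from .thresholding import PhansalkarParams, fill_holes, max_entropy_threshold, phansalkar_threshold
from .types import BinaryMask, EnFaceImage, as_mask, check_same_geometry

log = logging.getLogger(__name__)

#: Isolated foreground specks below this size are dropped from the
#: circumscribed telangiectasia mask.
MIN_OBJECT_PX = 10
#: Telangiectatic vessels are dilated; circumscribed components whose
#: widest contained vessel is narrower than this are capillary clutter.
MIN_TEL_VESSEL_WIDTH_PX = 4
#: SCP large-vessel component filters: minimum area and minimum maximum
#: inscribed width (capillaries are 1-2 px wide; large vessels much wider).
MIN_LARGE_VESSEL_PX = 300
MIN_WIDTH_PX = 4


@dataclass
class MarkedROI:
    """Operator-marked telangiectatic zone: a polygon (pixel coordinates,
    (row, col) vertices) or a coarse mask."""

    vertices: np.ndarray | None = None
    mask: BinaryMask | None = None

    def to_mask(self, shape: tuple[int, int]) -> BinaryMask:
        if self.mask is not None:
            m = as_mask(self.mask)
            if m.shape != shape:
                raise ValueError(f"ROI mask shape {m.shape} != image shape {shape}")
            return m
        if self.vertices is None:
            raise ValueError("MarkedROI needs either vertices or a mask")
        verts = np.asarray(self.vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
            raise ValueError("polygon needs >= 3 (row, col) vertices")
        return polygon2mask(shape, verts)


def circumscribe_telangiectasia(
    dcp: EnFaceImage,
    roi: MarkedROI | BinaryMask,
    params: PhansalkarParams | None = None,
    min_object_px: int = MIN_OBJECT_PX,
    min_vessel_width_px: int = MIN_TEL_VESSEL_WIDTH_PX,
    manual_add: BinaryMask | None = None,
    manual_remove: BinaryMask | None = None,
) -> BinaryMask:
    """Circumscribed telangiectasia area inside the marked ROI.

    Pipeline: Phansalkar local threshold of the (normalized) DCP angiogram,
    restricted to the ROI; hole filling to close the vessel loops; removal
    of isolated specks below ``min_object_px`` and of components that
    contain no dilated vessel (maximum inscribed vessel width below
    ``min_vessel_width_px`` — ordinary capillaries crossing the marked zone
    are not telangiectasia).  The result is always a subset of the ROI.

    ``manual_add`` / ``manual_remove`` model the grader's manual
    correction: optional masks applied last (add restricted to the ROI).
    The automated path runs unattended when they are omitted.
    """
    roi_mask = roi.to_mask(dcp.shape) if isinstance(roi, MarkedROI) else as_mask(roi)
    check_same_geometry(dcp.data, roi_mask)
    if not roi_mask.any():
        log.warning("empty ROI: returning empty telangiectasia mask")
        return np.zeros(dcp.shape, dtype=bool)
    vessels = phansalkar_threshold(dcp, params) & roi_mask
    # an opening at capillary calibre detaches and removes ordinary
    # capillary threads before holes are filled, so capillaries crossing
    # the marked zone neither bridge nor enclose spurious area; dilated
    # telangiectatic vessels are wide enough to pass
    thick = ndimage.binary_opening(vessels, structure=disk(2))
    filled = fill_holes(thick)
    labels, n = ndimage.label(filled, structure=np.ones((3, 3), dtype=int))
    if n > 0:
        idx = np.arange(1, n + 1)
        areas = ndimage.sum_labels(np.ones_like(labels), labels, index=idx)
        vessel_dt = ndimage.distance_transform_edt(thick)
        max_halfwidth = ndimage.maximum(vessel_dt, labels, index=idx)
        keep = np.zeros(n + 1, dtype=bool)
        keep[1:] = (areas >= min_object_px) & (2.0 * max_halfwidth >= min_vessel_width_px)
        out = keep[labels] & roi_mask
    else:
        out = filled
    if manual_add is not None:
        out = out | (as_mask(manual_add) & roi_mask)
    if manual_remove is not None:
        out = out & ~as_mask(manual_remove)
    return out


def scp_artifact_mask(
    scp: EnFaceImage,
    min_large_vessel_px: int = MIN_LARGE_VESSEL_PX,
    min_width_px: int = MIN_WIDTH_PX,
) -> BinaryMask:
    """Large SCP vessels only: maximum-entropy foreground, morphologically
    opened to disconnect capillary-calibre structures, then filtered to
    components with area >= ``min_large_vessel_px`` and maximum inscribed
    width >= ``min_width_px``.  A degenerate (constant) image yields an
    empty mask with a warning.
    """
    try:
        _, fg = max_entropy_threshold(scp)
    except ValueError as exc:
        log.warning("SCP artifact mask: %s; returning empty mask", exc)
        return np.zeros(scp.shape, dtype=bool)
    opened = ndimage.binary_opening(fg, structure=disk(max(1, min_width_px // 2)))
    labels, n = ndimage.label(opened, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return opened
    keep = np.zeros(n + 1, dtype=bool)
    dt = ndimage.distance_transform_edt(opened)
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    max_dt = ndimage.maximum(dt, labels, index=np.arange(1, n + 1))
    keep[1:] = (areas >= min_large_vessel_px) & (2.0 * max_dt >= min_width_px)
    return keep[labels]


def exclude_artifacts(tel: BinaryMask, scp_large: BinaryMask) -> BinaryMask:
    """Remove SCP large-vessel artifact pixels from the telangiectasia mask
    (conservative reading of 'distinguishing artifact from true dilated
    vessels').  The removed pixel count is logged for audit."""
    tel, scp_large = as_mask(tel), as_mask(scp_large)
    check_same_geometry(tel, scp_large)
    removed = int(np.count_nonzero(tel & scp_large))
    if removed:
        log.info("excluded %d telangiectasia px overlapping SCP large vessels", removed)
    return tel & ~scp_large
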