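"""Threshold operators used to binarize en-face angiograms.

Two operators cover the segmentation needs of the pipeline:

* :func:`phansalkar_threshold` — a local adaptive threshold designed for
  low-contrast vessel images.  The pixelwise threshold is

  .. math:: T(x) = \\mu(x)\\,[1 + p\\,e^{-q\\,\\mu(x)} + k(\\sigma(x)/r - 1)]

  with :math:`\\mu, \\sigma` the mean and standard deviation of the
  [0, 1]-normalized intensities over a circular window centred at *x*
  (clipped at the image border).  A pixel is foreground iff its intensity
  strictly exceeds :math:`T(x)`.

* :func:`max_entropy_threshold` — Kapur's global maximum-entropy threshold:
  the histogram split maximizing the sum of Shannon entropies of the
  below- and above-threshold intensity distributions.

:func:`fill_holes` closes enclosed background to turn binarized vessel
loops into circumscribed areas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import BinaryMask, EnFaceImage, as_mask


@dataclass(frozen=True)
class PhansalkarParams:
    """Constants of the Phansalkar threshold formula.

    Defaults are the widely used values (k=0.25, r=0.5, p=2, q=10 on
    [0, 1]-normalized intensities) with a 15 px circular window radius.
    """

    radius: int = 15
    k: float = 0.25
    r: float = 0.5
    p: float = 2.0
    q: float = 10.0

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("window radius must be >= 1")
        if self.r <= 0:
            raise ValueError("normalization constant r must be > 0")


def _disk_footprint(radius: int) -> np.ndarray:
    """Circular window: pixels whose centre lies within `radius` of the origin."""
    y, x = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (x * x + y * y) <= radius * radius


def _windowed_mean_std(img: np.ndarray, footprint: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean and SD over a footprint clipped at the image border.

    Implemented as three correlations (count, sum, sum of squares) with
    zero padding; dividing by the in-image count makes the border behave
    exactly like a per-pixel loop over the clipped window.
    """
    kernel = footprint.astype(np.float64)
    ones = np.ones_like(img)
    count = ndimage.correlate(ones, kernel, mode="constant", cval=0.0)
    s1 = ndimage.correlate(img, kernel, mode="constant", cval=0.0)
    s2 = ndimage.correlate(img * img, kernel, mode="constant", cval=0.0)
    mean = s1 / count
    var = s2 / count - mean * mean
    std = np.sqrt(np.clip(var, 0.0, None))
    return mean, std


def phansalkar_threshold(img: EnFaceImage | np.ndarray, params: PhansalkarParams | None = None) -> BinaryMask:
    """Binarize an image with the Phansalkar local adaptive threshold.

    Parameters
    ----------
    img
        En-face image (or bare array).  Intensities are min-max normalized
        to [0, 1] first, so the result is invariant to positive affine
        intensity rescaling.
    params
        Formula constants; defaults per :class:`PhansalkarParams`.

    Returns
    -------
    Boolean mask, foreground where normalized intensity > T(x).  A constant
    image yields an all-background mask.
    """
    if params is None:
        params = PhansalkarParams()
    if not isinstance(img, EnFaceImage):
        img = EnFaceImage(np.asarray(img, dtype=np.float64))
    norm = img.normalized()
    mean, std = _windowed_mean_std(norm, _disk_footprint(params.radius))
    thresh = mean * (1.0 + params.p * np.exp(-params.q * mean) + params.k * (std / params.r - 1.0))
    return norm > thresh


def max_entropy_threshold(
    img: EnFaceImage | np.ndarray, nbins: int = 256
) -> tuple[float, BinaryMask]:
    """Kapur maximum-entropy global threshold.

    The intensity range is divided into `nbins` equal bins; for every
    candidate split the Shannon entropies of the renormalized histograms
    below (bins <= t) and above it are summed, with empty bins skipped
    (0 log 0 := 0).  Ties are broken toward the lowest level.

    Returns
    -------
    (level, mask)
        ``level`` is the intensity at the upper edge of the optimal
        background bin; ``mask = img > level``.

    Raises
    ------
    ValueError
        If the image is constant (degenerate histogram: no split exists).
    """
    data = img.data if isinstance(img, EnFaceImage) else np.asarray(img, dtype=np.float64)
    lo, hi = float(data.min()), float(data.max())
    if hi <= lo:
        raise ValueError("degenerate histogram: constant image has no entropy split")
    counts, edges = np.histogram(data, bins=nbins, range=(lo, hi))
    p = counts / counts.sum()

    cum = np.cumsum(p)
    # entropy of bins [0..t] and (t..nbins-1] for every candidate t
    plogp = np.zeros_like(p)
    nz = p > 0
    plogp[nz] = p[nz] * np.log(p[nz])
    cum_plogp = np.cumsum(plogp)
    total_plogp = cum_plogp[-1]

    best_t, best_h = None, -np.inf
    for t in range(nbins - 1):  # at least one bin on each side of the split
        w0, w1 = cum[t], 1.0 - cum[t]
        if w0 <= 0 or w1 <= 0:
            continue
        h0 = np.log(w0) - cum_plogp[t] / w0
        h1 = np.log(w1) - (total_plogp - cum_plogp[t]) / w1
        h = h0 + h1
        if h > best_h + 1e-12:  # strict improvement => lowest-level tie-break
            best_h, best_t = h, t
    if best_t is None:
        raise ValueError("degenerate histogram: no valid split")
    level = float(edges[best_t + 1])
    return level, data > level


def fill_holes(mask: BinaryMask) -> BinaryMask:
    """Fill enclosed background: holes are background components not
    4-connected to the image border (foreground is treated 8-connected
    by duality).  Idempotent and monotone in the foreground.
    """
    return ndimage.binary_fill_holes(as_mask(mask))
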