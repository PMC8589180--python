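"""Core containers shared by every stage of the pipeline.

The study geometry is a square en-face field of view: by default 304x304
pixels spanning 3 mm x 3 mm, so one pixel covers (3/304)^2 mm^2.  All images
and masks of one eye share this geometry; operations that combine arrays
check it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt

#: A binary mask is a plain 2D boolean array sharing the image geometry.
BinaryMask = npt.NDArray[np.bool_]

DEFAULT_GRID = 304
DEFAULT_FIELD_MM = 3.0


@dataclass
class EnFaceImage:
    """A 2D en-face intensity image with its physical scale.

    Parameters
    ----------
    data : ndarray, shape (H, W)
        Intensities.  Stored as float64; :meth:`normalized` maps them to
        [0, 1] for threshold operators that are defined on that range.
    field_mm : float
        Physical side length of the (square) field of view in millimetres.
    """

    data: np.ndarray
    field_mm: float = DEFAULT_FIELD_MM
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"en-face image must be 2D, got shape {self.data.shape}")
        if self.field_mm <= 0:
            raise ValueError("field_mm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def scale_mm_per_px(self) -> float:
        """Physical pixel pitch (mm/pixel) along one axis."""
        return self.field_mm / self.data.shape[0]

    def normalized(self) -> np.ndarray:
        """Return intensities rescaled to [0, 1].

        Non-negative images are divided by their maximum (so the result is
        invariant under multiplication by a positive constant and data
        already in [0, 1] keeps its absolute levels up to that factor);
        images with negative values are min-max rescaled.  An all-zero
        image stays all zeros.
        """
        lo = float(self.data.min())
        hi = float(self.data.max())
        if hi == lo:  # constant image: full level if positive, else empty
            return np.ones_like(self.data) if lo > 0 else np.zeros_like(self.data)
        if lo >= 0:
            return self.data / hi
        return (self.data - lo) / (hi - lo)


def as_mask(arr: npt.ArrayLike) -> BinaryMask:
    """Coerce an array-like to a boolean mask (nonzero = foreground)."""
    return np.asarray(arr) != 0


def check_same_geometry(*arrays: np.ndarray) -> tuple[int, int]:
    """Assert all arrays share one 2D shape; return it."""
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"geometry mismatch: shapes {sorted(shapes)}")
    (shape,) = shapes
    if len(shape) != 2:
        raise ValueError(f"expected 2D arrays, got shape {shape}")
    return shape
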