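"""Decomposition of nested photoreceptor-disruption regions into exclusive
classes and physical areas.

The tracing protocol yields three *combined* regions per eye, nested by
construction:

* ``A`` — all photoreceptor disruption (IZ attenuation + IZ loss + EZ loss),
* ``B`` — IZ loss + EZ loss,
* ``C`` — EZ loss,

with C ⊆ B ⊆ A (every EZ-loss pixel also has IZ loss).  The exclusive
classes are obtained by subtraction: IZ attenuation only = A \\ B and
IZ loss only = B \\ C; these plus C partition A.  Pixel counts convert to
mm² through the squared pixel pitch.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .types import BinaryMask, as_mask, check_same_geometry

log = logging.getLogger(__name__)

NestingPolicy = Literal["clip", "strict"]


@dataclass
class RegionSet:
    """Nested disruption masks of one eye plus the derived exclusive classes."""

    A: BinaryMask
    B: BinaryMask
    C: BinaryMask
    attn_only: BinaryMask
    izloss_only: BinaryMask
    scale_mm_per_px: float
    clipped_px: int = 0  # pixels removed to restore nesting (clip policy)


@dataclass
class EyeRecord:
    """Per-eye scalar summary consumed by the statistics stage.

    Overlap percentages are fractions of the telangiectasia area falling in
    each exclusive disruption class; they are NaN for eyes without
    telangiectasia (undefined ratio).
    """

    patient_id: str
    eye_id: str
    laterality: str
    stage: int
    pooled_group: str
    tel_area_mm2: float
    attn_area_mm2: float
    izloss_area_mm2: float
    ezloss_area_mm2: float
    overlap_attn_pct: float
    overlap_izloss_pct: float
    overlap_ezloss_pct: float
    extra: dict = field(default_factory=dict)


def decompose(
    A: BinaryMask,
    B: BinaryMask,
    C: BinaryMask,
    scale_mm_per_px: float,
    policy: NestingPolicy = "clip",
) -> RegionSet:
    """Split combined regions into exclusive disruption classes.

    Under ``policy="clip"`` nesting violations are repaired (B := B ∩ A,
    C := C ∩ B) and the number of removed pixels is counted and logged;
    under ``policy="strict"`` any violation raises.  Decomposition of
    already-nested masks is the identity on A, B, C.
    """
    A, B, C = as_mask(A), as_mask(B), as_mask(C)
    check_same_geometry(A, B, C)
    b_out = int(np.count_nonzero(B & ~A))
    # C must lie inside the *repaired* B under clip; under strict any pixel
    # of C outside the raw B is a violation as well.
    if policy == "strict":
        c_out = int(np.count_nonzero(C & ~B))
        if b_out or c_out:
            raise ValueError(
                f"nesting violated: {b_out} px of B outside A, {c_out} px of C outside B"
            )
        clipped = 0
    elif policy == "clip":
        B = B & A
        c_out = int(np.count_nonzero(C & ~B))
        C = C & B
        clipped = b_out + c_out
        if clipped:
            log.warning("nesting repaired by clipping %d px (B\\A: %d, C\\B: %d)", clipped, b_out, c_out)
    else:
        raise ValueError(f"unknown nesting policy: {policy!r}")
    return RegionSet(
        A=A,
        B=B,
        C=C,
        attn_only=A & ~B,
        izloss_only=B & ~C,
        scale_mm_per_px=scale_mm_per_px,
        clipped_px=clipped,
    )


def area_mm2(mask: BinaryMask, scale_mm_per_px: float) -> float:
    """Physical area: foreground pixel count x (mm per pixel)^2."""
    if scale_mm_per_px <= 0:
        raise ValueError("scale must be positive")
    return int(np.count_nonzero(as_mask(mask))) * scale_mm_per_px**2


def percent_overlap(tel: BinaryMask, region: BinaryMask) -> float:
    """Overlap of a region with telangiectasia, as % of telangiectasia area.

    Returns NaN (with a warning) when the telangiectasia mask is empty:
    the ratio is undefined for eyes without telangiectasia.
    """
    tel, region = as_mask(tel), as_mask(region)
    check_same_geometry(tel, region)
    denom = int(np.count_nonzero(tel))
    if denom == 0:
        log.warning("empty telangiectasia mask: percent overlap undefined")
        return math.nan
    return 100.0 * int(np.count_nonzero(tel & region)) / denom
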