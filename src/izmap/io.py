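"""Reading and writing of images, masks, ROIs and cohort tables.

Images travel as single-channel TIFF (16-bit) or PNG with a JSON sidecar
carrying the physical scale and eye metadata; masks as 8-bit {0, 255}
TIFF/PNG; ROIs as JSON polygon lists or mask images; cohort records as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .regions import EyeRecord
from .segmentation import MarkedROI
from .types import DEFAULT_FIELD_MM, BinaryMask, EnFaceImage, as_mask


def _read_array(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path))
    arr = np.asarray(Image.open(path))
    if arr.ndim == 3:  # collapse any colour channels
        arr = arr[..., :3].mean(axis=-1)
    return arr


def read_image(path: str | Path, field_mm: float | None = None) -> EnFaceImage:
    """Read a TIFF/PNG en-face image; a `<name>.json` sidecar, if present,
    supplies ``field_mm`` and metadata."""
    path = Path(path)
    arr = _read_array(path).astype(np.float64)
    meta: dict = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    fm = field_mm or meta.get("field_mm", DEFAULT_FIELD_MM)
    return EnFaceImage(arr, field_mm=fm, meta=meta)


def write_image(path: str | Path, img: EnFaceImage) -> None:
    """Write a 16-bit single-channel TIFF (intensities scaled to the full
    range) plus a JSON sidecar with field_mm and metadata."""
    path = Path(path)
    norm = img.normalized()
    tifffile.imwrite(path, (norm * 65535).astype(np.uint16))
    sidecar = {"field_mm": img.field_mm, "grid_size": img.shape[0], **img.meta}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_mask(path: str | Path) -> BinaryMask:
    return as_mask(_read_array(Path(path)))


def write_mask(path: str | Path, mask: BinaryMask) -> None:
    tifffile.imwrite(Path(path), (as_mask(mask).astype(np.uint8) * 255))


def read_region(path: str | Path, shape: tuple[int, int]) -> BinaryMask:
    """Region mask from a mask image (its own geometry) or a JSON polygon
    file rasterized to ``shape``."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return read_roi(path).to_mask(shape)
    return read_mask(path)


def read_roi(path: str | Path, shape: tuple[int, int] | None = None) -> MarkedROI:
    """ROI from a JSON polygon file (``{"vertices": [[row, col], ...]}`` or a
    bare vertex list) or from a mask image."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        obj = json.loads(path.read_text())
        verts = obj["vertices"] if isinstance(obj, dict) else obj
        return MarkedROI(vertices=np.asarray(verts, dtype=float))
    return MarkedROI(mask=read_mask(path))


def records_to_frame(records: list[EyeRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = {k: v for k, v in vars(r).items() if k != "extra"}
        d.update(r.extra)
        rows.append(d)
    return pd.DataFrame(rows)


def write_records(path: str | Path, records: list[EyeRecord] | pd.DataFrame) -> None:
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df.to_csv(path, index=False)
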