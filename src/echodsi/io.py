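"""Plain-text cohort I/O: contour CSV, label CSV, masks and feature tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .morphology import LesionContour, LesionMask


def save_contour_csv(contour: LesionContour, path) -> None:
    """Closed polygon as (x_px, y_px) rows, 0-based pixel coordinates."""
    pd.DataFrame(contour.vertices, columns=["x_px", "y_px"]).to_csv(path, index=False)


def load_contour_csv(path) -> LesionContour:
    df = pd.read_csv(path)
    return LesionContour(vertices=df[["x_px", "y_px"]].to_numpy(dtype=float))


def save_labels_csv(rows: list[dict], path) -> None:
    """Label table with columns (case_id, label, area_cm2)."""
    pd.DataFrame(rows, columns=["case_id", "label", "area_cm2"]).to_csv(path, index=False)


def load_labels_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    bad = set(df["label"].unique()) - {-1, 1}
    if bad:
        raise ValueError(f"labels must be -1/+1, found {sorted(bad)}")
    return df


def save_mask_png(mask: LesionMask, path) -> None:
    """Binary mask as an 8-bit PNG (0 background, 255 lesion)."""
    img = (mask.mask.astype(np.uint8)) * 255
    Image.fromarray(img, mode="L").save(path, format="PNG")


def load_mask_png(path, axial_pitch: float = 1.0, lateral_pitch: float = 1.0) -> LesionMask:
    arr = np.asarray(Image.open(Path(path)).convert("L"))
    return LesionMask(mask=arr > 127, axial_pitch=axial_pitch, lateral_pitch=lateral_pitch)
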