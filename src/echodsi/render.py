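"""Probability-of-malignancy maps and color overlays on B-mode.

The combined score (PC1, projection or SVM distance) is clipped between
training-derived limits and mapped linearly to a probability of malignancy
in [0, 1]. Within a lesion, the H-scan color level is the only localized
feature, so the per-pixel combined parameter replaces the lesion-global
H-scan value with the pixel's own level while the remaining features stay
at their lesion-global values. The resulting map is median- then
Gaussian-smoothed (mask-aware) and color-coded over the grayscale B-mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from scipy.stats import spearmanr

from .frames import BModeImage
from .hscan import HScanMap
from .scoring import DSIModel

COLORMAPS = ("green_red", "lightblue_red")


def colormap_table(name: str = "lightblue_red") -> np.ndarray:
    """256-entry uint8 RGB lookup table, low probability -> high probability.

    ``green_red`` interpolates green to red (benign to malignant);
    ``lightblue_red`` interpolates light blue to red via white, matching the
    overlay color bar convention.
    """
    t = np.linspace(0.0, 1.0, 256)[:, None]
    if name == "green_red":
        lo, hi = np.array([0, 200, 0.0]), np.array([255, 0, 0.0])
        rgb = (1 - t) * lo + t * hi
    elif name == "lightblue_red":
        lo, mid, hi = (
            np.array([120, 200, 255.0]),
            np.array([255, 255, 220.0]),
            np.array([255, 30, 0.0]),
        )
        first = t < 0.5
        rgb = np.where(first, (1 - 2 * t) * lo + 2 * t * mid, (2 - 2 * t) * mid + (2 * t - 1) * hi)
    else:
        raise ValueError(f"unknown colormap {name!r}; choose from {COLORMAPS}")
    return np.round(rgb).astype(np.uint8)


def export_colormap_csv(path, name: str = "lightblue_red") -> None:
    """Write the 256-row (index, R, G, B) lookup table for reproducibility."""
    table = colormap_table(name)
    df = pd.DataFrame(
        {"index": np.arange(256), "R": table[:, 0], "G": table[:, 1], "B": table[:, 2]}
    )
    df.to_csv(path, index=False)


def score_to_probability(score, limits: tuple[float, float]) -> np.ndarray:
    """Clip a score between (d_lo, d_hi) and map linearly onto [0, 1]."""
    d_lo, d_hi = limits
    if not d_lo < d_hi:
        raise ValueError("require d_lo < d_hi")
    score = np.asarray(score, dtype=float)
    return (np.clip(score, d_lo, d_hi) - d_lo) / (d_hi - d_lo)


def pixelwise_parameter(
    hmap: HScanMap,
    mask: np.ndarray,
    global_features: dict | pd.Series,
    model: DSIModel,
    combiner: str = "pc1",
) -> np.ndarray:
    """Per-pixel combined score over the lesion (NaN outside the mask).

    Each lesion pixel's feature vector equals the lesion-global vector with
    ``hscan_color_level`` replaced by the pixel's own color level.
    """
    if not hasattr(model, "scorers_"):
        raise ValueError("model is not trained")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != hmap.color_level.shape:
        raise ValueError("mask and H-scan map shapes differ")
    names = model.feature_names_
    if "hscan_color_level" not in names:
        raise ValueError("model does not use the localized hscan_color_level feature")
    base = np.array([float(global_features[n]) for n in names])
    n_px = int(mask.sum())
    X = np.tile(base, (n_px, 1))
    X[:, names.index("hscan_color_level")] = hmap.color_level[mask].astype(float)
    scores = model.decision_function(X, combiner=combiner)
    out = np.full(mask.shape, np.nan)
    out[mask] = scores
    return out


def smooth_within_lesion(
    score_map: np.ndarray,
    mask: np.ndarray,
    median_kernel: int = 5,
    gaussian_sigma: float = 2.0,
) -> np.ndarray:
    """Mask-aware 2-D median then Gaussian smoothing of a lesion score map.

    Pixels outside the lesion never contribute: the median ignores them and
    the Gaussian renormalizes over in-mask weight. Output values stay within
    the input's [min, max] over the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if median_kernel % 2 != 1:
        raise ValueError("median kernel must be odd")
    rows = np.any(mask, axis=1).sum()
    cols = np.any(mask, axis=0).sum()
    if median_kernel > max(rows, cols):
        raise ValueError("median kernel exceeds the lesion extent")
    work = np.where(mask, score_map, np.nan)

    med = ndimage.generic_filter(
        work, np.nanmedian, size=median_kernel, mode="constant", cval=np.nan
    )

    filled = np.where(mask, med, 0.0)
    num = ndimage.gaussian_filter(filled, gaussian_sigma)
    den = ndimage.gaussian_filter(mask.astype(float), gaussian_sigma)
    smooth = np.where(mask & (den > 0), num / np.maximum(den, 1e-12), np.nan)

    vals = score_map[mask]
    smooth[mask] = np.clip(smooth[mask], vals.min(), vals.max())
    out = np.full(score_map.shape, np.nan)
    out[mask] = smooth[mask]
    return out


@dataclass
class DSIOverlay:
    rgb: np.ndarray  # uint8 [H, W, 3]
    colormap_id: str
    alpha: float

    def save_png(self, path) -> None:
        Image.fromarray(self.rgb, mode="RGB").save(path, format="PNG")


def render_overlay(
    bmode: BModeImage,
    mask: np.ndarray,
    prob: np.ndarray,
    colormap: str = "lightblue_red",
    alpha: float = 0.6,
) -> DSIOverlay:
    """Alpha-blend the probability colormap over grayscale B-mode within the lesion.

    Pixels outside the lesion equal the (rounded 8-bit) grayscale B-mode;
    with ``alpha = 0`` the overlay is exactly the B-mode.
    """
    mask = np.asarray(mask, dtype=bool)
    if bmode.intensity.shape != mask.shape or prob.shape != mask.shape:
        raise ValueError("B-mode, mask, and probability map shapes differ")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    p = prob[mask]
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("probabilities outside [0, 1]")
    gray = np.round(bmode.intensity).astype(np.uint8)
    rgb = np.repeat(gray[:, :, None], 3, axis=2).astype(float)
    table = colormap_table(colormap)
    idx = np.clip(np.round(p * 255).astype(int), 0, 255)
    colors = table[idx].astype(float)
    rgb[mask] = alpha * colors + (1.0 - alpha) * rgb[mask]
    return DSIOverlay(
        rgb=np.round(rgb).astype(np.uint8), colormap_id=colormap, alpha=alpha
    )


def score_grade_correlation(scores, reader_grades) -> float:
    """Spearman rank correlation between combined scores and ordinal reader grades."""
    scores = np.asarray(scores, dtype=float)
    grades = np.asarray(reader_grades, dtype=float)
    if scores.size < 3 or scores.size != grades.size:
        raise ValueError("need >= 3 paired observations")
    if np.all(scores == scores[0]) or np.all(grades == grades[0]):
        raise ValueError("constant input; rank correlation undefined")
    rho, _ = spearmanr(scores, grades)
    return float(rho)
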