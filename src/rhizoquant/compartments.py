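"""BFA-body quantification: threshold, label, and measure particles.

Brefeldin A collapses secretory endomembranes into aggregates ("BFA
bodies"); their number, area and brightness report on secretory-pathway
activity.  The workflow mirrors the standard particle-analysis chain:
threshold the image to a binary, label connected components, discard
speckles, and measure each particle's pixel area and its mean intensity
on the ORIGINAL image (never on the binary).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as _label
from skimage.measure import regionprops_table
from skimage.morphology import remove_small_objects

__all__ = ["segment_particles", "particle_stats", "quantify"]


def _resolve_threshold(image: np.ndarray, threshold_method) -> float:
    if threshold_method == "otsu":
        if image.max() == image.min():
            return float(image.max())
        return float(threshold_otsu(image))
    return float(threshold_method)


def segment_particles(
    image: np.ndarray,
    threshold_method: str | float = "otsu",
    min_area: int = 4,
    connectivity: int = 2,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Label connected particles above a global threshold.

    Foreground is ``image > threshold``; components are labeled with
    8-connectivity by default (``connectivity=1`` for 4-connectivity),
    components smaller than ``min_area`` pixels are discarded, and labels
    are re-numbered contiguously from 1.  An optional binary ``mask``
    restricts the analysis to one cell.  Returns the label matrix and
    the threshold value used.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    t = _resolve_threshold(image, threshold_method)
    fg = image > t
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != image.shape:
            raise ValueError("mask shape must match image shape")
        fg &= mask
    if min_area > 1:
        # max_size removes components <= value: discard strictly below min_area
        fg = remove_small_objects(fg, max_size=min_area - 1,
                                  connectivity=connectivity)
    labels = _label(fg, connectivity=connectivity)
    return labels, t


def particle_stats(
    labels: np.ndarray,
    image: np.ndarray,
    pixel_size: float | None = None,
) -> pd.DataFrame:
    """Per-particle area, mean original-image intensity, and centroid.

    ``pixel_size`` (µm per pixel) adds an ``area_um2`` column.  Intensity
    is always measured on the original image the labels were derived
    from, not on the binary.
    """
    labels = np.asarray(labels)
    image = np.asarray(image, dtype=np.float64)
    if labels.shape != image.shape:
        raise ValueError(f"shape mismatch: {labels.shape} vs {image.shape}")
    if labels.max() == 0:
        cols = ["particle_id", "area_px", "mean_intensity",
                "centroid_row", "centroid_col"]
        df = pd.DataFrame(columns=cols)
    else:
        props = regionprops_table(
            labels, intensity_image=image,
            properties=("label", "area", "intensity_mean", "centroid"),
        )
        df = pd.DataFrame(props).rename(columns={
            "label": "particle_id", "area": "area_px",
            "intensity_mean": "mean_intensity",
            "centroid-0": "centroid_row", "centroid-1": "centroid_col",
        })
    if pixel_size is not None:
        df["area_um2"] = df["area_px"] * pixel_size**2
    return df


def quantify(
    image: np.ndarray,
    threshold_method: str | float = "otsu",
    min_area: int = 4,
    connectivity: int = 2,
    mask: np.ndarray | None = None,
    pixel_size: float | None = None,
) -> tuple[pd.DataFrame, float]:
    """Segment and measure in one call; returns (table, threshold_used)."""
    labels, t = segment_particles(image, threshold_method, min_area,
                                  connectivity, mask)
    return particle_stats(labels, image, pixel_size), t
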