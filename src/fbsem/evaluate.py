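"""Quantitative evaluation: NRMSE, Gaussian post-filtering, line profiles
and multi-method comparison tables.

NRMSE convention: root-sum-of-squares error over a region divided by the
root-sum-of-squares of the reference over the same region, so it is
invariant to a common rescaling of both images. ROI tables use the phantom
tissue and lesion masks eroded by one pixel to reduce boundary ambiguity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "nrmse",
    "gaussian_post_filter",
    "line_profile",
    "roi_masks",
    "compare_methods",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def nrmse(x: np.ndarray, ref: np.ndarray, roi: np.ndarray | None = None) -> float:
    """sqrt(sum_roi (x - ref)^2) / sqrt(sum_roi ref^2)."""
    x = np.asarray(x, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if x.shape != ref.shape:
        raise ValueError("image and reference shapes differ")
    if roi is not None:
        if roi.shape != ref.shape:
            raise ValueError("roi shape differs")
        if not np.any(roi):
            raise ValueError("empty ROI")
        x, ref = x[roi], ref[roi]
    denom = np.sqrt(np.sum(ref**2))
    if denom == 0:
        raise ValueError("reference is identically zero on the ROI")
    return float(np.sqrt(np.sum((x - ref) ** 2)) / denom)


def gaussian_post_filter(x: np.ndarray, fwhm_mm: float, spacing_mm: float = 2.08) -> np.ndarray:
    """Isotropic Gaussian smoothing with the given full-width-half-maximum."""
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return np.asarray(x, dtype=np.float64).copy()
    sigma_px = fwhm_mm * FWHM_TO_SIGMA / spacing_mm
    return ndimage.gaussian_filter(np.asarray(x, dtype=np.float64), sigma_px)


def line_profile(
    x: np.ndarray,
    start_mm: tuple[float, float],
    end_mm: tuple[float, float],
    spacing_mm: float = 2.08,
    n_points: int | None = None,
    order: int = 1,
) -> pd.DataFrame:
    """Sample the image along a segment given in physical (y, x) mm from the
    grid centre; returns position along the segment and activity."""
    x = np.asarray(x, dtype=np.float64)
    size = np.array(x.shape)

    def to_px(p):
        return np.array(p) / spacing_mm + size / 2.0 - 0.5

    p0, p1 = to_px(start_mm), to_px(end_mm)
    if np.any(p0 < -0.5) or np.any(p0 > size - 0.5) or np.any(p1 < -0.5) or np.any(p1 > size - 0.5):
        raise ValueError("profile endpoints fall outside the grid")
    length_mm = float(np.hypot(*(np.array(end_mm) - np.array(start_mm))))
    if n_points is None:
        n_points = max(int(np.ceil(length_mm / spacing_mm)) * 2 + 1, 2)
    frac = np.linspace(0.0, 1.0, n_points)
    coords = p0[:, None] * (1 - frac) + p1[:, None] * frac
    vals = ndimage.map_coordinates(x, coords, order=order, mode="nearest")
    return pd.DataFrame({"position_mm": frac * length_mm, "activity": vals})


def roi_masks(sample, erode_px: int = 1) -> dict[str, np.ndarray]:
    """Evaluation ROIs from a phantom sample: grey/white matter and pooled
    hot/cold lesion masks, each eroded by ``erode_px`` pixels (erosion is
    skipped for a region it would empty)."""

    def _erode(m):
        if erode_px > 0:
            e = ndimage.binary_erosion(m, iterations=erode_px)
            if np.any(e):
                return e
        return m

    rois = {
        "grey_matter": _erode(sample.tissue_masks["grey"]),
        "white_matter": _erode(sample.tissue_masks["white"]),
    }
    for pol in ("hot", "cold"):
        pooled = np.zeros(sample.shape, dtype=bool)
        for les in sample.lesions:
            if les.polarity == pol and les.placement != "mr_only":
                pooled |= les.mask
        if np.any(pooled):
            rois[f"{pol}_lesions"] = _erode(pooled)
    rois["global"] = np.ones(sample.shape, dtype=bool)
    return rois


def compare_methods(records, methods: dict, erode_px: int = 1) -> pd.DataFrame:
    """Tabulate NRMSE per method, ROI and count level.

    ``methods`` maps a method name to a callable ``record -> 2D image``.
    Returns a tidy DataFrame with one row per (method, ROI, count level),
    averaging NRMSE over the records at each count level.
    """
    rows = []
    for name, fn in methods.items():
        per_roi: dict[tuple[str, float], list[float]] = {}
        for rec in records:
            img = fn(rec)
            img = img.data if hasattr(img, "data") else np.asarray(img)
            for roi_name, roi in roi_masks(rec.sample, erode_px).items():
                key = (roi_name, rec.count_level)
                per_roi.setdefault(key, []).append(
                    nrmse(img, rec.reference.data, roi)
                )
        for (roi_name, level), errs in per_roi.items():
            rows.append(
                {
                    "method": name,
                    "roi": roi_name,
                    "count_level": level,
                    "nrmse": float(np.mean(errs)),
                    "n_samples": len(errs),
                }
            )
    return pd.DataFrame(rows)
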