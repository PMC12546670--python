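"""Automated grain ROI extraction from corrected hypercubes.

The workflow mirrors a standard seed-tray protocol: threshold a score image
(coarse 70/250 plus optional polygon mask, fine 25/250), clean the mask
morphologically, label 8-connected components, drop sub-threshold specks
(< 80 px), sort grains into rows by centroid Y and left-to-right within each
row, then average the reflectance of each grain's pixels into one spectrum
per grain.  A false-color RGB rendering from three NIR bands (954.15 /
927.55 / 904.28 nm) is produced for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import polygon2mask
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from .hsi import ReflectanceCube

__all__ = [
    "SegmentationParams", "GrainROI", "score_image", "segment_grains",
    "label_and_filter", "order_rois", "extract_mean_spectra", "render_fc_rgb",
    "extract_rois", "rois_to_frame",
]

FC_RGB_NM = (954.15, 927.55, 904.28)  # R, G, B channel center wavelengths


def _elliptical_footprint(size=3):
    # 3x3 ellipse == plus-shaped cross
    yy, xx = np.mgrid[:size, :size] - (size - 1) / 2
    r = (size - 1) / 2
    return (yy ** 2 + xx ** 2) <= r ** 2 + 1e-9


@dataclass
class SegmentationParams:
    coarse_threshold: float = 70.0   # 0-250 scale
    fine_threshold: float = 25.0     # 0-250 scale
    polygon_mask: np.ndarray | None = None   # (K, 2) vertices (y, x)
    morph_kernel: int = 3
    min_area: int = 80
    n_rows: int = 5
    use_otsu: bool = False           # compute Otsu instead of the fixed fine threshold

    def __post_init__(self):
        if not 0 < self.fine_threshold < self.coarse_threshold <= 250:
            raise ValueError(
                "need 0 < fine_threshold < coarse_threshold <= 250")
        if self.min_area < 1:
            raise ValueError("min_area must be at least 1 pixel")
        if self.n_rows < 1:
            raise ValueError("n_rows must be at least 1")


@dataclass
class GrainROI:
    """One labeled grain: pixel set, centroid, area, and raster position."""

    label: int
    pixels: np.ndarray               # (area, 2) of 0-based (row, col)
    centroid: tuple                  # (y, x)
    area: int
    raster_index: int | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, int)
        if self.area != len(self.pixels):
            raise ValueError("area must equal the pixel count")


def score_image(cube: ReflectanceCube, wavelength_nm: float = FC_RGB_NM[0],
                window: int = 1) -> np.ndarray:
    """Reflectance plane (optionally a small band-window mean) on a 0-250 scale."""
    b = cube.grid.index_of(wavelength_nm)
    lo = max(0, b - window // 2)
    plane = cube.values[:, :, lo:lo + window].mean(axis=2)
    return np.clip(plane, 0.0, 1.0) * 250.0


def segment_grains(score: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Binary grain mask from a 0-250 score image.

    Coarse threshold (plus optional polygon mask) bounds the candidate
    region; the fine threshold (fixed 25/250 by default, Otsu optionally)
    is applied within it.  Opening removes isolated noise; closing and hole
    filling complete grain interiors.
    """
    score = np.asarray(score, float)
    if score.ndim != 2:
        raise ValueError("score image must be 2-D")
    if score.size == 0 or not score.any():
        return np.zeros_like(score, bool)

    candidate = score > params.coarse_threshold
    if params.polygon_mask is not None:
        candidate &= polygon2mask(score.shape, np.asarray(params.polygon_mask))
    # dilate the coarse region so the fine threshold can recover grain borders
    candidate = ndimage.binary_dilation(candidate, iterations=2)

    fine_t = params.fine_threshold
    if params.use_otsu and candidate.any():
        fine_t = float(threshold_otsu(score[candidate]))
    mask = (score > fine_t) & candidate

    fp = _elliptical_footprint(params.morph_kernel)
    mask = ndimage.binary_opening(mask, structure=fp)
    mask = ndimage.binary_closing(mask, structure=fp)
    return ndimage.binary_fill_holes(mask)


def label_and_filter(mask: np.ndarray, min_area: int = 80) -> list:
    """8-connected components with area >= ``min_area``, relabeled 1..N."""
    mask = np.asarray(mask, bool)
    lab = cc_label(mask, connectivity=2)
    rois = []
    for region in regionprops(lab):
        if region.area < min_area:
            continue
        rois.append(GrainROI(label=len(rois) + 1, pixels=region.coords,
                             centroid=tuple(region.centroid),
                             area=int(region.area)))
    return rois


def order_rois(rois: list, n_rows: int = 5) -> list:
    """Assign raster indices: rows by centroid Y, left-to-right within rows.

    Rows are found by sorting centroid Y and splitting at the ``n_rows - 1``
    largest gaps — deterministic and robust to a few pixels of row jitter.
    Returns a new list sorted by raster index.
    """
    if not rois:
        raise ValueError("no ROIs to order")
    if n_rows > len(rois):
        raise ValueError(f"n_rows={n_rows} exceeds the ROI count ({len(rois)})")
    ys = np.array([r.centroid[0] for r in rois])
    order = np.argsort(ys, kind="stable")
    row_id = np.zeros(len(rois), int)
    if n_rows > 1:
        gaps = np.diff(ys[order])
        # the (n_rows-1) widest gaps separate the rows
        cuts = np.sort(np.argsort(gaps)[-(n_rows - 1):])
        boundaries = np.zeros(len(rois), int)
        boundaries[cuts + 1] = 1
        row_of_sorted = np.cumsum(boundaries)
        row_id[order] = row_of_sorted
    xs = np.array([r.centroid[1] for r in rois])
    final = np.lexsort((xs, row_id))
    out = []
    for rank, idx in enumerate(final):
        r = rois[idx]
        out.append(GrainROI(label=r.label, pixels=r.pixels, centroid=r.centroid,
                            area=r.area, raster_index=rank))
    return out


def extract_mean_spectra(cube: ReflectanceCube, rois: list) -> np.ndarray:
    """Per-ROI mean spectrum, shape (n_rois, B), ordered by raster index."""
    ordered = sorted(rois, key=lambda r: (r.raster_index is None,
                                          r.raster_index))
    H, W, _ = cube.values.shape
    out = np.empty((len(ordered), cube.grid.n_bands), np.float64)
    for i, roi in enumerate(ordered):
        if roi.area == 0:
            raise ValueError(f"ROI {roi.label} has no pixels")
        ys, xs = roi.pixels[:, 0], roi.pixels[:, 1]
        if ys.max() >= H or xs.max() >= W or ys.min() < 0 or xs.min() < 0:
            raise ValueError(f"ROI {roi.label} extends outside the cube")
        out[i] = cube.values[ys, xs, :].mean(axis=0)
    return out


def render_fc_rgb(cube: ReflectanceCube, r_nm=FC_RGB_NM[0], g_nm=FC_RGB_NM[1],
                  b_nm=FC_RGB_NM[2]) -> np.ndarray:
    """False-color RGB from three bands, each min-max scaled to 0-255."""
    chans = []
    for nm in (r_nm, g_nm, b_nm):
        plane = cube.band_at(nm).astype(np.float64)
        lo, hi = plane.min(), plane.max()
        if hi == lo:
            chans.append(np.full(plane.shape, 127.5))
        else:
            chans.append((plane - lo) / (hi - lo) * 255.0)
    return np.stack(chans, axis=2).astype(np.uint8)


def extract_rois(cube: ReflectanceCube, params: SegmentationParams | None = None):
    """Full pipeline: segment -> label/filter -> order -> mean spectra.

    Returns ``(rois, spectra)`` with rois sorted by raster index.
    """
    params = params or SegmentationParams()
    mask = segment_grains(score_image(cube), params)
    rois = label_and_filter(mask, params.min_area)
    rois = order_rois(rois, params.n_rows)
    spectra = extract_mean_spectra(cube, rois)
    return rois, spectra


def rois_to_frame(rois: list) -> pd.DataFrame:
    """ROI geometry table (one row per grain)."""
    return pd.DataFrame([
        {"grain_id": r.label, "raster_index": r.raster_index,
         "centroid_y": r.centroid[0], "centroid_x": r.centroid[1],
         "area": r.area}
        for r in rois
    ])
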