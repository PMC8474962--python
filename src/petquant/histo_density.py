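"""Nuclei counting and cellular density (cells/mm^2) on histology-like images.

Detection pipeline per rectangular ROI: threshold at a dark-intensity
percentile (stains vary in absolute intensity, so the cutoff is relative),
remove objects below a minimum area, then split merged blobs by a
distance-transform watershed seeded at local maxima separated by at least
one nucleus radius. The density statistic — not pixel-perfect agreement with
any particular interactive detector — is the quantity that matters
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.segmentation import watershed

__all__ = ["ROI", "DensityResult", "count_nuclei"]


@dataclass(frozen=True)
class ROI:
    """Rectangular region of interest in pixel coordinates (row, col, h, w)."""

    row: int
    col: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("ROI must have positive height and width")


@dataclass(frozen=True)
class DensityResult:
    """Per-ROI counts and areas plus the mean cellular density."""

    counts: tuple[int, ...]
    areas_mm2: tuple[float, ...]
    densities: tuple[float, ...]  # cells/mm^2 per ROI

    @property
    def mean_density(self) -> float:
        return float(np.mean(self.densities))


def _remove_small(mask: np.ndarray, min_px: int) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[labels]


def _count_in_patch(
    patch: np.ndarray,
    pixel_size_um: float,
    min_area_um2: float,
    intensity_percentile: float | None,
    nucleus_radius_um: float,
) -> int:
    if intensity_percentile is None:
        if patch.max() == patch.min():
            return 0
        thr = threshold_otsu(patch)
    else:
        thr = np.percentile(patch, intensity_percentile)
    dark = patch <= thr
    if dark.all() or not dark.any():
        return 0
    # nucleus-free patch: Otsu then splits background noise; real nuclei are
    # far darker than the background class spread
    if patch[dark].mean() > patch[~dark].mean() - 5.0 * patch[~dark].std():
        return 0
    min_px = max(1, int(round(min_area_um2 / pixel_size_um**2)))
    dark = _remove_small(dark, min_px)
    if not dark.any():
        return 0
    dist = ndimage.distance_transform_edt(dark)
    # seeds closer than half a nucleus radius are one nucleus; tighter
    # suppression than a full radius is needed to split strongly merged pairs
    min_sep_px = max(1, int(round(0.5 * nucleus_radius_um / pixel_size_um)))
    peaks = peak_local_max(
        dist, min_distance=min_sep_px, labels=sk_label(dark), exclude_border=False
    )
    if peaks.shape[0] == 0:
        return int(sk_label(dark).max())
    markers = np.zeros(patch.shape, dtype=int)
    markers[tuple(peaks.T)] = np.arange(1, peaks.shape[0] + 1)
    segmented = watershed(-dist, markers, mask=dark)
    # re-apply the size filter to the split objects
    ids, sizes = np.unique(segmented[segmented > 0], return_counts=True)
    return int((sizes >= min_px).sum())


def count_nuclei(
    image: np.ndarray,
    rois: list[ROI],
    pixel_size_um: float,
    min_area_um2: float = 9.0,
    intensity_percentile: float | None = None,
    nucleus_radius_um: float = 3.0,
) -> DensityResult:
    """Count nuclei and compute cellular density in each rectangular ROI.

    ``image`` is a grayscale (hematoxylin-channel) array where nuclei are
    dark; ``pixel_size_um`` sets the physical scale. The dark/background
    cutoff is Otsu's threshold by default (robust to how much of the field
    nuclei cover); pass ``intensity_percentile`` to threshold at a fixed
    darkest percentile instead. Typically 3-4 ROIs are averaged per section.
    A zero-nuclei ROI yields count 0, not an error.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D grayscale image")
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be > 0 um")
    if not rois:
        raise ValueError("at least one ROI is required")
    counts, areas, densities = [], [], []
    for roi in rois:
        if (
            roi.row < 0
            or roi.col < 0
            or roi.row + roi.height > img.shape[0]
            or roi.col + roi.width > img.shape[1]
        ):
            raise ValueError(f"ROI {roi} outside image of shape {img.shape}")
        patch = img[roi.row : roi.row + roi.height, roi.col : roi.col + roi.width]
        n = _count_in_patch(
            patch, pixel_size_um, min_area_um2, intensity_percentile, nucleus_radius_um
        )
        area_mm2 = roi.height * roi.width * (pixel_size_um / 1000.0) ** 2
        counts.append(n)
        areas.append(area_mm2)
        densities.append(n / area_mm2)
    return DensityResult(
        counts=tuple(counts), areas_mm2=tuple(areas), densities=tuple(densities)
    )
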