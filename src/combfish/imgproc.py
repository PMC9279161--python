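"""Linear pre-filtering of raw fluorescence images and spot detection.

Rolling-circle products (RCPs) appear as diffraction-limited dots on a
slowly varying autofluorescent background.  Before any downstream step every
image is band-pass filtered with a *difference of Hannings*: a sum-one
Hanning kernel of radius 0.5 um minus a sum-one Hanning kernel of radius
1 um.  The difference sums to zero, so constant backgrounds vanish and a dot
of roughly the small-kernel size is preserved.  Nuclear-stain (DAPI) images
instead get a disk top-hat with an 8 um radius.  Spots are strict local
maxima of the filtered image above a detection threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk, white_tophat

__all__ = [
    "FilterKernel",
    "SpotCloud",
    "difference_of_hannings",
    "filter_image",
    "tophat_background",
    "detect_spots",
    "mad_threshold",
]


@dataclass(frozen=True)
class FilterKernel:
    """A 2D convolution kernel plus the pixel pitch it was built for."""

    values: np.ndarray
    pixel_size_um: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class SpotCloud:
    """Detected spot coordinates (row, col; zero-based) and intensities."""

    coordinates: np.ndarray  # (n, 2) int
    intensities: np.ndarray  # (n,)
    tile: int | None = None
    round: int | None = None
    channel: int | None = None

    def __len__(self) -> int:
        return len(self.coordinates)


def _hanning_kernel_1d(half_width: int) -> np.ndarray:
    """Hanning window of length ``2*half_width + 1`` with zero endpoints,
    normalized to sum 1."""
    w = np.hanning(2 * half_width + 1)
    return w / w.sum()


def _hanning_kernel_2d(half_width: int) -> np.ndarray:
    h = _hanning_kernel_1d(half_width)
    return np.outer(h, h)


def difference_of_hannings(
    pixel_size_um: float, r_small_um: float = 0.5, r_large_um: float = 1.0
) -> FilterKernel:
    """Band-pass kernel H(r_small) - H(r_large), each H normalized to sum 1.

    Radii in microns are rounded to the nearest whole pixel; both must be
    at least one pixel and the small radius strictly smaller.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    if r_small_um >= r_large_um:
        raise ValueError("r_small_um must be smaller than r_large_um")
    w_small = round(r_small_um / pixel_size_um)
    w_large = round(r_large_um / pixel_size_um)
    if w_small < 1:
        raise ValueError(
            f"small Hanning radius rounds to {w_small} px; must be >= 1"
        )
    if w_large <= w_small:
        raise ValueError("Hanning radii collapse to the same pixel width")
    small = _hanning_kernel_2d(w_small)
    large = _hanning_kernel_2d(w_large)
    pad = w_large - w_small
    kernel = -large
    kernel[pad:-pad, pad:-pad] += small
    return FilterKernel(values=kernel, pixel_size_um=pixel_size_um)


def filter_image(image: np.ndarray, kernel: FilterKernel) -> np.ndarray:
    """Convolve with reflect boundary handling; output has the input shape."""
    image = np.asarray(image, dtype=float)
    if image.shape[0] < kernel.shape[0] or image.shape[1] < kernel.shape[1]:
        raise ValueError(
            f"image {image.shape} smaller than kernel {kernel.shape}"
        )
    return ndimage.convolve(image, kernel.values, mode="reflect")


def tophat_background(
    image: np.ndarray, pixel_size_um: float, radius_um: float = 8.0
) -> np.ndarray:
    """White top-hat with a disk footprint of radius round(radius_um/pixel)."""
    radius_px = round(radius_um / pixel_size_um)
    if radius_px < 1:
        raise ValueError("top-hat radius rounds below one pixel")
    image = np.asarray(image, dtype=float)
    if min(image.shape) < 2 * radius_px + 1:
        raise ValueError("image smaller than the top-hat footprint")
    return white_tophat(image, footprint=disk(radius_px))


def mad_threshold(filtered: np.ndarray, k: float = 6.0) -> float:
    """Detection threshold as k times the median absolute deviation.

    A difference-of-Hannings image is zero-centred over background, so the
    MAD is a robust noise scale unaffected by the sparse bright spots.
    """
    med = np.median(filtered)
    return float(k * np.median(np.abs(filtered - med)))


def detect_spots(filtered: np.ndarray, threshold: float) -> SpotCloud:
    """Strict 8-neighbourhood local maxima at or above ``threshold``.

    A plateau of equal-valued adjacent maxima is reported once, at its
    lexicographically smallest (row, col).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    filtered = np.asarray(filtered, dtype=float)
    footprint = np.ones((3, 3), dtype=bool)
    local_max = ndimage.maximum_filter(filtered, footprint=footprint, mode="reflect")
    candidates = (filtered == local_max) & (filtered >= threshold)
    if not candidates.any():
        return SpotCloud(
            coordinates=np.empty((0, 2), dtype=int), intensities=np.empty(0)
        )
    # collapse plateaus: adjacent candidate pixels are necessarily equal-valued
    # (each equals a 3x3 max that includes the other), so each 8-connected
    # component is one spot, placed at its lexicographically smallest pixel.
    # A plateau with no strictly lower neighbour anywhere (e.g. a constant
    # image) is not a maximum and is discarded.
    local_min = ndimage.minimum_filter(filtered, footprint=footprint, mode="reflect")
    labels, n_labels = ndimage.label(candidates, structure=footprint)
    rr, cc = np.nonzero(candidates)
    order = np.lexsort((cc, rr))
    rr, cc = rr[order], cc[order]
    labs = labels[rr, cc]
    has_lower = np.zeros(n_labels + 1, dtype=bool)
    np.logical_or.at(has_lower, labs, local_min[rr, cc] < filtered[rr, cc])
    uniq, first = np.unique(labs, return_index=True)
    keep = has_lower[uniq]
    coords = np.column_stack([rr[first[keep]], cc[first[keep]]])
    if len(coords) == 0:
        return SpotCloud(
            coordinates=np.empty((0, 2), dtype=int), intensities=np.empty(0)
        )
    coords = coords[np.lexsort((coords[:, 1], coords[:, 0]))]
    intensities = filtered[coords[:, 0], coords[:, 1]]
    return SpotCloud(coordinates=coords, intensities=intensities)
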