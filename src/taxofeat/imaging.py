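"""Specimen photograph preprocessing.

The chain turns a raw photograph with a roughly uniform background into the
rasters every downstream descriptor consumes:

    raw -> background removed -> grayscale -> mean filter -> median filter
        -> binary mask -> contour -> skeleton

All rasters are numpy arrays in row-major (row, col) order; wherever the
classical moment/texture formulas speak of ``(x, y)``, x is the column index
and y is the row index.  Grayscale intensities live in [0, 255] (float64
after filtering); masks are boolean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk

__all__ = [
    "PreprocessResult",
    "to_grayscale",
    "remove_background",
    "denoise",
    "binarize",
    "extract_contour",
    "skeletonize",
    "preprocess",
]

#: ITU-R BT.601 luminance weights (R, G, B).
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

_EIGHT = np.ones((3, 3), bool)


@dataclass(frozen=True)
class PreprocessResult:
    """Output bundle of the preprocessing chain.

    ``gray`` is the denoised grayscale raster (background zeroed), ``mask``
    the specimen region, ``contour`` its boundary pixels and ``skeleton``
    the one-pixel-wide medial thinning.  All four share the input shape;
    ``contour`` and ``skeleton`` are subsets of ``mask``.
    """

    gray: np.ndarray
    mask: np.ndarray
    contour: np.ndarray
    skeleton: np.ndarray


def _as_image(image) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim not in (2, 3) or arr.size == 0:
        raise ValueError("expected a non-empty 2-D or 3-channel image")
    return arr


def to_grayscale(image) -> np.ndarray:
    """Convert a color raster to luminance (0.299 R + 0.587 G + 0.114 B).

    Already-gray input is passed through unchanged (as float64).  The
    intensity range of the input is preserved.
    """
    arr = _as_image(image).astype(np.float64)
    if arr.ndim == 2:
        return arr
    if arr.shape[2] != 3:
        raise ValueError(f"expected 3 channels, got {arr.shape[2]}")
    return arr @ LUMA_WEIGHTS


def remove_background(image, rect: tuple[int, int, int, int] | None = None,
                      mask: np.ndarray | None = None):
    """Separate the specimen from a roughly uniform background.

    The background intensity model is estimated from the pixels outside
    ``rect`` (default: the full frame inset by 2 px on each side, i.e. the
    2-px border ring is assumed background).  Pixels deviating from that
    model by more than three standard deviations are labelled foreground,
    then cleaned up morphologically (closing, hole filling, small-object
    removal).

    Parameters
    ----------
    image : array
        Color (H, W, 3) or grayscale (H, W) raster.
    rect : (row0, col0, row1, col1), optional
        Half-open box assumed to contain the whole specimen.
    mask : bool array, optional
        Pre-segmented foreground; bypasses estimation entirely and returns
        the input raster unchanged alongside the given mask.

    Returns
    -------
    (masked_image, mask)
        The input raster with background pixels set to 0, and the boolean
        foreground mask.
    """
    arr = _as_image(image)
    if mask is not None:
        mask = np.asarray(mask, bool)
        if mask.shape != arr.shape[:2]:
            raise ValueError("mask shape does not match image")
        if not mask.any():
            raise ValueError("segmentation produced empty foreground")
        return arr, mask

    h, w = arr.shape[:2]
    if rect is None:
        rect = (2, 2, h - 2, w - 2)
    r0, c0, r1, c1 = rect
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"rect {rect} outside image bounds {(h, w)}")

    gray = to_grayscale(arr)
    inside = np.zeros((h, w), bool)
    inside[r0:r1, c0:c1] = True
    bg_pixels = gray[~inside]
    if bg_pixels.size == 0:  # rect covers the frame: fall back to border ring
        ring = np.ones((h, w), bool)
        ring[1:-1, 1:-1] = False
        bg_pixels = gray[ring]
    bg_mu = float(bg_pixels.mean())
    bg_sd = max(float(bg_pixels.std()), 1.0)

    fg = (np.abs(gray - bg_mu) > 3.0 * bg_sd) & inside
    if fg.any():
        fg = ndi.binary_closing(fg, structure=disk(2))
        fg = ndi.binary_fill_holes(fg)
        labels, n = ndi.label(fg, structure=np.ones((3, 3), int))
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        fg = sizes[labels] >= 16  # drop speckle components
        fg &= inside
    if not fg.any():
        raise ValueError("segmentation produced empty foreground")

    out = arr.copy()
    out[~fg] = 0
    return out, fg


def denoise(gray: np.ndarray, kernel: int = 3) -> np.ndarray:
    """Smooth then despeckle: ``kernel``x``kernel`` mean filter followed by a
    median filter of the same size, both with reflect padding at the edges.
    """
    gray = np.asarray(gray, np.float64)
    if gray.ndim != 2 or gray.size == 0:
        raise ValueError("expected a non-empty grayscale raster")
    # sum-then-divide keeps constant regions exactly constant
    box = np.ones((kernel, kernel))
    smoothed = ndi.correlate(gray, box, mode="reflect") / (kernel * kernel)
    return ndi.median_filter(smoothed, size=kernel, mode="reflect")


def binarize(gray: np.ndarray) -> np.ndarray:
    """Threshold to a {0,1} mask with Otsu's method.

    The foreground is the side of the threshold NOT held by the majority of
    frame-border pixels (specimens sit in the image interior).  A constant
    image admits no threshold and raises.
    """
    gray = np.asarray(gray, np.float64)
    if gray.ndim != 2 or gray.size == 0:
        raise ValueError("expected a non-empty grayscale raster")
    if np.ptp(gray) == 0:
        raise ValueError("no threshold separates foreground")
    t = threshold_otsu(gray)
    fg = gray > t
    border = np.concatenate([fg[0, :], fg[-1, :], fg[1:-1, 0], fg[1:-1, -1]])
    if border.mean() > 0.5:  # bright side touches the frame: specimen is dark
        fg = ~fg
    if not fg.any():
        raise ValueError("no threshold separates foreground")
    return fg


def extract_contour(mask: np.ndarray) -> np.ndarray:
    """Boundary of a region: foreground pixels with >= 1 background neighbor
    under 8-connectivity.  Outside the frame counts as background, so a
    region touching the border contributes its frame-edge pixels too.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask has no contour")
    interior = ndi.binary_erosion(mask, structure=_EIGHT, border_value=0)
    return mask & ~interior


def _zhang_suen_pass(m: np.ndarray, first: bool) -> np.ndarray:
    """One Zhang–Suen subiteration; returns the deletion mask."""
    p = np.pad(m, 1).astype(np.uint8)
    # neighbors clockwise from north: P2..P9
    P2 = p[:-2, 1:-1]
    P3 = p[:-2, 2:]
    P4 = p[1:-1, 2:]
    P5 = p[2:, 2:]
    P6 = p[2:, 1:-1]
    P7 = p[2:, :-2]
    P8 = p[1:-1, :-2]
    P9 = p[:-2, :-2]
    ring = [P2, P3, P4, P5, P6, P7, P8, P9]
    B = sum(ring)
    A = sum((ring[i] == 0) & (ring[(i + 1) % 8] == 1) for i in range(8))
    cond = m & (B >= 2) & (B <= 6) & (A == 1)
    if first:
        cond &= (P2 * P4 * P6 == 0) & (P4 * P6 * P8 == 0)
    else:
        cond &= (P2 * P4 * P8 == 0) & (P2 * P6 * P8 == 0)
    return cond


def _zs_deletable(p: np.ndarray, r: int, c: int, first: bool) -> bool:
    """Zhang–Suen deletion conditions for one pixel of a padded raster."""
    P2 = p[r - 1, c]
    P3 = p[r - 1, c + 1]
    P4 = p[r, c + 1]
    P5 = p[r + 1, c + 1]
    P6 = p[r + 1, c]
    P7 = p[r + 1, c - 1]
    P8 = p[r, c - 1]
    P9 = p[r - 1, c - 1]
    ring = (P2, P3, P4, P5, P6, P7, P8, P9)
    B = sum(ring)
    if not 2 <= B <= 6:
        return False
    A = sum((not ring[i]) and ring[(i + 1) % 8] for i in range(8))
    if A != 1:
        return False
    if first:
        return not (P2 and P4 and P6) and not (P4 and P6 and P8)
    return not (P2 and P4 and P8) and not (P2 and P6 and P8)


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Zhang–Suen thinning to a 1-px-wide, 8-connected skeleton.

    The two classical subiterations run to a fixed point (so the operation
    is idempotent), but each deletion candidate is re-validated against the
    current raster before it is removed.  Fully parallel deletion can
    annihilate 2-px-wide structures outright; the sequential re-check keeps
    the thinning topology-preserving — every 8-connected component of the
    input survives in the skeleton (an isolated pixel is left unchanged).
    """
    m = np.asarray(mask, bool)
    if not m.any():
        raise ValueError("empty mask has no skeleton")
    p = np.pad(m, 1)
    while True:
        changed = False
        for first in (True, False):
            # vectorized pre-screen, then sequential confirmation
            cand = _zhang_suen_pass(p, first=first)
            for r, c in np.argwhere(cand):
                if _zs_deletable(p, r, c, first):
                    p[r, c] = False
                    changed = True
        if not changed:
            return p[1:-1, 1:-1]


def preprocess(image, mask: np.ndarray | None = None,
               rect: tuple[int, int, int, int] | None = None,
               kernel: int = 3) -> PreprocessResult:
    """Run the full chain on one photograph.

    When ``mask`` is supplied the segmentation and binarization stages are
    bypassed (the mask is trusted); the grayscale raster is still denoised,
    because the texture descriptors read it.
    """
    arr = _as_image(image)
    if mask is not None:
        mask = np.asarray(mask, bool)
        if mask.shape != arr.shape[:2]:
            raise ValueError("mask shape does not match image")
        if not mask.any():
            raise ValueError("segmentation produced empty foreground")
        gray = denoise(to_grayscale(arr), kernel=kernel)
        bin_mask = mask
    else:
        removed, _ = remove_background(arr, rect=rect)
        gray = denoise(to_grayscale(removed), kernel=kernel)
        bin_mask = binarize(gray)
    gray = np.where(bin_mask, gray, 0.0)
    contour = extract_contour(bin_mask)
    skel = skeletonize(bin_mask)
    return PreprocessResult(gray=gray, mask=bin_mask, contour=contour,
                            skeleton=skel)
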