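"""First- and second-order texture statistics of the specimen region.

First order works on the gray-level histogram of the masked pixels; second
order on a gray-level co-occurrence matrix (GLCM) taken at a single offset:
distance r = 1 pixel along the -45 degree diagonal, i.e. (drow, dcol) =
(+1, +1) in row-major image coordinates.  The matrix is NOT symmetrized,
matching the single-offset conditional-probability definition.

Intensities are quantized uniformly over the masked min-max range, so every
co-occurrence feature is invariant to adding a constant to the image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "IntensityHistogram",
    "GLCM",
    "TextureStats",
    "first_order_stats",
    "quantize",
    "compute_glcm",
    "glcm_features",
    "texture_features",
]


@dataclass(frozen=True)
class IntensityHistogram:
    """Probability of each observed gray level within the region."""

    levels: np.ndarray  # distinct gray values, ascending
    probs: np.ndarray   # frequencies / masked area; sums to 1


@dataclass(frozen=True)
class GLCM:
    p: np.ndarray                 # L x L pair probabilities, sums to 1
    levels: int
    offset: tuple[int, int]       # (drow, dcol)


@dataclass(frozen=True)
class TextureStats:
    """The six texture features: histogram mean/variance + four GLCM stats."""

    mu: float
    var: float
    uniformity: float
    entropy: float
    homogeneity: float
    inertia: float

    def as_tuple(self) -> tuple:
        return (self.mu, self.var, self.uniformity, self.entropy,
                self.homogeneity, self.inertia)


def _masked(gray: np.ndarray, mask: np.ndarray) -> np.ndarray:
    gray = np.asarray(gray, np.float64)
    mask = np.asarray(mask, bool)
    if gray.shape != mask.shape:
        raise ValueError("gray and mask shapes differ")
    vals = gray[mask]
    if vals.size == 0:
        raise ValueError("empty mask")
    return vals


def first_order_stats(gray, mask):
    """Histogram, mean and variance of the masked gray levels.

    mu = sum_x x h(x) and var = sum_x (x - mu)^2 h(x), with h the gray-level
    frequencies normalised by the masked area.

    Returns
    -------
    (IntensityHistogram, mu, var)
    """
    vals = _masked(gray, mask)
    levels, counts = np.unique(vals, return_counts=True)
    probs = counts / vals.size
    mu = float(levels @ probs)
    var = float(((levels - mu) ** 2) @ probs)
    return IntensityHistogram(levels=levels, probs=probs), mu, var


def quantize(gray, mask, levels: int) -> np.ndarray:
    """Uniform quantization of masked intensities to ``levels`` bins over the
    masked min-max range (min -> bin 0, max -> bin levels-1).  Pixels outside
    the mask get bin 0; callers must ignore them via the mask."""
    if levels < 2:
        raise ValueError("levels must be >= 2")
    gray = np.asarray(gray, np.float64)
    mask = np.asarray(mask, bool)
    vals = _masked(gray, mask)
    lo, hi = float(vals.min()), float(vals.max())
    q = np.zeros(gray.shape, np.intp)
    if hi > lo:
        scaled = (gray - lo) * (levels / (hi - lo))
        q = np.clip(np.floor(scaled), 0, levels - 1).astype(np.intp)
        q[~mask] = 0
    return q


def compute_glcm(gray, mask, levels: int = 16,
                 offset: tuple[int, int] = (1, 1)) -> GLCM:
    """Co-occurrence matrix of quantized intensities at one pixel offset.

    Counts ordered pairs (p, q) where q sits at ``offset`` from p and BOTH
    pixels belong to the mask, then normalises to probabilities.  Raises on
    a mask with no valid pair (degenerate co-occurrence).
    """
    q = quantize(gray, mask, levels)
    mask = np.asarray(mask, bool)
    dr, dc = offset
    h, w = mask.shape
    rows = slice(max(0, -dr), min(h, h - dr))
    cols = slice(max(0, -dc), min(w, w - dc))
    rows2 = slice(max(0, dr), min(h, h + dr))
    cols2 = slice(max(0, dc), min(w, w + dc))
    valid = mask[rows, cols] & mask[rows2, cols2]
    n_pairs = int(valid.sum())
    if n_pairs == 0:
        raise ValueError("degenerate co-occurrence: no valid pixel pair")
    a = q[rows, cols][valid]
    b = q[rows2, cols2][valid]
    counts = np.bincount(a * levels + b, minlength=levels * levels)
    p = counts.reshape(levels, levels) / n_pairs
    return GLCM(p=p, levels=levels, offset=(dr, dc))


def glcm_features(glcm: GLCM, entropy_base: float = math.e):
    """The four co-occurrence features.

    uniformity  = sum P^2              (a.k.a. energy / angular 2nd moment)
    entropy     = -sum P log P         (0 log 0 := 0; natural log default)
    homogeneity = sum P / (1 + |x-y|)
    inertia     = sum P (x-y)^2        (a.k.a. contrast)

    Returns ``(uniformity, entropy, homogeneity, inertia)``.
    """
    p = np.asarray(glcm.p, np.float64)
    L = p.shape[0]
    x = np.arange(L)
    absdiff = np.abs(x[:, None] - x[None, :])
    uniformity = float((p * p).sum())
    nz = p > 0
    entropy = float(-(p[nz] * np.log(p[nz])).sum())
    if entropy_base != math.e:
        entropy /= math.log(entropy_base)
    homogeneity = float((p / (1.0 + absdiff)).sum())
    inertia = float((p * absdiff.astype(np.float64) ** 2).sum())
    return uniformity, entropy, homogeneity, inertia


def texture_features(gray, mask, levels: int = 16,
                     offset: tuple[int, int] = (1, 1),
                     entropy_base: float = math.e) -> TextureStats:
    """All six texture features of a masked grayscale region."""
    _, mu, var = first_order_stats(gray, mask)
    glcm = compute_glcm(gray, mask, levels=levels, offset=offset)
    uni, ent, hom, ine = glcm_features(glcm, entropy_base=entropy_base)
    return TextureStats(mu=mu, var=var, uniformity=uni, entropy=ent,
                        homogeneity=hom, inertia=ine)
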