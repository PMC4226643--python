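"""Image moments and moment-invariant shape descriptors.

Raw (Cartesian) moments m_pq = sum x^p y^q I(x, y) are taken over the masked
pixels with x = column, y = row and unit pixel area.  Central moments u_pq
recentre on the intensity centroid and are translation invariant; the
normalized central moments n_pq = u_pq / u00^gamma with gamma = (p+q)/2
(for p+q >= 2) are exposed as well.

Three invariant features are derived:

    hu1  = (u20 + u02) / u00^2          first Hu invariant (translation,
                                        rotation and scale invariant)
    ami1 = (u20 u02 - u11^2) / u00^4    first affine moment invariant
    ami2 = (u30^2 u03^2 - 6 u30 u21 u12 u03 + 4 u30 u12^3 + 4 u21^3 u03
            - 3 u21^2 u12^2) / u00^10   second affine moment invariant

For binary input the raw moments are exact integers and the central moments
exact rationals (kept as ``fractions.Fraction``), so oracle comparisons can
be made in exact arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

__all__ = ["MomentSet", "compute_moments", "invariant_features"]

_ORDERS = [(p, q) for p in range(4) for q in range(4) if p + q <= 3]


@dataclass(frozen=True)
class MomentSet:
    """Raw, central and normalized central moments of one region (order <= 3).

    ``m``/``u``/``n`` are dicts keyed by (p, q).  ``m_exact``/``u_exact``
    hold exact integer/rational values when the input raster was binary or
    integer-valued, else None.  ``hu1_raw`` is the raw-moment reading
    m20 + m02 (not translation invariant; kept for comparison only).
    """

    m: dict = field(repr=False)
    u: dict = field(repr=False)
    n: dict = field(repr=False)
    centroid: tuple[float, float]  # (x_bar, y_bar)
    hu1: float
    hu1_raw: float
    ami1: float
    ami2: float
    m_exact: dict | None = field(default=None, repr=False)
    u_exact: dict | None = field(default=None, repr=False)


def _central_from_raw(m, xb, yb):
    """Central moments to order 3 from raw moments via the standard
    translation identities (exact when inputs are Fractions)."""
    u = {}
    u[0, 0] = m[0, 0]
    u[1, 0] = 0 * m[0, 0]
    u[0, 1] = 0 * m[0, 0]
    u[1, 1] = m[1, 1] - xb * m[0, 1]
    u[2, 0] = m[2, 0] - xb * m[1, 0]
    u[0, 2] = m[0, 2] - yb * m[0, 1]
    u[3, 0] = m[3, 0] - 3 * xb * m[2, 0] + 2 * xb ** 2 * m[1, 0]
    u[0, 3] = m[0, 3] - 3 * yb * m[0, 2] + 2 * yb ** 2 * m[0, 1]
    u[2, 1] = m[2, 1] - 2 * xb * m[1, 1] - yb * m[2, 0] + 2 * xb ** 2 * m[0, 1]
    u[1, 2] = m[1, 2] - 2 * yb * m[1, 1] - xb * m[0, 2] + 2 * yb ** 2 * m[1, 0]
    return u


def compute_moments(raster, mask: np.ndarray | None = None) -> MomentSet:
    """Moments of a masked raster.

    Parameters
    ----------
    raster : array
        Binary mask (the default shape-descriptor case, I in {0,1}) or a
        grayscale raster for intensity-weighted moments.
    mask : bool array, optional
        Region of support.  Defaults to ``raster > 0``; required when
        ``raster`` is grayscale and should be restricted.
    """
    arr = np.asarray(raster)
    if mask is None:
        mask = arr > 0 if arr.dtype != bool else arr
    mask = np.asarray(mask, bool)
    if arr.shape != mask.shape:
        raise ValueError("raster and mask shapes differ")
    if not mask.any():
        raise ValueError("empty mask has no moments")

    rows, cols = np.nonzero(mask)
    x = cols.astype(np.int64)
    y = rows.astype(np.int64)
    integral = arr.dtype == bool or np.issubdtype(arr.dtype, np.integer)
    if arr.dtype == bool:
        w = np.ones(x.size, np.int64)
    else:
        w = arr[mask].astype(np.int64 if integral else np.float64)

    m = {}
    for p, q in _ORDERS:
        m[p, q] = (x ** p) * (y ** q) @ w
    if m[0, 0] == 0:
        raise ValueError("zero total mass")

    if integral:
        m_exact = {k: int(v) for k, v in m.items()}
        xb = Fraction(m_exact[1, 0], m_exact[0, 0])
        yb = Fraction(m_exact[0, 1], m_exact[0, 0])
        u_exact = _central_from_raw(
            {k: Fraction(v) for k, v in m_exact.items()}, xb, yb)
        u = {k: float(v) for k, v in u_exact.items()}
        m = {k: float(v) for k, v in m_exact.items()}
        centroid = (float(xb), float(yb))
    else:
        m_exact = u_exact = None
        m = {k: float(v) for k, v in m.items()}
        xb, yb = m[1, 0] / m[0, 0], m[0, 1] / m[0, 0]
        u = _central_from_raw(m, xb, yb)
        centroid = (xb, yb)

    u00 = u[0, 0]
    n = {k: u[k] / u00 ** ((k[0] + k[1]) / 2.0)
         for k in u if k[0] + k[1] >= 2}

    hu1 = (u[2, 0] + u[0, 2]) / u00 ** 2
    hu1_raw = m[2, 0] + m[0, 2]
    ami1 = (u[2, 0] * u[0, 2] - u[1, 1] ** 2) / u00 ** 4
    ami2 = (u[3, 0] ** 2 * u[0, 3] ** 2
            - 6 * u[3, 0] * u[2, 1] * u[1, 2] * u[0, 3]
            + 4 * u[3, 0] * u[1, 2] ** 3
            + 4 * u[2, 1] ** 3 * u[0, 3]
            - 3 * u[2, 1] ** 2 * u[1, 2] ** 2) / u00 ** 10
    return MomentSet(m=m, u=u, n=n, centroid=centroid, hu1=hu1,
                     hu1_raw=hu1_raw, ami1=ami1, ami2=ami2,
                     m_exact=m_exact, u_exact=u_exact)


def invariant_features(ms: MomentSet, hu1_mode: str = "normalized"):
    """The three moment-invariant features ``(hu1, ami1, ami2)``.

    ``hu1_mode='normalized'`` (default) returns the scale-normalized first
    Hu invariant; ``'raw'`` returns the raw-moment reading m20 + m02.
    """
    if hu1_mode == "normalized":
        hu1 = ms.hu1
    elif hu1_mode == "raw":
        hu1 = ms.hu1_raw
    else:
        raise ValueError(f"unknown hu1_mode {hu1_mode!r}")
    return hu1, ms.ami1, ms.ami2
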