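"""Shared fixtures: deterministic shapes, random blobs and the synthetic
identification benchmark (computed once per session)."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage as ndi

import taxofeat as tf


def digital_disk(r: int, size: int | None = None) -> np.ndarray:
    """Binary disk of radius r (pixel centers within r of the middle)."""
    size = size or 2 * r + 9
    yy, xx = np.mgrid[0:size, 0:size]
    c = size / 2
    return (xx - c) ** 2 + (yy - c) ** 2 <= r * r


def fourier_blob(shear: float = 0.0, scale: float = 1.0,
                 size: int = 201) -> np.ndarray:
    """Smooth irregular blob (ellipse + 3 radial harmonics), optionally
    sheared/scaled in the continuum before rasterization."""
    yy, xx = np.mgrid[0:size, 0:size]
    c = size / 2
    x = (xx - c).astype(float)
    y = (yy - c).astype(float)
    x = x - shear * y
    x /= scale
    y /= scale
    u, v = x / 60.0, y / 38.0
    rho = np.hypot(u, v)
    ang = np.arctan2(v, u)
    r = (1 + 0.10 * np.cos(2 * ang + 0.5) + 0.07 * np.cos(3 * ang + 1.1)
         + 0.04 * np.cos(4 * ang + 2.0))
    return rho <= r


def random_blob(rng, size: int = 24) -> np.ndarray:
    """Random connected-ish blob from thresholded smoothed noise."""
    field = ndi.gaussian_filter(rng.normal(size=(size, size)), 2.5)
    blob = field > np.quantile(field, 0.7)
    if not blob.any():
        blob[size // 2, size // 2] = True
    return blob


def symmetric_specimen(size: int = 120, pad: int = 0):
    """Textured specimen whose silhouette AND texture are mirror-symmetric
    about the vertical axis (the co-occurrence offset direction pair
    (+1,+1)/(+1,-1) is then statistically identical, making all 15 features
    exactly invariant under 90-degree grid rotation)."""
    n = size + 2 * pad
    yy, xx = np.mgrid[0:n, 0:n]
    c = n / 2
    s = (xx - c) / 38.0
    t = (yy - c) / 24.0
    rho = np.hypot(s, t)
    ang = np.arctan2(t, s)
    mask = rho <= 1 + 0.12 * np.cos(2 * ang) + 0.05 * np.cos(4 * ang)
    gray = 100 + 40 * np.cos(3 * np.pi * s) + 20 * np.cos(2 * np.pi * t)
    gray = np.where(mask, gray, 205.0)
    return gray, mask


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def benchmark_table():
    """Feature table of the full synthetic benchmark: 10 species x 30
    individuals at default (moderate) separation, end-to-end through the
    segmentation pipeline."""
    ds = tf.generate_dataset(tf.default_specs(10), 30, seed=1)
    vecs = [tf.extract_features(im) for im in ds.images]
    return tf.feature_table(vecs, ds.labels)


@pytest.fixture(scope="session")
def small_table():
    """Cheap 4-species table for evaluation-protocol unit tests (masks
    supplied, so extraction is fast and deterministic)."""
    ds = tf.generate_dataset(tf.default_specs(4), 12, seed=7)
    vecs = [tf.extract_features(im, mask=mk)
            for im, mk in zip(ds.images, ds.masks)]
    return tf.feature_table(vecs, ds.labels)
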