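"""Assembly of the 15-dimensional descriptor vector and its CSV plumbing.

The fixed feature order (and the CSV header) is:

    A, P, D, C, Co, S        six geometric features
    u, d2, E, H, HG, I       six texture features (histogram mean and
                             variance; GLCM uniformity, entropy,
                             homogeneity, inertia)
    phi1, I1, I2             first Hu invariant, two affine invariants

Every feature is invariant to integer translation of the specimen within
the frame; the geometric and moment features are additionally exact under
90-degree grid rotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import imaging
from .geometry import compute_geometry
from .moments import compute_moments, invariant_features
from .texture import texture_features

__all__ = [
    "FEATURE_NAMES",
    "FeatureConfig",
    "extract_features",
    "extract_directory",
    "feature_table",
    "write_feature_table",
    "read_feature_table",
]

FEATURE_NAMES = ["A", "P", "D", "C", "Co", "S",
                 "u", "d2", "E", "H", "HG", "I",
                 "phi1", "I1", "I2"]

LABEL_COLUMN = "species"


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs of the extraction pipeline that change feature values.

    glcm_levels
        Gray-level count of the co-occurrence quantization (recorded in the
        trained model file because features depend on it).
    glcm_offset
        Pixel offset of the co-occurrence pair; (+1, +1) is distance 1 along
        the -45 degree diagonal.
    kernel
        Mean/median filter size of the denoising stage.
    hu1_mode
        'normalized' (scale-invariant first Hu moment) or 'raw' (m20 + m02).
    entropy_base
        Logarithm base of the co-occurrence entropy (natural log default).
    largest_component
        Restrict geometry to the biggest connected component.
    """

    glcm_levels: int = 16
    glcm_offset: tuple[int, int] = (1, 1)
    kernel: int = 3
    hu1_mode: str = "normalized"
    entropy_base: float = math.e
    largest_component: bool = False


def extract_features(image, mask: np.ndarray | None = None,
                     config: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """Run preprocessing + all three descriptor families on one image.

    Returns the fixed-order 15-vector (float64).  Preprocessing failures
    propagate as ValueError.
    """
    pre = imaging.preprocess(image, mask=mask, kernel=config.kernel)
    geo = compute_geometry(pre.mask, pre.contour,
                           largest_component=config.largest_component)
    tex = texture_features(pre.gray, pre.mask, levels=config.glcm_levels,
                           offset=config.glcm_offset,
                           entropy_base=config.entropy_base)
    ms = compute_moments(pre.mask)
    hu1, ami1, ami2 = invariant_features(ms, hu1_mode=config.hu1_mode)
    vec = np.array(geo.as_tuple() + tex.as_tuple() + (hu1, ami1, ami2),
                   dtype=np.float64)
    if not np.all(np.isfinite(vec)):
        bad = [FEATURE_NAMES[i] for i in np.nonzero(~np.isfinite(vec))[0]]
        raise ValueError(f"non-finite feature(s): {', '.join(bad)}")
    return vec


def feature_table(vectors, labels) -> pd.DataFrame:
    """Build a feature table from parallel sequences of 15-vectors and
    species labels."""
    if isinstance(vectors, np.ndarray):
        arr = np.asarray(vectors, np.float64)
    else:
        vectors = list(vectors)
        arr = (np.asarray(vectors, np.float64) if vectors
               else np.empty((0, len(FEATURE_NAMES))))
    if arr.ndim != 2 or arr.shape[1] != len(FEATURE_NAMES):
        raise ValueError(f"expected rows of {len(FEATURE_NAMES)} features")
    df = pd.DataFrame(arr, columns=FEATURE_NAMES)
    df[LABEL_COLUMN] = list(labels)
    return df


def extract_directory(root, config: FeatureConfig = FeatureConfig(),
                      use_masks: bool = True) -> pd.DataFrame:
    """Extract features from a labeled directory tree (one folder per
    species; images PNG/JPEG/TIFF).  A sibling file ``NAME_mask.png`` is
    used as a segmentation bypass when present and ``use_masks`` is true.
    """
    from PIL import Image

    root = Path(root)
    rows, labels = [], []
    for species_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for img_path in sorted(species_dir.iterdir()):
            if img_path.suffix.lower() not in {".png", ".jpg", ".jpeg",
                                               ".tif", ".tiff"}:
                continue
            if img_path.stem.endswith("_mask"):
                continue
            img = np.asarray(Image.open(img_path))
            mask = None
            mask_path = img_path.with_name(img_path.stem + "_mask.png")
            if use_masks and mask_path.exists():
                mask = np.asarray(Image.open(mask_path)) > 127
            try:
                rows.append(extract_features(img, mask=mask, config=config))
            except ValueError as exc:
                raise ValueError(f"{img_path}: {exc}") from exc
            labels.append(species_dir.name)
    if not rows:
        raise ValueError(f"no images found under {root}")
    return feature_table(rows, labels)


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write the table as CSV (header = feature names + species)."""
    cols = FEATURE_NAMES + [LABEL_COLUMN]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"table missing column(s): {', '.join(missing)}")
    table[cols].to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature CSV back; errors name the offending column or line."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed feature CSV {path}: {exc}") from exc
    missing = [c for c in FEATURE_NAMES + [LABEL_COLUMN]
               if c not in df.columns]
    if missing:
        raise ValueError(
            f"feature CSV {path} missing column(s): {', '.join(missing)}")
    numeric = df[FEATURE_NAMES].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        line = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # 1-based + header
        raise ValueError(f"feature CSV {path}: non-numeric value at line {line}")
    df[FEATURE_NAMES] = numeric
    return df[FEATURE_NAMES + [LABEL_COLUMN]]
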