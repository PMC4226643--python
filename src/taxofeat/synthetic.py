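"""Synthetic labeled "species" image sets.

Stands in for museum photograph collections: each species is a parametric
silhouette — an ellipse whose radius is modulated by a low-order Fourier
series — filled with a striped, noisy texture and placed on a uniform
light background.  Individuals of a species jitter around the species
parameters and are randomly rotated and translated, giving controllable
intra-species variation; inter-species separation is controlled by the
parameter spacing (down to near-identical "congener" pairs differing in a
single axis).

The silhouette in body coordinates (u, v) is

    inside  <=>  rho <= 1 + sum_k amp_k cos(k * ang + phase_k),  k = 2..4

with rho = hypot(u/a, v/b) and ang = atan2(v/b, u/a).  Its exact area is
pi * a * b * (1 + 0.5 * sum_k amp_k^2), which serves as the oracle for the
rasterized masks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, field
from pathlib import Path

import numpy as np

__all__ = ["SpeciesSpec", "SyntheticSet", "default_specs", "confusable_pair",
           "render_individual", "generate_dataset", "save_dataset",
           "analytic_area"]

BACKGROUND_LEVEL = 205.0
BACKGROUND_NOISE_SD = 2.0


@dataclass(frozen=True)
class SpeciesSpec:
    """Parameters of one synthetic species.

    axes
        Base ellipse semi-axes (a, b) in pixels.
    fourier_amps / fourier_phases
        Radial boundary modulation for harmonics k = 2, 3, 4
        (dimensionless fractions of the base radius).
    mean_intensity
        Mean interior gray level (0-255); the background sits at
        ~205, so darker species segment cleanly.
    stripe_freq / stripe_amp
        Sinusoidal stripe pattern along the body axis (cycles per
        half-body; gray-level amplitude).
    noise_sd
        Per-pixel Gaussian texture noise.
    axis_jitter, amp_jitter, intensity_jitter, stripe_jitter
        Intra-species standard deviations of the respective parameters.
    """

    name: str
    axes: tuple[float, float] = (24.0, 14.0)
    fourier_amps: tuple[float, float, float] = (0.06, 0.0, 0.02)
    fourier_phases: tuple[float, float, float] = (0.0, 0.0, 0.0)
    mean_intensity: float = 110.0
    stripe_freq: float = 2.0
    stripe_amp: float = 12.0
    noise_sd: float = 6.0
    axis_jitter: float = 0.6
    amp_jitter: float = 0.008
    intensity_jitter: float = 3.5
    stripe_jitter: float = 1.0


@dataclass
class SyntheticSet:
    """In-memory dataset: parallel lists of uint8 images, boolean
    ground-truth masks and species labels, plus provenance."""

    images: list
    masks: list
    labels: list
    specs: list
    seed: int
    size: int

    def __len__(self):
        return len(self.images)


def default_specs(n_species: int = 10, separation: float = 1.0) -> list:
    """A deterministic family of ``n_species`` moderately separated species.

    Parameters are spread over decorrelated grids (shape, boundary waviness,
    interior brightness, striping).  ``separation`` scales every species
    parameter toward (0) or away from (>1) the family midpoint, so 0 gives
    identical species and 1 the default moderate separation.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    span = max(n_species - 1, 1)

    def spread(center, half, frac):
        return center + separation * half * (2.0 * frac - 1.0)

    specs = []
    for i in range(n_species):
        f1 = i / span
        f2 = (i * 3) % n_species / span
        f3 = (i * 7) % n_species / span
        f4 = (i * 9) % n_species / span
        specs.append(SpeciesSpec(
            name=f"sp{i:02d}",
            axes=(spread(23.0, 5.0, f1), spread(13.5, 3.5, f2)),
            fourier_amps=(spread(0.08, 0.04, f3),
                          0.03 * (i % 3) * separation,
                          0.02 * (i % 2) * separation),
            fourier_phases=(0.7 * i * separation, 0.4 * i * separation,
                            1.1 * i * separation),
            mean_intensity=spread(115.0, 45.0, f4),
            stripe_freq=float(i % 4),
            stripe_amp=(12.0 if i % 4 else 0.0) * min(separation, 1.0),
        ))
    return specs


def confusable_pair(spec: SpeciesSpec, delta: float) -> SpeciesSpec:
    """Clone of ``spec`` whose major axis differs by ``delta`` pixels (all
    other parameters identical) — an artificial congener."""
    if delta < 0:
        raise ValueError("delta must be >= 0")
    a, b = spec.axes
    return replace(spec, name=spec.name + "_b", axes=(a + delta, b))


def analytic_area(axes, amps) -> float:
    """Exact area of the perturbed ellipse (continuum, before pixelation)."""
    a, b = axes
    return math.pi * a * b * (1.0 + 0.5 * sum(x * x for x in amps))


def _jitter_spec(spec: SpeciesSpec, rng) -> SpeciesSpec:
    for _ in range(100):
        a = spec.axes[0] + rng.normal(0, spec.axis_jitter)
        b = spec.axes[1] + rng.normal(0, spec.axis_jitter)
        amps = tuple(x + rng.normal(0, spec.amp_jitter)
                     for x in spec.fourier_amps)
        if a > 2 and b > 2 and sum(abs(x) for x in amps) < 0.6:
            return replace(
                spec, axes=(a, b), fourier_amps=amps,
                mean_intensity=spec.mean_intensity
                + rng.normal(0, spec.intensity_jitter),
                stripe_amp=max(spec.stripe_amp
                               + rng.normal(0, spec.stripe_jitter), 0.0))
    raise ValueError(f"species {spec.name!r}: degenerate after 100 jitters")


def render_individual(spec: SpeciesSpec, rng, size: int = 96):
    """Render one jittered, rotated, translated individual.

    Returns ``(image uint8 (size, size), mask bool, realized_spec)``.
    """
    ind = _jitter_spec(spec, rng)
    a, b = ind.axes
    angle = rng.uniform(0, 2 * math.pi)
    margin = max(a, b) * (1 + sum(abs(x) for x in ind.fourier_amps))
    wiggle = max((size / 2 - 3) - margin, 0.0)
    cy = size / 2 + rng.uniform(-1, 1) * min(wiggle, 5.0)
    cx = size / 2 + rng.uniform(-1, 1) * min(wiggle, 5.0)

    yy, xx = np.mgrid[0:size, 0:size]
    dx, dy = xx - cx, yy - cy
    cos_t, sin_t = math.cos(angle), math.sin(angle)
    u = cos_t * dx + sin_t * dy
    v = -sin_t * dx + cos_t * dy
    s, t = u / a, v / b
    rho = np.hypot(s, t)
    ang = np.arctan2(t, s)
    radius = np.ones_like(rho)
    for k, (amp, ph) in enumerate(zip(ind.fourier_amps, ind.fourier_phases),
                                  start=2):
        radius += amp * np.cos(k * ang + ph)
    mask = rho <= radius

    img = BACKGROUND_LEVEL + rng.normal(0, BACKGROUND_NOISE_SD, (size, size))
    body = (ind.mean_intensity
            + ind.stripe_amp * np.sin(math.pi * ind.stripe_freq * s)
            + rng.normal(0, ind.noise_sd, (size, size)))
    img = np.where(mask, body, img)
    return np.clip(img, 0, 255).astype(np.uint8), mask, ind


def generate_dataset(specs, n_per_species: int, seed: int,
                     size: int = 96) -> SyntheticSet:
    """Render ``n_per_species`` individuals of every species.

    Deterministic given ``seed``: one child RNG stream per individual,
    derived from (seed, species index, individual index)."""
    specs = list(specs)
    if len(specs) < 2:
        raise ValueError("need at least 2 species")
    if n_per_species < 2:
        raise ValueError("need at least 2 individuals per species")
    images, masks, labels = [], [], []
    ss = np.random.SeedSequence(seed)
    for si, spec in enumerate(specs):
        for j in range(n_per_species):
            rng = np.random.default_rng(ss.spawn(1)[0])
            img, mask, _ = render_individual(spec, rng, size=size)
            images.append(img)
            masks.append(mask)
            labels.append(spec.name)
    return SyntheticSet(images=images, masks=masks, labels=labels,
                        specs=specs, seed=seed, size=size)


def save_dataset(ds: SyntheticSet, outdir) -> None:
    """Write the layout ``extract`` consumes: one folder per species with
    PNG images and ``*_mask.png`` ground-truth masks, plus labels.csv."""
    from PIL import Image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counters: dict = {}
    rows = []
    for img, mask, label in zip(ds.images, ds.masks, ds.labels):
        k = counters.get(label, 0)
        counters[label] = k + 1
        sub = outdir / label
        sub.mkdir(exist_ok=True)
        name = f"img_{k:03d}.png"
        Image.fromarray(img).save(sub / name)
        Image.fromarray((mask.astype(np.uint8)) * 255).save(
            sub / f"img_{k:03d}_mask.png")
        rows.append(f"{label}/{name},{label}")
    (outdir / "labels.csv").write_text(
        "filename,species\n" + "\n".join(rows) + "\n")
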