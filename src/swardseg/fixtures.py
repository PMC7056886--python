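"""Procedural plant samples, soil backgrounds, and sample libraries.

Real sward imagery pairs compact lobed clover leaves against long thin
ryegrass blades over dark textured soil.  These generators reproduce that
structure with minimal parametric shapes — three overlapping elliptical
leaflets for clover, bezier-curved blades for grass — so that every
downstream stage (scene composition, training, stitching) is exercisable
without any captured imagery.

Shape morphometry is a free choice of this package: no reference
measurements exist for cropped pasture samples, so leaflet radii, blade
widths and hue ranges were picked once to look plausible at the target
ground sample distance of 2-3 px/mm and are documented in the methods note.
All randomness flows from one explicit seed through named child streams, so
any individual sample is reproducible in isolation.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.color import hsv2rgb

from .types import CLOVER, EXCLUDED, GRASS, OBJECT, PlantSample, SampleLibrary

# Hue ranges (HSV, [0,1]) per species: distinct but overlapping greens, so
# colour alone is informative yet not sufficient — mirrors the real task.
CLOVER_HUE = (0.26, 0.36)
GRASS_HUE = (0.18, 0.28)


@dataclass
class FixtureConfig:
    """Parameters of the procedural sample generators.

    ``image_size`` is the scene/background size in pixels (height, width);
    ``sample_size`` the plant-patch size.  ``ground_sample_distance`` is the
    nominal resolution in px/mm; it scales nothing directly here but is
    recorded so stitching metadata stays consistent.
    """

    image_size: tuple[int, int] = (100, 100)
    sample_size: int = 48
    ground_sample_distance: float = 2.5
    clover_hue: tuple[float, float] = CLOVER_HUE
    grass_hue: tuple[float, float] = GRASS_HUE
    hue_noise: float = 0.03
    value_noise: float = 0.06
    rng_seed: int = 0

    def validate(self, encoder_reduction: int | None = None) -> None:
        h, w = self.image_size
        if h < 32 or w < 32:
            raise ValueError("image_size must be at least 32x32")
        if encoder_reduction is not None and (h % encoder_reduction or w % encoder_reduction):
            raise ValueError(
                f"image_size {self.image_size} must be divisible by the encoder "
                f"reduction factor {encoder_reduction} for training use"
            )
        if self.ground_sample_distance <= 0:
            raise ValueError("ground_sample_distance must be > 0")
        if self.sample_size < 8:
            raise ValueError("sample_size must be at least 8")


def child_rng(seed: int, *keys: str | int) -> np.random.Generator:
    """A named child stream of the master seed.

    String keys are hashed with CRC32 so streams are stable across runs and
    platforms; integer keys pass through.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            entropy.append(zlib.crc32(k.encode()))
        else:
            entropy.append(int(k) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _smooth_noise(shape: tuple[int, int], sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean unit-ish amplitude smooth noise field."""
    n = ndimage.gaussian_filter(rng.normal(size=shape), sigma)
    s = np.std(n)
    return n / s if s > 0 else n


def _colour_object(
    mask: np.ndarray,
    hue_range: tuple[float, float],
    sat_range: tuple[float, float],
    val_range: tuple[float, float],
    config: FixtureConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render an OBJECT mask to uint8 RGB with per-pixel HSV jitter."""
    h, w = mask.shape
    hue = rng.uniform(*hue_range)
    sat = rng.uniform(*sat_range)
    val = rng.uniform(*val_range)
    hsv = np.empty((h, w, 3), dtype=np.float64)
    hsv[..., 0] = hue + rng.normal(0.0, config.hue_noise, (h, w))
    hsv[..., 1] = sat + rng.normal(0.0, 0.05, (h, w))
    # a little low-frequency shading so texture carries information too
    hsv[..., 2] = val + 0.10 * _smooth_noise((h, w), 2.0, rng) + rng.normal(0.0, config.value_noise, (h, w))
    hsv = np.clip(hsv, 0.0, 1.0)
    rgb = (hsv2rgb(hsv) * 255).astype(np.uint8)
    # dark soil-ish fill outside the object; those pixels are EXCLUDED anyway
    rgb[mask == 0] = (45, 35, 25)
    return rgb


def _oriented_extent_ratio(coords: np.ndarray) -> float:
    """Aspect ratio of the PCA-oriented bounding box of pixel coordinates."""
    c = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    proj = c @ vt.T
    ext = proj.max(axis=0) - proj.min(axis=0) + 1.0
    return float(ext[0] / ext[1])


def make_clover_sample(config: FixtureConfig, rng: np.random.Generator) -> PlantSample:
    """A clover patch: three overlapping rounded leaflets on a common petiole.

    The OBJECT region is a single connected component covering between 5%
    and 80% of the patch; parameters are redrawn (from the same stream) in
    the rare event noise disconnects the leaflets.
    """
    s = config.sample_size
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    for _ in range(20):
        cy = s / 2 + rng.uniform(-0.06, 0.06) * s
        cx = s / 2 + rng.uniform(-0.06, 0.06) * s
        theta0 = rng.uniform(0, 2 * np.pi)
        f = np.full((s, s), np.inf)
        for k in range(3):
            th = theta0 + k * 2 * np.pi / 3 + rng.uniform(-0.25, 0.25)
            a = rng.uniform(0.14, 0.22) * s          # semi-major, along th
            b = a * rng.uniform(0.6, 0.9)            # semi-minor
            d = a * rng.uniform(0.55, 0.8)           # petiole-to-centre distance
            ly, lx = cy + d * np.sin(th), cx + d * np.cos(th)
            u = (xx - lx) * np.cos(th) + (yy - ly) * np.sin(th)
            v = -(xx - lx) * np.sin(th) + (yy - ly) * np.cos(th)
            f = np.minimum(f, (u / a) ** 2 + (v / b) ** 2 - 1.0)
        noise = 0.18 * _smooth_noise((s, s), 1.5, rng)
        obj = (f + noise) < 0.0
        frac = obj.mean()
        if not (0.05 <= frac <= 0.80):
            continue
        labels, n = ndimage.label(obj)
        if n != 1:
            continue
        break
    else:  # extremely unlikely; fall back to noiseless ellipses
        obj = f < 0.0

    rgb = _colour_object(obj, config.clover_hue, (0.55, 0.80), (0.42, 0.65), config, rng)
    mask = np.where(obj, OBJECT, EXCLUDED).astype(np.uint8)
    return PlantSample(rgb=rgb, mask=mask, species=CLOVER)


def _draw_blade(canvas: np.ndarray, rng: np.random.Generator) -> None:
    """Paint one bezier-curved blade (2-6 px wide) onto a boolean canvas."""
    s = canvas.shape[0]
    width = rng.uniform(2.0, 6.0)
    length = rng.uniform(0.65, 0.95) * s * np.sqrt(2) * 0.75
    theta = rng.uniform(0, np.pi)
    mid = np.array([s / 2, s / 2]) + rng.uniform(-0.1, 0.1, 2) * s
    direction = np.array([np.sin(theta), np.cos(theta)])
    p0 = mid - direction * length / 2
    p2 = mid + direction * length / 2
    normal = np.array([-direction[1], direction[0]])
    p1 = mid + normal * rng.uniform(-1, 1) * length / 10
    t = np.linspace(0, 1, int(3 * length))[:, None]
    pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2
    r = width / 2
    for py, px in pts:
        y0, y1 = int(np.floor(py - r)), int(np.ceil(py + r))
        x0, x1 = int(np.floor(px - r)), int(np.ceil(px + r))
        y0c, x0c = max(y0, 0), max(x0, 0)
        y1c, x1c = min(y1, s - 1), min(x1, s - 1)
        if y1c < y0c or x1c < x0c:
            continue
        yy, xx = np.mgrid[y0c : y1c + 1, x0c : x1c + 1]
        canvas[y0c : y1c + 1, x0c : x1c + 1] |= (yy - py) ** 2 + (xx - px) ** 2 <= r * r


def make_grass_sample(config: FixtureConfig, rng: np.random.Generator) -> PlantSample:
    """A grass patch: 1-3 thin elongated blades.

    Every connected component of the OBJECT mask has an oriented
    bounding-box aspect ratio of at least 4 (blades are redrawn until this
    holds), and total coverage stays at or below half the patch.
    """
    s = config.sample_size
    for _ in range(30):
        obj = np.zeros((s, s), dtype=bool)
        n_blades = rng.integers(1, 4)
        for _ in range(n_blades):
            _draw_blade(obj, rng)
        if obj.mean() > 0.5 or not obj.any():
            continue
        labels, n = ndimage.label(obj)
        ok = True
        for comp in range(1, n + 1):
            coords = np.argwhere(labels == comp)
            if len(coords) < 8 or _oriented_extent_ratio(coords) < 4.0:
                ok = False
                break
        if ok:
            break
    else:
        # fallback: one straight horizontal blade, trivially elongated
        obj = np.zeros((s, s), dtype=bool)
        obj[s // 2 : s // 2 + 2, 2 : s - 2] = True

    rgb = _colour_object(obj, config.grass_hue, (0.50, 0.75), (0.55, 0.85), config, rng)
    mask = np.where(obj, OBJECT, EXCLUDED).astype(np.uint8)
    return PlantSample(rgb=rgb, mask=mask, species=GRASS)


def make_background(config: FixtureConfig, rng: np.random.Generator) -> np.ndarray:
    """A full-size textured soil image, darker on average than plant matter."""
    h, w = config.image_size
    hsv = np.empty((h, w, 3), dtype=np.float64)
    hsv[..., 0] = rng.uniform(0.05, 0.11) + rng.normal(0, 0.01, (h, w))
    hsv[..., 1] = rng.uniform(0.30, 0.55) + rng.normal(0, 0.04, (h, w))
    val = rng.uniform(0.18, 0.32)
    hsv[..., 2] = (
        val
        + 0.06 * _smooth_noise((h, w), 1.0, rng)
        + 0.05 * _smooth_noise((h, w), 4.0, rng)
        + rng.normal(0, 0.02, (h, w))
    )
    hsv = np.clip(hsv, 0.0, 1.0)
    return (hsv2rgb(hsv) * 255).astype(np.uint8)


def make_sample_library(
    counts: tuple[int, int, int],
    config: FixtureConfig,
    seed: int | None = None,
    role: str = "train",
) -> SampleLibrary:
    """Build a library of (clover, grass, background) fixtures.

    ``role`` ("train" or "test") is folded into every child seed, so train
    and test libraries drawn from the same master seed share no random
    stream — the procedural analogue of keeping cropped sample sets
    separate between the training and testing datasets.
    """
    if seed is None:
        seed = config.rng_seed
    n_clover, n_grass, n_bg = counts
    lib = SampleLibrary(role=role, seed=seed)
    for i in range(n_clover):
        s = make_clover_sample(config, child_rng(seed, role, "clover", i))
        s.sample_id = f"{role}-clover-{i:04d}"
        lib.clover.append(s)
    for i in range(n_grass):
        s = make_grass_sample(config, child_rng(seed, role, "grass", i))
        s.sample_id = f"{role}-grass-{i:04d}"
        lib.grass.append(s)
    for i in range(n_bg):
        lib.backgrounds.append(make_background(config, child_rng(seed, role, "background", i)))
    return lib
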