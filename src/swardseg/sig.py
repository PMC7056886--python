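"""Synthetic scene composition and dataset assembly.

Labelled training scenes are built by pasting augmented plant samples over
soil backgrounds (painter's algorithm: later samples occlude earlier ones).
Sample boundary pixels are relabelled as ignore so edge artefacts of the
cut-and-paste process do not teach the network false edges, and Gaussian
drop shadows darken the canvas beneath roughly half the scenes to vary
lighting.  Patches are pasted without blending; the resulting seams are
accepted as a further lighting augmentation rather than hidden.

Augmentation ranges: horizontal/vertical flips (p=0.5 each), scale +-25%,
gamma +-10%, saturation +-25%; rotation is off by default because at
2-3 px/mm it destroys blade texture.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.color import hsv2rgb, rgb2hsv
from skimage.transform import resize

from .types import (
    BACKGROUND,
    CLOVER,
    EXCLUDED,
    GRASS,
    IGNORE,
    IGNORE_EDGE,
    OBJECT,
    ContaminationError,
    PlantSample,
    SampleLibrary,
)


@dataclass
class SigConfig:
    """Scene-composition parameters.

    ``n_samples_range`` is inclusive.  Jitters are relative half-widths:
    ``scale_jitter=0.25`` draws scale factors uniformly in [0.75, 1.25].
    ``shadow_probability`` gates drop shadows per image; when the per-image
    coin lands, every pasted sample casts one (both granularities exist in
    the field; the per-image coin is what "approximately half of our
    synthetic images" quantifies, so that is the configurable gate).
    """

    n_samples_range: tuple[int, int] = (2, 20)
    flip_probability: float = 0.5
    scale_jitter: float = 0.25
    gamma_jitter: float = 0.10
    saturation_jitter: float = 0.25
    shadow_probability: float = 0.5
    shadow_sigma_range: tuple[float, float] = (0.5, 1.5)   # x sample radius
    shadow_intensity_range: tuple[float, float] = (0.2, 0.6)
    edge_ignore_width: int = 1
    rotation_enabled: bool = False
    species_weights: tuple[float, float] | None = None  # None -> area-balanced
    record_placements: bool = False  # keep per-sample paste geometry in provenance

    def validate(self) -> None:
        lo, hi = self.n_samples_range
        if not (1 <= lo <= hi):
            raise ValueError("n_samples_range must satisfy 1 <= min <= max")
        for name in ("scale_jitter", "gamma_jitter", "saturation_jitter"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name} must lie in [0, 1)")
        if not (0 <= self.shadow_probability <= 1):
            raise ValueError("shadow_probability must lie in [0, 1]")
        if self.edge_ignore_width < 0:
            raise ValueError("edge_ignore_width must be >= 0")


@dataclass
class DatasetSpec:
    """Composition of one dataset build.

    total = n_synthetic + n_partial * flip_expand_factor; the flip factor is
    fixed at 4 (identity, hflip, vflip, both).
    """

    n_synthetic: int
    n_partial: int
    flip_expand_factor: int = 4
    sample_counts: tuple[int, int, int] | None = None

    @property
    def total(self) -> int:
        return self.n_synthetic + self.n_partial * self.flip_expand_factor


@dataclass
class Dataset:
    """Built dataset: parallel image/label lists plus a provenance manifest."""

    images: list[np.ndarray]
    labels: list[np.ndarray]
    manifest: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.images)


def mark_edge_ignore(mask: np.ndarray, width: int) -> np.ndarray:
    """Relabel OBJECT pixels within ``width`` (Chebyshev) of non-OBJECT.

    Pixels beyond the patch border count as non-OBJECT, so a fully-OBJECT
    patch still grows an ignore rim.  EXCLUDED pixels are untouched.
    """
    if width < 0:
        raise ValueError("width must be >= 0")
    if width == 0:
        return mask.copy()
    obj = mask == OBJECT
    structure = np.ones((2 * width + 1, 2 * width + 1), dtype=bool)
    interior = ndimage.binary_erosion(obj, structure=structure, border_value=0)
    out = mask.copy()
    out[obj & ~interior] = IGNORE_EDGE
    return out


def augment_sample(
    sample: PlantSample,
    config: SigConfig,
    rng: np.random.Generator,
    return_params: bool = False,
) -> PlantSample | tuple[PlantSample, dict]:
    """Flip/scale/gamma/saturation augmentation of one sample.

    The mask is transformed geometrically in lockstep with the RGB
    (nearest-neighbour); gamma and saturation touch the RGB only.  All five
    random draws happen unconditionally so the stream layout is independent
    of the parameter values.  ``return_params`` additionally reports the
    drawn factors.
    """
    hflip = rng.random() < config.flip_probability
    vflip = rng.random() < config.flip_probability
    scale = rng.uniform(1 - config.scale_jitter, 1 + config.scale_jitter)
    gamma = rng.uniform(1 - config.gamma_jitter, 1 + config.gamma_jitter)
    saturation = rng.uniform(1 - config.saturation_jitter, 1 + config.saturation_jitter)

    rgb, mask = sample.rgb, sample.mask
    if hflip:
        rgb, mask = rgb[:, ::-1], mask[:, ::-1]
    if vflip:
        rgb, mask = rgb[::-1, :], mask[::-1, :]
    if scale != 1.0:
        h = int(round(rgb.shape[0] * scale))
        w = int(round(rgb.shape[1] * scale))
        if h < 1 or w < 1:
            raise ValueError("scale augmentation collapsed the sample below 1x1")
        rgb = resize(rgb, (h, w), order=1, preserve_range=True, anti_aliasing=False)
        mask = resize(mask, (h, w), order=0, preserve_range=True, anti_aliasing=False).astype(np.uint8)
    rgb = np.asarray(rgb, dtype=np.float64)
    if gamma != 1.0:
        rgb = ((rgb / 255.0) ** gamma) * 255.0
    if saturation != 1.0:
        hsv = rgb2hsv(rgb / 255.0)
        hsv[..., 1] = np.clip(hsv[..., 1] * saturation, 0.0, 1.0)
        rgb = hsv2rgb(hsv) * 255.0
    rgb = np.clip(np.round(rgb), 0, 255).astype(np.uint8)
    out = PlantSample(rgb=rgb, mask=np.ascontiguousarray(mask), species=sample.species,
                      sample_id=sample.sample_id)
    if return_params:
        return out, {"hflip": hflip, "vflip": vflip, "scale": scale,
                     "gamma": gamma, "saturation": saturation}
    return out


def _species_probability(library: SampleLibrary, config: SigConfig) -> float:
    """P(clover) for sample selection, balancing by mean OBJECT area.

    Grass blades are thin and clover lobes compact, so uniform selection
    over-represents clover area; weighting clover by the grass/clover mean
    area ratio balances expected coverage per species.
    """
    if config.species_weights is not None:
        wc, wg = config.species_weights
        return wc / (wc + wg)
    if not library.grass:
        return 1.0
    if not library.clover:
        return 0.0
    mean_c = np.mean([np.sum(s.mask == OBJECT) for s in library.clover])
    mean_g = np.mean([np.sum(s.mask == OBJECT) for s in library.grass])
    wc = mean_g / mean_c
    return float(wc / (wc + 1.0))


def _cast_shadow(canvas: np.ndarray, cy: float, cx: float, radius: float,
                 config: SigConfig, rng: np.random.Generator) -> None:
    """Darken the canvas with an elliptical Gaussian centred under a sample."""
    sigma = rng.uniform(*config.shadow_sigma_range) * radius
    peak = rng.uniform(*config.shadow_intensity_range)
    aniso = rng.uniform(0.7, 1.3)
    h, w = canvas.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    alpha = peak * np.exp(
        -((yy - cy) ** 2 / (2 * sigma**2) + (xx - cx) ** 2 / (2 * (sigma * aniso) ** 2))
    )
    canvas[:] = np.clip(np.round(canvas * (1.0 - alpha[..., None])), 0, 255).astype(np.uint8)


def compose_image(
    background: np.ndarray,
    library: SampleLibrary,
    config: SigConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Compose one labelled scene; returns (rgb, label map, provenance).

    Between ``n_samples_range`` samples are augmented and pasted at uniform
    random positions (partial off-canvas overhang allowed, clipped), later
    samples occluding earlier ones.  Shadows alter the RGB only; the label
    map takes the class of the topmost OBJECT pixel, IGNORE for topmost
    edge pixels, BACKGROUND elsewhere.
    """
    if not library.clover and not library.grass:
        raise ValueError("sample library is empty")
    lo, hi = config.n_samples_range
    canvas = background.copy()
    H, W = canvas.shape[:2]
    labels = np.full((H, W), BACKGROUND, dtype=np.uint8)

    n = int(rng.integers(lo, hi + 1))
    shadow_on = bool(rng.random() < config.shadow_probability)
    # Shadow parameters come from a dedicated child stream (seeded here
    # unconditionally), so toggling shadow_probability changes the RGB only:
    # sample selection and placement — hence the label map — are untouched.
    shadow_rng = np.random.default_rng(int(rng.integers(2**62)))
    p_clover = _species_probability(library, config)
    used = []
    placements = []
    for _ in range(n):
        species = CLOVER if rng.random() < p_clover else GRASS
        pool = library.samples_of(species)
        sample = pool[int(rng.integers(len(pool)))]
        aug = augment_sample(sample, config, rng)
        mask = mark_edge_ignore(aug.mask, config.edge_ignore_width)
        sh, sw = mask.shape
        top = int(rng.integers(-(sh // 2), H - sh // 2 + 1))
        left = int(rng.integers(-(sw // 2), W - sw // 2 + 1))
        if shadow_on:
            radius = np.sqrt(np.sum(mask != EXCLUDED) / np.pi)
            _cast_shadow(canvas, top + sh / 2, left + sw / 2, radius, config, shadow_rng)
        y0, x0 = max(top, 0), max(left, 0)
        y1, x1 = min(top + sh, H), min(left + sw, W)
        if y1 <= y0 or x1 <= x0:
            used.append(sample.sample_id)
            continue
        m = mask[y0 - top : y1 - top, x0 - left : x1 - left]
        r = aug.rgb[y0 - top : y1 - top, x0 - left : x1 - left]
        visible = m != EXCLUDED
        canvas[y0:y1, x0:x1][visible] = r[visible]
        lab = labels[y0:y1, x0:x1]
        lab[m == OBJECT] = species
        lab[m == IGNORE_EDGE] = IGNORE
        used.append(sample.sample_id)
        if config.record_placements:
            placements.append({"species": species, "top": top, "left": left, "mask": mask})
    provenance = {"n_samples": n, "shadow": shadow_on, "sample_ids": used}
    if config.record_placements:
        provenance["placements"] = placements
    return canvas, labels, provenance


def flip_expand(image: np.ndarray, labels: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """The four flip variants {identity, hflip, vflip, hflip+vflip}."""
    return [
        (image.copy(), labels.copy()),
        (image[:, ::-1].copy(), labels[:, ::-1].copy()),
        (image[::-1, :].copy(), labels[::-1, :].copy()),
        (image[::-1, ::-1].copy(), labels[::-1, ::-1].copy()),
    ]


def build_dataset(
    spec: DatasetSpec,
    library: SampleLibrary,
    partials: list[tuple[np.ndarray, np.ndarray]],
    config: SigConfig,
    rng: np.random.Generator,
    expected_role: str | None = None,
    keep_images: bool = True,
) -> Dataset:
    """Assemble a dataset of composed scenes plus flip-expanded partials.

    ``expected_role`` guards against train/test contamination: building a
    "train" dataset from a library tagged "test" (or vice versa) raises.
    With ``keep_images=False`` every image is still generated (and counted
    in the manifest) but not retained, for memory-light composition checks.
    """
    if expected_role is not None and library.role is not None and library.role != expected_role:
        raise ContaminationError(
            f"library role {library.role!r} used in a {expected_role!r} build"
        )
    if spec.n_synthetic > 0 and not library.backgrounds:
        raise ValueError("library has no backgrounds for synthetic composition")
    if len(partials) < spec.n_partial:
        raise ValueError(f"need {spec.n_partial} partial images, got {len(partials)}")

    images: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    entries = []
    for i in range(spec.n_synthetic):
        bg = library.backgrounds[int(rng.integers(len(library.backgrounds)))]
        rgb, lab, prov = compose_image(bg, library, config, rng)
        if keep_images:
            images.append(rgb)
            labels.append(lab)
        entries.append({"kind": "synthetic", "index": i, **prov})
    flips = ("identity", "hflip", "vflip", "hvflip")
    for j in range(spec.n_partial):
        rgb, lab = partials[j]
        for name, (fr, fl) in zip(flips, flip_expand(rgb, lab)):
            if keep_images:
                images.append(fr)
                labels.append(fl)
            entries.append({"kind": "partial", "index": j, "flip": name})

    total = len(entries)
    assert total == spec.total, "dataset total violates n_synthetic + 4*n_partial"
    manifest = {
        "role": expected_role or library.role,
        "n_synthetic": spec.n_synthetic,
        "n_partial": spec.n_partial,
        "flip_expand_factor": spec.flip_expand_factor,
        "total": total,
        "library": library.manifest(),
        "entries": entries,
    }
    return Dataset(images=images, labels=labels, manifest=manifest)


def stratified_kfold(
    sub_datasets: dict[str, list],
    k: int,
    rng: np.random.Generator,
) -> list[dict[str, list]]:
    """Split each named group independently into k near-equal parts.

    Fold i aggregates part i of every group, so heterogeneous sub-datasets
    (sample-collection batches, partially labelled images) contribute
    proportionally to every fold.  Splitting sample libraries this way
    BEFORE synthetic generation guarantees no sample appears in two folds'
    synthetic images.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    for name, items in sub_datasets.items():
        if len(items) < k:
            raise ValueError(f"group {name!r} has {len(items)} items, fewer than k={k}")
    folds: list[dict[str, list]] = [dict() for _ in range(k)]
    for name, items in sub_datasets.items():
        order = rng.permutation(len(items))
        for i, part in enumerate(np.array_split(order, k)):
            folds[i][name] = [items[j] for j in part]
    return folds
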