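"""Odometry-aided rasterising stitcher for push-broom style frame sequences.

Adjacent top-down frames overlap heavily; normalised cross-correlation of
the shared band recovers the overlap row count, the overlap is divided
into strips whose central rows act as representatives, wheel-encoder
travel places each representative row in along-track millimetres (with
per-frame px/mm for the across-track axis), and all samples are averaged
into a metric raster grid (1.2 x 1.2 mm cells by default).  Class maps are
stitched with the SAME parameters computed from the RGB pass, accumulated
as one-hot votes and finalised by per-cell argmax — averaging class
integers would be meaningless.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .types import FrameSequence, UnstitchablePairError

log = logging.getLogger(__name__)


@dataclass
class StitchConfig:
    """Stitcher parameters.

    ``n_strips`` per overlap region (clamped down when the overlap is
    shallow); ``cell_size_mm`` raster resolution; ``correlation_floor`` the
    minimum acceptable normalised cross-correlation peak before a frame
    pair is declared unstitchable; ``min_overlap_px`` bounds the overlap
    search from below (a physical prior from vehicle speed and frame rate).
    """

    n_strips: int = 22
    cell_size_mm: float = 1.2
    correlation_floor: float = 0.4
    min_overlap_px: int = 8


@dataclass
class RasterGrid:
    """Metric accumulation grid: per-cell running sums and sample counts."""

    cell_size: float
    origin: tuple[float, float]      # (y_mm, x_mm) of cell (0, 0)'s corner
    shape: tuple[int, int]
    n_channels: int = 3
    sums: np.ndarray = field(init=False)
    counts: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        ny, nx = self.shape
        self.sums = np.zeros((ny, nx, self.n_channels), dtype=np.float64)
        self.counts = np.zeros((ny, nx), dtype=np.int64)

    def add(self, y_mm: np.ndarray, x_mm: np.ndarray, values: np.ndarray) -> None:
        """Accumulate samples at metric positions into their cells."""
        iy = np.floor((np.asarray(y_mm) - self.origin[0]) / self.cell_size).astype(np.intp)
        ix = np.floor((np.asarray(x_mm) - self.origin[1]) / self.cell_size).astype(np.intp)
        ok = (iy >= 0) & (iy < self.shape[0]) & (ix >= 0) & (ix < self.shape[1])
        iy, ix = iy[ok], ix[ok]
        v = np.asarray(values, dtype=np.float64).reshape(-1, self.n_channels)[ok]
        np.add.at(self.sums, (iy, ix), v)
        np.add.at(self.counts, (iy, ix), 1)

    def finalise(self) -> np.ndarray:
        """Per-cell means; untouched cells are NaN."""
        out = np.full_like(self.sums, np.nan)
        filled = self.counts > 0
        out[filled] = self.sums[filled] / self.counts[filled, None]
        return out

    @property
    def empty_mask(self) -> np.ndarray:
        return self.counts == 0


@dataclass
class PairParams:
    """Stitch parameters of one adjacent frame pair (computed from RGB)."""

    frame_index: int           # index of the later frame
    overlap: int               # shared rows
    shift_px: int              # along-track displacement in pixels
    strip_rows: np.ndarray     # representative row indices in the later frame
    base_mm: float             # along-track position of the later frame's row 0
    scale: float               # px/mm of the later frame


def _grey(frame: np.ndarray) -> np.ndarray:
    f = np.asarray(frame, dtype=np.float64)
    return f.mean(axis=-1) if f.ndim == 3 else f


def estimate_overlap(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    config: StitchConfig | None = None,
    max_overlap: int | None = None,
) -> int:
    """Overlap row count maximising normalised cross-correlation.

    The later frame ``frame_b`` shares its first ``overlap`` rows with the
    last ``overlap`` rows of ``frame_a``; every feasible overlap in
    [min_overlap_px, max_overlap] is scored exhaustively on mean-subtracted
    greyscale bands.  A peak below ``correlation_floor`` raises
    :class:`UnstitchablePairError` so the pair can be dropped and logged.
    """
    config = config or StitchConfig()
    a, b = _grey(frame_a), _grey(frame_b)
    if a.shape[1] != b.shape[1]:
        raise ValueError("frames must share width")
    h = min(a.shape[0], b.shape[0])
    hi = min(max_overlap if max_overlap is not None else h, h)
    lo = max(config.min_overlap_px, 1)
    if lo > hi:
        raise ValueError("infeasible overlap range")
    best_ncc, best_overlap = -np.inf, None
    for overlap in range(lo, hi + 1):
        seg_a = a[a.shape[0] - overlap :, :].ravel()
        seg_b = b[:overlap, :].ravel()
        da = seg_a - seg_a.mean()
        db = seg_b - seg_b.mean()
        denom = np.linalg.norm(da) * np.linalg.norm(db)
        ncc = float(da @ db / denom) if denom > 0 else 0.0
        if ncc > best_ncc:
            best_ncc, best_overlap = ncc, overlap
    if best_ncc < config.correlation_floor:
        raise UnstitchablePairError(
            f"correlation peak {best_ncc:.3f} below floor {config.correlation_floor}"
        )
    return int(best_overlap)


def extract_strips(frame: np.ndarray, overlap: int, n_strips: int = 22) -> np.ndarray:
    """Representative row indices: the overlap's strips' central rows.

    The first ``overlap`` rows of the (later) frame are partitioned into
    ``n_strips`` contiguous bands; each band's representative is its
    central row (index floor((h-1)/2) within the band).  Overlaps
    shallower than ``n_strips`` clamp the strip count with a warning.
    """
    if overlap < 1:
        raise ValueError("overlap must be >= 1")
    if overlap < n_strips:
        log.warning("overlap %d < %d strips; clamping", overlap, n_strips)
        n_strips = overlap
    bands = np.array_split(np.arange(overlap), n_strips)
    return np.array([band[(len(band) - 1) // 2] for band in bands], dtype=np.intp)


def place_strips(
    strip_rows: np.ndarray,
    n_cols: int,
    base_mm: float,
    travel_mm: float,
    shift_px: int,
    scale: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Metric coordinates of strip pixels.

    Along-track positions interpolate the encoder travel across the
    overlap: ``travel_mm`` corresponds to ``shift_px`` rows of displacement,
    so row r sits at ``base_mm + r * travel_mm / shift_px``.  When the
    encoder registered no movement the per-frame scale is used instead.
    Across-track positions come from the column index over ``scale``.
    """
    if shift_px > 0 and travel_mm > 0:
        mm_per_row = travel_mm / shift_px
    else:
        mm_per_row = 1.0 / scale
    y_mm = base_mm + np.asarray(strip_rows, dtype=np.float64) * mm_per_row
    x_mm = (np.arange(n_cols, dtype=np.float64) + 0.5) / scale
    return y_mm, x_mm


def _pair_parameters(seq: FrameSequence, config: StitchConfig) -> list[PairParams]:
    params: list[PairParams] = []
    base_mm = 0.0
    for i in range(1, len(seq)):
        base_mm += float(seq.encoder_travel[i])
        try:
            overlap = estimate_overlap(seq.frames[i - 1], seq.frames[i], config)
        except UnstitchablePairError as err:
            log.warning("dropping frame pair (%d, %d): %s", i - 1, i, err)
            continue
        shift = seq.frames[i - 1].shape[0] - overlap
        rows = extract_strips(seq.frames[i], overlap, config.n_strips)
        params.append(PairParams(
            frame_index=i, overlap=overlap, shift_px=shift,
            strip_rows=rows, base_mm=base_mm, scale=float(seq.scale[i]),
        ))
    return params


def _grid_for(params: list[PairParams], seq: FrameSequence,
              config: StitchConfig, n_channels: int) -> RasterGrid:
    ys, xs = [], []
    for p in params:
        travel = float(seq.encoder_travel[p.frame_index])
        y, x = place_strips(p.strip_rows, seq.frames[p.frame_index].shape[1],
                            p.base_mm, travel, p.shift_px, p.scale)
        ys.append(y)
        xs.append(x)
    y_all = np.concatenate(ys)
    x_all = np.concatenate(xs)
    cell = config.cell_size_mm
    y0 = np.floor(y_all.min() / cell) * cell
    x0 = np.floor(x_all.min() / cell) * cell
    ny = int(np.floor((y_all.max() - y0) / cell)) + 1
    nx = int(np.floor((x_all.max() - x0) / cell)) + 1
    return RasterGrid(cell_size=cell, origin=(y0, x0), shape=(ny, nx), n_channels=n_channels)


def rasterize(
    seq: FrameSequence,
    params: list[PairParams],
    config: StitchConfig,
    images: list[np.ndarray] | None = None,
    n_channels: int = 3,
) -> RasterGrid:
    """Mean-accumulate strip samples into the metric raster.

    ``images`` defaults to the sequence's own frames; passing one-hot
    encoded class maps with the RGB-derived ``params`` reuses identical
    placement for mask stitching.
    """
    if images is None:
        images = seq.frames
    grid = _grid_for(params, seq, config, n_channels)
    for p in params:
        img = np.asarray(images[p.frame_index], dtype=np.float64)
        if img.ndim == 2:
            img = img[..., None]
        travel = float(seq.encoder_travel[p.frame_index])
        y_mm, x_mm = place_strips(p.strip_rows, img.shape[1], p.base_mm,
                                  travel, p.shift_px, p.scale)
        for row, y in zip(p.strip_rows, y_mm):
            grid.add(np.full(img.shape[1], y), x_mm, img[row])
    return grid


def stitch_sequence(
    seq: FrameSequence, config: StitchConfig | None = None
) -> tuple[RasterGrid, list[PairParams]]:
    """Full RGB pass: overlaps, strips, placement, raster; returns params too."""
    config = config or StitchConfig()
    seq.validate()
    params = _pair_parameters(seq, config)
    if not params:
        raise UnstitchablePairError("no stitchable frame pairs in sequence")
    return rasterize(seq, params, config), params


def stitch_mask(
    class_maps: list[np.ndarray],
    seq: FrameSequence,
    params: list[PairParams],
    config: StitchConfig | None = None,
    n_classes: int = 3,
) -> tuple[np.ndarray, RasterGrid]:
    """Categorical raster from per-frame class maps with reused parameters.

    Maps are one-hot encoded, mean-accumulated exactly as the RGB samples
    were, and finalised by per-cell argmax over the vote means.  Returns
    (class raster with 255 in empty cells, the vote grid).
    """
    config = config or StitchConfig()
    onehot = [np.eye(n_classes, dtype=np.float64)[np.asarray(m, dtype=np.intp)]
              for m in class_maps]
    grid = rasterize(seq, params, config, images=onehot, n_channels=n_classes)
    votes = grid.finalise()
    out = np.full(grid.shape, 255, dtype=np.uint8)
    filled = ~grid.empty_mask
    out[filled] = np.nanargmax(votes[filled], axis=-1).astype(np.uint8)
    return out, grid


@dataclass
class PassConfig:
    """Synthetic camera-pass settings bracketing the real capture platform:
    14 frames per second at 0.14-0.37 m/s ground speed, ~2.5 px/mm."""

    frame_height_px: int = 128
    scale_px_mm: float = 2.5
    fps: float = 14.0
    speed_range_m_s: tuple[float, float] = (0.14, 0.37)
    noise_std: float = 0.0   # additive pixel noise on emitted frames


@dataclass
class SimulatedPass:
    sequence: FrameSequence
    offsets_px: np.ndarray   # ground-truth texture row of each frame's row 0
    texture: np.ndarray


def simulate_pass(
    texture: np.ndarray,
    config: PassConfig,
    rng: np.random.Generator,
) -> SimulatedPass:
    """Slide a virtual camera down a ground-truth texture.

    Per-frame speed is drawn uniformly from the configured range; frame
    offsets are rounded to whole pixel rows and the encoder reports the
    corresponding exact travel, so round-trip tests isolate stitching
    error from odometry error.
    """
    tex = np.asarray(texture)
    h_f = config.frame_height_px
    if tex.shape[0] <= h_f:
        raise ValueError("texture shorter than one frame")
    frames, travel, scales, offsets = [], [0.0], [config.scale_px_mm], [0]
    o = 0
    while True:
        speed = rng.uniform(*config.speed_range_m_s)
        shift = int(round(speed * 1000.0 / config.fps * config.scale_px_mm))
        shift = max(shift, 1)
        o_next = o + shift
        if o_next + h_f > tex.shape[0]:
            break
        offsets.append(o_next)
        travel.append(shift / config.scale_px_mm)
        scales.append(config.scale_px_mm)
        o = o_next
    for off in offsets:
        frame = tex[off : off + h_f].astype(np.float64)
        if config.noise_std > 0:
            frame = frame + rng.normal(0, config.noise_std, frame.shape)
        frames.append(np.clip(frame, 0, 255).astype(np.uint8))
    seq = FrameSequence(
        frames=frames,
        encoder_travel=np.asarray(travel, dtype=np.float64),
        scale=np.asarray(scales, dtype=np.float64),
    )
    return SimulatedPass(sequence=seq, offsets_px=np.asarray(offsets), texture=tex)
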