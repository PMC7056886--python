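"""Shared domain types for the sward-segmentation pipeline.

Class and mask encodings are fixed integers used consistently across the
package; palette PNG I/O maps them to the colour conventions used for
pasture labelling (red = clover, green = grass, black = background,
white = ignore).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Per-pixel semantic classes for scene label maps and network outputs.
CLOVER = 0
GRASS = 1
BACKGROUND = 2
IGNORE = 3  # excluded from loss and metrics

CLASS_NAMES = ("clover", "grass", "background")
N_CLASSES = 3

# Tri-state plant-sample mask values.
OBJECT = 0        # plant pixels carrying the species label
IGNORE_EDGE = 1   # boundary pixels pasted into scenes but ignored in loss
EXCLUDED = 2      # not part of the sample at all

# Palettes (RGB) for paletted PNG export.
LABEL_PALETTE = {
    CLOVER: (255, 0, 0),
    GRASS: (0, 255, 0),
    BACKGROUND: (0, 0, 0),
    IGNORE: (255, 255, 255),
}
MASK_PALETTE = {
    OBJECT: (255, 0, 0),
    IGNORE_EDGE: (0, 0, 255),
    EXCLUDED: (0, 0, 0),
}
CLASSMAP_PALETTE = {
    CLOVER: (255, 0, 0),
    GRASS: (0, 255, 0),
    BACKGROUND: (0, 0, 0),
}


@dataclass
class PlantSample:
    """An RGB patch plus tri-state mask for one cropped plant.

    ``rgb`` is H x W x 3 uint8; ``mask`` is H x W uint8 over
    {OBJECT, IGNORE_EDGE, EXCLUDED}; ``species`` is CLOVER or GRASS.
    """

    rgb: np.ndarray
    mask: np.ndarray
    species: int
    sample_id: str = ""

    def validate(self) -> None:
        if self.rgb.shape[:2] != self.mask.shape:
            raise ValueError("rgb and mask spatial shapes differ")
        if self.species not in (CLOVER, GRASS):
            raise ValueError(f"species must be CLOVER or GRASS, got {self.species}")
        if not np.any(self.mask == OBJECT):
            raise ValueError("sample has no OBJECT pixels")
        states = np.unique(self.mask)
        if not np.all(np.isin(states, [OBJECT, IGNORE_EDGE, EXCLUDED])):
            raise ValueError("mask contains values outside the tri-state set")

    @property
    def object_fraction(self) -> float:
        return float(np.mean(self.mask == OBJECT))


@dataclass
class SampleLibrary:
    """Collections of plant samples and soil backgrounds with provenance.

    ``role`` tags the library as belonging to the training or testing side
    of the dataset so cross-contamination can be detected downstream.
    """

    clover: list[PlantSample] = field(default_factory=list)
    grass: list[PlantSample] = field(default_factory=list)
    backgrounds: list[np.ndarray] = field(default_factory=list)
    role: str | None = None
    seed: int | None = None

    def samples_of(self, species: int) -> list[PlantSample]:
        return self.clover if species == CLOVER else self.grass

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.clover), len(self.grass), len(self.backgrounds))

    def manifest(self) -> dict:
        return {
            "role": self.role,
            "seed": self.seed,
            "counts": {
                "clover": len(self.clover),
                "grass": len(self.grass),
                "background": len(self.backgrounds),
            },
            "clover_ids": [s.sample_id for s in self.clover],
            "grass_ids": [s.sample_id for s in self.grass],
        }


@dataclass
class FrameSequence:
    """Ordered top-down frames with odometry and scale metadata.

    ``encoder_travel`` holds per-frame along-track travel (mm) since the
    previous frame (first entry 0); ``scale`` holds per-frame resolution in
    px/mm (from height sensing, supplied here as metadata).
    """

    frames: list[np.ndarray]
    encoder_travel: np.ndarray
    scale: np.ndarray

    def validate(self) -> None:
        n = len(self.frames)
        if len(self.encoder_travel) != n or len(self.scale) != n:
            raise ValueError("frames, encoder_travel and scale lengths differ")
        if np.any(np.asarray(self.encoder_travel) < 0):
            raise ValueError("encoder travel must be >= 0")
        if np.any(np.asarray(self.scale) <= 0):
            raise ValueError("scale must be > 0")

    def __len__(self) -> int:
        return len(self.frames)


class ContaminationError(ValueError):
    """Raised when a testing sample library is used to build training data."""


class UnstitchablePairError(ValueError):
    """Raised when cross-correlation finds no credible overlap between frames."""
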