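"""File formats: paletted PNGs, sidecar CSVs, JSON manifests, YAML configs.

Label maps, tri-state sample masks, and class rasters are stored as
paletted PNGs under the conventional colour schemes (samples: red=object,
blue=ignored edge, black=excluded; labels: red=clover, green=grass,
black=background, white=ignore).  Frame sidecars are CSVs with columns
(frame_id, encoder_travel_mm, scale_px_per_mm).
"""
from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .types import (
    CLASSMAP_PALETTE,
    LABEL_PALETTE,
    MASK_PALETTE,
    FrameSequence,
    PlantSample,
    SampleLibrary,
)


def _write_paletted(path: str | Path, indices: np.ndarray, palette: dict[int, tuple]) -> None:
    img = Image.fromarray(np.asarray(indices, dtype=np.uint8), mode="P")
    flat = [0] * (256 * 3)
    for idx, rgb in palette.items():
        flat[3 * idx : 3 * idx + 3] = rgb
    img.putpalette(flat)
    img.save(path)


def _read_paletted(path: str | Path) -> np.ndarray:
    img = Image.open(path)
    if img.mode != "P":
        raise ValueError(f"{path} is not a paletted PNG")
    return np.asarray(img, dtype=np.uint8)


def write_rgb(path: str | Path, rgb: np.ndarray) -> None:
    Image.fromarray(np.asarray(rgb, dtype=np.uint8), mode="RGB").save(path)


def read_rgb(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"), dtype=np.uint8)


def write_labelmap(path: str | Path, labels: np.ndarray) -> None:
    _write_paletted(path, labels, LABEL_PALETTE)


def read_labelmap(path: str | Path) -> np.ndarray:
    return _read_paletted(path)


def write_classmap(path: str | Path, classmap: np.ndarray) -> None:
    _write_paletted(path, classmap, CLASSMAP_PALETTE)


def write_sample(directory: str | Path, sample: PlantSample) -> None:
    """Paired ``<id>_rgb.png`` / ``<id>_mask.png`` files."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_rgb(d / f"{sample.sample_id}_rgb.png", sample.rgb)
    _write_paletted(d / f"{sample.sample_id}_mask.png", sample.mask, MASK_PALETTE)


def write_library(directory: str | Path, library: SampleLibrary) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for sample in library.clover + library.grass:
        write_sample(d, sample)
    for i, bg in enumerate(library.backgrounds):
        write_rgb(d / f"{library.role or 'lib'}-background-{i:04d}.png", bg)
    with open(d / "manifest.json", "w") as fh:
        json.dump(library.manifest(), fh, indent=2)


def write_sidecar(path: str | Path, seq: FrameSequence) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame_id", "encoder_travel_mm", "scale_px_per_mm"])
        for i in range(len(seq)):
            w.writerow([i, float(seq.encoder_travel[i]), float(seq.scale[i])])


def read_sidecar(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """(encoder_travel_mm, scale_px_per_mm) arrays, ordered by frame_id."""
    rows = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            rows.append((int(rec["frame_id"]), float(rec["encoder_travel_mm"]),
                         float(rec["scale_px_per_mm"])))
    rows.sort()
    travel = np.array([r[1] for r in rows])
    scale = np.array([r[2] for r in rows])
    return travel, scale


def write_json(path: str | Path, obj: dict) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2)


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_world_file(path: str | Path, grid) -> None:
    """Cell size and origin of a raster, in the sidecar-JSON style."""
    write_json(path, {
        "cell_size_mm": grid.cell_size,
        "origin_mm": list(grid.origin),
        "shape": list(grid.shape),
    })
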