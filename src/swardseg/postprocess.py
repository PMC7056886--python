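"""Confidence thresholding and sward-composition summaries.

Network outputs are softened class distributions; a pixel whose maximum
class probability falls below the confidence threshold (default 80%) is
declared background rather than guessed, and the remaining pixels take
their argmax class.  The clover/vegetation fraction of a region is then
the clover pixel count over the clover-plus-grass pixel count, and the
agreement with harvested dry-matter fractions is summarised by the
ordinary-least-squares coefficient of determination.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

from .types import BACKGROUND, CLOVER, GRASS


def apply_confidence_rule(probabilities: np.ndarray, tau: float = 0.8) -> np.ndarray:
    """Class map from probabilities: argmax, or BACKGROUND below ``tau``.

    ``probabilities`` is H x W x C with per-pixel distributions (validated
    to sum to 1 within 1e-4).  ``tau`` in (0, 1]; as tau -> 0 this reduces
    to a pure argmax map.
    """
    probs = np.asarray(probabilities, dtype=np.float64)
    if probs.ndim != 3:
        raise ValueError("probabilities must be H x W x C")
    if not (0 < tau <= 1):
        raise ValueError("tau must lie in (0, 1]")
    sums = probs.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=1e-4):
        raise ValueError("probabilities do not sum to 1 per pixel")
    cmap = probs.argmax(axis=-1).astype(np.uint8)
    cmap[probs.max(axis=-1) < tau] = BACKGROUND
    return cmap


def clover_fraction(classmap: np.ndarray, region: np.ndarray | None = None) -> float:
    """Clover share of vegetation: |clover| / (|clover| + |grass|).

    ``region`` optionally restricts the tally (e.g. to exclude a harvest
    frame); it must be non-empty.  Raises when the region holds no
    vegetation at all — the fraction is undefined there.
    """
    classmap = np.asarray(classmap)
    if region is None:
        region = np.ones(classmap.shape, dtype=bool)
    region = np.asarray(region, dtype=bool)
    if region.shape != classmap.shape:
        raise ValueError("region and classmap shapes differ")
    if not region.any():
        raise ValueError("region is empty")
    n_clover = int(np.sum((classmap == CLOVER) & region))
    n_grass = int(np.sum((classmap == GRASS) & region))
    if n_clover + n_grass == 0:
        raise ValueError("no vegetation pixels in region; fraction undefined")
    return n_clover / (n_clover + n_grass)


def linear_r2(x: np.ndarray, y: np.ndarray) -> float:
    """OLS coefficient of determination of y regressed on x."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points for a meaningful R^2")
    res = stats.linregress(x, y)
    return float(res.rvalue**2)
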