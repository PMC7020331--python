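"""Crest-based metrics for vertical structure silhouettes.

The crest of a column is the top edge of its topmost black cell, counted in
whole rows from the bottom edge of the image (a column with no black cell
has crest 0 — ground level). From the per-column crests we derive the
maximum height, per-section altitudinal statistics, and the topline: the
Euclidean length of the polyline joining consecutive columns' crest points,
a measure of crest roughness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, UndefinedMetricError
from .matrix import BinaryMatrix


@dataclass(frozen=True)
class SectionStats:
    """Mean and sample standard deviation of crest heights in one band of
    columns (sd is None for a single-column band)."""

    section_index: int
    start: int
    end: int
    mean_height: float
    sd_height: float | None


@dataclass(frozen=True)
class HeightProfile:
    crest_heights: tuple[float, ...]  # per column, scaled if height_size given
    section_stats: tuple[SectionStats, ...]
    height_size: float | None
    width_size: float | None


def crest_heights(m: BinaryMatrix) -> np.ndarray:
    """Per-column crest height in rows from the bottom edge (0 = no black)."""
    black = m.is_black
    any_black = black.any(axis=0)
    top_row = np.argmax(black, axis=0)  # first True from the top
    heights = np.where(any_black, m.n_rows - top_row, 0)
    return heights.astype(float)


def height_maximum(m: BinaryMatrix, height_size: float | None = None) -> float:
    """Height of the highest black pixel, in cm when a scale is given,
    else in rows."""
    if height_size is None:
        height_size = m.height_size
    h = crest_heights(m)
    if not (h > 0).any():
        raise UndefinedMetricError(
            "maximum height is undefined: no black cell in the matrix")
    scale = (height_size / m.n_rows) if height_size is not None else 1.0
    return float(h.max()) * scale


def altitudinal_profile(m: BinaryMatrix, section_width: int,
                        height_size: float | None = None) -> HeightProfile:
    """Mean and sample sd of column crest heights per band of
    ``section_width`` columns (left-anchored; last band may be short)."""
    if not 1 <= section_width <= m.n_cols:
        raise ParameterError(
            f"section_width must be in [1, {m.n_cols}], got {section_width}")
    if height_size is None:
        height_size = m.height_size
    scale = (height_size / m.n_rows) if height_size is not None else 1.0
    h = crest_heights(m) * scale
    stats = []
    for k, start in enumerate(range(0, m.n_cols, section_width)):
        end = min(start + section_width, m.n_cols)
        band = h[start:end]
        mean = float(band.mean())
        sd = float(band.std(ddof=1)) if band.size >= 2 else None
        stats.append(SectionStats(k, start, end, mean, sd))
    return HeightProfile(tuple(float(x) for x in h), tuple(stats),
                         height_size, m.width_size)


def topline(m: BinaryMatrix, height_size: float | None = None,
            width_size: float | None = None) -> float:
    """Length of the crest polyline.

    Crest points are (column center x, crest height y) for every column,
    including columns with no black cell (crest 0). Segment lengths are
    Euclidean. With both physical scales given the length is in cm; with
    neither, in pixel units. Giving only one scale is an error — a silent
    pixel/cm mix would be meaningless.
    """
    if height_size is None:
        height_size = m.height_size
    if width_size is None:
        width_size = m.width_size
    if (height_size is None) != (width_size is None):
        raise ParameterError(
            "topline needs both height_size and width_size (cm), or neither "
            "(pixel units); mixing units is not supported")
    h = crest_heights(m)
    if not (h > 0).any():
        raise UndefinedMetricError(
            "topline is undefined: no black cell in the matrix")
    if height_size is not None:
        y = h * (height_size / m.n_rows)
        dx = width_size / m.n_cols
    else:
        y = h
        dx = 1.0
    dy = np.diff(y)
    return float(np.sqrt(dx * dx + dy * dy).sum())
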