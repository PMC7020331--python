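"""Run-length ("hole") analysis of same-color sequences in rows and columns.

A hole is a maximal run of same-color pixels within a single line (row or
column). In vegetation or nest-wall images the white runs are light gaps;
their number and size distribution describe how fragmented the structure
is. Transparent cells terminate runs: a hole never spans a region excluded
from analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .matrix import BLACK, WHITE, BinaryMatrix


@dataclass(frozen=True)
class RunRecord:
    """One maximal same-color run within a row or column."""

    line_index: int
    color: str  # "black" or "white"
    start: int  # inclusive, 0-based position within the line
    length: int


@dataclass(frozen=True)
class SectionSummary:
    """Summary statistics of the runs found in a band of lines.

    ``sd_length`` is the sample standard deviation (n-1 denominator);
    statistics are None when there is no run (or, for the sd, fewer than
    two runs).
    """

    n_runs: int
    mean_length: float | None
    sd_length: float | None
    min_length: int | None
    max_length: int | None
    total_cells_in_runs: int


def _color_value(color: str) -> float:
    if color == "black":
        return BLACK
    if color == "white":
        return WHITE
    raise ParameterError(f"color must be 'black' or 'white', got {color!r}")


def _line_runs(line: np.ndarray, value: float, line_index: int,
               color: str) -> list[RunRecord]:
    match = (line == value).astype(np.int8)
    # run starts where match goes 0->1; ends where it goes 1->0
    padded = np.concatenate(([0], match, [0]))
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [RunRecord(line_index, color, int(s), int(e - s))
            for s, e in zip(starts, ends)]


def hole_runs_row(m: BinaryMatrix, color: str = "white") -> list[RunRecord]:
    """All maximal runs of ``color`` in every row, top to bottom.

    Transparent cells break runs; runs on either side of a transparent
    stretch are reported separately.
    """
    value = _color_value(color)
    out: list[RunRecord] = []
    for i in range(m.n_rows):
        out.extend(_line_runs(m.cells[i], value, i, color))
    return out


def hole_runs_column(m: BinaryMatrix, color: str = "white") -> list[RunRecord]:
    """All maximal runs of ``color`` in every column, left to right."""
    value = _color_value(color)
    out: list[RunRecord] = []
    for j in range(m.n_cols):
        out.extend(_line_runs(m.cells[:, j], value, j, color))
    return out


def summarize_runs(runs: list[RunRecord]) -> SectionSummary:
    lengths = [r.length for r in runs]
    n = len(lengths)
    if n == 0:
        return SectionSummary(0, None, None, None, None, 0)
    mean = sum(lengths) / n
    if n >= 2:
        sd = math.sqrt(sum((x - mean) ** 2 for x in lengths) / (n - 1))
    else:
        sd = None
    return SectionSummary(n, mean, sd, min(lengths), max(lengths),
                          sum(lengths))


def hole_section_summary(m: BinaryMatrix, color: str, axis: str,
                         start: int, end: int) -> SectionSummary:
    """Summary of the runs of ``color`` over lines [start, end) along
    ``axis`` ('row' or 'column')."""
    if axis == "row":
        axis_len = m.n_rows
        all_runs = hole_runs_row(m, color)
    elif axis == "column":
        axis_len = m.n_cols
        all_runs = hole_runs_column(m, color)
    else:
        raise ParameterError(f"axis must be 'row' or 'column', got {axis!r}")
    if not 0 <= start < end <= axis_len:
        raise ParameterError(
            f"need 0 <= start < end <= {axis_len}, got [{start}, {end})")
    return summarize_runs([r for r in all_runs if start <= r.line_index < end])


@dataclass(frozen=True)
class LightGap:
    """Per-row distances from the image edges to the outermost black pixels.

    For a row without any black pixel both distances equal the row width
    and ``no_black`` is True, so batch outputs stay rectangular.
    """

    row_index: int
    left_distance: int
    right_distance: int
    no_black: bool


def light_gap(m: BinaryMatrix) -> list[LightGap]:
    """Per row: cells left of the first black pixel and right of the last."""
    out = []
    width = m.n_cols
    for i, row in enumerate(m.is_black):
        idx = np.flatnonzero(row)
        if idx.size == 0:
            out.append(LightGap(i, width, width, True))
        else:
            out.append(LightGap(i, int(idx[0]), int(width - 1 - idx[-1]),
                                False))
    return out
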