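"""Black-pixel proportion metrics.

Denseness is the proportion of black pixels among non-transparent pixels.
When the photographed subject is a canopy against the sky, 1 - denseness
is the canopy openness; when it is standing vegetation against a white
panel, denseness measures vegetation density. The height quantile
(``height_proportion``) reports the physical height below which a given
fraction of the black pixels lies, scanning rows from the bottom edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, UndefinedMetricError
from .matrix import BinaryMatrix


@dataclass(frozen=True)
class SectionDensity:
    """Black fraction of one band of rows (or columns).

    ``start`` is inclusive, ``end`` exclusive (0-based). ``fraction_black``
    is among non-transparent cells and is None when the band contains no
    non-transparent cell.
    """

    section_index: int
    start: int
    end: int
    fraction_black: float | None


def denseness_total(m: BinaryMatrix) -> float:
    """Proportion of black among non-transparent cells."""
    nb, nw = m.n_black, m.n_white
    if nb + nw == 0:
        raise UndefinedMetricError(
            "denseness is undefined: every cell is transparent")
    return nb / (nb + nw)


def _denseness_sections(cells: np.ndarray, section_size: int,
                        axis_len: int) -> list[SectionDensity]:
    out = []
    for k, start in enumerate(range(0, axis_len, section_size)):
        end = min(start + section_size, axis_len)
        band = cells[start:end]
        nb = int((band == 1.0).sum())
        nw = int((band == 0.0).sum())
        frac = nb / (nb + nw) if nb + nw else None
        out.append(SectionDensity(k, start, end, frac))
    return out


def denseness_row(m: BinaryMatrix, section_size: int) -> list[SectionDensity]:
    """Black fraction per band of ``section_size`` consecutive rows.

    Bands are anchored at the top row (reading order); the last band may be
    shorter and is kept.
    """
    if not 1 <= section_size <= m.n_rows:
        raise ParameterError(
            f"section_size must be in [1, {m.n_rows}], got {section_size}")
    return _denseness_sections(m.cells, section_size, m.n_rows)


def denseness_column(m: BinaryMatrix, section_size: int) -> list[SectionDensity]:
    """Black fraction per band of ``section_size`` consecutive columns,
    anchored at the left edge."""
    if not 1 <= section_size <= m.n_cols:
        raise ParameterError(
            f"section_size must be in [1, {m.n_cols}], got {section_size}")
    return _denseness_sections(m.cells.T, section_size, m.n_cols)


def height_proportion(m: BinaryMatrix, proportion: float,
                      height_size: float | None = None) -> float:
    """Height below which ``proportion`` of the black pixels lies.

    Rows are accumulated from the bottom edge; the returned height is that
    of the *top edge* of the first row at which the cumulative black count
    reaches the requested proportion, i.e. (rows counted from the bottom /
    n_rows) x height_size. With no ``height_size`` the height is in rows.
    """
    if not 0.0 < proportion <= 1.0:
        raise ParameterError(
            f"proportion must be in (0, 1], got {proportion}")
    if height_size is None:
        height_size = m.height_size
    per_row = m.is_black.sum(axis=1)
    total = int(per_row.sum())
    if total == 0:
        raise UndefinedMetricError(
            "height quantile is undefined: no black cell in the matrix")
    cum = np.cumsum(per_row[::-1])  # from the bottom row up
    rows_from_bottom = int(np.searchsorted(cum, proportion * total - 1e-12) + 1)
    scale = (height_size / m.n_rows) if height_size is not None else 1.0
    return rows_from_bottom * scale
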