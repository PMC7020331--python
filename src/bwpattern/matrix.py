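"""The binary-matrix container shared by every metric.

A digitized photograph is represented as a 2D grid over three pixel states:
black (the subject: vegetation, nest wall, ...), white (background: sky,
cloth panel, ...) and transparent (pixels excluded from every metric, e.g.
an erased background behind a nest). Internally the grid is a float array
where black = 1.0, white = 0.0 and transparent = NaN, mirroring the 1/0/NA
encoding the metrics are defined on.

Row 0 is the top image row and column 0 the left one; all height metrics
count rows from the bottom edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InputFormatError, ParameterError

BLACK: float = 1.0
WHITE: float = 0.0
TRANSPARENT: float = float("nan")

_NA_TOKEN = "NA"


@dataclass(frozen=True)
class ImageInfo:
    """Cell counts and fractions of a binary matrix."""

    n_rows: int
    n_cols: int
    n_black: int
    n_white: int
    n_transparent: int
    fraction_black: float
    fraction_white: float
    fraction_transparent: float

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "n_black": self.n_black,
            "n_white": self.n_white,
            "n_transparent": self.n_transparent,
            "fraction_black": self.fraction_black,
            "fraction_white": self.fraction_white,
            "fraction_transparent": self.fraction_transparent,
        }


class BinaryMatrix:
    """2D grid of black/white/transparent cells with optional physical scale.

    Parameters
    ----------
    cells
        Array-like of shape (n_rows, n_cols) with values 1 (black),
        0 (white) or NaN (transparent).
    height_size, width_size
        Optional physical size of the imaged frame in centimetres. They are
        carried along so height/length metrics can report physical units.
    """

    __slots__ = ("cells", "height_size", "width_size")

    def __init__(self, cells, height_size: float | None = None,
                 width_size: float | None = None):
        arr = np.asarray(cells, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ParameterError(
                f"cells must be a 2D grid with at least one cell, got shape {arr.shape}")
        finite = arr[~np.isnan(arr)]
        if not np.all((finite == BLACK) | (finite == WHITE)):
            bad = finite[(finite != BLACK) & (finite != WHITE)]
            raise ParameterError(
                f"cells must contain only 1 (black), 0 (white) or NaN "
                f"(transparent); found value {bad.flat[0]!r}")
        if height_size is not None and height_size <= 0:
            raise ParameterError("height_size must be positive")
        if width_size is not None and width_size <= 0:
            raise ParameterError("width_size must be positive")
        self.cells = arr
        self.height_size = height_size
        self.width_size = width_size

    # -- basic geometry -------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.cells.shape[0]

    @property
    def n_cols(self) -> int:
        return self.cells.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.cells.shape

    # -- state masks and counts -----------------------------------------
    @property
    def is_black(self) -> np.ndarray:
        return self.cells == BLACK

    @property
    def is_white(self) -> np.ndarray:
        return self.cells == WHITE

    @property
    def is_transparent(self) -> np.ndarray:
        return np.isnan(self.cells)

    @property
    def n_black(self) -> int:
        return int(self.is_black.sum())

    @property
    def n_white(self) -> int:
        return int(self.is_white.sum())

    @property
    def n_transparent(self) -> int:
        return int(self.is_transparent.sum())

    # -- structural helpers ----------------------------------------------
    def transpose(self) -> "BinaryMatrix":
        return BinaryMatrix(self.cells.T, height_size=self.width_size,
                            width_size=self.height_size)

    def with_scale(self, height_size: float | None = None,
                   width_size: float | None = None) -> "BinaryMatrix":
        return BinaryMatrix(self.cells,
                            height_size=height_size if height_size is not None else self.height_size,
                            width_size=width_size if width_size is not None else self.width_size)

    def __eq__(self, other) -> bool:
        if not isinstance(other, BinaryMatrix):
            return NotImplemented
        if self.shape != other.shape:
            return False
        a, b = self.cells, other.cells
        return bool(np.all((a == b) | (np.isnan(a) & np.isnan(b))))

    def __hash__(self):
        raise TypeError("BinaryMatrix is mutable; not hashable")

    def __repr__(self) -> str:
        return (f"BinaryMatrix({self.n_rows}x{self.n_cols}, "
                f"black={self.n_black}, white={self.n_white}, "
                f"transparent={self.n_transparent})")


def image_information(m: BinaryMatrix) -> ImageInfo:
    """Summarize cell counts and fractions of a binary matrix."""
    total = m.n_rows * m.n_cols
    nb, nw, nt = m.n_black, m.n_white, m.n_transparent
    return ImageInfo(
        n_rows=m.n_rows, n_cols=m.n_cols,
        n_black=nb, n_white=nw, n_transparent=nt,
        fraction_black=nb / total,
        fraction_white=nw / total,
        fraction_transparent=nt / total,
    )


def write_matrix(m: BinaryMatrix, path) -> None:
    """Serialize a matrix as CSV with cells written as 1, 0 and NA."""
    tokens = np.where(m.is_black, "1", np.where(m.is_white, "0", _NA_TOKEN))
    with open(path, "w", encoding="ascii", newline="\n") as fh:
        for row in tokens:
            fh.write(",".join(row))
            fh.write("\n")


def read_matrix(path, height_size: float | None = None,
                width_size: float | None = None) -> BinaryMatrix:
    """Read a CSV matrix written by :func:`write_matrix`.

    Raises :class:`InputFormatError` naming the offending row/column for a
    malformed token, and for ragged rows.
    """
    rows: list[list[float]] = []
    width = None
    with open(path, "r", encoding="ascii") as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n").rstrip("\r")
            if line == "" and width is not None:
                continue  # trailing blank line
            tokens = line.split(",")
            parsed = []
            for j, tok in enumerate(tokens):
                tok = tok.strip()
                if tok == "1":
                    parsed.append(BLACK)
                elif tok == "0":
                    parsed.append(WHITE)
                elif tok == _NA_TOKEN:
                    parsed.append(TRANSPARENT)
                else:
                    raise InputFormatError(
                        f"{path}: invalid token {tok!r} at row {i}, column {j} "
                        f"(expected 1, 0 or NA)")
            if width is None:
                width = len(parsed)
            elif len(parsed) != width:
                raise InputFormatError(
                    f"{path}: ragged row {i} has {len(parsed)} cells, "
                    f"expected {width}")
            rows.append(parsed)
    if not rows:
        raise InputFormatError(f"{path}: empty matrix file")
    return BinaryMatrix(np.array(rows), height_size=height_size,
                        width_size=width_size)
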