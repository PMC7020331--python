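"""Square <-> circular matrix remapping for circular subjects.

Photographs of round subjects (a nest wall imaged around a white sphere, a
hemispherical canopy frame) are more naturally analyzed on a disk. The
mapping used here is angular-preserving with a radial rescale: along every
direction theta from the grid center, the disk radius is mapped linearly to
the distance from the center to the square's boundary along theta, and
cells are filled by nearest-neighbor lookup at cell centers. The center of
the grid is the continuous point (n/2, n/2) — a cell-corner point for
even n.

``compress_to_circle`` pulls the whole square into the inscribed disk and
marks cells outside the disk transparent; ``stretch_to_square`` is its
inverse and fills the corners from boundary-radius values.
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError
from .matrix import TRANSPARENT, BinaryMatrix


def _polar_grid(n: int):
    """Cell-center offsets from the grid center, radius and boundary scale."""
    centers = np.arange(n) + 0.5 - n / 2.0
    dy, dx = np.meshgrid(centers, centers, indexing="ij")
    r = np.hypot(dx, dy)
    # distance from center to the square boundary along each direction,
    # divided by the disk radius n/2
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.maximum(np.abs(dx), np.abs(dy))
        scale = np.where(denom > 0, r / denom, 1.0)
    return dx, dy, r, scale


def _nearest_cell(x: np.ndarray, y: np.ndarray, n: int):
    """Indices of the cells containing continuous points (x, y)."""
    col = np.clip(np.floor(x).astype(int), 0, n - 1)
    row = np.clip(np.floor(y).astype(int), 0, n - 1)
    return row, col


def compress_to_circle(m: BinaryMatrix) -> BinaryMatrix:
    """Map a square matrix onto its inscribed disk.

    Each cell whose center lies inside the disk of radius n/2 samples the
    source at the radially stretched position (same angle, radius scaled so
    the disk rim reaches the square boundary); cells outside the disk
    become transparent.
    """
    if m.n_rows != m.n_cols:
        raise ParameterError(
            f"compress_to_circle needs a square matrix, got "
            f"{m.n_rows}x{m.n_cols}")
    n = m.n_rows
    c = n / 2.0
    dx, dy, r, scale = _polar_grid(n)
    inside = r <= c
    sx = c + dx * scale
    sy = c + dy * scale
    row, col = _nearest_cell(sx, sy, n)
    out = np.full((n, n), TRANSPARENT)
    out[inside] = m.cells[row[inside], col[inside]]
    return BinaryMatrix(out, height_size=m.height_size,
                        width_size=m.width_size)


def _check_circular(m: BinaryMatrix) -> None:
    n = m.n_rows
    c = n / 2.0
    _, _, r, _ = _polar_grid(n)
    outside = r > c
    if not np.isnan(m.cells[outside]).all():
        raise ParameterError(
            "input is not a circular matrix: found non-transparent cells "
            "whose centers lie outside the inscribed disk")


def stretch_to_square(m: BinaryMatrix) -> BinaryMatrix:
    """Inverse of :func:`compress_to_circle`.

    Every output cell (corners included) samples the disk at the radially
    compressed position; corners are filled from boundary-radius values, so
    no geometric transparency remains.
    """
    if m.n_rows != m.n_cols:
        raise ParameterError(
            f"stretch_to_square needs a square matrix, got "
            f"{m.n_rows}x{m.n_cols}")
    _check_circular(m)
    n = m.n_rows
    c = n / 2.0
    dx, dy, r, scale = _polar_grid(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        inv = np.where(scale > 0, 1.0 / scale, 1.0)
    ox = dx * inv
    oy = dy * inv
    # samples at exactly the rim radius can fall, after nearest-neighbor
    # discretization, into a cell whose center is outside the disk (pure
    # geometric transparency); pull those samples inward along their ray
    # until they land on a disk cell
    outside_center = r > c  # per-cell geometric transparency of the input
    row, col = _nearest_cell(c + ox, c + oy, n)
    bad = outside_center[row, col]
    shrink = np.ones_like(ox)
    for _ in range(64):
        if not bad.any():
            break
        shrink[bad] *= 0.97
        row, col = _nearest_cell(c + ox * shrink, c + oy * shrink, n)
        bad = outside_center[row, col]
    out = m.cells[row, col]
    return BinaryMatrix(out, height_size=m.height_size,
                        width_size=m.width_size)
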