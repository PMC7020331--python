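"""Deterministic synthetic patterns and PNG/JPEG rendering.

Every metric in the package is testable without photographs: the generators
below emulate the archetypal subjects — chessboard and side-split grids
(the extremal aggregation arrangements), i.i.d. random grids of given
density, vegetation silhouettes (black shapes rising from the bottom edge
against white, produced by a bounded random walk of crest heights), and a
black disk on a transparent background (a round subject with erased
surroundings). Generators are bit-reproducible from (kind, dims, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from .binarize import ThresholdConfig
from .errors import ParameterError
from .matrix import BLACK, TRANSPARENT, WHITE, BinaryMatrix

KINDS = ("chessboard", "halves", "random", "silhouette", "disk")
ORIENTATIONS = ("left", "right", "top", "bottom")


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    n_rows: int
    n_cols: int
    density: float = 0.5          # random only
    orientation: str = "left"     # halves only: which side is black
    seed: int | None = None       # random, silhouette

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ParameterError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ParameterError("n_rows and n_cols must be >= 1")
        if not 0.0 <= self.density <= 1.0:
            raise ParameterError(f"density must be in [0, 1], got {self.density}")
        if self.orientation not in ORIENTATIONS:
            raise ParameterError(
                f"orientation must be one of {ORIENTATIONS}, got {self.orientation!r}")


def chessboard(n_rows: int, n_cols: int) -> BinaryMatrix:
    """Alternating parity grid; black on even row+column."""
    r, c = np.indices((n_rows, n_cols))
    return BinaryMatrix(np.where((r + c) % 2 == 0, BLACK, WHITE))


def halves(n_rows: int, n_cols: int, orientation: str = "left") -> BinaryMatrix:
    """One half of the grid black (all same-color pixels on one side)."""
    cells = np.full((n_rows, n_cols), WHITE)
    if orientation == "left":
        cells[:, : n_cols // 2] = BLACK
    elif orientation == "right":
        cells[:, n_cols - n_cols // 2:] = BLACK
    elif orientation == "top":
        cells[: n_rows // 2, :] = BLACK
    else:
        cells[n_rows - n_rows // 2:, :] = BLACK
    return BinaryMatrix(cells)


def random_grid(n_rows: int, n_cols: int, density: float = 0.5,
                seed: int | None = None) -> BinaryMatrix:
    """i.i.d. black cells with probability ``density``."""
    rng = np.random.default_rng(seed)
    cells = np.where(rng.random((n_rows, n_cols)) < density, BLACK, WHITE)
    return BinaryMatrix(cells)


def silhouette(n_rows: int, n_cols: int, seed: int | None = None) -> BinaryMatrix:
    """Vegetation-like silhouette: black below a random-walk crest line.

    The first column's crest is uniform over the middle third of the
    height; each next crest moves by a uniform step in {-2..2}, clamped to
    [0, n_rows].
    """
    rng = np.random.default_rng(seed)
    lo = n_rows // 3
    hi = max(lo + 1, 2 * n_rows // 3)
    crest = np.empty(n_cols, dtype=int)
    crest[0] = rng.integers(lo, hi + 1)
    steps = rng.integers(-2, 3, size=max(0, n_cols - 1))
    for j in range(1, n_cols):
        crest[j] = min(n_rows, max(0, crest[j - 1] + steps[j - 1]))
    rows = np.arange(n_rows)[:, None]
    cells = np.where(rows >= n_rows - crest[None, :], BLACK, WHITE)
    return BinaryMatrix(cells)


def disk(n_rows: int, n_cols: int) -> BinaryMatrix:
    """Black inscribed disk on a transparent background."""
    r, c = np.indices((n_rows, n_cols))
    cy, cx = n_rows / 2.0, n_cols / 2.0
    radius = min(n_rows, n_cols) / 2.0
    inside = np.hypot(c + 0.5 - cx, r + 0.5 - cy) <= radius
    return BinaryMatrix(np.where(inside, BLACK, TRANSPARENT))


def make_fixture(spec: FixtureSpec) -> BinaryMatrix:
    """Build the pattern described by ``spec``."""
    if spec.kind == "chessboard":
        return chessboard(spec.n_rows, spec.n_cols)
    if spec.kind == "halves":
        return halves(spec.n_rows, spec.n_cols, spec.orientation)
    if spec.kind == "random":
        return random_grid(spec.n_rows, spec.n_cols, spec.density, spec.seed)
    if spec.kind == "silhouette":
        return silhouette(spec.n_rows, spec.n_cols, spec.seed)
    return disk(spec.n_rows, spec.n_cols)


def render_png(m: BinaryMatrix, path, alpha_for_transparent: bool = True,
               alpha_rule: str = "opaque_above", **save_kwargs) -> None:
    """Render a matrix to an image file (format from the extension).

    Black cells become (0,0,0), white (255,255,255). Transparent cells are
    encoded in the alpha channel so that re-thresholding the file with the
    matching ``alpha_rule`` recovers the matrix exactly: under
    ``opaque_above`` (conventional) transparent pixels get alpha 0 and the
    rest 255; under ``paper_text`` the encoding is inverted. With
    ``alpha_for_transparent=False`` (or when saving to JPEG) transparent
    cells are flattened to white and no alpha channel is written.
    """
    if alpha_rule not in ("paper_text", "opaque_above"):
        raise ParameterError(f"unknown alpha_rule {alpha_rule!r}")
    gray = np.where(m.is_black, 0, 255).astype(np.uint8)
    rgb = np.stack([gray] * 3, axis=-1)
    suffix = str(path).lower()
    # only write an alpha channel when there is transparency to encode:
    # an all-opaque RGBA file would read back all-transparent under the
    # literal paper_text alpha rule
    use_alpha = (alpha_for_transparent and m.n_transparent > 0 and not
                 (suffix.endswith(".jpg") or suffix.endswith(".jpeg")))
    if use_alpha:
        if alpha_rule == "opaque_above":
            alpha = np.where(m.is_transparent, 0, 255).astype(np.uint8)
        else:
            alpha = np.where(m.is_transparent, 255, 0).astype(np.uint8)
        img = Image.fromarray(np.dstack([rgb, alpha]), mode="RGBA")
    else:
        img = Image.fromarray(rgb, mode="RGB")
    img.save(path, **save_kwargs)
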