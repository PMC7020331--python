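import numpy as np
import pytest

from bwpattern import BLACK, TRANSPARENT, WHITE, BinaryMatrix


def mat(diagram: str, **kwargs) -> BinaryMatrix:
    """Build a matrix from a diagram: '#' black, '.' white, '-' transparent.

    >>> mat("#.\\n.#")  # 2x2 chessboard
    """
    table = {"#": BLACK, ".": WHITE, "-": TRANSPARENT}
    rows = [[table[ch] for ch in line] for line in diagram.split()]
    return BinaryMatrix(np.array(rows), **kwargs)


@pytest.fixture
def chessboard6():
    from bwpattern.fixtures import chessboard
    return chessboard(6, 6)


@pytest.fixture
def halves6():
    from bwpattern.fixtures import halves
    return halves(6, 6)


def random_matrix(rng, n_rows, n_cols, p_black=0.4, p_transparent=0.0):
    """Random matrix possibly containing transparent cells."""
    u = rng.random((n_rows, n_cols))
    cells = np.where(u < p_black, BLACK, WHITE)
    if p_transparent:
        cells = np.where(rng.random((n_rows, n_cols)) < p_transparent,
                         TRANSPARENT, cells)
    return BinaryMatrix(cells)
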