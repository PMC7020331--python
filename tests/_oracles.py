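"""Independent naive scanners used as oracles.

Everything here is deliberately written as plain Python loops over nested
lists — no numpy vectorization, no reuse of package internals — so the
oracles stay independent of the implementations they check.
"""

import math

NA = None  # transparent marker in oracle grids


def to_grid(m):
    """BinaryMatrix -> list of lists with 1/0/None cells."""
    out = []
    for row in m.cells.tolist():
        out.append([None if x != x else int(x) for x in row])
    return out


def naive_row_runs(grid, color):
    """Maximal same-color runs per row; transparency breaks runs.
    Returns tuples (row, color_value, start, length)."""
    runs = []
    for i, row in enumerate(grid):
        start = None
        for j, cell in enumerate(row + [NA]):  # sentinel terminates last run
            if cell == color:
                if start is None:
                    start = j
            else:
                if start is not None:
                    runs.append((i, color, start, j - start))
                    start = None
    return runs


def naive_crest_heights(grid):
    """Per column: rows from the bottom edge to the top of the highest
    black cell; 0 when the column has no black cell."""
    n_rows = len(grid)
    n_cols = len(grid[0])
    heights = []
    for j in range(n_cols):
        h = 0
        for i in range(n_rows):
            if grid[i][j] == 1:
                h = n_rows - i
                break
        heights.append(h)
    return heights


def naive_scnp_mean(grid, neighborhood=4):
    """Mean same-color-neighbor proportion over interior cells.

    neighborhood=4 uses orthogonal neighbors, 8 adds diagonals.
    Transparent centers are skipped; transparent neighbors drop out of the
    denominator.
    """
    n_rows = len(grid)
    n_cols = len(grid[0])
    if neighborhood == 4:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offsets = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
                   if (di, dj) != (0, 0)]
    values = []
    for i in range(1, n_rows - 1):
        for j in range(1, n_cols - 1):
            c = grid[i][j]
            if c is NA:
                continue
            same = 0
            valid = 0
            for di, dj in offsets:
                nb = grid[i + di][j + dj]
                if nb is not NA:
                    valid += 1
                    if nb == c:
                        same += 1
            if valid:
                values.append(same / valid)
    if not values:
        raise ValueError("no defined interior cell")
    return sum(values) / len(values)


def naive_light_gap(grid):
    out = []
    for i, row in enumerate(grid):
        width = len(row)
        first = next((j for j, c in enumerate(row) if c == 1), None)
        if first is None:
            out.append((i, width, width, True))
        else:
            last = max(j for j, c in enumerate(row) if c == 1)
            out.append((i, first, width - 1 - last, False))
    return out


def naive_height_proportion(grid, proportion, height_size):
    """Scan rows bottom-up accumulating black counts; height of the top
    edge of the first row reaching the quantile."""
    n_rows = len(grid)
    total = sum(cell == 1 for row in grid for cell in row)
    cum = 0
    for k in range(1, n_rows + 1):  # k rows counted from the bottom
        cum += sum(cell == 1 for cell in grid[n_rows - k])
        if cum / total >= proportion - 1e-12:
            return k / n_rows * height_size
    return height_size
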