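# Methods

This note records the conventions, parameter choices and numerical
decisions behind `bwpattern`, and what the test suite does and does not
establish.

## Image → matrix conversion

A photograph becomes a grid over {black = 1, white = 0, transparent = NA}.
Row 0 is the top image row, column 0 the left one; every height metric
counts whole rows from the bottom edge.

- **Channel and threshold.** The selected channel intensity (red, green,
  blue, or the mean of the three) is normalized by the 8-bit maximum 255.
  A pixel is black iff intensity < `threshold_value` (default 0.5). The
  rule is strict: intensity exactly equal to the threshold is white.
  Grayscale images return the single gray channel for every selector.
  No automatic threshold selection (e.g. Otsu) is attempted; difficult
  light conditions are better handled by thresholding in an image editor
  and feeding the pre-binarized file in.
- **Alpha.** Transparency takes precedence over color. Two rules:
  `paper_text` (default) marks a pixel transparent when alpha >
  threshold — the published description of the method taken literally,
  which inverts standard PNG semantics (alpha = 255 conventionally means
  opaque); `opaque_above` implements the conventional reading
  (transparent when alpha < threshold). Both are first-class because the
  two readings cannot be reconciled; users of editor-exported PNGs will
  normally want `opaque_above`. Images without an alpha channel are fully
  opaque under either rule.
- **Resampling.** Thresholding happens at full resolution first; the
  binary matrix is then reduced by nearest-neighbor lookup (source index =
  floor((i + 0.5)·src/dst)), which keeps cells strictly
  black/white/transparent and is deterministic. Scaled dimensions are
  rounded half away from zero with a floor of one cell. Four sizing
  modes: `proportional` (rate in (0, 1]), `width_fixed`/`height_fixed`
  (aspect-preserving) and `frame_fixed`.

Because the resampling kernel of the original implementation of this
method is not documented, bit-exact agreement with matrices produced by
other software is not guaranteed; comparisons against externally produced
values use tolerances.

## Denseness and height metrics

- Denseness = #black / (#black + #white); transparent cells appear in
  neither numerator nor denominator. Undefined (an error) when every cell
  is transparent. 1 − denseness is the white fraction (openness).
- Row sections are anchored at the top (reading order), column sections at
  the left; the final, possibly short, section is kept. A section with no
  non-transparent cell reports its fraction as missing rather than
  erroring, so batch output stays rectangular.
- The height quantile accumulates black counts from the bottom row and
  reports the height of the **top edge** of the first row at which the
  cumulative fraction reaches the requested proportion:
  (rows from bottom / n_rows) × height_size. Granularity is therefore one
  row height; ties resolve toward the lower height.

## Holes and light gaps

A hole is a maximal same-color run within one row or column. Transparent
cells terminate runs — a hole cannot span a region excluded from analysis.
Section summaries use the sample standard deviation (n − 1); a single run
reports its sd as missing. Per-row light gaps count cells outside the
outermost black pixels; a row with no black pixel reports both distances
as the row width with a `no_black` flag instead of erroring.

## Crest profile

The crest of a column is the top edge of its topmost black cell, in rows
from the bottom; a column with no black cell has crest 0 (ground level)
and still participates in the topline — a gap in vegetation drops the
crest to the soil line. The topline is the Euclidean length of the
polyline through (column center, crest height); in pixel units it is at
least n_cols − 1, with equality iff the crest is flat. Physical units
require both `height_size` and `width_size`; supplying only one is an
error rather than a silent pixel/cm mix. Whether the original
implementation of the topline sums Euclidean segments or counts boundary
steps is not documented; the Euclidean polyline was chosen as the natural
length of the crest curve.

## Aggregation index

- **SCNP.** For each interior cell (marginal rows/columns excluded as
  centers, though marginal cells still count as neighbors) the same-color
  neighbor proportion is computed over the 4 orthogonal neighbors;
  transparent neighbors leave the denominator, transparent centers are
  skipped. The 4-neighborhood is a reverse-engineered constraint, not a
  published statement: on the side-split 6×6 grid an 8-neighbor count
  yields 0.8125 while the published worked value is 0.875, which the
  4-neighbor count reproduces exactly (asserted in the tests).
- **References.** Given the dimensions, black count and transparency
  pattern, the minimal reference fills non-transparent cells in
  chessboard-parity order (even row+column first, row-major within each
  parity class, overflowing into the other class) and the maximal
  reference in plain row-major order. These are constructive archetypes:
  at exactly half density they are provably/exhaustively extremal (the
  suite enumerates all 12 870 half-density 4×4 grids), but for arbitrary
  densities or transparency patterns exact optimality is not claimed, and
  an observed arrangement can in principle fall slightly outside them —
  in which case the adjusted index leaves [0, 1]. A single-color image
  makes the references coincide; the adjusted index is then reported as
  undefined (with the observed mean still returned) rather than dividing
  by zero.
- **Adjusted index.** (observed − min) / (max − min), dimensionless,
  0 = most dispersed, 1 = most aggregated.

## Square ↔ circular remapping

For round subjects the square matrix can be pulled onto its inscribed
disk and back. The mapping preserves angle and rescales radius linearly
so the disk rim corresponds to the square boundary along each direction;
sampling is nearest-neighbor at cell centers, and the grid center is the
continuous point (n/2, n/2) — a cell corner for even n. Compression marks
exactly the cells whose centers fall outside the disk transparent;
stretching fills the corners from rim values and introduces no
transparency of its own (rim samples that discretize onto an
outside-the-disk cell are pulled inward along their ray). The published
description of these maps is one line each, so this precise geometry is
this package's own convention, stated here for reproducibility; the round
trip is not exact (nearest-neighbor discretization), and the suite
quantifies it: ≥ 95 % of disk cells recover their state on a 101×101
half-split grid, and denseness of angularly unbiased patterns is
preserved within 2 % at 201×201. No fisheye lens-projection correction is
applied.

## Synthetic fixtures

Every metric is exercised without photographs. `chessboard` and `halves`
are the extremal aggregation arrangements; `random` draws i.i.d. black
cells at a given density (default 0.5); `silhouette` emulates a
vegetation profile — the first column's crest is uniform over the middle
third of the height and each subsequent crest moves by a uniform step in
{−2, …, 2}, clamped to the frame, black below the crest — chosen so
crest metrics vary at any size; `disk` is a black inscribed disk on a
transparent background (a round subject with erased surroundings). All
generators are bit-reproducible from (kind, dimensions, seed).

What the fixtures do **not** emulate: sensor noise, JPEG artifacts beyond
a round-trip check, uneven illumination, color casts, or the spatial
correlation of real foliage. Passing tests therefore validate the
arithmetic of the metrics and the documented conventions, not the
photographic pipeline; for real photographs the choice of threshold and
editor preprocessing still dominates data quality.

## Problem sizes and determinism

The oracle-equivalence suite checks run-length records and crest heights
on 10 000 seeded random matrices with sides 3–50 (mean SCNP on a fifth of
them) against deliberately naive pure-Python scanners. The
worked-example arrangements with mean SCNP 0.75 and 0.5 are found by a
seeded stochastic hill-climb over black/white swaps (mean SCNP on a 6×6
grid is a multiple of 1/64, so exact hits exist and are found in
milliseconds). Property tests use hypothesis in derandomized mode; all
other randomness flows through explicit numpy `default_rng` seeds.

## Known limitations

- The two alpha conventions cannot both match the original
  implementation; the literal rule is the default, the conventional one a
  flag.
- Agreement with metric values computed by other implementations on real
  photographs depends on their (undocumented) resampling kernel and
  extremal-reference construction, so such comparisons are tolerance-based.
- Hole analysis is strictly per-row/per-column; no 2D connected-component
  labeling is offered.
- 8-bit images only; no EXIF or color-profile correction.
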