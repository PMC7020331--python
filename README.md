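# bwpattern

Structural pattern metrics for black/white photographs of natural
structures — canopy openness, vertical vegetation profiles, bird nest-wall
openness — built around a binary-matrix representation of the image and a
standardized pixel **aggregation index**.

Field ecologists routinely photograph a subject against a contrasting
background (sky behind a canopy, a white cloth panel behind standing
vegetation, a white sphere inside a nest chamber) and want numbers that
describe the structure: how closed it is, how high, how rough its crest
line, how clumped or dispersed its holes are. `bwpattern` turns a PNG/JPEG
photograph into a matrix over three cell states — black `1` (subject),
white `0` (background) and `NA` (transparent: pixels excluded from all
metrics, e.g. an erased background) — and computes those metrics on the
matrix.

## The model

**Binarization.** For each pixel the intensity of the red, green or blue
channel (or their average), normalized to [0, 1], is compared with a
threshold *t* (default 0.5): the pixel is black iff intensity < *t*. In
images with an alpha channel, pixels can instead be marked transparent;
two alpha conventions are provided (see `ThresholdConfig`), because the
method's published description — "alpha above the threshold means
transparent" — inverts standard PNG semantics. Large photographs are
resampled to analysis size *after* thresholding by nearest-neighbor
lookup, keeping the grid strictly binary.

**Denseness and openness.** Denseness = #black / (#black + #white); canopy
openness = 1 − denseness of a canopy photograph. Row/column sections,
run-length ("hole") statistics, per-row light gaps, crest heights, the
topline (Euclidean length of the crest polyline) and the height quantile
(height below which a fraction *p* of the black pixels lies, counted in
whole rows from the bottom edge) follow the conventions established for
vertical vegetation photographs.

**Aggregation index.** For every interior cell, the same-color-neighbor
proportion (SCNP) is the fraction of its 4 orthogonal neighbors sharing
its color (transparent neighbors drop out of the denominator). With mean
observed SCNP s̄ and the means s̄_min, s̄_max of two constructed reference
arrangements with the same size, black count and transparency pattern — a
chessboard-parity fill (most interleaved) and a row-major side-packed fill
(most aggregated) — the adjusted index is

    A = (s̄ − s̄_min) / (s̄_max − s̄_min)

so a chessboard scores 0 and a side-split image scores 1 regardless of
image size. On a 6×6 grid with 18 black cells: chessboard → s̄ = 0,
A = 0; side-split → s̄ = 0.875, A = 1; arrangements with s̄ = 0.75 and
0.5 give A = 0.857 and 0.571.

## Worked example

```python
from bwpattern import (FixtureSpec, make_fixture, denseness_total,
                       height_proportion, topline, aggregation_index)

# a synthetic vegetation silhouette on a 100 cm x 100 cm frame
m = make_fixture(FixtureSpec("silhouette", 100, 100, seed=42))

print(denseness_total(m))                        # 0.4468
print(height_proportion(m, 0.75, height_size=100))  # 34.0
print(topline(m, 100, 100))                      # 160.4812032472894
print(aggregation_index(m).adjusted)             # 0.9935832292906709
```

44.7 % of the frame is vegetation; three quarters of it lies below
34 cm; the crest polyline is 160.5 cm long (a perfectly flat crest would
measure 99 cm, so the crest is rough); and the silhouette is almost
maximally aggregated (index ≈ 0.99), as expected for a solid shape.

The same workflow from the shell:

```sh
bwpattern fixtures make --kind silhouette --rows 100 --cols 100 --seed 42 --out veg.png
bwpattern denseness --input veg.png
bwpattern height --mode proportion --proportion 0.75 --height-size 100 --input veg.png
bwpattern aggregation --input veg.png
```

For a real canopy photograph, openness is
`bwpattern denseness --input canopy.jpg --method proportional --rate 0.1 --complement`.

## Layout

- `src/bwpattern/binarize.py` — image → matrix conversion, resampling, CSV I/O
- `src/bwpattern/density.py` — denseness, sections, height quantile
- `src/bwpattern/holes.py` — run-length analysis, light gaps
- `src/bwpattern/profile.py` — crest heights, altitudinal profile, topline
- `src/bwpattern/aggregation.py` — SCNP, extremal references, adjusted index
- `src/bwpattern/geometry.py` — square ↔ circular remapping
- `src/bwpattern/fixtures.py` — deterministic synthetic patterns, PNG/JPEG rendering
- `src/bwpattern/cli.py` — the `bwpattern` command

See `docs/methods.md` for the full account of conventions, numerical
choices and limitations.
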