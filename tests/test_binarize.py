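import numpy as np
import pytest
from PIL import Image

from bwpattern import (BinaryMatrix, InputFormatError, ParameterError,
                       ResampleSpec, ThresholdConfig, image_information,
                       read_matrix, resample_matrix, threshold_image,
                       threshold_image_list, write_matrix)
from bwpattern.fixtures import chessboard

from .conftest import mat


def save_rgb(path, arr, alpha=None):
    arr = np.asarray(arr, dtype=np.uint8)
    if alpha is not None:
        arr = np.dstack([arr, np.asarray(alpha, dtype=np.uint8)])
        Image.fromarray(arr, "RGBA").save(path)
    else:
        Image.fromarray(arr, "RGB").save(path)


@pytest.fixture
def img_dir(tmp_path):
    return tmp_path


class TestThresholdImage:
    def test_pure_black_and_white(self, img_dir):
        black = img_dir / "black.png"
        white = img_dir / "white.png"
        save_rgb(black, np.zeros((2, 2, 3)))
        save_rgb(white, np.full((2, 2, 3), 255))
        assert threshold_image(black).is_black.all()
        assert threshold_image(white).is_white.all()

    def test_half_split_with_opaque_alpha(self, img_dir):
        rgb = np.empty((4, 8, 3))
        rgb[:, :4] = 10
        rgb[:, 4:] = 245
        p = img_dir / "split.png"
        save_rgb(p, rgb, alpha=np.full((4, 8), 255))
        m = threshold_image(p, ThresholdConfig(alpha_rule="opaque_above"))
        assert m.is_black[:, :4].all()
        assert m.is_white[:, 4:].all()
        assert m.n_transparent == 0

    def test_paper_text_alpha_rule_marks_high_alpha_transparent(self, img_dir):
        # literal published rule: alpha above the threshold -> transparent
        rgb = np.zeros((2, 2, 3))
        alpha = np.array([[255, 0], [0, 255]])
        p = img_dir / "a.png"
        save_rgb(p, rgb, alpha=alpha)
        m = threshold_image(p)  # default alpha_rule="paper_text"
        assert m.is_transparent[0, 0] and m.is_transparent[1, 1]
        assert m.is_black[0, 1] and m.is_black[1, 0]

    def test_opaque_above_rule_is_conventional(self, img_dir):
        rgb = np.zeros((2, 2, 3))
        alpha = np.array([[255, 0], [0, 255]])
        p = img_dir / "a.png"
        save_rgb(p, rgb, alpha=alpha)
        m = threshold_image(p, ThresholdConfig(alpha_rule="opaque_above"))
        assert m.is_black[0, 0] and m.is_black[1, 1]
        assert m.is_transparent[0, 1] and m.is_transparent[1, 0]

    def test_boundary_intensity_equal_to_threshold_is_white(self, img_dir):
        p = img_dir / "g.png"
        save_rgb(p, np.full((1, 1, 3), 128))
        # 128/255 with threshold 128/255: strict < rule -> white
        m = threshold_image(p, ThresholdConfig(threshold_value=128 / 255))
        assert m.is_white.all()

    def test_grayscale_all_channels_agree(self, img_dir):
        p = img_dir / "gray.png"
        Image.fromarray(np.array([[30, 220]], dtype=np.uint8), "L").save(p)
        for ch in ("red", "green", "blue", "rgb_average"):
            m = threshold_image(p, ThresholdConfig(channel=ch))
            assert m.is_black[0, 0] and m.is_white[0, 1]

    def test_single_channel_selection(self, img_dir):
        # pixel that is black on the red channel but white on blue
        p = img_dir / "c.png"
        save_rgb(p, np.array([[[10, 10, 240]]]))
        assert threshold_image(p, ThresholdConfig(channel="red")).is_black.all()
        assert threshold_image(p, ThresholdConfig(channel="blue")).is_white.all()

    def test_invert_flag_swaps_classes(self, img_dir):
        p = img_dir / "b.png"
        save_rgb(p, np.zeros((2, 2, 3)))
        assert threshold_image(p, ThresholdConfig(invert=True)).is_white.all()

    def test_threshold_monotonicity(self, img_dir):
        rng = np.random.default_rng(7)
        p = img_dir / "r.png"
        save_rgb(p, rng.integers(0, 256, size=(16, 16, 3)))
        counts = [threshold_image(p, ThresholdConfig(threshold_value=t)).n_black
                  for t in (0.0, 0.2, 0.5, 0.8, 1.0)]
        assert counts == sorted(counts)
        assert counts[0] == 0  # nothing is strictly below 0

    def test_row_permutation_locality(self, img_dir):
        rng = np.random.default_rng(3)
        arr = rng.integers(0, 256, size=(8, 5, 3))
        perm = rng.permutation(8)
        p1, p2 = img_dir / "x.png", img_dir / "y.png"
        save_rgb(p1, arr)
        save_rgb(p2, arr[perm])
        m1 = threshold_image(p1)
        m2 = threshold_image(p2)
        assert np.array_equal(m1.cells[perm], m2.cells)

    def test_unreadable_file_raises_format_error(self, img_dir):
        p = img_dir / "junk.png"
        p.write_text("this is not an image")
        with pytest.raises(InputFormatError):
            threshold_image(p)


class TestThresholdImageList:
    def test_order_preserved(self, img_dir):
        b, w = img_dir / "b.png", img_dir / "w.png"
        save_rgb(b, np.zeros((2, 2, 3)))
        save_rgb(w, np.full((2, 2, 3), 255))
        ms = threshold_image_list([b, w])
        assert ms[0].is_black.all() and ms[1].is_white.all()

    def test_empty_list_is_an_error(self):
        with pytest.raises(ParameterError):
            threshold_image_list([])

    def test_repeated_file_is_deterministic(self, img_dir):
        p = img_dir / "r.png"
        save_rgb(p, np.random.default_rng(0).integers(0, 256, (6, 6, 3)))
        ms = threshold_image_list([p, p, p])
        assert ms[0] == ms[1] == ms[2]

    def test_fail_fast_names_offending_path(self, img_dir):
        good, bad = img_dir / "g.png", img_dir / "bad.png"
        save_rgb(good, np.zeros((2, 2, 3)))
        bad.write_text("nope")
        with pytest.raises(InputFormatError, match="bad.png"):
            threshold_image_list([good, bad])

    def test_skip_errors_drops_and_reports(self, img_dir):
        good, bad = img_dir / "g.png", img_dir / "bad.png"
        save_rgb(good, np.zeros((2, 2, 3)))
        bad.write_text("nope")
        seen = []
        ms = threshold_image_list([good, bad], skip_errors=True,
                                  on_error=lambda p, e: seen.append(p))
        assert len(ms) == 1 and seen == [bad]


class TestResample:
    def test_proportional_dimensions(self):
        m = BinaryMatrix(np.zeros((2500, 2500)))
        out = resample_matrix(m, ResampleSpec("proportional", compress_rate=0.1))
        assert out.shape == (250, 250)

    def test_rate_one_is_identity(self, chessboard6):
        out = resample_matrix(chessboard6,
                              ResampleSpec("proportional", compress_rate=1.0))
        assert out == chessboard6

    def test_method_none_is_identity(self, chessboard6):
        assert resample_matrix(chessboard6, ResampleSpec()) == chessboard6

    def test_frame_fixed_nearest_neighbor_centers(self):
        src = chessboard(6, 6)
        out = resample_matrix(src, ResampleSpec("frame_fixed", target_width=3,
                                                target_height=3))
        # brute-force nearest source index per target cell
        idx = [int(np.floor((i + 0.5) * 6 / 3)) for i in range(3)]
        expected = src.cells[np.ix_(idx, idx)]
        assert np.array_equal(out.cells, expected)

    def test_width_fixed_preserves_aspect(self):
        m = BinaryMatrix(np.zeros((100, 200)))
        out = resample_matrix(m, ResampleSpec("width_fixed", target_width=50))
        assert out.shape == (25, 50)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ParameterError):
            ResampleSpec("proportional", compress_rate=0.0)
        with pytest.raises(ParameterError):
            ResampleSpec("proportional", compress_rate=1.5)

    def test_tiny_rate_floors_at_one_cell(self):
        m = BinaryMatrix(np.ones((4, 4)))
        out = resample_matrix(m, ResampleSpec("proportional", compress_rate=0.01))
        assert out.shape == (1, 1)


class TestImageInformation:
    def test_chessboard_counts(self, chessboard6):
        info = image_information(chessboard6)
        assert (info.n_black, info.n_white, info.n_transparent) == (18, 18, 0)
        assert info.fraction_black == 0.5

    def test_all_transparent(self):
        info = image_information(mat("--\n--"))
        assert info.fraction_transparent == 1.0

    def test_mixed_fractions(self):
        info = image_information(mat("##.\n...\n..-"))
        assert info.n_black == 2 and info.n_white == 6 and info.n_transparent == 1
        assert info.fraction_black == pytest.approx(2 / 9)
        total = (info.fraction_black + info.fraction_white
                 + info.fraction_transparent)
        assert total == pytest.approx(1.0)


class TestMatrixCsv:
    def test_round_trip_with_transparency(self, tmp_path):
        m = mat("#.-\n-#.\n..#")
        p = tmp_path / "m.csv"
        write_matrix(m, p)
        assert read_matrix(p) == m

    def test_literal_na_token(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("1,0\nNA,1\n")
        m = read_matrix(p)
        assert m.shape == (2, 2)
        assert m.is_transparent[1, 0]

    def test_ragged_rows_rejected_with_position(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("1,0,1\n0,1\n")
        with pytest.raises(InputFormatError, match="row 1"):
            read_matrix(p)

    def test_malformed_token_reports_row_and_column(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("1,0\n0,x\n")
        with pytest.raises(InputFormatError, match="row 1, column 1"):
            read_matrix(p)
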