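import math

import numpy as np
import pytest
from scipy import stats, ndimage

from quack.video_io import VideoStack
from quack.kymogram import (
    Kymogram,
    place_grid,
    make_transect,
    sample_kymogram,
    binarize_kymogram,
    skeletonize_kymogram,
    read_transects_csv,
    write_transects_csv,
)
from quack.kymogram import _yokoi_simple


def make_stack(frames, px=0.1):
    return VideoStack(frames=np.asarray(frames, float), frame_interval_s=1.0,
                      pixel_size_um=px)


def binary_kymo(img):
    return Kymogram(np.asarray(img, bool), "binary", 1.0, 0.1)


class TestPlaceGrid:
    def test_line_spacing_in_pixels(self):
        stack = make_stack(np.zeros((2, 128, 128)))
        grid = place_grid(stack, spacing_um=5.0, seed=0)
        assert grid.spacing_px == 50.0
        xs = np.array(grid.xs)
        assert np.allclose(np.diff(xs), 50.0)
        assert 0 <= grid.offset_px[0] < 50.0

    def test_seeded_offsets_reproducible(self):
        stack = make_stack(np.zeros((2, 64, 64)))
        a = place_grid(stack, 2.0, seed=5)
        b = place_grid(stack, 2.0, seed=5)
        assert a.offset_px == b.offset_px

    def test_offsets_uniform_over_seeds(self):
        stack = make_stack(np.zeros((2, 64, 64)))
        grids = [place_grid(stack, 2.0, seed=s) for s in range(1000)]
        offs = [g.offset_px[0] / 20.0 for g in grids] + [g.offset_px[1] / 20.0 for g in grids]
        assert stats.kstest(offs, "uniform").pvalue > 0.01

    def test_oversized_spacing_rejected(self):
        stack = make_stack(np.zeros((2, 32, 32)))
        with pytest.raises(ValueError):
            place_grid(stack, 100.0, seed=0)


class TestMakeTransect:
    @pytest.mark.parametrize("length_um,expected", [(20.0, 201), (2.0, 21)])
    def test_sample_count_from_length(self, length_um, expected):
        stack = make_stack(np.zeros((2, 64, 260)))
        tr = make_transect((5.0, 30.0), "horizontal", length_um, stack)
        assert tr.n_samples == expected
        p0, p1 = tr.endpoints_um()
        assert np.linalg.norm(p1 - p0) == pytest.approx(length_um)

    def test_exceeding_canvas_rejected(self):
        stack = make_stack(np.zeros((2, 32, 32)))
        with pytest.raises(ValueError, match="canvas"):
            make_transect((30.0, 5.0), "horizontal", 2.0, stack)

    def test_invalid_pixels_rejected(self):
        stack = make_stack(np.zeros((2, 32, 32)))
        stack.valid_mask[:, 16:] = False
        with pytest.raises(ValueError, match="invalid"):
            make_transect((10.0, 5.0), "horizontal", 1.5, stack)

    def test_round_trip_csv(self, tmp_path):
        stack = make_stack(np.zeros((2, 64, 64)))
        trs = [
            make_transect((5.0, 10.0), "horizontal", 3.0, stack, label="a"),
            make_transect((8.0, 5.0), math.radians(45), 2.0, stack, label="b"),
        ]
        path = write_transects_csv(trs, tmp_path / "t.csv")
        back = read_transects_csv(path, stack)
        for orig, got in zip(trs, back):
            assert got.anchor == orig.anchor
            assert got.angle_rad == pytest.approx(orig.angle_rad)
            assert got.length_um == orig.length_um
            assert got.label == orig.label


class TestSampleKymogram:
    def test_static_spot_gives_bright_column(self):
        frames = np.full((6, 32, 32), 10.0)
        frames[:, 16, 10] = 100.0
        stack = make_stack(frames)
        tr = make_transect((5.0, 16.0), "horizontal", 1.0, stack)
        kymo = sample_kymogram(stack, tr)
        assert kymo.values.shape == (6, 11)
        assert np.all(kymo.values[:, 5] == 100.0)  # column at x=10 px
        assert np.all(kymo.values[:, 0] == 10.0)

    def test_moving_spot_gives_diagonal(self):
        frames = np.full((8, 32, 48), 1.0)
        for t in range(8):
            frames[t, 10, 12 + t] = 50.0
        stack = make_stack(frames)
        tr = make_transect((10.0, 10.0), "horizontal", 2.0, stack)
        kymo = sample_kymogram(stack, tr)
        for t in range(8):
            assert kymo.values[t, 2 + t] == 50.0

    def test_integer_lattice_sampling_is_exact(self, gradient_stack):
        tr = make_transect((3.0, 7.0), "horizontal", 2.0, gradient_stack)
        kymo = sample_kymogram(gradient_stack, tr)
        expected = gradient_stack.frames[:, 7, 3:24]
        assert np.allclose(kymo.values, expected)

    def test_frozen_movie_has_identical_rows(self, gradient_stack):
        frozen = gradient_stack.copy_with(
            frames=np.repeat(gradient_stack.frames[:1], 10, axis=0)
        )
        tr = make_transect((2.0, 5.0), math.radians(30), 2.0, frozen)
        kymo = sample_kymogram(frozen, tr)
        assert np.allclose(kymo.values, kymo.values[0])

    def test_sampling_linear_in_intensity(self, gradient_stack):
        tr = make_transect((3.0, 7.0), "horizontal", 2.5, gradient_stack)
        k1 = sample_kymogram(gradient_stack, tr)
        k3 = sample_kymogram(
            gradient_stack.copy_with(frames=3.0 * gradient_stack.frames), tr
        )
        assert np.allclose(k3.values, 3.0 * k1.values)


class TestBinarize:
    def test_otsu_separates_two_levels(self):
        img = np.full((20, 30), 0.2)
        img[5:15, 10:20] = 0.8
        kymo = Kymogram(img, "raw", 1.0, 0.1)
        out = binarize_kymogram(kymo, method="otsu")
        thr = out.provenance["binarize"]["threshold"]
        assert 0.2 < thr < 0.8
        assert np.array_equal(out.values, img > 0.5)

    def test_fixed_threshold_exact_mask(self):
        rng = np.random.default_rng(0)
        img = rng.random((15, 15))
        out = binarize_kymogram(Kymogram(img, "raw", 1.0, 0.1), "fixed", threshold=0.5)
        assert np.array_equal(out.values, img > 0.5)

    def test_constant_kymogram_flagged_empty(self):
        out = binarize_kymogram(Kymogram(np.full((10, 10), 3.0), "raw", 1.0, 0.1))
        assert out.flagged_empty
        assert not out.values.any()
        assert out.provenance["binarize"]["degenerate"]

    def test_synthetic_trace_recall(self, static_filament):
        from quack.video_io import stretch_contrast

        stack, tracks, cfg = static_filament
        noisy = stack.copy_with(
            frames=stack.frames + np.random.default_rng(0).normal(
                0, cfg.amplitude / 10, stack.frames.shape)
        )
        pre = stretch_contrast(noisy)
        tr = make_transect((1.0, 22.0), "horizontal", 10.0, pre)
        out = binarize_kymogram(sample_kymogram(pre, tr))
        true_col = round(6.0 / cfg.pixel_size_um) - 1  # anchor at x=1 px
        recall = out.values[:, true_col].mean()
        assert recall >= 0.9


class TestSkeletonize:
    def test_wide_bar_thins_to_full_height_line(self):
        img = np.zeros((40, 15), bool)
        img[3:37, 6:9] = True
        skel = skeletonize_kymogram(binary_kymo(img)).values
        rows, cols = np.nonzero(skel)
        assert rows.min() == 3 and rows.max() == 36
        # unit width along the bar interior
        for r in range(6, 34):
            assert skel[r].sum() == 1

    def test_solid_disc_collapses(self):
        yy, xx = np.mgrid[0:21, 0:21]
        disc = (yy - 10) ** 2 + (xx - 10) ** 2 <= 49
        skel = skeletonize_kymogram(binary_kymo(disc)).values
        # collapses to a thin extent-preserving cross: a small fraction of
        # the disc area, entirely inside the disc
        assert skel.sum() <= disc.sum() * 0.25
        assert not (skel & ~disc).any()

    def test_component_count_preserved_on_random_blobs(self):
        from skimage.measure import label

        rng = np.random.default_rng(1)
        for _ in range(40):
            img = ndimage.binary_dilation(rng.random((30, 30)) < 0.3)
            skel = skeletonize_kymogram(binary_kymo(img)).values
            assert label(img, connectivity=2).max() == label(skel, connectivity=2).max()
            assert not (skel & ~img).any()  # skeleton within foreground

    def test_residual_2x2_blocks_are_topologically_required(self):
        """Unit width is enforced except where deleting any pixel of a 2x2
        block would change the topology (e.g. an X-crossing of diagonals)."""
        rng = np.random.default_rng(2)
        for _ in range(60):
            img = ndimage.binary_dilation(rng.random((30, 30)) < 0.35)
            skel = skeletonize_kymogram(binary_kymo(img)).values
            padded = np.pad(skel, 1)
            blocks = padded[:-1, :-1] & padded[1:, :-1] & padded[:-1, 1:] & padded[1:, 1:]
            for y, x in zip(*np.nonzero(blocks)):
                for dy, dx in ((0, 0), (0, 1), (1, 0), (1, 1)):
                    py, px = y + dy, x + dx
                    assert not _yokoi_simple(padded[py - 1 : py + 2, px - 1 : px + 2])

    def test_empty_in_empty_out(self):
        out = skeletonize_kymogram(binary_kymo(np.zeros((10, 10))))
        assert not out.values.any()
        assert out.flagged_empty

    def test_oracle_equivalence_on_noise_free_movie(self, static_filament):
        """Rows where the skeleton has foreground near the predicted column
        equal the frames where the ground-truth track crosses the transect."""
        from quack.video_io import stretch_contrast
        from quack.synthetic import oracle_transect_metrics

        stack, tracks, cfg = static_filament
        pre = stretch_contrast(stack)
        tr = make_transect((1.0, 22.0), "horizontal", 10.0, pre)
        skel = skeletonize_kymogram(binarize_kymogram(sample_kymogram(pre, tr)))
        pred_col = round((6.0 - 0.1) / cfg.pixel_size_um)
        window = skel.values[:, pred_col - 1 : pred_col + 2]
        rows_with_trace = set(np.nonzero(window.any(axis=1))[0])
        expected = set(range(cfg.n_frames))  # crosses in every frame
        assert rows_with_trace == expected
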