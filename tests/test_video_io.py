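import math

import numpy as np
import pytest

from quack.video_io import (
    VideoStack,
    MarkerLine,
    load_stack,
    write_stack,
    to_grayscale,
    stretch_contrast,
    rotate_to_axis,
    add_gaussian_noise,
    transform_point,
)
from oracles import rotate_point_oracle


def make_stack(frames, **kw):
    kw.setdefault("frame_interval_s", 1.0)
    kw.setdefault("pixel_size_um", 0.1)
    return VideoStack(frames=np.asarray(frames, dtype=float), **kw)


class TestVideoStack:
    def test_metadata_passthrough(self):
        s = make_stack(np.zeros((120, 16, 16)), frame_interval_s=1.0)
        assert s.n_frames == 120
        assert s.duration_s == 120.0
        assert s.valid_mask.all()

    @pytest.mark.parametrize(
        "frames,interval,px",
        [
            (np.zeros((1, 16, 16)), 1.0, 0.1),   # single frame
            (np.zeros((5, 4, 16)), 1.0, 0.1),    # too small
            (np.zeros((5, 16, 16)), 0.0, 0.1),   # bad interval
            (np.zeros((5, 16, 16)), 1.0, -1.0),  # bad pixel size
        ],
    )
    def test_invalid_inputs_rejected(self, frames, interval, px):
        with pytest.raises(ValueError):
            VideoStack(frames=frames, frame_interval_s=interval, pixel_size_um=px)


class TestLoadWrite:
    def test_round_trip_bit_identical(self, tmp_path):
        rng = np.random.default_rng(0)
        frames = rng.integers(0, 4000, size=(6, 16, 20)).astype(float)
        stack = make_stack(frames)
        write_stack(stack, tmp_path / "s.tif")
        back = load_stack(tmp_path / "s.tif", 0.1, 1.0)
        assert np.array_equal(back.frames, frames)
        assert back.n_frames == 6

    def test_single_frame_file_rejected(self, tmp_path):
        import tifffile

        tifffile.imwrite(tmp_path / "one.tif", np.zeros((16, 16), dtype=np.uint16))
        with pytest.raises(ValueError, match="2 frames"):
            load_stack(tmp_path / "one.tif", 0.1, 1.0)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_stack(tmp_path / "absent.tif", 0.1, 1.0)


class TestGrayscale:
    def test_grayscale_input_unchanged(self, gradient_stack):
        assert to_grayscale(gradient_stack) is gradient_stack

    def test_equal_channels_give_channel_value(self):
        rng = np.random.default_rng(1)
        plane = rng.random((4, 16, 16))
        rgb = np.stack([plane] * 3, axis=-1)
        out = to_grayscale(make_stack(rgb))
        assert np.allclose(out.frames, plane)

    def test_channel_select_exact_plane(self):
        rng = np.random.default_rng(2)
        rgb = rng.random((4, 16, 16, 3))
        out = to_grayscale(make_stack(rgb), channel="G")
        assert np.array_equal(out.frames, rgb[..., 1])

    def test_channel_out_of_range(self):
        rgb = np.zeros((4, 16, 16, 3))
        with pytest.raises(IndexError):
            to_grayscale(make_stack(rgb), channel=5)


class TestStretchContrast:
    def test_linear_map_definition(self):
        frame = np.linspace(10, 200, 16 * 16).reshape(16, 16)
        stack = make_stack(np.stack([frame, frame]))
        out = stretch_contrast(stack, saturation_fraction=0.0)
        expected = (frame - 10) / 190
        assert np.allclose(out.frames[0], expected)

    def test_bleaching_cancelled(self, gradient_stack):
        """Pure multiplicative bleaching of a static scene stretches to
        identical frames."""
        base = gradient_stack.frames[0]
        decays = np.exp(-np.arange(12) / 5.0)
        stack = make_stack(np.stack([base * d for d in decays]))
        out = stretch_contrast(stack, saturation_fraction=0.0)
        for k in range(1, 12):
            assert np.allclose(out.frames[k], out.frames[0], atol=1e-12)

    def test_positive_scaling_invariance(self, gradient_stack):
        a = stretch_contrast(gradient_stack, 0.0)
        b = stretch_contrast(
            gradient_stack.copy_with(frames=gradient_stack.frames * 7.3), 0.0
        )
        assert np.allclose(a.frames, b.frames, atol=1e-12)

    def test_idempotent_at_zero_saturation(self, gradient_stack):
        once = stretch_contrast(gradient_stack, 0.0)
        twice = stretch_contrast(once, 0.0)
        assert np.allclose(once.frames, twice.frames, atol=1e-12)

    def test_constant_frame_flagged(self):
        frames = np.stack([np.full((16, 16), 5.0), np.linspace(0, 1, 256).reshape(16, 16)])
        out = stretch_contrast(make_stack(frames))
        assert np.all(out.frames[0] == 0.0)
        assert out.meta["zero_variance_frames"] == [0]

    def test_saturation_fraction_range_enforced(self, gradient_stack):
        with pytest.raises(ValueError):
            stretch_contrast(gradient_stack, 0.2)


class TestRotateToAxis:
    def test_horizontal_marker_is_identity(self, gradient_stack):
        out = rotate_to_axis(gradient_stack, MarkerLine((2.0, 5.0), (30.0, 5.0)))
        assert np.array_equal(out.frames, gradient_stack.frames)

    def test_vertical_marker_matches_affine_oracle(self):
        rng = np.random.default_rng(3)
        frame = rng.random((20, 30))
        stack = make_stack(np.stack([frame, frame]))
        out = rotate_to_axis(stack, MarkerLine((5.0, 2.0), (5.0, 15.0)))
        # pixel positions must map according to the documented convention
        for p in [(3.0, 4.0), (25.0, 10.0), (0.0, 0.0)]:
            expected = rotate_point_oracle(p, (20, 30), math.pi / 2)
            got = transform_point(p, (20, 30), math.pi / 2)
            assert np.allclose(got, expected, atol=1e-9)
        # a 90 deg rotation swaps height and width
        assert out.shape == (30, 20)
        # values at mapped integer positions match the source
        q = transform_point((7.0, 11.0), (20, 30), math.pi / 2)
        assert out.frames[0, round(q[1]), round(q[0])] == pytest.approx(frame[11, 7], abs=1e-6)

    def test_diagonal_stripe_becomes_horizontal(self):
        h = w = 64
        yy, xx = np.mgrid[0:h, 0:w]
        stripe = np.exp(-((yy - xx) ** 2) / 18.0)  # 45 deg bright stripe
        stack = make_stack(np.stack([stripe, stripe]))
        out = rotate_to_axis(stack, MarkerLine((0.0, 0.0), (10.0, 10.0)))
        img = out.frames[0] * out.valid_mask
        total = img.sum()
        ybar = (np.arange(out.shape[0])[:, None] * img).sum() / total
        xbar = (np.arange(out.shape[1])[None, :] * img).sum() / total
        yy2, xx2 = np.mgrid[0 : out.shape[0], 0 : out.shape[1]]
        mu_yy = ((yy2 - ybar) ** 2 * img).sum()
        mu_xx = ((xx2 - xbar) ** 2 * img).sum()
        mu_xy = ((yy2 - ybar) * (xx2 - xbar) * img).sum()
        angle = 0.5 * math.atan2(2 * mu_xy, mu_xx - mu_yy)
        assert abs(math.degrees(angle)) < 0.5

    def test_inverse_rotation_recovers_valid_region(self, gradient_stack):
        from scipy.ndimage import map_coordinates

        angle = math.atan2(5.0, 10.0)
        fwd = rotate_to_axis(gradient_stack, MarkerLine((0.0, 0.0), (10.0, 5.0)))
        back = rotate_to_axis(fwd, MarkerLine((0.0, 5.0), (10.0, 0.0)))
        h, w = gradient_stack.shape
        ys, xs = np.mgrid[4 : h - 4, 4 : w - 4]
        pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
        # compose the two forward maps to locate each original pixel
        mapped = np.array([
            transform_point(transform_point(p, (h, w), angle), fwd.shape, -angle)
            for p in pts
        ])
        rec = map_coordinates(back.frames[0], [mapped[:, 1], mapped[:, 0]], order=1)
        ref = gradient_stack.frames[0, ys.ravel(), xs.ravel()]
        dyn = ref.max() - ref.min()
        assert np.abs(rec - ref).mean() < 0.02 * dyn

    def test_degenerate_marker_rejected(self):
        with pytest.raises(ValueError):
            MarkerLine((3.0, 3.0), (3.0, 3.0))


class TestAddGaussianNoise:
    def test_zero_sd_identity(self, gradient_stack):
        out = add_gaussian_noise(gradient_stack, 0.0, seed=1)
        assert np.array_equal(out.frames, gradient_stack.frames)

    def test_sample_sd_matches_requested(self):
        stack = make_stack(np.full((8, 400, 400), 30000.0), pixel_size_um=0.1)
        out = add_gaussian_noise(stack, 100.0, seed=2)
        diff = out.frames - stack.frames
        assert diff.size >= 1_000_000
        assert abs(diff.std() - 100.0) < 2.0

    def test_deterministic_in_seed(self, gradient_stack):
        a = add_gaussian_noise(gradient_stack, 50.0, seed=7)
        b = add_gaussian_noise(gradient_stack, 50.0, seed=7)
        c = add_gaussian_noise(gradient_stack, 50.0, seed=8)
        assert np.array_equal(a.frames, b.frames)
        assert not np.array_equal(a.frames, c.frames)

    def test_negative_sd_rejected(self, gradient_stack):
        with pytest.raises(ValueError):
            add_gaussian_noise(gradient_stack, -1.0, seed=0)

    def test_clipped_to_bit_depth(self):
        stack = make_stack(np.full((4, 32, 32), 65500.0))
        out = add_gaussian_noise(stack, 500.0, seed=3)
        assert out.frames.max() <= 65535.0
        assert out.frames.min() >= 0.0
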