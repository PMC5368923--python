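"""Loading, calibration and preconditioning of time-lapse stacks.

A recording enters the pipeline as a :class:`VideoStack`: a T×H×W (or
T×H×W×C before grayscale reduction) intensity raster together with the
physical calibration (seconds per frame, micrometres per pixel) that every
downstream duration/displacement conversion relies on.  Preconditioning
covers grayscale reduction, per-frame histogram stretching (which cancels
global photobleaching), rotation onto a user-placed marker axis, and
controlled Gaussian noise injection for robustness experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
from scipy import ndimage

__all__ = [
    "VideoStack",
    "MarkerLine",
    "load_stack",
    "write_stack",
    "to_grayscale",
    "stretch_contrast",
    "rotate_to_axis",
    "add_gaussian_noise",
]

#: ITU-R BT.601 luma weights used for default RGB -> grayscale reduction.
BT601_WEIGHTS = np.array([0.299, 0.587, 0.114])

_CHANNEL_NAMES = {"R": 0, "G": 1, "B": 2}


@dataclass
class VideoStack:
    """Calibrated time-lapse stack.

    Parameters
    ----------
    frames
        ``(T, H, W)`` grayscale or ``(T, H, W, C)`` multi-channel raster,
        non-negative intensities within the declared bit depth.
    frame_interval_s
        Seconds between consecutive frames (Δt).
    pixel_size_um
        Micrometres per pixel (square pixels assumed).
    valid_mask
        ``(H, W)`` boolean; False marks pixels that carry no real image
        data (e.g. canvas fill introduced by rotation).  Identical across
        frames.
    bit_depth
        Dynamic range of the source data (intensities in
        ``[0, 2**bit_depth - 1]``); preconditioned stacks may instead hold
        floats in ``[0, 1]``.
    meta
        Free-form provenance/flags (e.g. zero-variance frame indices).
    """

    frames: np.ndarray
    frame_interval_s: float
    pixel_size_um: float
    valid_mask: np.ndarray = None  # type: ignore[assignment]
    bit_depth: int = 16
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim not in (3, 4):
            raise ValueError("frames must be (T, H, W) or (T, H, W, C)")
        t, h, w = self.frames.shape[:3]
        if t < 2:
            raise ValueError("need >=2 frames")
        if h < 8 or w < 8:
            raise ValueError("frames must be at least 8x8 pixels")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.valid_mask is None:
            self.valid_mask = np.ones((h, w), dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != (h, w):
                raise ValueError("valid_mask shape must match frame shape")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of a single frame."""
        return self.frames.shape[1:3]

    @property
    def duration_s(self) -> float:
        """Total recorded duration, counting frames inclusively."""
        return self.n_frames * self.frame_interval_s

    def copy_with(self, **kwargs: Any) -> "VideoStack":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class MarkerLine:
    """Visually placed landmark axis, as two image points (x, y) in pixels."""

    p0: tuple[float, float]
    p1: tuple[float, float]

    def __post_init__(self) -> None:
        if tuple(self.p0) == tuple(self.p1):
            raise ValueError("marker line is degenerate (p0 == p1)")

    @property
    def angle_rad(self) -> float:
        """Angle of the marker in image coordinates (x right, y down)."""
        dx = self.p1[0] - self.p0[0]
        dy = self.p1[1] - self.p0[1]
        return math.atan2(dy, dx)


def load_stack(path: str | Path, pixel_size_um: float, frame_interval_s: float) -> VideoStack:
    """Read a multi-page TIFF (or AVI via imageio) as a calibrated stack.

    Calibration must be supplied by the caller: TIFF metadata written by
    acquisition software is too unreliable to trust silently.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        frames = tifffile.imread(str(path))
    else:
        import imageio.v3 as iio

        frames = iio.imread(str(path))
    frames = np.asarray(frames)
    if frames.ndim == 2:
        raise ValueError(f"{path.name}: need >=2 frames, got a single image")
    if frames.ndim not in (3, 4):
        raise ValueError(f"{path.name}: unsupported array shape {frames.shape}")
    if frames.shape[0] < 2:
        raise ValueError(f"{path.name}: need >=2 frames, got {frames.shape[0]}")
    bit_depth = 8 * frames.dtype.itemsize if frames.dtype.kind in "ui" else 16
    return VideoStack(
        frames=frames.astype(np.float64),
        frame_interval_s=frame_interval_s,
        pixel_size_um=pixel_size_um,
        bit_depth=bit_depth,
        meta={"source": str(path)},
    )


def write_stack(stack: VideoStack, path: str | Path, dtype: np.dtype | type = np.uint16) -> Path:
    """Write a stack as a multi-page TIFF for audit, rounding to ``dtype``."""
    import tifffile

    path = Path(path)
    info = np.iinfo(dtype)
    data = np.clip(np.round(stack.frames), info.min, info.max).astype(dtype)
    tifffile.imwrite(str(path), data)
    return path


def to_grayscale(stack: VideoStack, channel: int | str | None = None) -> VideoStack:
    """Reduce a multi-channel stack to a single channel.

    Grayscale input is returned unchanged.  Multi-channel input is either
    reduced with BT.601 luma weights (3-channel, default) or by selecting
    one channel (``channel`` as index or one of ``"R"/"G"/"B"``).
    """
    if stack.frames.ndim == 3:
        return stack
    n_ch = stack.frames.shape[3]
    if channel is not None:
        idx = _CHANNEL_NAMES.get(channel, channel) if isinstance(channel, str) else channel
        if not isinstance(idx, int) or not 0 <= idx < n_ch:
            raise IndexError(f"channel {channel!r} out of range for {n_ch}-channel stack")
        gray = stack.frames[..., idx]
    elif n_ch == 3:
        gray = stack.frames @ BT601_WEIGHTS
    else:
        raise ValueError(
            f"{n_ch}-channel stack needs an explicit channel selection"
        )
    return stack.copy_with(frames=np.ascontiguousarray(gray, dtype=np.float64))


def stretch_contrast(stack: VideoStack, saturation_fraction: float = 0.0035) -> VideoStack:
    """Per-frame linear histogram stretch to the unit interval.

    For each frame independently, the lowest and highest
    ``saturation_fraction / 2`` of valid pixels are clipped and the rest
    mapped linearly onto ``[0, 1]``.  Because the stretch is frame-wise, a
    movie dimming by a global multiplicative factor (photobleaching of a
    static scene) comes out with identical frames.

    Frames with zero intensity variance are returned as all zeros and their
    indices flagged in ``meta["zero_variance_frames"]`` (discard
    candidates).
    """
    if not 0.0 <= saturation_fraction <= 0.05:
        raise ValueError("saturation_fraction must be in [0, 0.05]")
    if stack.frames.ndim != 3:
        raise ValueError("stretch_contrast expects a grayscale stack")
    q_lo = 100.0 * saturation_fraction / 2.0
    vals = stack.frames[:, stack.valid_mask]  # (T, n_valid)
    lo, hi = np.percentile(vals, [q_lo, 100.0 - q_lo], axis=1)
    span = hi - lo
    degenerate = span <= 0
    span[degenerate] = 1.0
    out = np.clip((stack.frames - lo[:, None, None]) / span[:, None, None], 0.0, 1.0)
    out[degenerate] = 0.0
    flagged = np.nonzero(degenerate)[0].tolist()
    meta = dict(stack.meta)
    if flagged:
        meta["zero_variance_frames"] = flagged
    return stack.copy_with(frames=out, meta=meta)


def _rotation_geometry(
    shape: tuple[int, int], angle_rad: float
) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """Forward map q = R(-angle) (p - c) - m and expanded output shape.

    Returns (R_fwd 2x2 acting on (x, y), translation so all corners map to
    non-negative coordinates, output (H, W)).
    """
    h, w = shape
    c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    ca, sa = math.cos(angle_rad), math.sin(angle_rad)
    # R(-angle) in x-right / y-down coordinates
    r_fwd = np.array([[ca, sa], [-sa, ca]])
    corners = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], dtype=float)
    q = (corners - c) @ r_fwd.T
    mn = q.min(axis=0)
    mx = q.max(axis=0)
    out_w = int(math.ceil(mx[0] - mn[0])) + 1
    out_h = int(math.ceil(mx[1] - mn[1])) + 1
    return r_fwd, mn, (out_h, out_w)


def transform_point(
    p: tuple[float, float], shape: tuple[int, int], angle_rad: float
) -> tuple[float, float]:
    """Map an (x, y) image point through the rotation used by rotate_to_axis."""
    h, w = shape
    c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    r_fwd, mn, _ = _rotation_geometry(shape, angle_rad)
    q = r_fwd @ (np.asarray(p, dtype=float) - c) - mn
    return float(q[0]), float(q[1])


def rotate_to_axis(stack: VideoStack, marker: MarkerLine) -> VideoStack:
    """Rotate every frame so the marker line becomes horizontal.

    The canvas is expanded so no valid pixel is cropped; pixels with no
    source data are excluded via ``valid_mask`` (never injected as fake
    zeros).  Bilinear interpolation.
    """
    if stack.frames.ndim != 3:
        raise ValueError("rotate_to_axis expects a grayscale stack")
    angle = marker.angle_rad
    h, w = stack.shape
    if abs(angle) < 1e-12:
        return stack
    r_fwd, mn, (out_h, out_w) = _rotation_geometry((h, w), angle)
    c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    # inverse map for resampling: p = R(angle) (q + mn) + c, in (y, x) index order
    r_inv = r_fwd.T
    a_yx = np.array([[r_inv[1, 1], r_inv[1, 0]], [r_inv[0, 1], r_inv[0, 0]]])
    off_xy = r_inv @ mn + c
    off_yx = np.array([off_xy[1], off_xy[0]])
    frames = np.empty((stack.n_frames, out_h, out_w), dtype=np.float64)
    for t in range(stack.n_frames):
        frames[t] = ndimage.affine_transform(
            stack.frames[t], a_yx, offset=off_yx, output_shape=(out_h, out_w),
            order=1, mode="constant", cval=0.0,
        )
    mask = ndimage.affine_transform(
        stack.valid_mask.astype(np.float64), a_yx, offset=off_yx,
        output_shape=(out_h, out_w), order=1, mode="constant", cval=0.0,
    ) > 0.999
    # sanity: transformed marker must be horizontal
    q0 = transform_point(marker.p0, (h, w), angle)
    q1 = transform_point(marker.p1, (h, w), angle)
    residual = math.degrees(math.atan2(abs(q1[1] - q0[1]), abs(q1[0] - q0[0])))
    if residual > 0.5:
        raise RuntimeError(f"rotation failed to align marker (residual {residual:.3f} deg)")
    meta = dict(stack.meta)
    meta["rotation_rad"] = -angle
    return stack.copy_with(frames=frames, valid_mask=mask, meta=meta)


def add_gaussian_noise(stack: VideoStack, sd: float, seed: int) -> VideoStack:
    """Add i.i.d. zero-mean Gaussian noise (source-intensity units).

    Values are clipped to the stack's declared bit-depth range.
    Deterministic given ``seed``.
    """
    if sd < 0:
        raise ValueError("noise sd must be non-negative")
    if sd == 0:
        return stack
    rng = np.random.default_rng(seed)
    top = float(2 ** stack.bit_depth - 1)
    noisy = stack.frames + rng.normal(0.0, sd, size=stack.frames.shape)
    return stack.copy_with(frames=np.clip(noisy, 0.0, top))
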