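"""Grids, transects and kymograms.

A kymogram is the 2-D projection of a movie along a fixed straight
transect: row ``t`` holds the bilinearly interpolated intensities of frame
``t`` at equally spaced positions along the segment.  Static structures
crossing the transect draw vertical traces, laterally moving ones slanted
traces; binarization and thinning reduce each trace to a unit-width
skeleton whose bounding box carries the lifetime/mobility information.

Array convention: row 0 is the first frame.  Published kymograph figures
often draw time upward; that flip is a display concern only.
Image coordinates are (x = column, y = row), origin top-left, 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Literal

import numpy as np
import pandas as pd
from scipy import ndimage

from .video_io import VideoStack

__all__ = [
    "Grid",
    "Transect",
    "Kymogram",
    "place_grid",
    "make_transect",
    "sample_kymogram",
    "binarize_kymogram",
    "skeletonize_kymogram",
    "read_transects_csv",
    "write_transects_csv",
]

_ORIENT_ALIASES = {"horizontal": 0.0, "vertical": math.pi / 2}


@dataclass(frozen=True)
class Grid:
    """Randomly offset axis-aligned overlay grid (placement aid)."""

    spacing_um: float
    spacing_px: float
    offset_px: tuple[float, float]  # (x, y), each in [0, spacing_px)
    xs: tuple[float, ...]  # vertical line abscissae
    ys: tuple[float, ...]  # horizontal line ordinates

    def anchors(self) -> list[tuple[float, float]]:
        """Grid intersections, usable as suggested transect anchors."""
        return [(x, y) for y in self.ys for x in self.xs]


@dataclass(frozen=True)
class Transect:
    """Straight sampling segment of exact physical length.

    ``anchor`` is the starting endpoint in pixels; the segment extends by
    ``length_um`` at ``angle_rad`` (0 = horizontal, +π/2 = downward).
    """

    anchor: tuple[float, float]
    angle_rad: float
    length_um: float
    pixel_size_um: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.length_um <= 0:
            raise ValueError("length_um must be positive")

    @property
    def n_samples(self) -> int:
        """Sample count: one per pixel-size step, endpoints inclusive."""
        return int(round(self.length_um / self.pixel_size_um)) + 1

    @property
    def length_px(self) -> float:
        return self.length_um / self.pixel_size_um

    def sample_points_px(self) -> np.ndarray:
        """(P, 2) array of (x, y) sample positions in pixels."""
        p = self.n_samples
        s = np.linspace(0.0, self.length_px, p)
        ux, uy = math.cos(self.angle_rad), math.sin(self.angle_rad)
        x0, y0 = self.anchor
        return np.column_stack([x0 + s * ux, y0 + s * uy])

    def endpoints_um(self) -> tuple[np.ndarray, np.ndarray]:
        pts = self.sample_points_px()
        return pts[0] * self.pixel_size_um, pts[-1] * self.pixel_size_um


@dataclass
class Kymogram:
    """T×P raster sampled along one transect (raw, binary or skeleton)."""

    values: np.ndarray
    variant: Literal["raw", "binary", "skeleton"]
    frame_interval_s: float
    pixel_size_um: float
    provenance: dict[str, Any] = field(default_factory=dict)
    flagged_empty: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("kymogram must be 2-D (time x position)")
        if self.variant in ("binary", "skeleton"):
            self.values = self.values.astype(bool)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_positions(self) -> int:
        return self.values.shape[1]


def place_grid(stack: VideoStack, spacing_um: float, seed: int) -> Grid:
    """Overlay grid with seeded uniform random offset in [0, spacing)."""
    spacing_px = spacing_um / stack.pixel_size_um
    if spacing_px < 2:
        raise ValueError("grid spacing below 2 px is meaningless")
    h, w = stack.shape
    if spacing_px > max(h, w):
        raise ValueError("grid spacing exceeds the image")
    rng = np.random.default_rng(seed)
    ox, oy = rng.uniform(0.0, spacing_px, size=2)
    xs = tuple(np.arange(ox, w, spacing_px))
    ys = tuple(np.arange(oy, h, spacing_px))
    return Grid(spacing_um=spacing_um, spacing_px=spacing_px, offset_px=(ox, oy), xs=xs, ys=ys)


def make_transect(
    anchor: tuple[float, float],
    orientation: float | str,
    length_um: float,
    stack: VideoStack,
    label: str = "",
) -> Transect:
    """Create a transect, rejecting segments that leave the valid region.

    ``orientation`` is an angle in radians or ``"horizontal"``/``"vertical"``.
    The full segment (every sample point) must lie inside ``valid_mask`` —
    the analyst's guarantee that kymogram columns are read from real,
    in-focus pixels.
    """
    angle = _ORIENT_ALIASES.get(orientation, orientation) if isinstance(orientation, str) else float(orientation)
    tr = Transect(anchor=tuple(anchor), angle_rad=float(angle), length_um=length_um,
                  pixel_size_um=stack.pixel_size_um, label=label)
    pts = tr.sample_points_px()
    h, w = stack.shape
    if (pts[:, 0].min() < -0.5 or pts[:, 0].max() > w - 0.5
            or pts[:, 1].min() < -0.5 or pts[:, 1].max() > h - 0.5):
        raise ValueError(
            f"transect {label or anchor} leaves the image canvas "
            f"({length_um} um from {anchor})"
        )
    cols = np.clip(np.round(pts[:, 0]).astype(int), 0, w - 1)
    rows = np.clip(np.round(pts[:, 1]).astype(int), 0, h - 1)
    if not stack.valid_mask[rows, cols].all():
        raise ValueError(f"transect {label or anchor} touches invalid pixels")
    return tr


def sample_kymogram(stack: VideoStack, transect: Transect) -> Kymogram:
    """Sample the raw kymogram: row t = frame t read along the transect.

    Bilinear interpolation; sampling is exact at integer pixel positions.
    """
    if stack.frames.ndim != 3:
        raise ValueError("sample_kymogram expects a grayscale stack")
    if abs(transect.pixel_size_um - stack.pixel_size_um) > 1e-12:
        raise ValueError("transect and stack pixel size disagree")
    pts = transect.sample_points_px()
    p = pts.shape[0]
    t_idx = np.repeat(np.arange(stack.n_frames, dtype=np.float64), p)
    yy = np.tile(pts[:, 1], stack.n_frames)
    xx = np.tile(pts[:, 0], stack.n_frames)
    vals = ndimage.map_coordinates(stack.frames, np.stack([t_idx, yy, xx]), order=1)
    return Kymogram(
        values=vals.reshape(stack.n_frames, p),
        variant="raw",
        frame_interval_s=stack.frame_interval_s,
        pixel_size_um=stack.pixel_size_um,
        provenance={"transect": transect, "stack_meta": dict(stack.meta)},
    )


def binarize_kymogram(
    kymo: Kymogram,
    method: Literal["otsu", "fixed", "adaptive"] = "otsu",
    threshold: float | None = None,
    window: int = 15,
) -> Kymogram:
    """Threshold a raw kymogram to a binary one.

    ``otsu`` (default) picks the threshold per kymogram; ``fixed`` uses the
    given absolute threshold; ``adaptive`` uses a local-mean threshold over
    ``window`` pixels.  A constant kymogram cannot be thresholded and is
    returned as a flagged empty binary (discard candidate), mirroring the
    policy of flagging rather than silently dropping degenerate data.
    """
    if kymo.variant != "raw":
        raise ValueError("binarize_kymogram expects a raw kymogram")
    vals = np.asarray(kymo.values, dtype=np.float64)
    prov = dict(kymo.provenance)
    if np.ptp(vals) == 0:
        prov["binarize"] = {"method": method, "threshold": None, "degenerate": True}
        return Kymogram(np.zeros_like(vals, dtype=bool), "binary", kymo.frame_interval_s,
                        kymo.pixel_size_um, prov, flagged_empty=True)
    if method == "otsu":
        from skimage.filters import threshold_otsu

        thr = float(threshold_otsu(vals))
        fg = vals > thr
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed method needs a threshold")
        thr = float(threshold)
        fg = vals > thr
    elif method == "adaptive":
        from skimage.filters import threshold_local

        if window % 2 == 0:
            window += 1
        loc = threshold_local(vals, block_size=window)
        thr = float("nan")
        fg = vals > loc
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    prov["binarize"] = {"method": method, "threshold": thr}
    return Kymogram(fg, "binary", kymo.frame_interval_s, kymo.pixel_size_um, prov,
                    flagged_empty=not fg.any())


def _yokoi_simple(nb: np.ndarray) -> bool:
    """Yokoi connectivity number == 1 for the 8 neighbours of a pixel
    (N, NE, E, SE, S, SW, W, NW order): deleting the pixel then preserves
    local topology under 8-connected foreground."""
    x = [nb[1, 2], nb[0, 2], nb[0, 1], nb[0, 0], nb[1, 0], nb[2, 0], nb[2, 1], nb[2, 2]]
    xb = [1 - int(v) for v in x]
    c = 0
    for k in (0, 2, 4, 6):
        c += xb[k] - xb[k] * xb[(k + 1) % 8] * xb[(k + 2) % 8]
    return c == 1


def _resolve_2x2_blocks(skel: np.ndarray) -> np.ndarray:
    """Remove one simple pixel from every remaining 2×2 foreground block.

    Thinning algorithms can leave 2×2 blocks at diagonal crossings; each is
    resolved by deleting a pixel whose removal provably keeps the local
    topology.  Blocks with no simple pixel (true minimal rings) are left.
    """
    skel = skel.copy()
    padded = np.pad(skel, 1)
    for _ in range(4):
        blocks = padded[:-1, :-1] & padded[1:, :-1] & padded[:-1, 1:] & padded[1:, 1:]
        ys, xs = np.nonzero(blocks)
        if ys.size == 0:
            break
        changed = False
        for y, x in zip(ys, xs):
            if not (padded[y, x] & padded[y + 1, x] & padded[y, x + 1] & padded[y + 1, x + 1]):
                continue  # already resolved by an earlier deletion
            for dy, dx in ((0, 0), (0, 1), (1, 0), (1, 1)):
                py, px = y + dy, x + dx
                if 1 <= py < padded.shape[0] - 1 and 1 <= px < padded.shape[1] - 1:
                    if _yokoi_simple(padded[py - 1 : py + 2, px - 1 : px + 2]):
                        padded[py, px] = False
                        changed = True
                        break
        if not changed:
            break
    return padded[1:-1, 1:-1]


_LUT_CACHE: dict[str, np.ndarray] = {}


def _neighborhood_luts() -> tuple[np.ndarray, np.ndarray]:
    """512-entry lookup tables over 3×3 binary neighborhoods.

    Bit layout is row-major with the centre at bit 4.  ``removable[idx]``
    is True when the centre is foreground, has at least 3 foreground
    pixels in its neighbourhood, and deleting it leaves the number of
    8-connected components of the neighbourhood unchanged (a topologically
    safe deletion that can never erode a trace end).  ``nbg[idx]`` counts
    background pixels (cornerness: cornery pixels are processed last).
    """
    if "removable" not in _LUT_CACHE:
        eight = np.ones((3, 3), dtype=int)
        removable = np.zeros(512, dtype=bool)
        nbg = np.zeros(512, dtype=np.int64)
        for idx in range(512):
            pat = np.array([(idx >> k) & 1 for k in range(9)], dtype=bool).reshape(3, 3)
            nbg[idx] = 9 - pat.sum()
            if not pat[1, 1] or pat.sum() < 3:
                continue
            without = pat.copy()
            without[1, 1] = False
            removable[idx] = (
                ndimage.label(pat, structure=eight)[1]
                == ndimage.label(without, structure=eight)[1]
            )
        _LUT_CACHE["removable"] = removable
        _LUT_CACHE["nbg"] = nbg
    return _LUT_CACHE["removable"], _LUT_CACHE["nbg"]


def _extent_preserving_thin(img: np.ndarray) -> np.ndarray:
    """Medial-axis-style thinning that keeps trace ends and corners.

    Foreground pixels are visited in order of increasing distance to the
    background (ties: least cornery first, then scan order) and deleted
    when the deletion is topologically safe and the pixel is not a trace
    end.  Because end pixels (< 3 neighbours) are never deleted, the
    bounding box of every trace — its temporal and spatial extent, the
    quantities measured downstream — is preserved exactly.
    """
    if not img.any():
        return img.copy()
    removable, nbg = _neighborhood_luts()
    dist = ndimage.distance_transform_edt(img)
    n_fg_neigh = ndimage.convolve(img.astype(np.uint8), np.ones((3, 3), np.uint8),
                                  mode="constant")
    ys, xs = np.nonzero(img)
    order = np.lexsort((xs, ys, (9 - n_fg_neigh)[ys, xs], dist[ys, xs]))
    res = np.pad(img, 1).astype(np.uint8)
    oy = ys + 1
    ox = xs + 1
    weights = (2 ** np.arange(9)).reshape(3, 3).astype(np.uint16)
    for k in order:
        y, x = oy[k], ox[k]
        idx = int((res[y - 1 : y + 2, x - 1 : x + 2] * weights).sum())
        if removable[idx]:
            res[y, x] = 0
    return res[1:-1, 1:-1].astype(bool)


def skeletonize_kymogram(binary: Kymogram) -> Kymogram:
    """Thin the binary kymogram to unit-width, topology-preserving traces.

    Extent-preserving medial-axis thinning (which keeps the full
    spatial/temporal extent of each trace, including its corners) followed
    by hit-or-miss thinning to unit width; residual 2×2 blocks at diagonal
    crossings are resolved by simple-point deletion where that keeps the
    topology (blocks that cannot be resolved without changing topology —
    X-crossings, minimal rings around holes — are left intact).  The
    skeleton is a subset of the input foreground and connected components
    correspond one-to-one.
    """
    if binary.variant != "binary":
        raise ValueError("skeletonize_kymogram expects a binary kymogram")
    from skimage.morphology import thin

    img = np.asarray(binary.values, dtype=bool)
    skel = _resolve_2x2_blocks(thin(_extent_preserving_thin(img)))
    return Kymogram(skel, "skeleton", binary.frame_interval_s, binary.pixel_size_um,
                    dict(binary.provenance), flagged_empty=not skel.any())


def write_transects_csv(transects: list[Transect], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {
                "anchor_x": t.anchor[0],
                "anchor_y": t.anchor[1],
                "angle_deg": math.degrees(t.angle_rad),
                "length_um": t.length_um,
                "label": t.label,
            }
            for t in transects
        ]
    ).to_csv(path, index=False)
    return path


def read_transects_csv(path: str | Path, stack: VideoStack) -> list[Transect]:
    """Load transect definitions and validate them against a stack."""
    df = pd.read_csv(path, keep_default_na=False)
    return [
        make_transect(
            (float(r["anchor_x"]), float(r["anchor_y"])),
            math.radians(float(r["angle_deg"])),
            float(r["length_um"]),
            stack,
            label=str(r.get("label", "")),
        )
        for _, r in df.iterrows()
    ]
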