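"""Image-to-image correlation comparator.

Pearson correlation of frame pairs as a function of the time lag between
them: a static scene stays at r = 1 at every lag, and the faster the
overall structural rearrangement, the faster the mean correlation decays.
This is an orthogonal, whole-frame measure of dynamics that complements the
per-transect kymogram metrics.  When the signal fades into the noise
(e.g. from strong photobleaching) the curve flattens at a floor value and
the assay becomes non-informative from that lag on; the curve flags this
plateau.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .video_io import VideoStack

__all__ = ["CorrelationCurve", "frame_pair_correlation", "correlation_curve"]


@dataclass
class CorrelationCurve:
    """Mean (± SD) frame-pair Pearson correlation per time lag."""

    lags_s: np.ndarray
    mean_r: np.ndarray
    sd_r: np.ndarray
    n_pairs: np.ndarray
    floor_lag_s: float | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lag_s": self.lags_s, "mean_r": self.mean_r,
             "sd_r": self.sd_r, "n_pairs": self.n_pairs}
        )

    def plot(self, ax=None, **kwargs):
        """Plot mean r vs lag with a ±SD band; marks the plateau if any."""
        if ax is None:
            import matplotlib

            matplotlib.use("Agg", force=False)
            import matplotlib.pyplot as plt

            _, ax = plt.subplots()
        (line,) = ax.plot(self.lags_s, self.mean_r, **kwargs)
        ax.fill_between(self.lags_s, self.mean_r - self.sd_r, self.mean_r + self.sd_r,
                        alpha=0.2, color=line.get_color())
        if self.floor_lag_s is not None:
            ax.axvline(self.floor_lag_s, ls="--", color="gray")
        ax.set_xlabel("lag (s)")
        ax.set_ylabel("mean frame-pair correlation r")
        return ax


def frame_pair_correlation(
    frame_a: np.ndarray, frame_b: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Pearson correlation of two frames over the valid pixels.

    Returns NaN (reported as missing) when either frame has zero variance
    over the mask.
    """
    a = np.asarray(frame_a, dtype=np.float64)
    b = np.asarray(frame_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("frames must share a shape")
    if mask is not None:
        a = a[mask]
        b = b[mask]
    else:
        a = a.ravel()
        b = b.ravel()
    if a.size < 2:
        raise ValueError("need at least 2 valid pixels")
    a = a - a.mean()
    b = b - b.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return float("nan")
    return float(np.clip((a @ b) / (na * nb), -1.0, 1.0))


def correlation_curve(
    stack: VideoStack,
    max_lag_s: float | None = None,
    mode: Literal["all_pairs", "anchored"] = "all_pairs",
    plateau_window: int = 10,
    plateau_slope_tol: float = 1e-4,
    roi: tuple[slice, slice] | None = None,
) -> CorrelationCurve:
    """Correlation-decay curve of a recording.

    For each lag (one frame interval up to ``max_lag_s``) the Pearson r of
    every frame pair at that lag is computed over the valid mask (or a
    rectangular ``roi``) and summarized by mean and SD.  ``all_pairs``
    (default) uses all T − k pairs per lag; ``anchored`` only pairs with
    frame 0, for comparison with protocols that measure against the first
    frame.

    The non-informative floor is detected by least-squares slopes over a
    trailing window of ``plateau_window`` lags: ``floor_lag_s`` is the
    earliest lag from which every subsequent window stays flatter than
    ``plateau_slope_tol`` (in r per second).
    """
    if stack.frames.ndim != 3:
        raise ValueError("correlation_curve expects a grayscale stack")
    dt = stack.frame_interval_s
    t = stack.n_frames
    if max_lag_s is None:
        max_lag_s = (t - 1) * dt
    max_lag = int(round(max_lag_s / dt))
    if not 1 <= max_lag <= t - 1:
        raise ValueError("max_lag_s must be within the recording length")
    mask = stack.valid_mask if roi is None else np.zeros_like(stack.valid_mask)
    if roi is not None:
        mask[roi] = stack.valid_mask[roi]
    flat = stack.frames[:, mask].astype(np.float64)
    flat -= flat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(flat, axis=1)
    ok = norms > 0
    unit = np.zeros_like(flat)
    unit[ok] = flat[ok] / norms[ok, None]
    gram = unit @ unit.T
    lags = np.arange(1, max_lag + 1)
    mean_r = np.full(max_lag, np.nan)
    sd_r = np.full(max_lag, np.nan)
    n_pairs = np.zeros(max_lag, dtype=int)
    for i, k in enumerate(lags):
        if mode == "all_pairs":
            ii = np.arange(t - k)
            jj = ii + k
        else:
            ii = np.array([0])
            jj = np.array([k])
        good = ok[ii] & ok[jj]
        rs = gram[ii[good], jj[good]]
        n_pairs[i] = rs.size
        if rs.size:
            mean_r[i] = rs.mean()
            sd_r[i] = rs.std(ddof=0)
    lags_s = lags * dt
    floor = _detect_plateau(lags_s, mean_r, plateau_window, plateau_slope_tol)
    return CorrelationCurve(lags_s=lags_s, mean_r=mean_r, sd_r=sd_r,
                            n_pairs=n_pairs, floor_lag_s=floor)


def _detect_plateau(
    lags_s: np.ndarray, mean_r: np.ndarray, window: int, slope_tol: float
) -> float | None:
    n = len(lags_s)
    if n < window:
        return None
    flat = np.zeros(n - window + 1, dtype=bool)
    for i in range(n - window + 1):
        x = lags_s[i : i + window]
        y = mean_r[i : i + window]
        good = np.isfinite(y)
        if good.sum() < 3:
            continue
        slope = np.polyfit(x[good], y[good], 1)[0]
        flat[i] = abs(slope) < slope_tol
    # earliest start from which every trailing window is flat
    for i in range(len(flat)):
        if flat[i:].all():
            return float(lags_s[i])
    return None
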