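"""Skeleton trace measurement.

Automates the per-kymogram measurements that are done by hand in the
original protocol: the vertical (time-axis) extent of the longest trace is
the longest event duration — a proxy for structure lifetime/stability —
and the horizontal (space-axis) extent of the widest trace is the maximum
lateral displacement — a proxy for lateral mobility.  The two maxima are
taken over connected components independently: the longest and the widest
trace need not be the same structure.

Sign conventions are deliberate and asymmetric: duration counts rows
inclusively (+1), so a structure visible in exactly one frame scores one
frame interval and a full-height trace scores exactly the recording
duration; displacement counts the column span exclusively, so a perfectly
vertical trace (a static structure) scores zero movement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Literal, Sequence

import numpy as np

from .kymogram import Kymogram

__all__ = [
    "TraceComponent",
    "MeasurementRecord",
    "QualityThresholds",
    "label_components",
    "longest_event_duration",
    "max_lateral_displacement",
    "measure_kymogram",
    "advise_transect_size",
    "TransectSizeAdvisory",
]


@dataclass(frozen=True)
class TraceComponent:
    """One 8-connected skeleton trace with its bounding box."""

    rows: np.ndarray
    cols: np.ndarray
    row_min: int
    row_max: int
    col_min: int
    col_max: int
    size: int

    @property
    def row_span(self) -> int:
        """Number of frames covered (inclusive)."""
        return self.row_max - self.row_min + 1

    @property
    def col_span(self) -> int:
        """Lateral pixel travel (exclusive span)."""
        return self.col_max - self.col_min


@dataclass
class QualityThresholds:
    """Calibration defaults for the visual quality classes.

    ``meshwork``: a single trace covering nearly the whole kymogram in both
    axes (saturated, uninterpretable measurement).  ``fragmented``: many
    short traces with none spanning a meaningful fraction of the recording
    (noise indicator).  The classes are defined visually in the original
    protocol; these cutoffs are exposed configuration, not claims.
    """

    meshwork_row_frac: float = 0.9
    meshwork_col_frac: float = 0.9
    fragmented_max_row_frac: float = 0.1
    fragmented_min_components: int = 10


@dataclass
class MeasurementRecord:
    """Per-kymogram result row (the input contract for the statistics)."""

    longest_event_duration_s: float
    max_lateral_displacement_um: float
    n_traces: int
    extreme_low: bool
    extreme_high: bool
    quality: Literal["distinct", "meshwork", "fragmented", "empty"]
    provenance: dict[str, Any] = field(default_factory=dict)

    @property
    def extreme(self) -> bool:
        return self.extreme_low or self.extreme_high


def label_components(skeleton: Kymogram) -> list[TraceComponent]:
    """All 8-connected foreground components, ordered by (row_min, col_min)."""
    if skeleton.variant != "skeleton":
        raise ValueError("label_components expects a skeleton kymogram")
    from skimage.measure import label, regionprops

    lab = label(np.asarray(skeleton.values, dtype=bool), connectivity=2)
    comps = []
    for rp in regionprops(lab):
        rows = rp.coords[:, 0]
        cols = rp.coords[:, 1]
        comps.append(
            TraceComponent(
                rows=rows, cols=cols,
                row_min=int(rows.min()), row_max=int(rows.max()),
                col_min=int(cols.min()), col_max=int(cols.max()),
                size=int(rp.area),
            )
        )
    comps.sort(key=lambda c: (c.row_min, c.col_min))
    return comps


def longest_event_duration(components: Sequence[TraceComponent], frame_interval_s: float) -> float:
    """Max inclusive row span over traces, in seconds (0 if empty)."""
    if not components:
        return 0.0
    return max(c.row_span for c in components) * frame_interval_s


def max_lateral_displacement(components: Sequence[TraceComponent], pixel_size_um: float) -> float:
    """Max exclusive column span over traces, in micrometres (0 if empty)."""
    if not components:
        return 0.0
    return max(c.col_span for c in components) * pixel_size_um


def measure_kymogram(
    skeleton: Kymogram,
    thresholds: QualityThresholds | None = None,
    provenance: dict[str, Any] | None = None,
) -> MeasurementRecord:
    """Measure one skeletonized kymogram.

    Flags extremes the way the transect-size calibration needs them:
    ``extreme_low`` when the longest event lasts at most two frames (or the
    kymogram is empty), ``extreme_high`` when it saturates the full
    recording length — both situations where the measurement carries little
    information.
    """
    th = thresholds or QualityThresholds()
    comps = label_components(skeleton)
    dt = skeleton.frame_interval_s
    n_rows = skeleton.n_frames
    n_cols = skeleton.n_positions
    duration = longest_event_duration(comps, dt)
    displacement = max_lateral_displacement(comps, skeleton.pixel_size_um)
    if not comps:
        quality = "empty"
    elif any(
        c.row_span >= th.meshwork_row_frac * n_rows
        and (c.col_span + 1) >= th.meshwork_col_frac * n_cols
        for c in comps
    ):
        quality = "meshwork"
    elif (
        len(comps) >= th.fragmented_min_components
        and all(c.row_span <= th.fragmented_max_row_frac * n_rows for c in comps)
    ):
        quality = "fragmented"
    else:
        quality = "distinct"
    return MeasurementRecord(
        longest_event_duration_s=duration,
        max_lateral_displacement_um=displacement,
        n_traces=len(comps),
        extreme_low=duration <= 2 * dt,
        extreme_high=duration >= n_rows * dt,
        quality=quality,
        provenance=provenance or dict(skeleton.provenance),
    )


@dataclass(frozen=True)
class TransectSizeAdvisory:
    extreme_fraction: float
    n_records: int
    verdict: Literal["ok", "suboptimal", "reject"]


def advise_transect_size(records: Sequence[MeasurementRecord]) -> TransectSizeAdvisory:
    """Judge a transect-size setting from its measurement records.

    A setting is rejected when two-thirds or more of the kymograms hit an
    extreme (floor or full-recording ceiling) value, accepted when at least
    half are non-extreme, and flagged sub-optimal in between.  Fewer than 4
    records (the recommended minimum per recording) triggers a warning but
    still yields a verdict.
    """
    if not records:
        raise ValueError("advise_transect_size needs at least one record")
    if len(records) < 4:
        warnings.warn(
            f"only {len(records)} records; at least 4 transects per recording "
            "are recommended for a reliable advisory",
            stacklevel=2,
        )
    extreme_fraction = float(np.mean([r.extreme for r in records]))
    if extreme_fraction >= 2.0 / 3.0:
        verdict = "reject"
    elif 1.0 - extreme_fraction >= 0.5:
        verdict = "ok"
    else:
        verdict = "suboptimal"
    return TransectSizeAdvisory(extreme_fraction, len(records), verdict)
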