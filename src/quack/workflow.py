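"""End-to-end orchestration: the full kymogram-quantification run and the
supporting experiments (noise robustness, transect-size calibration,
anisotropy comparison).

The pipeline order is fixed: grayscale → per-frame contrast stretch →
(optional rotation onto a marker axis) → random grid → kymogram sampling
along transects → binarization → skeletonization → trace measurement →
nonparametric statistics.  Every automated choice (thresholds, seeds, grid
offsets) is logged into the audit bundle so a run can be re-derived without
the original stacks.  Quality flags surface discard candidates, but
discarding a recording remains a human decision — nothing is dropped
automatically.

Seeds: one master seed per run; per-stage/per-recording sub-seeds are
derived with ``derive_seed`` (CRC-32 mix of the master seed and stage
keys), so adding a recording never shifts the seeds of the others.
"""

from __future__ import annotations

import json
import math
import warnings
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .video_io import (
    VideoStack,
    MarkerLine,
    load_stack,
    to_grayscale,
    stretch_contrast,
    rotate_to_axis,
    add_gaussian_noise,
)
from .kymogram import (
    place_grid,
    make_transect,
    sample_kymogram,
    binarize_kymogram,
    skeletonize_kymogram,
)
from .trace_metrics import (
    MeasurementRecord,
    QualityThresholds,
    measure_kymogram,
    advise_transect_size,
)
from .stats_report import GroupedMeasurements, ComparisonReport, compare_groups

__all__ = [
    "TransectSpec",
    "RunConfig",
    "StageError",
    "QuackResult",
    "derive_seed",
    "run_quack",
    "run_transect_sweep",
    "run_noise_experiment",
    "run_anisotropy_study",
]

METRICS = {
    "duration_s": "longest event duration (s)",
    "displacement_um": "max lateral displacement (um)",
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and recording id."""

    def __init__(self, stage: str, recording_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for recording {recording_id!r}: {cause}")
        self.stage = stage
        self.recording_id = recording_id
        self.cause = cause


def derive_seed(master: int, *keys: str | int) -> int:
    """Deterministic sub-seed below 2**31 from a master seed and stage keys."""
    h = zlib.crc32(str(int(master)).encode())
    for k in keys:
        h = zlib.crc32(str(k).encode(), h)
    return h & 0x7FFFFFFF


@dataclass
class TransectSpec:
    """Placement request for one transect (validated against the stack)."""

    anchor: tuple[float, float]
    orientation: float | str
    length_um: float
    label: str = ""
    direction_label: str = ""


@dataclass
class RunConfig:
    """Configuration of a full run.

    ``stacks`` maps recording id -> VideoStack or path; paths are loaded
    with the shared calibration below.  Transect placement is user-driven:
    ``transects`` maps recording id -> list of TransectSpec.  ``groups``
    assigns each recording to a sample/treatment group for the statistics;
    ``plants`` optionally records the source individual for the
    replication-design checks.
    """

    stacks: Mapping[str, VideoStack | str | Path]
    transects: Mapping[str, Sequence[TransectSpec]]
    groups: Mapping[str, str] = field(default_factory=dict)
    plants: Mapping[str, str] = field(default_factory=dict)
    pixel_size_um: float = 0.1
    frame_interval_s: float = 1.0
    channel: int | str | None = None
    saturation_fraction: float = 0.0035
    markers: Mapping[str, MarkerLine] = field(default_factory=dict)
    grid_spacing_um: float = 5.0
    binarize_method: str = "otsu"
    binarize_threshold: float | None = None
    quality_thresholds: QualityThresholds = field(default_factory=QualityThresholds)
    alpha: float = 0.05
    seed: int = 0
    output_dir: str | Path | None = None

    def validate(self) -> None:
        for rid in self.stacks:
            if rid not in self.transects or not self.transects[rid]:
                raise ValueError(f"recording {rid!r} has no transects")
        for rid, stack in self.stacks.items():
            if isinstance(stack, VideoStack):
                for spec in self.transects[rid]:
                    max_um = max(stack.shape) * stack.pixel_size_um
                    if spec.length_um > max_um:
                        raise ValueError(
                            f"transect {spec.label or spec.anchor} ({spec.length_um} um) "
                            f"exceeds recording {rid!r} ({max_um:.1f} um)"
                        )


@dataclass
class QuackResult:
    measurements: pd.DataFrame
    reports: dict[str, ComparisonReport]
    audit: dict[str, Any]


def _resolve_stack(config: RunConfig, rid: str) -> VideoStack:
    src = config.stacks[rid]
    if isinstance(src, VideoStack):
        return src
    return load_stack(src, config.pixel_size_um, config.frame_interval_s)


def _preprocess(config: RunConfig, rid: str, stack: VideoStack) -> VideoStack:
    try:
        stack = to_grayscale(stack, config.channel)
        stack = stretch_contrast(stack, config.saturation_fraction)
    except Exception as e:  # noqa: BLE001
        raise StageError("preprocess", rid, e) from e
    marker = config.markers.get(rid)
    if marker is not None:
        try:
            stack = rotate_to_axis(stack, marker)
        except Exception as e:  # noqa: BLE001
            raise StageError("rotate", rid, e) from e
    return stack


def measure_transect(
    stack: VideoStack,
    spec: TransectSpec,
    binarize_method: str = "otsu",
    binarize_threshold: float | None = None,
    quality_thresholds: QualityThresholds | None = None,
    recording_id: str = "",
    keep_kymograms: bool = False,
) -> tuple[MeasurementRecord, dict[str, Any]]:
    """Measure a single transect: sample → binarize → skeletonize → measure."""
    tr = make_transect(spec.anchor, spec.orientation, spec.length_um, stack, label=spec.label)
    raw = sample_kymogram(stack, tr)
    binary = binarize_kymogram(raw, method=binarize_method, threshold=binarize_threshold)
    skel = skeletonize_kymogram(binary)
    record = measure_kymogram(
        skel,
        thresholds=quality_thresholds,
        provenance={
            "recording_id": recording_id,
            "transect_label": spec.label,
            "direction_label": spec.direction_label,
            "threshold": binary.provenance.get("binarize", {}),
        },
    )
    extras: dict[str, Any] = {"transect": tr, "threshold": binary.provenance.get("binarize", {})}
    if keep_kymograms:
        extras.update({"raw": raw, "binary": binary, "skeleton": skel})
    return record, extras


def _measure_all(
    config: RunConfig, keep_kymograms: bool = False
) -> tuple[pd.DataFrame, dict[str, Any]]:
    rows = []
    audit: dict[str, Any] = {"seed": config.seed, "grids": {}, "thresholds": {}, "kymograms": {}}
    for rid in config.stacks:
        stack = _resolve_stack(config, rid)
        stack = _preprocess(config, rid, stack)
        grid_seed = derive_seed(config.seed, "grid", rid)
        try:
            grid = place_grid(stack, config.grid_spacing_um, grid_seed)
        except Exception as e:  # noqa: BLE001
            raise StageError("grid", rid, e) from e
        audit["grids"][rid] = {"seed": grid_seed, "offset_px": grid.offset_px}
        for j, spec in enumerate(config.transects[rid]):
            label = spec.label or f"t{j}"
            try:
                record, extras = measure_transect(
                    stack, spec,
                    binarize_method=config.binarize_method,
                    binarize_threshold=config.binarize_threshold,
                    quality_thresholds=config.quality_thresholds,
                    recording_id=rid,
                    keep_kymograms=keep_kymograms,
                )
            except StageError:
                raise
            except Exception as e:  # noqa: BLE001
                raise StageError("kymogram", rid, e) from e
            audit["thresholds"][f"{rid}/{label}"] = extras["threshold"]
            if keep_kymograms:
                audit["kymograms"][f"{rid}/{label}"] = extras
            rows.append(
                {
                    "recording_id": rid,
                    "transect_label": label,
                    "direction_label": spec.direction_label,
                    "duration_s": record.longest_event_duration_s,
                    "displacement_um": record.max_lateral_displacement_um,
                    "n_traces": record.n_traces,
                    "quality": record.quality,
                    "extreme_low": record.extreme_low,
                    "extreme_high": record.extreme_high,
                    "group": config.groups.get(rid, ""),
                    "plant_id": config.plants.get(rid, ""),
                }
            )
    return pd.DataFrame(rows), audit


def _grouped(df: pd.DataFrame, by: str, metric: str) -> GroupedMeasurements:
    groups = {str(k): g[metric].tolist() for k, g in df.groupby(by) if str(k)}
    prov = {
        str(k): g[["recording_id", "plant_id"]].reset_index(drop=True)
        for k, g in df.groupby(by)
        if str(k)
    }
    return GroupedMeasurements(groups=groups, metric=metric, provenance=prov)


def _write_audit(config: RunConfig, df: pd.DataFrame, audit: dict[str, Any],
                 reports: dict[str, ComparisonReport]) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "measurements.csv", index=False)
    kymos = audit.pop("kymograms", {})
    if kymos:
        import tifffile
        from imageio.v3 import imwrite

        kdir = out / "kymograms"
        kdir.mkdir(exist_ok=True)
        for key, extras in kymos.items():
            stem = key.replace("/", "_")
            raw = extras["raw"].values
            rng = np.ptp(raw)
            raw16 = ((raw - raw.min()) / rng * 65535).astype(np.uint16) if rng else \
                np.zeros_like(raw, dtype=np.uint16)
            tifffile.imwrite(kdir / f"{stem}_raw.tif", raw16)
            imwrite(kdir / f"{stem}_skeleton.png",
                    (extras["skeleton"].values.astype(np.uint8) * 255))
    (out / "audit.json").write_text(json.dumps(
        {"seed": audit["seed"], "grids": audit["grids"], "thresholds": audit["thresholds"]},
        indent=2, default=str))
    for metric, rep in reports.items():
        (out / f"report_{metric}.txt").write_text(rep.summary())
        rep.to_csv(out / f"report_{metric}.csv")


def run_quack(config: RunConfig, keep_kymograms: bool | None = None) -> QuackResult:
    """Execute the full pipeline and group statistics.

    Returns the tidy per-transect measurement table, one comparison report
    per metric (when at least two groups are configured) and the audit
    information; with ``output_dir`` set, everything — including kymogram
    images and realized thresholds — is persisted.
    """
    config.validate()
    keep = bool(config.output_dir) if keep_kymograms is None else keep_kymograms
    df, audit = _measure_all(config, keep_kymograms=keep)
    reports: dict[str, ComparisonReport] = {}
    if df["group"].nunique() >= 2:
        for metric in METRICS:
            reports[metric] = compare_groups(_grouped(df, "group", metric), alpha=config.alpha)
    if config.output_dir:
        _write_audit(config, df, audit, reports)
    return QuackResult(measurements=df, reports=reports, audit=audit)


def run_transect_sweep(config: RunConfig, lengths_um: Sequence[float]) -> pd.DataFrame:
    """Transect-size calibration sweep.

    Repeats the measurement at each candidate length (same anchors and
    orientations) and judges each setting by its fraction of extreme
    records: the calibration step recommended before any large-scale study.
    """
    if len(lengths_um) < 2:
        raise ValueError("transect sweep needs at least 2 candidate lengths")
    rows = []
    for length in lengths_um:
        transects = {
            rid: [TransectSpec(s.anchor, s.orientation, length, s.label, s.direction_label)
                  for s in specs]
            for rid, specs in config.transects.items()
        }
        sub = RunConfig(**{**_config_kwargs(config), "transects": transects, "output_dir": None})
        df, _ = _measure_all(sub)
        records = [
            MeasurementRecord(
                longest_event_duration_s=r.duration_s,
                max_lateral_displacement_um=r.displacement_um,
                n_traces=r.n_traces, extreme_low=r.extreme_low,
                extreme_high=r.extreme_high, quality=r.quality,
            )
            for r in df.itertuples()
        ]
        adv = advise_transect_size(records)
        rows.append(
            {"length_um": length, "extreme_fraction": adv.extreme_fraction,
             "n_records": adv.n_records, "verdict": adv.verdict,
             "median_duration_s": float(df["duration_s"].median()),
             "median_displacement_um": float(df["displacement_um"].median())}
        )
    return pd.DataFrame(rows)


def _config_kwargs(config: RunConfig) -> dict[str, Any]:
    kw = {f: getattr(config, f) for f in config.__dataclass_fields__}
    return kw


def run_noise_experiment(
    config: RunConfig, sd_levels: Sequence[float], n_seeds: int = 1
) -> pd.DataFrame:
    """Noise-robustness experiment.

    For each noise SD (source-intensity units), Gaussian noise is injected
    into every raw recording *before* the standard pipeline, the
    measurement is repeated and per-level summaries are reported.  The
    sd = 0 level is the unmodified baseline.
    """
    if any(sd < 0 for sd in sd_levels):
        raise ValueError("noise sd levels must be non-negative")
    rows = []
    for sd in sd_levels:
        for rep in range(n_seeds):
            noisy_stacks = {}
            for rid in config.stacks:
                stack = _resolve_stack(config, rid)
                noise_seed = derive_seed(config.seed, "noise", rid, int(sd * 1000), rep)
                noisy_stacks[rid] = add_gaussian_noise(stack, sd, noise_seed)
            sub = RunConfig(**{**_config_kwargs(config), "stacks": noisy_stacks,
                               "output_dir": None})
            df, _ = _measure_all(sub)
            df["noise_sd"] = sd
            df["noise_rep"] = rep
            rows.append(df)
    all_df = pd.concat(rows, ignore_index=True)
    return all_df


def summarize_noise_experiment(records: pd.DataFrame) -> pd.DataFrame:
    """Per-level medians and quality fractions from run_noise_experiment."""
    out = []
    for sd, g in records.groupby("noise_sd"):
        out.append(
            {
                "noise_sd": sd,
                "median_duration_s": float(g["duration_s"].median()),
                "median_displacement_um": float(g["displacement_um"].median()),
                "fragmented_fraction": float((g["quality"] == "fragmented").mean()),
                "n_records": len(g),
            }
        )
    return pd.DataFrame(out).sort_values("noise_sd").reset_index(drop=True)


def run_anisotropy_study(config: RunConfig) -> dict[str, ComparisonReport]:
    """Compare metrics between transect direction labels.

    Transects must carry at least two distinct ``direction_label`` values
    (e.g. longitudinal vs transversal); measurements are grouped by
    direction and compared per metric with the standard battery.
    """
    labels = {s.direction_label for specs in config.transects.values() for s in specs}
    labels.discard("")
    if len(labels) < 2:
        raise ValueError("anisotropy study needs >= 2 transect direction labels")
    df, _ = _measure_all(config)
    counts = df["direction_label"].value_counts()
    if (counts < 4).any():
        warnings.warn("fewer than 4 transects in some direction; advisory only", stacklevel=2)
    reports = {}
    for metric in METRICS:
        gm = GroupedMeasurements(
            groups={str(k): g[metric].tolist() for k, g in df.groupby("direction_label") if str(k)},
            metric=metric,
        )
        reports[metric] = compare_groups(gm, alpha=config.alpha)
    return reports
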