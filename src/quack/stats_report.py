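"""Nonparametric statistical battery and reporting.

Longest event durations and lateral displacements are censored at the
recording length, so their distributions cannot be assumed normal; group
comparisons therefore use rank-based tests — a Kruskal–Wallis omnibus gate
followed by pairwise two-sided Wilcoxon–Mann–Whitney tests with Bonferroni
correction — and results are summarized as box plots (median, quartiles,
Tukey whiskers) rather than means ± errors.  Fractions (e.g. of moving
structures) are compared with Pearson's chi-square.

The test statistics are delegated to scipy.stats; this module fixes the
conventions (two-sided throughout, exact Mann–Whitney p for small tie-free
samples, mid-rank tie handling, no Yates continuity correction) and adds
the replication-design checks of the recommended sampling scheme.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupedMeasurements",
    "ComparisonReport",
    "mann_whitney_u",
    "kruskal_wallis",
    "bonferroni_adjust",
    "chi_square_test",
    "boxplot_summary",
    "compare_groups",
    "design_warnings",
]

#: recommended minimum replication per sample/treatment
MIN_RECORDINGS = 10
MIN_PLANTS = 5
MAX_RECORDINGS_PER_PLANT = 2
MIN_TRANSECTS_PER_RECORDING = 4


@dataclass
class GroupedMeasurements:
    """Metric values per group, with optional per-value provenance.

    ``groups`` maps group label -> values; ``provenance`` (optional) maps
    group label -> DataFrame with columns among ``recording_id``,
    ``plant_id`` (one row per value) used for replication-design checks.
    """

    groups: Mapping[str, Sequence[float]]
    metric: str = "value"
    provenance: Mapping[str, pd.DataFrame] | None = None

    def __post_init__(self) -> None:
        for label, vals in self.groups.items():
            arr = np.asarray(list(vals), dtype=float)
            if arr.size and (not np.isfinite(arr).all() or (arr < 0).any()):
                raise ValueError(f"group {label!r} has non-finite or negative values")


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon–Mann–Whitney test.

    Returns (U statistic of sample ``a``, two-sided p).  The p-value is the
    exact permutation probability when the combined sample size is at most
    20 and tie-free; otherwise the tie-corrected normal approximation with
    continuity correction is used.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample needs n >= 3")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H with chi-square approximation p."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    if any(g.size == 0 for g in arrays):
        raise ValueError("empty group")
    if np.unique(np.concatenate(arrays)).size == 1:
        return 0.0, 1.0  # all values identical: scipy rejects this degenerate case
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def bonferroni_adjust(p_values: Sequence[float]) -> np.ndarray:
    """min(1, p * m) for a family of m comparisons."""
    p = np.asarray(list(p_values), dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)


def chi_square_test(contingency: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson chi-square on a 2×k table (no continuity correction).

    Expected counts below 1 are rejected; below 5 a validity warning is
    emitted.
    """
    obs = np.asarray(contingency, dtype=float)
    if obs.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    expected = stats.contingency.expected_freq(obs)
    if (expected < 1).any():
        raise ValueError("expected counts below 1; chi-square invalid")
    if (expected < 5).any():
        warnings.warn("expected counts below 5; chi-square p is approximate", stacklevel=2)
    chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return float(chi2), float(p)


def boxplot_summary(values: Sequence[float]) -> dict[str, float]:
    """Median, linear-interpolation (type-7) quartiles, Tukey whiskers, n."""
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("boxplot_summary needs at least one value")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    in_lo = x[x >= q1 - 1.5 * iqr]
    in_hi = x[x <= q3 + 1.5 * iqr]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_lo": float(in_lo.min()),
        "whisker_hi": float(in_hi.max()),
        "n": int(x.size),
    }


def design_warnings(provenance: Mapping[str, pd.DataFrame] | None) -> list[str]:
    """Check replication against the recommended minimum design."""
    if not provenance:
        return []
    notes = []
    for label, df in provenance.items():
        # ignore provenance columns that carry no information (all empty)
        keep = [c for c in df.columns if df[c].astype(str).ne("").any()]
        df = df[keep]
        if "recording_id" in df.columns:
            recs = df["recording_id"]
            if recs.nunique() < MIN_RECORDINGS:
                notes.append(
                    f"group {label!r}: {recs.nunique()} recordings "
                    f"(recommend >= {MIN_RECORDINGS})"
                )
            per_rec = recs.value_counts()
            if (per_rec < MIN_TRANSECTS_PER_RECORDING).any():
                notes.append(
                    f"group {label!r}: some recordings have fewer than "
                    f"{MIN_TRANSECTS_PER_RECORDING} transects"
                )
        if "plant_id" in df.columns:
            plants = df["plant_id"]
            if plants.nunique() < MIN_PLANTS:
                notes.append(
                    f"group {label!r}: {plants.nunique()} plants (recommend >= {MIN_PLANTS})"
                )
            if "recording_id" in df.columns:
                per_plant = df.groupby("plant_id")["recording_id"].nunique()
                if (per_plant > MAX_RECORDINGS_PER_PLANT).any():
                    notes.append(
                        f"group {label!r}: more than {MAX_RECORDINGS_PER_PLANT} "
                        "recordings from one individual"
                    )
    return notes


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


@dataclass
class ComparisonReport:
    """Omnibus + pairwise comparison of one metric across groups."""

    metric: str
    omnibus: dict[str, float | str]
    pairwise: pd.DataFrame
    box_summaries: dict[str, dict[str, float]]
    warnings: list[str] = field(default_factory=list)
    alpha: float = 0.05

    def summary(self) -> str:
        lines = [
            f"Comparison of {self.metric} across {len(self.box_summaries)} groups",
            f"Omnibus {self.omnibus['test']}: statistic = "
            f"{self.omnibus['statistic']:.4g}, p = {self.omnibus['p']:.4g}",
            "",
            "Pairwise Wilcoxon-Mann-Whitney (Bonferroni-adjusted):",
            self.pairwise.to_string(index=False),
            "",
            "Per-group box summaries (median [Q1, Q3], whiskers, n):",
        ]
        for label, s in self.box_summaries.items():
            lines.append(
                f"  {label}: {s['median']:.4g} [{s['q1']:.4g}, {s['q3']:.4g}], "
                f"({s['whisker_lo']:.4g} .. {s['whisker_hi']:.4g}), n = {s['n']}"
            )
        for w in self.warnings:
            lines.append(f"DESIGN WARNING: {w}")
        return "\n".join(lines)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.pairwise.to_csv(path, index=False)
        return path


def compare_groups(gm: GroupedMeasurements, alpha: float = 0.05) -> ComparisonReport:
    """Full comparison: Kruskal–Wallis gate, then pairwise Mann–Whitney
    with Bonferroni correction over all pairs of the metric's family."""
    labels = list(gm.groups.keys())
    if len(labels) < 2:
        raise ValueError("need >= 2 groups to compare")
    arrays = {k: np.asarray(list(v), dtype=float) for k, v in gm.groups.items()}
    h, p_omni = kruskal_wallis(list(arrays.values()))
    pairs = list(itertools.combinations(labels, 2))
    rows = []
    for a, b in pairs:
        u, p = mann_whitney_u(arrays[a], arrays[b])
        rows.append({"group_a": a, "group_b": b, "U": u, "p_raw": p})
    table = pd.DataFrame(rows)
    table["p_adjusted"] = bonferroni_adjust(table["p_raw"].to_numpy())
    table["significance"] = [_stars(p) for p in table["p_adjusted"]]
    return ComparisonReport(
        metric=gm.metric,
        omnibus={"test": "Kruskal-Wallis", "statistic": h, "p": p_omni},
        pairwise=table,
        box_summaries={k: boxplot_summary(v) for k, v in arrays.items()},
        warnings=design_warnings(gm.provenance),
        alpha=alpha,
    )


def plot_boxes(gm: GroupedMeasurements, ax=None):
    """Box plot (median/quartiles/Tukey whiskers) of the grouped metric."""
    if ax is None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    labels = list(gm.groups.keys())
    ax.boxplot([np.asarray(list(gm.groups[k]), dtype=float) for k in labels],
               tick_labels=labels, whis=1.5)
    ax.set_ylabel(gm.metric)
    return ax
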