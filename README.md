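# quack-kymo

Quantitative analysis of cytoskeletal kymograms: a library and CLI that
turn fluorescence time-lapse recordings of the cortical cytoskeleton
(actin filaments, microtubules) into per-transect measurements of
**structure lifetime** and **lateral mobility**, plus the nonparametric
statistics needed to compare genotypes, markers or treatments.

## The problem and the method

Live imaging of plant cortical cytoskeleton (spinning-disc confocal or
variable-angle epifluorescence, ~1 s frame interval, ~2 min recordings)
shows filamentous structures appearing, disappearing and sliding sideways.
Tracking individual filaments by hand is accurate but prohibitively slow.
The kymogram shortcut: place a straight transect of fixed physical length
over the movie and plot the intensity along it for every frame — a 2-D
image with position on one axis and time on the other. A structure crossing
the transect draws a *trace*: its extent along the time axis is the time the
structure spent on the transect (a lifetime/stability proxy), and its extent
along the space axis is how far it moved laterally (a mobility proxy).

The pipeline, per recording:

1. grayscale conversion and **per-frame linear histogram stretch** (this
   cancels global photobleaching: a frame multiplied by a decaying constant
   stretches to the same image);
2. optional rotation that aligns a user-placed marker line with the
   horizontal axis (for anisotropic samples such as elongated epidermal
   cells);
3. a randomly offset grid (seeded) to support unbiased manual transect
   placement; transects of a pre-defined length (e.g. 20 μm) are placed in
   the well-focused part of the field;
4. kymogram sampling (bilinear, one sample per pixel-size step), Otsu
   binarization and topology-preserving thinning to unit-width skeleton
   traces;
5. per kymogram: **longest event duration** = max over 8-connected traces
   of the inclusive row span × frame interval, and **maximum lateral
   displacement** = max over traces of the exclusive column span × pixel
   size. A full-height trace scores exactly the recording duration; a
   vertical (static) trace scores zero displacement;
6. group statistics: Kruskal–Wallis omnibus, pairwise two-sided
   Wilcoxon–Mann–Whitney with Bonferroni correction, box-plot summaries
   (durations are censored at the recording length, so rank-based tests are
   used instead of t/ANOVA).

Supporting procedures: a transect-size advisory (reject a setting when ≥ 2/3
of kymograms hit floor/ceiling values; accept when ≥ 1/2 are non-extreme), a
controlled noise-injection experiment (strong Gaussian noise fragments long
traces and lowers measured durations), a frame-pair Pearson correlation
decay curve as an independent whole-frame dynamics comparator (with
plateau/floor detection where the assay becomes non-informative), and a
**synthetic filament-movie simulator** with exact per-filament ground truth
used to validate every stage.

## Worked example

Two synthetic "genotypes" differing only in structure lifetime
(exponential means 12 s vs 35 s), at the recommended replication of 10
recordings × 4 transects per group:

```python
from quack import SimConfig, simulate_video, RunConfig, TransectSpec, run_quack

stacks, transects, groups, plants = {}, {}, {}, {}
for group, mean_lifetime in (("wt", 12.0), ("mutant", 35.0)):
    for rep in range(10):
        cfg = SimConfig(
            image_shape=(96, 96), n_frames=120, frame_interval_s=1.0,
            pixel_size_um=0.1, filament_birth_rate=0.25,
            lifetime_model=("exponential", mean_lifetime),
            drift_speed_model=("half_normal", 0.05),
        )
        rid = f"{group}{rep}"
        stacks[rid], _ = simulate_video(cfg, seed=100 + 10 * rep + (group == "mutant"))
        transects[rid] = [
            TransectSpec(anchor=(20.0, 20.0 + 18.0 * k), orientation="horizontal",
                         length_um=5.0, label=f"t{k}")
            for k in range(4)
        ]
        groups[rid] = group
        plants[rid] = f"{group}_plant{rep // 2}"

config = RunConfig(stacks=stacks, transects=transects, groups=groups,
                   plants=plants, seed=7)
result = run_quack(config)
print(result.reports["duration_s"].summary())
```

prints

```
Comparison of duration_s across 2 groups
Omnibus Kruskal-Wallis: statistic = 16.91, p = 3.928e-05

Pairwise Wilcoxon-Mann-Whitney (Bonferroni-adjusted):
group_a group_b      U   p_raw  p_adjusted significance
 mutant      wt 1227.0 0.00004     0.00004           **

Per-group box summaries (median [Q1, Q3], whiskers, n):
  mutant: 41 [28.5, 63], (14 .. 110), n = 40
  wt: 24 [18, 31.25], (7 .. 50), n = 40
```

The planted direction is recovered: the long-lifetime group's median
longest event duration (41 s) exceeds the short-lifetime group's (24 s),
with a Bonferroni-adjusted Mann–Whitney p < 0.01 (`**`). The box summaries
are the numbers to plot; `result.measurements` is the tidy per-transect
table (recording, transect, duration_s, displacement_um, trace count,
quality class, extremeness flags).

From the shell the same pipeline is available as subcommands:
`quack simulate`, `preprocess`, `kymo`, `measure`, `stats`, `correlate`,
`sweep`, `noise-exp` and `run` (end-to-end from a JSON config). Every run
logs seeds, grid offsets and realized thresholds; with an output directory
set it also writes each kymogram (raw TIFF + skeleton PNG) so results can
be re-derived without the original stacks.

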