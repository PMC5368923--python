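# Methods

This note documents the models, conventions and numerical choices behind
the package, and what its synthetic validation does and does not show.

## Coordinate and unit conventions

Image coordinates are (x = column, y = row), origin top-left, 0-based.
Angles are measured in this frame (y down), so +π/2 points down the image.
All physical quantities carry explicit units: micrometres for lengths and
pixel size, seconds for time and frame interval. Kymogram arrays have row
0 = first frame; figures that draw time upward are a display-side flip.

## Preprocessing

**Contrast stretch.** Each frame is independently mapped linearly onto
[0, 1], clipping the lowest and highest `saturation_fraction/2` of valid
pixels (default 0.0035, the common "enhance contrast" default; 0 gives a
pure min–max stretch). Because the mapping is per frame, any global
multiplicative intensity decay — photobleaching of a statically structured
scene — is cancelled exactly; this is the package's bleaching compensation,
and also why a frame with *no* signal anywhere is dangerous: its noise gets
stretched to full contrast. Frames with zero intensity variance are
returned as zeros and flagged (`meta["zero_variance_frames"]`) rather than
dropped; discarding recordings is always the analyst's decision.

**Rotation.** For anisotropic samples the stack is rotated so a user-placed
marker line becomes horizontal: bilinear interpolation about the frame
centre, canvas expanded so nothing is cropped, and pixels with no source
data tracked in `valid_mask` (they never enter kymograms as fake zeros).
The transformed marker is checked to be horizontal within 0.5°.

**Noise injection** (for robustness experiments) adds i.i.d. zero-mean
Gaussian noise in source-intensity units, clipped to the declared bit
depth, *before* the rest of the pipeline, and is a pure function of
(stack, sd, seed).

## Kymograms and their skeletons

A transect of physical length L at pixel size p is sampled at
`round(L/p) + 1` equally spaced positions (endpoints inclusive, one sample
per pixel-size step); sampling is bilinear and exact on the pixel lattice.
Transects must lie entirely inside the valid mask — the guarantee that
every kymogram column reads real, in-focus data. Only straight transects
are supported.

**Binarization** defaults to Otsu per kymogram. Otsu assumes the kymogram
actually contains two intensity populations; on a near-empty kymogram it
will split the noise instead, producing dense spurious foreground. This
failure mode is intentional to keep visible (the transect-size advisory is
how it surfaces); for data where empty kymograms are expected, the fixed
threshold mode at 0.5 on stretched kymograms (the half-maximum/FWHM
criterion) is the recommended alternative, and an adaptive local-mean mode
exists for uneven illumination. The realized threshold is always logged.

**Skeletonization** must preserve exactly the two quantities measured from
the skeleton: each trace's extent in time (rows) and in space (columns).
Standard thinning erodes the ends of a thick trace by about half its width,
which would bias every duration downward by 2–5 frames. The package
therefore uses an extent-preserving medial-axis thinning: foreground pixels
are deleted in order of increasing distance to the background (ties broken
by cornerness, then scan order — fully deterministic) whenever the deletion
keeps the local 8-connectivity unchanged and the pixel has ≥ 3 foreground
neighbours; trace end pixels are thereby never deleted and every
component's bounding box survives exactly. A final hit-or-miss thinning
pass enforces unit width, and residual 2×2 blocks are resolved by deleting
a topologically simple pixel (Yokoi connectivity number 1). Two properties
follow, and are tested: the skeleton is a subset of the binary foreground,
and connected components correspond one-to-one. Two caveats are accepted
deliberately: (i) a 2×2 block whose four pixels are all non-simple (a
perfect X-crossing of diagonal traces, or a minimal ring around a one-pixel
hole) is left intact — removing it would change the topology; (ii) a solid
blob keeps a thin cross reaching its bounding box rather than collapsing to
a point, because for kymogram traces the bounding box *is* the measurement.

## Trace metrics

Duration counts rows inclusively: a structure visible in exactly one frame
scores one frame interval, and a full-height trace scores exactly the
recording duration (the saturation case the transect advisory watches for).
Displacement counts columns exclusively: a perfectly vertical trace — a
static structure — scores zero. The asymmetry is deliberate: duration
measures occupancy, displacement measures movement. The longest and the
widest trace are found independently; they need not be the same structure.

Because traces have a finite width (PSF × threshold), the bounding-box
displacement of a *moving* trace is inflated by roughly (trace width − 1)
pixels contributed by its square ends. With Otsu binarization traces are
typically 3–5 px wide, a ~+0.2–0.4 μm bias at 0.1 μm pixels; at the
half-maximum threshold traces stay at their resolution-limited ~2–3 px and
the bias drops to ≤ 2 px. Absolute mobility work should use the FWHM mode;
comparative (between-group) work is unaffected because the bias is common
to all groups.

Extremeness flags: `extreme_low` when the longest event lasts ≤ 2 frames
(or the kymogram is empty), `extreme_high` when it spans the full
recording. The transect-size advisory rejects a setting when the extreme
fraction is ≥ 2/3, accepts when the non-extreme fraction is ≥ 1/2, and
calls it sub-optimal in between; fewer than 4 records per setting warns.
Quality classes are calibration defaults exposed in `QualityThresholds`:
*meshwork* = one component spanning ≥ 90% of rows and columns (saturated),
*fragmented* = ≥ 10 components with none spanning > 10% of the rows (noise
indicator), *empty*, else *distinct*. These mimic a visual classification
and are conservative: heavily noise-corrupted kymograms often retain one
larger component and classify as *distinct* even when their long traces
have visibly shattered — the measured duration drop, not the class label,
is the reliable noise signal.

## Statistics

Durations and displacements are censored at the recording length and floor
respectively, so normality cannot be assumed: comparisons use a
Kruskal–Wallis omnibus followed by pairwise two-sided Wilcoxon–Mann–Whitney
with Bonferroni correction (family = all pairwise comparisons within one
metric; families are never pooled across metrics). Mann–Whitney p-values
are exact permutation probabilities for tie-free combined samples of ≤ 20,
otherwise the tie-corrected normal approximation with continuity
correction. Chi-square (for fractions) is Pearson's without continuity
correction; expected counts < 1 are an error, < 5 a warning. Box summaries
use linear-interpolation (type-7) quartiles and Tukey 1.5 × IQR whiskers.
Replication-design checks warn when a group has fewer than 10 recordings,
fewer than 5 individuals, more than 2 recordings from one individual, or
recordings with fewer than 4 transects.

## Correlation comparator

Frame-pair Pearson correlation over the valid mask as a function of lag,
aggregated over *all* pairs at each lag (maximizing pair counts; an
anchored-to-frame-0 mode exists for comparison), with per-lag SD and pair
counts reported. The non-informative floor is flagged where the
least-squares slope over a trailing 10-lag window stays below 1e-4 r/s for
the remainder of the curve; both window and tolerance are documented
defaults, not claims. Pearson correlation is invariant to affine intensity
transforms, so the curve is unchanged by global scaling and — on statically
structured movies — by the per-frame contrast stretch.

## Synthetic data generator

The simulator emulates SDCM/VAEM recordings: straight filaments born as a
Poisson process (uniform birth times over the recording), each with a fixed
or exponential lifetime, drifting rigidly at constant signed speed
perpendicular to its own axis, rendered as a line convolved with a Gaussian
PSF onto a constant background, the whole frame multiplied by an optional
exponential bleaching factor, plus Gaussian camera noise. Lifetimes
extending past the movie are censored at the last frame, reproducing the
truncation that motivates the rank-based statistics. Orientation is uniform
or von Mises; orientation anisotropy applies lifetime/drift multipliers
interpolated by a cos² law (full factor parallel to the reference axis,
none perpendicular). Defaults: 0.1 μm pixels (σ of the Gaussian PSF
0.10 μm, the diffraction-limited width for an NA ≈ 1.45 oil objective at
~510 nm emission), 1 s frame interval, 120 frames, amplitude/noise SD
= 2000/200 (SNR ≈ 10), 16-bit range. The generator's parameters are
calibration knobs for validation, not biological claims.

Ground truth is exact: every filament's geometry, birth/death and drift are
returned, and `oracle_transect_metrics` computes by direct segment–segment
geometry the ideal longest occupancy (longest contiguous run of crossing
frames × Δt) and lateral drift range (span of intersection positions along
the transect) for any transect — the reference against which the pipeline
is validated.

**What the simulator omits** — filament bending, severing, bundling,
branching, treadmilling/end growth (end dynamics enter only through
birth/death), intensity-based thickness classes, focus drift and
non-uniform background. Passing validation therefore demonstrates geometric
and statistical correctness of the measurement chain on idealized
filaments, not robustness to every artefact of real recordings; thick vs
thin bundles are explicitly not distinguished.

## Validation studies and their problem sizes

All studies run on one CPU in minutes; sizes were chosen as the smallest
that leave comfortable statistical margins.

- **Parameter recovery**: 100 single-filament noise-free movies each for
  lifetime (fixed 40 s; measured duration within one frame of the oracle)
  and mobility (0.1 μm/s for 60 s across a 20 μm transect; displacement
  within 2 px of 6.0 μm). These studies binarize at half-maximum (see trace
  metrics above).
- **Group difference**: per transect, one small movie whose 8 μm transect
  is crossed by a Poisson (mean 10) number of filaments in distinct lateral
  slots (overlapping structures would merge into one trace, which the
  method does not disentangle); exponential lifetimes 20 s vs 40 s, 40
  transects per group, 100 repetitions for power at adjusted p < 0.01, 100
  identical-distribution repetitions for the null rate.
- **Noise robustness**: single full-recording trace, Gaussian noise at SD
  0/1600/2400 on amplitude 2000 injected before the pipeline, 30 seeds.
  Thresholding tolerates noise well below the signal amplitude, so the
  informative levels bracket the amplitude itself.
- **Transect-size calibration**: a dense field of stable filaments drifting
  at 0.12 μm/s (long transects keep every structure in view for the whole
  recording → ceiling values; short ones see drift-throughs) and a sparse
  short-lived field with two permanent off-transect anchor filaments
  (keeping per-frame stretch pinned to real signal) where short transects
  mostly read empty.
- **Anisotropy**: aligned arrays (von Mises κ = 6 about the horizontal)
  with parallel filaments given 2× lifetime and 0.5× drift; two
  longitudinal and two transversal 5 μm transects on each of four
  independent movies per seed (nearby transects share filaments, which
  would correlate the readings); 10 pooled seeds for recovery, 40 seeds for
  the isotropic null.
- **Correlation**: paired fast (mean lifetime 4 s) vs slow (20 s) turnover
  movies over 30 seeds, compared per lag on 1–30 s (beyond ~half the
  recording both curves sit at the noise floor).
- **Statistics core**: enumeration/hand-formula checks and 2000-draw null
  simulations for the 5% type-I error of both rank tests.

## Known limitations

- Lateral mobility from bounding boxes conflates drift with trace width
  (quantified above) and, on transects nearly parallel to a moving
  filament, geometric sweep amplification; direction-labeled comparisons
  remain valid because both apply to all groups.
- Per-frame stretch requires signal somewhere in every frame; all-noise
  frames come out at full contrast and should be discarded upstream.
- The quality classifier is a proxy for visual judgement and is not claimed
  equivalent to it; it flags, never discards.
- No drift correction or registration: recordings with visible stage drift
  should be excluded, not corrected.
- AVI input is decoded through imageio and depends on the codecs available
  in the environment; multi-page TIFF is the first-class format.
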