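# Methods

This note documents the models behind each pipeline stage, the parameters
that matter, the numerical choices made where the design was genuinely open,
and what the synthetic generators do and do not emulate.

## 1. 3-D morphometry

### Processing chain

Each stack carries a membrane channel (cell bodies) and a nucleus channel.
Per channel: min–max normalisation to [0, 1], Gaussian blur
(`blur_sigma_px`, default 2 px), thresholding (Otsu by default; a fixed
threshold on the normalised scale is available), and block down-sampling by
`downsample_factor` (default 4) with strict-majority voting per block. The
down-sampled voxel edge is the "unit" in which all volumes and distances are
expressed; `unit_to_um` (default 0.62) converts to μm, so the default volume
cutoffs correspond to ≈ 12 μm³ (cells, 50 units) and ≈ 1 μm³ (nuclei,
5 units) and the centroid-distance cutoff of 100 units to ≈ 62 μm.

Foreground voxels are clustered with DBSCAN (`eps = 2` units,
`min_samples = 10`); voxels labelled noise are dropped and logged. Output
cells are sorted by centroid (lexicographic Z, Y, X) so the clustering
iteration order can never influence records. Nuclei are assigned to the cell
whose voxel set contains their centroid, falling back to the nearest cell
centroid within the centroid-distance cutoff; each cell keeps at most one
nucleus (nearest wins, ties break toward the lower cell index and are
logged).

### Descriptors

With `X = range_x / 2` and `Y = range_y / 2` (ranges are inclusive voxel
extents, so a single voxel has range 1):

- aspect ratio `range_y / range_x`;
- circularity `C = 4πA/P²` evaluated on the ellipse fitted from the ranges,
  `A_e = πXY`, `P_e = 2π√((X²+Y²)/2)`, which simplifies to `2XY/(X²+Y²)`;
  an alternative `projected_area` mode keeps the ellipse perimeter but uses
  the true XY-projected area. Both are provided because a contour-based
  `4πA/P²` on real, ragged cell outlines yields much smaller values than the
  pure ellipse form, and which combination a given study used is often not
  recoverable from its text; the ellipse mode is the default since it is the
  one fully determined by the printed formulas.
- centroid distance: Euclidean, body vs nucleus centroid, in units and μm;
- solidity: convex-hull volume over body volume. The hull is taken over the
  8 corner points of every voxel cube, not voxel centres, so flat or
  single-voxel bodies keep a full-dimensional hull and solidity stays
  finite; a grid-aligned convex box scores exactly 1. Note the orientation:
  hull over body, hence ≥ 1, with larger values meaning *less* convex — the
  reciprocal of the area-fraction solidity common elsewhere. For smooth
  voxelised bodies the corner-point hull overshoots the continuum hull by
  roughly `(1 + 0.5/r)³` (≈ 13% for a radius-12 ball), which is a
  discretisation property, not an error;
- ramification `(P/A)/(2√(π/A))` of the maximum-area axis projection
  (area ties break deterministically by axis), `P` from the 2-D convex hull
  of that projection's pixel corners. 1 for a disk, `2/√π ≈ 1.128` for a
  square.

### QC

Records are flagged rather than silently dropped: `no_nucleus`,
`centroid_out_of_range` (strictly greater than the cutoff),
`boundary_abnormal` (non-finite or non-positive metric, hull failure), and
`grubbs_outlier`. Grubbs runs per metric across the surviving records,
two-sided at `grubbs_alpha = 0.05`, iteratively removing at most one record
per iteration; it needs at least 3 records (otherwise skipped with a
warning) and is a no-op at zero variance. The volume filters use the strict
"below" reading: a 50-unit cell is retained, a 49-unit cell is not.

## 2. Calcium events

### Trace model

`ΔF/F₀ = (F_t − F₀)/F₀` with `F₀` the mean fluorescence over the pixels
outside the cell mask at each time point. This background-referenced
normalisation measures cell-over-background contrast rather than change
from the cell's own baseline; it is kept as the default because it is the
stated convention of the workflow this package reimplements. Two
consequences worth knowing:

1. a cell with baseline `F_b` over background `B` carries a constant offset
   `(F_b − B)/B` (removed by the high-pass), and
2. an intracellular transient of fractional amplitude `a` appears in ΔF/F₀
   with amplitude `(F_b/B)·a` — e.g. 5× at the generator defaults
   (baseline 100, background 20).

A conventional per-ROI-baseline mode (`baseline_mode="roi"`) is available
but off by default.

### Filtering

6th-order Butterworth low-pass at 1 Hz, then 2nd-order high-pass at
0.01 Hz, both applied forward–backward (`sosfiltfilt`) by default so event
kinetics are not phase-shifted; a causal single-pass mode exists behind
`zero_phase=False`. Zero-phase application squares each magnitude response.
A consequence that shapes everything downstream: a transient of mass
`∫ΔF/F dt = M` loses roughly `2 f_c M` of its peak to a high-pass at `f_c`
(the filter must remove the event's own quasi-DC content), and leaves a
shallow undershoot that decays with the filter time constant
(~22 s here). Slow events (decay constant ≳ 7 s) therefore lose more than
20% of their peak — not an implementation artefact but a property of the
published band.

### Detection and kinetics

On the filtered trace: maximal runs above `event_threshold_dff = 0.1` are
candidates; each run is extended outward to the nearest zero crossings; each
boundary is then refined inward to the minimum of the flank between the zero
crossing and the threshold crossing (ties toward the earlier frame) —
"the deepest dip adjacent to the event". Overlapping candidates merge.
Events are disjoint, temporally ordered, with
`onset ≤ peak ≤ offset`. Kinetics: amplitude = max filtered value on
[onset, offset]; AUC = trapezoidal integral over the same span (ΔF/F·s);
duration = onset→offset; rise = onset→peak; decay = peak→offset. Under
these definitions duration = rise + decay *by construction*; studies that
report otherwise are using boundary definitions that cannot be recovered
from a duration/rise/decay triple alone, so no claim of numerical
comparability is made.

"Large calcium events" means exactly the events passing the 0.1 threshold;
no second criterion is applied. Activity per recording is summarised as the
proportion of ROIs with ≥ 1 event plus the per-active-cell event-count
distribution.

## 3. Viability

Nuclei: blur (2 px) → Otsu → components ≥ 20 px → distance-transform
watershed splitting (peaks ≥ 5 px apart) for touching pairs. A
contrast guard treats a field as empty when the foreground–background
separation is below 3 background standard deviations, so Otsu cannot
manufacture nuclei out of noise. Dead cells: a nucleus is dead when the
mean dead-channel intensity in a 4-px disk around its centroid exceeds the
Otsu cutoff of the (blurred) dead channel; a single-valued dead channel
means zero dead; dead signal with no nucleus nearby is ignored and logged.
`viability = 100·(total − dead)/total`; the live (calcein) channel is not
needed for the counts and is retained for inspection only.

## 4. Statistics

- One-way ANOVA, F on `(k−1, N−k)` df, with Tukey's HSD via the
  studentized-range distribution on the pooled within-group mean square;
  each pair also reports the unadjusted pooled-t p-value (adjusted ≥
  unadjusted always).
- Two-sample t: pooled variance by default, `n_a + n_b − 2` df, two-tailed.
  Zero pooled variance returns t = 0 for equal means and is an error
  otherwise.
- Kolmogorov–Smirnov: `D = sup|ECDF_a − ECDF_b|`, asymptotic two-sided p.
- Grubbs: `G = max|x − x̄|/s` against the two-sided critical value
  `((n−1)/√n)·√(t²/(n−2+t²))`, `t = t_{α/(2n), n−2}`, applied iteratively;
  flagged indices refer to the original input order.

Degrees of freedom are reported unadjusted for multiple comparisons;
Tukey's correction acts on pairwise p-values only.

**Calibration helpers.** Type-I-error rates are estimated by vectorized
null simulation. For Tukey, looping a studentized-range survival-function
call per replicate costs ~80 ms each (hours at 10⁴ replicates), so the
helper uses the decision-identical rejection rule
`q_max > q_crit(α, k, df)` with the critical value computed once; the
equivalence with per-call adjusted p-values is asserted in the test suite.
At the viability design (k = 3 groups of n = 3) both the t-test rejection
rate and the Tukey family-wise error land at 5% ± 1% over 10⁴ replicates.

## 5. Synthetic data: what it emulates, and what not

**Morphology stacks.** Cells are axis-aligned ellipsoids (optionally
stellate bodies with cylindrical arms) with offset nuclear spheres, rendered
at constant intensity over background, Gaussian-blurred and corrupted with
additive Gaussian read noise. Placement is reject-and-retry with disjoint
(clearance-padded) bounding boxes, bounded at 1000 tries, so ground truth is
unambiguous. Default random cells use semi-axes of 6–12 μm — the scale of
cultured astrocyte somatic domains; at the 0.6 μm-class voxel pitch used in
the recovery scenarios, substantially smaller bodies would push the
±1-voxel range quantisation past a 10% aspect-ratio error, i.e. the limit
is resolution, not the pipeline. Truth records carry exact analytic
volumes (`4/3·πabc`), ranges (2× semi-axes) and centroids. Not emulated:
realistic PSFs beyond Gaussian blur, GFAP filament texture, touching cells,
camera-specific noise.

**Calcium movies and traces.** Transients follow
`A·(1 − e^{−Δ/τ_r})·e^{−Δ/τ_d}` (zero before onset; closed-form peak at
`Δ* = τ_r ln(1 + τ_d/τ_r)`), riding on per-cell baselines with optional
exponential bleach and Gaussian noise. Movie defaults keep the target
acquisition's 10 Hz × 5 min; the frame is a spatially reduced field
(256 px at 5.2 μm/px spans the same ≈ 1.33 mm as 2048 px at 0.65 μm/px)
since trace analysis is indifferent to the pixel grid once ROIs are placed.
Default random events model rare spontaneous large-scale transients: 1–2
per cell, ≥ 150 s apart, τ_r ∈ [1.0, 1.3] s, τ_d ∈ [3.0, 4.5] s, onsets
≥ 40 s clear of the record end. These defaults are deliberately inside the
regime where the 0.01–1 Hz band passes the events (peak loss ≤ 20%,
A = 0.3 still clears the 0.1 threshold); see §2 for why slower decays or
close event pairs necessarily violate that budget. Not emulated: somatic
vs process microdomains, wave propagation, dye bleaching heterogeneity,
motion.

**Viability fields.** Disk-shaped nuclei with a minimum separation
(reject-and-retry), a random dead subset marked in the dead channel, wider
cytoplasmic disks for live cells, optional blur and noise. Not emulated:
intensity gradients, partial staining, confluent monolayers.

Passing tests on these inputs demonstrates that the computational chain is
correct and self-consistent under known ground truth; it does not establish
performance on real micrographs, whose segmentation difficulty (touching
cells, uneven illumination, debris) the generators intentionally omit.

## 6. Problem sizes and determinism

Every generator is bit-reproducible from spec + seed
(`numpy.random.default_rng`). The test and acceptance scenarios use sizes
chosen to exercise each stage fully at desk scale: 5-cell stacks of
72×240×240 voxels at 0.62 μm pitch for morphometry recovery, 100 seeded
3000-frame traces for detection calibration (Gaussian noise sd 0.02 ΔF/F),
three 640-px viability fields of 100 cells, and 10⁴ null replicates for
the statistical calibration. Under noise, per-event bounds (amplitude
within 20%, onset within 3 frames) are asserted as rates (≥ 95% of events),
matching the rate form of the recall/precision requirements: a max-type
bound over hundreds of noisy events is violated with probability
approaching 1 as the event count grows even when each event individually
meets the bound with high probability. Zero-noise recovery is asserted
event-for-event at max.

## 7. Known limitations

- The morphometry "unit" system ties physical interpretation to
  `unit_to_um`; stacks whose pitch differs from the assumed 0.155 μm native
  pitch (0.62 μm after 4× down-sampling) need `unit_to_um` set accordingly.
- The background-referenced ΔF/F₀ makes amplitudes depend on mask quality
  and cell density (through the background mean), unlike per-ROI baselines.
- Solidity's corner-point hull overshoots for smooth bodies at coarse
  resolution (§1); comparisons are meaningful within a fixed pitch, not
  across pitches.
- The event detector assumes transients are positive-going and sparse;
  oscillatory or plateau activity would be merged or split by the
  zero-crossing logic.
- Grubbs assumes approximate normality per metric; heavy-tailed descriptor
  distributions (solidity, ramification) can over-flag.
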