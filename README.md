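# gliascope

Quantitative image analysis for astrocyte cultures: 3-D morphometry from
membrane/nucleus confocal stacks, calcium-transient detection from
fluorescence time lapses, live/dead viability counting, and the statistical
battery that compares treatment conditions — plus seeded synthetic-data
generators that emit every input with exact ground truth, so the whole chain
is testable end to end without microscope data.

It is aimed at the workflow used in nanomaterial-biocompatibility studies of
cultured astrocytes (e.g. dose–response exposure to 2-D nanomaterials), where
morphology, spontaneous somatic Ca²⁺ activity and viability are the three
read-outs.

## What it computes

**3-D morphometry** (`gliascope.morphology`). Membrane and nucleus channels
are normalised, blurred, thresholded (Otsu), block-down-sampled to a coarse
"unit" grid, and clustered into cells with DBSCAN; fragments below 50 units
(cells) or 5 units (nuclei) are discarded and nuclei are matched to host
cells. Five descriptors per cell:

- aspect ratio `AR = Y_range / X_range`
- circularity `C = 4πA/P²` of the ellipse fitted from the X/Y ranges
  (semi-axes `X, Y`), which reduces to `C = 2XY/(X² + Y²)`
- centroid distance `d = ‖r_cell − r_nucleus‖₂` (units and μm)
- solidity `S = V_hull / V_body ≥ 1` (convex-hull over voxel-cube corners)
- ramification `R = (P/A) / (2√(π/A))` of the maximum-area projection, with
  `P` from that projection's convex hull (`R = 1` for a disk)

QC removes cells without a nucleus, centroid distances beyond 100 units
(≈ 62 μm at 0.62 μm/unit), degenerate geometry, and per-metric iterative
Grubbs outliers.

**Calcium events** (`gliascope.calcium`). A cell mask from the
maximum-intensity projection (Otsu + dilation + hole filling + small-object
removal); per-ROI fluorescence from 5-pixel-radius disks around annotated
centres; `ΔF/F₀ = (F_t − F₀)/F₀` with `F₀` the mean background (outside-mask)
fluorescence at each time point; a 6th-order Butterworth low-pass (1 Hz) and
2nd-order high-pass (0.01 Hz), zero-phase; event detection by a fixed 0.1
threshold with zero-crossing extension and local-minimum boundary
refinement; kinetics (amplitude, AUC, duration, rise, decay) and the
proportion of active cells.

**Viability** (`gliascope.viability`). Total cells from the nucleus channel
(blur → Otsu → size filter → watershed splitting), dead cells from
colocalised dead-channel signal, and
`viability (%) = 100 · (total − dead) / total`.

**Statistics** (`gliascope.stats`). One-way ANOVA with Tukey's HSD,
two-tailed pooled-variance t-tests, two-sample Kolmogorov–Smirnov, and the
iterative two-sided Grubbs outlier test, with vectorized null-simulation
helpers for type-I-error calibration.

## Worked example

Simulate a 5-minute, 10 Hz recording of three cells (two of them active,
each with two spontaneous transients) and run the full analysis chain:

```python
import numpy as np
from gliascope import synthetic as s, calcium as c

rng = np.random.default_rng(0)
cells = [s.CalciumCellSpec(center_px=(x, y))
         for x, y in [(40.0, 40.0), (120.0, 40.0), (80.0, 120.0)]]
events = s.random_events(len(cells), rng, active_fraction=0.7)
spec = s.CalciumMovieSpec(frame_shape=(160, 160), cells=cells,
                          events=events, noise_sd=1.0, seed=0)
movie, truth, centers = s.generate_calcium_movie(spec)

traces, detected, summary = c.analyze_movie(movie, centers)
print(f"{summary.n_active}/{summary.n_rois} ROIs active "
      f"(proportion {summary.proportion_active:.2f})")
for e in detected:
    print(f"ROI {e.roi_id}: onset {e.onset_idx/10:.1f} s, "
          f"amplitude {e.amplitude:.2f} dF/F, "
          f"duration {e.duration_s:.1f} s, AUC {e.auc:.2f}")
```

prints

```
2/3 ROIs active (proportion 0.67)
ROI 0: onset 15.5 s, amplitude 0.63 dF/F, duration 11.0 s, AUC 3.04
ROI 0: onset 212.1 s, amplitude 2.25 dF/F, duration 11.6 s, AUC 11.54
ROI 2: onset 13.7 s, amplitude 2.33 dF/F, duration 11.2 s, AUC 11.52
ROI 2: onset 223.3 s, amplitude 2.08 dF/F, duration 10.0 s, AUC 9.18
```

All four true transients (onsets 15.4, 212.0, 13.5 and 223.2 s) are
recovered within ~1 frame, and the quiet ROI stays quiet. The amplitudes are
on the background-referenced ΔF/F₀ scale: with the generator's baseline
(100) and background (20), an event of unit waveform peak appears at
amplitude 5 (see `docs/methods.md`).

The same pattern works for the other stages (`morphology.analyze_stack`,
`viability.analyze_field`), and a thin CLI wraps them all:

```sh
gliascope simulate viability --spec via.yaml --seed 4 --out sim/
gliascope viability --in sim/field.tif --out counts.csv
gliascope morph --in stack.tif --config morph.yaml --out records.csv
gliascope calcium --movie mov.tif --centers centers.csv --out out/
gliascope stats --design design.yaml --out report.json
```

## Layout

```
src/gliascope/
  synthetic.py    seeded generators with analytic ground truth
  morphology.py   3-D segmentation + five shape descriptors + QC
  calcium.py      masks, ROI traces, dF/F, Butterworth band, events
  viability.py    live/dead counting and the viability percentage
  stats.py        ANOVA+Tukey, t, KS, Grubbs, calibration helpers
  io.py           TIFF/CSV/YAML round-trip with metadata sidecars
  cli.py          the `gliascope` umbrella command
docs/methods.md   models, parameter choices, numerical details
tests/            pytest suite incl. end-to-end acceptance checks
```
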