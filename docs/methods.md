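# Methods

## Imaging model and assumptions

The pipeline assumes one field of view captured as three co-registered 8-bit
images: bright-field (cells darker than the background), green fluorescence
(GF; fluorescein from FDA hydrolysis, live cells) and red fluorescence (RF;
propidium iodide, dead cells). Registration is the instrument's job; no
alignment is attempted. Colour inputs are reduced on load — fluorescence
images to their named RGB plane (no re-weighting), bright-field to grayscale
with ITU-R BT.601 weights (0.299, 0.587, 0.114), rounded to the nearest
integer. 16-bit TIFFs are linearly rescaled to 8-bit; all internal arithmetic
is on the 0–255 scale. Pixels are indexed (row, col), row-major.

## Segmentation

Each channel is first denoised with a 3×3 median filter (edge-replicated
borders). The median is chosen because single-pixel sensor noise is the
dominant artefact at yeast scale and the filter preserves the cell edge;
the same denoised images are used later for intensity measurement, so the
statistics that set the threshold and the intensities that drive
classification are read from the same data.

The global threshold is T = μ − α·σ for dark objects and T = μ + α·σ for
bright objects, where μ and σ are the mean and *population* (divide-by-MN)
standard deviation of the whole image and α defaults to 3. The mirrored
bright-object form is required because fluorescence channels have inverted
contrast relative to bright-field; α is the same constant in both. T is
clamped to [0, 255] so degenerate high-variance images still yield a valid
threshold, and the comparison is strict (I < T, I > T), so a constant image
produces an empty mask. On pure Gaussian noise, α = 3 marks ≈0.135% of
pixels (one-sided tail); those isolated pixels are removed by the median
filter or fall below the minimum-area gate.

The GF and RF binaries are combined by pixelwise union into the yeast
candidate mask: live cells are green-only and dead cells red-dominant, so an
intersection would discard nearly every cell. Components are extracted with
8-connectivity (matching contour-style detection); each carries area,
perimeter, centroid, bounding box, equivalent diameter 2·√(area/π) and
circularity 4π·area/perimeter², capped at 1.0 because rasterized disks can
overshoot; a single-pixel component (zero perimeter) is defined as round.
Touching cells merge into one component — no watershed or declumping is
attempted, so dense clumps undercount by design.

Otsu's histogram threshold is included only as a baseline: with very sparse
or dim foregrounds its between-class criterion is maximised inside the
background mode, and the shipped failure-mode test demonstrates this on a
0.1%-foreground field at amplitude 150 over the N(40, 5) background, where
Otsu's threshold lands at the background mean (false-positive area hundreds
of times the true foreground) while the Gaussian threshold keeps full
recall. At higher contrast (amplitude ≳200 with this noise level) Otsu can
still succeed on the same sparsity; the failure regime is sparse *and*
moderate-contrast, which is the practically relevant one.

## Classification

A four-rule cascade, first match wins: (1) geometry — area outside
[min_area_px, max_area_px] or circularity < 0.5 → debris; (2) unstained —
both fluorescence means below their signal floors → debris (bright-field
visible but non-fluorescent particles: hop, grape, rice flour); (3) mean
GF > mean RF → live; (4) otherwise dead. An exact GF/RF tie is dead: PI in
the cell means the membrane is compromised, and the conservative call is the
one that does not inflate viability.

Defaults, all overridable via `ClassifierConfig` (JSON-serialisable):

| parameter | default | rationale |
|---|---|---|
| α | 3 | sufficient separation of the Gaussian background tail |
| image scale | 0.6 μm/px | puts typical 3–8 μm yeast at 5–13 px diameter |
| min/max area | 9 / 218 px² | disks of 2 μm and 10 μm diameter at that scale |
| min circularity | 0.5 | yeast are near-circular; flour/hop debris irregular |
| GF/RF signal floors | per-frame μ + α·σ of that channel | reuses the threshold statistic instead of a new constant |
| bf_dark_contrast | 30 gray levels | deficit vs frame mean marking a real bright-field object |
| volume factor | 10⁶/437 cells·ml⁻¹ per count | reference pairing of 437 counted cells ≡ 1×10⁶ cells/ml |

The max-area gate is deliberately generous relative to the nominal cell
size: segmentation footprints of bright cells extend 1–2 px beyond the
geometric disk (defocus blur crossing the threshold), and a gate tuned to
the bare disk area silently reclassifies large cells as debris.

Because debris is defined by *absence* of fluorescence, purely bright-field
objects never enter the fluorescence candidate mask. The pipeline therefore
additionally scans the thresholded bright-field image for dark components
that overlap no candidate pixel, exceed the minimum area and are at least
`bf_dark_contrast` below the frame's mean gray; these are reported as debris
with rule tag `bf_only`. This scan is an extension of the candidate-mask
design and is logged on every run so its contribution is auditable.

## Bright-field size refinement

Fluorescence footprints scale with exposure and stain uptake; the dark cell
body in bright-field does not. `size_from_brightfield` re-thresholds the
bright-field channel inside the object's bounding box (padded by 2 px to
capture the cell-wall ring) using the *frame-global* dark-object threshold —
a per-box histogram would be unstable on tiny crops — and returns the area
of the dark component under the object's centroid (largest-overlap component
if the centroid pixel is not dark; fluorescence-mask area if nothing dark
overlaps). The area is the exported size; the equivalent diameter is
exported alongside since either convention is in use.

## Quantification

Viability is 100·live/(live+dead); debris never enter cell totals. An empty
frame has no defined viability and is reported as missing with a warning,
never as 0% or 100%. Concentration is count × volume factor, an explicit
instrument-calibration input. Replicate CV uses the sample (n−1) standard
deviation over the mean — the statistical convention for replicate
dispersion. The viability calibration is an ordinary least-squares line of
measured against theoretical viability with R² the squared Pearson
correlation; it requires ≥3 points and a non-degenerate design.

## Synthetic scenes

The generator emulates the assay's signal structure, not its optics: cells
are hard-edged disks (radius uniform in 4–6 px by default, i.e. ~5–7 μm at
the default scale) softened by a fixed σ = 1 px Gaussian blur standing in
for slight defocus; live cells add 180 intensity levels to the GF channel
(with a 10-level red bleed), dead cells 170 to RF (10-level green bleed);
both fluorescence channels sit on a mean-40 ambient background; bright-field
is a 200-level background with every cell 60 levels darker; debris are spiky
random polygons darkened in bright-field only. i.i.d. Gaussian noise
(σ = 5 by default) is added per channel before clipping to [0, 255].
Objects are placed by rejection sampling with a guaranteed 4 px gap, so
ground-truth counts are exact and components never touch; an infeasible
packing raises an error naming the attempted density. One integer seed
drives everything; per-frame seeds in a series derive from the master seed
by a fixed affine map (kept below 2³¹).

An optional staining-kinetics factor scales the live-cell green amplitude
with FDA incubation time as k(t) = 1 − exp(−t·ln 20/10): zero added signal
at t = 0 and ≥95% of the plateau at the recommended 10-minute incubation.
The exponential form is a documented stand-in for the qualitative
fast-rise-then-plateau behaviour, used only by the generator — nothing is
fitted to it.

What passing on these scenes does **not** show: robustness to illumination
gradients, optical point-spread functions, photobleaching, budding or
clumped cells, or out-of-focus debris — none of which the generator
produces. Results on synthetic fields bound what the arithmetic of the
pipeline can do, not what a specific instrument will achieve. One visible
artefact of the noise model: at extreme viabilities the nearly-empty
fluorescence channel has a low threshold, and a handful of pixel-scale noise
fragments enter the candidate mask; they are gated into the debris class by
area and never perturb the live/dead totals, but absolute debris counts on
noisy scenes are approximate.

## Benchmark problem sizes

The shipped benchmarks use 1024×1024 px frames with 400 cells/frame
(viability calibration, levels 0/25/50/75/100%) and 500 cells/frame
(counting stability), the largest sizes at which the full five-frame series
stays comfortably interactive; counts at these densities (≈5% area coverage)
are placement-feasible with large margin. Property suites run on 320–640 px
frames with 30–100 cells, 100 seeds where a rate is asserted.
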