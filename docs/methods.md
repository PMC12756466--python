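# Methods

## Pipeline model

The package reimplements a two-stage particle-analysis workflow for
fluorescence images of spheroid cultures bearing surface neurospheres.
All analysis is 2-D, single-plane, and operates on 8-bit arbitrary units
(16-bit input is mapped linearly onto [0, 255] with round-half-up).

**Neurosphere stage** (pan-neuronal channel): invert → inclusive intensity
window → binary closing-then-opening with one disk element → watershed on the
negated Euclidean distance transform → particle gate. The closing-then-opening
order is a deliberate choice: closing first consolidates a neurosphere's
speckled stain into one blob, the subsequent opening removes sub-element
debris. The element radius defaults to 25 px (midpoint of the plausible
20–30 px range). The post-inversion window defaults to [0, 200]
(i.e. original intensity ≥ 55 a.u.); this value is not prescribed anywhere
and is exposed in config.

**Nucleus stage** (DAPI, within each ROI): rolling background subtraction
(30 px) → threshold → median filter (1 px disk, i.e. the 5-pixel plus
neighborhood, borders edge-replicated) → watershed → gate. The stage's
threshold window [0, 13] a.u. is interpreted as *delimiting the residual
background* of the background-subtracted image; the foreground is its
complement (pixels > 13 a.u.). The polarity is recorded explicitly in config
(`window_selects: background`) because the alternative reading — inverting
first and windowing the dark nuclei — would require near-saturated nuclei
and cannot be reconciled with a dark-background subtracted image.

**Rolling background** is implemented as grayscale opening with a disk of
the stated radius (white top-hat residual), using a decomposed ("sequence")
footprint that differs from the exact disk opening by at most 1 a.u. while
running in near-linear time. The operator is anti-extensive and removes any
structure wider than the element; it is not the paraboloid sliding-ball
estimator, and no bit-parity with any particular program is claimed — all
validation is parameter recovery on synthetic ground truth.

**Watershed seeding**: local maxima of the distance transform separated by at
least `min_distance` px (5 px for nuclei, 50 px for neurospheres, both in
config). Components that receive no seed are seeded at their deepest pixel,
so every foreground pixel gets exactly one label; seed labels are assigned in
(row, col) order and label propagation uses 8-connectivity, making label
images deterministic and consistent with the 8-connected component
convention. A pixel equidistant to two seeds goes to the seed reached first
in this fixed order.

**Geometry**: particle area is the pixel count; the perimeter is the Crofton
estimate over 4 directions; circularity is 4π·A/P² capped at 1.0. Crofton was
chosen because marching-squares contour length overestimates disk perimeters
by ~8% (pushing a radius-25 disk to circularity 0.89) and raw pixel-edge
counting is worse; under Crofton, rasterized disks of radius 10–50 score
0.94–1.00, so the printed circularity gates select what they name. Gate
bounds are inclusive on both ends, matching the printed closed intervals.

**ROI membership**: a nucleus belongs to a neurosphere iff its centroid lies
inside the ROI mask — unambiguous for nuclei straddling a ROI edge.
Segmentation runs on a margin-expanded bounding box (3× the rolling radius)
so edge nuclei keep their true geometry. Particles touching the image border
are retained. Manual ROIs travel in a plain-text polygon format with an
include/exclude flag per entry, standing in for interactive review;
rasterization uses the pixel-center-inside rule.

**Classification**: per-marker mean intensity over the nucleus mask, on
channels that are 8-bit-converted and background-subtracted (toggle
`markers.subtract_background`, default true — stated for the multichannel
design and applied uniformly for consistent intensity semantics). Positivity
is strict (`mean > t`); defaults t = 10 a.u. (HU, green, far-red) and
30 a.u. (red). Strictness generalizes the single-marker ">10 a.u." rule.

**Migration**: emigrated particles are segmented with the nucleus-stage
primitives outside the spheroid mask; each particle contributes its pixel
farthest from the spheroid border (ties break to the smallest (row, col)),
so neurite tips rather than centroids terminate the measurement. A point's
border distance is the exact minimum Euclidean distance to any boundary
pixel; boundary points themselves count as external with distance 0. The
read-out is the five largest distances, sorted descending — "longest
projections / most distant cells" reduce to the same border-to-point
distance, distinguished only by a metric label. Distances are in pixels; no
micron calibration is applied unless a scale factor is supplied.

**Statistics**: Kruskal–Wallis (mid-rank ties; H = 0, p = 1 for degenerate
all-identical input) or one-way ANOVA as omnibus; Dunn's rank-based z tests
(pooled mid-ranks, tie-corrected variance), Tukey HSD, or Mann–Whitney
(exact enumeration when both n ≤ 8 and there are no ties, otherwise the
tie-corrected normal approximation) as pairwise tests; all two-sided. Holm
step-down adjustment is applied within each pairwise family, not across
metrics. Which metric gets which test is explicit configuration, not
automatic normality testing — reproducibility over convenience.

## Synthetic ground truth

The generator renders what the analysis assumes: spheroid disks on the
pan-neuronal channel (default intensity 80 a.u.), hard-disk nuclei
(DAPI 200 a.u.) packed by bounded rejection sampling inside each spheroid,
and per-nucleus marker disks at `mu_pos`/`mu_neg` (defaults 120/5 a.u.)
drawn either independently per marker or from a full joint sign table.
Background is flat (4 a.u.) with additive Gaussian noise (σ = 4 a.u.,
a realistic dark confocal floor; the default nucleus contrast of ~49σ far
exceeds the ≥5σ regime the recovery checks target), clipped to [0, 255].
One `numpy` `default_rng` seed drives every draw, so stacks and truth are
bit-reproducible.

`min_separation` is the *edge-to-edge* gap between nuclei (centroid distance
≥ r_i + r_j + gap, default 2 px): with hard disks this makes planted counts
recoverable at any positive gap, whereas a 2 px centroid separation would be
near-total overlap and no counting method could be benchmarked against it.
Default nucleus radii are 3.0–4.5 px and spheroid radii 105–120 px: the
neurosphere gate caps usable spheroids at 50,000 px² (radius ≈ 126 px), and
at the default gap up to 200 nuclei per spheroid then occupy ≈ 41% of the
spheroid — comfortably below random-sequential-addition saturation, so
packing terminates. Larger nuclei at these densities would not fit any
gate-passing spheroid.

What the generator deliberately omits: optics (PSF blur, depth effects),
Poisson shot noise, intensity gradients, nucleus shape variation, and
tissue-section geometry. Passing recovery tests therefore demonstrates the
correctness of the measurement chain under its own assumptions — not
robustness to out-of-focus light, touching irregular nuclei, or staining
artifacts in real sections, where the manual-review step and per-stage
thresholds carry more weight.

Migration fields place cells at given radial offsets from the spheroid
border at evenly spaced, jittered angles (guaranteeing non-overlap for
realistic counts); the planted distance of a cell is computed from the
rasterized geometry with the same boundary definition the measurement uses,
so the ±1 px recovery check isolates pipeline error from rasterization.

Stage presets (`e8`, `e12`, `d0`) encode a declining green⁺red⁺
(PHOX2B⁺SOX10⁺) joint fraction (0.60 → 0.30 → 0.05) with falling far-red
(EdU) labeling (0.35 → 0.25 → 0.10). These are illustrative defaults for
demonstrations and tests, not measurements.

## Numerical conventions and edge cases

- Inclusive threshold windows; disjoint windows partition [0, 255].
- 8-bit conversion rounds half up; 8-bit input is returned unchanged.
- Empty record sets summarize to `n_nuclei = 0` with proportions flagged
  `None` (written as `NA`), never 0 or NaN.
- CSV floats are written in shortest round-trip plain-decimal form, so
  re-parsing reproduces counts and proportions exactly; reruns with the same
  config, inputs and seed are byte-identical.
- Config parsing rejects unknown keys and out-of-range values
  (thresholds within [0, 255], ordered gate bounds); an empty config file
  yields exactly the published defaults.
- Fewer than five points outside a spheroid is an error naming the count;
  an ROI built from an empty mask is an error.

## Problem sizes

Default validation uses 512×768 px fields with two spheroids of 50–200
nuclei each (count recovery, seeds 1–10), 256×320 px single-spheroid fields
with 100 nuclei (classification, seeds 1–10), a 1,000-nucleus field for the
co-expression binomial check, and 10,000 null replicates (3 groups, n = 12)
for the type-I calibration of the omnibus test. These sizes give tight
binomial/empirical intervals while keeping the full suite around a minute.

## Known limitations

- The rolling-background stand-in (morphological opening) flattens any
  plateau wider than the element; very large, uniformly bright nuclei
  clusters could lose interior signal. Not triggered at the default radii.
- Watershed over-splitting of highly elongated objects is possible; the
  seed `min_distance` is the only guard.
- Dunn's test uses the normal approximation; very small groups (< 4) get
  conservative p-values.
- Migration measurement assumes a single connected spheroid mask; multiple
  spheroids per field must be measured one mask at a time.
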