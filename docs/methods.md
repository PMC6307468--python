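# Methods

This note documents the models, parameter choices, and numerical decisions
behind `cablemorph`, and what the synthetic benchmarks do and do not show
about real data.

## Geometric estimators

All cross-section estimators reduce a deformed filament to its perimeter
`P`, the one quantity robust to preparation-induced shape change, and derive
`δ_R = P/N_R` and `d_ESD = P/π` from it.  Two cross-section models are
supported and nothing more general: a full ellipse of width `W` and
flattening `ε` (embedded/SEM-style material) and a half-ellipse of width `W`
and height `H` with `ε = 2H/W` plus a flat base (air-dried material adhering
to the substrate).  The ellipse perimeter uses Ramanujan's second
approximation.  Its relative error against adaptive quadrature of the
elliptic arc-length integral is below 10⁻⁵ for `ε ≥ 0.2` and peaks at
4×10⁻⁴ in the degenerate flat limit (`P = 1.99920·W` against the true
ribbon perimeter `2W`) — negligible against measurement noise, and the
reason the flat limit is conventionally quoted as `P ≈ 2W`.

Degenerate `ε` of exactly 0 or 1 are allowed (the closed form is exact at
both ends); no epsilon clipping is applied.  For SEM-style input the
flattening must be judged from image context, so `EllipseSpec` takes a
per-filament `ε`; when omitted the filament is assumed round (`ε = 1`) and
a warning is logged rather than inventing an estimator.

Internally every length is a nanometer; public entry points take an
explicit unit tag (`nm`/`um`) because envelope derivations routinely mix
micrometer perimeters with nanometer widths.  Derived values are kept at
full precision; rounding (3 significant figures) happens only at the
reporting layer.

Two distinct "ridge width" notions exist and are never conflated: the
perimeter share `δ_R = P/N_R` (section-based) and the AFM valley-to-valley
distance across one ridge.  On air-dried filaments the latter is smaller
(shrinkage); measurement records store the two under separate names.

## Envelope model

A filament is `n_cells` cells of length `L`; junction planes sit at
`z = 0, L, …, n_cells·L` (both ends are junctions).  The mid-cell envelope
is a circle of perimeter `N_R·δ_R`, carrying `N_R` half-circular ridge
compartments on its outside; fiber `k` occupies compartment `k` in every
section, making fibers identically indexable along the filament.

Construction choices where the geometry is genuinely open:

* **Compartment chord.**  Half-circles with chord exactly `δ_R` would be
  mutually tangent (their centers sit closer than `δ_R` apart on the
  circle), merging all compartments into one connected raster region.
  Compartments therefore use chord `δ_R − valley_gap` (default gap 20 nm,
  configurable), consistent with the ~30 nm valleys that separate ridges on
  extracted filaments.
* **Bulb ring.**  Junction bulbs sit tangent to the envelope circle from
  the inside (center radius `R − δ_B/2`).  Some measured parameter sets
  (16 ridges, 111 nm bulbs on a 2.0 µm perimeter) cannot host that ring —
  neighbors would overlap — so the ring is widened to the mutually tangent
  radius `δ_B / (2 sin(π/N_R))`; a packing error is raised only when even
  that exceeds the envelope radius, or when fibers cannot fit inside a
  compartment.
* **Spoke tree.**  Stalks merge pairwise inward (balanced binary merging;
  an odd branch is carried to the next level), each parent at the scaled
  midpoint of its children, and the surviving root connects to the central
  node at the section centroid.  The tree is connected and acyclic with one
  leaf per bulb by construction; no merge schedule is implied by the
  imagery, so the balanced deterministic one is used.
* **Junction axial extent** defaults to `δ_B` (half-width), configurable —
  the cartwheel's axial thickness is visible but not quantified.
* **Lining thickness** is a single configurable width (default 10 nm),
  rendered but not measured.

The area-conservation report divides the bulb area `π(δ_B/2)²` by the
mid-cell compartment area — the measured `ridge_area` when the
parameterization carries one, else the geometric half-disc area.  Ratios
near 1 express that a compartment carries the same periplasmic material in
both shapes.

## Synthetic imagery

The generator emulates the two quantitative modalities, with the study
conditions as defaults.

**AFM height maps.**  An air-dried filament deflates into a half-ellipse
whose aspect `H/W` is the thick-filament value 0.87/3.71 by default.  The
absolute scale follows from perimeter conservation of the shrunken
envelope: air-drying shrinks the perimeter by a class-specific factor
(0.63 thick, 0.567 thin, 0.853 extracted — the ratio of the air-dried to
the embedded perimeter for each class), and `W` solves
`half_ellipse_perimeter(W, H) = shrink · N_R·δ_R` (closed form, the
perimeter being linear in `W` at fixed aspect).  Junctions resist
deflation: 30 % higher and 11 % narrower than mid-cell by default
(extracted filaments: 320/120 ≈ 2.67× higher), blended over twice the
junction half-width by a raised-cosine weight.  Ridge corrugation is a
raised cosine with crest-to-crest spacing `shrink·δ_R` and 30 nm valleys
(the observed valley depth), amplitude-tapered toward the filament edges so
valleys never undercut the substrate.  Noise is additive i.i.d. Gaussian on
heights, default SD 5 nm (no noise characterization exists for the real
instrument; 5 nm is conservative for peak-force AFM on mica), seeded;
heights are clipped at the substrate plane (0).  The filament lies along
the raster rows, optionally rotated in-plane; rasters are 32-bit float TIFF
(nm) with a JSON sidecar carrying pixel size, parameters, seed, and the
ground-truth block.  Rendering is analytic point sampling at pixel centers
— no tip convolution, no scan-line artifacts.

**Section images.**  Transverse sections are rasterized from the model
geometry into an exact integer label raster (background, cytoplasm,
compartment lining, fiber/bulb core, bulb, spoke) and an idealized
intensity raster (stained material dark: lining/spokes 0.15, bulbs 0.20;
cytoplasm 0.55; unstained cores 0.75; resin 0.85; Gaussian noise SD 0.02).
Compartments are painted strictly outside the envelope circle so the cell
body remains an exact disk.  Pixel size must resolve stalks (`≤ δ_S/3`);
the AFM pixel size must resolve the corrugation (`≤` spacing/4), both
enforced with explicit errors.

**Fixture suite.**  Two filaments per class — thick (61/58 ridges of
205/213 nm), thin (15/16 of 231/126 nm), extracted (62/52 of 120/140 nm) —
with per-class deflation conditions, three cells each by default; a truth
CSV holds one row per (filament, cell).  All randomness derives from one
top-level seed via seed-sequence spawning.

Passing recovery tests on these fixtures shows the measurement chain is
unbiased on idealized geometry at realistic dimensions and noise; it does
not validate against tip-sample convolution, drift, stain variability, or
segmentation of real backscatter contrast.

## Measurement pipeline

* **Substrate and threshold.**  A least-squares plane over the border
  pixels estimates the substrate; the filament threshold is 3 noise-SDs
  above it (floor 1 nm for noise-free data).  Because stored heights are
  clipped at zero, the border SD is corrected by the half-normal factor
  0.5838 when clipping is detected.
* **Profiles.**  Transverse profiles are lightly smoothed (3-pixel uniform
  filter); `W` spans the longest contiguous above-threshold run, `H` is the
  run maximum.  Valleys are prominence-filtered local minima (default 10 nm,
  one third of the valley depth) with parabolic sub-pixel refinement.  The
  mean valley spacing is consolidated harmonically — each spacing is read
  as an integer multiple of the base spacing (`Σdᵢ/Σkᵢ`) — so valleys
  missed near the tapered filament edges do not bias the estimate.
* **Junctions.**  Axial height and width profiles are moving-averaged
  (250 nm window); junctions are height maxima (prominence 20 nm, minimum
  spacing 1 µm) that coincide with a width minimum within twice the window.
  Filaments without such coincident extrema fall back to a single cell with
  a warning.  Cell length is the mean junction spacing.  Maps are
  auto-rotated to axis-along-columns from the mask's second moments when
  the estimated tilt exceeds 0.5°.
* **Per-cell chain.**  Mid-cell `W1/H1` and junction `W2/H2` feed
  `P = half_ellipse_perimeter(W1, H1)` and `d_ESD = P/π`; the stored record
  recomputes `d_ESD` from the stored `P` so the identity holds to machine
  precision.
* **Sections.**  Counting uses the labeled compartment regions
  (lining ∪ core, or bulbs at a junction), splitting point-tangent
  neighbors by iterative erosion and taking the maximum stable component
  count — safe because the regions are convex; erosion stops before blobs
  fragment (median area < 9 px).  The envelope perimeter is the sub-pixel
  contour of the filled cell body, moving-averaged to remove the
  marching-squares staircase (which otherwise inflates lengths ~5 %);
  outlines truncated at the image border are extrapolated via a Kasa circle
  fit and `P = L·2π/θ`, with a warning below 10 % visibility.  Bulb and
  core diameters are equivalent-circle diameters (total-area/count when
  bulbs touch); the stalk width is twice the median medial-axis half-width
  of the spoke mask — a deliberate simplification of caliper measurement
  that runs ~5 % high where spokes overlap at merge nodes.  An
  intensity-only fallback (three-class Otsu) supports mid-cell counting;
  junction cartwheels are too interconnected for it and require labels.
* **Statistics.**  Summaries report mean, sample SD (n−1), and N per group;
  a single record reports SD as missing.  Group comparison is a Welch
  two-sample t-test with raw two-sided p-values (a single planned
  comparison; no multiplicity correction), with the zero-variance
  degenerate case resolved directly.

## Printed-table recomputation

The published tables flag `δ_R`, `d_ESD`, `A_B`, and the AFM `P` as
calculated from other parameters.  `reproduce_printed_derivations`
recomputes each from the printed raw inputs.  Pass rule: the interval
obtained by propagating half a printed unit-in-the-last-place of each input
must overlap the printed output's half-ulp interval, or the relative error
must fall below the tolerance (default 1 %); zero tolerance demands exact
equality and fails on rounding, by design.  The AFM perimeter chain on the
printed mean `W`, `H` is reported unchecked: the printed value is a mean of
per-filament perimeters, and a mean of ratios is not the ratio of means
(3.6 % apart for the thick class).

## Problem sizes

Default fixtures use three cells per filament, pixel sizes of 20/10/12 nm
for thick/thin/extracted AFM maps (set by the corrugation-sampling rule)
and 12 nm for sections, giving rasters of roughly 150×750 px and the full
demo a few seconds of runtime; recovery is additionally exercised over ten
seeds at default noise.  Accuracy at these sizes: noise-free recovery
within ~3 % for widths/heights/spacings (5 % bound), exact ridge counts,
δ_B within 0.5 %; under 5 nm noise everything stays within ~7 % (10 %
bound).

## Known limitations

* Rendering is geometric: no AFM tip convolution (real widths run wider by
  the tip radius), no beam/stain physics, idealized contrast.
* The corrugation shape on intact filaments is not quantified anywhere;
  the raised cosine is a modeling choice, flagged in fixture metadata.
* The spoke-width estimator biases ~5 % high; caliper-style measurement
  perpendicular to local orientation would remove this at the cost of
  fragility on merged masks.
* Erosion-based splitting assumes convex compartments/bulbs; it would
  over-split strongly non-convex regions in real segmentations.
* `N_R = 2·N_obs` (one-sided surface counting) is exposed in the geometry
  layer, but no surface-SEM modality is synthesized.
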