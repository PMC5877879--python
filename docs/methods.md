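# Methods

This note records the model behind `famorph`, the conventions the
implementation fixes where the underlying method leaves choices open,
the design of the synthetic validation data, and known limits. It
states nothing the test suite or `scripts/acceptance.py` does not
itself compute.

## Pipeline model

The pipeline assumes three registered single-plane grayscale images —
actin (cell body), DAPI (nucleus), vinculin or another adhesion marker
(FA) — sharing one µm/px calibration. All size thresholds are stored in
micrometres and converted to pixels at run time, so the same
configuration applies across objectives; the calibration is always
supplied by the user (there is no safe default).

Cell and nucleus segmentation is marker-controlled watershed on the
Euclidean distance transform of the Otsu foreground. The watershed is
seeded with the h-maxima of the distance map: regional maxima whose
prominence is below `h` are merged away, so `h` trades over-segmentation
(splitting one cell) against under-segmentation (merging touching
cells). `h` is a property of the imaging setting — magnification, cell
type, edge raggedness — and must be re-tuned per dataset; the default
is 3 px, which is correct for the synthetic study conditions below.

Adhesion detection must first remove the diffuse cytosolic pool of the
marker protein. The white top-hat with an 80 px disk removes every
structure the disk fits inside (the cytosol-filled cell body, uneven
illumination); subtracting a median-filtered background (window 4 µm,
the width of the largest adhesions) removes the residual; Otsu plus
8-connected components then indexes individual adhesions. Objects
smaller than 0.1 µm² are counted as noise, objects with Feret diameter
above 30 µm as non-adhesion staining artifacts. Touching adhesions
that merge into one thresholded component are **not** split — there is
deliberately no shape-based post-splitting step.

### Tunable parameters

| parameter | default | unit | meaning |
|---|---|---|---|
| `h_marker_suppression` | 3 | px | prominence floor for watershed seeds; per-dataset |
| `min_cell_area_um2` | 20 | µm² | below this an object is not a single cell |
| `min_fa_area_um2` | 0.1 | µm² | below this an adhesion detection is noise |
| `max_fa_length_um` | 30 | µm | above this Feret length a structure is an artifact |
| `fa_tophat_disk_diameter_px` | 80 | px | disk for vinculin-channel top-hat |
| `fa_median_kernel_um` | 4 | µm | median window = width of the largest adhesions |
| `closing_radius_px` | 1 | px | box closing is (2r+1)×(2r+1) |
| `cell/nucleus_tophat_disk_diameter_px` | 80 | px | per-channel top-hat disks; must exceed the objects' minor width |
| `maturation_bins_um` | (2, 6) | µm | nascent / mature / supermature breakpoints |

## Conventions fixed by this implementation

* **Closing element.** The closing after hole filling uses a 3×3 box
  (r = 1). A 1×1 closing would be the identity and make the step
  pointless; the element size is configurable.
* **Connectivity.** 8-connectivity for foreground components and
  regional maxima, 4-connectivity for background (hole definition) —
  the standard dual pair.
* **Otsu.** 256 uniform bins over [0, 1] after affine rescaling; the
  threshold is the upper edge of the argmax bin (ties to the lowest
  bin); foreground is strictly `> t*`. Constant images are an error.
* **Markers.** The h-maxima transform is implemented as regional maxima
  of the grayscale reconstruction of (D − h) under D. Thresholding the
  reconstruction *residue* at h instead (a common shortcut) marks
  equal-height twin peaks above a shallow saddle as two separate seeds
  — precisely the discrete shape of an ellipse's distance ridge — and
  systematically splits elongated cells; the reconstruction-maxima form
  merges them into one plateau.
* **Watershed.** Flooded on −D, restricted to the mask, no watershed
  lines: regions exactly partition the foreground (8-connected), ties
  resolved deterministically by flooding order. The image frame counts
  as background for D.
* **Top-hat boundary.** The world outside the frame counts as the
  darkest observed background (image minimum). Reflective or +inf
  padding lets a half-disk "fit" inside a frame-clipped cell, flattening
  its border-adjacent part and leaving an interior fragment that the
  border-exclusion rule cannot see; with outside = dark, border-clipped
  objects survive the top-hat whole and are then removed whole. The
  disk erosion/dilation is computed exactly by decomposing the disk
  {(dx,dy): dx²+dy² ≤ (d/2)²} into horizontal runs and combining 1-D
  min/max filters — orders of magnitude faster than a naive 2-D
  footprint at d = 80 and bit-identical to it.
* **Median window.** Physical size is converted to the nearest odd
  pixel count ≥ 3 (ties upward) so the window is centred; reflect
  boundary; negative values after subtraction clamp to 0.
* **Exclusion boundaries.** All "smaller than" rules are strict: an
  object exactly at 20 µm², 0.1 µm² or 30 µm is kept. Maturation bins
  are left-closed: a 2.0 µm adhesion is mature, a 6.0 µm one
  supermature. The 30 µm cap runs before classification.
* **Orientation.** 0° is the image x-axis, angles increase toward +y
  (row direction), reported in [0°, 180°). The ellipse fit uses second
  central moments of pixel centres; axis lengths are 4·sqrt(eigenvalue),
  which equals the full axis length for a solid ellipse. A perfectly
  isotropic region reports orientation 0 by convention; collinear
  regions report a capped sentinel aspect ratio (10³).
* **Length vs Feret.** `length_um` is the moment-ellipse major-axis
  length; `feret_um` is the maximum distance between pixel centres
  (single pixel → 0). Both are emitted; maturation uses `length_um`.
* **Perimeter.** Weighted-step boundary estimate (exact on axis-aligned
  edges; diagonal steps carry √2-type weights, a 10×10 square gives
  36 px), with an isolated pixel counted as its 4 sides. It is biased
  on diagonal boundaries like every local estimator.
* **ROI.** Simple polygons only; an adhesion belongs to the ROI iff its
  centroid is covered by the polygon, boundary inclusive; each
  exclusion is logged.
* **Pairing.** A cell claimed by zero or several nuclei remains in the
  cell table with nucleus-dependent features missing; such nuclei and
  nuclei outside every cell are reported as unassigned.

## Synthetic study conditions

The generator emulates the target imagery at a 40×-objective-like
calibration of 0.25 µm/px: spindle-shaped cells 28–48 µm × 12–19 µm
(widths stay below the 80 px top-hat disk so whole cells survive
background suppression), nuclei 14–22 µm × 8–12 µm at the cell centre
(DAPI intensity 0.75–0.95, distinctly brighter than the actin channel),
30–60 adhesions per cell of length 0.6–7 µm placed in the cell
periphery, diffuse cytosolic vinculin at 0.15, background 0.1, optional
linear illumination gradient, additive Gaussian noise of sd 0.05 (5% of
the dynamic range), all clipped to [0, 1]. One seeded generator per
scene makes everything bit-reproducible. Rasterization is pixel-centre-
in-ellipse; soft edges (1 px linear ramp) exist but default off so
noiseless masks are exact oracles.

Two size choices matter and were made once, for realism: nuclei use
absolute (not cell-proportional) dimensions typical of spread
fibroblasts, and adhesions number in the dozens per cell. Both keep the
bright class of each channel above roughly half a percent of the frame
even in sparse five-cell fields — below that, a global Otsu threshold
genuinely flips to splitting the background noise mode (its known
small-class failure), which is a property of the method, not of the
implementation, and is equally visible on real sparse fields.

What passing these tests does **not** show about real data: no
point-spread function, no intensity heterogeneity inside objects, no
stress fibres or protrusions in the actin channel, no photobleaching,
and touching cells occur only as clean two-ellipse overlaps. Recovery
rates on real micrographs will be lower and h will need retuning.

## Validation design and measured limits

The validation suite (tests and `scripts/acceptance.py`) checks
properties, not biology: oracle equivalence of the Otsu search,
parameter recovery on rasterized ellipses, ≥95% cell recovery at
IoU ≥ 0.8 with correct nucleus pairing on twenty noisy 1024² scenes,
100% exclusion of border-touching cells, existence of an h that splits
seeded dumbbell pairs plus monotonicity of the marker count in h,
exact agreement of the adhesion exclusion rules with brute-force
counts, byte-level determinism, and feature invariance under
translation and 90° rotation. The acceptance script runs the same
computations at reduced scene counts (6 segmentation scenes, 6
dumbbells) to keep its runtime near half a minute; the test suite runs
the full counts.

Two rasterization limits are documented rather than hidden:

* The orientation of a near-circular rasterized ellipse is not
  measurable — the quantity itself degenerates as aspect → 1, and below
  roughly 21 px major axis the lattice jitter on the second moments
  exceeds 2° even for moderately elongated shapes. The ellipse-recovery
  fixture therefore uses clearly anisotropic ellipses (minor ≤ 0.75 ×
  major, major ≥ 24 px), where the measured worst-case error is ≈1.4°.
* A pixel-centre Feret length under-reads the analytic maximum chord of
  a high-aspect ellipse by up to ≈1.7 px, because centre-in
  rasterization truncates the pointed tips; the mean error is ≈0.5 px.
  This is a property of the lattice, not of the measurement — the
  measured Feret equals the exhaustive max-pair oracle exactly — and
  the corresponding 1 px acceptance assertion is left failing by
  design with this explanation attached.

## Known limitations

* Confluent monolayers cannot be segmented: intensity variation along
  touching cell boundaries is too small for distance-based markers, and
  over-segmentation results. A membrane stain would be needed.
* Adhesions merged into one thresholded component stay one object.
* Global Otsu misbehaves when the bright class occupies ≲0.5% of the
  frame (sparse fields at low magnification); crop or use an ROI.
* The feature set is 2-D; z-stacks, time series and OME metadata are
  out of scope, as are downstream statistics beyond the per-object
  tables.
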