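# Methods

## Model and procedure

The package quantifies invasion from paired nuclear-stain images of the
same spheroid at an initial (Day 0) and final (Day 2) timepoint. The
measurement is *pixel-based*: after binarization, every stained Day-2
pixel whose centre lies outside the Day-0 boundary polygon ("outer
pixel") contributes to the metrics directly. No nuclei or cells are ever
segmented, so clustered cells — the failure mode of object-based
counting — cost nothing. The working assumptions are:

- the stain marks nuclei with high contrast so a single global
  threshold separates foreground across a batch;
- invasion proceeds outward from cells at the spheroid surface, so the
  Day-0 boundary is the correct per-spheroid reference (this controls
  for initial size and shape);
- between timepoints the spheroid may drift but does not rotate or
  rescale appreciably: alignment is pure centroid translation.

Pipeline per spheroid: binarize both images → segment the Day-0
boundary → translate it onto the Day-2 frame by centroid overlap →
collect outer pixels with their ray distances and angles → metrics
(ΔA, D̄, max d, I_r) → optional PCA directionality. Batch stage:
MAD outlier flagging and consolidation into one table.

## Coordinate and boundary conventions

Image-frame coordinates throughout: x = column, y = row, 0-based,
pixel centres at integers, y increasing downward. Angles from
`atan2(Δy, Δx)` in [−180°, 180°); with y down, positive angles turn
clockwise on screen.

Boundary segmentation: morphological closing (disk, radius 5 px,
config-exposed) bridges gaps the nuclear stain leaves in the
silhouette; holes are filled; the largest 8-connected component is
kept (smaller than 10 px is a degenerate-spheroid error); its outer
contour is traced at the 0.5 iso-level (marching squares, subpixel).
On a rasterized disk of radius 50 px this polygon has mean radius
50.02 px — the half-pixel staircase bias oscillates with direction and
averages out — so distances measured from it agree with continuum
geometry to well under 1%.

Two centroids are kept deliberately: the polygon *area centroid* is the
(x₀, y₀) reference for rays and angles; the *mask-pixel mean* of the
largest component is used for Day0→Day2 alignment, computed the same
way on both masks so identical masks align with exactly zero
translation. The Day-2 alignment centroid uses only the largest
connected component (the spheroid bulk), so scattered invading nuclei
cannot bias the overlay.

Ray distance: the ray from (x₀, y₀) through an outer pixel p is
intersected with every polygon edge; the crossing with the largest ray
parameter not beyond p (the *last* crossing) is taken, so for
non-convex boundaries d measures penetration beyond the outermost edge
actually passed. If no crossing is found (numerically degenerate
geometry) the minimum distance to the polygon ring is used and the
pixel is flagged; flagged pixels are included in the metrics but
counted in a QC field, since excluding them would bias dense
concavities. For convex boundaries the crossing is unique and
d ≤ |p − centroid| always.

## Binarization choices

- Intensities are normalised by dtype maximum (255/65535), never by
  per-image maximum, so one threshold is comparable across a batch.
  Default threshold 0.16 on [0, 1]; the comparison is strict (>), so
  threshold 1.0 yields an empty mask.
- Contrast enhancement is a percentile-clipped linear stretch (1st/99th
  by default), robust to hot pixels; a constant image passes through
  unchanged.
- Background subtraction is Gaussian-blur subtraction (sigma in px,
  default 0 = off), deterministic and parameter-light; after
  subtraction the maximum is rescaled to the input maximum.
- Interactive artifact erasing is replaced by an optional artifact-mask
  image (foreground = erase), keeping runs scriptable and reproducible.
- The circular field mask keeps pixels within radius min(H, W)/2 of the
  geometric image centre ((W−1)/2, (H−1)/2), preventing bias toward
  the frame's long axis and corners.

Masks are monotone in threshold (lower threshold ⇒ superset), so
n_outer, outer area, mean distance and I_r are non-increasing in
threshold — *provided the Day-0 boundary stays sane*. At thresholds
within ~2 noise SDs of background, noise specks merged by the closing
step can inflate the boundary and break this; the property tests
therefore use noise σ = 0.02, where the lowest tested threshold (0.10)
sits 5σ above background.

## Directionality

PCA of the outer-pixel coordinates (2×2 covariance eigendecomposition)
gives the principal axes; axis orientations are reported in [−90°, 90°).
The coordinates are centred on the mean outer-pixel position by default
(the Day-0 centroid is selectable). With x' along the maximum-invasion
axis, `I_max = Σ x'² dA` and `I_min = Σ y'² dA`; outputs are labelled by
meaning (max/min) rather than by the x/y symbol, since "the moment
about x'" conventionally sums y'². The directional mean distance is the
mean |coordinate| along each axis — the only sign-free reading that
yields positive values. Fold changes are max/min ratios:
`moment_fold_change` equals the covariance eigenvalue ratio exactly
(the dA constant cancels). Eigenvalue ratios below 1.05 set an
isotropy flag (an exactly-degenerate spectrum returns angle 0); a cloud
collapsed onto a line gives an infinite moment fold with a
degenerate-minor-axis flag rather than an error.

## Units and parameters

| parameter | default | meaning |
|---|---|---|
| `pixel_size_um` | per run (config) | physical pixel edge, µm; never read from TIFF tags (dialects vary) — tags only trigger a warning if >1% off |
| `threshold` | 0.16 | global binarization threshold on [0, 1] |
| `contrast_percentiles` | (1, 99) | linear-stretch clip points |
| `background_sigma_px` | 0 (off) | Gaussian background sigma, px |
| `closing_radius_px` | 5 | boundary closing disk radius, px |
| MAD `k` | 3 | outlier cut in scaled MADs (scale 1.4826) |

Areas are mm², distances mm, moments mm⁴ (dA = (pixel_size_um/1000)²).
Scaling laws are exact: pixel size ×s multiplies areas ×s², distances
×s, I_r ×s⁴. ΔA (whole-image difference) and outer area (pixels past
the boundary) are both reported: they differ when the Day-2 bulk
shrinks or holds interior holes. Negative ΔA is allowed and warned,
never clamped.

## Statistics

Outliers per metric, within experimental group: |v − median| >
k·1.4826·MAD (normal-consistency constant). Zero-MAD groups flag any
value differing from the median. Flags are stored alongside the data;
rows are never dropped, and only the summary statistics exclude flagged
values. Whether to filter per metric or jointly is a genuine choice;
per-metric matches the violin-plot-per-metric reporting style this
workflow feeds and is what is implemented. Inferential statistics
(normality tests, ANOVA, post hocs) are deliberately left to standard
statistics environments reading the consolidated CSV.

## Synthetic fixtures

The generator rasterizes a disk/ellipse spheroid (pixel foreground iff
its centre satisfies the shape inequality) and adds invasion as (a) a
uniform annulus r0 < r ≤ r1, (b) an anisotropic Gaussian pixel cloud,
or (c) explicit (r, θ) pixels; a grayscale variant renders flat
intensities (nucleus 0.8, background 0.0) plus seeded Gaussian noise.
Truth records hold closed forms where they exist — annulus mean
distance `(2/(r1²−r0²))·∫(r−r0)·r dr` = 5.1515 px for (50, 60), ring
moment `2π·∫u²(u+r0)du` = 2π·19166.67 px⁴ — plus pixel-exact references
computed from the analytic circle (d = r − r0), so tests can separate
rasterization error (≈1% at r0 = 50) from algorithmic error. Identical
specs produce byte-identical fixtures.

What the fixtures do *not* emulate: textured nuclei, uneven
illumination, z-projection artefacts, debris, or spheroids touching
the frame. Passing tests therefore validate the geometry and the
metric definitions, not robustness to real microscope noise beyond the
flat + Gaussian model; the threshold, contrast and background controls
exist precisely because real batches need per-batch adjustment.

## Problem sizes and numerical notes

Default test/fixture frames are 161×161–301×301 px with r0 = 50 px,
~3.4k outer pixels and ~600-vertex boundary polygons; ray intersection
is vectorised over (pixel × edge) in chunks of 4096 pixels. Ties and
edge cases: points exactly on the polygon count as inside (hence not
outer); a pixel exactly at the centroid has no angle (error); empty
outer sets yield zero metrics with an explicit zero-invasion flag;
intersection tolerances are 1e-9 on edge parameters. The batch CLI
writes no timestamps, so reruns are byte-identical.

## Known limitations

- Pure-translation alignment: real spheroids that rotate or swell
  between timepoints violate the overlay assumption.
- The projected 2D analysis ignores the z-extent of invasion; z-stacks
  are collapsed by maximum projection.
- d is measured along the centroid ray, not the true nearest-surface
  path; for strongly non-convex boundaries the two differ.
- A single global threshold cannot rescue images with strong local
  background variation; the background-subtraction and artifact-mask
  hooks mitigate but do not remove this.
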