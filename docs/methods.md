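# Methods

This note records the models, conventions and numerical choices behind
`cardiomorph`, and what the synthetic-data tests do and do not establish
about real data.

## Coordinate and angle conventions

All geometry lives in the image frame: x to the right, y downward, µm,
origin at the top-left pixel corner; pixel `(i, j)` has its centre at
`((j+0.5)·s, (i+0.5)·s)` for pixel size `s`. Angles shown to users are
converted once, centrally, to the mathematical y-up frame. Cell
orientation axes are *axial* quantities: Ψ lives in [0°, 180°), relative
angles on the half-open scale (−90°, 90°] with ties at ±90° mapped to
+90° so the fold is deterministic.

## Mesh construction from label rasters

Cells are polygonised along pixel edges (crack following with a
right-turn preference, interior kept on the traversal's right), not by
sub-pixel contouring. This makes area bookkeeping exact — the polygon
area of every cell equals its pixel count times the pixel area — and
gives junction detection an exact oracle: a pixel corner is a junction
vertex when at least three distinct nonzero labels occur in its 2×2
pixel block. Every label must form a single 4-connected component;
violations raise naming the label.

Rasterised or anti-aliased segmentations split genuine 4-fold vertices
into two 3-fold vertices one pixel apart. Vertex clusters closer than
`merge_tol_um` are therefore merged transitively (union-find; position =
cluster mean, incident set = union). The default is one pixel diagonal
(`√2·s`); it is what makes "four cells sharing a single boundary point"
operational on rasters, and the transition-state injector relies on it
(below). The tolerance is exposed on the CLI because the behaviour of
segmentation tools on anti-aliased junctions varies.

## Morphometrics

Circularity is the isoperimetric quotient `4πA/P²`. Pixel-edge
boundaries carry a staircase that inflates P by up to √2, so
perimeter-sensitive measures (circularity, orientation) are computed on
a lightly smoothed copy of the boundary: a cyclic moving average, window
3, two passes. Two passes bring a 45° staircase within ~1 % of its true
length while changing the area of a ~100-vertex cell by well under 2 %;
areas always use the raw boundary. Both smoothed and raw modes are
available because which of the two an upstream tool used is generally
unknowable.

Orientation and elongation come from the exact Green's-theorem second
central moments of the polygon, not from vertex scatter, which is biased
by uneven vertex spacing. Elongation is `1 − λ_min/λ_max`; when the
eigenvalue ratio exceeds `1 − 1e−6` the axis is undefined (NaN) and the
cell is excluded from angle statistics with its count logged.

## Transition states

A transition state is a merged junction vertex of order ≥ 4 (order 4:
T1; higher: rosette). Frequencies are reported per 100 cells. By
default, cells touching the image edge or the tissue rim are excluded
from the denominator and states all of whose incident cells are rim
cells from the numerator: edge junctions are partly outside the imaged
field and would otherwise bias the count. The flag, like every numeric
knob, is echoed into the output.

The one-way ANOVA helper uses the classical sums-of-squares formulas
with pooled-variance pairwise t tests and Bonferroni adjustment
(`p·m` capped at 1); with zero within-group variance the F statistic is
capped at 10¹².

## Outline model, segments, axial angles

The traced outline is interpolated by a closed composite cubic Bezier
with Catmull-Rom control points (tension 0.5, C1): it passes through
every traced point, needs no free parameters beyond the sampling density
(20 samples per span, recorded), and is reproducible. Note an
interpolating spline bulges slightly outside sharp corners, so its
length can marginally exceed the traced polygon's. The cardiac centre
is the arithmetic mean of the curve samples (not the area centroid).

Landmarks 1–4 are inputs (AV→IC, IC→OFT, OFT→OC, OC→AV transitions on
the outline); they are snapped to the nearest curve sample (tolerance
5 µm) and must appear in cyclic order along the outline. Landmarks 5
and 6 sit at one-third and two-thirds of the outer-curvature arc from 3
to 4, found by inverting the cumulative arc-length table; the three
sub-arcs agree to 1e−6 relative by construction. The walk direction
flips with `reverse_outer` for mirrored hearts. Rays from the centroid
through the six points bound six sectors (IC, OFT, OC near OFT, OC
middle, OC near AV, AV) that tile the circle; a cell belongs to the
sector containing its centroid.

Per-cell axial angles compare Ψ with the outline direction at the
sample nearest the cell centroid (tangent by central difference, outward
normal pointing away from the centroid). Two conventions are computed:
**normal** (0° = cell axis along the surface normal, the default) and
**tangent** (0° = circumferential). Both are kept because the two
natural readings of "angle between the cell axis and the local surface"
differ by 90° for circumferentially elongated cells, and published
figures and methods texts do not always use the same one; every output
carries its convention. Under the default, inner/outer-curvature cells
score near 0° and outflow-tract/AV cells near 90°.

The looping angle is the acute angle ([0°, 90°]) between the line
through the two AVJ endpoints and the midline direction, invariant to
endpoint order and midline sign.

## Axial circular statistics

Angles are doubled before any circular computation (the standard device
for axial data), so θ and θ+180° are indistinguishable. Reported per
group: n, mean axis (half the doubled-angle mean direction, in [0°,180°)
plus its ±90° alias), the mean resultant length R̄ of the doubled
angles, circular variance 1 − R̄, `Z = nR̄²`, and the Rayleigh p-value
from the classical series

    p ≈ e^(−Z) · [1 + (2Z − Z²)/(4n) − (24Z − 132Z² + 76Z³ − 9Z⁴)/(288n²)]

clamped to (0, 1]. A seeded Monte-Carlo null of Z is available and the
suite checks the series against it (within 10 % at reference points) and
calibrates the type-I error at α = 0.05 on uniform axial samples
(rejection rate within [0.03, 0.07] at n = 50, 1000 replicates).
Because the literature uses "Rayleigh's R" both for concentration-like
quantities and for p-values, this package never prints a bare "R": R̄, Z
and p are always separate named fields.

## Intensity analysis

Line profiles emulate a wide line scan: samples at one-pixel arc
spacing; at each, the mean of `width_px` (default 10) bilinear
sub-samples straddling the path symmetrically along the local
perpendicular. Min–max normalisation is over the profile's own
selection; for apical-vs-basal comparisons the two profiles are
normalised jointly on a shared scale so they stay comparable. All
normalised outputs are invariant to positive affine intensity
rescaling.

The apical-accumulation (aa) call is `mean(apical) − mean(basal) >
margin` over the OFT window on jointly normalised profiles, margin 0.2
by default. The published criterion for "aa" is visual; a fixed, logged
margin makes it reproducible, and the amplitude-sweep test characterises
the decision boundary: the call flips within about one sweep step
(±0.05–0.06) of the margin. The residual offset is a property of
min–max normalisation itself — the sample extremes under noise inflate
the denominator by a few percent — not of the call rule.

Presence of a channel at a transition state is a disc statistic: mean
intensity within `radius_um` (default 1.5 µm) of the vertex above the
channel's background mean + `k_sigma`·s.d. (default 2). Co-localised
means present in both channels; percentages are reported as half-up
rounded integers. Ventricular mean intensity is background-subtracted,
divided by the ROI area (size adjustment) and normalised by the cohort
average. Background ROI placement is explicit configuration.

## Synthetic epithelium generator

The generator emulates a bean-shaped, single-layered ventricular
epithelium in top-down projection, with the statistical structure the
analysis assumes:

* **Outline**: a Fourier-perturbed ellipse (default 90 × 60 µm semi-axes,
  two mild harmonics); the traced outline is a 36-point subsample, the
  four landmarks sit at fixed parameter angles chosen so the six sectors
  have plausible proportions.
* **Cells** fill the band between the outline and its 40 µm inward
  offset. Seeds are laid on a curvilinear lattice — columns along each
  segment's outline arc, rows descending along the inward normal, with
  per-segment spacing set by the target area and aspect — then corrected
  per sector: surplus seeds are dropped and deficits filled at random
  band pixels so that every sector holds exactly
  `round(sector area / target area)` seeds. Mean cell area per region is
  therefore controlled by counting, and the pooled means land within a
  few percent of the targets. The band pixels are partitioned by an
  anisotropically weighted nearest-seed rule: each seed carries a metric
  stretched along an axis drawn from an axial von Mises distribution
  about the local outline normal (mean and concentration per segment; a
  helper converts a requested axial s.d., e.g. 15°, into the
  doubled-angle concentration), with the stretch ratio solved from the
  segment's target circularity via the stretched-hexagon isoperimetric
  quotient. Two rounds of centroidal relaxation follow; lattice rows
  aligned with the normal matter here — a lattice along centroid rays
  drags measured axes several degrees off the injected mean.
* **Defaults** encode the chamber-stage wild-type regime: IC 83 µm² /
  circularity 0.60 / axis along the normal; OC 107 µm² / 0.53 / normal;
  OFT and AV circumferential; axial s.d. 15° everywhere; transition-state
  rates 5.5 per 100 cells (presets at 9.0, 4.5 and 8.8 for the
  tube-stage, late-stage and PCP-deficient-like regimes, the latter with
  a shifted, dispersed OFT axis); looping angle 29° (42° in the deficient
  preset); pixel size 0.2 µm; tissues of ~150–230 cells.
* **Transition states** are injected by contracting randomly chosen
  interior junction edges (both cells losing the junction must be
  interior; preference for below-median-length edges). A four-cell point
  has zero measure on a raster, so the contraction hands the one-pixel
  corridor of boundary pixels to the two gaining cells, split at the
  contraction corner, leaving two 3-fold corners one pixel apart that
  the default merge tolerance unifies into one order-4 vertex. Each
  contraction is verified by local re-detection and connectivity checks
  and reverted on failure, and accidental order-≥4 vertices elsewhere
  are broken by one- or two-pixel repairs, so injected counts are
  recovered exactly. Per-tissue injected counts (and the
  channel-B-absent counts below) use stochastic rounding so that rates
  are unbiased across seeds despite the ~1.5-per-100 quantisation of a
  ~60-cell denominator.
* **Channels** render every membrane with a Gaussian cross-section
  (σ = 1 px) whose amplitude depends on the cell's segment, plus
  Gaussian noise, clipped to 8 bit; channel B can be suppressed in discs
  around a chosen fraction of the injected states for co-localisation
  experiments. The mid-sagittal generator draws two nested membrane
  arcs with a ramp-plus-plateau amplitude profile; the injected
  apical−basal contrast is defined directly on the normalised scale, and
  a noise-free calibration render equalises the two membranes' rendered
  gain (inner and outer arcs keep slightly different shares of their
  nominal amplitude) so the injected contrast is realised by a wide line
  scan. The recorded OFT window starts 2 µm past the amplitude
  transition to keep rendering smear out of the window means.

What passing the recovery tests shows: the analysis stack is unbiased
and correctly calibrated on tissues whose geometry, noise and regional
structure match its assumptions. What it does not show: robustness to
segmentation errors, uneven illumination, out-of-plane curvature of a
real projected ventricle, anisotropic pixels, or cell-shape families far
from stretched-polygon cells — none of which the generator emulates.

## Problem sizes in the test and acceptance runs

The suite analyses 20 chamber-stage tissues (~150 cells each) for shape
and rate recovery, 20 enlarged-OFT tissues (~90 OFT cells per heart, the
per-heart sample size of the orientation experiments) for angle
recovery, 100 random ≤ 64×64 label images against the exhaustive
junction oracle, 1000 uniform replicates for Rayleigh calibration, and a
33-point amplitude sweep for the aa boundary; the acceptance script uses
24 + 18 tissue cohorts and a 200-state co-localisation set. These sizes
keep the full suite at a few minutes on one CPU while leaving binomial
and circular standard errors comfortably inside the asserted bands.

## Known limitations

* The generator injects T1 (order-4) states only; rosettes are covered
  by detection tests on constructed meshes, not by the tissue generator.
* Cells gaining a contraction corridor acquire a one-pixel tail, a
  slight local distortion of their shape metrics.
* Per-OC-sub-segment area means wobble by ±6 % because cells whose
  centroids drift across a sector boundary carry their neighbour's
  target size; comparisons should pool the outer curvature, as its
  regional statistics are defined.
* Time-lapse dynamics (formation vs resolution of transition states) and
  3-D geometry are out of scope throughout.
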