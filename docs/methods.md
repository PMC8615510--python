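# Methods

This note documents the models, the numerical choices and the defaults
the package ships with, and what the synthetic-data generators do and
do not emulate.

## Histomorphometry

**Pre-processing.** Images are blurred with a Gaussian of physical
width `sigma_um` (default 0.65 µm, converted to pixels through the
declared pixel size; reflective borders; kernel truncated at 6σ so the
discrete kernel matches the analytic Gaussian to <1e-6). A blur wider
than a quarter of the image is rejected as a likely unit error.

**Color deconvolution.** The RGB image is converted to optical density
`OD = −log10(I/I0)` (I0 = 1 for images scaled to [0, 1], floor 1e-6)
and unmixed by inverting a 3×3 stain matrix whose rows are unit OD
vectors for the cell stain, the matrix stain and a residual channel.
The default matrix is the standard hematoxylin/eosin/DAB convention
with rows re-normalized to unit length. Stains are never exactly
orthogonal, so negative concentrations appear; they are clipped to zero
and the clipped mass plus the re-mixing residual norm are reported so
unmixing quality can be audited. Matrices with condition number above
1e6 are rejected.

**Segmentation.** Otsu's threshold on the cell OD channel (explicit
override available; an all-foreground result is rejected with a hint to
override). Objects smaller than `min_area_um2` (default 20 µm², about a
third of a nucleus) are removed. Touching cells are split by watershed
on the negated distance transform; within each connected component the
markers are the connected regions where the distance transform exceeds
half its local maximum. This "distance-core" seeding splits only where
a genuine neck separates two cores, so an isolated cell — however
elongated — yields exactly one marker. (Seeding at distance-transform
*maxima* was tried first and shatters elongated cells, whose distance
ridge is a plateau.)

**Circularity.** `4π·hull_area / hull_perimeter²` of the convex hull of
the region, with the hull taken over *pixel corners*: every pixel
contributes its four half-integer corners. This makes the hull of a
w×h pixel block exactly the w×h rectangle, so closed-form shape values
(square π/4 ≈ 0.785, 10:1 rectangle ≈ 0.260) are met without the ~1 px
shrink bias that pixel-center hulls carry. Perimeter is the polygonal
hull perimeter, not a pixel count. Values are capped at 1.0 on report.
A bare (N, 2) float array passed to `hull_circularity` is treated as
polygon vertices (no corner expansion); collinear vertex sets return 0
with a warning.

**Morphotypes.** Epithelioid at or above the circularity cutoff,
mesenchymal-like below; ties go to epithelioid. The default cutoff 0.7
sits in the gap between round (axis ratio ≈ 1.1, circularity ≈ 1.0) and
elongated (axis ratio ≈ 4, circularity ≈ 0.55) populations; a
data-driven alternative (`circularity_cutoff_otsu`) splits the observed
circularity histogram. The cutoff is a reporting choice, not a fitted
quantity, and is recorded in the per-run config.

**Compartments and depth.** A cell belongs to the compartment under its
centroid; if its hull straddles the parenchymal/stromal boundary with
less than 80 % majority it is reported "mixed". Invasion depth is the
Euclidean distance transform of the section mask at the cell centroid
times the pixel size; the "invasion front" is a percentile of the depth
distribution (default 95th — more robust than the maximum while still
tracking the deepest cells). Relative cellularity is the area fraction
of segmented cell pixels within the section mask, in percent; a count
density is also derivable from the per-cell table but area fraction is
the primary definition.

## Vasculometry

**Pipeline.** Green channel (vessels have the strongest contrast
there on brightfield CAM images) → percentile histogram stretch
(defaults 1st/99th percentile to [0, 1]) → ridge detection → skeleton
graph → per-ROI metrics → per-egg means → group statistics.

**Ridge detector.** Gaussian-derivative (Steger-style) line detection:
image derivatives at scale σ, principal curvature = largest Hessian
eigenvalue (positive across a dark line), sub-pixel line-point test
(the directional extremum must fall within ~0.7 px of the pixel
center), hysteresis linking between the low and high response
thresholds, binary closing of 1-px gaps, thinning to an 8-connected
unit-width skeleton, and iterative pruning of terminal spurs shorter
than 5 px. The scale defaults to σ = w/(2√3) for an expected vessel
width w (the bar-profile relation at which the second-derivative
response across the line stays single-moded); `sigma_for_width` exposes
it. The response is γ-normalized (σ²·λ) so thresholds are comparable
across scales. The default hysteresis thresholds (low 0.04, high 0.10)
were calibrated on synthetic membranes: a matched vessel of unit
post-stretch contrast peaks near 0.3, while sensor-like noise on a
vessel-bearing image stays below ~0.01.

**Lengths.** Two estimators are used deliberately. (1) Skeleton *edge*
geometric length is the arc length of the pixel chain resampled every
4 px (plus endpoints): the raw unit/√2 chain metric overestimates
oblique digital lines by up to 8 % (≈5.5 % on average over angles),
which would consume most of the 5 % recovery budget on its own, while
polygonal resampling is unbiased to ≈0.5 % for curvature radii well
above the sampling step. (2) *Branch length density* inside an ROI
keeps the plain 8-connected step metric (1 per axial, √2 per diagonal
step, both pixels inside the ROI), which makes the straight-line closed
form exact and the measure trivially decomposable over ROIs. On
rendered networks the two agree to a few percent.

**Junctions.** Skeleton pixels with ≥3 neighbors, merged within a
radius of twice the vessel width (default 6 px): an X-crossing of
width-w lines thins into two 3-way nodes up to ~2w apart, so finer
separations do not correspond to distinct crossings. Junction counts
on synthetic trees track the generator truth to within a few counts;
residual disagreement comes from shallow-angle crossings that are
genuinely ambiguous at the rendered resolution.

**Group statistics.** ECDFs of ROI-level densities pooled across eggs
within a group; per-egg mean densities for Mann–Whitney comparisons
(both levels are emitted, since published workflows differ). KS uses
the exact small-sample distribution when n·m ≤ 10 000 and the
asymptotic Kolmogorov distribution above; Mann–Whitney uses the exact
null for small tie-free samples and the tie-corrected normal
approximation otherwise (both via scipy, verified in the test suite
against exhaustive permutation enumeration).

## Growth dynamics

The logistic law is evaluated in a form stable for large `d·t`
(underflow of e^{−dt} saturates cleanly at Cmax). Fitting is nonlinear
least squares over all replicate points (fitting per-time means is an
option); positivity is enforced by optimizing log-parameters inside
wide data-relative bounds. Noisy slow-growth series (replicate noise
comparable to C0) have a spurious flat-line basin at extreme C0, so
three growth-rate initializations (0.1, 0.5, 2 day⁻¹) are tried and the
lowest-residual solution kept. Convergence tolerance is 1e-10 on the
objective. Standard errors come from the Gauss–Newton covariance,
delta-method-transformed to the natural scale; a flat series is flagged
as having an unidentifiable rate rather than failing. Time is fixed to
days throughout.

## Dose–response

Eq.-style dead fractions propagate the absorbance spread linearly
(σ_E = 100 σ_A / A0, with σ carrying whatever spread the input column
declares — replicate s.d. by default). Negative E (growth above
control) is reported unclipped.

The Hill fit runs on log₁₀ dose with weights 1/σ_E, clipped at the 95th
percentile of the weights so a single near-zero-σ point cannot dominate;
all-zero σ falls back to unit weights with a warning. The zero-dose
control cannot be log-transformed, so it is anchored at a pseudo-dose
**four decades below** the smallest nonzero dose with a ×10 weight
multiplier. Four decades (rather than the two often used) keeps the
model's own value at the anchor below optimizer tolerance for any slope
h ≳ 0.8, so noiseless generator tables are recovered exactly; both the
offset and the multiplier are exposed as parameters. The default fit
constrains 0 < Emax ≤ 100 and h > 0 through a smooth reparameterization
(logit/log); a fully unconstrained mode is selectable. IC50 uses the
closed-form inversion and agrees with numeric root-finding on the
fitted curve to <1e-6 whenever both are defined; "not reached" is
returned when Emax ≤ 50 % or the crossing exceeds the tested dose
range. The resistance report ratios linear-scale EC50s (3D over 2D)
per formulation.

## Synthetic data

The generators define the study conditions the tests run under; all
randomness flows from one `numpy` Generator per spec, so a fixed spec
is byte-reproducible.

**Histology.** Two compartments (vertical split by default, custom
label masks accepted): parenchymal cells nearly round (axis ratio
1.1 ± 0.05), stromal cells elongated (4.0 ± 0.3), geometric-mean
semi-axis 6 ± 0.5 µm — nucleus-scale objects at the default 1 µm/px.
Cells are ellipses rendered through the Beer–Lambert model
(I = 10^−OD, OD = concentration × unit stain vectors; cell stain OD
0.9 against matrix OD 0.15/0.3 per compartment), with additive Gaussian
intensity noise (s.d. 0.01) clipped to [0, 1]. Placement is
rejection-sampled non-overlapping by default; a compartment that cannot
host its requested count raises an error naming it. The truth records
every ellipse with its *analytic* hull circularity (elliptic-integral
perimeter — the hull of an ellipse is itself).

**Vessels.** Branching random walks from border roots: segment lengths
120 ± 30 µm, heading jitter 0.08 rad/step, bifurcation probability 0.7
per segment end up to depth 4, width 3 px, rendered as dark
anti-aliased strokes (radial coverage profile) on a bright membrane,
darkest in green. Walks entering a 30 px border margin are steered back
toward the interior, and trees below a minimum plexus density of
0.002 µm/µm² (about 5–10× below typical generated densities) are
regrown deterministically — a chorioallantoic membrane is always
perfused, and a near-empty field would make the percentile stretch
amplify background noise into spurious detections (see limitations).
The truth stores the centerline polylines, their exact arc length, and
a junction count that includes both branch events and incidental
crossings of distinct branches (merged below one vessel width), since a
skeleton cannot distinguish the two.

**Curves and tables.** Viability series evaluate the logistic law
exactly (d = 0 defined as constant C0) plus i.i.d. Gaussian replicate
noise, floored at 0. Dose–response tables evaluate the Hill sigmoid at
each nonzero dose and 0 at the control, add replicate noise, clip to
[0, 100] (a dead fraction), and report per-dose mean/s.d./n; replicate
values are kept in the truth for per-dose rank tests.

**What the generators do not emulate** — and hence what passing tests
do not show about real data: staining variability and batch effects
(no stain normalization), overlapping/touching nuclei in dense linings
(optional overlap mode exists but defaults off), uneven illumination
and vignetting, vessel diameter variation along a branch, parallel
vessels closer than the detector scale, out-of-focus blur, and any 3D
structure (sections and membranes are treated as planar).

## Known limitations

- The percentile histogram stretch assumes a vessel-bearing field; on a
  nearly empty image it amplifies background noise to full contrast and
  the ridge detector will hallucinate structure. Real CAM ROIs are
  always perfused, and the generator enforces the same, but users
  feeding arbitrary crops should check the skeleton overlay QC image.
- Hill-fit recovery is exact to optimizer tolerance for h ≳ 0.8; for
  very shallow slopes the control anchor's residual model value biases
  parameters at the ~0.5 % level (move the anchor further out if that
  matters).
- Junction counts are resolution-limited around shallow-angle
  crossings; treat them as accurate to a few counts, not exact.
- The circularity cutoff separating morphotypes is a documented default
  (0.7), not a biological constant; sensitivity to it should be checked
  per dataset (the Otsu-based data-driven cutoff helps).

## Problem sizes used in the shipped benchmarks

Acceptance-style checks run on: 20 seeded vessel trees of 384×384 px at
2 µm/px; histology sections of 384–640 px at 1 µm/px with 100–200
cells; dose grids of 8 points (0–10 µg/mL); 28-day viability courses
with 5 time points. These sizes were chosen to exercise every code path
at comfortable statistical power while keeping the full suite fast
enough to run on every change.
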