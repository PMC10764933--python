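# Methods

## Model and conventions

`avpnorm` operates on binary occupancy grids. Every volume is reoriented
on load to one canonical layout — x: left→right, y: anterior→posterior,
z: inferior→superior — so a coronal slice is always `grid[:, k, :]`.
Voxel indexing is 0-based, a voxel's world position is its center, and
slice 0 of a pathway is the most anterior intraorbital slice (the nerve
head), which is also the atlas origin. Non-binary label volumes are
binarized at > 0. The acquisition resolution the defaults assume is
0.6 mm isotropic.

The optic chiasm arrives as a single trunk and is split into hemi-trunks
at a sagittal plane; both an explicit voxel index and the grid x-midline
("auto") are supported, since segmentation protocols differ in whether
the midsagittal plane is anatomically fitted or taken from the image.

## Straightening

Segment length is defined by the centroid polyline: per coronal slice
the centroid of the set voxels, and `TL = Σ Dᵢ` over the 3-D Euclidean
inter-centroid steps. `Dᵢ` deliberately includes the in-plane drift —
for a curved course it exceeds the 0.6 mm slice pitch, and preserving it
through straightening is the point of the sub-slice rebuild.

Slice centering uses **integer-voxel translations only**. The target is
the voxel-coordinate midline `((N−1)/2, (N−1)/2)` of the working
in-plane grid (default 64×64): with this choice the mirror flip
`i → N−1−i` used to pool right-side masks maps the centerline onto
itself, so flipped and unflipped masks superimpose without a one-voxel
offset. Shifts are rounded half-away-from-zero; the residual sub-voxel
centroid offset (< 0.3 mm per axis) is recorded as metadata rather than
corrected, because fractional-shift interpolation would break the exact
CSA guarantee.

Each centroid gap is rebuilt as `nᵢ = round(Dᵢ / 0.06)` fine slices
(minimum 1; for a straight 0.6 mm gap this is the ten-fold replication).
Each fine slice replicates the nearer flanking source slice; an odd
count ties to the anterior one. Every fine slice is therefore a
translated copy of exactly one acquired slice: CSA conservation is
bit-exact and is asserted, not assumed. Provenance (segment, source
slice) is kept per fine slice and exported as a sidecar.

## Length normalization and resampling

All straightened pathways are rescaled to a common target length —
by default the cohort mean of the summed-segment TLs (both sides
pooled). Rescaling re-plans whole fine slices only: the new total count
`N′ = round(N·s)` is apportioned by largest remainder, first across
segments and then across gaps within each segment (each gap keeps at
least one slice). This keeps every slice's CSA untouched, bounds each
segment boundary within one fine slice of its proportional position, and
supports shrinking as well as lengthening. Per-gap re-rounding
(`round(s·Dᵢ/0.06)` independently) was rejected: it cancels the global
scale for small `s−1` and cannot hit the target count.

Resampling to the 0.6 mm cohort grid pools each run of 10 fine slices
and sets an output voxel where occupancy ≥ 0.5. The majority threshold
is unbiased for monotone tube boundaries; its CSA behavior is verified
on uniform tubes (within 5 %) rather than asserted. The shared output
grid defaults to 64×128×64 voxels (76.8 mm axial coverage), configurable.

## Atlas and validation

The atlas value is `100 × (masks covering the voxel) / n_masks`, with
right-side masks mirrored to the left first; per-segment child atlases
are built from each mask restricted to its segment's axial range.
Thresholding is inclusive (≥), which keeps the 50 % level well defined
for even cohort sizes. Dice similarity defines both-empty operands as 1
(identical emptiness) and one-empty as 0 — segment-restricted
comparisons can produce both.

Leave-one-out validation withholds **both** sides of a subject (leaving
one in would leak the contralateral anatomy into the reference), scores
each withheld mask against the remaining cohort's 50 %-threshold atlas,
and averages the two Dice values into one score per subject. The summary
reports the 50th and 5th percentiles of subject scores — the median
subject and the level reached by 95 % of participants.

## Biometry

Per segment and side: volume = voxel count × voxel volume; length = TL;
mCSA = volume / length; ε = unweighted mean of per-slice ellipticity
over slices with ≥ 3 voxels (fewer are moment-degenerate). Hemi-axes
come from the equivalent ellipse of the in-plane second central moments:
`h = 2√λ` for the eigenvalues of the slice's coordinate covariance,
using the **pixel-broadened** covariance (voxel-center covariance plus
the uniform per-pixel term s²/12, i.e. the exact covariance of the union
of pixel squares). The broadening removes the ≈ s²/12 downward bias of
bare voxel centers, keeps ε in [0, 1) for degenerate (single-voxel or
collinear) slices, and yields ε = 0 for a single voxel without a special
case. Multiple in-plane connected components are measured as their union
(the cross-section may fragment at segment boundaries).

Because volume counts n slices while the centroid path spans n−1 gaps,
mCSA carries a structural `n/(n−1)` inflation relative to the true
cross-section — ≈ +5 % for a 12 mm segment, < +2 % beyond 20 mm. This
end effect is inherent to the volume/length convention, affects any
implementation of it equally, and is why short-tube mCSA checks in the
test suite use a 30 mm cylinder.

Cohort statistics: descriptive summaries per segment/side with Gaussian
95 % CIs and median/quartiles (a Shapiro–Wilk check at α = 0.05 flags
which presentation is appropriate — no specific test is canonical here,
this is the conventional default); paired t-tests for left–right
differences in closed form (identical sides give t = 0; constant nonzero
differences are flagged degenerate); between-subject CV as
100·SD/mean (n−1 denominator) of left/right-averaged values — a plain
between-subject dispersion, deliberately simpler than a mixed-model
variance decomposition, so published mixed-model CVs are comparable only
approximately. Standardized metrics express segment volume and length as
percent of the whole pathway and segment mCSA/ε as percent deviation
from the whole-pathway mean. Compound segments (ON = iOrb+iCan+iCran;
whole aVP) sum volumes and lengths exactly; their table-level ε is the
length-weighted mean of segment values (slice counts are proportional to
length at fixed pitch), whereas mask-level compound ε can be computed
exactly from the voxel union.

## Phantom generator

Phantoms are curved elliptical tubes voxelized slice-by-slice on the
0.6 mm grid: a voxel is set iff its center lies inside the local
ellipse, matching the counting-based CSA used throughout. The
centerline is a cubic spline through control points emulating the
orbital bend, plus two realism terms: fine-scale sinusoidal tortuosity
(0.25 mm amplitude) and an oblique linear drift (≈ 6.3/4.7 mm laterally/
vertically over the path — the pathway does not run parallel to the
scanner axis). Besides realism, these keep consecutive cross-sections
from sitting at one frozen sub-voxel lattice phase; without them,
center-sampling voxelization acquires systematic per-segment count
biases of several percent and recovery tests would measure lattice
alignment, not the pipeline. Curvature is checked against the tube
radius to exclude self-intersection.

Defaults place phantoms in the plausible adult regime: total length
61.1 mm; segment length shares 36.6/11.4/25.7/10.7/15.6 %; per-segment
cross-sections 7.7/5.6/6.9/14.4/7.6 mm² with ellipticity
0.15/0.20/0.43/0.57/0.39. Segment fractions are shares of the summed
within-segment lengths (the way length proportions are tabulated), so
boundary gaps are excluded from the budget before slicing. Ground truth
is slice-stacked and exact for the generated solid: volume = Σ (ellipse
area × pitch), length = the centerline polyline through the slice
centers, mCSA = volume/length, ε = the profile value.

Cohorts draw total length lognormally (fractional spread = the
`variability` parameter, default 0.05), jitter fractions, profiles,
bend scale and tortuosity phase per side, and are fully reproducible
from the seed.

What passing phantom tests do **not** show: phantoms have clean
boundaries, elliptical cross-sections and no segmentation error, so
agreement on phantoms validates the geometry pipeline, not the
robustness of manual segmentation or the behavior on pathological
anatomy.

## Numerical choices and limitations

- Rounding is half-away-from-zero everywhere a count or report value is
  rounded, for cross-platform reproducibility.
- Apportionment ties break toward the more anterior entry.
- Measured lengths carry a small positive bias (≈ 1 %) relative to the
  analytic centerline, because per-slice centroid quantization jitter
  adds to the inter-centroid steps in quadrature. This is a property of
  centroid-polyline length at 0.6 mm with ~20-voxel cross-sections, and
  it is why length-recovery checks run at the whole-pathway level.
- Per-segment volume recovery against *analytic* truth at 0.6 mm has
  irreducible lattice-count scatter of a few percent for the shortest
  segments (≈ 11–12 slices); volume checks against truth therefore run
  at the whole-pathway level, while per-slice CSA conservation through
  the pipeline is asserted bit-exactly.
- Single-slice segments have zero centroid-path length; their mCSA is
  undefined and signalled, not silently patched.
- The pipeline consumes masks only: no intensity images, no DICOM, no
  registration to a standard brain template, and no nonlinear axial
  warping of segment boundaries — each subject is scaled by one global
  factor.

## Problem sizes

The default test and acceptance workloads use bilateral synthetic
cohorts of 8 subjects (20 for the conservation sweep), ~100 coronal
slices per pathway and ~1000 fine slices after straightening — sizes at
which every stage's behavior is already asymptotic while the full suite
runs in seconds.
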