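# Methods

This note documents the models, conventions and numerical choices behind
`saxcompare`, and what the synthetic phantoms do and do not establish
about real cine CMR data.

## Geometry and representation

Contours are closed planar polygons in 0-based pixel coordinates;
physical position is `pixel × pixel_spacing` with isotropic in-plane
spacing.  Outer rings are canonicalised counter-clockwise (holes
clockwise) and self-intersecting rings are **rejected, not repaired** —
automatic repair would mask annotation or export bugs precisely where a
comparison tool must surface them.  Coordinates stay real-valued
throughout (sub-pixel vendor contours round-trip unchanged); conversion
to mm happens once, at compute time.

The LV myocardium is never stored as a ring-with-hole.  It is
materialised at comparison time as epicardium minus endocardium (minus or
plus the papillary union, depending on mode), mirroring how epicardial
and endocardial contours are merged in clinical post-processing.
Papillary muscles may be multiple blobs per slice; they are unioned and
clipped to the endocardial cavity before any area arithmetic, so a blob
straying outside the cavity cannot drive an effective blood-pool area
negative.

All area and intersection computations use exact polygon clipping
(shapely/GEOS).  Boundary distances use points densified along each edge
so consecutive samples are at most `max_arc` apart (default **0.1 mm**);
the Hausdorff distance is the symmetric max–min over those point sets via
k-d trees.  For the myocardial annulus the Hausdorff distance is the
maximum of the epicardial-surface and endocardial-surface distances, each
compared like-for-like, so drift of either surface is penalised; the
Dice for the annulus is computed on the annulus region itself, and
papillary muscles never enter the segmentation-metric strata.

## Clinical parameters

Volumes use slice summation (Simpson's method): segmented area × slab
thickness, slab = slice thickness + inter-slice gap (both configurable
per slice).  Whether vendors include the gap is not generally knowable,
so the convention is explicit and configurable.  LV mass uses myocardial
density **1.05 g/ml** (the universal CMR convention, configurable) at
end-diastole only.  ED/ES are input labels, not detected from a volume
curve.  SV = EDV − ESV and EF = 100·SV/EDV are recorded as-is —
EDV ≥ ESV is deliberately not enforced, because reader disagreement is
exactly what the tool measures; EF is reported missing when EDV = 0.
A slice with an epicardial but no endocardial contour contributes its
full epicardial area to mass and emits a warning record.

## Slice-decision classification and rates

Positions are defined solely by the expert's segmented range per region
and phase (index 0 = most basal acquired slice).  If the expert segmented
a single slice, it is basal and apical at once and basal takes
precedence.  Candidate slices above the basal slice count as basal false
positives (one per slice), a missed basal slice as a basal false
negative, symmetrically at the apex, and missed in-range slices as
midventricular false negatives.  A case whose expert stratum is empty is
excluded from that stratum with a logged reason.

Rate denominators are per-slice opportunities: basal/apical rates use one
labelled slice per case (FP rates count extra slices per case and can in
principle exceed 100%), the midventricular FN rate uses in-range slice
opportunities.  Summary tables average metrics directly over slices by
default; a `per_case_first` switch averages within cases first (the two
differ when cases contribute unequal slice counts, and the choice is
covered by a regression test).

## Acceptability statistics

For each clinical parameter the per-case differences (default
orientation candidate − expert, configurable and stated in every output)
are summarised by

* bias CI: mean ± t₍₀.₉₇₅,ₙ₋₁₎ · s/√n, and
* tolerance interval: mean ± k·s with Howe's approximation
  k = z₍(1+p)/2₎ · √(ν(1+1/n)/χ²₍ν,1−γ₎), ν = n−1, content p = 0.68,
  confidence γ = 0.95.

Howe's k is validated in the test suite against an exact
numerical-integration oracle (relative error ≈ 0.16% at n = 50), and both
procedures against Monte-Carlo coverage simulations.  Verdicts use the
subset rule: bias acceptable iff the CI lies inside ±BTR, variability
acceptable iff the tolerance interval lies inside ±VTR.  Intervals
require n ≥ 3; Pearson r is computed on the paired raw values (not
differences) and reported missing for zero-variance series, as is the
t-test p-value for zero-spread differences.  No multiple-comparison
correction is applied: the per-parameter tests are descriptive, not
independent hypotheses.  BTR/VTR encode acceptable intra-/inter-reader
variability and must be calibrated by the user; the shipped example table
is an illustrative placeholder of plausible magnitude only.

## Correction burden

Cut-offs per (region, phase): area cut-off = 1.96·SD of per-slice
interobserver area differences; Dice cut-off = median − MAD with the
**unscaled** MAD (no 1.4826 consistency factor — the definition is
literally median minus the median absolute deviation).  Calibration
refuses strata with fewer than 10 jointly-contoured slices and flags
degenerate (identical-reader) calibrations instead of silently accepting
them.  Decision errors (false-positive/negative slices) always require
manual action, so they count as corrections by default even though
cut-offs are defined only for present contours; a flag disables this.
Loosening any cut-off can only decrease counts (tested).

## Phantom cohorts

Each phantom case is a stack of `slices_per_case` slices (default 12,
pixel spacing 1.79 mm, thickness 7.08 mm — typical clinical short-axis
acquisition values); the expert segments all but the outermost two, so
over-inclusion errors have somewhere to go.  The LV endocardium is a
circle of base radius 27 mm tapering linearly by 5% per slice toward the
apex; the epicardium adds an 8 mm wall; two 4 mm papillary blobs sit
inside the cavity; the RV is the difference of a 35 mm disc offset 28 mm
septally and the epicardial disc — a crescent whose area has a closed
form (disc minus circle–circle lens), used as ground truth.  End-systole
scales all in-plane radii by `ed_es_scale` (default 0.63, i.e. EF ≈ 60%),
applied uniformly to the whole RV construct so both ventricles obey
EF = 100·(1 − s²) exactly.  Defaults give a normal adult heart
(EDV ≈ 100 ml, LVM ≈ 90 g); `dilated` and `hypertrophic` presets shift
radii, wall, papillary size and contraction accordingly.  Per-case
anatomy jitter (overall scale SD 8%, wall SD 5%, ES-scale SD 0.03) gives
the cohort realistic between-case spread; setting the SDs to zero makes
every closed form exact.  Contours are 360-gons, whose area deficit
relative to the true circle is ≈ 5·10⁻⁵ — far below every tolerance used.

Perturbation profiles emulate AI behaviour: a radial displacement field
`bias + noise(θ)` applied about each contour's centroid, where the noise
is a band-limited Gaussian field (8 Fourier harmonics with i.i.d.
coefficients scaled so each vertex's marginal is exactly N(0, sd²)).
A smooth field is used rather than i.i.d. per-vertex noise because
per-vertex noise at 360 vertices folds rings into self-intersection —
which the core types rightly reject — and because real AI contours are
smooth; the marginal distribution, and hence all first-order area
predictions (e.g. a +1 mm bias on a radius-r circle adds
≈ π((r+1)² − r²)), are unchanged.  Slice-decision errors draw
independently per case, structure group (all LV contours move together,
RV separately) and phase.  Anatomy and perturbation use independent seed
streams, so one cohort can be re-perturbed reproducibly under several
profiles.

**What the phantoms do not show.**  They contain no imaging physics: no
partial-volume effects, no basal out-of-plane motion, no trabeculation,
no through-plane misregistration, and their shapes are convex-ish and
smooth.  Passing the phantom suite demonstrates that the *measurement
pipeline* is correct and calibrated — not that any particular AI product
is acceptable on clinical data.  Real evaluations need real cohorts and
site-calibrated BTR/VTR and cut-offs.

## Problem sizes and determinism

Test and demo cohorts use 3–20 cases (500 for the binomial
rate-recovery check, with overlap metrics disabled where only decisions
matter); Monte-Carlo interval calibration uses 10,000 replicates of
n = 50; geometry oracles use 1,000 random convex polygon pairs against a
pixel-centre rasterisation oracle (320² grid on the tight bounding box,
max observed relative error ≈ 0.1%) and an O(n²) brute-force Hausdorff
loop.  All randomness flows from explicit integer seeds
(`numpy.random.default_rng` with seed sequences); figures regenerate
deterministically from the same config and seeds.
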