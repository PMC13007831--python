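# Methods

`thalnet` models the analysis chain used to relate structural connectivity
between seizure-onset zones (SOZs) and the thalamus to clinical outcomes
under thalamic responsive neurostimulation (RNS): probabilistic tractography
from SOZ regions to a thalamic segmentation, track-density probability maps,
electric-field modeling of the volume of tissue activated (VTA), two
engagement metrics, and nonparametric outcome statistics. Because no imaging
data are deposited for the 12-patient cohort whose summary tables ship as
fixtures, all imaging inputs are synthetic phantoms with known ground truth.

## Coordinate conventions

World space is RAS millimetres. Voxel indices are 0-based; the affine maps
voxel *centers* to mm. A continuous point belongs to the voxel whose center
is nearest (round half up). These conventions are asserted by fixed-affine
tests and used consistently by every intersection test in the package.

## Synthetic phantoms

Each phantom patient consists of:

* **Label map** (default 64³ voxels at 1.0 mm): cortex, white matter,
  brainstem, and a reduced thalamic segmentation {ANT, CM, MD, Pulv, other}
  as spheres/cylinders at fixed anatomical-scale positions. The full
  25-nucleus histological segmentation used clinically is deliberately
  reduced to the nuclei that matter for thalamic neuromodulation; the label
  dictionary is open so more can be added.
* **SOZ ROIs**: spheres of 10 mm radius placed in the cortical shell,
  matching the segmentation practice of drawing a sphere around the
  seizure-onset electrode contact that includes adjacent white matter.
* **Bundles**: tubes (radius 3 mm) around cubic-spline centerlines from each
  SOZ into a target nucleus. Inside a tube the orientation field carries a
  lobe along the centerline tangent with amplitude 1.0; background voxels
  carry an isotropic lobe at amplitude 0.05, below the 0.1 tracking cutoff,
  so streamlines cannot leave a bundle. Each bundle occupies its own lobe
  slot, so converging bundles coexist in shared voxels the way crossing
  fibers coexist in a fiber-orientation distribution; by default the two
  bundles' directions differ by >50° where they merge, which is beyond the
  45° turning limit, so streams cannot switch corridors.
* **Electrode**: one quadripolar depth electrode (3.5 mm center-to-center
  contact spacing), its cathode placed at a controlled offset from the
  target-nucleus center, perpendicular to the local bundle direction. The
  offset (0–6 mm across the default 12-patient cohort) is the single dial
  that varies engagement between patients; tract geometry is held fixed so
  the metrics, not the anatomy, drive the outcome signal.
* **Outcome model**: expected seizure reduction is a scaled logistic in the
  true activation proportion p — `100 / (1 + exp(-k (p - p0)))` with
  midpoint `p0 = 0.12` and steepness `k = 25` — plus Gaussian noise
  (sd 15 percentage points), clamped to [0, 100]. The midpoint and steepness
  were chosen so the printed per-patient range of activation percentages
  (5–29%) spans the outcome range, and `k = 0` gives an exact null. With
  noise sd 0 the link is strictly increasing in p.

### Geometric ground truth

The generator reports, per patient, a tracker-independent activation
proportion: the fraction of centerline-parallel curves — uniform offsets
across the bundle cross-section, carried in a rotation-minimizing normal
frame — that pass through the computed VTA. Three voxelization effects are
modeled so this oracle describes the corridor actually planted in the grid:

1. the tube, built as a union of balls around centerline samples, has
   hemispherical end caps; oracle curves are extended through them;
2. corridor membership is by voxel center, shortening each cap by half a
   voxel;
3. trajectories within half a voxel of the tube wall are not sustained by
   the voxelized corridor (one step at the rough wall exits into sub-cutoff
   territory and the streamline dies before reaching the thalamus), so the
   oracle samples the survivable cross-section of radius `r_tube − voxel/2`.

With these corrections the pipeline-measured proportion agrees with the
oracle within ±0.06 across the default cohort at 1.0 mm voxels (the test
suite asserts ±0.1). At 1.5 mm voxels the half-voxel wall model becomes too
crude (deviations up to ~0.13), which is why the default grid is 1.0 mm.

### What the phantoms do and do not emulate

They emulate the *logical* inputs of the analysis — orientation fields with
a dominant bundle direction, waypoint/exclusion anatomy, electrode geometry,
and a monotone engagement–outcome link. They do not emulate diffusion-MRI
signal formation, fiber dispersion or partial-volume effects, lesioned
anatomy, registration error, or the heterogeneity of real seizure networks.
Passing tests therefore demonstrate that the pipeline measures what it is
supposed to measure on data with known truth, not that the clinical effect
size would replicate in new patients.

## Tractography

Probabilistic streamline tracking with: seeding uniformly inside the SOZ
mask (rejection of sub-cutoff seed points), initial lobe sampled among
supra-cutoff lobes proportional to amplitude, bidirectional propagation
(two passes with opposed initial directions, concatenated), step 0.5 mm,
maximum turning angle 45° per step, maximum length 250 mm, amplitude cutoff
0.1, nearest-voxel lobe lookup without interpolation. At each step the
candidate lobes are those within the turning angle of the incoming direction
(lobes are axial; the sign better aligned with travel is used) and at or
above the cutoff; the next direction is drawn with probability proportional
to lobe amplitude. Generation continues until `n_select` streamlines are
retained or 100 × `n_select` seeds have been tried; the 100× factor reflects
that only ~8% of a 10 mm SOZ sphere intersects a 3 mm bundle, so most seeds
legitimately produce nothing. A streamline is retained only if it visits the
thalamus waypoint mask; a streamline with an endpoint in the brainstem mask
is rejected whole rather than truncated. On a field with exactly one
supra-cutoff lobe per voxel the sampler has no choice and the tracker
reduces to deterministic integration, which is how it is validated.

Per-SOZ tracts are merged by concatenation into a single per-patient tract;
counts are additive and provenance is preserved.

## Probability maps

The probability of connectivity at a voxel is the fraction of the tract's
streamlines with at least one point in the voxel (distinct-streamline
counting keeps values in [0, 1]; a streamline crossing a voxel twice counts
once). The "95%" threshold retains the smallest set of top-valued voxels
carrying 95% of the total visitation mass and zeroes the diffuse tail; ties
at the boundary value are all retained, and the mass target stays relative
to the raw map's total so the operation is idempotent. An alternative
percentile reading (zero voxels below the 5th percentile of nonzero values)
is provided as `threshold_map_percentile`; the mass interpretation is the
default because reported peak probabilities well below 1 imply the map
values are visitation fractions, for which tail-mass trimming is the
standard track-density operation.

## Stimulation field and VTA

The electric field is an analytic point-source superposition: each active
contact is a monopole at its center carrying a share of the programmed
current (cathodes split −I equally, anodes +I), in locally sampled scalar
conductivity — 0.33 S/m in gray matter (cortex and thalamic nuclei),
0.14 S/m in white matter and elsewhere. The field of a single cathode in
homogeneous tissue is `|E| = I / (4π σ r²)`, giving a threshold radius
`r* = sqrt(I / (4π σ E*))` — the closed form against which the gridded
implementation is verified (≈2.38 mm for 2 mA in white matter at the 0.2
V/mm activation threshold). The VTA is the set of voxels whose center field
reaches the threshold; bilateral VTAs are merged by voxel union. Evaluation
at a contact center is capped at 10⁶ V/mm rather than diverging.

Deliberate simplifications, exposed as configuration: conductivities are
interpreted in S/m (a literal S/mm flag exists but yields sub-millimetre
activation volumes inconsistent with clinically reported VTAs of order
100–700 mm³); the printed mA value is treated as total cathodic current
split equally among cathodes; pulse width and frequency are carried as
metadata but do not modulate the threshold. This is not a finite-element
four-compartment model — no electrode body, encapsulation layer, or
anisotropic tensors — and its volumes are checked for order-of-magnitude
plausibility (10–2000 mm³ across the programmed 0.5–6 mA settings), not for
equality with any finite-element result. The interface leaves room for a
different field backend.

## Engagement metrics

* **Activation proportion**: a streamline is activated iff any of its points
  falls in a VTA voxel (an alternative minimum-traversal rule was considered
  and rejected for lack of a principled length scale); the per-patient value
  pools counts across sides/tracts as Σ activated / Σ total, and the percent
  column is rounded half away from zero.
* **Peak probability**: maximum of the thresholded probability map inside
  the VTA, 0 if disjoint, ties broken at the lowest voxel index; per patient
  the maximum across sides is taken. The thresholded map is used because
  peaks are extracted from the maps as produced by the thresholding step; a
  raw-map option remains.
* **Pattern classifier** (heuristic, labeled as such in reports): dominant
  nucleus per tract is the thalamic label holding the most streamline
  endpoints (falling back to visited-point counts for pass-through tracts —
  endpoint counting is what separates a bundle terminating in CM from one
  merely passing ANT en route). Two or more tracts sharing a dominant
  nucleus → convergent; all-distinct dominant nuclei with overlapping
  thalamic footprints → transthalamic; one tract → single; otherwise
  unclassified.

## Outcome statistics

Seizure reduction is `max(0, 100 (pre − post) / pre)`; worsened patients
clamp to 0. Categories: responder (> 50%), partial (25–50%, both boundaries
included, consistent with a 50%-reduction patient being grouped with
partial/nonresponders), nonresponder (< 25%). Responders are compared with
pooled partial/nonresponders.

* **Spearman** uses average ranks for ties; the p-value is the
  t-approximation with n−2 df, with an exact permutation option used
  automatically for n ≤ 8.
* **Mann–Whitney U** is exact by full enumeration of all C(n₁+n₂, n₁)
  group assignments (with average-rank tie handling) for combined n ≤ 20 —
  792 assignments for the 7-vs-5 split — otherwise a normal approximation
  with tie correction. Two-sided p doubles the smaller tail including the
  point mass, capped at 1.
* IQR is the 25th–75th percentile with linear interpolation.

Both exact paths are hand-enumerated and cross-checked in tests against
scipy and against independent brute-force enumerations written inside the
tests; the asymptotic flavors match scipy's formulas.

The correlation between activation and outcome is computed from unrounded
count ratios, not the rounded percent column (a sensitivity check in the
test suite shows the difference is < 0.02 in rho on the packaged tables).

## Packaged tables

Two CSV fixtures transcribe the published per-patient tables of the
12-patient cohort (clinical/demographic variables; imaging counts,
stimulation settings, seizure frequencies). One transcription note: case 3
prints a seizure reduction of 95 while the printed pre/post frequencies
(750 → 4 per month) give 99.47; the fixture keeps the printed column
verbatim and the reduction operation computes from pre/post — the response
category is unaffected (both exceed 50). `reproduce_paper_tables()`
recomputes the activated-percent column (12/12 rows match), the response
counts (7/2/3), the activation–reduction Spearman (rho rounds to .78), and
the cohort mean age (26) from these fixtures.

## Problem sizes and reproducibility

Default study conditions: 12 patients, 64³ grid at 1.0 mm, 5000 streamlines
requested per SOZ, FOD cutoff 0.1, 10 mm SOZ radius, 3.5 mm contact
spacing, 0.2 V/mm threshold. The test suite and the acceptance script run
the same pipeline at 120–800 streamlines per SOZ, which keeps Monte-Carlo
error on the proportion below ~0.03 while finishing in seconds per patient;
the Monte-Carlo power/calibration loops (100 effect replicates, 1000 null
replicates) resample outcomes from the outcome model on fixed geometric
proportions rather than re-running tractography per replicate, since the
statistic under calibration is a function of the outcome noise only.

Everything is seeded: one global seed derives per-stage and per-patient
substreams via `numpy.random.SeedSequence`, and a run directory's manifest
records a config hash plus SHA-256 checksums of every artifact; rerunning
with the same config and seed reproduces identical checksums.

## Known limitations

* The point-source VTA underestimates low-amplitude volumes relative to
  finite-element models (no encapsulation or pulse-width dependence).
* The pattern classifier reconstructs a qualitative taxonomy; its labels
  are heuristic and should not be over-read.
* Group medians and p-values for the peak-probability comparison on the
  *clinical* cohort cannot be recomputed here: the per-patient peak values
  were never published, so those quantities are validated only on phantoms.
* Tracker agreement with the geometric oracle degrades at voxel sizes
  coarser than ~1 mm relative to a 3 mm bundle radius (wall-roughness
  effects grow with voxel size).
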