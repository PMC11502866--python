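# Methods

## Scope and conventions

All world coordinates are nanometres, ordered (z, y, x) to match numpy
indexing of label volumes; voxel spacing is explicit per axis and never
assumed isotropic. A world point `p` belongs to voxel `floor(p / spacing)`
(half-open voxels); voxel centres sit at `(i + 0.5) * spacing`, and
interpolated sampling of scalar fields is defined on those centres.
Microtubule traces are inputs (SWC or node–edge CSV); this package does not
trace tubules from raw grayscale EM, form images (no noise/PSF model), or
process fluorescence images — marker positivity is an input annotation.

## Skeleton morphometry

Arc length is the sum of Euclidean segment lengths of the raw trace.
Tortuosity is arc length over end-to-end chord distance — the standard
estimator — computed on the raw trace rather than a resampled one to avoid
smoothing bias; a closed trace (coincident endpoints) yields an `inf`
sentinel with a warning instead of an exception so batch runs survive.
Resampling is arc-length-uniform linear interpolation with endpoints
preserved; it exists to define the point-index axis of distance profiles,
not to alter geometry.

Doublet pairing is greedy mutual-nearest matching on the mean inter-curve
distance over 50 evenly spaced arc fractions of the shorter member, with a
35 nm acceptance gap (A–B spacing in real doublets is 23–30 nm; adjacent
doublets on a ~85 nm ring are ≥ ~58 nm apart). One refinement proved
necessary: when both members carry a known A/B class, only A–B combinations
are candidates. Two doublets displaced toward the cilium centre bring their
B-tubules arbitrarily close together near the axis, and class-agnostic
matching can then pair B with B; a doublet is one A- plus one B-tubule, so
the class constraint encodes exactly that. Unknown-class tubules pair
freely. Basal-body triplet stubs are not pairing candidates and are
excluded by callers before pairing.

Group summaries use the sample SD (n−1 denominator) throughout, matching
the ± convention of the published figure legends; a single-value group
reports SD 0 with a warning.

## Membrane-distance profiles

The distance field is the Euclidean distance transform of the complement of
the ciliary-membrane label (`scipy.ndimage.distance_transform_edt` with
per-axis sampling), i.e. distance to the membrane shell voxels themselves,
not to extracellular space. Profiles sample this field by trilinear
interpolation at points resampled every voxel edge along the tubule;
out-of-bounds points are excluded and counted.

Smoothing is a 1-D Gaussian along the point-index axis. The smoothing scale
"σ = 3" is interpreted as 3 points on that axis with the resampling step
equal to one voxel edge; both are parameters. The reflect boundary with a
unit-sum kernel preserves the profile mean exactly; σ = 0 is the identity.

A *major transition* — a doublet leaving the membrane toward the cilium
centre — is an explicit, documented operationalization of what was a visual
call in the source analyses: the smoothed profile exceeds θ = 70 nm (the
midpoint of the ~40 nm peripheral and ~100 nm displaced levels) for at
least 10 consecutive points (suppressing voxel noise); one event per
contiguous run, onset at the run's first index, peak its maximum. In the
validation suites, events are evaluated per doublet on the outer (A)
member's profile: the B-tubule sits 25 nm inside A, so its baseline is
~65 nm — right at the threshold — and per-B detection would be
systematically ambiguous, whereas the doublet's displacement target is
defined by its A member.

## Pocket and contacts

Pocket length: the axis polyline (base first) is resampled every 50 nm; at
each point a ring of 36 probes at `membrane_radius + 28 nm` (in the plane
normal to the local tangent) is labelled, and the enclosure fraction is the
share of probes inside the parent cell. The pocket is the initial
contiguous run with fraction ≥ 0.75; its arc length is the pocket length.
The 28 nm probe offset clears the 3-voxel membrane shell plus the few-nm
pocket cleft; the 0.75 threshold, like the transition rule, is an explicit
stand-in for visual identification and is exposed as a parameter.

Contacts: for each non-parent, non-cilium label, ciliary-membrane voxels
within `gap_max = 20 nm` of that label (a "few nanometres" of true gap plus
one 8 nm voxel of segmentation slack) are clustered with 26-connectivity;
clusters of ≥ 10 voxels become contact records with area = count × voxel
face area and the minimum gap. Distances are exact: the nearest-target
search queries a KD-tree over the target's surface voxels, restricted to
the membrane voxels inside the target's dilated bounding box (any membrane
voxel outside it is provably farther than `gap_max`). Shrinking `gap_max`
can split a patch into several clusters on a jagged voxel surface, so the
monotonicity guarantee is at the neighbour level: a neighbour detected at a
smaller gap is always detected at a larger one.

Contact-fraction and marker-positivity statistics are computed per
biological replicate (animal or islet) first and then summarized as
mean ± sample SD across replicates, matching how the published percentages
are reported.

## Expansion calibration and group statistics

The expansion factor divides the measured (true-scale) proximal basal-body
width by the 225 nm reference of that structure — the biological ruler —
e.g. 968 / 225 ≈ 4.3. FWHM uses the global profile minimum as baseline
(simplest defensible choice; a fixed-baseline mode exists) and locates the
two half-level crossings adjacent to the peak by linear interpolation,
erroring when a crossing is missing. The expansion-corrected nucleus
cross-sectional size is `√area / factor`, exactly invariant under
`area → f²·area, factor → f·factor`.

The two-sample t-test is computed from (mean, SD, n) summaries so printed
values are directly testable; raw-data input summarizes then delegates.
Student's pooled variant is the default because it reproduces the published
cilium-length p-values from the printed summaries (beta vs non-beta
p = 0.655 against the printed 0.6546; both ductal comparisons < 1e-10 with
the published ordering); Welch (p = 0.608 for the same comparison, farther
from the printed value) is available by flag. No multiple-testing
correction machinery is provided, matching the three uncorrected pairwise
comparisons being reproduced.

The isotropy check compares pre-expansion measurements with corrected
post-expansion measurements by that t-test at α = 0.05. The accompanying
simulation models a fixed true structure measured with 3% multiplicative
Gaussian noise, n = 25 per arm, factor 4.2; areas are products of two
measured orthogonal extents. Under isotropy the test is calibrated (~95% of
replicates exceed p = 0.05); a 20% single-axis stretch applied to linear
dimensions is a ~6.7σ effect and is flagged in essentially all replicates.

## Synthetic scenes

The generator is the package's source of ground truth and emulates the
study conditions, not arbitrary data:

* 9 doublets on a ring at `membrane_radius − 40 nm` (radius 125 nm by
  default — the membrane radius of beta-cell cilia is not published, so a
  typical primary-cilium radius is used and exposed); A and B are parallel
  offset curves 25 nm apart with B pointing toward the axis; basal-body
  triplet stubs of 500 nm; B truncated before A.
* Mouse FIB-SEM preset: 4 nm voxels, A lengths ~ N(4570, 140) nm, B ~
  N(3030, 1010) nm clipped to [800, A−200]; human tomography preset:
  1.307 nm voxels, A ~ N(2050, 1010), B ~ N(1200, 650) with inverted
  termination allowed. The clipping keeps B physical (shorter than A,
  longer than the basal body) and slightly biases the realized B mean low.
* Displacement events blend the doublet's radial position by a smoothstep
  over 500 nm of arc from the ring to `membrane_radius − 100 nm`, then
  hold — matching the gradual profile transitions being emulated. Onsets
  are drawn in 1200–2600 nm; 1–2 doublets per mouse scene.
* Wiggle (the tortuosity driver) is a sum of 3 low-frequency sinusoids with
  random phases per doublet and per transverse axis, with the total
  transverse magnitude bounded by the 8 nm amplitude so that a
  non-displaced tubule's membrane distance stays within the ±(1 voxel +
  10 nm) band around 40 nm. Both members of a doublet share wiggle and
  displacement, keeping the pair parallel.
* Curves are sampled every 8 nm of axis and truncated at the exact
  requested arc length (interpolated endpoint), so truth lengths equal the
  request to numerical precision; truth tortuosity is computed inline from
  the emitted points, independently of the morphometry module.
* Voxelization: membrane shell of 3 voxels at the membrane radius, lumen
  fill, basal parent-cell slab, pocket realized as parent material wrapping
  the proximal `pocket_length` with an 8 nm cleft, neighbours and an
  optional axon as disjoint angular sectors at their requested surface
  gaps (6–14 nm for in-range neighbours, 40–60 nm for out-of-range ones,
  10 nm for the axon). Population draws are normal, floored at zero, which
  slightly biases means upward for large SD/mean ratios.

What the generator does *not* emulate: image formation (no noise, PSF or
contrast), curved cilium axes (the axis is straight; tortuosity lives in
the tubule wiggle), microvilli, vesicles, or fluorescence. Passing
recovery therefore demonstrates the correctness of the measurement
operations on clean segmentations, not robustness to segmentation error in
real volumes.

## Validation problem sizes and numerical choices

The recovery suite runs 20 mouse-preset scenes (~1250×126×126 voxels at
4 nm); the distance-field oracle runs 20 random 64³ volumes with
anisotropic spacings against an exact KD-tree nearest-neighbour search; the
isotropy suite runs 100 replicates. These sizes make the full validation
run in a few minutes on one CPU while keeping every per-scene condition at
the study's stated voxel sizes and tubule dimensions. All randomness flows
through explicit integer seeds (`numpy.random.default_rng`); regenerating
with the same seed is bit-identical.

Degenerate inputs are contracts, not crashes: single-point polylines
measure length 0 with a warning; flat FWHM profiles and missing membrane
labels are errors; zero-SD t-tests are flagged degenerate; zero-total
islets and zero-contact groups are excluded with warnings.

## Known limitations

* NRRD volumes are not supported (TIFF/HDF5 only); SWC is the only skeleton
  exchange format besides node–edge CSV.
* The pocket rule (ring enclosure ≥ 0.75) and the transition rule
  (70 nm / 10 points) are explicit operationalizations of visual calls;
  they are parameters, not claims of equivalence to expert annotation.
* Contact counting on voxelized surfaces is resolution-dependent: the
  recorded minimum gap is a centre-to-centre voxel distance and carries
  one-voxel discretization slack.
* The human tomography preset voxelizes to very large volumes at 1.307 nm;
  routine validation voxelizes the mouse preset and exercises the human
  preset at the skeleton level.
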