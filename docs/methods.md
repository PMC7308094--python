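# Methods

This note documents the models, statistics and numerical choices behind
`conemosaic`, and what the synthetic-data tests do and do not establish
about real microscopy data.

## Coordinate frame and geometry

All analysis is planar: positions are in micrometres in a retina-centred
frame with the origin at the optic-nerve head, +y dorsal and +x nasal.
Flat-mount curvature is ignored.  Quadrants (DT, DN, VT, VN) are the four
sign quadrants of this frame; the DT–VN axis, along which the 1 mm
circular analysis samples are placed (centres 1 mm from the origin), is
the (−1, +1)/√2 → (+1, −1)/√2 diagonal.

## Synthetic retina generator

**Positions.** Cone and SCBC mosaics are generated by random sequential
adsorption (RSA): uniform proposals are accepted if no prior point lies
within the hard-core distance (4 μm for cones, 10 μm for SCBCs), with
position-dependent thinning for density gradients.  RSA reproduces the
"quasi-even" character of biological mosaics with a single interpretable
parameter and exact reproducibility from a seed.  The generator fails
explicitly (rather than stalling) if it jams — 30,000 consecutive
rejections or an overall attempt budget — which happens near ~43,500
points/mm² for a 4 μm core, safely above the 17,300 cones/mm² ceiling of
the mouse range.  The realized count equals the target count by
construction whenever the request is feasible.

**Cone classes.** Each cone is MIXED (M⁺S⁺), TRUE_S (S⁺M⁻) or M_ONLY
(M⁺S⁻) with probabilities that are logistic functions of the
dorso-ventral coordinate.  The pigmented preset uses a true-S profile with
asymptotes 1% (dorsal) and 33% (ventral), midpoint −600 μm and slope
250 μm, and an M-only profile with asymptotes 97%/0%, midpoint 0 and slope
150 μm; the albino preset changes the ventral true-S asymptote to 29% and
the dorsal M-only asymptote to 7%.  Midpoints and slopes were calibrated
once so that sampling bands ±1.5 mm from the optic-nerve head reproduce
the reported regional compositions while the whole-retina true-S fraction
comes out near 10%.  Where probabilities would momentarily sum past 1 the
pair is renormalized.  Expression levels (used only for rendering) follow
shallow logistic gradients with Gaussian jitter, clipped to [0.3, 1] so
that every expressing cone is detectable; pedicles are displaced from the
soma by an isotropic Gaussian (σ = 3 μm, truncated at 10 μm).

**Clonal clustering.** The biological speculation that ventral true-S
enrichment arises by clonal expansion is emulated by a Neyman–Scott-style
relabelling: mother cones are drawn among true S-cones (Poisson rate per
mm², default 3), and each converts its k nearest non-true-S cones within
18 μm to TRUE_S (k constant or Poisson, default mean 5).  An equal number
of true-S cones far from any mother are converted away, so the total
true-S count — and hence the proportion held fixed by the shuffled null —
is exactly conserved.  No quantitative clustering model is reported for
the real data; these defaults are free parameters chosen to give clusters
of roughly half a dozen cells at ventral densities.

**SCBC mosaic and wiring.** SCBCs form a sparser hard-core mosaic with a
shallow ventral gradient (defaults 430 → 690 cells/mm², ceiling 1,400),
chosen so the dorsal true-S:SCBC density ratio is ≈ 1:3.6 under the
default cone preset while keeping the gradient visibly shallower than the
cone gradient.  Wiring is distance-limited (default dendritic reach
80 μm): in the dorsal/divergent mode each true-S pedicle contacts its k
nearest SCBCs within reach, k ~ 1 + Poisson(mean − 1) with mean 3.8; in
the ventral/convergent mode each SCBC contacts its m nearest pedicles,
mean 4.6.  The truncation at 1 keeps every analyzed cell connected, as in
the counting procedure it emulates.  Optional "blind endings" (dendrites
ending on no pedicle) are appended per SCBC at a configurable rate and
carry a null pedicle id.

**Rendering.** Each cone expressing a channel's opsin contributes an
isotropic Gaussian spot (σ = 1 μm at 0.5 μm/px by default, amplitude
proportional to expression level) over a constant-plus-gradient
background, with Gaussian (default, σ = 60 counts against an amplitude of
4,000) or Poisson noise, quantized to 16-bit.  The ground-truth table
carries sub-pixel centroids in both retina and pixel coordinates.

## Detection

The counting routine is: background subtraction → threshold at a fixed
fraction (default 0.157) of the post-subtraction channel maximum → binary
median despeckle (3 px) → marker-controlled watershed → connected
components → size/shape filter (2–30 μm², circularity ≥ 0.3) →
intensity-weighted centroids.  Background subtraction uses a white top-hat
with a disk structuring element (radius 10 μm), which removes smooth
background exactly as a rolling ball does for these field sizes while
remaining fast and monotone.

The threshold reference is a package decision: the 15.7% figure is applied
to the maximum of the background-subtracted channel.  The associated
background-noise figures (9.6 ± 1.2% and 15.2 ± 3.2% for the S and M
channels) are recorded here as the rationale for a threshold of that
magnitude; they play no computational role.

**Watershed markers.** Markers are h-maxima of the lightly smoothed
(σ = 1 px) background-subtracted intensity, with h expressed as a fraction
of the channel maximum (default 0.05); the watershed floods the negated
intensity within the threshold mask.  Distance-transform markers were
considered and rejected: two cones 3 μm apart at σ = 1 μm merge at the
default threshold into an essentially convex blob whose distance transform
has *no* saddle, so no h-minima setting can split it, while the intensity
profile between the two peaks dips by ~35% and splits cleanly.  A side
benefit is an exact monotonicity property: the markers do not depend on
the threshold, so lowering the threshold (growing the mask) can only add
pre-filter objects, never remove them.

Validation is the squared Pearson correlation between automated and
reference per-field counts; vectors with zero variance yield a flagged NaN
rather than a spurious 1.

## Typing and topography

S- and M-channel detections are matched by mutual nearest neighbours
within 3 μm; mutual matching makes the pairing deterministic, symmetric in
the input order, and uses each detection at most once.  Matched pairs
become MIXED cones at the midpoint; unmatched S and M detections become
TRUE_S and M_ONLY.  Regional composition pools three 135 × 135 μm squares
per region at dorsal (+1.5 mm), medial (off the nerve head at +0.3 mm
nasal) and ventral (−1.5 mm) locations.

Density maps bin positions on an 83.3 μm grid aligned to integer bin
multiples (making the grid exactly equivariant under one-bin
translations); density is count divided by bin area, and each population
carries its 10-step color scale (17,300 cones/mm² for all/mixed/M-only;
5,000 for true S and albino M-only; 1,400 for SCBCs).  No smoothing is
applied by default — contour interpolation is a plotting concern.
Quadrant profiles use annular sectors of width 166.6 μm (two grid bins;
the original bin width is not reported) and flag bins with fewer than 20
cones.

## Regularity and clustering statistics

For a circular sample of N cones in area A, the search radius
r = 3·√(A/(√2·π·N)) estimates the first minimum of the density recovery
profile — the radius enclosing a cone's first tier of neighbours in an
even mosaic.  The radical is read as 3 × square root; a cube root would
not carry length units.

Cones closer to the sample edge than r are excluded as *focal* points for
all three statistics but remain as potential neighbours, nearest-neighbour
candidates and Voronoi generators.  NNRI and VDRI are mean/SD ratios using
the sample SD (n − 1), appropriate for the small dorsal focal counts; an
SD of zero (perfect lattice) is flagged as infinite regularity rather than
an error.  For VDRI, cells that are unbounded *or extend beyond the sample
boundary* are excluded: a near-edge generator's cell can be finite yet
arbitrarily large (its vertices fall far outside the disk), and a single
such cell destroys the area SD — on 5,000-point random patterns this rule
recovers the expected Poisson–Voronoi value (VDRI ≈ 1.9, area CV ≈ 0.53),
and the NNRI of the same patterns matches the closed form
0.5·√(4π/(4−π)) ≈ 1.913.

SCNR for a focal cone is the number of true S-cones among all *other*
cones within r, divided by the number of those cones; the focal cone is
excluded from its own denominator because self-inclusion would
mechanically inflate the true-S focal mean.  Focal cones with no
neighbour are dropped and counted.  Means are reported over true-S focal
cones and over all focal cones; for label-exchangeable samples the
all-cones mean equals the true-S proportion exactly in expectation.

**Null models.** The shuffled null permutes cone identities uniformly
over the fixed positions, holding class counts constant.  The distributed
null spreads K virtual points (K = true-S count) by pairwise
inverse-square repulsion with a fixed 2 μm step along the net force and a
reflecting disk boundary, keeps the iterate with the largest minimum
pairwise distance (the fixed-step dynamics oscillate around the optimum),
and snaps each virtual point to its nearest unclaimed cone position,
greedily by snap distance with deterministic tie-breaking.  The package
default is 500 iterations; the ensemble-based tests use 120–300, since the
separation between distributed and shuffled metrics is enormous (the
ordering holds in ≥ 99% of paired draws already at ~100 iterations) and
the shorter runs keep 200-simulation ensembles inexpensive.

Ensembles default to 200 simulations; a simulation with an undefined
metric is regenerated and logged, and the ensemble aborts if regenerations
exceed 10% of the requested count.  Real measurements are normalized as
z = (real − ensemble mean)/ensemble SD; a Kolmogorov–Smirnov check against
a fitted normal is provided for the ensemble values.  Across samples,
one-tailed one-sample t-tests compare the z-scores to 0 (direction
"greater" for SCNR clustering, "less" for regularity deficits), with the
degenerate all-zero case reported as the p = 0.5 boundary.

**Exchangeability caveat.** The shuffled null tests whether labels are
exchangeable across positions.  A dorso-ventral gradient *within* a sample
is itself a violation: an unclustered ventral sample generated with the
full strain preset shows z(NNRI) ≈ −6 purely from the gradient.  This is a
property of the statistic, not an artifact — a real retina's gradient
contributes to its clustering signal in the same way.  Calibration checks
(the ±2.5 SD band containing ≈ 99% of shuffled samples, and the
false-positive rate of unclustered mosaics) therefore use samples with a
spatially constant true-S fraction, where exchangeability holds by
construction; the leave-one-out calibration of the shuffled ensemble
itself is insensitive to this choice because every value in it is a
shuffled draw.

## Connectivity counting rules

Blind endings are never counted.  Within one SCBC, repeated records of the
same branch touching the same pedicle collapse to a single contact;
distinct secondary bifurcations reaching a pedicle are retained as
multiple contact *sites* on one edge.  Divergence (SCBCs per pedicle) and
convergence (pedicles per SCBC) are distinct-partner counts — the reported
3.8/4.6-type means are partner counts, so site multiplicities only matter
for the cluster-convergence report.  Group means are computed per retina
and then averaged, with the SD taken across retinas.  True-S clusters for
the convergence report are connected components of the 18 μm neighbour
graph with at least 3 cones (configurable); for each cluster the SCBCs
contacting ≥ 2 of its pedicles are listed, flagging those contacted by a
majority of the cluster.

## Pipeline, determinism and problem sizes

All randomness derives from a single master seed; identical configurations
produce byte-identical CSV outputs.  Unknown configuration keys are
rejected.  When the detection stage is enabled, the pipeline renders the
nine 135 μm typing squares in both channels, detects, classifies and uses
the result for the composition table (full-retina rendering at 0.5 μm/px
would be an ~8 gigapixel image and is out of scope); topography and mosaic
statistics always consume the generator's ground-truth mosaic.

Default problem sizes were chosen so that a complete study-scale run — a
2 mm-radius retina at 12,000 cones/mm² (~150,000 cones), two 1 mm samples
with 200-simulation shuffled ensembles — completes in a few minutes on one
CPU; the bundled tests use smaller disks (150–600 μm) where a property
does not require full scale.

## What the synthetic tests do and do not show

The generator matches the statistical structure the analysis assumes —
hard-core spacing, opposing logistic opsin gradients, a conserved-count
clustering surrogate, distance-limited wiring with truncated-Poisson
degrees, Gaussian-spot imaging.  It does not emulate optical aberrations,
uneven illumination, antibody-labelling variability, tissue tears or
curvature-induced distortion.  Passing tests therefore establish that the
*implementation* of each statistic is correct and well calibrated under
its own null, and that generator parameters are recoverable at realistic
densities and sample sizes — not that the detection defaults are optimal
for any particular microscope's images.

## Known limitations

* The repulsion dynamics are a heuristic spreader, not an optimal
  max–min solver; it is only required to dominate the shuffled null,
  which it does with a wide margin.
* RSA mosaics are more irregular than real cone mosaics shaped by
  developmental interactions; NNRI/VDRI of the full synthetic mosaic are
  accordingly modest (≈ 2–4), which is sufficient for label-level
  statistics but not a model of mosaic development.
* Edge handling near the retinal margin (partial quadrant-profile bins,
  cut edges of real flat-mounts) is simplified: the synthetic retina is a
  clean disk.
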