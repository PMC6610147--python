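# Methods

`neuropheno` implements four image-based phenotyping assays for cultured
human neurons — 24-hour neurite outgrowth, growth-cone area, axonal
swelling burden, and culture composition — together with a synthetic
fluorescence-scene simulator that carries full ground truth and a
replicate-level statistical layer. This note records the models, the
parameters that matter, and the numerical choices, in enough detail to
reproduce or criticize them.

## The scene model

A scene is one field of view of a sparse post-mitotic culture
(default 332.8 µm square, 25 neurons ≈ 2.2·10⁴ cells/cm², matching the
low-density replating used for short-term outgrowth read-outs).

**Somata and nuclei.** Nucleus radii are Uniform(3.2, 3.9) µm; somata extend
0.5 µm beyond the nucleus. Placement is dart-throwing with a separation
slack of 1.5 µm; a configurable fraction of nuclei (default 8%) is placed
as deliberately touching pairs (centres at the sum of radii minus 0.3 µm)
to exercise seed-based splitting. 10% extra pyknotic dead-cell nuclei
(radius 1.3–2.0 µm, DAPI-bright, no TUBB3) exist solely to exercise the
size-exclusion filter.

**Neurite trees.** Per-neuron total neurite length is lognormal with the
preset's mean and coefficient of variation (default CV 0.5; the source
statistics give only group means and SDs, and outgrowth lengths are
strictly positive and right-skewed). The total is split over 1–3 root
neurites (probabilities 0.3/0.5/0.2) by a Dirichlet(2) weight vector; a
root longer than 12 µm bifurcates once with probability 0.35. Polylines
are persistent random walks (step 2 µm, heading noise SD 0.18 rad)
reflected at the field border; the turning noise is deliberately gentle so
the curvature radius stays far above the ribbon width and PSF scale —
sub-resolution wiggle would be erased by rendering and no measurement
could recover it. Arc length is exact by construction (each step consumes
exactly its length), so ground-truth totals equal the sum of branch arc
lengths to 10⁻⁶ µm.

**Between-replicate effects.** Each biological replicate draws one additive
shift of the neurite-length mean, Normal(0, sd) with sd equal to the
published between-replicate SD (11.1 µm control, 5.4 µm patient),
truncated so the shifted mean stays inside the published range of
replicate means (39–75 µm and 17–39 µm). The truncation is what makes both
published facts — the SD *and* the range — hold simultaneously; a plain
normal with sd 11.1 puts only ~88% of replicate means inside 39–75 µm.
The truncation shifts the control grand mean down by ≈1.4 µm (−2.3%),
which is treated as part of the model. Growth-cone area means get the same
treatment (SDs 0.9 / 1.0 µm², ranges 4–17 / 20–37 µm²).

**Growth cones.** One cone per neurite leaf with probability 0.8; areas
lognormal (preset mean, CV 0.4), rendered as bright disks centred on the
leaf tip over a faint actin-positive neurite background.

**Axons and swellings (day-50 presets).** Each neuron grows one axon
(lognormal length, mean 400 µm, CV 0.3; smooth walk, step 3 µm, heading
noise 0.15 rad) of baseline width 0.6 µm, plus two MAP2-positive dendrites
(40–90 µm, width 1.2 µm). Swelling counts are Poisson with the preset's
rate over the axon's full arc length; diameters are Uniform(1, 7) µm;
positions are uniform over the distal portion of the arc (starting at
max(20 µm, 20% of arc)), reflecting the observation that varicosities
cluster distally and keeping them clear of the soma-proximal stretch where
dendrites fasciculate with the axon. Rendered axonal intensity scales with
local thickness, so beads are proportionally brighter than the shaft.

**Presets.** `control-24h` / `spg4-24h` carry the published outgrowth and
growth-cone statistics (60.6 / 29.4 µm; 11.2 / 27.9 µm²);
`control-d50` / `spg4-d50` the swelling rates (0.07 / 1.54 per mm);
`gaba-control` / `gaba-spg4` share one parameter set by design, encoding
the absence of a genotype effect in GABAergic cultures; `composition`
carries the culture fractions (97.7% neurons, 92.1% projection neurons
among them; projection identity maps to TBR1 with p=0.55 and CTIP2 with
p=0.65, conditioned on at least one).

**Rendering.** Structures are rasterized (Bresenham centrelines dilated to
the nominal width; disks by inclusive Euclidean tests), composited by
maximum, placed on a background plane with a random tilt of up to ±15%,
blurred with an isotropic Gaussian PSF (σ 0.4 µm), and degraded with shot
noise (0.1 photons per count) plus Gaussian read noise (SD 30 counts)
before clipping to 16 bits at 0.325 µm/px over 1024². These optics are
invented plumbing — the source acquisition parameters are not stated —
chosen so the 1 µm swelling threshold spans ≥3 px. With noise and blur
disabled the forward model is exact: every object is recoverable by
thresholding, which the oracle tests exploit.

What the simulator does **not** emulate: uneven illumination beyond a
planar gradient, optical aberrations and depth effects, autofluorescence
texture, fasciculation and contact-mediated growth, variable staining
efficiency, segmentation-relevant debris other than pyknotic nuclei.
Passing recovery tests therefore demonstrates correctness of the
measurement chain under a controlled forward model, not robustness to
every real-world artifact.

## Measurement chain

**Nuclei.** Rolling-ball background subtraction (radius 25 µm, estimated at
4× reduced scale for speed), Otsu threshold, speck removal, hole filling.
Markers for the watershed are the exact-EDT erosion of the foreground by
2.2 µm followed by a 3×3 opening (which snaps single-pixel bridges
surviving between the cores of marginally overlapping nuclei); components
that erode away keep a centroid seed. Watershed runs on the negated
distance transform. The retained-area gate is [25, 300] µm²: healthy
nuclei occupy 32–48 µm², debris stays below ~15 µm². Excluded objects are
reported with reason "size". The erosion depth and gate were tuned on the
simulator and are exposed in `NucleiParams`.

**Neurites.** The TUBB3 channel is enhanced by adding back a white top-hat
(2 µm disk) — monotone, non-negative, and contrast-increasing for thin
ridges — then thresholded (Otsu). The nucleus mask dilated with the 7×7
pixel kernel is subtracted, excluding somata. The declared reference for
length is the chain-code rule on the thinned skeleton: 1·pixel_size per
4-neighbour step, √2·pixel_size per diagonal. Three numerical points:

- *Redundant-diagonal reduction.* A diagonal adjacency whose elbow pixel is
  also foreground is not an edge (the path runs through the elbow);
  without this rule corners and junctions create spurious triangles and
  double-counted length.
- *Idempotent thinning.* A mask that is already 1 px wide (no 2×2 block) is
  traced as-is; running thinning anyway would clip elbow pixels.
- *Tip extension.* Thinning retreats a ribbon's medial axis from the mask
  end by about its half-width. Terminal edges are lengthened by
  max(EDT(tip) − 1 px, 0)·pixel_size; the correction is identically zero
  for 1-px-wide masks, so the chain-code reference examples are unchanged.

The chain-code rule overestimates the analytic length of a straight
segment by up to +8.2% (at 22.5°), +5.5% on average over directions; tip
retreat partially cancels it, leaving a net bias of roughly +3–4% which
the oracle test bounds at 5% in aggregate.

Skeleton components are assigned to cells through root contact: a
component touching (within a few pixels, allowing for tip retreat) exactly
one 7×7-dilated soma belongs to that nucleus; components touching several
are split geodesically — each chain step goes to the nucleus with the
shorter along-skeleton distance (ties to the lower label) — and flagged
shared; unattached components are reported unassigned. Short unattached
components (<5 µm) are dropped as specks; soma-attached stubs are kept at
any length, since a 4 µm process emerging from a soma is a neurite, not a
speck. Neurons without any detected neurite enter the per-neuron table
with total 0, and are included in group means by default; the
`mean_neurite_length_um` column carries the per-root alternative reading.

**Growth cones.** The actin channel is median-filtered (3 px) and Otsu
thresholded; foreground objects are split at the waist of their distance
transform (watershed from EDT maxima ≥2 µm apart) so cones from
neighbouring tips fused by blur are measured separately. An object is a
growth cone iff it overlaps the neurite mask by ≥1 px *and* its centroid
lies within 5 µm of a skeleton endpoint ("at the end of a neurite"; the
source does not quantify "end", 5 µm is the default gate). Per-object area
is refined at half-peak — the footprint above background + 0.5·(object
peak − background), connected to the object — which makes the area
independent of where the global Otsu level happens to land in the
histogram mix and reduces to the exact footprint in the noise/blur-free
limit. Objects below 2 µm² are rejected as noise. The replicate statistic
is the mean over retained cones (per-cone, not per-neuron). Condition
means can be expressed relative to untreated controls for drug plates.

**Axons and swellings.** TAU1 segmentation is ridge-calibrated: a robust
(median + 4·MAD) provisional mask gives a provisional skeleton; the median
image intensity along it estimates the shaft brightness; the final
threshold is background + 0.75·(ridge − background). This keeps the
sub-micron shaft mask near its true width under PSF blur — a half-max or
global-Otsu threshold widens a 0.6 µm line past the 1 µm rule and floods
the detector. When a MAP2 channel is present its dilated mask is
subtracted (default on), except where TAU1 exceeds 3 shaft units above
background: a bead crossing a dendrite is still axonal. Skeleton fragments
shorter than 5 µm are dropped unless they contain supra-micron structure
(a bead isolated by dendritic subtraction must survive). Spur pruning uses
3 µm here because large beads shed medial-axis spurs up to about half
their diameter.

Local diameter along the skeleton is (2·EDT − 1 px)·pixel_size; the −1 px
corrects the half-pixel overshoot of the distance transform at a
centreline (a 3-px-wide line reads 3 px, not 4). Swellings are maximal
runs with diameter > 1 µm, merged along the arc within 3 µm and then
positionally (one physical bead can put runs on several graph edges, since
the medial axis of a large blob branches). Three guards target the
dominant false positives of dense networks: candidates near (within 2 µm
of) a *thin* junction are vetoed (two crossing sub-micron axons are
locally wider than 1 µm; junctions inside genuinely wide beads are
exempt); runs shorter than 0.25 µm along the arc are vetoed (single-pixel
bumps); and when the intensity image is supplied, a candidate must be ≥3
shaft units above background — a bead is a three-dimensional bulge with
proportionally more fluorophore, while even a triple stack of crossing
shafts stays below about three. The guards cost sensitivity only below
≈1.35 µm diameter. The rate is count / TAU1⁺ skeleton length in mm; a
blank channel yields a flagged result, never 0/0. The automated detector
replaces a manual counting step by design; its acceptance standard is
equivalence to simulation ground truth, where it achieves recall ≈0.97
and precision ≈1.0 at default noise.

**Composition.** Per-marker thresholds default to Otsu over
nucleus-restricted intensities; a nucleus is positive when ≥50% of its
pixels exceed the threshold (the co-localization criterion; the 50%
overlap fraction is this package's choice). Marker signal outside every
nucleus contributes to no call. Reported: % TUBB3⁺ of retained nuclei,
% TBR1⁺, % CTIP2⁺, % projection (TBR1 ∪ CTIP2 among TUBB3⁺), % double
positives (TBR1 ∩ CTIP2).

## Statistics

Tests run on biological-replicate means (the unit in which such assays
report n), gated at ≥100 cells per replicate; under-gated replicates are
flagged and excluded. Mann–Whitney U is exact — full enumeration of group
assignments, valid under ties — for combined n ≤ 12, and the tie-corrected
normal approximation otherwise. The unpaired t-test is pooled-variance by
default with Welch as an option. Two-way ANOVA uses Type-II sums of
squares on the replicate table; a constant response returns flagged F=0,
p=1 rather than the machine-epsilon garbage of a degenerate OLS fit.
Degenerate inputs elsewhere (all pooled values identical; zero pooled
variance) also return flagged results with p=1, keeping p ∈ [0, 1]. No
multiple-testing correction is applied by default (per-assay reporting);
Holm adjustment is available. Stars map as * <0.05, ** <0.01, *** <0.001,
**** <0.0001.

## Problem sizes and determinism

The recovery protocols use 3 replicates × 300 neurons per genotype for the
24-hour assays (scenes of 25 neurons at plating density), ~200 mm of
simulated axon per genotype for the swelling assay (the Poisson sampling
error of a 1.54/mm rate over 50 mm alone is ±11%; 200 mm brings it under
6%), and 1,000 nuclei for composition. One integer seed drives everything:
replicate seeds derive as base + index, scene and render seeds from the
replicate generator. Identical seeds give bit-identical scenes, images,
tables and statistics.

## Known limitations

- Crossing arbors are split geodesically; per-neuron totals at crossings
  are approximate (group means are nearly unbiased, single cells are not).
- The swelling intensity guard assumes bead brightness scales with
  thickness; detectors on real data should recalibrate `intensity_ratio`.
- Growth cones fused with another cone are split by shape, not identity;
  heavily overlapping cones bias areas slightly upward.
- The published "11.2 ± 0.9 µm²" control growth-cone figure is far tighter
  than the published per-replicate range (4–17 µm²); it is read here as
  the between-replicate spread of means, which the preset encodes. The
  related published claim of a "60%" cone-area increase is inconsistent
  with the printed group means (which imply ≈149%); the presets follow the
  printed means and no attempt is made to reconcile the two.
- Axon length is measured as TAU1⁺ skeleton length; fasciculated or
  overlapping stretches count once, so measured length underestimates
  ground truth by ~5–10% at the default axon density, partially offset in
  the rate by the matching loss of beads on hidden stretches.
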