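# Methods

This note documents the models, conventions and numerical choices behind
`gaitmat`: what each stage assumes, which parameters matter, what the
synthetic walkway does and does not emulate, and where the design was
genuinely open.

## Coordinate and device conventions

The walkway is modelled as a 90 × 420 cm mat sampled on a square grid with
pitch 1.27 cm; integer cell indices (0-based, cell centres) convert to
centimetres by multiplication with the pitch. The long (walking) axis is
*y*, the lateral axis *x*. Raw exports carry one row per sensor activation
sample with time, x/y indices, pressure, and optional device annotations
(foot type, foot count, footfall id, pass index). The device's footfall and
foot-type columns are read and carried through but never used for
segmentation — footfalls are re-derived from the point cloud, and the device
columns remain available for cross-validation of the segmentation.

## Peak-pressure reduction

A cell sampled repeatedly during stance is reduced to a single point at the
time of its maximum pressure. Ties go to the earliest sample, matching
first-contact semantics and making the reduction deterministic under any row
ordering. A cell re-activated after more than 0.2 s of silence starts a new
activation episode, so the same cell can legitimately contribute one point
to each of two footfalls; the 0.2 s default is far below any plausible
same-spot re-contact interval at walking speed yet far above device sampling
gaps. The reduction is idempotent and conserves the set of active cells.

## Footfall segmentation

*Count and seeding.* Successive footprints are longitudinally disjoint at
walking speed: intra-print gaps between sorted y-coordinates stay near one
grid pitch while inter-print gaps are several centimetres. The number of
footfalls and the initial cluster centres therefore come from a scan for
gaps exceeding 4 × pitch (5.08 cm) in the sorted longitudinal projection.
Seeding K-means with the gap-scan group means removes initialization
randomness; the subsequent K-means pass (scikit-learn, one seeded
initialization) only has to refine boundary cells.

*Enclosing quadrilateral.* Each footprint is enclosed in its minimum-area
rotated bounding rectangle (shapely). A rectangle — rather than an arbitrary
quadrilateral or an axis-aligned box — makes the long axis, the "width
across a slice", and the equal-length tripartition all well defined, and is
rotation/translation equivariant (verified by property tests). The rectangle
is cut into three equal-length slices along the long axis; heel versus fore
orientation follows the pass's direction of progression (first to last
footfall centroid), which stays deterministic even when contact timing is
degenerate. Sub-centroids are the means of the sensor points falling in each
slice, not the slice polygon centroids, so they respond to the actual
pressure distribution.

*Sides.* Sides must alternate in contact order; the only free choice is the
global left/right orientation, which is fixed by the mean signed lateral
offset of the two alternation parity groups from the pass's central line.
Equal offsets (a pathological, perfectly in-line walk) fall back to contact
order with a logged warning. Footprints touching the mat edge are excluded
with a warning; partial prints are out of scope.

## Feature definitions

"Heel center" is implemented as the heel-slice sub-centroid and "midline
midpoint" as the midpoint of the heel→fore centroid segment; these anchor
points are named but not constructed by convention elsewhere, so the
construction is fixed here once and used everywhere (including the
simulator's ground truth).

Two deliberate asymmetries follow the conventional definitions: step length
is the *longitudinal component* of the heel-to-heel displacement of opposite
feet, while stride length is the *Euclidean* heel-to-heel distance of
same-side feet. Step width is the lateral (perpendicular-to-walkway)
component of the midline-midpoint displacement; stride width and base width
are point-to-line distances against the opposite foot's midpoint line and
line of progression respectively.

Temporal features come from per-footfall first/last contact (min/max of the
member points' peak times): step time (first contacts of consecutive
opposite feet), stride time (consecutive same-side), stance time
(last − first of one foot), single support (next same-side first contact −
current last contact) and double support (current last contact − next
opposite first contact). Negative double support — flight, which cannot
occur in walking but can arise from noise — is clamped to zero with a
warning. Velocities are length/time and are missing whenever their time is
missing or zero.

The signed toe angle is measured between the footprint midline and its line
of progression, positive for toe-out (lateral rotation away from the body
midline); the sign convention is configurable. The toe direction feature is
**1**[θ ≥ 0], and the magnitude |θ| replaces the signed angle in the
augmented set. The LOP deviation angle uses overall footprint centroids by
default (heel centers are a defensible alternative and available as a
switch). Hull and BOS areas are convex-hull areas of one footprint's points
and of two consecutive footprints' pooled points. Foot length is 1.5 × the
heel–fore centroid distance: for a uniformly covered footprint the two
sub-centroids sit at 1/6 and 5/6 of the foot, so the factor recovers the
full length; the multiplier is applied verbatim. Toe angle and LOP deviation
are computed per footfall against the *next* same-side footfall; step/stride
quantities reference the *preceding* footfalls, so that each velocity's
numerator and denominator describe the same displacement.

Footfalls lacking the required neighbour carry missing values, and rows with
a missing modelling feature are dropped before classification. In a pass of
n footfalls only indices 2 … n−3 carry every feature, which typically keeps
roughly a third of the rows; this is the price of strictly local,
well-defined features at pass boundaries.

## Feature sets

The standard set starts from 13 numeric spatiotemporal parameters (step/
stride time, step/stride velocity, single/double support, stance time,
signed toe angle, step/stride length, step/stride width, base width) plus
the categorical foot type. The augmented set replaces the signed toe angle
with its magnitude, adds foot length/width/area, hull area, BOS area and
the LOP deviation angle, and carries foot type plus toe direction as
categoricals. Correlation filtering routinely removes the stride-time /
stride-velocity / base-width block (stride quantities are near-deterministic
functions of their step counterparts), so the post-filter sets land near 10
and 15 features.

## Preprocessing and selection pipeline

Order of operations on each training fold: height normalization (foot
length, foot width, foot area and hull area divided by subject height in
cm — a row-local operation, safe before splitting) → SMOTE balancing →
z-scaling → Pearson correlation filter → ANOVA-F ranking → cross-validated
subset-size choice → categorical reintroduction. Test rows are transformed
with the training fold's statistics only; nothing is fitted on test rows
(asserted by a leakage test that perturbs labels outside the training fold).

*SMOTE* is implemented in-package: each synthetic sample is a uniform point
on the segment between a random minority sample and one of its k = 5 nearest
minority neighbours, repeated until the class counts are equal. Synthesis
happens in the full encoded feature space, so synthetic rows can carry
fractional values for binary columns; the downstream models are indifferent
to this. The public operation requires a minority larger than k; the inner
cross-validation drivers shrink k automatically on very small folds so that
hyperparameter search remains defined on toy cohorts.

*Scaling* uses the population standard deviation (ddof 0). Zero-variance
columns are centred but not divided, and flagged.

*Correlation filter.* Features are visited in descending ANOVA-F order; a
feature with |Pearson r| ≥ 0.8 against an already-retained one is dropped,
recording the partner and r. Visiting by F makes the rule deterministic and
signal-preserving: of a correlated pair, the member more associated with the
class survives. NaN correlations (constant columns) count as zero with a
warning.

*ANOVA ranking* uses the one-way F statistic (scikit-learn `f_classif`),
which for two classes equals the squared pooled t statistic — an identity
the tests verify against scipy. A feature with zero within-group variance
but distinct group means receives an infinite score and ranks first: a
perfect separator is maximally informative, not an error.

*Size selection* evaluates every prefix of the ranked list with a
default-configuration SVM under grouped five-fold cross-validation (each
inner training fold independently balanced and scaled) and keeps the size
with the highest mean accuracy, ties going to the smallest size.

## Models and evaluation

Grids: SVM over kernel {poly, rbf, sigmoid} × C {5, 3, 1, 0.5, 0.1} ×
degree {3, 4, 5}; logistic regression over solver {newton-cg, lbfgs,
liblinear} × penalty {l1, l2} × C {1000 … 0.01}, restricted to the
solver/penalty pairs the optimizers support (l1 requires liblinear;
elasticnet would need a solver outside the grid and is omitted); gradient-
boosted trees (XGBoost) over max_depth {2, 3} × eta {0.3, 0.4} × objective
{binary:logistic, binary:logitraw, binary:hinge}. Grid search is exhaustive
over grouped inner folds with per-fold balancing and scaling; ties go to the
first combination in grid order. Hyperparameter search conditions on the
feature set already selected for the fold — selection is part of
preprocessing, shared by all three models, as reflected in the pipeline
diagram order.

Evaluation is grouped five-fold cross-validation at the footfall-row level,
with the subject visit as the group key; folds are seeded permutations of
the groups balanced in group counts (±1), and no visit ever appears in both
train and test. Confusion counts are pooled over the outer folds
(micro-averaging; per-fold accuracies are also reported), and accuracy,
precision, recall and F1 are computed from the pooled counts in percent,
with zero-denominator metrics reported as missing rather than zero. ROC and
PR curves sweep the pooled continuous decision scores — class probability
for logistic regression, the signed margin for SVM and XGBoost — with AUROC
as the trapezoidal area (equal to the Mann–Whitney concordance probability)
and AUPRC as step-wise average precision. Identical seeds reproduce the
whole experiment byte for byte.

## The synthetic walkway

The generator's role is to produce raw sensor exports whose statistical
structure matches what the analysis assumes, with exact ground truth.

*Planning.* A pass is a sequence of alternating footfalls advancing along
the mat. Per class, each gait parameter is a Gaussian (mean, sd); a
subject's means are drawn once (between-subject spread 0.8 × sd) and each
step is perturbed around them (within-subject spread 0.5 × sd). Draws are
truncated to feasibility: steps stay longitudinally disjoint (floor at foot
length + 10 cm), contact durations stay positive, and footprints are pulled
back from the mat edges. A per-pass walking-direction drift produces
non-zero LOP deviation angles.

*Defaults.* Controls: step length 65 ± 5 cm, step width 9 ± 2 cm, toe angle
5 ± 3°, step time 0.53 ± 0.04 s, stance 0.62 ± 0.05 s, drift sd 1°.
The impaired profile shifts toward shorter, more variable steps
(50 ± 8 cm), a wider base (13 ± 3 cm), larger toe-angle variance (8 ± 6°),
slower cadence (0.62 ± 0.08 s) and longer relative stance (0.78 ± 0.09 s,
hence longer double support), with drift sd 3°. These magnitudes are chosen
to be physiologically plausible for a moderately impaired adult cohort and
are fully configurable; they are simulation fixtures, not clinical claims.
Foot dimensions default to 25.4 × 9.5 cm for both classes, subject heights
to 170 ± 8 cm.

*Rasterization.* The foot outline is a rectangle in foot-local coordinates,
rotated by drift ± toe angle and translated to the heel position; the
emitted cells are exactly those whose centres fall inside the polygon. Each
cell emits two or three samples spanning the contact window with a
piecewise-linear rise and fall; the peak phase increases linearly with the
cell's longitudinal position along the foot, so heel cells peak earlier (and
harder) than fore cells and the rearmost/foremost cells peak exactly at
first/last contact. Peak-timestamp reduction therefore recovers the planned
contact window exactly, which is what makes temporal ground truth exact
while spatial ground truth is exact only up to rasterization.

*Ground truth.* Geometric/temporal truth is evaluated analytically on the
planned continuous geometry using the same anchor constructions as the
extractor (heel centroid at 1/6 of the foot, etc.), so extraction error on a
zero-variance cohort is pure rasterization error, bounded by about one grid
pitch for lengths and widths. Area truth (foot, hull, BOS) is evaluated on
the emitted cell set, since the cell-count area is the quantity the features
define. Cell memberships per footfall are recorded for segmentation
validation.

*What is not emulated.* Pressure magnitudes are schematic (no body-weight
calibration, no double-peaked vertical force profile); feet are rectangles,
not anatomical outlines; there are no partial prints at mat edges, no
overlapping prints, no assistive-device artefacts, no turning or stopping
mid-pass, and no within-visit fatigue drift. Passing recovery tests on this
simulator therefore demonstrates correctness of the reconstruction and
feature definitions under the stated assumptions — not robustness to every
artefact of clinical recordings.

## Numerical choices and degenerate inputs

- Peak ties → earliest time; grid-search and size-selection ties → first in
  order / smallest size.
- Footprints with < 3 points, collinear points, or an empty heel/mid/fore
  slice raise a degenerate-footprint error and are excluded from the feature
  table with a logged count.
- Angles are reported in (−90°, 90°] (toe) and [0°, 90°] (LOP deviation);
  coincident anchor points make an angle undefined (missing value).
- All randomness flows through seeded numpy generators; experiments are
  reproducible byte for byte under a fixed seed.
- Simulation sizes in the test suite (cohorts of 4–50 subjects, two to three
  passes each) are chosen so the full suite and the acceptance script each
  complete in about a minute while keeping several hundred footfall rows in
  the end-to-end experiments.

## Known limitations

- Stride-width and base-width use the bracketing opposite-foot pair
  (i−1, i+1); the first and last footfalls of a pass never carry them, and
  strict row-wise completeness discards roughly two-thirds of footfalls in
  short passes. Pooling features per pass would retain more data at the cost
  of per-footfall granularity.
- Classification quality on the simulator reflects the configured profile
  separation and should not be read as a clinical performance estimate.
- The side-assignment fallback for perfectly in-line walking is arbitrary up
  to a global flip (flagged in logs).
- SMOTE in the encoded space interpolates binary columns; a mode-based
  categorical variant was not needed for the bundled models but would be
  required for models sensitive to non-binary categorical values.
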