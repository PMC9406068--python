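# Methods

`protoadapt` is a desk-scale simulation framework for one question: when
an intensity-modulated proton therapy (IMPT) plan is re-optimized online
on the anatomy of the day, how much plan quality is lost by optimizing
on deformably *propagated* contours instead of physician-drawn ones —
and how much of that loss can be recovered by folding the
contour-propagation uncertainty into the optimization itself?  Everything
runs on synthetic phantoms, so every "clinical" (ground-truth) contour
is known by construction and every comparison is exact.

## Phantoms and the study cohort

Two analytic templates cover the two constraint regimes of the study:

* **abdomen** — a stereotactic pancreatic-head-like case (50 Gy-RBE in
  5 fractions, 3 posterior/oblique beams).  CTV ≈ 46 cm³, surrounded by
  stomach, duodenum, small and large bowel, spinal cord, kidneys and a
  > 700 cm³ liver.  Organ limits are hard constraints; target coverage
  is the soft, second priority.
* **head_neck** — a standard-fractionation case (70/54 Gy-RBE in 30
  fractions to nested high/low-risk CTVs, 4 anterior-oblique beams) with
  brainstem, spinal cord, pharyngeal constrictors, larynx and parotids.
  Coverage outranks organ limits.

Shapes are ellipsoids, capsules and an elliptic-cylinder body outline,
placed relative to the grid centre; default grids are 60×48×48 at 4 mm
(abdomen) and 48×48×54 at 3.5 mm (head & neck).  Densities are relative
stopping powers (water 1.0, air 1.2×10⁻³, a vertebral column at 1.45
for heterogeneity).  A cohort varies organ centres by a truncated
Gaussian jitter (σ 3 mm, clipped at 2σ) and radii by ±5%.

Structures may overlap (duodenum abuts the CTV, constrictors overlap
the low-risk CTV); overlapping voxels are deliberately kept in every
structure they belong to and handled by the optimizer's competing
penalty terms, never re-assigned by hand.

Voxel indices are 0-based; world coordinates are mm with
`world = origin + index · spacing`; masks are written as uint8 NIfTI
with the spacing/origin in the affine.

## Interfractional change

The daily anatomy is the planning phantom warped by one displacement
field applied identically to the density and every mask, so image and
contours can never disagree.  The field is a sum of

* a random rigid shift (per-axis SD 2 mm abdomen / 1.5 mm head & neck),
* a smooth random *divergence-free* motion field (per-component SD 6 mm
  abdomen / 4 mm head & neck, correlation length 30 mm).  The curl-of-
  a-potential construction makes the motion volume-preserving to first
  order: organs shift and squeeze past each other without being created
  or destroyed, which matters because the liver sparing rule
  (Vtot−V15 > 700 cc) is volume-sensitive — a compressible field
  silently deflates the liver and violates the rule for every plan;
* for head & neck, a transverse (x–y) shrink of the external contour by
  8% of its volume per default, emulating weight loss.  Transverse-only
  scaling maps the cylindrical body outline exactly to a scaled copy
  (volume factor λ², λ the linear factor) and avoids the voxel-layer
  quantization a longitudinal shrink suffers at flat body ends.

Warping is a pull-back `out(x) = in(x + u(x))`; masks are transported
as level sets (linear interpolation of the 0/1 indicator, threshold
0.5).  One consequence worth knowing: a boundary displacement smaller
than half a voxel cannot flip any voxel, so volume changes below that
scale are invisible on the grid.

## Simulated contour propagation

Real adaptive workflows propagate contours with several deformable
registration (DIR) algorithms; the propagated sets disagree with each
other and with the physician.  We emulate three algorithms without any
registration: algorithm *k* warps the daily ground-truth contours by a
per-algorithm *systematic bias* field (fixed across fractions — real
intensity-based DIRs have characteristic failure modes, which also makes
the algorithms mutually correlated) plus an independent per-fraction
random field.  Default amplitudes: bias 3.5 mm / random 2.0 mm for the
abdomen (soft-tissue registration), bias 2.0 mm / random 1.2 mm for
head & neck (anchored by bone); correlation length 25 mm.  These
magnitudes sit in the range reported for abdominal/HN DIR
target-registration errors and produce visible, few-mm contour
disagreement.

Contour quality is policed by a per-structure Dice acceptance band
(default lower bounds 0.5 abdomen / 0.6 head & neck, upper bound 1.0):
out-of-band draws are re-sampled with a perturbed seed, first of the
random field only, then — emulating a plausibility check rejecting an
algorithm's output outright — of the bias too; after a bounded number
of retries the generator errors, naming the structure.  Dice is
size-sensitive: on a 6 mm-radius spinal cord a 3–4 mm offset already
drops Dice near 0.5 while being an unremarkable error in mm, which is
why the lower bounds look permissive.  The band guarantees "reasonable"
contours; it does not prevent the clinically important failure mode in
which some true target voxels are covered by *no* propagated set — on
seeded cohorts this happens in a fraction of days, and is asserted by
test.

## Dose engine

Spot dose is separable: an analytic depth-dose profile in
water-equivalent depth (WED) times a lateral Gaussian (σ 5 mm) around
the spot axis.  WED is obtained by resampling the density onto a
beam-aligned grid and integrating along the beam axis once per
(phantom, beam); setup-shift scenarios then only re-interpolate.  The
depth profile is not a fitted Bragg parametrization — no clinical dose
engine is being imitated — but an analytic shape with the features that
drive the study's logic, for peak position R:

    D(w) = exp(−(R−w)² / 2σ(w)²)  +  0.3 · expit((R−w−0.125R) / 0.012R)
    σ(w) = 0.05R proximal of the peak, 0.015R distal

i.e. a single maximum at the nominal range (±2%), a 30%-of-peak
entrance plateau, a wide proximal and sharp distal shoulder, and <1% of
peak beyond 1.05R.  Spots are placed by binning target(+5 mm margin)
voxels laterally (7 mm abdomen / 10 mm head & neck) and laying energy
layers across each bin's WED interval (6 / 9 mm), so every target voxel
is within one spacing of a spot's Bragg position.

Influence matrices (spot × voxel, Gy-RBE per unit weight per fraction)
are sparse: entries below 2×10⁻³ of a spot's maximum or beyond 3σ
laterally are dropped, and dose is scored in tissue only (air voxels
carry no entries).  Error scenarios follow the usual robustness model:
nominal + six ±3 mm axis shifts + 3% range under/overshoot = 9
scenarios (a 21-scenario cross-product is available).  A setup shift
evaluates dose at `x + shift`; a range scale multiplies every WED.
Plans are optimized and scored as total-course dose (fraction dose ×
number of fractions) so the clinical limits apply directly; RBE is the
constant 1.1 folded into the Gy-RBE prescriptions.

## Objectives and the minimax solver

Constraint rows map to standard penalty terms: one-sided quadratic
under/overdose penalties, quadratic mean-excess penalties, and
quota-based DVH penalties that touch only the smallest voxel set whose
doses must move (an upper DVH row pushes down the coolest voxels beyond
the allowed hot volume; a lower row lifts the warmest deficient
voxels).  Hard rows weigh 10× soft rows (the planning sheet gives
priorities, not weights; the ratio is configurable).  Each coverage row
also spawns an auxiliary uniform min-dose term at half weight so the
whole target, not just the DVH quota, feels a gradient.  The sparing
rule Vtot−V(d) > Q cc becomes an upper DVH quota of (structure volume −
Q).  A voxel belonging to several structures contributes to all their
terms.

Robust optimization is objective-wise minimax: minimize over
non-negative spot weights the maximum of the composite objective over
all (structure-set alternative × scenario) pairs.  The non-smooth max
is replaced by a log-sum-exp soft maximum annealed over three rounds
(relative smoothing gaps 0.2 / 0.05 / 0.01), each solved by L-BFGS-B
with bound constraints and a monotone line search; everything is
deterministic given the configuration and start.  Influence columns
outside every term mask cannot affect the objective and are dropped
from the solve, which cuts the matrix-vector cost several-fold.  Initial
weights are uniform, scaled so the mean target dose hits the coverage
level; the initial plan receives an extra warm continuation pass so it
sits at the solver's fixed point (a converged plan of record), and
daily re-optimizations warm-start from its weights (the clinical
analogue: the plan of record is the starting point of adaptation).  There is no whole-body dose cap by default —
dose outside all constrained structures influences neither the
objective nor the score — though an external max-dose term is available
in the configuration.

## Adaptation strategies

All strategies share the planning spot roster, beam geometry,
constraint list and weights; only the structures (and, for the
probabilistic strategy, per-term weights) differ:

* **reference** — optimize on the daily ground-truth contours (the
  physician-drawn structures of a clinical workflow).
* **single_dir_k** — optimize on algorithm k's propagated set,
  uncorrected.
* **multi_dir** — worst case across all three propagated sets ×
  scenarios in one minimax problem.
* **conservative** — combine the ensemble: organs take the union;
  the target takes the intersection under stereotactic priority
  (smallest defensible target) and the union under coverage priority.
* **probabilistic** — partition each structure's ensemble union into
  exact agreement levels (33/67/100% for three algorithms) and
  replicate every term per level with weight factor k/K.  Absolute
  volume quotas (cc) are apportioned to levels in proportion to their
  volume, so a 1 cc limit is not silently tripled and a sparing quota
  is not silently zeroed.
* **no_adaptation** — keep the planning weights; recompute dose on the
  daily anatomy.

Exact-level (not cumulative) substructures are used; labels are
`round(100·k/K)` while internal arithmetic keeps exact fractions k/K.

## Scoring

Every plan is evaluated on the *clinical* structures of its day,
whatever it was optimized on.  Each violated constraint contributes its
absolute exceedance in native units (Gy, cc, percentage points) times a
score weight (1 by default); contributions sum to a unit-mixing score in
arbitrary units (au).  A value exactly at its limit is not a violation;
V(d) counts voxels with dose ≥ d; the max metric is the hottest voxel.
Hard and soft rows score identically — importance shapes optimization
weights, not the score.  Per-fraction scores are differenced against the
reference adaptation of the same phantom and fraction, and per-strategy
means/ranges of the differences are reported; a sensitivity sweep
re-scores stored per-constraint contributions under target-only and
organ-only multipliers 1–10 and checks whether the best and worst
strategies change.

One reading choice: the head-and-neck sheet limits V57.8 on the
low-risk CTV, which *contains* the 70 Gy high-risk CTV; taken literally
the row can never be met.  We evaluate it on the low-risk CTV minus the
high-risk CTV plus a 10 mm dose-gradient margin, mirroring the sheet's
own "Liver (-GTV)" exclusion style — the 70→54 Gy gradient physically
needs about a centimetre.

## What the defaults do and do not show

The default study (2 templates × 3 phantoms × 3 fractions, fixed seeds)
reproduces the qualitative structure of the clinical finding: reference
adaptation is best by construction of the evaluation, no adaptation is
worst, and the uncertainty-aware strategies fall in between, with the
conservative/probabilistic variants paying a coverage price under the
stereotactic prescription.  The generator emulates inter-algorithm
contour scatter, systematic DIR bias, organ motion and weight loss; it
does not emulate imaging contrast, registration failure modes tied to
image content, intra-fraction motion, density-override artefacts, or
clinical dose-calculation accuracy.  Absolute scores therefore carry no
clinical meaning — only the relative ordering of strategies under the
stated noise model does, and the per-fraction ordering is stochastic;
only cohort means are asserted.

## Numerical choices and limitations

* Tolerances: solver pgtol 10⁻⁷, ftol 10⁻¹⁰, ≤ 60 L-BFGS-B iterations
  per annealing round; term gradients verified against central finite
  differences to 10⁻⁴ relative.
* Determinism: every stochastic component is a pure function of an
  explicit seed; study-level seeds derive from the config seed by
  hashing (template, phantom index), and reruns are bit-identical.
* Degenerate inputs: empty masks skip objective terms (recorded on the
  composite) and error in metrics/scoring; an empty conservative target
  intersection is a warning, not an error; deformations that empty the
  target or push it off-grid raise.
* Problem sizes were chosen so the full default study runs in tens of
  minutes on one core: ~1000 spots (abdomen) / ~3000 (head & neck),
  9 scenarios, ~10⁶ influence entries per scenario.
* Known limitations: no nuclear halo or heterogeneity-induced lateral
  scatter; no deliverability constraints; no dose accumulation across
  fractions; Dice is the only contour-quality diagnostic; sub-half-voxel
  boundary displacements are invisible to the level-set mask transport.
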