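# Methods

## Scope and data model

The package analyzes one open-field session per animal, represented as a
frame-aligned pair:

* an **ethogram** — one movement label per frame from a closed vocabulary
  of 13 spontaneous movements, partitioned into 5 functional clusters
  (locomotion, exploration, forced posture, maintenance, nap);
* a **trajectory** — the back keypoint in mm, center-origin coordinates,
  on a 400 x 400 mm arena floor (all |x|, |y| <= 200 after calibration).

Conventions: 0-based frames, half-open bout intervals `[start, end)`,
seconds for time, millimetres for space. The frame rate is not fixed by the
upstream capture system; 30 frames/s is the default and is carried in data
files as a `# frame_rate=` comment. The movement vocabulary is closed:
readers normalize case/whitespace and reject unknown labels, because the
ontology is fixed upstream and silent extension would corrupt every
downstream count.

## Time budgets and temporal dynamics

For a set of frames and label *i*, the time fraction is
`T_i = M_i / M_total` and the bout frequency is bouts of *i* per minute
("frequency" is plotted unitless in the source analyses; bouts/min is this
package's standardization, and whole-session bout counts are also exposed).
Cluster-level quantities map frames through the cluster partition first and
re-derive bouts after the merge, so cluster fractions are exactly the sums
of their member-movement fractions while cluster bout counts are at most
the movement bout counts.

Temporal profiles recompute both quantities inside consecutive bins (60 s
or 600 s). A bout straddling a bin boundary contributes frames to each bin
it touches but its *count* only to the bin containing its start frame —
the source analyses are silent here and this rule keeps per-bin counts a
partition of the whole-session count. Trailing partial bins are dropped
with a warning. Group profiles are unweighted means over animals.

Travel distance is the summed Euclidean step length of the smoothed back
trajectory (same 0.33 s smoothing as label correction, for internal
consistency; window 0 gives raw steps).

## Kinematic label correction

Pose classifiers occasionally emit labels that contradict gross
kinematics. A correction rule relabels bouts of a source movement whose
mean smoothed back speed is **strictly below** a threshold and whose
duration is **strictly above** a minimum; the shipped default is the single
published rule, sniffing < 15 mm/s for > 3 s becomes pausing. Strictness at
the boundary follows the rule as printed: exactly 15 mm/s or exactly 3 s is
not corrected. Speeds use a centered moving average of 0.33 s (the
upstream smoothing is unspecified; the window is configurable, 0 disables).
Within one pass, bouts are derived once and the first fully qualifying rule
decides each bout; relabeled frames can match later rules only in further
passes (default: one pass). For the default rule a single pass is a fixed
point: corrected bouts become pausing, which no rule targets.

## Arena zoning

Calibration maps the four observed corner points onto (±200, ±200) mm with
an exact projective (homography) transform; the published corner list
contains a duplicated corner, read here as the four distinct corners of
the square. The **growth curve** counts frames whose back point lies in the
centered square `[-a, a]^2` for `a` on a 1-mm grid to the wall, and the
occupancy **density** is the count increment per annular frame area
(frames/mm²). `a` is interpreted as the *half*-width of the center square:
at the standardized boundary `a` = 135 mm this leaves a ~65 mm perimeter
band, physically plausible for wall-hugging; the literal "side length"
reading would make the center span only ±67.5 mm. Density (not the
cumulative curve) carries the thigmotaxis peak, matching the "density
distribution curve" naming of the source figure; both choices are surfaced
in configuration.

The data-driven boundary locates the most prominent peak of the density
curve (curve endpoints are treated as valleys, so a high plateau reaching
the wall counts as a peak, while a curve that decreases monotonically from
the center has no admissible peak and raises an error with the traditional
division as fallback). The boundary is the smallest grid `a`, scanning
outward from the peak's left base along its rising flank, at which density
reaches within `prominence_fraction` (default 0.10) of the prominence below
the peak — equivalently, the start of the 90%-prominence region. The two
printed formulations ("within 10% of the peak prominence" and "starting
point of the 90% peak prominence") coincide under this reading.

Single-session density curves on a 1-mm grid are noisy near the center
(inner annuli have areas of a few mm²); boundary detection is intended for
pooled or long recordings, and the pipeline pools frames per genotype.
The traditional division fixes `a` = 100 mm (center = half the arena
length). Zone membership is Chebyshev (`max(|x|, |y|) <= a`), boundary
inclusive to the center. Per-zone movement budgets renormalize fractions
within the zone; an unvisited zone yields an empty, flagged budget.

## Transition networks

Frames map to clusters; maximal runs merge into **events** (each cluster
fragment is one event regardless of length). State probabilities and
transition probabilities are empirical event counts; the event-level
diagonal is structurally zero, so self-transitions are defined at
movement-bout level within a cluster (walking -> stepping is a locomotion
self-transition). Edges with probability below 0.05 are pruned — the source
Methods' phrase about excluding "statistically significant P < 0.05
transition probability" cannot be executed as written, and the figure
legend's probability-threshold reading is used, with the threshold
exposed. A Methods/legend conflict line is the only interpretation made.

Betweenness centrality is computed on the pruned directed graph with edge
distance `-log p` (likelier transitions are shorter), normalized by
`(n-1)(n-2)`; an unweighted variant exists since the source does not state
weighting. Group graphs either average per-animal matrices (default) or
pool event counts (`pool="events"`), both implemented because the source
does not say which was used. Session stability is the Pearson correlation
between the movement-fraction vectors of the two half-sessions (cosine
available); a flat budget vector has no defined correlation and yields NaN.

## Genotype discrimination

Per-animal feature sets: movements (13 fractions + 13 frequencies),
grooming (2), total distance (1), position under the traditional division
(2), clusters (5 + 5). Sexes are modeled separately throughout. Features
are z-scored; LDA uses the eigen solver with Ledoit-Wolf ("auto")
within-class covariance shrinkage, which keeps the 26-feature /
~15-animals-per-class regime well posed; if a degenerate fold (e.g. a
single-sample class) still yields a non-positive-definite scatter, a fixed
shrinkage of 0.5 is applied with a logged note. Evaluation is leave-one-out
by default (no CV scheme is stated upstream; LOO suits the small n), with
stratified k-fold available. The **discrimination** score is the mean of
the row-normalized confusion diagonal — mean per-class recall, matching
the "diagonal black = 1" geometry of the source figure — and overall
accuracy is reported alongside since the source does not disambiguate.
The published discrimination values (e.g. movements: male 1.0, female
0.92) depend on the unreleased recordings and are not reproduction
targets.

## Synthetic cohorts

The generator exists because the study's recordings are not deposited; it
emulates the *structure* of the data, not its effect sizes.

**Ethogram**: a semi-Markov bout process — a 13-state bout-to-bout Markov
chain with zero diagonal selects successive movements, and each bout draws
a lognormal duration (σ_log = 0.6; movement-specific means from 0.7 s for
stepping to 4 s for grooming). Dwell and selection are decoupled so time
fractions and bout frequencies can vary independently, which a frame-wise
chain cannot do. The chain is built from genotype-specific selection
weights (`P(i -> j) ∝ w_j`), with the grooming-pausing entries boosted
(x1 WT, x1.6 HE, x2.5 KO) to create the maintenance-nap coupling
contrast. The closed-form long-run time fraction — stationary bout weights
x mean dwell, renormalized — serves as the oracle for convergence tests.

**Trajectory**: each bout draws an attractor — with probability
`wall_affinity` (0.60 WT, 0.68 HE, 0.76 KO) the nearest wall-band midline
(band 35 mm), otherwise a uniform point of the central region (half-width
100 mm). The mean path travels toward the attractor at the movement's
nominal speed (switching to an exponential relaxation, τ = 2 s, when
close), so locomotion carries the animal while slow movements park it;
AR(1)-filtered Gaussian jitter is superposed, floored at a 15 mm/s raw
posture/tracking sway so resting animals occupy a small blob rather than a
point (a movement with nominal speed exactly 0 stays perfectly still), and
positions reflect at the walls. Sessions start near a fixed corner, as
animals are introduced there.

Engineered contrasts are *orderings only*: walking/stepping mass WT > HE >
KO, grooming/pausing/hunching mass KO > HE > WT, thigmotaxis KO > WT, and
a walking sex factor largest in WT and absent in KO. No numeric per-group
time-budget table exists upstream, so all magnitudes are stand-ins chosen
once for plausibility. The default cohort uses the published per-group
sizes (male 20/15/19, female 21/12/17 for KO/HE/WT; 104 animals), 60-min
sessions at 30 frames/s. Per-animal seeds are
`SHA-256("{master_seed}:{animal_id}")` truncated to 31 bits, so cohorts
are reproducible piecewise.

What the generator does **not** emulate: realistic movement kinematics
(posture, turning geometry), spatial covariates of behavior (movements are
spatially homogeneous given the attractor process), habituation within the
session (no time-inhomogeneity), inter-animal variability beyond sampling
noise, or the upstream classifier's label errors beyond the slow-sniffing
case. Passing recovery tests therefore demonstrates the *estimators* are
correct and the pipeline preserves engineered group structure — not that
real Shank3b data would yield these effect sizes. In particular, hour-long
synthetic sessions make per-animal estimates so precise that even
single-feature sets often discriminate perfectly; the movements-set
dominance invariant is checked on shorter sessions where noise matters.

## Numerical choices and test scales

* Tolerances: stochastic-convergence tests use max-abs error 0.05 (5,000
  events, transition matrices), 0.02 (state probabilities and time
  fractions at >= 20,000 bouts); exact identities (cluster partition, zone
  conservation) at 1e-9 or better.
* The bout-chain recovery unit test runs at 200,000 bouts so that its 0.02
  bound sits above four binomial standard errors for the rarest of the 13
  states.
* Boundary-recovery fixtures: a sharp occupancy step at 135 mm and an
  analytic ramp whose 90%-prominence level crosses at 186 mm, both
  recovered within one 1-mm grid step.
* Replicate-contrast checks run 20 cohorts of 4 animals per group with
  10-min sessions; determinism is verified by running the full pipeline on
  the complete study design (104 animals, 60 min at 30 fps) twice and
  comparing SHA-256 digests of every output file.
* Homography calibration solves the 4-point DLT by SVD and rejects
  configurations whose second-smallest singular value vanishes
  (collinear/duplicated corners).
* NaN is used deliberately for undefined quantities (self-loop of an
  unvisited cluster, similarity of a flat budget) and flagged, never
  silently zeroed.

## Known limitations

* Boundary detection assumes a thigmotaxis peak; center-loving occupancy
  profiles raise an error by design (callers fall back to the traditional
  division).
* Event-level transition estimates for rare clusters (forced posture in
  WT) are high-variance on single sessions; group averaging is the
  intended use.
* The correction engine implements threshold rules of the published form
  only; it is not a general re-classifier.
* Discrimination scores on synthetic cohorts reflect the generator's
  engineered separability and should not be read as expected performance
  on real recordings.
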