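# Methods

This note documents the models, estimators and design choices behind
`hfmaze`, in the order the pipeline applies them.

## Arena geometry and reference frame

The arena is a disc of radius 60 cm with 100 holes (25 per quadrant)
whose pattern is invariant under rotations by multiples of 90° about the
center, and one entrance per quadrant on the wall. All analyses use a
common frame: origin at the center, units cm, counter-clockwise positive,
and the *aligned start* at (0, +60). Entrance q sits at wall angle
90° − (q−1)·90°, so rotating a quadrant-q trajectory counter-clockwise by
(q−1)·90° moves its start onto the aligned start. The rotationally
equivalent location (REL) of a point is its image under a 90°/180°/270°
rotation about the center; an animal navigating egocentrically from a
rotated entrance arrives at the REL of its trained goal.

Layout generation rejection-samples quadrant-1 holes uniformly in their
sector (wall margin 3 cm) and takes exact rotational images for the other
quadrants; candidates are tested against the full orbit of accepted holes
so the complete set respects the 8 cm minimum spacing (average spacing
≈ 10 cm at 25 holes/quadrant). Generation is deterministic given a seed
and fails loudly if the packing budget runs out.

Target selection enforces the placement rules of the task: static
protocol — wall distance > 35 cm and > 60 cm from the start; random
protocol — wall distance > 30 cm and > 40 cm from every entrance. Both
exclude a band around the line through the center perpendicular to the
start–center line (half-width 10 cm; a target there reduces the task to a
left/right choice) and a narrower band (6 cm) around the start–center
axis itself (a target there is directionally indistinguishable from its
180° REL). Ties break to the lowest hole id. The rotated-probe protocol
additionally requires the target vector and its REL vector to subtend at
least 20° from the start, since its readout is exactly that angular
contrast; not every hole pattern offers such a hole, in which case the
protocol refuses the layout rather than running a degenerate experiment.

## Trajectories and kinematics

Trajectories are nose-point samples at nominally 30 Hz. On read, gaps up
to 0.5 s are filled by linear interpolation on the nominal grid; longer
gaps are an error; points outside the disc are clipped radially and
counted. Speed is a centered finite difference smoothed with a 5-sample
boxcar; the same smoothed series feeds the event detector, so the
smoothing window is a single config knob (`detect.smoothing_window`).

Latency runs from the first sample to the first entry within the capture
radius (1.5 cm: hole radius 0.6 cm plus rim and nose extent); paths are
truncated at first capture before distances are measured, so post-capture
behavior never contaminates d_total. Heading deviation at each sample is
the angle between the instantaneous displacement and the direction from
the *current* position to the target (the bearing is re-evaluated as the
animal moves); the food-line distance is the perpendicular distance to
the straight start-to-target segment.

The learning fit is nonlinear least squares of d_total = B·exp(−Trial/K),
with K's standard deviation from the fit covariance and CV = sd(K)/K.
Flat or rising series return CV = ∞ and an `unstable` flag (a timescale
more than 10× the observation window is not identifiable) instead of an
exception, because "no distance learning" is a legitimate outcome (it is
the expected result of the random-entrance protocol). Note that on data
of the form offset + exponential the raw-d_total fit overestimates K by
design of the model family; when the goal is recovering a generative
timescale, fit the excess distance d_total − d_target, which removes the
irreducible straight-run offset.

## Hole-check detection

Method 1 requires, simultaneously: nose within 3 cm of a hole; smoothed
speed below 20% of the trial maximum; a strict 3-sample local minimum;
and a drop of at least 5 cm/s from the preceding local maximum to that
minimum. Repeated minima at the same hole within the 0.5 s merge window
count once. Method 2 runs afterwards and adds downward crossings of the
20% threshold while within 3 cm of a hole, skipping crossings already
claimed at that hole within the merge window. A visit at a speed that is
below threshold before and after never fires either detector — a known
blind spot of the velocity criteria, reproduced faithfully. The 20%
threshold uses the smoothed maximum (config-switchable via the smoothing
window).

Spatial statistics weight each hole by its normalized check frequency;
because every event contributes its hole's coordinates, the weighted mean
and covariance equal the plain moments over the event list (population
covariance, ddof = 0). The restricted moments use only checks within
20 cm of the target, and σ_D = √(λ₁+λ₂) of the restricted covariance is
the spatial uncertainty attached to the TEV magnitude. Near/far area
densities divide counts by the area of the 20 cm disc clipped to the
arena (circle–circle lens formula) and its complement. The across-mice
count entropy is the plug-in Shannon entropy (natural log) of the
empirical count histogram.

## Displacement map

An L×L lattice (default 11, boxes ≈ 10.9 cm, comparable to a dentate
place-field) covers the arena's bounding square. Trajectories become
site sequences with consecutive duplicates collapsed; transitions between
non-adjacent sites (possible at high speed) are decomposed into an
axis-aligned staircase, horizontal steps first, so no step is silently
dropped (a drop-instead mode exists for sensitivity checks). Step counts
S per site and direction are pooled over mice within a trial.

Weights blend observation with the null stepping probability P₀ = 1/4:

    W_dir = S_dir/ns + P₀ − (S_dir/ns)·P₀,   P_dir = W_dir / Σ_dir W_dir,
    M = (P→ − P←, P↑ − P↓),

where **ns is the total number of steps out of the site being updated**.
The worked three-step configuration (two up, one down at one site ⇒
P↑ = 3/7, P↓ = 2/7, P→ = P← = 1/7, M = (0, 1/7)) pins this normalization:
a trial-wide ns would make the summed field Σ_sites M collapse, by a
telescoping identity on S→ − S←, onto the net start-to-end displacement
direction for any trajectory, which would render every cohort that finds
the food "significantly directional" and the summed-vector magnitude
meaningless. With per-site normalization a site traversed once
contributes a unit-order vector in its transit direction, so the summed
field of a direct run has magnitude ≈ the start-target distance in box
units, while long wandering searches contribute many nearly-canceling
unit vectors and the summed direction becomes noise-dominated — the
behavior the downstream significance test relies on. Sites with no data
keep P_dir = P₀ and M = 0.

## Jackknife, significance, TEV

Leave-one-out over the N mice of a trial yields N fields M_k (each from
the pooled N−1 remaining mice) and their per-site mean. The directional
statistic is the angular standard deviation of the summed vectors
u_k = Σ_sites M_k: rotate so the mean direction is 0°, wrap to
(−180°, 180°], and take σ = √(Σθ²/(N−1)). Its significance is the
probability that N uniform angles produce an angular S.D. at or below the
observed value. The null is Monte Carlo (10,000 draws by default); below
Monte-Carlo resolution (10/n_draws) an analytic tail takes over: the
volume of the ball Σθ² ≤ (N−1)σ² relative to the 360^N hypercube,
p = V_N(√(N−1)·σ)/360^N. Whether the null draws should be rotated to
zero circular mean before applying the S.D. formula is genuinely
ambiguous; both constructions are implemented (`centered` flag, default
uncentered) and their reference values bracket each other within an order
of magnitude (at N = 8, σ = 30°: ≈ 2.3×10⁻⁵ uncentered, ≈ 3.4×10⁻⁴
centered; at σ = 5° both are below 10⁻⁷). The centered analytic tail
lives in the (N−1)-dimensional complement of the common rotation,
p = √N·V_{N−1}(√(N−1)σ)/360^{N−1}.

The TEV direction is û_k = u_k/|u_k|; when the jackknife directions are
tight (angular S.D. ≤ 5°, the same cut used to display field vectors,
p < 10⁻⁷ at N = 8) the magnitude D is the distance from the trial origin
(the start, or target B in a B→A probe) to the restricted hole-check
mean, and D_k = D·û_k; otherwise no preferred direction is detected and
D_k = u_k itself. The reported TEV is the average of the D_k, its
directional error the angular S.D., and its magnitude error σ_D. If the
directions are tight but no checks fall within 20 cm of the target, the
magnitude is undefined and the fallback branch is taken with a warning.

Per-site display significance uses the same statistic on each site's
jackknife vectors; sites that any jackknife sample leaves empty are
ineligible (a site visited by a single mouse yields N−1 identical
leave-one-out vectors, which would trivially pass).

## Probe analyses

Search bias totals occupancy of the 30×30 cm squares centered on the
target and on its three RELs over the first 120 s (shorter probes warn
and use what exists); quadrant occupancy uses half-open 90° sectors and
always partitions 100%. REL arrival is first passage within 5 cm. The
randomized-piece control draws 10 random index pairs whose straight-line
separation matches a reference distance within 2 cm (exact separations
are unrealizable on sampled paths) and averages a metric over the pieces.
Distance-to-point chance levels use points drawn uniformly over the
arena disc (uniform points, not uniform holes — documented choice).

## Synthetic cohort generator

The generator emulates the statistical structure of the tracking data;
its defaults are the study conditions (8 mice, 14 trials, 30 Hz, 20 min
timeout, 2 min probes). Motion is a discrete-time heading process with
Gaussian angular innovation (diffusion 90°/√s), per-segment speeds from a
skill-interpolated distribution clipped to [0.6, 1.4]× the mean (naive
6 cm/s → trained 17 cm/s), and specular wall reflection. Learning enters
through a goal weight w(trial) = 1 − exp(−trial/K) with K = 5 trials:

- an exploratory budget ≈ 11·d_target·(1−w) of wall-following
  (thigmotaxis fading with familiarity) and interior excursions precedes
  the goal run, making the expected excess distance decay exponentially
  with the generator's timescale (trial-1 normalized length ≈ 10, trial
  14 ≈ 1.4, trained latency ≈ 7 s);
- the goal run heads to a *believed* target: the true target corrupted by
  angular (4°) and radial (3 cm) noise that shrinks with training to a
  floor of one half (path integration over ~80 cm is never mm-precise),
  plus a slow within-trial drift (0.3 cm per √m walked) mimicking
  accumulating path-integration error;
- near the believed target the animal searches among the surrounding
  holes with a widening radius until its nose enters the food hole.

Hole passes trigger check dwells (0.3–1.0 s settles onto the hole with a
smooth velocity dip) once per zone entry with probability
p = p₀ + p₀·b·w·exp(−(d/λ)²), where p₀ corresponds to a baseline of
1 check per meter traveled, b = 8 and λ = 18 cm: the per-meter rate stays
roughly constant over learning while checking concentrates near the
believed target, and trained animals cast a slightly wider sensory net
(trigger radius up to 4 cm) close to where they expect food. Finding the
food ends the trial with a 1.5 s settle on the target hole — the final,
rewarded check, which dominates the trained spatial check distribution.
Nose-point tracking jitter (0.08 cm S.D.) is added to emitted positions.

Protocol schedules: static — fixed entrance; random — Latin-square
blocks of four mice so that every trial uses all four entrances, counts
are exactly balanced per mouse, and no mouse repeats its previous
entrance (directional skill stays at zero: the target's egocentric
direction is unlearnable, only running speed and familiarity improve);
two-target — stage A, stage B, then a no-food probe visiting believed B
then believed A; rotated probe — static training plus a final probe from
a rotated entrance with the believed target carried in the egocentric
frame, so the animal heads to the REL. Probe searches revisit the
believed site repeatedly, alternating lingers (8–16 s) with short
excursions, which concentrates probe occupancy at the expected location.

What the generator does **not** emulate, and what passing tests therefore
do not show about real data: body posture and biomechanics; sensory
guidance (odor, vision); post-capture homing and inter-trial behavior
(trials end at the food hole, so analyses of the return journey are out
of reach); individual differences beyond seed-to-seed variation; and
tracking artifacts beyond isotropic jitter. Real early-trial directional
statistics may also differ wherever they are driven by behaviors outside
this repertoire.

## Numerical choices and degenerate inputs

Probability normalization at every lattice site holds to 10⁻¹²; the
angular wrap maps to (−180°, 180°]; nearest-hole and target-selection
ties break to the lowest hole id; zero-displacement samples are skipped
in heading series; zero hole checks yield an empty-stats marker rather
than division by zero; an all-zero vector sample makes the angular S.D.
undefined (NaN) with a warning. Simulation problem sizes in the test
suite (cohorts of 3–8 mice, 4–14 trials) were chosen so the full suite
and the cohort-level acceptance checks each run comfortably on a single
CPU while leaving every statistical conclusion at its stated threshold.

## Known limitations

- The displacement map is the lattice construction only; no
  kernel-smoothed continuous field is offered.
- The detector inherits the velocity criteria's blind spot for visits at
  persistently low speed; no manual-annotation pathway exists.
- Group-level hypothesis testing beyond thin scipy calls
  (paired tests in the acceptance checks) is out of scope.
- `fit_learning_curve` on raw d_total is faithful to the conventional
  analysis but, as noted, biased for offset + exponential data; use the
  excess distance for parameter recovery.
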