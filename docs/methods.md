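# Methods

## The world

The arena is a square of side 110 cm bounded by walls, frame origin at
the bottom-left corner, x right / y up, angles in radians CCW from +x.
Two circular food zones of diameter 22 cm sit at (27.5, 55) and
(82.5, 55); their exact coordinates are a free design choice, and the
symmetric placement preserves the premise of two *identical* food
sources.  Four robots with circular 5.5 cm chassis are
identified by fixed colours: green (0,255,0), blue (0,0,255),
light-blue (0,255,255), yellow (255,255,0).

Time is discrete and dimensionless: speeds are cm per step, with
`wheel_speed_max = 1.3` cm/step (a Khepera-like scale, chosen once and
fixed).  One step applies, per robot:

1. **Sense** (all robots perceive the same pre-movement state).
2. **Act**: the controller maps the 18 sensor values to wheel speeds.
3. **Move**: exact unicycle update — linear speed `(v_l+v_r)/2`,
   angular speed `(v_r−v_l)/5.5` (the chassis diameter is used as the
   wheelbase), integrated in closed form along the circular arc so pure
   rotation and pure translation are exact.  A fine-step Euler oracle
   agrees to < 10⁻³ cm over 100 steps.
4. **Resolve collisions**: a robot overlapping a wall (chassis
   protruding) or another robot (center distance < 5.5 cm) is displaced
   by 5.5 cm in a uniformly random direction to a legal spot and given
   a random heading — the "bumped to a nearby location" rule.
   Resolution sweeps repeatedly: a robot whose every displacement is
   blocked (cornered between a wall and two not-yet-moved neighbours —
   a real occurrence in crowded groups) is deferred until the
   neighbours have moved, then re-tried.  A configuration that stays
   unresolvable raises an error rather than silently overlapping.
5. **Score** zone occupancy (below).

Initial placement draws all four poses uniformly over the legal box
`[2.75, 107.25]²` with full-configuration rejection on any chassis
overlap, so positional marginals are exactly uniform; headings are
uniform on [0, 2π).  Robots may start inside food zones (a
configuration flag excludes them if desired).

## Sensors

* **Linear retina** — five RGB photoreceptors spanning [−45°, +45°]
  around the heading, 18° per sector (half-open on the right, last
  sector closed).  Another robot at center distance d subtends the
  bearing interval `bearing ± arcsin(2.75/d)`; a sector overlapping at
  least one robot's interval reports the normalised colour
  (component/255) of the nearest such robot — occlusion, binary
  per-sector activation, no intensity falloff (distance is conveyed by
  how many sectors a robot covers, not by brightness).  Range is
  unlimited; walls and zones are invisible to the retina.
* **Smell sensors** — three quadrant sensors reporting on two binary
  lines which quadrant faces the *nearest* food-zone center: bearing
  [0°, 90°) → (0,1); [90°, 270°) → (1,0); [270°, 360°) → (1,1).  The
  code is never (0,0).  With two zones some disambiguation of which zone is smelled is
  required; nearest-zone is the minimal rule and is fixed here.
* **Ground sensor** — 1.0 when the chassis center is strictly inside a
  zone disc (the floor there is grey), else 0.0.  Zone membership uses
  the same robot-center-inside-disc convention everywhere (fitness,
  ground sensor, individual-fitness measure).

Sensors are deterministic and purely relative: readings are invariant
under rigid motions of the whole scene, and a robot has no access to
its absolute position.

## Controller and genotype

A 24-neuron feed-forward network: 18 inputs
(R0,G0,B0,…,R4,G4,B4, S0, S1, G) → 4 logistic hidden units → 2 logistic
outputs.  Output o ∈ (0,1) maps to a wheel speed (2o−1)·v_max, so 0.5
is a stopped wheel.  The logistic activation and the symmetric output
map are package choices; logistic is the standard choice for this
robot family, and the
symmetric map makes "silent network = motionless robot" hold exactly.

All 86 parameters (72 + 4 + 8 + 2) live in [−5, +5], each encoded as
8 bits (MSB first): byte b ↦ −5 + 10·b/255.  Genotype length 688 bits.
The parameter order (input→hidden row-major by input, hidden biases,
hidden→output row-major by hidden, output biases) is frozen in the
archive format and recorded in every manifest.

## The Heterogeneous Genetic Algorithm

Four populations of 20 genotypes, one per colour role, fixed binding.
Per generation: each population contributes one genotype per trial via
an independent uniform **permutation** of its 20 indices — 20 trials,
no quadruple repeated, every genotype evaluated exactly once.  (Non-repetition alone would allow a genotype to go unevaluated, which
leaves separate ranking undefined; permutations guarantee each genotype
a score.)  A genotype's generation fitness is its single trial's
score; the per-generation group fitness series stores the best and the
mean trial score.

Fitness modes: `collective` (default; +1 to every robot for each step
on which all four occupy the same zone), `individual` (+1 per step a
robot is on any zone) and `mixed` (sum) — two alternatives kept as
configuration options for comparison; only the purely collective
reward ties higher fitness directly to social coordination.

Reproduction per population: sort by fitness descending (ties broken by
lower index, for reproducibility); the top 4 each produce 5 offspring —
1 exact copy (elitism) and 4 with every bit independently flipped with
probability 0.02 (the "2 %" mutation is read as a per-bit rate, the
standard GA convention).  No crossover, no migration.

Reproducibility: every random stream (population init, scheduling,
mutation, trial seeds) derives from the master seed via named
substreams keyed additionally by generation, so a checkpointed run
resumes bit-identically and any trial can be regenerated in isolation.

## Measures

* **Barycenter measure**: pin each robot in turn at the arena center
  (the center is the symmetric choice for the pinning spot) while the other three run; per step compute the Euclidean
  distance from the pinned robot to the barycenter of all four robots
  (n = 4; the formula sums over every robot — a flag switches to the
  three free robots only); average over 3000 steps, 20 trials and the
  last 20 generations' best teams, where "best team" is the top-ranked
  genotype of each population.  Argmin identifies the leader.
* **Leadership measure**: population (divisor n) standard deviation of
  the quadruple; with n = 4 the sample/population distinction is
  material, so the choice is frozen.
* **Individual fitness**: all four robots free; per robot count steps
  on any zone; same averaging.
* **Collective fitness indicator**: mean of the per-generation best
  group fitness over the final 20 generations.
* **Capability of followers**: leader pinned at the center; first step
  each follower comes within `reach_radius = 11` cm (two chassis
  diameters, chosen once), censored at trial length
  (3000) for followers that never arrive; averaged over followers and
  20 trials of the final-generation team.
* **Mobility of leaders**: distinct cells of the 20 × 20 grid of
  5.5 cm cells containing the leader's center, per trial, averaged.
* **Vision of leaders**: steps per trial with ≥ 1 active photoreceptor.
* **Removal test**: re-run the final team with one robot deleted from
  the world (its population unused); collective fitness is scored over
  the survivors and compared with an intact baseline on paired seeds.

## Temporal analysis

Barycenter and individual-fitness protocols are re-run at every 10th
generation (single-generation versions, 20 trials each); the collective
curve reads the stored group-fitness series.  Curves are smoothed with
Friedman's variable-span super-smoother — implemented here directly:
three fixed spans (0.05, 0.2, 0.5 of the data) fitted by running local
linear regression, per-point span selection by smoothed leave-one-out
absolute residuals (computed by exact point-exclusion refits — the
leverage shortcut degenerates at the 2-point tweeter span), selected
spans themselves smoothed, final fit interpolated between the
bracketing fixed-span fits; optional bass enhancement biases selection
toward the woofer span.  Derivatives are central finite differences on
the smoothed curves with respect to generations (one-sided at the
ends).

The **event-order** question — does a robot's foraging skill rise
before its leadership status? — compares the argmax generation of the
smoothed individual-fitness derivative with that of the smoothed
*negated* barycenter derivative (the barycenter trend decreases as
leadership consolidates; negation preserves the argmax and is simpler
than max+min reflection).  Ties count as "no".

**Style classification** sorts the leaders' vision counts and places
two breakpoints at the two largest consecutive gaps: lowest group
passive, middle weak-active, highest strong-active.  Style assignment is ultimately a behavioural-inspection judgement
made from such a sorted bar-plot; the largest-gap rule is the minimal
automatic analogue and can be overridden with manual thresholds.  All-equal input is flagged
degenerate.  Pearson correlations (SciPy, two-sided t-based p) link
leadership to collective fitness, follower capability to leader
mobility, and mobility to vision.

## Scripted fixtures

`leadersim.fixtures` registers ground-truth scenarios built from
scripted wheel-speed policies run under the *same* physics as evolved
controllers: `passive_leader_group` (robot 0 straight to zone 0 and
parks; robots 1–3 pursue robot 0 with a standoff above the collision
distance), `weak_active_group` (leader additionally spins on the spot
at intervals), `strong_active_group` (leader orbits a circle near the
zone), `leaderless_group` (four random walkers), `follower_only`.
Closed-form constructions (exact circular orbits from constant wheel
speeds, straight-line approaches, spin-in-place exposure counts) give
every measure an analytic expected value.

Scripted policies read true world state; they are test instruments, not
evolvable controllers.  What fixture-passing shows is that the
*measures* compute what they claim on known behaviour; it does not by
itself validate the evolutionary dynamics, which the scaled-down
emergence study covers.

## Problem sizes and what the scaled-down study shows

Full-scale conditions are 600 generations × 30 replications.  The test
suite and the acceptance script run a scaled-down study — 150
generations, 5–6 replications, the full 20-trial measure protocols —
sized so the whole pipeline (a few hundred thousand simulated trials)
completes in minutes on one CPU; the simulation core is numba-compiled
(~7 ms per 3000-step trial).  Under these conditions collective
foraging reliably emerges (group fitness from ~0 to ~1000–1500 of
3000) and a barycenter-minimal leader appears in every replication.
Two caveats are inherent to the reduced scale: (i) in an occasional
replication two robots remain near-equally skilled at generation 150,
so the barycenter leader need not yet be the strict individual-fitness
maximum; (ii) cross-replication correlations computed from ~6
replications carry large sampling error.  Both sharpen with longer
runs and more replications.

One emergent regularity worth knowing: the yellow robot is the most
frequent leader.  Yellow (255,255,0) is the only colour with a red
component, hence the most linearly discriminable stimulus on the
retina, and follower networks find it easiest to key on.  This is a
property of the colour coding, not of any per-robot asymmetry in the
algorithm.

## Known limitations

- Kinematics only: no inertia, friction or wheel slip; no sensor
  noise; no physical-robot interface.
- The retina's analytic sector activation can differ from a
  bearing-sampling check on states where a robot clips a sector by less
  than the sampling resolution (sub-0.1° slivers; ~0.3 % of random
  states) — a property of any sampled oracle, not an error bound on
  the implementation.
- Trial logs replay exactly through the kinematics except on steps
  where a robot was randomly repositioned by collision handling; those
  steps are flagged in the log and skipped by the replay check.
- The style classifier is a declared heuristic; with few replications
  the three-group split can be driven by sampling noise.
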