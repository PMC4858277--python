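# Methods

## Model overview

The package simulates a two-player stag hunt embodied in a continuous 2D
arena. Two circular hunters (diameter 14 length-units) move by differential
drive among stationary prey — hares and stags, same body size — inside an
800×800 square with solid walls and no other obstacles. A prey is captured
when at least one hunter keeps its centre within the catching distance
(28 units, equal to the proximity-sensor reach so a catching hunter can
always sense its prey) for 800 *consecutive* time steps of a 20 000-step
episode. The hunt is **cooperative** iff both hunters are within catching
distance at the trigger step; every in-range hunter receives the full table
reward (nothing is split). Captured prey respawn immediately at a uniform
random non-overlapping position with the same type, so the prey census is
invariant throughout an episode.

Rewards (baseline): hare 50 alone or together; stag 0 alone (a failed hunt —
the stag is still removed), 500 each cooperatively. The `stag-alone-reward`
condition raises the solo stag reward to 50, removing the risk of stag
hunting while keeping the cooperative premium.

## Perception

Each hunter senses the world through:

* **12 proximity sensors**, evenly spaced over 360° relative to the heading.
  With `d` the surface-to-surface distance along the sensor ray to the
  nearest obstacle (wall or any agent body), the activation is
  `max(0, 1 − d/28)` — 1 at contact, 0 beyond range. Proximity sensors are
  type-blind: obstacle detection and agent identification are deliberately
  separated.
* **A camera of 12 rays** spread over a 90° cone centred on the heading
  (rays at the 12 bin centres, so none lies exactly on the heading). Each
  ray yields 4 values: two type bits for the first agent disk it intersects
  — none (0,0), hunter (0,1), hare (1,0), stag (1,1) — a proximity value,
  and a presence flag. Rays are unbounded, so proximity is normalised by the
  arena diagonal, `max(0, 1 − d/diag)`, measured to whatever terminated the
  ray (agent, else wall). The presence flag makes "no target" distinguishable
  from "distant target"; the choice of the 4th value and the bit assignment
  are design decisions of this package (only two pieces of information per
  ray — type and proximity — are fixed by the model family).

The input vector is `[12 proximity | 12 × (bit, bit, proximity, presence) |
bias 1]` = 61 values, all in [0, 1].

## Controller and genome

A fully connected sigmoid MLP: 61 inputs → 8 hidden → 2 outputs, hidden
bias included, `σ(x) = 1/(1+e^{−x})`. Each output drives one wheel through
the signed map `v = (2o − 1)·V_max` (V_max = 2 units/step), so the
all-zero-weight controller stands still and wheels can reverse. Genomes are
flat vectors of reals in [0, 1]; gene `g` decodes to weight `(2g − 1)·W_max`
with W_max = 5 (wide enough to saturate the sigmoid — standard in
evolutionary robotics). The stated architecture implies
61·8 + (8+1)·2 = **506** weights; the genome length is always derived from
the architecture, which is configurable (e.g. a camera-only 49-8-2 reading
gives 410).

Kinematics per step: `heading += (v_r − v_l)/wheel_base` (wheel base = body
diameter), then the centre advances by the mean wheel speed along the new
heading. Hunters move sequentially in id order; after each move the mover is
clamped out of walls (axis clamp) and pushed out of any overlapped disk
along the centre-to-centre axis to exact contact, iterating to a fixed
point. Only the mover is ever displaced; prey never move.

## Evolution

Wright-Fisher neuroevolution with constant population 20 over 3000
generations. Per generation each individual is evaluated as the focal
player: 5 partner draws (uniform over the other 19, a fresh draw each time,
never itself) × 5 episodes per draw = 25 episodes; fitness is the focal
player's summed payoff divided by 25. Partner payoffs during a focal
evaluation do not count toward the partner. Parents are sampled with
probability proportional to fitness (uniform fallback if every fitness is
0); each offspring is a mutated clone — per gene, with probability 5·10⁻³,
add `Normal(0, 0.1²)` and clip to [0, 1]. Clipping (rather than reflection)
keeps the genome domain simple; σ = 0.1 is the variance-derived value of the
model's `N(0, 0.01)` mutation operator (a σ = 0.2 reading also circulates;
it is available via `evo.mutation_sigma`).

**Clonal mode** pairs every individual with an identical copy of itself
(relatedness 1). **Hare-only pre-evolution** runs the same loop with every
prey a hare (default 1000 generations) to produce populations sitting at the
solitary equilibrium before stags are introduced.

`evolve` records generation `g`'s evaluation before reproducing, so a run of
G generations performs G evaluations and G−1 reproduction events and the
final snapshot carries evaluated fitnesses.

## The one-locus baseline

`gt_baseline` strips the genotype-phenotype map to a single binary locus
(hare/stag) under the *same* machinery: 5 partner draws × 5 bouts, the same
Wright-Fisher sampler (literally the same function), flip mutation at the
gene mutation probability, 3000 generations. A hare player always earns the
hare reward; a stag player earns the cooperative stag reward iff its partner
also plays stag and the solo reward otherwise, the failed attempt still
counting as a hunted prey. Bouts are deterministic, so the number of bouts
per "simulation" only rescales fitness and is provably neutral to the
dynamics. The replicator invasion threshold
`p* = (R_hare − R_s,solo)/(R_s,coop − R_s,solo)` is 0.1 under baseline
rewards and 0 once stags reward 50 alone.

### Measured transition dynamics

Under these conditions a lone stag mutant always has fitness 0 (it can
never be paired with itself), so leaving the hare equilibrium requires at
least two simultaneous flips — probability ≈ C(20,2)·(5·10⁻³)² ≈ 0.0045 per
generation, ≈ 13.6 opportunities per 3000-generation run. The package's own
measurements give a fixation probability of ≈ 0.11 from a two-stag state and
a per-run transition probability of ≈ 0.85 (51 of 60 seeds; the acceptance
script typically reports 25–28 transitions out of 30). Reports of the
transition occurring in every run are consistent only with a somewhat
higher effective mutation supply or a payoff-sharing pairing scheme; the
package keeps the parameters above and reports what they produce.

## Metrics

The headline metric is `100 · coop_stags / (hares + coop_stags +
solo_stags)` — the percentage of *hunted* prey that were cooperatively
hunted stags. The denominator includes failed solo stag hunts because they
are prey removals (switchable via `include_failed=False`). Condition
summaries aggregate the last generation's per-episode category counts per
run (mean and population s.d.) and cross-run metric curves. Two-condition
comparisons use a two-sided Mann-Whitney U: exact by full enumeration for
tie-free samples with n ≤ 12, otherwise the normal approximation with tie
and continuity corrections (p = 1 when the tie-corrected variance is 0).
The `circling_statistic` quantifies the mutual-orbiting coordination style:
the mean absolute per-step increment of the bearing from one hunter to the
other, wrapped to (−π, π], symmetrised; two points orbiting a common centre
at ω rad/step score exactly ω, while stationary or straight parallel motion
scores 0.

## Randomness and reproducibility

One master seed per run; every stochastic consumer (initial genomes,
placements, pairing, selection, mutation, respawns) draws from a labelled
substream (`make_rng(seed, label)`, a PCG64 seeded by folding the label
bytes into the seed entropy), so runs are bit-reproducible across processes
and components are independently testable. Episode respawns use a 31-bit
seed derived from the episode's stream. Experiment directories carry a JSON
manifest (condition, seeds, full configuration) from which a run can be
re-executed byte-identically.

## Scale profiles and what the tests show

The full study protocol (30 runs × 3000 generations × 25 episodes ×
20 000 steps) is ≈ 10¹⁰ controller evaluations per run — cluster work, not
CI work. The package therefore defines a **desk** profile used by the smoke
tests and examples: 200×200 arena, 2000-step episodes, 200-step capture
window, 6 prey (3+3), population 10, 50 generations (and 50 pre-evolution
generations), keeping the 5×5 pairing scheme. At this scale hare-hunting
competence evolves clearly (mean hares per episode rises from ≈ 1 to ≈ 7–8
within 50 generations), which validates the machinery without reproducing
the full-scale embodied statistics. The one-locus model runs at full
study scale everywhere, including the acceptance script.

The synthetic worlds the tests use (uniform random placement, stationary
prey, noise-free sensors) match the model's own idealisations; passing
tests therefore validate the implementation of this model, not the
behaviour of physical robots or noisy sensors.

## Numerical choices and edge cases

* Capture counters are consecutive-presence and reset on any step with no
  hunter in range (the reading most consistent with "remains close enough"
  and with cooperation judged at the final step); a cumulative mode exists
  behind `evo.cumulative_capture`. Several prey reaching the threshold on
  one step are processed in prey-id order.
* Collision resolution iterates wall clamp + disk push-out to a fixed point
  (≤ 8 passes); separations are exact to ~10⁻¹² and tested to 10⁻⁹.
* Ray-disk intersection uses the standard half-chord form; an origin inside
  a disk hits the far boundary. The episode kernel culls agents that
  provably cannot intersect a ray (out of proximity reach, or outside the
  disk's angular window) before running the identical intersection math; a
  standing test asserts exact agreement with the per-ray operations.
* `stag_proportion` of zero hunts is defined as 0. Coincident hunters make
  the partner bearing undefined; such steps contribute 0 to the circling
  statistic.
* Placement rejection-samples up to 10⁴ times per agent and raises if the
  arena is too crowded.

## Known limitations

* Prey neither move nor avoid hunters; sensor noise is absent.
* The embodied experiments' full-scale outcome statistics are out of CI
  reach by design; desk-scale results demonstrate mechanism, not effect
  sizes.
* The one-locus transition count depends on unreported details of the
  original game-theoretic setup (see "Measured transition dynamics").
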