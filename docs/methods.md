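# Methods

## The problem

Human adults combine cues across sensory modalities close to the Bayesian
optimum, while children tend to base multisensory judgments on a single
modality. `multisense` implements a reward-maximization account of that
developmental switch: a single-step interactive learner with no prior
knowledge of its sensors' noise models that learns, in parallel, in every
sensory subspace and in the joint space, and per decision *selects* the
source of information whose evidence is currently most useful. Sensory
selection (childhood) and integration (adulthood) both fall out of the same
mechanism; the transition is emergent, not preprogrammed.

## Model

An agent has `k` discrete sensors; the environment is fully observable in
the joint observation space `S = O^1 x ... x O^k`. At each step it observes
`s = (o^1, ..., o^k)`, picks an action `a`, and receives a reward drawn from
an unknown stationary distribution for `(s, a)` with known support
`[lo, hi]` (default `[0, 1]`).

**Statistics.** Each (observation, action) cell stores `(n, sum r, sum r²)`.
With learning rate `1/n` the incremental Q-update equals the running sample
mean, so these three numbers are sufficient for the Q-value, the sample SD,
and every confidence interval used below. Statistics are additive, which
gives two exact identities the package exploits and tests:

* *Marginalization*: the statistics of a sensor subset ("source") at
  observation `o^i` are the sums of the joint cells projecting onto `o^i`.
  They are maintained incrementally on every experience (O(#sources) per
  step) and are integer-exactly equal to a from-scratch re-marginalization.
* *Residual extraction*: subtracting the current joint cell from a source's
  marginal cell leaves the experience that source gathered in *other* states
  aliased onto the same observation — the only part that is independent
  evidence about the source's generalization ability.

**Confidence intervals.** Three constructions on a cell's mean, all
two-sided at confidence `1 − α`:

1. Student-t: `q ± t_{α/2, n−1} · s/√n`; needs `n ≥ 2`.
2. Chebyshev with worst-case variance `(hi−lo)²/4`:
   `q ± (hi−lo)/(2√(nα))`; distribution-free, very conservative; `n ≥ 1`.
3. Empirical Bernstein ("variance-aware"):
   `q ± [ s·√(2·ln(3/α)/n) + 3(hi−lo)·ln(3/α)/n ]`; `n ≥ 2`.

Below those sample counts a cell's interval is unbounded on both sides.
That is a deliberate design choice: an unbounded upper bound implements
optimism in the face of uncertainty, so untried actions are explored before
tried ones are repeated, and an unbounded residual interval means a source
passes the generalization test whenever no independent evidence against it
exists.

**Generalization test.** Perceptual aliasing in a subspace is *beneficial*
when the states it merges share a reward structure and *harmful*
("garbage") when they do not. Per state, source and action, the test builds
the joint cell's interval `M` and the residual interval `B̂` and accepts the
source iff they intersect (closed intervals; touching endpoints intersect).
Early in learning both intervals are wide and everything passes; with
evidence, only genuinely generalizing sources survive. With deterministic,
opposite rewards in two aliased states the test rejects with certainty once
both cells hold a handful of samples.

**Decision policies.** Per action, the accepted sources' *marginal*
intervals plus the joint interval are reduced to one representative value:

* MOS takes the greatest upper bound among accepted sources;
* LUS takes the upper bound of the shortest candidate interval (the joint
  interval is itself a candidate; length ties prefer the joint, then the
  lowest sensor index).

Either value is capped at the joint interval's upper bound — the joint
space has no aliasing, so anything above its upper bound is unrealistically
optimistic — and a capped decision is attributed to the joint source. The
action with the greatest representative value is executed, exact ties
broken uniformly at random. "Dominance" of a source means it supplied the
chosen action's representative value; its time course operationalizes the
selection-to-integration transition.

**Baselines.** UCB1 (`q + √(c·ln N/n)`, untried action → ∞) on single
sensors and on the joint space, and the Bayesian ideal observer, which
knows the Gaussian noise SDs and fuses readings by inverse-variance
weighting (pure-noise sensors get weight zero).

## Task

30 discrete positions; a uniformly random stimulus per step; each Gaussian
sensor reads `round_half_up(stimulus + N(0, σ))` clamped (not wrapped) to
the grid; a `uniform_noise` sensor reads a uniform position independent of
the stimulus. The agent answers with one of the 30 positions and earns
reward 1 iff its answer lies within 3 grid units of the stimulus (binary
default; a linear shape `(radius+1−d)/(radius+1)` is available and is still
strictly positive at `d = radius`).

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `alpha` | 0.05 | significance level of every interval; the framework's single free parameter. Smaller α → wider intervals → more exploration and a later switch to integration (see the α sweep). |
| bound | `student_t` | tightest of the three; Chebyshev/Bernstein are distribution-free but conservative, and are best used with larger α. |
| `σ_visual, σ_auditory` | 1.0, 2.0 grid units | vision the more reliable modality; both sensors informative. Fully configurable. |
| `reward_radius` | 3 | reward support of the task. |
| UCB1 `c` | 0.2 | the classical value 2 causes periodic re-exploration waves in the 900-state joint space; a small coefficient speeds all baselines up. |
| smoothing window | 500 (two-sensor runs), 1000 (three-sensor runs) | trailing moving average used in all reported series. |

## Experiment conventions

Run `i` of an experiment derives every random stream from `base_seed + i`;
the stimulus/reading streams and each agent's tie-breaking stream are
separate substreams, so all agents of a run face the identical world
(paired comparison) and the whole pipeline is bit-reproducible.

The learning-speed criterion is *steps to a fraction of Bayes*: the first
step at which an agent's cumulative reward reaches `frac` of the paired
ideal observer's cumulative reward. Because a random agent earns a reward
on its very first step with probability ≈ 7/30, a literal first-crossing
rule fires spuriously at `t = 1` in a quarter of runs; the reported metric
is therefore the *sustained* crossing (the first step from which the
condition holds through the evaluated horizon). Both modes are implemented;
`steps_to_fraction(..., mode="first")` gives the literal rule. Runs that
never durably cross contribute the evaluated horizon (a lower bound) to
averages, with the count of crossing runs reported alongside.

Dominance percentages in the summary table are computed over all steps up
to each run's crossing step.

## Numerical choices

* Sample-variance radicands can go slightly negative by cancellation for
  near-constant rewards; they are clamped to zero (a 0.4-reward cell yields
  a ~1e-8-length interval rather than a point — harmless).
* Student-t quantiles are cached per α: exact (scipy) up to 4096 degrees of
  freedom, then a second-order Cornish–Fisher expansion around the normal
  quantile (relative error < 1e-4 at the switch point, shrinking as 1/dof).
* The per-step selection loop is JIT-compiled with numba; a pure-numpy
  reference implementation of the identical algorithm ships alongside and a
  test asserts the two produce bit-identical trajectories across all
  policy × bound combinations. Without numba the package silently uses the
  numpy path.
* LUS tie-breaks (joint first, then lowest sensor index) and the MOS
  greatest-upper tie-break (lowest sensor index) are deterministic so that
  trajectories are reproducible.
* A single-sensor agent has no proper subspaces: its source list is empty
  and it reduces to the joint-interval policy, rather than treating its one
  sensor as both a source and the joint space.

## What the simulator does and does not emulate

The generator reproduces the structural features the theory needs —
discrete fully-observable joint space, conditionally independent sensor
noise, stationary rewards with bounded support, an uninformative sensor,
an abrupt reliability collapse. It does not emulate continuous stimulus
spaces, correlated or signal-dependent sensor noise, non-uniform stimulus
priors, or slow sensory drift. Passing tests therefore demonstrate the
mechanism (selection → integration as a reward-maximizing consequence of
interval widths), not quantitative fidelity to any behavioral dataset.

## Scales used in the shipped checks

The test suite and the acceptance script run the real pipeline at sizes
chosen to keep routine runs short while preserving every phenomenon
checked: learning-speed ordering uses 5–20 paired runs at horizons of
3–10 × 10⁴ steps; the three-sensor and sensor-failure studies use 10⁵-step
phases; interval calibration uses 10⁴ replicates. The transition check
needs ≥ 6 × 10⁴ steps: at shorter horizons the visual share is still on its
early rise and only the auditory decline is visible.

## Known limitations

* Absolute step-counts depend strongly on the sensor noise SDs: noisier
  sensors spread experience over more effective joint states and slow the
  joint-space baseline disproportionately. The defaults (σ_V = 1, σ_A = 2)
  are one reasonable operating point; orderings and dominance shares are
  robust across nearby settings, absolute step-counts are not.
* Dense tables scale as `positions^k`; the power-set extension multiplies
  the per-step cost by `2^k − 2`. Fine for a few sensors, not for many.
* Stationarity is assumed by the statistics (`1/n` learning rate); the
  failure scenario shows recovery happens via the generalization test, but
  a long pre-failure history still slows re-adaptation (no forgetting
  mechanism is implemented).
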