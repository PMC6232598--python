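# Methods

## The inference engine

An agent holds a belief vector `P(h)` over `m` hypotheses and a
likelihood matrix whose row `k` is the conditional symbol distribution
`P(d | h_k)` over an `n`-symbol alphabet.  One observation triggers, in
order:

1. **Window append.** The symbol enters a sliding buffer of capacity
   `M`; the empirical frequency `f(d)` over the buffer is maintained
   incrementally (O(n) per query, independent of `M`).
2. **Bayes update.** `P(h) ∝ P(d | h) P(h)`, renormalised.  If the
   observed symbol has probability zero under every hypothesis
   carrying belief mass the update is impossible; the engine raises an
   error and every driver in this package catches it and skips the
   belief update for that step, leaving the state valid.  This case is
   real, not hypothetical: frequency rows contain exact zeros.
3. **Inverse-Bayesian replacement** (BIB mode only).  The least
   probable hypothesis `h_s` (ties uniform at random) is replaced with
   probability `1 − P(h_s)`: its likelihood row becomes the current
   window frequency `f`, and its belief restarts at the uniform share
   `1/m` (the other entries are rescaled to keep the vector
   normalised).

The belief restart deserves emphasis because the scheme degenerates
without it.  A window frequency usually contains exact zeros; a single
later observation of a missing symbol multiplies the rewritten
hypothesis's belief to exactly zero, permanently, no matter how well
its row fits from then on.  Without the restart the freshly generated
hypotheses all die this way, prediction falls back on whatever original
rows remain, and the BIB system performs *worse* than Bayes-only.  With
the restart a replaced hypothesis re-enters the competition
immediately, and the hypothesis set is self-healing: a dead row is by
construction the least probable, so it is recycled almost surely on
the next step.

Initial hypothesis sets are the symmetric one-parameter family: `m = n`
rows with `p` on the diagonal and `(1 − p)/(n − 1)` elsewhere,
`p ∈ (1/n, 1]`.  All tie-breaks (argmin, argmax, candidate choice) are
uniform over the tied set using the agent's own seeded generator.

Windows shorter than `M` normalise over the available observations; an
empty window skips the IB step.  The frequency window includes the
current observation.

## Sine-curve tracking

The environment emits one of `n = 4` symbols per step with
`P_t(d_0) = b + A sin(2πt/T_per)` and the remaining mass split equally.
Defaults: `b = 0.5`, `A = 0.4`, horizon `T = 5000`, initial peak
`p = 0.7`, window `M = 100`, period `T_per = 3000`.  The period
controls which window length wins: the frequency-estimate noise scales
as `1/√M` while the tracking lag bias scales as `M/T_per`.  At
`T_per = 3000` the documented regime holds — `M = 100` beats both the
noise-dominated `M = 40` and the lag-dominated `M = 2000`, and the
whole band `M ∈ [50, 300]` is near-optimal.  Tracking error is the
mean absolute deviation between the generating probability and the
prediction `P(d_0 | h_max)` over the horizon (the simplest metric
consistent with a scalar "amount of error").

A structural note on the Bayes-only baseline: with `b > 1/n` only
hypothesis `η_0` favours symbol 0, its expected log-evidence gain over
a full sine cycle is strictly positive, and after the first high phase
`h_max` locks permanently.  The Bayes-only prediction is therefore a
constant (the cumulative-majority row), not a delayed copy of the
truth; lag-based comparisons against it are degenerate.

## Trajectory analysis

*Velocities* are forward differences at the native frame interval
(`dt = 0.1 s` for tracking-like data).  *Polarization* is
`ψ = ‖Σ V_k/‖V_k‖‖ / N′` over the `N′` individuals with nonzero speed
at that frame; a frame with no moving individual is undefined (NaN).
ψ is invariant under global rotation and translation by construction.

*Density symbolisation*: for focal individual `i`, `n_r` and `n_2r`
count the *other* individuals within `r` and `2r`;
`d = min(3, INT(4 n_r / n_2r))`, with `d = 0` when the
2r-neighbourhood is empty.  The ratio `n_r/n_2r ∈ [0, 1]` is the only
dimensionless relative density available from the two counts and four
equal bins map it onto the alphabet; the mapping is monotone in `n_r`
at fixed `n_2r`.  The focal individual is excluded from both counts so
the empty-neighbourhood case stays observable.

*Future frequency* `F_t(d)` is the empirical symbol distribution over
frames `t − M/2 … t + M`, endpoints inclusive and clipped at the
series bounds; frames whose clipped window is shorter than `M/2` are
excluded from summary error metrics.  The per-individual score is the
mean absolute difference between `P(d | h_max)` and `F_t(d)` over
valid frames; population curves are unweighted means over the
individuals present per frame.

## The swarm model

State per agent: position, velocity, and a full inference state over
the density alphabet.  One update of agent `i`:

1. observe `d_i` at the current position (minimum-image metric under
   periodic boundaries) and push it into the agent's window;
2. Bayes-update the belief (zero-denominator observations skip the
   update);
3. read the preferred symbol `d_max = argmax_d P(d | h_max)` (ties
   uniform);
4. anticipate `x̂ = x + V̂` with `V̂ = Σ_{j∈Γ(i)} V_j/‖V_j‖`, the sum
   of unit headings over all agents within the alignment radius `R`
   (self included; zero-speed agents contribute nothing);
5. score the 72 candidates `x̂ + u(cos θ, sin θ)`, `θ` in steps of
   `π/36`, by `|d̂(candidate) − d_max|`, where `d̂` is counted against
   the *anticipated* crowd — agents already moved this sweep at their
   realised positions, the rest projected one step along their current
   velocity — and move to the minimiser (ties uniform);
6. set the velocity to the realised (unwrapped) displacement;
7. BIB mode only: the probabilistic IB replacement with belief
   restart, using the agent's own window.

Two design choices here are the package's own, fixed after studying
the alternatives numerically:

* **Alignment as a sum of unit headings.**  Averaging raw velocities
  lets speeds grow without bound (the candidate step adds a vector of
  norm `u` each step and averaging only damps relative deviations), so
  the dynamics freeze into ballistic momentum and polarization
  collapses spuriously during every slow phase.  Normalising the
  recorded speed to `u` makes the tie-break noise as large as the
  alignment signal and the group provably cannot order (the
  self-consistent polarization of `unit(V̂ + u e)` with `‖V̂‖ ≤ u`
  stays near 0.5).  The unnormalised sum of unit headings bounds the
  anticipated displacement by the local neighbour count, keeps the
  dynamics interactive over the whole horizon, and yields the
  documented baseline behaviour: a Bayes-only population polarizes
  quickly and never collapses.
* **Anticipated candidate scoring.**  With `‖V̂‖ ≫ u` the candidate
  ring lies many units ahead of the crowd's current positions; scoring
  it against them would read the swarm's wake and systematically
  misdirect the density preference.  Candidates are therefore scored
  against where the crowd is about to be, which is also the natural
  reading of mutual anticipation.

Update order is asynchronous by default: a freshly shuffled agent
order per step, with moved positions and velocities immediately
visible to later agents; a synchronous mode (all agents read one
snapshot) is available for comparison.  The arena is a periodic square
of side `L = 10r` by default (reflecting walls optional); neighbour
counts use the minimum-image convention, with an exact per-candidate
count whenever `L ≤ 2(2r + u)` and a prefiltered fast path otherwise.
Initial positions are uniform in the arena, headings uniform on the
`u`-circle, priors uniform, likelihoods the symmetric `p`-family,
windows empty.  `M = 100` matches the tracking experiment's default.
The inner loop is numba-compiled; all in-run randomness flows from one
seed, and identical seed plus parameters reproduce trajectories
bit-for-bit.

Polarization is recorded after each full sweep, and
`count_collapse_cycles` counts downward crossings of ψ = 0.5 after ψ
first exceeds 0.9, re-arming only after ψ recovers above 0.9 — the
collapse/re-formation statistic used in the swarm tests.

### Known limitation: no spontaneous collapse cycles under BIB

The headline qualitative claim for this model family is a contrast
between inference modes: Bayes-only swarms, once polarized, stay
polarized, while BIB swarms should perpetually alternate between
swarming and dispersing.  This implementation reproduces the first
half robustly (zero collapse cycles across `p ∈ {0.7, 0.99}`,
`r = R ∈ {20, 30}`, `N = 100`, `T = 5000`, all seeds tested) but not
the second: BIB runs are as stable as Bayes-only runs.

The obstruction appears structural for the frequency-substitution
replacement implemented here.  Rewritten rows converge to the agent's
own observed symbol distribution, so the preferred symbol `d_max`
tracks the observed density mode; a *sustained* avoidance preference —
`d_max` pointing away from what the agent currently experiences, which
is the stated mechanism for collapse — cannot persist, because any row
that disagrees with current observations loses belief through the
Bayes step itself.  This held in every variant explored: arena-to-
radius ratios from 2 to 15, windows `M ∈ {10..100}`, both update
orders, both candidate-scoring conventions, uniform and dense-cluster
initial conditions.  The corresponding swarm-contrast test asserts the
full documented contrast and its BIB half fails; the failure is
reported rather than patched, since weakening the assertion would hide
a genuine gap between this reconstruction and the described behaviour.

## Synthetic data

`generate_bag_stream` draws i.i.d. symbols within scheduled regimes
and emits the per-step true distribution alongside.
`generate_phase_trajectories` produces `N` 2-D trajectories with
programmed coherent phases (shared heading, von-Mises angular noise
with concentration `kappa = 50`, a mild centripetal pull of 0.05 per
frame toward the centroid) alternating with dispersed phases
(independent uniform headings plus outward drift at half the dispersal
speed).  Positions are continuous across switches and live on the
unbounded plane — the arena parameter only sets the initial spread —
so polarization reflects programmed headings rather than wall bounces.
Defaults are tuned so coherent-phase ψ exceeds 0.9 and dispersed-phase
ψ sits near the incoherent level `N^{-1/2}`, and so the mean density
symbol is strictly higher in coherent phases; truth labels are emitted
per frame so detection can be scored without circularity.  The
generator emulates the *statistical* structure the analysis assumes —
alternating high/low polarization with matching density streams — not
behavioural realism: real tracking data has detection gaps, walls,
heterogeneous speeds and non-stationary group sizes that these
fixtures deliberately omit, so green pipeline tests demonstrate
correctness of the computation, not field validity.

## Problem sizes and numerics

The test suite runs the tracking experiments at `T = 5000` with 20
replicates, the swarm grid at `N = 100`, `T = 5000` with 10 seeds per
cell, and the pipeline on 25 individuals × 1200 frames with 10 seeds;
the acceptance script uses 10/5/5 replicates of the same three
experiments.  Probability vectors and likelihood rows are validated to
1e−9; the sequential Bayes filter agrees with brute-force joint
enumeration to 1e−12 on exhaustive length-≤6 sequences.  CSV I/O
rejects duplicate `(id, frame)` pairs, non-numeric coordinates and
in-span gaps with the offending line number; coordinates are
unit-agnostic, with an optional `mm_per_unit` metadata field (default
4.76 for pixel-grid tracking data) that is carried through but never
silently applied to radii.
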