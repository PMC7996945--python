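# Methods

## The task

The grid-sailing task (GST) presents a W×H grid (default 10×10) with a
start, a sub-goal and a goal cell. Keypresses move a cursor by fixed
displacement vectors; a trial succeeds when the cursor reaches the goal
*after* visiting the sub-goal, within a 9 s limit. An optimal path is a
minimum-keypress trajectory through the sub-goal; it earns the maximum 100
points, each excess move costs 5 points (floored at 0 — the scoring never
goes negative), and a timeout scores 0. The first optimal trajectory a
subject produces is *locked*: from then on, only exact reproductions are
successful, so all analyzed successful trials share one identical
16-keypress sequence.

Coordinates are 0-based `(col, row)` with the origin at the top-left and
rows increasing downward. The default key mapping is `4 → left (−1, 0)`,
`5 → up (0, −1)`, `6 → right (+1, 0)`, and the default geometry is start
(4, 9), sub-goal (8, 5), goal (5, 0). These defaults are a modeling choice:
the original task's exact direction set and waypoint coordinates are not
published, and the one hard constraint a reconstruction must satisfy is
that the optimal path is exactly 16 keypresses (the keypress positions
1–16 analyzed throughout). A three-direction left/up/right mapping with
the geometry above meets that constraint: 8 moves to the sub-goal plus 8
to the goal. A purely "forward" (all-upward) three-direction mapping
cannot — on a 10-row grid every such path has at most 9 moves — which is
why the mapping includes horizontal directions. Mappings and geometry are
fully configurable and every analysis is mapping-agnostic.

`optimal_path_length` is a shortest path on the product space
(cell × sub-goal-visited flag), delegated to networkx; infeasible tasks
(possible under restricted mappings) raise an explicit error. Among
multiple optima, `optimal_trajectory` deterministically returns the
lexicographically smallest key sequence (BFS with sorted key expansion),
so generators and tests agree on one concrete path.

## Keypress RT definitions

For a successful trial with keypress timestamps t₁ < … < t₁₆ (ms from
stimulus onset): RT₁ = t₁ is the *reaction time*; RTₙ = tₙ − tₙ₋₁ for
n ≥ 2 are inter-keypress intervals; *execution time* = t₁₆ − t₁ (reaction
time excluded by construction). Position 1 is included in the chunk
analysis and in phase mean RTs by default (`include_first=False` drops
it); only successful trials are ever analyzed.

## The synthetic-behavior generator

No raw behavioral data are distributed with the task, so the simulator is
a first-class module: it defines the conditions under which everything
downstream is validated.

**RT model.** RT(t, n) = (B + A·t^(−β)) · mₙ · ε with t the
successful-trial index, B = 200 ms the asymptotic keypress time,
A = 200 ms the practice amplitude, β = 0.5 the practice exponent, and
ε = exp(σZ) unit-median log-normal noise with σ = 0.15. The power law
with asymptote is the standard law-of-practice form and keeps medians
analytic (the noise has unit median, so the noise-free value is the
distribution median). mₙ = 1 + δ on chunk-initial positions (δ = 0.5
boundary slowing; position 1 always counts as chunk-initial) and 1
elsewhere; an optional within-chunk linear ramp (off by default) plants
monotonically decreasing within-chunk RTs for stress-testing the
append-on-decrease rule. A fixed 300 ms is added to position 1 only,
standing in for stimulus processing and trajectory recall in the reaction
time. With these defaults a cohort's mean execution time falls from
≈ 6.7 s on the first successful trial to ≈ 3.7 s on the 60th, and mean
keypress RT falls from ≈ 360 ms (early phase) to ≈ 270 ms (late) —
magnitudes chosen to sit in the range reported for practiced human
performance on this task.

**Chunk structure.** Two planted partitions of positions 1–16: early
{3, 4, 5, 4} (4 chunks) and late {7, 5, 4} (3 chunks — the first two early
chunks merged). The late partition abruptly replaces the early one at
successful trial 30. Real consolidation is presumably gradual; since only
the early (trials 1–10) and late (trials 51–60) phases are ever contrasted,
an abrupt switch midway is the simplest model whose phase-level structure is
unambiguous. Per-subject boundary jitter (±1) is available but off by
default, so the planted truth is shared across subjects.

**Error process.** The number of error attempts preceding success k is
geometric with failure probability q_k = q₀·exp(−r(k−1)), q₀ = 0.95,
r = 0.24. These values were set from the closed form so the expected
error share of a session is 30.6% (≈ 26 error attempts per 60 successes,
≈ 86 attempts per session), matching the error rate reported for human
cohorts on this task, with errors concentrated before the first few
successes. Error attempts carry corrupted, truncated key sequences (one
key substituted, sequence cut short of the goal) so they can never score
100; their RTs are generated but excluded from every analysis. A sampled
successful repetition whose duration exceeds the 9 s limit is demoted to a
timeout error and redrawn, keeping success flags consistent with the
scoring rules. Rest breaks after every 20 successful trials are recorded
as an attempt-level marker and ignored by analysis.

**What the simulator does not emulate.** Exploration is not modeled
cognitively (error attempts are random corruptions, not planning); RT
autocorrelation within trials, fatigue, and gradual chunk formation are
absent. Passing tests therefore show that the *pipeline* recovers planted
structure under realistic noise — not that real behavior follows this
generative model.

## Chunk identification

For one subject and phase, the successful trials' RTs form a 10×16 matrix.
Each adjacent pair of positions is compared with a paired two-sided
Wilcoxon signed-rank test across trials (minimum 6 trials — the smallest n
whose exact two-sided p can fall below 0.05). Zero differences are dropped
(classical treatment); the exact null distribution is used for ≤ 25
nonzero tie-free pairs, a midrank normal approximation otherwise; a
pair with all-zero differences reports p = 1, direction 0. The direction
is the sign of the median paired difference (robust to outlying trials).

Segmentation: position 1 opens the first segment; a significant increase
at pair (n, n+1) closes the current segment and opens a new one at n+1;
anything else — non-significant in either direction, or significantly
*decreasing* — appends. "Monotonically decreasing" membership is thus
operationalized as a significant Wilcoxon decrease; a non-significant
decrease is already covered by the non-significance clause, and only
increases ever create boundaries. Segments of length 1 remain in the
partition but are not chunks; the chunk count and mean chunk length
exclude them from numerator and denominator alike.

Defaults: α = 0.05, two-sided, uncorrected across the 15 pairs. The level
and sidedness are exposed as parameters rather than asserted as canonical:
with 15 uncorrected exact tests at n = 10, the per-pair false-boundary
(significant-increase) probability under exchangeability is 0.0244, so a
fully correct 4-chunk partition is recovered in at most
(1 − 0.0244)⁸ ≈ 82% of phases (8 pairs carry no planted signal) no matter
how strong the boundary slowing — an inherent ceiling of uncorrected
per-pair testing that users should weigh against the power loss of a
correction. Phase windows are the first and last 10 successful trials.

## Phase statistics

- **Learning curves:** per success index, the across-subject mean
  execution time (±SEM) and the mean number of error attempts preceding
  that success.
- **Friedman test** (subjects × 60 trials) for an effect of trial on
  execution time; fully tied inputs return χ² = 0, p = 1.
- **Paired t-test** on per-subject mean keypress RT (positions 1–16 over
  the phase's 10 trials), early vs late. Zero-variance differences are
  flagged degenerate (t = 0 or ±∞) rather than reported as NaN.
- **Wilcoxon signed-rank tests** on per-subject chunk count and mean chunk
  length, early vs late. Subjects with no detected chunk in a phase enter
  the count test with 0 but are excluded pairwise from the length test
  (and listed in the result).

Because n ≈ 13, asymptotic reference distributions are rough; every test
therefore also reports an exact p-value: full sign-flip enumeration for
the paired t (2ⁿ patterns when feasible, seeded Monte Carlo beyond),
the exact signed-rank distribution for Wilcoxon (with the z and
normal-approximation p reported alongside, since tie handling makes exact
and approximate regimes differ on discrete features), and within-subject
permutation (enumerated when (k!)ⁿ is small) for Friedman. Each is
validated in the test suite against an independently coded enumeration
oracle.

## Numerical and interface choices

- All randomness flows from numpy `SeedSequence`; per-subject streams are
  spawned from the master seed, so cohorts are reproducible and subjects
  independent.
- Partitions are tuples of inclusive 1-based (start, end) pairs and are
  validated to tile 1..N; RT matrices must be strictly positive.
- The trial log is one row per keypress with strict validation (positions
  1..k, strictly increasing timestamps, success ⟺ reward = 100); errors
  name the offending file lines.
- Problem sizes in the test suite (e.g. 200 brute-force tasks, 1000 random
  segmentation patterns, 2000 null phases, 200 recovery replicates per
  condition, 100 cohorts) were chosen to keep Monte-Carlo error well below
  the asserted margins while the full suite runs in a few minutes on one
  core.

## Known limitations

- The chunk detector assumes a fixed sequence across trials (guaranteed by
  trajectory locking) and cannot handle phases whose successful trials
  differ in length.
- Uncorrected per-pair testing trades exact-partition recovery (capped
  near 82% at α = 0.05, n = 10, as derived above) for per-boundary power;
  a corrected or FDR variant is a one-line change via the α parameter but
  alters the null calibration.
- The abrupt consolidation switch cannot express partial/gradual merging;
  detected partitions in trials near the switch mix both regimes if a
  custom window straddles it.
- Statistical results at n = 13 subjects rely on exact/permutation
  p-values; the normal-approximation z values are reported for
  comparability but inherit the usual discreteness caveats.
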