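# Methods

## Model

`recallnet` treats recall of a small signed social network as a two-stage
stochastic reconstruction from partial exact memory.

**Structural pass.**  Given a target network (n nodes, |E| undirected
ties) and a seed character set, every target tie incident to a seed
character is recalled exactly.  The pass then visits each still
unconnected node pair exactly once, in a uniformly random order drawn per
replicate.  A visited pair that would complete at least one triangle in
the recalled-so-far graph gains a tie with probability
`P_Triangle = T_Closed / T`; any other visited pair gains a tie with the
background probability `P = (|E| − T_Closed) / ((n(n−1)/2) · T)`.  Both
probabilities are computed from the *target's* triplet census — the
modelling assumption is that people carry an approximately correct sense
of how much triadic closure and overall density a network has, so the
true values stand in for the central tendency of those impressions.  One
probability draw per pair; a pair rejected under the closure draw does
not get a second background draw.  The pass makes a single sweep and
stops when all pairs have been considered.

**Affective pass.**  Seed ties start from their true valences, then a
fraction `x` of them (round-half-up of `x·|seed|`, chosen uniformly) is
redrawn uniformly from {+1, −1} — "randomly chosen", not "flipped", so
about half the redraws remain accidentally correct.  Every heuristically
added tie is valenced by the balance heuristic: the sign of the mean sign
product over the open triplets the pair closes *in the recalled graph at
the moment the tie was added* (implemented by replaying the structural
pass's addition order, so the closure context matches exactly); an
exact-zero mean falls to the `zero_tiebreak` (default positive); a tie
closing no triplet takes +1, the positivity bias.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `p_triangle`, `p_background` | derived from target | explicit overrides for degenerate/robustness analyses |
| `t_closed_override` | none | replaces T_Closed in **both** formulas (mis-remembered closure); range [0, T] |
| `census_mode` | `triplets` | `triplets`: T_Closed = 3 × triangle count (P_Triangle is the global clustering coefficient); `triangles`: T_Closed = triangle count |
| `background_mode` | `literal` | denominator `(n(n−1)/2)·T`; `subtractive` uses `n(n−1)/2 − T` |
| `closure_against` | `recalled` | closure judged against the evolving recalled graph; `seed_only` freezes it at the seed graph |
| `x` | 0.30 | seed-valence corruption fraction; the model's operating point |
| `zero_tiebreak` | `positive` | consistent with the positivity bias |
| replicates | 1000 | per sweep unit; a `--fast` profile uses 100 |

Two genuine ambiguities in the probability definitions are exposed as
configuration rather than resolved silently.  (1) Whether T_Closed counts
closed triplets (three per triangle) or triangles: the ratio P_Triangle
is unaffected, but the background numerator |E| − T_Closed is not, so
both census modes exist.  (2) The background denominator reads naturally
as a product or as a difference; both are implemented.  Defaults are the
closed-triplet census with the product denominator.  On the canonical
fixture that combination makes the numerator negative (T_Closed = 27 >
|E| = 23), so the background probability clamps to 0 with a logged
warning; spurious cross-component ties then require either the
`triangles` census mode or an explicit `p_background`.

## The stimulus fixture

The canonical stimulus is a 15-character, 23-tie signed network in two
disconnected components (8 + 7 nodes, Lewis's component the larger),
15 positive and 8 negative ties, density 23/105 ≈ 0.219.  Seven
characters carry hard degree constraints (Isabelle 2, Victoria 3,
James 3, Alyssa 4, Catherine 4, Lewis 5, Peter 5), and every
multi-character seed set in the 35-row catalogue must have an incident
tie count equal to the *sum* of its members' degrees — which forces
every co-listed pair to be non-adjacent.

That additivity makes the topology nearly unique.  Only four pairs among
the constrained characters are never co-listed (Lewis–Peter,
Lewis–Catherine, Peter–Catherine, Alyssa–James); counting degrees shows
all four must be ties and that exactly one tie can join two
unconstrained characters.  We spend it on Henry–Elizabeth, which together
with the forced James–Henry and James–Elizabeth ties preserves the
mutually connected Henry–Elizabeth–James triplet; an Anne–Henry tie is
arithmetically impossible under the catalogue, so Anne's sole tie is to
Alyssa (and Anne–Elizabeth stays absent).  The only remaining freedom —
which three filler characters join Lewis's component and which two of
them tie to Isabelle and to Catherine — is driven by the generator's
seed; the packaged canonical fixture is frozen from a fixed seed and a
test asserts regeneration equals the shipped file.

**Valences.**  A balanced arrangement is found via the two-colouring
characterisation of structural balance: each component's nodes are split
into two groups and exactly the cross-group ties are negative, so every
triangle has an even number of negative ties and a positive sign
product; the generator enumerates colourings and picks one giving exactly
8 negative ties.  The imbalanced arrangement starts from a balanced one
and applies seeded greedy sign swaps (one +1 with one −1, preserving the
15/8 split) maximising the number of negative-product triangles.  We
deliberately generate a *strongly* imbalanced layout (all 9 triangles
imbalanced in the frozen fixture) rather than the minimal one-triangle
perturbation, because the imbalanced experimental condition is a
systematically imbalanced arrangement of the same valence counts; the
contrast between conditions (e.g. quality's sensitivity to `x`) is only
meaningful against a genuinely imbalanced target.

The kin/non-kin manipulation affects relationship wording only; the data
model carries it as an optional per-tie label with no structural role.

## What the generator does and does not emulate

The fixture reproduces every printed structural constraint of the
experimental stimulus: size, tie count, valence counts, components,
density, the degree catalogue with its 35 seed-set counts, and the
balance structure of each condition.  It is a constraint-equivalent
stand-in, not a replica: the original stimulus's exact topology is not
machine-recoverable, so fixture triangles and filler-character wiring are
one consistent solution among the few the constraints permit.  Model
results that depend only on the census, degrees and balance structure
transfer; results sensitive to unconstrained wiring details need not.
Passing tests therefore demonstrate correctness of the mechanism under
the printed constraints, not agreement with unpublished raw recall data
— experimental means and SDs enter only through the δ operation as
user-supplied inputs.

## Randomness and reproducibility

Every stochastic element consumes a `numpy.random.Generator`.  Sweeps
derive one child stream per replicate from a master seed via
`SeedSequence(master, spawn_key=(sweep_id, unit_index, replicate))`, so
full tables are bit-reproducible, replicate batches can be split or
parallelised without changing any number, and the balanced and
imbalanced conditions share common random numbers (reducing the variance
of between-condition contrasts such as the x-sensitivity comparison).

## Numerical and degenerate-input choices

- Background probability clamped into [0, 1] after evaluation; one
  logged warning per distinct clamping configuration.
- Undefined metrics (precision of an empty recall, quality with zero
  correct ties) propagate as missing values, are excluded from sweep
  means, and are counted in an `n_undefined` column — never coerced to 0.
- P_Triangle on a target with no connected triplets, and the background
  probability with a non-positive denominator, raise errors rather than
  returning conventions.
- Sample SDs use ddof = 1; single-replicate cells report SD 0.

## Test problem sizes

Monte-Carlo property checks (monotonicity of recalled tie count in the
background probability and in the T_Closed override; monotonicity of
quality in `x`; the balanced-vs-imbalanced sensitivity contrast) use 500
replicates per level, which puts the standard error of each estimated
mean well below the effect sizes asserted.  Census correctness is
cross-checked against a brute-force triple enumeration on 200 random
graphs of up to 12 nodes.  Sweep defaults remain 1000 replicates per
unit for production runs.

## Known limitations

- Single-pass recall: no forgetting dynamics, study-time effects, or
  working-memory covariates.
- Undirected, binary-valence ties only; no directed or graded affect, no
  kin-specific valence priors.
- The corruption convention (uniform redraw) is one of two defensible
  readings; a "must-flip" convention would shift the effective operating
  point of `x` and can be emulated by rescaling.
- Fitting `x` is done by inspection of the sweep table, not formal
  optimisation.
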