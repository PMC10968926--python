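# Methods

## The model

`spatial_ultimatum` simulates a population of emotion-endowed agents playing a
survival variant of the Ultimatum Game on an n×n square lattice with periodic
boundaries (a torus). Each cell holds exactly one agent; agents interact with
their von Neumann neighborhood of unit radius — the four orthogonally adjacent
cells (north, east, south, west).

Each agent carries a fixed emotional trait e ∈ {anger, fear, joy, sadness,
surprise} that fully determines its bargaining behavior through two numbers:
the offered fraction x_e (how much of the stake it offers when proposing) and
the aspiration y_e (the minimum fraction it accepts when responding):

| emotion  | offer x_e      | acceptance rule            |
|----------|----------------|----------------------------|
| anger    | 0.20           | offers > 0.50              |
| fear     | 0.50           | any offer (y = 0)          |
| joy      | uniform(0, 1)  | any offer (y = 0)          |
| sadness  | 0.50           | offers > 0.20              |
| surprise | uniform(0, 1)  | fair coin flip, offer ignored |

State per agent: money d_i(t) (real-valued dollars, never rounded) and an
integer count of lives ℓ_i(t). At t = 0 every agent holds D dollars and L
lives, with emotions assigned independently and uniformly, so each initial
fraction fluctuates around 1/5.

### One time step

Agents are visited in a fixed row-major sweep. At its turn, an agent proposes
once to each of its four neighbors (N, E, S, W order) provided it is alive and
holds at least the minimum stake m; the amount wagered on each neighbor is
f·d_i/4, evaluated from the proposer's money *at that moment*. The responder
accepts or rejects according to its rule above. On success the offered amount
moves from proposer to responder and **both gain a life**; on failure no money
moves and **both lose a life**. Money and lives update in place, so later
games in the sweep see the outcomes of earlier ones. Money is globally
conserved — it is only redistributed.

Death is immediate: an agent whose lives reach zero leaves an empty cell for
the remainder of the step and plays no further games in either role (games
"with" an empty cell simply do not happen). At the step boundary every empty
cell is refilled simultaneously by a newborn that inherits the dead agent's
money, receives L fresh lives, and adopts the predominant emotion among its
**surviving** neighbors (copycat), with ties broken uniformly at random; if
all four neighbors also died, the emotion is drawn uniformly from the five.
An alternative replacement rule (`replacement_rule="richest_neighbor"`)
adopts the emotion of the richest surviving neighbor instead; it is off by
default and not used in any shipped analysis.

### Why these exact mechanics

Three details of the step carry almost all of the selective signal, and each
is a deliberate design decision:

- **Ties fail.** Acceptance requires the offered fraction to *strictly*
  exceed the aspiration. The canonical parameters collide exactly at the
  margins — fear's and sadness's 50% offers meet anger's 50% aspiration, and
  anger's 20% offers meet sadness's 20% aspiration — so the tie rule decides
  whether anger can close deals with the two most generous strategies at all.
  With strict acceptance, anger rejects the standard 50% offer and keeps
  losing lives; this is what drives anger close to extinction at the baseline
  and makes the ±0.1 perturbation sweeps informative (a perturbation of
  either side breaks the tie in a definite direction). With tie-acceptance,
  perturbing fear's offer from 0.50 to 0.60 would change no decision anywhere
  and the sweep would be vacuous.
- **Immediate death (the "ghost cell").** Because lives change one unit at a
  time during the sweep, an agent can be eliminated mid-step before its
  neighbors have played it. This makes the survival buffer L bite: with an
  end-of-step net settlement, agents whose successful games outnumber their
  failures would never be at risk, lives would accumulate without bound for
  everyone, and selection would switch off after a few steps.
- **Survivors-only copycat vote.** Deaths cluster spatially (an unlucky
  region loses several agents in the same sweep). Counting only surviving
  neighbors in the newborn's vote prevents a death cluster from re-seeding
  itself with the very strategies that just failed there, which is what lets
  fear, joy and sadness expand into hostile regions.

Lives are unbounded above: successful agents bank an arbitrarily large
survival buffer. The alternative (capping lives at L) was examined and
discarded — it makes the two coin-flipping games per neighbor a sustained
mortality source that all but eliminates surprise, and it introduces a parity
artifact (with an even number of games per step, L = 1 and L = 2 become
dynamically identical).

### Metrics

For each emotion e, with N_e agents holding M_e dollars out of N = n² agents
and D·N dollars total:

- p_e = N_e / N, q_e = M_e / (D·N); both vectors sum to 1.
- φ_e = M_e / N_e = D·q_e / p_e — per-capita money; reported as missing when
  an emotion is extinct (never fabricated as zero).
- H_p = −Σ_e p_e ln p_e / ln 5 and H_q analogously — normalized Shannon
  entropies in [0, 1]. The normalization stays ln 5 even if emotions go
  extinct, because five emotions are always in play; 0·ln 0 := 0.
- I_p = 1 − H_p, I_q = 1 − H_q — inhomogeneities: 0 for an even five-way
  split, 1 for a monoculture/monopoly.

Natural logarithms are used internally; the base cancels in the
normalization. Entropies are computed with `scipy.stats.entropy`; the test
suite cross-checks against a direct −Σ f ln f implementation to 1e-12.

## Parameters, defaults and units

| symbol | name (code)        | default | meaning                                  |
|--------|--------------------|---------|------------------------------------------|
| n      | `side`             | 50      | lattice side; N = n² agents              |
| D      | `money_init`       | 100     | dollars per agent at t = 0               |
| L      | `lives_init`       | 1       | lives per agent at t = 0 and per newborn |
| f      | `fraction`         | 0.5     | fraction of money allocated per step     |
| m      | `min_stake`        | 1       | minimum money to act as proposer         |
| T      | `steps`            | 100     | horizon in steps                         |
| Δ      | `deltas`           | {}      | per-emotion strategy perturbation        |

The defaults are the baseline competitive scenario. A perturbation Δ
intensifies (Δ > 0) or softens (Δ < 0) a deterministic emotion: anger becomes
x = 0.20 − Δ, y = 0.50 + Δ; fear x = 0.50 + Δ; sadness x = 0.50 + Δ,
y = 0.20 + Δ. Perturbed values clip to [0, 1] (fractions outside that range
are meaningless); Δ is rejected for joy and surprise, whose rules have no
tunable intensity. Decisions depend only on percentages, so D is a pure unit:
scaling it rescales every balance exactly and changes no outcome (the m = 1
eligibility threshold never binds at the scales shipped).

By t = 100 the composition has settled near its asymptotic value, which is
why scenarios measure at the final step rather than time-averaging.

## Replication design

A scenario is one parameter combination simulated `replicates` times
(default 10) with independent seeds spawned from a master seed via numpy's
`SeedSequence` (recorded in every summary for audit). Summaries report the
sample mean and the n−1 sample SD of p_e, q_e, φ_e, I_p and I_q at the
measurement step; φ statistics for an emotion cover the replicates in which
it is present. The default sweep manifest holds fifteen scenarios: the
initial-money sweep D ∈ {20, 60, 100, 140} at L = 1 (the D = 100 member is
the baseline), the lives sweep L ∈ {2..6} at D = 100, and single-emotion
perturbations Δ ∈ {−0.1, +0.1} for anger, fear and sadness. This is one
consistent de-duplication of the study grid; the manifest is plain data and
users can edit or replace it.

## Numerical and implementation choices

- The sweep is compiled with numba; random draws (offers for joy/surprise
  proposers, coins for surprise responders) are consumed lazily in sweep
  order from a per-step seed derived from the replicate's `numpy.random`
  Generator, so runs are bit-reproducible given a seed. A fresh offer is
  drawn per interaction, honoring "unpredictable offers".
- The uniform(0, 1) offer distribution for joy and surprise is the
  minimal-assumption choice for "a random number averaging around 50%".
- Replacement is vectorized: neighbor votes are counted with toroidal rolls,
  and a uniform(0, 1) noise term added to the integer counts implements the
  uniform tie-break without disturbing strict majorities.
- Tests include an independent scalar oracle: a dict-based reimplementation
  of the sweep for deterministic-emotion lattices, compared cell-for-cell
  (exact float equality — both paths perform identical arithmetic in the
  same order) over five steps on 3×3 fixtures chosen so every replacement
  vote has a strict majority.
- Degenerate inputs: n < 3 is rejected (the four neighbors would not be
  distinct); T = 0 returns the single t = 0 record; a 1-replicate scenario
  reports its SDs as missing.

## What the simulations do and do not show

The generator of initial conditions is the model itself (iid uniform
emotions, equal endowments); there is no external data. Passing tests
demonstrate internal consistency of the dynamics and reproducibility of the
summary statistics under the stated conditions. They say nothing about human
bargaining: the emotion strategies are stylized encodings of qualitative
tendencies, not fitted behavioral models.

Known limitations:

- Emotions are immutable traits; there is no contagion, learning, mutation
  or state-dependent switching.
- Results at the shipped scales have residual sweep-order structure: the
  fixed row-major order is part of the model definition. Randomizing the
  order changes summary statistics by well under one replicate SD.
- The composition that the dynamics settles into is a frozen state (agents
  that survive the early cull bank enough lives to become effectively
  immortal); the reported asymptotics are those of the t = 100 snapshot, not
  of a mixing stationary distribution.
- The joy/sadness split at large n is sensitive to micro-details of the
  sweep at the ~0.015 level; see the repository's test suite for the exact
  tolerances verified.
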