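# Methods

## Model overview

The agent couples two binary networks operating on the environment's
discrete time step.

The **context selector** is an Amari–Hopfield network of `N = 1200`
threshold units. Its activity vector splits into a stimulus domain
(`D_stim` units, a copy of the current external stimulus) and a context
domain (`N − D_stim` units carrying the agent's subjective context).
One environmental state can own several contextual states — the same
place approached with a different history — stored as separate
attractors. Storage is one-shot Hebbian on the ±½-centred activity;
forgetting is its exact additive inverse, so a store/forget pair leaves
the weights bit-identical. Recall iterates the synchronous threshold
dynamics from an initial state and is classified by its fixed point:
*success* (stimulus domain reproduces the presented stimulus exactly),
*hallucination* (a fixed point carrying a different stimulus), or
*default fallback* (no convergence within 50 iterations; the agent
reverts to the stimulus's default context). Synchronous updating with
"two identical consecutive states" as the convergence test means a
period-2 oscillation counts as non-convergence, which is exactly the
failure mode the default fallback is for.

The **sequence composer** is a pool of 300 binary neurons recruited on
demand into two roles. A *state-coding* neuron is tied to one
contextual state through one-shot cross-weights with learning rate
`(N+1)/2` and offset `N/(N+1)`; these constants make the binary
read-out of a single linked context exact (+½ on its active bits,
−N/2 elsewhere), so one neuron faithfully re-injects its context into
the attractor network. A *transition-coding* neuron represents one
learned transition out of a state neuron; once linked, its read-out
predicts the stimulus of the state it leads to. Planning sequences
alternate state/transition neurons, sampled with probability
proportional to the recurrent weight above the baseline `w0 = 0.3`
(eligibility margin 0.01), and stop at a transition neuron whose
reward value is positive — a plan always ends where it expects reward.

**Valuation.** Each transition neuron carries a reward value
`V ← V + α(R − V)` (α = 0.15, updated on positive reward) and a
no-good indicator `NG`. A reward event at the end of a sequence resets
NG when the reward beats the prediction and increments it by one
otherwise; when the reward falls short of the prediction all
indicators additionally decay by γ = 0.7, the increment being applied
first (so a single disappointment of an established plan lands exactly
at the suppression threshold θ_NG = 0.7). While NG ≥ θ_NG the
sequence value SV = V − (V + NG) is negative: the plan is transiently
suppressed without being devalued.

**Control loop.** At each state the agent holds a context and its
state neuron, draws up to nine candidate sequences (accepting the
first with SV > 0, otherwise choosing uniformly among the candidates
minus the single worst), and executes the plan transition by
transition. Two error signals reorganise the context map:

* *Sensory prediction error* — the observed stimulus differs from the
  planned one. The interrupted transition→state link decays by the
  factor (1 − α); among the other state neurons reachable from the
  interrupted transition neuron, one predicting the observed stimulus
  within θ_remap = 5 bits is activated if it exists; otherwise a new
  context (observed stimulus + random half-active context domain) is
  created, stored, given a state neuron, and the link onto it is
  pulled toward 0.65 — eligible for replay but below the rewarded
  asymptote 0.7.
* *Reward prediction error* — exploration. Whenever a state offers
  more transitions than the current state neuron has learned, the
  agent explores with probability 0.3, or with certainty while the
  followed plan is suppressed. An exploratory move activates a
  transition neuron for an action whose outcome nothing predicts yet,
  and the following state receives a fresh context.

After either remapping the newly recruited neurons predict nothing, so
fresh contexts are created at each following state until the agent
reaches a landmark (the task's start state), where a landmark-based
recall (stimulus + random context domain) re-anchors the episode.

On reward, every consecutively activated (transition, state) pair
since the previous reward event is potentiated toward `R − w0`; this
is what concatenates one-step segments into reward-to-reward plans.
The between-reward window restarts at the current state neuron, so
chains extend across trial boundaries: tasks whose reward states have
no outgoing action expose a single forced reset transition, executed
like any other action, which is why a trained cueing agent plans three
actions ahead (reset, branch, choice) from one reward to the next.

## Parameters

| parameter | value | meaning |
| --- | --- | --- |
| `N` | 1200 | context-selector units |
| `D_stim` | 200 / 30 / 600 | stimulus domain (control / SZ / ASD) |
| `θ`, `X⁰` | 0.5, 0.5 | threshold and offset of the attractor dynamics |
| capacity | 8 | stored contexts per stimulus before forgetting |
| SV protection | 0.7 | best sequence value exempting a context from forgetting |
| `N_H` | 300 | planning-network pool |
| `w0` | 0.3 | recurrent baseline / effective threshold |
| `α` | 0.15 | learning rate (values, reward-gated weights) |
| `θ_NG`, `γ` | 0.7, 0.7 | no-good threshold and decay |
| `θ_remap` | 5 bits | stimulus tolerance for context switching |
| `p_expl` | 0.3 | baseline exploration probability |
| switch target | 0.65 | weight pulled onto a newly created context |
| attempts | 9 | sequence-selection loop length |
| recall cap | 50 | attractor iterations before default fallback |
| trial guard | 50 steps | truncation guard per trial |

The model-free baseline uses tabular Q-learning over the last `n+1`
environmental states (n = 0…3), α = 0.4, γ = 0.6, R = 100 on the
rewarded transition and 1 otherwise, with successor choice
proportional to Q.

## Synthetic stimuli

Stimulus codes are the package's own construction (the model leaves
them unspecified): each environmental state receives a random
half-active binary code of length `D_stim`, re-drawn until all pairs
differ by at least `min(4·θ_remap, ⌈D_stim/4⌉)` bits — far enough
apart that the remapping tolerance can never confuse two states. The
morphed arena stimulus of the inference task takes exactly half of the
two parents' differing bits from each, making it literally equidistant
from both.

The default-context converter ranks a Gaussian projection of the
*centred* stimulus and activates the top half of the context domain.
Centring matters: projecting raw 0/1 stimuli adds the same offset
(half the projection matrix's row sums) to every stimulus, which
dominates the ranking and correlates the default contexts of different
stimuli (measured pairwise overlaps ≈ +100 in centred coding); the
attractor dynamics then mis-converge even at a handful of stored
patterns. With centred projections, contexts of different stimuli are
near-orthogonal and recall is reliable up to the stated capacity of 8
same-stimulus contexts — which is also where default fallbacks start
appearing, consistent with the chosen capacity bound.

What the generator does *not* emulate: graded stimulus similarity,
sensory noise within a state, and continuous time. Passing tests
therefore show the algorithm behaves as specified on clean,
well-separated discrete observations, not that it would survive noisy
or drifting sensory codes.

## Numerical and design choices

* **Synchronous recall, strict thresholds.** The update is a whole
  vector map; ties at threshold cannot occur away from measure-zero
  weights because all quantities are quarter-integers offset by 0.5.
* **Forgetting scope.** A capacity violation forgets *all* stored
  contexts of that stimulus that never produced a sequence value above
  0.7 (reward-unrelated episodic memory), not just the oldest one.
  One-at-a-time forgetting keeps every stimulus pinned at the capacity
  bound forever, which contradicts the sparse trained context maps the
  model is supposed to produce.
* **One link per transition neuron.** A transition neuron's context
  read-out is written once. Adding a second context turns the
  prediction into the bit-AND of two codes, which matches no stimulus
  and forces a prediction error on every use. Under pool exhaustion
  (SZ condition) state neurons *are* re-imprinted — that overlap, and
  the hallucinations it causes, is the degradation the condition is
  about.
* **Plan-consistency matching.** During execution the observed
  stimulus is compared with the stimulus of the *planned* next state
  neuron; the transition neuron's own read-out is used at the plan's
  final position and for history-based initialisation. In the
  stochastic branch of the cueing task this is what lets a
  minority-branch plan be confirmed by a minority outcome instead of
  being interrupted by it.
* **Landmark re-anchoring.** A hallucinated history-based recall at a
  landmark retries with the landmark initialisation instead of
  creating a context. Landmarks exist to terminate otherwise
  indefinite episodic sequences; without this rule a forgotten
  trial-boundary context spawns a new context at the start state on
  every episode.
* **Exploration bookkeeping.** Eligibility uses the stated
  count rule (available transitions vs. connected transition neurons),
  but exploration re-uses a connected-but-never-linked transition
  neuron before recruiting a fresh one and aims at an action whose
  outcome nothing predicts. This prevents duplicate neurons for one
  action from blocking the eligibility count permanently.
* **Degenerate inputs.** A plan whose transition neuron predicts
  nothing moves at random (logged as `plan_blind`); a sequence with no
  transition at all falls back to a random move; a runaway trial is
  truncated at 50 steps and flagged.

## Problem sizes

Cohort statistics use 40 agents (standard error over agents), the
context-map and capacity audits 10 agents; tasks run their standard
protocols (100 trials alternation, 80 for the 20/20/40-trial lap
phases, 120 for four 30-trial cueing blocks). A full 40-agent cueing
cohort takes on the order of a minute on one CPU; the whole test suite
a few minutes.

## Known limitations

* In the 2-lap task the first rewarded trajectory freezes the chain at
  whatever lap depth it happened to have; the ≥2-lap phase rewards any
  depth, so a fraction of successful agents settle on more than the
  minimal three S2-contexts. Shortening pressure exists (plans stop at
  the earliest positive-value transition) but often needs more than
  the 80-trial protocol to prune.
* Registries transiently hold remapping by-products alongside the
  behavioral map; `used_context_counts` (contexts actually adopted
  over a trial window) is the faithful read-out of the *learned* map,
  `context_counts` of the raw attractor census.
* The ASD condition expresses default-context dominance partly through
  successful recalls that collapse onto the default attractor rather
  than through explicit non-convergence; the reported default-usage
  statistic counts both routes.
* Sequence generation carries a hard length cap (40 neurons) as a
  guard against degenerate loops in pathological learned graphs; it is
  far above any plan length the tasks demand.
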