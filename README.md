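# remapseq

Simulator of **remapping-based hippocampal sequence learning**: a
model-based reinforcement-learning agent built from two coupled binary
networks, together with the discrete tasks, lesion and
stimulus-ratio manipulations, a model-free baseline, and the cohort
statistics used to study how context-dependent planning emerges — and
how it breaks down in schizophrenia-like (SZ) and autism-like (ASD)
regimes.

It is aimed at computational neuroscientists who want a tested,
reproducible implementation of the model to probe (splitter cells, lap
cells, replay statistics, entorhinal-inhibition effects) rather than a
general RL library.

## The model

**Context selector (X).** An Amari–Hopfield network of N = 1200 binary
units. Activity splits into a *stimulus domain* (a copy of the current
external stimulus ξ; 200 units in the control condition, 30 in SZ, 600
in ASD) and a *context domain* (the agent's subjective context).
Contextual states are stored one-shot,

    W_XX ← W_XX + (X − ½)(X − ½)ᵀ,

and retrieved by iterating X ← 1[W_XX(X − ½) − ½ > 0] from a
history-based initialisation (thresholded hippocampal feedback) or, at
a landmark, from (ξ, random). A fixed point whose stimulus domain
reproduces ξ is a successful recall; a fixed point with a different
stimulus domain is a hallucination-like recall; non-convergence within
50 iterations falls back to the stimulus's default context. Each
stimulus keeps at most 8 stored contexts; on overflow, contexts that
never produced a sequence value above 0.7 are forgotten by the exact
inverse of the storage rule.

**Sequence composer (H).** A pool of 300 binary neurons recruited on
demand as *state-coding* (one per contextual state) or
*transition-coding* (one per learned transition) units. From the
state neuron selected by the current context, a planning sequence is
sampled with branch probabilities ∝ (W_HH − w₀)/(1 − w₀) above an
eligibility margin, stopping at a transition neuron whose reward value
V > 0. Plasticity: state→transition links potentiate to 1 on use;
transition→state links relax toward R − w₀ = 0.7 on reward;
value updates V ← V + α(R − V) with α = 0.15; a *no-good* indicator
transiently suppresses recently unrewarded plans (threshold 0.7,
decay 0.7) and drives exploration.

**Remapping.** When the stimulus predicted by the plan differs from
the observed one (sensory prediction error), the interrupted link is
weakened and the agent switches to an alternative context predicted
within θ_remap = 5 bits, or creates a new one. When a suppressed plan
is being followed (reward prediction error), the agent explores an
untried transition and the following state receives a fresh context.
Either way, fresh contexts keep being created downstream until a
landmark re-anchors the episode.

## Worked example

```python
import numpy as np
from remapseq import AgentConfig, make_alternation_task, run_experiment
from remapseq.metrics import used_context_counts

cfg = AgentConfig()
res = run_experiment(
    cfg, lambda rng: make_alternation_task(cfg.d_stim, rng),
    n_agents=10, n_trials=100, seed=7,
)
late = res.trials[res.trials.trial >= 90]
print(late.groupby("agent")["rewarded"].mean().round(2).values)
print(late["planning_length"].mean().round(2))
print(used_context_counts(res.steps, (67, 100)).iloc[0].to_dict())
```

prints

```
[1.   1.   0.91 1.   1.   1.   1.   1.   1.   1.  ]
2.99
{'S1': 1, 'S2': 2, 'S3': 1, 'S4': 1, 'S5': 1}
```

— all ten agents solve the reward alternation, plans grow until an
agent leaving one reward site plans the full three actions to the
next, and the trained context map holds exactly two contexts at the
overlapping state S2 (one per approach direction — the splitter-cell
configuration) and one everywhere else.

The same cohort machinery is exposed on the command line:

```bash
remapseq run cueing --agents 40 --trials 120 --seed 1 --out runs/
remapseq run alternation --condition sz --agents 10 --seed 2 --out runs/
remapseq run two-lap --baseline-n 3 --agents 10 --seed 3 --out runs/
```

Each run writes tidy `trials.csv` / `steps.csv` logs, cohort summary
CSVs and a JSON manifest that reproduces the run byte for byte.

## Layout

| module | contents |
| --- | --- |
| `remapseq.context_selector` | Hopfield context memory, converter, recall |
| `remapseq.sequence_composer` | planning network, recruitment, plasticity |
| `remapseq.valuation` | reward values, no-good suppression |
| `remapseq.agent` | per-step controller, remapping, cohorts |
| `remapseq.environments` | the four task POMDPs, codebooks, conditions |
| `remapseq.baseline_q` | temporal-context Q-learning baseline |
| `remapseq.metrics` | correct rate, planning length, replay, decoding, ESR |
| `remapseq.analysis` | inhibition probe, behavioral decoding experiments |
| `remapseq.cli` | `remapseq run ...` |

See `docs/methods.md` for the full model description, parameter table
and the design decisions taken where the model left room.
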