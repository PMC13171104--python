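"""Model-free baseline: tabular Q-learning over temporal-context states.

The comparison learner has no context selector.  Instead its state is
the tuple of the last ``n + 1`` environmental states (a fixed-length
temporal context), and it learns action values over (history, successor)
pairs:

    Q(s_k, s_k+1) <- (1 - a) Q(s_k, s_k+1) + a (R + g max_s Q(s_k+1, s))

with a = 0.4, g = 0.6, R = 100 on the rewarded transition and 1
otherwise.  The policy samples the successor proportionally to the
(non-negative part of the) Q values, uniformly when all are zero.
A history length of n = 3 is the minimum that can solve the one-lap
phase of the lap task; the point of the baseline is how slowly it does
so compared with on-demand context creation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .environments import TaskPOMDP

__all__ = ["TemporalContextQ", "run_baseline"]

PAD = "_"  # sentinel for histories shorter than n at trial start


@dataclass
class TemporalContextQ:
    n: int
    alpha: float = 0.4
    gamma: float = 0.6
    q: dict[tuple, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.n <= 3:
            raise ValueError("history length n must be in 0..3")

    def _row(self, hist: tuple) -> dict[str, float]:
        return self.q.setdefault(hist, {})

    def value(self, hist: tuple, successor: str) -> float:
        return self._row(hist).get(successor, 0.0)

    def update(self, hist: tuple, successor: str, next_hist: tuple, reward: float) -> None:
        row = self._row(hist)
        future = max(self._row(next_hist).values(), default=0.0)
        old = row.get(successor, 0.0)
        row[successor] = (1 - self.alpha) * old + self.alpha * (reward + self.gamma * future)

    def policy(
        self, hist: tuple, candidates: list[str], rng: np.random.Generator
    ) -> str:
        """Successor sampled proportionally to Q.  A never-tried
        successor (Q = 0) is weighted like a once-tried unrewarded one,
        so untried branches are not starved once any Q is positive."""
        if not candidates:
            raise ValueError("no candidate successors")
        weights = np.array([max(self.value(hist, c), 0.0) for c in candidates])
        if weights.sum() <= 0:
            return str(rng.choice(candidates))
        weights[weights == 0] = 1.0
        return str(candidates[int(rng.choice(len(candidates), p=weights / weights.sum()))])


def run_baseline(
    env: TaskPOMDP,
    n: int,
    n_trials: int,
    rng: np.random.Generator,
    *,
    rewarded_r: float = 100.0,
    unrewarded_r: float = 1.0,
) -> pd.DataFrame:
    """Run the temporal-context learner on a task and log per-trial
    outcomes.  The action space is traversed as successor choice: the
    learner picks the next environmental state among those reachable."""
    table = TemporalContextQ(n=n)
    res = env.reset(rng)
    hist: tuple = (PAD,) * n + (res.state,)
    rows = []
    guard = n_trials * 60
    steps = 0
    while len(rows) < n_trials and steps < guard:
        steps += 1
        actions = env.available_actions()
        # one action per successor in these tasks; sample the successor
        options: dict[str, str] = {}
        for a in actions:
            for s, _ in env.successor_states(a):
                options.setdefault(s, a)
        successors = sorted(options)
        choice = table.policy(hist, successors, rng)
        res = env.step(options[choice], rng)
        next_hist = hist[1:] + (res.state,) if n > 0 else (res.state,)
        reward = rewarded_r if (res.reward or 0) > 0 else unrewarded_r
        table.update(hist, choice, next_hist, reward)
        if res.trial_ended:
            rows.append(
                {
                    "trial": res.trial_index - 1,
                    "rewarded": bool((res.reward or 0) > 0),
                    "hidden": res.hidden,
                }
            )
            next_hist = (PAD,) * n + (res.state,)
        hist = next_hist
    return pd.DataFrame(rows)
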