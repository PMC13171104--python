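"""Per-neuron reward value and no-good suppression.

Each transition-coding neuron carries a reward value ``V`` (exponential
average of the rewards its sequences earned) and a no-good indicator
``NG`` that transiently suppresses recently unrewarded plans.  The
sequence value of a plan is the value of its last transition neuron,
flipped negative while suppression is active:

    SV = V - (V + NG) * 1[NG >= theta_NG]

On a reward event at the end of a sequence, NG of the terminal neuron
drops to zero if the reward beat the prediction and increments by one
otherwise; when the reward fell short of the prediction every neuron's
NG additionally decays by the factor gamma.  The increment is applied
before the global decay, so a first disappointment lands exactly at the
suppression threshold (1 * 0.7 = theta_NG).
"""

from __future__ import annotations

import numpy as np

__all__ = ["ValueTable"]


class ValueTable:
    def __init__(
        self,
        n: int,
        *,
        alpha: float = 0.15,
        theta_ng: float = 0.7,
        gamma: float = 0.7,
    ) -> None:
        self.n = int(n)
        self.alpha = float(alpha)
        self.theta_ng = float(theta_ng)
        self.gamma = float(gamma)
        self.v = np.zeros(self.n)
        self.ng = np.zeros(self.n)

    def update_value(self, idx: int, reward: float) -> None:
        """Move V[idx] toward the reward; reward events with R <= 0 do
        not devalue (the no-good indicator handles disappointment)."""
        if reward <= 0:
            return
        self.v[idx] += self.alpha * (reward - self.v[idx])

    def sequence_value(self, idx: int) -> float:
        v, ng = self.v[idx], self.ng[idx]
        if ng >= self.theta_ng:
            return float(v - (v + ng))
        return float(v)

    def suppressed(self, idx: int) -> bool:
        return bool(self.ng[idx] >= self.theta_ng)

    def update_no_good(self, idx: int, reward: float) -> None:
        """No-good update for a reward event terminating at ``idx``.

        R > V resets NG[idx]; otherwise NG[idx] += 1.  If additionally
        R < V, all indicators decay by gamma (after the increment).
        R == V increments without triggering the decay.
        """
        v = self.v[idx]
        if reward > v:
            self.ng[idx] = 0.0
        else:
            self.ng[idx] += 1.0
        if reward < v:
            self.ng *= self.gamma

    def process_reward(self, idx: int, reward: float) -> None:
        """Full reward-event pipeline for terminal neuron ``idx``: the
        no-good comparison uses the pre-update value, then the value
        itself is updated."""
        self.update_no_good(idx, reward)
        self.update_value(idx, reward)
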