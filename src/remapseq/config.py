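"""Model constants and per-condition configuration.

All defaults are the reference parameter set of the model: a 1200-unit
binary attractor network (the context selector) coupled to a 300-unit
binary planning network (the sequence composer).  The split of the
context selector into a stimulus domain and a context domain is the one
knob that differs between the control, schizophrenia-like (SZ) and
autism-like (ASD) conditions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Any, Mapping

__all__ = ["AgentConfig", "CONDITION_STIM_SIZES", "apply_condition"]

#: stimulus-domain sizes for the three simulated populations
#: (16.7%, 2.5% and 50% of the 1200 context-selector units).
CONDITION_STIM_SIZES: dict[str, int] = {"control": 200, "sz": 30, "asd": 600}


@dataclass(frozen=True)
class AgentConfig:
    """Frozen bundle of every model constant.

    Parameters
    ----------
    n_context:
        Number of binary units in the context selector (``N``).
    n_hippocampus:
        Number of units in the sequence composer.
    d_stim:
        Size of the stimulus domain; the remaining ``n_context - d_stim``
        units form the context domain.  200 for control, 30 for the SZ
        condition, 600 for the ASD condition.
    theta, x0:
        Firing threshold and activity offset of the attractor dynamics.
    capacity:
        Maximum number of contextual states stored per external stimulus
        before reward-unrelated contexts are forgotten.
    sv_protect:
        A stored context whose sequences have ever reached a sequence
        value above this bound is protected from forgetting.
    w0:
        Baseline (and effective threshold) of the recurrent hippocampal
        weights.
    alpha:
        Learning rate shared by the value update and the reward-gated
        weight updates.
    theta_ng, gamma_ng:
        Threshold and decay factor of the no-good suppression variable.
    theta_remap:
        Hamming tolerance (bits, stimulus domain) for switching to an
        alternative context during prediction-error-driven remapping.
    p_explore:
        Baseline exploration probability; rises to 1 while the agent
        follows a suppressed (negative sequence value) plan.
    spe_switch_target:
        Target weight toward which the link onto a newly created context
        is pulled after a sensory prediction error.
    eligibility_margin:
        A recurrent weight takes part in sequence generation only while
        it exceeds ``w0`` by more than this margin.
    max_sequence_attempts:
        Sequence-selection loop length (candidate plans drawn per step).
    max_recall_iters:
        Attractor iterations allowed before a recall is declared failed.
    max_sequence_len:
        Hard cap on generated sequence length (neurons), a guard against
        degenerate cycles in the learned graph.
    max_trial_steps:
        Environment steps allowed per trial before it is truncated.
    """

    n_context: int = 1200
    n_hippocampus: int = 300
    d_stim: int = 200
    theta: float = 0.5
    x0: float = 0.5
    capacity: int = 8
    sv_protect: float = 0.7
    w0: float = 0.3
    alpha: float = 0.15
    theta_ng: float = 0.7
    gamma_ng: float = 0.7
    theta_remap: int = 5
    p_explore: float = 0.3
    spe_switch_target: float = 0.65
    eligibility_margin: float = 0.01
    max_sequence_attempts: int = 9
    max_recall_iters: int = 50
    max_sequence_len: int = 40
    max_trial_steps: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.d_stim < self.n_context:
            raise ValueError(
                f"d_stim must lie strictly between 0 and n_context, got {self.d_stim}"
            )

    @property
    def d_cont(self) -> int:
        """Size of the context domain."""
        return self.n_context - self.d_stim

    @property
    def eta(self) -> float:
        """Learning rate of the cross-module Hebbian updates, (N+1)/2."""
        return (self.n_context + 1) / 2

    @property
    def x1(self) -> float:
        """Activity offset of the cross-module updates, N/(N+1)."""
        return self.n_context / (self.n_context + 1)

    def replace(self, **changes: Any) -> "AgentConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "AgentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(mapping))


def apply_condition(config: AgentConfig, condition: str) -> AgentConfig:
    """Return a copy of ``config`` with the stimulus-domain size of the
    named condition (``control``, ``sz`` or ``asd``)."""
    key = condition.lower()
    if key not in CONDITION_STIM_SIZES:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {sorted(CONDITION_STIM_SIZES)}"
        )
    return config.replace(d_stim=CONDITION_STIM_SIZES[key])
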