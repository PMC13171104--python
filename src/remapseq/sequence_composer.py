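"""Binary recurrent planning network ("sequence composer").

A pool of 300 binary neurons is recruited on demand into two roles:
*state-coding* neurons, each tied to one contextual state, and
*transition-coding* neurons, each representing one learned transition
out of a state-coding neuron.  Planning sequences alternate
state/transition neurons; the next neuron is sampled with probability
proportional to the recurrent weight above the baseline ``w0``.

Cross-module weights couple the planning network to the context
selector: ``w_hx`` feeds a contextual state into its state-coding
neuron, ``w_xh`` reads out the context a neuron encodes (state-coding
neurons encode their own context, transition-coding neurons the context
they predict to follow).  The one-shot Hebbian updates use learning
rate (N+1)/2 and offset N/(N+1), which make the readout of a single
linked context exact: active bits carry +1/2, inactive bits -N/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .context_selector import ContextState
from .valuation import ValueTable

__all__ = [
    "ROLE_UNASSIGNED",
    "ROLE_STATE",
    "ROLE_TRANSITION",
    "HippocampalNetwork",
    "Sequence",
    "RecruitmentOverflow",
]

ROLE_UNASSIGNED = 0
ROLE_STATE = 1
ROLE_TRANSITION = 2


class RecruitmentOverflow(RuntimeError):
    """Raised when no unassigned neuron is left to recruit."""

    def __init__(self, role: str, n_state: int, n_transition: int) -> None:
        super().__init__(
            f"neuron pool exhausted while recruiting a {role} neuron "
            f"({n_state} state-coding, {n_transition} transition-coding assigned)"
        )
        self.role = role


@dataclass(frozen=True)
class Sequence:
    """One generated planning sequence.

    ``neurons`` alternates state- and transition-coding indices and
    starts with a state-coding neuron.  ``tau`` counts the
    transition-coding neurons, i.e. the number of actions the plan
    specifies ahead.  ``complete`` is False when the seed had no
    outgoing transition at all.
    """

    neurons: tuple[int, ...]
    tau: int
    complete: bool = True
    truncated: bool = False

    @property
    def last(self) -> int:
        return self.neurons[-1]

    @property
    def last_transition(self) -> int | None:
        """Last transition-coding neuron; its reward value defines the
        sequence value of the whole plan."""
        ts = self.transitions
        return ts[-1] if ts else None

    @property
    def transitions(self) -> tuple[int, ...]:
        return self.neurons[1::2]

    @property
    def states(self) -> tuple[int, ...]:
        return self.neurons[0::2]


class HippocampalNetwork:
    def __init__(
        self,
        n_h: int = 300,
        n_x: int = 1200,
        *,
        w0: float = 0.3,
        alpha: float = 0.15,
        eligibility_margin: float = 0.01,
        max_sequence_len: int = 40,
    ) -> None:
        self.n_h = int(n_h)
        self.n_x = int(n_x)
        self.w0 = float(w0)
        self.alpha = float(alpha)
        self.margin = float(eligibility_margin)
        self.max_sequence_len = int(max_sequence_len)
        self.eta = (self.n_x + 1) / 2
        self.x1 = self.n_x / (self.n_x + 1)
        self.w_hh = np.full((self.n_h, self.n_h), self.w0)
        self.w_hx = np.zeros((self.n_h, self.n_x))
        self.w_xh = np.zeros((self.n_x, self.n_h))
        self.roles = np.full(self.n_h, ROLE_UNASSIGNED, dtype=np.int8)
        #: state-coding neuron -> key of the context it was recruited for
        self.context_of: dict[int, bytes] = {}
        #: transition neurons whose context readout has been linked
        self.linked_transitions: set[int] = set()

    # -- bookkeeping ----------------------------------------------------

    @property
    def n_state(self) -> int:
        return int(np.count_nonzero(self.roles == ROLE_STATE))

    @property
    def n_transition(self) -> int:
        return int(np.count_nonzero(self.roles == ROLE_TRANSITION))

    def unassigned(self) -> np.ndarray:
        return np.flatnonzero(self.roles == ROLE_UNASSIGNED)

    def outgoing(self, idx: int, role: int) -> np.ndarray:
        """Indices of ``role`` neurons reachable from ``idx`` through an
        eligible recurrent weight."""
        rel = self.w_hh[:, idx] - self.w0
        return np.flatnonzero((rel > self.margin) & (self.roles == role))

    # -- recruitment and cross-module plasticity ------------------------

    def _cross_update(self, idx: int, x: ContextState) -> None:
        delta = self.eta * (x.bits.astype(float) - self.x1)
        self.w_hx[idx, :] = np.minimum(self.w_hx[idx, :] + delta, 0.5)
        self.w_xh[:, idx] = np.minimum(self.w_xh[:, idx] + delta, 0.5)

    def select_seed(self, x: ContextState) -> int | None:
        """State-coding neuron receiving the strongest drive from ``x``,
        or None when no state neuron is driven (novel context)."""
        state_idx = np.flatnonzero(self.roles == ROLE_STATE)
        if state_idx.size == 0:
            return None
        drive = self.w_hx[state_idx, :] @ x.bits.astype(float)
        best = int(np.argmax(drive))
        if drive[best] <= 0:
            return None
        return int(state_idx[best])

    def recruit_state_neuron(self, x: ContextState) -> int:
        """Assign the lowest-index free neuron to encode context ``x``."""
        if x.key in self.context_of.values():
            raise ValueError("context already has a state-coding neuron")
        free = self.unassigned()
        if free.size == 0:
            raise RecruitmentOverflow("state-coding", self.n_state, self.n_transition)
        idx = int(free[0])
        self.roles[idx] = ROLE_STATE
        self.context_of[idx] = x.key
        self._cross_update(idx, x)
        return idx

    def imprint_context(self, idx: int, x: ContextState) -> None:
        """Re-apply the cross-module update of an existing state neuron
        for an additional context (pool-exhaustion reuse; the readout
        becomes the overlap of the linked contexts)."""
        if self.roles[idx] != ROLE_STATE:
            raise ValueError("can only imprint state-coding neurons")
        self._cross_update(idx, x)

    def recruit_transition_neuron(self, state_idx: int, rng: np.random.Generator) -> int:
        """Attach a fresh, randomly chosen transition neuron to
        ``state_idx`` with full weight."""
        if self.roles[state_idx] != ROLE_STATE:
            raise ValueError("transition neurons attach to state-coding neurons")
        free = self.unassigned()
        if free.size == 0:
            raise RecruitmentOverflow(
                "transition-coding", self.n_state, self.n_transition
            )
        idx = int(rng.choice(free))
        self.roles[idx] = ROLE_TRANSITION
        self.w_hh[idx, state_idx] = 1.0
        return idx

    def link_transition(self, t_idx: int, x: ContextState) -> None:
        """Make transition neuron ``t_idx`` predict context ``x``
        (one-shot update of its context-selector readout)."""
        if self.roles[t_idx] != ROLE_TRANSITION:
            raise ValueError("only transition-coding neurons are linked")
        delta = self.eta * (x.bits.astype(float) - self.x1)
        self.w_xh[:, t_idx] = np.minimum(self.w_xh[:, t_idx] + delta, 0.5)
        self.linked_transitions.add(t_idx)

    # -- readouts --------------------------------------------------------

    def context_feedback(self, idx: int) -> np.ndarray:
        """binary(w_xh . onehot(idx) > 0): the context a neuron's
        feedback to the context selector expresses."""
        return (self.w_xh[:, idx] > 0).astype(np.uint8)

    def predict_next_stimulus(self, t_idx: int, d_stim: int) -> np.ndarray:
        """Stimulus-domain slice of a transition neuron's feedback;
        all-zero when the neuron has never been linked."""
        return self.context_feedback(t_idx)[:d_stim]

    # -- sequence generation ---------------------------------------------

    def generate_sequence(
        self,
        seed_idx: int,
        values: ValueTable,
        rng: np.random.Generator,
    ) -> Sequence:
        """Sample one planning sequence from ``seed_idx``.

        From a state neuron the walk moves to an eligible transition
        neuron; from a transition neuron it stops if the neuron's reward
        value is positive or no eligible successor remains, otherwise it
        moves to a state neuron.  Probabilities are proportional to the
        relative weight (w - w0)/(1 - w0).
        """
        if self.roles[seed_idx] != ROLE_STATE:
            raise ValueError("sequences are seeded at state-coding neurons")
        neurons = [int(seed_idx)]
        cur = int(seed_idx)
        want = ROLE_TRANSITION
        truncated = False
        while True:
            if len(neurons) >= self.max_sequence_len:
                truncated = True
                break
            candidates = self.outgoing(cur, want)
            if candidates.size == 0:
                break
            rel = (self.w_hh[candidates, cur] - self.w0) / (1 - self.w0)
            nxt = int(rng.choice(candidates, p=rel / rel.sum()))
            neurons.append(nxt)
            cur = nxt
            if want == ROLE_TRANSITION:
                if values.v[cur] > 0:
                    break  # the plan ends at a transition predicting reward
                want = ROLE_STATE
            else:
                want = ROLE_TRANSITION
        tau = sum(1 for n in neurons if self.roles[n] == ROLE_TRANSITION)
        return Sequence(
            neurons=tuple(neurons),
            tau=tau,
            complete=tau > 0,
            truncated=truncated,
        )

    # -- recurrent plasticity ---------------------------------------------

    def update_within_episode(self, s_idx: int, t_idx: int) -> None:
        """Reward-independent potentiation of the state->transition link,
        with one-time heterosynaptic depression of the other inputs to
        ``t_idx`` upon initial establishment."""
        fresh = self.w_hh[t_idx, s_idx] <= self.w0
        self.w_hh[t_idx, s_idx] = min(self.w_hh[t_idx, s_idx] + (1 - self.w0), 1.0)
        if fresh:
            others = np.arange(self.n_h) != s_idx
            self.w_hh[t_idx, others] = np.maximum(
                self.w_hh[t_idx, others] - 0.5 * self.alpha, 0.0
            )

    def update_between_episode(self, t_idx: int, s_idx: int, reward: float) -> None:
        """Reward-gated potentiation of the transition->state link toward
        ``reward - w0``; requires a positive reward."""
        if reward <= 0:
            raise ValueError("between-episode updates require a positive reward")
        fresh = self.w_hh[s_idx, t_idx] <= self.w0
        w = self.w_hh[s_idx, t_idx]
        self.w_hh[s_idx, t_idx] = float(np.clip(w + self.alpha * (reward - w - self.w0), 0.0, 1.0))
        if fresh:
            others = np.arange(self.n_h) != t_idx
            self.w_hh[s_idx, others] = np.maximum(
                self.w_hh[s_idx, others] - 0.5 * self.alpha, 0.0
            )

    def apply_spe_weight_changes(
        self, t_idx: int, interrupted_s: int | None, switched_s: int | None
    ) -> None:
        """Weight changes accompanying a sensory prediction error: the
        interrupted transition->state link decays multiplicatively; the
        link onto the switched-to (or newly created) state neuron is
        pulled toward the switch target 0.65."""
        if interrupted_s is not None:
            self.w_hh[interrupted_s, t_idx] *= 1 - self.alpha
        if switched_s is not None:
            w = self.w_hh[switched_s, t_idx]
            if w < 0.65:
                self.w_hh[switched_s, t_idx] = w + self.alpha * (0.65 - w)

    # -- lesioning ---------------------------------------------------------

    def apply_inhibition(
        self, d_stim: int, fraction: float, rng: np.random.Generator
    ) -> np.ndarray:
        """Silence the input from a random fraction of context-domain
        units to the planning network (zero the corresponding ``w_hx``
        columns).  Returns the zeroed columns so the lesion can be
        undone; use :meth:`restore_inhibition`."""
        d_cont = self.n_x - d_stim
        n_off = int(round(fraction * d_cont))
        cols = d_stim + rng.choice(d_cont, size=n_off, replace=False)
        self._inhibited = (cols, self.w_hx[:, cols].copy())
        self.w_hx[:, cols] = 0.0
        return cols

    def restore_inhibition(self) -> None:
        cols, saved = self._inhibited
        self.w_hx[:, cols] = saved
        del self._inhibited
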