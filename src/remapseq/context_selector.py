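"""Binary attractor memory for contextual states.

The context selector is an Amari–Hopfield network of ``N`` binary units.
Each activity vector ``X`` splits into a *stimulus domain* (a copy of the
current external stimulus) and a *context domain* (the agent's subjective
context for that stimulus).  Several contextual states may share one
stimulus; they are stored as attractors by one-shot Hebbian learning and
retrieved by iterating the threshold dynamics

    X <- 1[ W_XX (X - X0) - theta > 0 ]

A recall succeeds when the iteration reaches a fixed point whose stimulus
domain reproduces the presented stimulus exactly.  A fixed point with a
different stimulus domain is a hallucination-like recall; failure to
converge falls back to the stimulus's default context.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ContextState",
    "Converter",
    "ContextEntry",
    "ContextMemory",
    "RecallOutcome",
    "RecallResult",
    "ContextStateError",
    "make_default_context",
    "init_history",
    "init_landmark",
    "random_half_ones",
]


class ContextStateError(RuntimeError):
    """Raised when a registry operation violates its precondition
    (double store, forgetting a default or unknown context, ...)."""


def _as_bits(vec: np.ndarray) -> np.ndarray:
    arr = np.asarray(vec)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D binary vector")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("expected entries in {0, 1}")
    return arr.astype(np.uint8)


@dataclass(frozen=True)
class ContextState:
    """One activity vector of the context selector.

    ``bits`` is the full binary vector of length ``N``; ``d_stim`` marks
    where the stimulus domain ends and the context domain begins.
    """

    bits: np.ndarray
    d_stim: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", _as_bits(self.bits))
        if not 0 < self.d_stim < self.bits.size:
            raise ValueError("d_stim out of range")
        self.bits.setflags(write=False)

    @property
    def stim_view(self) -> np.ndarray:
        return self.bits[: self.d_stim]

    @property
    def cont_view(self) -> np.ndarray:
        return self.bits[self.d_stim :]

    @property
    def key(self) -> bytes:
        return self.bits.tobytes()

    @property
    def stim_key(self) -> bytes:
        return self.stim_view.tobytes()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ContextState):
            return NotImplemented
        return self.d_stim == other.d_stim and np.array_equal(self.bits, other.bits)

    def __hash__(self) -> int:
        return hash((self.key, self.d_stim))


class Converter:
    """Fixed random map from a stimulus to its default context domain.

    A Gaussian matrix ``A`` projects the stimulus; the half of the context
    domain receiving the largest projections is set active, so every
    default context has exactly ``d_cont // 2`` ones.  Ranking (rather
    than a global scalar threshold) realises the per-stimulus threshold
    deterministically, ties included.
    """

    def __init__(self, d_stim: int, d_cont: int, rng: np.random.Generator) -> None:
        self.d_stim = int(d_stim)
        self.d_cont = int(d_cont)
        self.matrix = rng.standard_normal((self.d_cont, self.d_stim))

    def __call__(self, stimulus: np.ndarray) -> np.ndarray:
        stim = _as_bits(stimulus)
        if stim.size != self.d_stim:
            raise ValueError(
                f"stimulus length {stim.size} does not match converter input {self.d_stim}"
            )
        # centering removes the stimulus-independent offset A.1/2, which
        # would otherwise dominate the ranking and correlate the default
        # contexts of different stimuli (ruining attractor separation)
        proj = self.matrix @ (stim.astype(float) - 0.5)
        top = np.argsort(-proj, kind="stable")[: self.d_cont // 2]
        out = np.zeros(self.d_cont, dtype=np.uint8)
        out[top] = 1
        return out


def make_default_context(stimulus: np.ndarray, conv: Converter) -> ContextState:
    """Default context of a stimulus: the stimulus itself plus the
    converter's deterministic half-active context pattern."""
    stim = _as_bits(stimulus)
    return ContextState(np.concatenate([stim, conv(stim)]), d_stim=conv.d_stim)


def random_half_ones(size: int, rng: np.random.Generator) -> np.ndarray:
    """Uniformly random binary vector with exactly ``size // 2`` ones."""
    out = np.zeros(size, dtype=np.uint8)
    out[rng.choice(size, size=size // 2, replace=False)] = 1
    return out


def init_history(w_xh: np.ndarray, h: np.ndarray, d_stim: int) -> ContextState:
    """History-based initial state: threshold the hippocampal feedback."""
    bits = (np.asarray(w_xh) @ np.asarray(h, dtype=float) > 0).astype(np.uint8)
    return ContextState(bits, d_stim=d_stim)


def init_landmark(
    stimulus: np.ndarray, d_cont: int, rng: np.random.Generator
) -> ContextState:
    """Landmark-based initial state: the stimulus plus a random
    half-active context domain."""
    stim = _as_bits(stimulus)
    return ContextState(
        np.concatenate([stim, random_half_ones(d_cont, rng)]), d_stim=stim.size
    )


class RecallOutcome(enum.Enum):
    SUCCESS = "success"
    HALLUCINATION = "hallucination"
    DEFAULT_FALLBACK = "default_fallback"


@dataclass(frozen=True)
class RecallResult:
    outcome: RecallOutcome
    final_state: ContextState
    iterations: int


@dataclass
class ContextEntry:
    """Registry record of one stored contextual state."""

    state: ContextState
    is_default: bool
    creation_index: int
    best_sequence_value: float = 0.0


class ContextMemory:
    """Hopfield weight matrix plus a per-stimulus registry of stored
    contextual states.

    The registry drives two behaviours beyond plain pattern storage:
    the default context of each stimulus acts as the fallback when a
    recall fails to converge, and a capacity rule forgets the oldest
    reward-unrelated context once a stimulus accumulates more than
    ``capacity`` stored states.
    """

    def __init__(
        self,
        n: int,
        d_stim: int,
        *,
        theta: float = 0.5,
        x0: float = 0.5,
        capacity: int = 8,
        sv_protect: float = 0.7,
    ) -> None:
        self.n = int(n)
        self.d_stim = int(d_stim)
        self.theta = float(theta)
        self.x0 = float(x0)
        self.capacity = int(capacity)
        self.sv_protect = float(sv_protect)
        self.w_xx = np.zeros((self.n, self.n))
        self.registry: dict[bytes, list[ContextEntry]] = {}
        self._by_key: dict[bytes, ContextEntry] = {}
        self._creation_counter = 0
        #: number of capacity checks where every stored context was
        #: protected and the registry was allowed to overflow
        self.overflow_events = 0

    # -- registry access ------------------------------------------------

    def entries_for(self, stimulus: np.ndarray) -> list[ContextEntry]:
        return self.registry.get(_as_bits(stimulus).tobytes(), [])

    def default_for(self, stimulus: np.ndarray) -> ContextEntry | None:
        for entry in self.entries_for(stimulus):
            if entry.is_default:
                return entry
        return None

    def lookup(self, state: ContextState) -> ContextEntry | None:
        return self._by_key.get(state.key)

    def is_registered(self, state: ContextState) -> bool:
        return state.key in self._by_key

    def count_for(self, stimulus: np.ndarray) -> int:
        return len(self.entries_for(stimulus))

    def max_load(self) -> int:
        """Largest number of stored contexts any stimulus currently has."""
        return max((len(v) for v in self.registry.values()), default=0)

    def note_sequence_value(self, state: ContextState, sv: float) -> None:
        """Track the best sequence value a stored context has produced;
        contexts above the protection bound are exempt from forgetting."""
        entry = self._by_key.get(state.key)
        if entry is not None and sv > entry.best_sequence_value:
            entry.best_sequence_value = float(sv)

    # -- plasticity -----------------------------------------------------

    def store(self, state: ContextState, *, is_default: bool = False) -> ContextEntry:
        """One-shot Hebbian storage of a settled contextual state."""
        if state.bits.size != self.n:
            raise ValueError("context length does not match memory size")
        if state.key in self._by_key:
            raise ContextStateError("context already stored")
        centered = state.bits.astype(float) - self.x0
        self.w_xx += np.outer(centered, centered)
        entry = ContextEntry(
            state=state, is_default=is_default, creation_index=self._creation_counter
        )
        self._creation_counter += 1
        self.registry.setdefault(state.stim_key, []).append(entry)
        self._by_key[state.key] = entry
        return entry

    def forget(self, state: ContextState) -> None:
        """Exact inverse of :meth:`store`; defaults cannot be forgotten."""
        entry = self._by_key.get(state.key)
        if entry is None:
            raise ContextStateError("cannot forget a context that was never stored")
        if entry.is_default:
            raise ContextStateError("default contexts are permanent")
        centered = state.bits.astype(float) - self.x0
        self.w_xx -= np.outer(centered, centered)
        self.registry[state.stim_key].remove(entry)
        del self._by_key[state.key]

    def enforce_capacity(self, stimulus: np.ndarray) -> list[ContextState]:
        """Make room for one more context at ``stimulus``.

        When the stimulus already holds ``capacity`` or more contexts,
        every stored context that never produced a sequence value above
        the protection bound is forgotten (forgetting of reward-unrelated
        episodic memory).  If every candidate is protected the overflow
        is permitted and counted.
        """
        forgotten: list[ContextState] = []
        if self.count_for(stimulus) >= self.capacity:
            candidates = [
                e
                for e in self.entries_for(stimulus)
                if not e.is_default and e.best_sequence_value <= self.sv_protect
            ]
            if not candidates:
                self.overflow_events += 1
            for victim in sorted(candidates, key=lambda e: e.creation_index):
                self.forget(victim.state)
                forgotten.append(victim.state)
        return forgotten

    # -- recall ---------------------------------------------------------

    def recall(
        self,
        x_init: ContextState,
        stimulus: np.ndarray,
        max_iter: int = 50,
    ) -> RecallResult:
        """Iterate the attractor dynamics from ``x_init``.

        Convergence means two consecutive identical states (a period-2
        oscillation therefore counts as failure).  Non-convergence falls
        back to the stimulus's default context, which must exist.
        """
        stim = _as_bits(stimulus)
        x = x_init.bits.astype(float)
        iterations = 0
        for _ in range(max_iter):
            nxt = (self.w_xx @ (x - self.x0) - self.theta > 0).astype(float)
            iterations += 1
            if np.array_equal(nxt, x):
                state = ContextState(nxt.astype(np.uint8), d_stim=self.d_stim)
                if np.array_equal(state.stim_view, stim):
                    return RecallResult(RecallOutcome.SUCCESS, state, iterations)
                return RecallResult(RecallOutcome.HALLUCINATION, state, iterations)
            x = nxt
        default = self.default_for(stim)
        if default is None:
            raise ContextStateError(
                "recall failed and no default context exists for this stimulus"
            )
        return RecallResult(RecallOutcome.DEFAULT_FALLBACK, default.state, iterations)

    # -- checkpointing ----------------------------------------------------

    def manifest(self) -> dict:
        """JSON-style summary of the registry (not the weight matrix)."""
        out: dict[str, list[dict]] = {}
        for stim_key, entries in self.registry.items():
            label = stim_key.hex()[:16]
            out[label] = [
                {
                    "creation_index": e.creation_index,
                    "is_default": e.is_default,
                    "best_sequence_value": e.best_sequence_value,
                }
                for e in entries
            ]
        return out


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    """Hamming distance between two binary vectors."""
    return int(np.count_nonzero(_as_bits(a) != _as_bits(b)))
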