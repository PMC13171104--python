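"""Discrete task environments (POMDPs) and stimulus codebooks.

Each task is a small graph of environmental states.  The agent observes
only the binary stimulus of its current state; reward contingencies
depend on a hidden variable (trial phase, lap count, or reward-driven
toggle) that the agent must resolve through context.  A trial runs from
the task's start state to a reward-delivery state; tasks whose reward
states have no outgoing action expose a single forced ``a_reset``
transition back to the start, so the agent experiences trials as one
continuous stream and can learn to plan across trial boundaries.

Stimuli are random half-active binary codes drawn once per environment,
with a minimum pairwise Hamming distance so that distinct states are
never confused by the remapping tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence as Seq

import numpy as np

from .config import apply_condition  # noqa: F401  (re-export)
from .context_selector import random_half_ones

__all__ = [
    "Codebook",
    "make_codebook",
    "StepResult",
    "TaskPOMDP",
    "make_alternation_task",
    "make_two_lap_task",
    "make_cueing_task",
    "make_contextual_inference_task",
    "apply_condition",
    "apply_inhibition",
    "RESET_ACTION",
]

RESET_ACTION = "a_reset"


@dataclass(frozen=True)
class Codebook:
    """Map from environmental state to its binary stimulus."""

    patterns: dict[str, np.ndarray]
    d_stim: int
    min_distance: int

    def __getitem__(self, state: str) -> np.ndarray:
        return self.patterns[state]

    def state_of(self, stimulus: np.ndarray) -> str | None:
        for name, bits in self.patterns.items():
            if np.array_equal(bits, stimulus):
                return name
        return None


def default_min_distance(d_stim: int, theta_remap: int = 5) -> int:
    """Codebook separation: four times the remapping tolerance, scaled
    down to a quarter of the stimulus dimension when that is smaller."""
    return min(4 * theta_remap, math.ceil(d_stim / 4))


def make_codebook(
    states: Seq[str],
    d_stim: int,
    rng: np.random.Generator,
    min_distance: int | None = None,
    max_tries: int = 2000,
) -> Codebook:
    if min_distance is None:
        min_distance = default_min_distance(d_stim)
    patterns: dict[str, np.ndarray] = {}
    chosen: list[np.ndarray] = []
    for name in states:
        for _ in range(max_tries):
            cand = random_half_ones(d_stim, rng)
            if all(int(np.sum(cand != p)) >= min_distance for p in chosen):
                break
        else:
            raise ValueError(
                f"could not draw {len(states)} patterns of length {d_stim} "
                f"with pairwise distance >= {min_distance}"
            )
        patterns[name] = cand
        chosen.append(cand)
    return Codebook(patterns=patterns, d_stim=d_stim, min_distance=min_distance)


@dataclass(frozen=True)
class StepResult:
    state: str
    stimulus: np.ndarray
    reward: float | None  # None outside reward-delivery states
    trial_ended: bool
    trial_index: int  # index of the trial now in progress
    hidden: int


class TaskPOMDP:
    """Base class: deterministic/stochastic transition table plus
    task-specific hidden-state and reward hooks."""

    name: str = "task"

    def __init__(
        self,
        states: Seq[str],
        transitions: dict[tuple[str, str], list[tuple[str, float]]],
        reward_sites: set[str],
        landmarks: set[str],
        codebook: Codebook,
    ) -> None:
        self.states = list(states)
        self.transitions = transitions
        self.reward_sites = set(reward_sites)
        self.landmarks = set(landmarks)
        self.codebook = codebook
        self._actions_of: dict[str, list[str]] = {s: [] for s in self.states}
        for (s, a), succ in transitions.items():
            self._actions_of[s].append(a)
            if abs(sum(p for _, p in succ) - 1.0) > 1e-9:
                raise ValueError(
                    f"transition probabilities for ({s}, {a}) do not sum to 1"
                )
        self.trial_index = 0
        self.current_state: str | None = None

    # -- hooks overridden per task ---------------------------------------

    def start_state(self) -> str:
        raise NotImplementedError

    def hidden_state(self) -> int:
        raise NotImplementedError

    def compute_reward(self, state: str, action: str) -> float:
        raise NotImplementedError

    def on_arrival(self, state: str) -> None:
        pass

    def on_trial_end(self, reward: float, rng: np.random.Generator) -> None:
        pass

    # -- uniform interface -------------------------------------------------

    def reset(self, rng: np.random.Generator) -> StepResult:
        self.trial_index = 1
        self._begin_run(rng)
        self.current_state = self.start_state()
        self.on_arrival(self.current_state)
        return StepResult(
            state=self.current_state,
            stimulus=self.codebook[self.current_state],
            reward=None,
            trial_ended=False,
            trial_index=self.trial_index,
            hidden=self.hidden_state(),
        )

    def _begin_run(self, rng: np.random.Generator) -> None:
        pass

    def stimulus_of(self, state: str) -> np.ndarray:
        return self.codebook[state]

    def is_landmark(self, state: str) -> bool:
        return state in self.landmarks

    def available_actions(self, state: str | None = None) -> list[str]:
        s = self.current_state if state is None else state
        acts = self._actions_of[s]
        if not acts:
            return [RESET_ACTION]
        return list(acts)

    def successor_states(
        self, action: str, state: str | None = None
    ) -> list[tuple[str, float]]:
        s = self.current_state if state is None else state
        if action == RESET_ACTION:
            return [(self.start_state(), 1.0)]
        return self.transitions[(s, action)]

    def step(self, action: str, rng: np.random.Generator) -> StepResult:
        succ = self.successor_states(action)
        states = [s for s, _ in succ]
        probs = np.array([p for _, p in succ])
        nxt = states[int(rng.choice(len(states), p=probs / probs.sum()))]
        self.current_state = nxt
        self.on_arrival(nxt)
        reward: float | None = None
        ended = False
        if nxt in self.reward_sites:
            reward = float(self.compute_reward(nxt, action))
            ended = True
            self.on_trial_end(reward, rng)
            self.trial_index += 1
        return StepResult(
            state=nxt,
            stimulus=self.codebook[nxt],
            reward=reward,
            trial_ended=ended,
            trial_index=self.trial_index,
            hidden=self.hidden_state(),
        )


# ---------------------------------------------------------------------------
# Alternation task: five states, reward alternates between S4 and S5.


class AlternationTask(TaskPOMDP):
    name = "alternation"

    def __init__(self, codebook: Codebook) -> None:
        transitions = {
            ("S1", "a12"): [("S2", 1.0)],
            ("S2", "a24"): [("S4", 1.0)],
            ("S2", "a25"): [("S5", 1.0)],
            ("S3", "a32"): [("S2", 1.0)],
            ("S4", "a43"): [("S3", 1.0)],
            ("S5", "a51"): [("S1", 1.0)],
        }
        super().__init__(
            states=["S1", "S2", "S3", "S4", "S5"],
            transitions=transitions,
            reward_sites={"S4", "S5"},
            landmarks={"S1"},
            codebook=codebook,
        )
        self._c = 1

    def _begin_run(self, rng: np.random.Generator) -> None:
        self._c = 1

    def start_state(self) -> str:
        return "S1"

    def hidden_state(self) -> int:
        return self._c

    def compute_reward(self, state: str, action: str) -> float:
        if state == "S4" and self._c == 1:
            return 1.0
        if state == "S5" and self._c == 2:
            return 1.0
        return 0.0

    def on_trial_end(self, reward: float, rng: np.random.Generator) -> None:
        if reward > 0:
            self._c = 2 if self._c == 1 else 1


def make_alternation_task(
    d_stim: int = 200,
    rng: np.random.Generator | None = None,
    min_distance: int | None = None,
) -> AlternationTask:
    rng = np.random.default_rng(0) if rng is None else rng
    cb = make_codebook(["S1", "S2", "S3", "S4", "S5"], d_stim, rng, min_distance)
    return AlternationTask(cb)


# ---------------------------------------------------------------------------
# 2-lap task: a loop whose rewarded lap count grows across phases.


class TwoLapTask(TaskPOMDP):
    name = "two_lap"

    def __init__(
        self,
        codebook: Codebook,
        variant: str = "three-phase",
        phases: tuple[int, int] = (20, 40),
    ) -> None:
        if variant not in ("three-phase", "alternating"):
            raise ValueError("variant must be 'three-phase' or 'alternating'")
        self.phases = tuple(phases)
        transitions = {
            ("S1", "a12"): [("S2", 1.0)],
            ("S2", "a23"): [("S3", 1.0)],
            ("S2", "a24"): [("S4", 1.0)],
            ("S3", "a32"): [("S2", 1.0)],
        }
        super().__init__(
            states=["S1", "S2", "S3", "S4"],
            transitions=transitions,
            reward_sites={"S4"},
            landmarks={"S1"},
            codebook=codebook,
        )
        self.variant = variant
        self._laps = 0

    def _begin_run(self, rng: np.random.Generator) -> None:
        self._laps = 0

    def start_state(self) -> str:
        return "S1"

    def hidden_state(self) -> int:
        t = self.trial_index
        if self.variant == "three-phase":
            if t <= self.phases[0]:
                return 1
            if t <= self.phases[1]:
                return 2
            return 3
        return 2 if (t % 60) <= 30 else 3

    def on_arrival(self, state: str) -> None:
        if state == "S3":
            self._laps += 1

    def on_trial_end(self, reward: float, rng: np.random.Generator) -> None:
        self._laps = 0

    def compute_reward(self, state: str, action: str) -> float:
        if state != "S4":
            return 0.0
        c, laps = self.hidden_state(), self._laps
        if self.variant == "three-phase" and laps == 0 and c == 1:
            return 1.0
        if laps == 1 and c == 2:
            return 1.0
        if laps >= 2 and c == 3:
            return 1.0
        return 0.0


def make_two_lap_task(
    variant: str = "three-phase",
    d_stim: int = 200,
    rng: np.random.Generator | None = None,
    min_distance: int | None = None,
    phases: tuple[int, int] = (20, 40),
) -> TwoLapTask:
    rng = np.random.default_rng(0) if rng is None else rng
    cb = make_codebook(["S1", "S2", "S3", "S4"], d_stim, rng, min_distance)
    return TwoLapTask(cb, variant=variant, phases=phases)


# ---------------------------------------------------------------------------
# Simplified probabilistic cueing task with periodic reward reversal.


class CueingTask(TaskPOMDP):
    name = "cueing"

    def __init__(
        self, codebook: Codebook, p: float = 0.8, schedule: str = "blocks30"
    ) -> None:
        if not 0.0 <= p <= 1.0:
            raise ValueError("p must be a probability")
        if schedule not in ("blocks30", "mod40"):
            raise ValueError("schedule must be 'blocks30' or 'mod40'")
        self.p = float(p)
        self.schedule = schedule
        transitions = {
            ("S0", "a0"): self._branch("S2", "S3", p),
            ("S1", "a1"): self._branch("S2", "S3", 1.0 - p),
            ("S2", "a24"): [("S4", 1.0)],
            ("S2", "a25"): [("S5", 1.0)],
            ("S3", "a34"): [("S4", 1.0)],
            ("S3", "a35"): [("S5", 1.0)],
        }
        super().__init__(
            states=["S0", "S1", "S2", "S3", "S4", "S5"],
            transitions=transitions,
            reward_sites={"S4", "S5"},
            landmarks={"S0", "S1"},
            codebook=codebook,
        )

    @staticmethod
    def _branch(a: str, b: str, p: float) -> list[tuple[str, float]]:
        if p >= 1.0:
            return [(a, 1.0)]
        if p <= 0.0:
            return [(b, 1.0)]
        return [(a, p), (b, 1.0 - p)]

    def start_state(self) -> str:
        return "S0" if self.hidden_state() == 1 else "S1"

    def hidden_state(self) -> int:
        t = self.trial_index
        if self.schedule == "blocks30":
            return 1 if ((t - 1) // 30) % 2 == 0 else 2
        return 1 if (t % 40) <= 20 else 2

    def compute_reward(self, state: str, action: str) -> float:
        c = self.hidden_state()
        rewarded = {
            1: {("S4", "a24"), ("S5", "a35")},
            2: {("S4", "a34"), ("S5", "a25")},
        }[c]
        return 1.0 if (state, action) in rewarded else 0.0


def make_cueing_task(
    p: float = 0.8,
    schedule: str = "blocks30",
    d_stim: int = 200,
    rng: np.random.Generator | None = None,
    min_distance: int | None = None,
) -> CueingTask:
    rng = np.random.default_rng(0) if rng is None else rng
    cb = make_codebook(["S0", "S1", "S2", "S3", "S4", "S5"], d_stim, rng, min_distance)
    return CueingTask(cb, p=p, schedule=schedule)


# ---------------------------------------------------------------------------
# Contextual-inference task: arena cue (square / circle / morph) followed
# by an equal-probability branch; no reward feedback in the test phase.


def _squircle_pattern(
    sq: np.ndarray, ci: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Bitwise morph of the two arena stimuli: shared bits are kept,
    exactly half of the differing bits take the square's value.  The
    morph is therefore equidistant from both parents."""
    out = sq.copy()
    diff = np.flatnonzero(sq != ci)
    take_ci = rng.choice(diff, size=diff.size // 2, replace=False)
    out[take_ci] = ci[take_ci]
    return out


class ContextualInferenceTask(TaskPOMDP):
    name = "inference"

    def __init__(
        self, codebook: Codebook, n_train: int = 60, rng_seeded: bool = True
    ) -> None:
        transitions = {
            ("Sq", "aSq"): [("S2", 0.5), ("S3", 0.5)],
            ("Ci", "aCi"): [("S2", 0.5), ("S3", 0.5)],
            ("SC", "aSC"): [("S2", 0.5), ("S3", 0.5)],
            ("S2", "a24"): [("S4", 1.0)],
            ("S2", "a25"): [("S5", 1.0)],
            ("S3", "a34"): [("S4", 1.0)],
            ("S3", "a35"): [("S5", 1.0)],
        }
        super().__init__(
            states=["Sq", "Ci", "SC", "S2", "S3", "S4", "S5"],
            transitions=transitions,
            reward_sites={"S4", "S5"},
            landmarks={"Sq", "Ci", "SC"},
            codebook=codebook,
        )
        self.n_train = int(n_train)
        self._next_arena = "Sq"

    def _begin_run(self, rng: np.random.Generator) -> None:
        self._next_arena = str(rng.choice(["Sq", "Ci"]))

    @property
    def in_test_phase(self) -> bool:
        return self.trial_index > self.n_train

    def start_state(self) -> str:
        return self._next_arena

    def hidden_state(self) -> int:
        # the arena type plays the role of the hidden context
        return {"Sq": 1, "Ci": 2, "SC": 3}[self._next_arena]

    def compute_reward(self, state: str, action: str) -> float:
        if self.in_test_phase:
            return 0.0  # no reward feedback during testing
        arena = self._next_arena
        rewarded = {
            "Sq": {("S4", "a24"), ("S5", "a35")},
            "Ci": {("S4", "a34"), ("S5", "a25")},
        }[arena]
        return 1.0 if (state, action) in rewarded else 0.0

    def on_trial_end(self, reward: float, rng: np.random.Generator) -> None:
        if self.trial_index + 1 > self.n_train:
            self._next_arena = str(rng.choice(["Sq", "Ci", "SC"]))
        else:
            self._next_arena = str(rng.choice(["Sq", "Ci"]))


def make_contextual_inference_task(
    n_train: int = 60,
    d_stim: int = 200,
    rng: np.random.Generator | None = None,
    min_distance: int | None = None,
) -> ContextualInferenceTask:
    rng = np.random.default_rng(0) if rng is None else rng
    base = ["Sq", "Ci", "S2", "S3", "S4", "S5"]
    cb = make_codebook(base, d_stim, rng, min_distance)
    patterns = dict(cb.patterns)
    patterns["SC"] = _squircle_pattern(patterns["Sq"], patterns["Ci"], rng)
    cb = Codebook(patterns=patterns, d_stim=cb.d_stim, min_distance=cb.min_distance)
    return ContextualInferenceTask(cb, n_train=n_train)


# ---------------------------------------------------------------------------


def apply_inhibition(net, d_stim: int, fraction: float, rng: np.random.Generator):
    """Silence a random ``fraction`` of the context-domain input to the
    planning network (see
    :meth:`remapseq.sequence_composer.HippocampalNetwork.apply_inhibition`)."""
    return net.apply_inhibition(d_stim, fraction, rng)
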