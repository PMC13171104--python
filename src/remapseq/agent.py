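"""Agent controller: the per-step loop tying the modules together.

At every environmental state the agent carries a contextual state (an
attractor of the context selector) and its state-coding neuron.  A
planning sequence is drawn from that neuron and executed action by
action; each transition-coding neuron predicts the stimulus of the state
it should lead to.  Two error signals reorganise the context map:

* a *sensory* prediction error (observed stimulus differs from the
  planned one) weakens the interrupted link and either switches to an
  existing alternative context or creates a new one;
* a *reward* prediction error (the no-good indicator of a recently
  unrewarded plan) drives exploration: an untried transition is taken
  and the following state receives a fresh context.

After either remapping, the newly recruited neurons predict nothing, so
fresh contexts keep being created at the following states until the
agent reaches a landmark (the task's start state), where the context is
re-anchored by a landmark-based recall.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .config import AgentConfig
from .context_selector import (
    ContextMemory,
    ContextState,
    Converter,
    RecallOutcome,
    init_landmark,
    make_default_context,
    random_half_ones,
)
from .environments import TaskPOMDP
from .sequence_composer import (
    ROLE_STATE,
    ROLE_TRANSITION,
    HippocampalNetwork,
    RecruitmentOverflow,
    Sequence,
)
from .valuation import ValueTable

__all__ = ["Agent", "PlanState", "CohortResult", "run_experiment"]


@dataclass
class PlanState:
    """A selected sequence unrolled into executable steps."""

    steps: list[tuple[int, int | None]]  # (transition neuron, planned next state neuron)
    sv: float
    tau: int
    pos: int = 0
    started: bool = False

    @property
    def exhausted(self) -> bool:
        return self.pos >= len(self.steps)

    @classmethod
    def from_sequence(cls, seq: Sequence, sv: float) -> "PlanState":
        states = list(seq.states)
        steps: list[tuple[int, int | None]] = []
        for i, t in enumerate(seq.transitions):
            nxt = states[i + 1] if i + 1 < len(states) else None
            steps.append((int(t), int(nxt) if nxt is not None else None))
        return cls(steps=steps, sv=float(sv), tau=seq.tau)


class Agent:
    """One simulated agent bound to one task environment."""

    def __init__(
        self,
        config: AgentConfig,
        env: TaskPOMDP,
        rng: np.random.Generator,
        *,
        remapping_enabled: bool = True,
        log_steps: bool = True,
    ) -> None:
        self.cfg = config
        self.env = env
        self.rng = rng
        self.remapping_enabled = remapping_enabled
        self.log_steps = log_steps

        self.conv = Converter(config.d_stim, config.d_cont, rng)
        self.memory = ContextMemory(
            config.n_context,
            config.d_stim,
            theta=config.theta,
            x0=config.x0,
            capacity=config.capacity,
            sv_protect=config.sv_protect,
        )
        self.net = HippocampalNetwork(
            config.n_hippocampus,
            config.n_context,
            w0=config.w0,
            alpha=config.alpha,
            eligibility_margin=config.eligibility_margin,
            max_sequence_len=config.max_sequence_len,
        )
        self.values = ValueTable(
            config.n_hippocampus,
            alpha=config.alpha,
            theta_ng=config.theta_ng,
            gamma=config.gamma_ng,
        )

        # running state
        self.cur_context: ContextState | None = None
        self.cur_s: int | None = None
        self.last_t: int | None = None
        self.plan: PlanState | None = None
        self._context_tag = ""  # how the current context was selected
        self._window: list[int] = []  # neurons activated since last reward

        # audits and logs
        self.max_context_audit = 0
        self.overflow_steps = 0
        self.recruit_overflows = 0
        self.step_rows: list[dict] = []
        self.trial_rows: list[dict] = []
        self._trial_acc = self._fresh_trial_acc()

    # ------------------------------------------------------------------
    # bookkeeping helpers

    @staticmethod
    def _fresh_trial_acc() -> dict:
        return {
            "steps": 0,
            "max_tau": 0,
            "contexts_created": 0,
            "hallucinations": 0,
            "default_fallbacks": 0,
            "spe_events": 0,
            "explorations": 0,
            "plans_started": 0,
        }

    def _activate_state_neuron(self, s_idx: int, context: ContextState, tag: str) -> None:
        self.cur_s = int(s_idx)
        self.cur_context = context
        self._context_tag = tag
        self._window.append(int(s_idx))

    def _context_id(self) -> int:
        """Stable identifier of the current context: the registry's
        creation index, or a negative hash for unregistered read-outs."""
        if self.cur_context is None:
            return -1
        entry = self.memory.lookup(self.cur_context)
        if entry is not None:
            return entry.creation_index
        return -(hash(self.cur_context.key) % 1_000_000) - 2

    def _context_is_default(self) -> bool:
        if self.cur_context is None:
            return False
        entry = self.memory.lookup(self.cur_context)
        return entry is not None and entry.is_default

    def _context_from_neuron(self, s_idx: int) -> ContextState:
        bits = self.net.context_feedback(s_idx)
        state = ContextState(bits, d_stim=self.cfg.d_stim)
        entry = self.memory.lookup(state)
        return entry.state if entry is not None else state

    def _log_step(self, **row) -> None:
        if self.log_steps:
            self.step_rows.append(row)

    # ------------------------------------------------------------------
    # context creation / selection

    def _register_new_context(self, stimulus: np.ndarray) -> ContextState:
        """Store a brand-new contextual state for ``stimulus``: the
        default on a first visit, otherwise a random context domain."""
        default = self.memory.default_for(stimulus)
        if default is None:
            x = make_default_context(stimulus, self.conv)
            self.memory.store(x, is_default=True)
            self._audit_registry(stimulus, overflowed=False)
            return x
        for _ in range(8):  # essentially never collides
            bits = np.concatenate(
                [np.asarray(stimulus, dtype=np.uint8),
                 random_half_ones(self.cfg.d_cont, self.rng)]
            )
            x = ContextState(bits, d_stim=self.cfg.d_stim)
            if not self.memory.is_registered(x):
                break
        pre = self.memory.overflow_events
        self.memory.enforce_capacity(stimulus)
        overflowed = self.memory.overflow_events > pre
        self.memory.store(x)
        self._audit_registry(stimulus, overflowed)
        return x

    def _audit_registry(self, stimulus: np.ndarray, overflowed: bool) -> None:
        if overflowed:
            self.overflow_steps += 1
        else:
            self.max_context_audit = max(
                self.max_context_audit, self.memory.count_for(stimulus)
            )

    def _ensure_state_neuron(self, x: ContextState) -> int:
        """State-coding neuron for ``x``: the strongest-driven existing
        neuron, or a newly recruited one (with the one-shot cross-module
        updates).  On pool exhaustion the best-driven existing neuron is
        re-used and additionally imprinted with ``x`` (representational
        overlap, the degradation mode of the small-stimulus-domain
        condition)."""
        seed = self.net.select_seed(x)
        if seed is not None and self.net.context_of.get(seed) == x.key:
            return seed
        existing = next(
            (s for s, k in self.net.context_of.items() if k == x.key), None
        )
        if existing is not None:
            # already coded, but crosstalk kept it from winning the
            # input competition; re-use its neuron without re-learning
            return existing
        try:
            s_idx = self.net.recruit_state_neuron(x)
        except RecruitmentOverflow:
            self.recruit_overflows += 1
            state_idx = np.flatnonzero(self.net.roles == ROLE_STATE)
            drive = self.net.w_hx[state_idx, :] @ x.bits.astype(float)
            s_idx = int(state_idx[int(np.argmax(drive))])
            self.net.imprint_context(s_idx, x)
            self.net.context_of[s_idx] = x.key
        # one-shot link from the transition that led here, first link only
        if self.last_t is not None and self.last_t not in self.net.linked_transitions:
            self.net.link_transition(self.last_t, x)
        # a fresh context gets its first (still unbound) transition neuron
        try:
            self.net.recruit_transition_neuron(s_idx, self.rng)
        except RecruitmentOverflow:
            self.recruit_overflows += 1
        return s_idx

    def _adopt_new_context(
        self, stimulus: np.ndarray, tag: str, *, spe_from: int | None = None
    ) -> None:
        """Create (or, with remapping disabled, fall back to the default)
        context for the observed stimulus and make it current."""
        if not self.remapping_enabled and self.memory.default_for(stimulus) is not None:
            entry = self.memory.default_for(stimulus)
            seed = self.net.select_seed(entry.state)
            s_idx = seed if seed is not None else self._ensure_state_neuron(entry.state)
            self._activate_state_neuron(s_idx, entry.state, tag="default_ablation")
            return
        x = self._register_new_context(stimulus)
        s_idx = self._ensure_state_neuron(x)
        if spe_from is not None:
            # pull the interrupted transition toward the new state neuron
            self.net.apply_spe_weight_changes(spe_from, None, s_idx)
        self._trial_acc["contexts_created"] += 1
        self._activate_state_neuron(s_idx, x, tag=tag)

    def _select_context_on_arrival(self, stimulus: np.ndarray) -> None:
        """Normal context selection at a state entered outside an active
        plan: history-based recall, landmark-based recall, or new-context
        creation on history mismatch."""
        if self.memory.default_for(stimulus) is None:
            # first visit of this environmental state
            self._adopt_new_context(stimulus, tag="first_visit")
            return
        pred = (
            self.net.context_feedback(self.last_t)
            if self.last_t is not None
            else np.zeros(self.cfg.n_context, dtype=np.uint8)
        )
        if pred.any():
            init = ContextState(pred, d_stim=self.cfg.d_stim)
            self._recall_and_adopt(init, stimulus, tag="history")
        elif self.env.is_landmark(self.env.current_state):
            init = init_landmark(stimulus, self.cfg.d_cont, self.rng)
            self._recall_and_adopt(init, stimulus, tag="landmark")
        else:
            self._adopt_new_context(stimulus, tag="history_mismatch")

    def _recall_and_adopt(
        self, init: ContextState, stimulus: np.ndarray, tag: str
    ) -> None:
        res = self.memory.recall(init, stimulus, self.cfg.max_recall_iters)
        if res.outcome is RecallOutcome.SUCCESS:
            x = res.final_state
            if not self.memory.is_registered(x):
                # a settled state is stored the first time it appears
                pre = self.memory.overflow_events
                self.memory.enforce_capacity(stimulus)
                self.memory.store(x)
                self._audit_registry(stimulus, self.memory.overflow_events > pre)
            seed = self.net.select_seed(x)
            s_idx = seed if seed is not None else self._ensure_state_neuron(x)
            self._activate_state_neuron(s_idx, x, tag=tag)
        elif res.outcome is RecallOutcome.DEFAULT_FALLBACK:
            self._trial_acc["default_fallbacks"] += 1
            x = res.final_state
            seed = self.net.select_seed(x)
            s_idx = seed if seed is not None else self._ensure_state_neuron(x)
            self._activate_state_neuron(s_idx, x, tag="default_fallback")
        else:  # hallucination-like recall: the agent is in a "new" context
            self._trial_acc["hallucinations"] += 1
            if tag == "history" and self.env.is_landmark(self.env.current_state):
                # landmarks anchor the context; a corrupted history recall
                # is re-anchored by the landmark-based initialization
                # rather than spawning contexts episode after episode
                init = init_landmark(stimulus, self.cfg.d_cont, self.rng)
                self._recall_and_adopt(init, stimulus, tag="landmark")
                return
            self._spe_step2_or_3(self.last_t, None, stimulus, tag="hallucination")

    # ------------------------------------------------------------------
    # remapping

    def _spe_step2_or_3(
        self,
        t_idx: int | None,
        interrupted_s: int | None,
        stimulus: np.ndarray,
        tag: str,
    ) -> None:
        """Steps 2-3 of the sensory-prediction-error pathway: try to
        switch to an alternative context predicted by another state
        neuron downstream of ``t_idx``; otherwise create a new one."""
        self._trial_acc["spe_events"] += 1
        if self.remapping_enabled and t_idx is not None:
            for s_alt in self.net.outgoing(t_idx, ROLE_STATE):
                if interrupted_s is not None and s_alt == interrupted_s:
                    continue
                pred = self.net.context_feedback(s_alt)[: self.cfg.d_stim]
                err = int(np.count_nonzero(pred != stimulus))
                if err < self.cfg.theta_remap:
                    x = self._context_from_neuron(s_alt)
                    self._activate_state_neuron(s_alt, x, tag=tag + "_switch")
                    return
        self._adopt_new_context(stimulus, tag=tag + "_new", spe_from=t_idx)

    def _spe_remap(
        self,
        t_idx: int,
        interrupted_s: int | None,
        stimulus: np.ndarray,
    ) -> None:
        """Full pathway.  Mid-plan errors (a planned next state exists)
        apply the link weakening and the alternative search; an error on
        the plan's final transition only creates the new context."""
        if interrupted_s is not None:
            if self.remapping_enabled:
                self.net.apply_spe_weight_changes(t_idx, interrupted_s, None)
            self._spe_step2_or_3(t_idx, interrupted_s, stimulus, tag="spe")
        else:
            self._trial_acc["spe_events"] += 1
            self._adopt_new_context(
                stimulus, tag="spe_new", spe_from=t_idx if self.remapping_enabled else None
            )

    # ------------------------------------------------------------------
    # sequence selection

    def _select_plan(self) -> None:
        """Draw up to ``max_sequence_attempts`` candidate sequences and
        keep the first with positive sequence value; failing that, pick
        uniformly among the candidates after dropping the single worst.
        When the current context came from a landmark-based recall, each
        attempt re-draws that recall with fresh randomness."""
        assert self.cur_s is not None and self.cur_context is not None
        attempts: list[tuple[Sequence, float, int, ContextState, str]] = []
        x, s_idx, tag = self.cur_context, self.cur_s, self._context_tag
        stimulus = self.env.stimulus_of(self.env.current_state)
        for k in range(self.cfg.max_sequence_attempts):
            if k > 0 and tag == "landmark":
                init = init_landmark(stimulus, self.cfg.d_cont, self.rng)
                res = self.memory.recall(init, stimulus, self.cfg.max_recall_iters)
                if res.outcome is RecallOutcome.SUCCESS and self.memory.is_registered(
                    res.final_state
                ):
                    x = res.final_state
                    seed = self.net.select_seed(x)
                    if seed is not None:
                        s_idx = seed
            seq = self.net.generate_sequence(s_idx, self.values, self.rng)
            last_t = seq.last_transition
            sv = self.values.sequence_value(last_t) if last_t is not None else 0.0
            self.memory.note_sequence_value(x, sv)
            if sv > 0:
                self._install_plan(seq, sv, x, s_idx, tag)
                return
            attempts.append((seq, sv, s_idx, x, tag))
        svs = np.array([a[1] for a in attempts])
        lowest = int(np.argmin(svs))  # ties: first (lowest index) excluded
        pool = [a for i, a in enumerate(attempts) if i != lowest]
        if not pool:
            pool = attempts
        seq, sv, s_idx, x, tag = pool[int(self.rng.integers(len(pool)))]
        self._install_plan(seq, sv, x, s_idx, tag)

    def _install_plan(
        self, seq: Sequence, sv: float, x: ContextState, s_idx: int, tag: str
    ) -> None:
        if s_idx != self.cur_s:
            self._activate_state_neuron(s_idx, x, tag)
        self.plan = PlanState.from_sequence(seq, sv)
        self._trial_acc["plans_started"] += 1

    # ------------------------------------------------------------------
    # action decoding

    def _decode_action(self, intended: np.ndarray) -> str | None:
        """Environment action whose successor stimulus is nearest to the
        intended stimulus (ties: first action in sorted order).  None
        when the prediction is empty."""
        if not intended.any():
            return None
        best_action, best_err = None, None
        for action in sorted(self.env.available_actions()):
            succ = self.env.successor_states(action)
            err = min(
                int(np.count_nonzero(self.env.stimulus_of(s) != intended))
                for s, _ in succ
            )
            if best_err is None or err < best_err:
                best_action, best_err = action, err
        return best_action

    # ------------------------------------------------------------------
    # step execution

    def _maybe_explore(self) -> bool:
        """Reward-prediction-error-facilitated exploration is possible
        when the state offers more transitions than the current state
        neuron has learned; it is certain while the followed plan is
        suppressed by its no-good indicator."""
        if self.cur_s is None:
            return False
        actions = self.env.available_actions()
        n_connected = self.net.outgoing(self.cur_s, ROLE_TRANSITION).size
        if len(actions) <= n_connected:
            return False
        p = 1.0 if (self.plan is not None and self.plan.sv < 0) else self.cfg.p_explore
        return bool(self.rng.random() < p)

    def _uncovered_actions(self) -> list[str]:
        """Actions none of whose outcomes any transition neuron of the
        current state neuron predicts yet (the natural targets of an
        exploratory move)."""
        actions = self.env.available_actions()
        covered: set[str] = set()
        for t in self.net.outgoing(self.cur_s, ROLE_TRANSITION):
            pred = self.net.predict_next_stimulus(int(t), self.cfg.d_stim)
            state = self.env.codebook.state_of(pred)
            if state is not None:
                covered.add(state)
        return [
            a
            for a in actions
            if not any(s in covered for s, _ in self.env.successor_states(a))
        ]

    def _explore_step(self) -> None:
        self._trial_acc["explorations"] += 1
        s_idx = self.cur_s
        assert s_idx is not None
        # a connected transition neuron that never came to predict
        # anything is re-used before a fresh neuron is recruited
        pending = [
            int(t)
            for t in self.net.outgoing(s_idx, ROLE_TRANSITION)
            if int(t) not in self.net.linked_transitions
        ]
        if pending:
            t_new = int(self.rng.choice(pending))
        else:
            try:
                t_new = self.net.recruit_transition_neuron(s_idx, self.rng)
            except RecruitmentOverflow:
                self.recruit_overflows += 1
                existing = self.net.outgoing(s_idx, ROLE_TRANSITION)
                t_new = int(self.rng.choice(existing)) if existing.size else None
        untried = self._uncovered_actions()
        action = str(self.rng.choice(untried if untried else self.env.available_actions()))
        if t_new is not None:
            self._window.append(t_new)
        self._execute(
            action,
            t_idx=t_new,
            planned_s=None,
            intended=None,
            source="explore",
            force_new_context=True,
        )

    def _plan_step(self) -> None:
        assert self.plan is not None and not self.plan.exhausted
        t_idx, planned_s = self.plan.steps[self.plan.pos]
        self.plan.pos += 1
        if not self.plan.started:
            self.plan.started = True
            self._trial_acc["max_tau"] = max(self._trial_acc["max_tau"], self.plan.tau)
        # reward-independent potentiation of the executed state->transition link
        if self.cur_s is not None:
            self.net.update_within_episode(self.cur_s, t_idx)
        if planned_s is not None:
            intended = self.net.context_feedback(planned_s)[: self.cfg.d_stim]
        else:
            intended = self.net.predict_next_stimulus(t_idx, self.cfg.d_stim)
        action = self._decode_action(intended)
        source = "plan"
        if action is None:
            # no usable prediction: move at random, plan cannot continue
            action = str(self.rng.choice(self.env.available_actions()))
            source = "plan_blind"
            intended = None
        self._window.append(t_idx)
        self._execute(
            action,
            t_idx=t_idx,
            planned_s=planned_s,
            intended=intended,
            source=source,
            force_new_context=False,
        )

    def _fallback_step(self) -> None:
        """Selected sequence had no transition at all: random move."""
        action = str(self.rng.choice(self.env.available_actions()))
        self.last_t = None
        self._execute(
            action,
            t_idx=None,
            planned_s=None,
            intended=None,
            source="fallback",
            force_new_context=False,
        )

    def _execute(
        self,
        action: str,
        *,
        t_idx: int | None,
        planned_s: int | None,
        intended: np.ndarray | None,
        source: str,
        force_new_context: bool,
    ) -> None:
        state_before = self.env.current_state
        lap_before = int(getattr(self.env, "_laps", 0))
        res = self.env.step(action, self.rng)
        if t_idx is not None:
            self.last_t = t_idx

        matched: bool | None = None
        if force_new_context:
            # exploration: the following state always gets a fresh context
            self.plan = None
            self._adopt_new_context(res.stimulus, tag="rpe_new")
        elif intended is not None:
            matched = bool(np.array_equal(intended, res.stimulus))
            if matched and planned_s is not None:
                x = self._context_from_neuron(planned_s)
                self._activate_state_neuron(planned_s, x, tag="plan")
                if self.plan is not None and self.plan.exhausted:
                    self.plan = None
            elif matched:
                # plan completed; re-anchor through the normal selection
                self.plan = None
                self._select_context_on_arrival(res.stimulus)
            else:
                self.plan = None
                assert t_idx is not None
                self._spe_remap(t_idx, planned_s, res.stimulus)
        else:
            self.plan = None
            self._select_context_on_arrival(res.stimulus)

        predicted_state = None
        if intended is not None:
            predicted_state = self.env.codebook.state_of(intended)
        self._log_step(
            trial=res.trial_index if not res.trial_ended else res.trial_index - 1,
            state=state_before,
            action=action,
            source=source,
            next_state=res.state,
            predicted_state=predicted_state or "",
            matched=matched,
            reward=res.reward,
            s_idx=self.cur_s,
            t_idx=t_idx,
            context_tag=self._context_tag,
            context_id=self._context_id(),
            context_is_default=self._context_is_default(),
            hidden=res.hidden,
            lap=lap_before,
        )

        if res.reward is not None:
            self._process_reward(res.reward, res)
        self._trial_acc["steps"] += 1
        if self._trial_acc["steps"] > self.cfg.max_trial_steps and not res.trial_ended:
            # runaway trial: abandon the plan, mark, and keep going
            self._trial_acc["truncated"] = True
            self.plan = None

    # ------------------------------------------------------------------
    # reward processing

    def _process_reward(self, reward: float, res) -> None:
        terminal = self.last_t
        if terminal is not None:
            self.values.process_reward(terminal, reward)
        if reward > 0:
            for a, b in zip(self._window, self._window[1:]):
                if (
                    self.net.roles[a] == ROLE_TRANSITION
                    and self.net.roles[b] == ROLE_STATE
                ):
                    self.net.update_between_episode(a, b, reward)
        # a new between-reward segment begins at the current state neuron
        self._window = [self.cur_s] if self.cur_s is not None else []
        acc = self._trial_acc
        self.trial_rows.append(
            {
                "trial": res.trial_index - 1,
                "rewarded": bool(reward > 0),
                "reward": float(reward),
                "hidden": res.hidden,
                "end_state": res.state,
                "steps": acc["steps"],
                "planning_length": acc["max_tau"],
                "contexts_created": acc["contexts_created"],
                "hallucinations": acc["hallucinations"],
                "default_fallbacks": acc["default_fallbacks"],
                "spe_events": acc["spe_events"],
                "explorations": acc["explorations"],
                "truncated": bool(acc.get("truncated", False)),
            }
        )
        self._trial_acc = self._fresh_trial_acc()

    # ------------------------------------------------------------------
    # main loop

    def run(self, n_trials: int, max_total_steps: int | None = None) -> pd.DataFrame:
        """Run ``n_trials`` trials and return the per-trial summary."""
        if max_total_steps is None:
            max_total_steps = n_trials * self.cfg.max_trial_steps * 2
        res = self.env.reset(self.rng)
        self._select_context_on_arrival(res.stimulus)
        steps = 0
        while len(self.trial_rows) < n_trials and steps < max_total_steps:
            if self.plan is None or self.plan.exhausted:
                self._select_plan()
            if self.plan is not None and not self.plan.steps:
                self.plan = None
                self._fallback_step()
            elif self._maybe_explore():
                self._explore_step()
            else:
                self._plan_step()
            steps += 1
        return self.trials_dataframe()

    def trials_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.trial_rows)

    def steps_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.step_rows)

    def context_counts(self) -> dict[str, int]:
        """Registered contexts per environmental state."""
        return {
            s: self.memory.count_for(self.env.stimulus_of(s))
            for s in self.env.states
        }


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortResult:
    trials: pd.DataFrame
    steps: pd.DataFrame
    context_counts: pd.DataFrame
    max_context_audit: int
    overflow_steps: int
    agents: list[Agent] = field(default_factory=list)


def run_experiment(
    config: AgentConfig,
    env_factory: Callable[[np.random.Generator], TaskPOMDP],
    n_agents: int,
    n_trials: int,
    seed: int,
    *,
    remapping_enabled: bool = True,
    log_steps: bool = True,
    keep_agents: bool = False,
) -> CohortResult:
    """Run a cohort of independently seeded agents.

    Each agent draws its own environment (stimulus codebook included)
    and random stream from a per-agent child seed, so the cohort is
    reproducible and insensitive to its own size ordering.
    """
    trial_frames, step_frames, count_rows = [], [], []
    audit, overflow = 0, 0
    agents: list[Agent] = []
    for i, child in enumerate(np.random.SeedSequence(seed).spawn(n_agents)):
        rng = np.random.default_rng(child)
        env = env_factory(rng)
        agent = Agent(
            config, env, rng, remapping_enabled=remapping_enabled, log_steps=log_steps
        )
        trials = agent.run(n_trials)
        trials.insert(0, "agent", i)
        trial_frames.append(trials)
        if log_steps:
            sdf = agent.steps_dataframe()
            sdf.insert(0, "agent", i)
            step_frames.append(sdf)
        counts = agent.context_counts()
        counts["agent"] = i
        count_rows.append(counts)
        audit = max(audit, agent.max_context_audit)
        overflow += agent.overflow_steps
        if keep_agents:
            agents.append(agent)
    return CohortResult(
        trials=pd.concat(trial_frames, ignore_index=True),
        steps=(
            pd.concat(step_frames, ignore_index=True) if step_frames else pd.DataFrame()
        ),
        context_counts=pd.DataFrame(count_rows).set_index("agent"),
        max_context_audit=audit,
        overflow_steps=overflow,
        agents=agents,
    )
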