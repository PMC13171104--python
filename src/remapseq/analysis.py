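"""Post-hoc experiments on trained agents.

Two analyses need more than the tidy logs: the entorhinal-inhibition
probe (compare lap-binned vs state-binned hippocampal activity with and
without silencing the context-domain input) and the behavioral decoding
of the contextual-inference task.  Both operate on copies of a trained
agent so the underlying run is left untouched.
"""

from __future__ import annotations

import copy

import numpy as np
import pandas as pd

from .agent import Agent
from .metrics import decode_behavior, esr_spatial_correlation

__all__ = [
    "probe_activity",
    "inhibition_experiment",
    "inference_decoding",
]


def probe_activity(
    agent: Agent,
    n_trials: int,
    *,
    inhibition: float = 0.0,
    n_lap_bins: int = 3,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Run ``n_trials`` further trials on a copy of a trained agent and
    return per-neuron firing rates binned by lap and by state.

    Returns ``(lap_rates, space_rates, states)`` with shapes
    (n_neurons, n_lap_bins) and (n_neurons, n_states).
    """
    probe = copy.deepcopy(agent)
    probe.log_steps = True
    probe.step_rows = []
    probe.trial_rows = []
    if inhibition > 0:
        probe.net.apply_inhibition(probe.cfg.d_stim, inhibition, probe.rng)
    start_len = len(probe.step_rows)
    probe.run(n_trials)
    steps = pd.DataFrame(probe.step_rows[start_len:])
    n = probe.cfg.n_hippocampus
    states = sorted(probe.env.states)
    lap_count = np.zeros((n, n_lap_bins))
    lap_occ = np.zeros(n_lap_bins)
    sp_count = np.zeros((n, len(states)))
    sp_occ = np.zeros(len(states))
    state_pos = {s: i for i, s in enumerate(states)}
    for row in steps.itertuples():
        lap = min(int(getattr(row, "lap", 0) or 0), n_lap_bins - 1)
        pos = state_pos[row.state]
        lap_occ[lap] += 1
        sp_occ[pos] += 1
        for idx in (row.s_idx, row.t_idx):
            if idx is not None and not (isinstance(idx, float) and np.isnan(idx)):
                lap_count[int(idx), lap] += 1
                sp_count[int(idx), pos] += 1
    lap_rates = lap_count / np.maximum(lap_occ, 1.0)
    space_rates = sp_count / np.maximum(sp_occ, 1.0)
    return lap_rates, space_rates, states


def inhibition_experiment(
    agent: Agent,
    rng: np.random.Generator,
    *,
    n_trials: int = 20,
    fraction: float = 0.985,
) -> tuple[float, float]:
    """Event-specific-rate vs spatial correlation between matched probe
    runs with the context-domain input intact and silenced.

    Correlations are computed over the cells recorded in both
    conditions (neurons silenced outright by the lesion carry no
    signal either way).  Expected signature of the model: lap coding
    degrades more than state coding, so esr_r < spatial_r.
    """
    lap_off, space_off, _ = probe_activity(agent, n_trials, inhibition=0.0)
    lap_on, space_on, _ = probe_activity(agent, n_trials, inhibition=fraction)
    active = (lap_off.sum(axis=1) > 0) & (lap_on.sum(axis=1) > 0)
    return esr_spatial_correlation(
        lap_on[active], lap_off[active], space_on[active], space_off[active], rng
    )


def _choice_label(state: str, action: str) -> str | None:
    """Behavioral reading of a branch choice in the inference task:
    which arena's reward mapping the action follows."""
    mapping = {
        ("S2", "a24"): "Sq",
        ("S2", "a25"): "Ci",
        ("S3", "a35"): "Sq",
        ("S3", "a34"): "Ci",
    }
    return mapping.get((state, action))


def inference_decoding(
    steps: pd.DataFrame,
    n_neurons: int,
    *,
    test_trials: tuple[int, int],
) -> dict[str, np.ndarray]:
    """Per-time-step decoding accuracy of the behavioral context in the
    inference task's test phase.

    For square/circle trials the decoded label is the presented arena;
    for morphed (SC) trials it is the arena whose contingency the agent
    behaved under.  Returns accuracy arrays keyed 'SqCi' and 'SC'.
    """
    lo, hi = test_trials
    sel = steps[(steps["trial"] >= lo) & (steps["trial"] <= hi)].copy()
    trials: dict[tuple[int, int], dict] = {}
    for row in sel.itertuples():
        key = (int(row.agent) if "agent" in sel.columns else 0, int(row.trial))
        rec = trials.setdefault(key, {"steps": [], "arena": None, "label": None})
        if row.state in ("Sq", "Ci", "SC") and rec["arena"] is None:
            rec["arena"] = row.state
        choice = _choice_label(row.state, row.action)
        if choice is not None:
            rec["label"] = choice
        rec["steps"].append((row.s_idx, row.t_idx))
    n_steps = 3  # arena, branch, outcome
    out: dict[str, np.ndarray] = {}
    for cond, keep in (
        ("SqCi", lambda r: r["arena"] in ("Sq", "Ci")),
        ("SC", lambda r: r["arena"] == "SC"),
    ):
        acts, labels = [], []
        for rec in trials.values():
            if not keep(rec) or len(rec["steps"]) < n_steps:
                continue
            label = rec["arena"] if rec["arena"] != "SC" else rec["label"]
            if label is None:
                continue
            mat = np.zeros((n_steps, n_neurons))
            for j in range(n_steps):
                s_idx, t_idx = rec["steps"][j]
                for idx in (s_idx, t_idx):
                    if idx is not None and not (
                        isinstance(idx, float) and np.isnan(idx)
                    ):
                        mat[j, int(idx)] = 1.0
            acts.append(mat)
            labels.append(label)
        if len(labels) >= 4 and len(set(labels)) >= 2:
            out[cond] = decode_behavior(np.asarray(acts), np.asarray(labels))
        else:
            out[cond] = np.full(n_steps, np.nan)
    return out
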