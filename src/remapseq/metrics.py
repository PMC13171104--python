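"""Cohort-level summary statistics.

Everything here consumes the tidy per-trial / per-step logs produced by
:mod:`remapseq.agent` (or raw activity arrays for the decoding and
inhibition analyses) and returns plain pandas objects, so results can
be written straight to CSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "correct_rate",
    "planning_length",
    "context_counts",
    "replay_probability",
    "decode_behavior",
    "esr_spatial_correlation",
    "paired_replay_ttest",
]


def correct_rate(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-trial fraction of rewarded agents with its standard error
    (SEM over agents)."""
    if trials.empty:
        raise ValueError("empty cohort")
    g = trials.groupby("trial")["rewarded"]
    out = g.agg(["mean", "count", "std"]).rename(columns={"mean": "rate"})
    out["sem"] = out.pop("std").fillna(0.0) / np.sqrt(out["count"])
    return out[["rate", "sem", "count"]]


def planning_length(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-trial mean (over agents) of the maximum number of actions a
    followed sequence planned ahead."""
    if trials.empty:
        raise ValueError("empty cohort")
    g = trials.groupby("trial")["planning_length"]
    out = g.agg(["mean", "count", "std"])
    out["sem"] = out.pop("std").fillna(0.0) / np.sqrt(out["count"])
    return out.rename(columns={"mean": "length"})[["length", "sem", "count"]]


def context_counts(cohort_counts: pd.DataFrame, states: list[str] | None = None) -> pd.DataFrame:
    """Cohort table of registered contexts per environmental state."""
    return cohort_counts if states is None else cohort_counts[states]


def used_context_counts(
    steps: pd.DataFrame,
    trial_window: tuple[int, int],
    states: list[str] | None = None,
) -> pd.DataFrame:
    """Contexts in active use per environmental state.

    Counts, per agent, the number of distinct contextual states that
    were current at each state over the trial window (inclusive) — the
    learned context map, as opposed to everything still held in the
    associative memory's registry.
    """
    lo, hi = trial_window
    sel = steps[(steps["trial"] >= lo) & (steps["trial"] <= hi)]
    agent_col = sel["agent"] if "agent" in sel.columns else pd.Series(0, index=sel.index)
    out = (
        sel.groupby([agent_col, sel["next_state"]])["context_id"]
        .nunique()
        .unstack(fill_value=0)
    )
    out.index.name = "agent"
    return out[states] if states is not None else out


def replay_probability(
    steps: pd.DataFrame,
    at_state: str,
    trial_window: tuple[int, int] | None = None,
) -> pd.Series:
    """Distribution of predicted next states among planning steps taken
    at ``at_state`` (optionally restricted to a trial window, inclusive).

    Exploration moves and steps without a usable prediction do not count
    as planning sequences.
    """
    sel = steps[(steps["state"] == at_state) & (steps["source"] == "plan")]
    sel = sel[sel["predicted_state"] != ""]
    if trial_window is not None:
        lo, hi = trial_window
        sel = sel[(sel["trial"] >= lo) & (sel["trial"] <= hi)]
    if sel.empty:
        return pd.Series(dtype=float)
    return sel["predicted_state"].value_counts(normalize=True).sort_index()


def decode_behavior(activity: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Leave-one-out nearest-centroid decoding accuracy per time step.

    Parameters
    ----------
    activity:
        Array of shape (n_trials, n_steps, n_neurons) of binary
        population activity.
    labels:
        Trial labels, length n_trials; at least two trials per class.

    Returns
    -------
    Accuracy per time step (length n_steps).
    """
    activity = np.asarray(activity, dtype=float)
    labels = np.asarray(labels)
    n_trials, n_steps, _ = activity.shape
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise ValueError("need at least two trials in each of two classes")
    acc = np.zeros(n_steps)
    for step in range(n_steps):
        x = activity[:, step, :]
        correct = 0
        for i in range(n_trials):
            best, best_d = None, None
            for c in classes:
                mask = (labels == c) & (np.arange(n_trials) != i)
                if not mask.any():
                    continue
                centroid = x[mask].mean(axis=0)
                d = float(np.abs(x[i] - centroid).sum())  # L1 ~ Hamming
                if best_d is None or d < best_d:
                    best, best_d = c, d
            correct += int(best == labels[i])
        acc[step] = correct / n_trials
    return acc


def esr_spatial_correlation(
    lap_on: np.ndarray,
    lap_off: np.ndarray,
    space_on: np.ndarray,
    space_off: np.ndarray,
    rng: np.random.Generator,
    spontaneous: float = 0.1,
) -> tuple[float, float]:
    """Event-specific-rate vs spatial correlation under inhibition.

    Per-neuron firing rates binned by lap (``lap_*``, shape
    (n_neurons, n_laps)) and by environmental state (``space_*``) are
    correlated between the inhibition-off and inhibition-on conditions;
    the mean over neurons of each Pearson coefficient is returned as
    (esr_r, spatial_r).  Neurons silent in a condition receive uniform
    random spontaneous activity in [0, ``spontaneous``] so the
    correlations are defined.
    """

    def _fill(a: np.ndarray) -> np.ndarray:
        a = np.asarray(a, dtype=float).copy()
        flat = a.std(axis=1) == 0
        a[flat] = rng.uniform(0.0, spontaneous, size=(int(flat.sum()), a.shape[1]))
        return a

    def _mean_r(x: np.ndarray, y: np.ndarray) -> float:
        rs = []
        for xi, yi in zip(x, y):
            if xi.std() == 0 or yi.std() == 0:
                continue
            rs.append(float(np.corrcoef(xi, yi)[0, 1]))
        return float(np.mean(rs)) if rs else float("nan")

    esr_r = _mean_r(_fill(lap_off), _fill(lap_on))
    spatial_r = _mean_r(_fill(space_off), _fill(space_on))
    return esr_r, spatial_r


def paired_replay_ttest(per_agent_major: np.ndarray, per_agent_minor: np.ndarray):
    """Paired t-test of per-agent replay frequencies for the two
    branches (pairing unit: agent)."""
    return stats.ttest_rel(per_agent_major, per_agent_minor)
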