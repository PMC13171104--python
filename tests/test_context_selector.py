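"""Attractor-memory unit tests: storage, recall, forgetting, capacity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from remapseq.context_selector import (
    ContextMemory,
    ContextState,
    ContextStateError,
    Converter,
    RecallOutcome,
    init_history,
    init_landmark,
    make_default_context,
    random_half_ones,
)

N, D = 1200, 200


def _memory(**kw):
    return ContextMemory(N, D, **kw)


def _random_context(stim, rng):
    return ContextState(
        np.concatenate([stim, random_half_ones(N - D, rng)]), d_stim=D
    )


class TestDefaultContext:
    def test_stimulus_domain_is_copied_bit_for_bit(self, rng):
        conv = Converter(D, N - D, rng)
        stim = random_half_ones(D, rng)
        x = make_default_context(stim, conv)
        assert np.array_equal(x.stim_view, stim)

    def test_context_domain_has_exactly_half_ones(self, rng):
        conv = Converter(D, N - D, rng)
        x = make_default_context(random_half_ones(D, rng), conv)
        assert int(x.cont_view.sum()) == (N - D) // 2 == 500

    def test_deterministic_per_stimulus(self, rng):
        conv = Converter(D, N - D, rng)
        stim = random_half_ones(D, rng)
        assert make_default_context(stim, conv) == make_default_context(stim, conv)

    def test_dimension_mismatch_rejected(self, rng):
        conv = Converter(D, N - D, rng)
        with pytest.raises(ValueError):
            conv(random_half_ones(D + 2, rng))

    def test_defaults_of_distinct_stimuli_are_nearly_orthogonal(self, rng):
        conv = Converter(D, N - D, rng)
        xs = [
            make_default_context(random_half_ones(D, rng), conv).bits.astype(float)
            - 0.5
            for _ in range(6)
        ]
        for i in range(6):
            for j in range(i + 1, 6):
                assert abs(xs[i] @ xs[j]) < N / 16


class TestInitialisation:
    def test_history_init_zero_weights_gives_zero_vector(self):
        x = init_history(np.zeros((N, 300)), np.zeros(300), D)
        assert not x.bits.any()

    def test_history_init_recovers_a_linked_context(self, rng):
        # one-shot cross weights put +1/2 on active bits and -N/2 on
        # inactive ones, so thresholding a one-hot drive is exact
        target = _random_context(random_half_ones(D, rng), rng)
        eta, x1 = (N + 1) / 2, N / (N + 1)
        w_xh = np.zeros((N, 300))
        w_xh[:, 17] = np.minimum(eta * (target.bits - x1), 0.5)
        h = np.zeros(300)
        h[17] = 1.0
        assert init_history(w_xh, h, D) == target

    def test_landmark_init_popcount_and_determinism(self, rng):
        stim = random_half_ones(D, rng)
        a = init_landmark(stim, N - D, np.random.default_rng(5))
        b = init_landmark(stim, N - D, np.random.default_rng(5))
        c = init_landmark(stim, N - D, np.random.default_rng(6))
        assert np.array_equal(a.stim_view, stim)
        assert int(a.cont_view.sum()) == (N - D) // 2
        assert a == b
        assert a != c


class TestRecall:
    def test_stored_pattern_is_a_fixed_point(self, rng):
        mem = _memory()
        stim = random_half_ones(D, rng)
        x = _random_context(stim, rng)
        mem.store(x, is_default=True)
        res = mem.recall(x, stim)
        assert res.outcome is RecallOutcome.SUCCESS
        assert res.final_state == x
        assert res.iterations <= 2

    def test_recovery_from_flipped_context_bits(self, rng):
        mem = _memory()
        stim = random_half_ones(D, rng)
        x = _random_context(stim, rng)
        mem.store(x, is_default=True)
        noisy = x.bits.copy()
        noisy[D : D + 3] ^= 1  # flip 3 context-domain bits
        res = mem.recall(ContextState(noisy, d_stim=D), stim)
        assert res.outcome is RecallOutcome.SUCCESS
        assert res.final_state == x

    def test_empty_weights_converge_to_zero_as_hallucination(self, rng):
        mem = _memory()
        stim = random_half_ones(D, rng)
        res = mem.recall(_random_context(stim, rng), stim)
        assert res.outcome is RecallOutcome.HALLUCINATION
        assert not res.final_state.bits.any()

    def test_oscillation_falls_back_to_default_context(self, rng):
        # W = -2I makes the synchronous update the bitwise complement,
        # a period-2 cycle that must never satisfy the convergence test
        mem = _memory()
        stim = random_half_ones(D, rng)
        default = _random_context(stim, rng)
        mem.store(default, is_default=True)
        mem.w_xx = -2.0 * np.eye(N)
        res = mem.recall(_random_context(stim, rng), stim, max_iter=50)
        assert res.outcome is RecallOutcome.DEFAULT_FALLBACK
        assert res.final_state == default
        assert res.iterations == 50

    def test_fallback_without_default_raises(self, rng):
        mem = _memory()
        mem.w_xx = -2.0 * np.eye(N)
        stim = random_half_ones(D, rng)
        with pytest.raises(ContextStateError):
            mem.recall(_random_context(stim, rng), stim)


class TestStoreForget:
    def test_store_adds_quarter_on_diagonal(self, rng):
        mem = _memory()
        x = _random_context(random_half_ones(D, rng), rng)
        mem.store(x)
        assert np.allclose(np.diag(mem.w_xx), 0.25)

    def test_store_then_forget_is_exact_identity(self, rng):
        mem = _memory()
        base = _random_context(random_half_ones(D, rng), rng)
        mem.store(base, is_default=True)
        before = mem.w_xx.copy()
        x = _random_context(base.stim_view, rng)
        mem.store(x)
        mem.forget(x)
        assert np.array_equal(mem.w_xx, before)

    def test_double_store_rejected(self, rng):
        mem = _memory()
        x = _random_context(random_half_ones(D, rng), rng)
        mem.store(x)
        with pytest.raises(ContextStateError):
            mem.store(x)

    def test_forget_default_or_unknown_rejected(self, rng):
        mem = _memory()
        stim = random_half_ones(D, rng)
        x = _random_context(stim, rng)
        mem.store(x, is_default=True)
        with pytest.raises(ContextStateError):
            mem.forget(x)
        with pytest.raises(ContextStateError):
            mem.forget(_random_context(stim, rng))


class TestCapacity:
    def _filled(self, rng, n, protect=()):
        mem = _memory()
        stim = random_half_ones(D, rng)
        xs = [_random_context(stim, rng) for _ in range(n)]
        for i, x in enumerate(xs):
            mem.store(x)
            if i in protect:
                mem.note_sequence_value(x, 0.9)
        return mem, stim, xs

    def test_below_capacity_is_a_no_op(self, rng):
        mem, stim, _ = self._filled(rng, 3)
        assert mem.enforce_capacity(stim) == []
        assert mem.count_for(stim) == 3

    def test_violation_forgets_reward_unrelated_contexts(self, rng):
        mem, stim, xs = self._filled(rng, 8)
        forgotten = mem.enforce_capacity(stim)
        assert len(forgotten) == 8
        assert mem.count_for(stim) == 0

    def test_protected_context_survives_regardless_of_age(self, rng):
        mem, stim, xs = self._filled(rng, 8, protect=(0,))
        mem.enforce_capacity(stim)
        assert mem.count_for(stim) == 1
        assert mem.lookup(xs[0]) is not None

    def test_all_protected_overflows_with_warning_counter(self, rng):
        mem, stim, _ = self._filled(rng, 8, protect=range(8))
        assert mem.enforce_capacity(stim) == []
        assert mem.overflow_events == 1


@settings(max_examples=25, deadline=None)
@given(st.lists(st.integers(0, 4), min_size=1, max_size=12), st.integers(0, 2**31 - 1))
def test_symmetry_preserved_under_store_forget_interleavings(ops, seed):
    rng = np.random.default_rng(seed)
    mem = ContextMemory(120, 20)
    stims = [random_half_ones(20, rng) for _ in range(2)]
    stored = []
    for op in ops:
        if op < 3 or not stored:  # store
            s = stims[op % 2]
            x = ContextState(
                np.concatenate([s, random_half_ones(100, rng)]), d_stim=20
            )
            if not mem.is_registered(x):
                mem.store(x)
                stored.append(x)
        else:  # forget
            x = stored.pop(rng.integers(len(stored)))
            mem.forget(x)
        assert np.array_equal(mem.w_xx, mem.w_xx.T)


@settings(max_examples=5, deadline=None)
@given(st.integers(1, 5), st.integers(0, 2**31 - 1))
def test_retrieval_fidelity_below_capacity(k, seed):
    """Every stored pattern is recalled exactly while each stimulus
    holds at most five contexts."""
    rng = np.random.default_rng(seed)
    mem = ContextMemory(N, D)
    for _ in range(3):
        stim = random_half_ones(D, rng)
        for i in range(k):
            x = ContextState(
                np.concatenate([stim, random_half_ones(N - D, rng)]), d_stim=D
            )
            if not mem.is_registered(x):
                mem.store(x, is_default=(i == 0))
    all_states = [e.state for v in mem.registry.values() for e in v]
    for entries in mem.registry.values():
        for e in entries:
            res = mem.recall(e.state, e.state.stim_view)
            assert res.outcome is RecallOutcome.SUCCESS
            # crosstalk between same-stimulus patterns can flip a few
            # context-domain bits near capacity; the recalled state must
            # still be the probed pattern's basin, not a sibling's
            dists = {
                int(np.count_nonzero(res.final_state.bits != s.bits)): s
                for s in all_states
            }
            d_self = int(np.count_nonzero(res.final_state.bits != e.state.bits))
            assert d_self <= 10
            assert d_self == min(dists)
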