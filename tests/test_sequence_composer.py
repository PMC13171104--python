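"""Planning-network unit tests: recruitment, generation, plasticity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from remapseq.context_selector import ContextState, random_half_ones
from remapseq.sequence_composer import (
    ROLE_STATE,
    ROLE_TRANSITION,
    ROLE_UNASSIGNED,
    HippocampalNetwork,
    RecruitmentOverflow,
)
from remapseq.valuation import ValueTable

N, D, NH = 1200, 200, 300


def _net(**kw):
    return HippocampalNetwork(NH, N, **kw)


def _context(rng):
    return ContextState(
        np.concatenate([random_half_ones(D, rng), random_half_ones(N - D, rng)]),
        d_stim=D,
    )


class TestRecruitment:
    def test_cross_weights_take_exact_values(self, rng):
        net = _net()
        x = _context(rng)
        s = net.recruit_state_neuron(x)
        active = x.bits == 1
        assert np.allclose(net.w_hx[s, active], 0.5)
        assert np.allclose(net.w_hx[s, ~active], -N / 2)
        assert np.allclose(net.w_xh[active, s], 0.5)
        assert np.allclose(net.w_xh[~active, s], -N / 2)

    def test_state_neuron_readout_recovers_its_context(self, rng):
        net = _net()
        x = _context(rng)
        s = net.recruit_state_neuron(x)
        assert np.array_equal(net.context_feedback(s), x.bits)

    def test_double_recruitment_for_same_context_rejected(self, rng):
        net = _net()
        x = _context(rng)
        net.recruit_state_neuron(x)
        with pytest.raises(ValueError):
            net.recruit_state_neuron(x)

    def test_transition_recruitment_sets_unit_weight(self, rng):
        net = _net()
        s = net.recruit_state_neuron(_context(rng))
        t = net.recruit_transition_neuron(s, rng)
        assert net.w_hh[t, s] == 1.0
        assert net.roles[t] == ROLE_TRANSITION

    def test_transition_recruitment_is_seed_reproducible(self):
        picks = []
        for _ in range(2):
            net = _net()
            s = net.recruit_state_neuron(_context(np.random.default_rng(0)))
            picks.append(net.recruit_transition_neuron(s, np.random.default_rng(3)))
        assert picks[0] == picks[1]

    def test_pool_exhaustion_raises_overflow(self, rng):
        net = HippocampalNetwork(2, N)
        net.recruit_state_neuron(_context(rng))
        net.recruit_state_neuron(_context(rng))
        with pytest.raises(RecruitmentOverflow):
            net.recruit_state_neuron(_context(rng))


class TestSeedSelection:
    def test_learned_context_drives_its_own_neuron(self, rng):
        net = _net()
        xs = [_context(rng) for _ in range(3)]
        idx = [net.recruit_state_neuron(x) for x in xs]
        for x, s in zip(xs, idx):
            assert net.select_seed(x) == s
        # drive of the winning neuron equals popcount / 2
        drive = net.w_hx[idx[0]] @ xs[0].bits
        assert drive == pytest.approx(xs[0].bits.sum() / 2)

    def test_zero_weights_signal_novel_context(self, rng):
        assert _net().select_seed(_context(rng)) is None

    def test_tie_broken_toward_lower_index(self, rng):
        net = _net()
        x = _context(rng)
        s = net.recruit_state_neuron(x)
        # force a duplicate row on a higher-index neuron
        net.roles[50] = ROLE_STATE
        net.w_hx[50] = net.w_hx[s]
        assert net.select_seed(x) == min(s, 50)


class TestSequenceGeneration:
    def _chain(self, rng):
        """S0 -> T0 -> {S1 (w 0.7), S2 (w 0.5)}; T1, T2 onward empty."""
        net = _net()
        s0, s1, s2 = (net.recruit_state_neuron(_context(rng)) for _ in range(3))
        t0 = net.recruit_transition_neuron(s0, rng)
        net.w_hh[s1, t0] = 0.7
        net.w_hh[s2, t0] = 0.5
        return net, s0, s1, s2, t0

    def test_single_candidate_followed_surely(self, rng):
        net, s0, *_ , t0 = self._chain(rng)
        values = ValueTable(NH)
        seq = net.generate_sequence(s0, values, rng)
        assert seq.neurons[1] == t0

    def test_branch_probabilities_follow_relative_weights(self, rng):
        # (0.7-w0)/(1-w0) vs (0.5-w0)/(1-w0) -> 2/3 vs 1/3
        net, s0, s1, s2, t0 = self._chain(rng)
        values = ValueTable(NH)
        n, hits = 100_000, 0
        draws = rng.random(0)  # keep a dedicated generator
        gen = np.random.default_rng(123)
        for _ in range(n):
            seq = net.generate_sequence(s0, values, gen)
            if len(seq.neurons) > 2 and seq.neurons[2] == s1:
                hits += 1
        p = 2 / 3
        sigma = np.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * sigma

    def test_positive_value_stops_the_sequence(self, rng):
        net, s0, s1, s2, t0 = self._chain(rng)
        values = ValueTable(NH)
        values.v[t0] = 0.15
        seq = net.generate_sequence(s0, values, rng)
        assert seq.neurons == (s0, t0)
        assert seq.tau == 1

    def test_seed_without_transitions_is_incomplete(self, rng):
        net = _net()
        s = net.recruit_state_neuron(_context(rng))
        seq = net.generate_sequence(s, ValueTable(NH), rng)
        assert seq.neurons == (s,)
        assert not seq.complete

    def test_roles_strictly_alternate(self, rng):
        net, s0, *_ = self._chain(rng)
        seq = net.generate_sequence(s0, ValueTable(NH), rng)
        roles = [net.roles[i] for i in seq.neurons]
        assert roles[0] == ROLE_STATE
        assert all(a != b for a, b in zip(roles, roles[1:]))


class TestPlasticity:
    def test_within_episode_fresh_pair_reaches_one(self, rng):
        net = _net()
        net.update_within_episode(3, 7)
        assert net.w_hh[7, 3] == 1.0

    def test_within_episode_depression_amount(self, rng):
        net = _net()
        net.update_within_episode(3, 7)
        others = np.arange(NH) != 3
        assert np.allclose(net.w_hh[7, others], 0.3 - 0.075)

    def test_no_depression_on_established_pair(self, rng):
        net = _net()
        net.update_within_episode(3, 7)
        before = net.w_hh[7].copy()
        net.update_within_episode(3, 7)  # re-activation
        others = np.arange(NH) != 3
        assert np.array_equal(net.w_hh[7, others], before[others])

    def test_between_episode_single_step_value(self, rng):
        net = _net()
        net.update_between_episode(7, 3, reward=1.0)
        assert net.w_hh[3, 7] == pytest.approx(0.3 + 0.15 * (1 - 0.3 - 0.3))

    def test_between_episode_converges_to_reward_minus_baseline(self, rng):
        net = _net()
        for _ in range(200):
            net.update_between_episode(7, 3, reward=1.0)
        assert net.w_hh[3, 7] == pytest.approx(0.7, abs=1e-6)

    def test_between_episode_requires_positive_reward(self, rng):
        with pytest.raises(ValueError):
            _net().update_between_episode(7, 3, reward=0.0)

    def test_spe_changes(self, rng):
        net = _net()
        net.w_hh[5, 9] = 0.7
        net.apply_spe_weight_changes(9, 5, None)
        assert net.w_hh[5, 9] == pytest.approx(0.595)
        net.w_hh[6, 9] = 0.3
        net.apply_spe_weight_changes(9, None, 6)
        assert net.w_hh[6, 9] == pytest.approx(0.3525)
        net.w_hh[8, 9] = 0.66
        net.apply_spe_weight_changes(9, None, 8)
        assert net.w_hh[8, 9] == 0.66


class TestInhibition:
    def test_fraction_counts_columns_exactly(self, rng):
        net = _net()
        net.w_hx[:] = 0.2
        cols = net.apply_inhibition(D, 0.985, rng)
        assert cols.size == round(0.985 * (N - D)) == 985
        assert (cols >= D).all()
        assert np.all(net.w_hx[:, cols] == 0.0)
        net.restore_inhibition()
        assert np.all(net.w_hx == 0.2)

    def test_zero_and_full_fractions(self, rng):
        net = _net()
        net.w_hx[:] = 0.2
        assert net.apply_inhibition(D, 0.0, rng).size == 0
        net.restore_inhibition()
        cols = net.apply_inhibition(D, 1.0, rng)
        assert cols.size == N - D
        assert np.all(net.w_hx[:, D:] == 0.0)


@settings(max_examples=20, deadline=None)
@given(st.lists(st.tuples(st.integers(0, 3), st.integers(0, 39), st.integers(0, 39)),
                min_size=1, max_size=30),
       st.integers(0, 2**31 - 1))
def test_weight_bounds_hold_under_random_operation_sequences(ops, seed):
    rng = np.random.default_rng(seed)
    net = HippocampalNetwork(40, 120)
    for kind, a, b in ops:
        if a == b:
            continue
        if kind == 0:
            net.update_within_episode(a, b)
        elif kind == 1:
            net.update_between_episode(a, b, reward=1.0)
        elif kind == 2:
            net.apply_spe_weight_changes(a, b, None)
        else:
            net.apply_spe_weight_changes(a, None, b)
        assert net.w_hh.min() >= 0.0 and net.w_hh.max() <= 1.0
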