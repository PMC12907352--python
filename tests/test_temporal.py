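"""Transition matrices, sequence complexity and group statistics."""

import numpy as np
import pytest

import playseq as ps
from playseq.errors import ParameterError
from playseq.temporal import GroupSummary


def _merge_logs(a, b):
    from playseq.behavior import EventLog

    return EventLog(events=a.events + b.events, alphabet=a.alphabet)


class TestTransitionCounts:
    def test_direct_pair_counting(self, seq_log, alphabet6):
        log = seq_log(["nonverbal_initiation", "responsive", "nonverbal_initiation", "responsive"])
        tm = ps.transition_counts(log)
        i, j = alphabet6.index("nonverbal_initiation"), alphabet6.index("responsive")
        assert tm.counts[i, j] == 2 and tm.counts[j, i] == 1

    def test_self_transitions(self, seq_log, alphabet6):
        tm = ps.transition_counts(seq_log(["avoidance"] * 3, dur=3.5))
        i = alphabet6.index("avoidance")
        assert tm.counts[i, i] == 2 and tm.counts.sum() == 2

    def test_session_boundary_never_crossed(self, seq_log, alphabet6):
        a = seq_log(["nonverbal_initiation", "responsive"], session="s1")
        b = seq_log(["responsive", "nonverbal_initiation"], session="s2")
        tm = ps.transition_counts(_merge_logs(a, b))
        j = alphabet6.index("responsive")
        assert tm.counts[j, j] == 0 and tm.counts.sum() == 2

    def test_brute_force_equivalence_on_random_logs(self, seq_log, alphabet6, rng):
        for _ in range(10):
            codes = [alphabet6.codes[i] for i in rng.integers(0, 6, size=rng.integers(2, 50))]
            tm = ps.transition_counts(seq_log(codes))
            expected = np.zeros((6, 6), dtype=int)
            for x, y in zip(codes, codes[1:]):
                expected[alphabet6.index(x), alphabet6.index(y)] += 1
            assert np.array_equal(tm.counts, expected)

    def test_lag_two(self, seq_log, alphabet6):
        log = seq_log(["nonverbal_initiation", "avoidance", "responsive"])
        tm = ps.transition_counts(log, lag=2)
        assert tm.counts.sum() == 1
        assert tm.counts[alphabet6.index("nonverbal_initiation"), alphabet6.index("responsive")] == 1

    def test_errors(self, seq_log, alphabet6):
        from playseq.behavior import EventLog

        with pytest.raises(ParameterError):
            ps.transition_counts(seq_log(["responsive"]), lag=0)
        with pytest.raises(ParameterError):
            ps.transition_counts(EventLog(events=[], alphabet=alphabet6))


class TestTransitionProbabilities:
    def test_deterministic_alternation(self, seq_log, alphabet6):
        log = seq_log(["nonverbal_initiation", "responsive"] * 2 + ["nonverbal_initiation"])
        tm = ps.transition_probabilities(ps.transition_counts(log))
        i, j = alphabet6.index("nonverbal_initiation"), alphabet6.index("responsive")
        assert tm.probs[i, j] == 1.0 and tm.probs[j, i] == 1.0

    def test_split_row(self, seq_log, alphabet6):
        log = seq_log(["nonverbal_initiation", "nonverbal_initiation", "responsive"])
        tm = ps.transition_probabilities(ps.transition_counts(log))
        i, j = alphabet6.index("nonverbal_initiation"), alphabet6.index("responsive")
        assert tm.probs[i, i] == 0.5 and tm.probs[i, j] == 0.5

    def test_defined_rows_sum_to_one(self, seq_log, alphabet6, rng):
        codes = [alphabet6.codes[i] for i in rng.integers(0, 6, size=200)]
        tm = ps.transition_probabilities(ps.transition_counts(seq_log(codes)))
        sums = np.nansum(tm.probs, axis=1)
        defined = ~tm.undefined_rows
        assert np.allclose(sums[defined], 1.0, atol=1e-12)

    def test_zero_count_rows_undefined_without_smoothing(self, seq_log, alphabet6):
        tm = ps.transition_probabilities(ps.transition_counts(seq_log(["responsive", "avoidance"])))
        assert tm.undefined_rows[alphabet6.index("emotion_sharing")]
        smoothed = ps.transition_probabilities(ps.transition_counts(seq_log(["responsive", "avoidance"])), alpha=0.5)
        assert not smoothed.undefined_rows.any()
        assert np.allclose(smoothed.probs.sum(axis=1), 1.0)

    def test_long_chain_recovers_generating_row(self, alphabet6, rng):
        from playseq.cohort import asd_group_kernel, simulate_event_log

        kernel = asd_group_kernel(6)
        log = simulate_event_log(kernel, alphabet6, 10000, rng)
        tm = ps.transition_probabilities(ps.transition_counts(log))
        row = tm.probs[alphabet6.index("nonverbal_initiation")]
        assert np.abs(row - kernel[0]).max() < 0.04

    def test_monte_carlo_consistency_with_chain_length(self, alphabet6):
        # estimated rows approach the generating rows as chains grow
        from playseq.cohort import asd_group_kernel, simulate_event_log

        kernel = asd_group_kernel(6)
        errs = []
        for n in (200, 2000, 20000):
            rng = np.random.default_rng(7)
            log = simulate_event_log(kernel, alphabet6, n, rng)
            tm = ps.transition_probabilities(ps.transition_counts(log))
            errs.append(np.nanmax(np.abs(tm.probs - kernel)))
        assert errs[2] < errs[0]
        assert errs[2] < 0.05

    def test_negative_alpha_rejected(self, seq_log):
        tm = ps.transition_counts(seq_log(["responsive", "avoidance"]))
        with pytest.raises(ParameterError):
            ps.transition_probabilities(tm, alpha=-0.1)


class TestKStepTransition:
    def _uniform_tm(self, alphabet6, rng):
        from playseq.cohort import simulate_event_log, td_group_kernel

        log = simulate_event_log(td_group_kernel(), alphabet6, 500, rng)
        return ps.transition_probabilities(ps.transition_counts(log), alpha=1.0)

    def test_single_step_identity_case(self, alphabet6, rng):
        tm = self._uniform_tm(alphabet6, rng)
        ms = ps.k_step_transition(tm, T=1, lam=1.0)
        assert np.allclose(ms.matrix, tm.probs)

    def test_two_state_swap_squares_to_identity(self, alphabet6):
        tm = ps.TransitionMatrix(
            alphabet=alphabet6, counts=np.zeros((6, 6), dtype=int), probs=np.eye(6)[::-1].copy()
        )
        # a pure permutation matrix: applying it twice returns to start
        ms = ps.k_step_transition(tm, T=2, lam=1.0)
        assert np.allclose(ms.matrix, np.eye(6))

    def test_decay_scaling_law(self, alphabet6, rng):
        tm = self._uniform_tm(alphabet6, rng)
        ms = ps.k_step_transition(tm, T=2, lam=0.5)
        assert np.allclose(ms.matrix, 0.25 * (tm.probs @ tm.probs))

    def test_matches_naive_repeated_multiplication(self, alphabet6, rng):
        tm = self._uniform_tm(alphabet6, rng)
        acc = np.eye(6)
        for _ in range(4):
            acc = acc @ tm.probs
        assert np.allclose(ps.k_step_transition(tm, T=4).matrix, acc)

    def test_rows_sum_to_one_without_decay(self, alphabet6, rng):
        tm = self._uniform_tm(alphabet6, rng)
        assert np.allclose(ps.k_step_transition(tm, T=3).matrix.sum(axis=1), 1.0)


class TestBehavioralEntropy:
    def test_strict_alternation_is_one_bit(self, seq_log):
        log = seq_log(["nonverbal_initiation", "responsive"] * 10 + ["nonverbal_initiation"])
        assert ps.behavioral_entropy(log).H == pytest.approx(1.0)

    def test_constant_sequence_is_zero(self, seq_log):
        log = seq_log(["avoidance"] * 20, dur=3.5)
        assert ps.behavioral_entropy(log).H == pytest.approx(0.0)
        assert ps.behavioral_entropy(log, "unigram").H == pytest.approx(0.0)

    def test_iid_uniform_approaches_log2_36(self, seq_log, alphabet6, rng):
        codes = [alphabet6.codes[i] for i in rng.integers(0, 6, size=40000)]
        h = ps.behavioral_entropy(seq_log(codes)).H
        assert h == pytest.approx(np.log2(36), abs=0.05)

    def test_bounds_and_relabeling_invariance(self, seq_log, alphabet6, rng):
        for _ in range(10):
            idx = rng.integers(0, 6, size=rng.integers(2, 60))
            codes = [alphabet6.codes[i] for i in idx]
            sm = ps.behavioral_entropy(seq_log(codes))
            assert 0.0 <= sm.H <= np.log2(sm.n_cells) + 1e-12
            perm = rng.permutation(6)
            relabeled = [alphabet6.codes[perm[i]] for i in idx]
            assert ps.behavioral_entropy(seq_log(relabeled)).H == pytest.approx(sm.H)

    def test_single_event_bigram_rejected(self, seq_log):
        with pytest.raises(ParameterError):
            ps.behavioral_entropy(seq_log(["responsive"]))


class TestAverageSequenceLength:
    def test_arithmetic_mean_of_episode_sizes(self, make_log):
        triples = [("responsive", t, t + 1.0) for t in [0, 2, 4]]  # episode of 3
        triples += [("responsive", t, t + 1.0) for t in [20, 22, 24, 26, 28]]  # episode of 5
        assert ps.average_sequence_length(make_log(triples)) == pytest.approx(4.0)

    def test_all_gaps_below_threshold_single_episode(self, seq_log):
        log = seq_log(["responsive"] * 7, gap=1.0)
        assert ps.average_sequence_length(log) == 7.0

    def test_synthetic_cohort_hits_planted_mean(self, alphabet6):
        from playseq.cohort import simulate_event_log, td_group_kernel

        rng = np.random.default_rng(11)
        asl = np.mean(
            [
                ps.average_sequence_length(
                    simulate_event_log(
                        td_group_kernel(), alphabet6, 200, rng, episode_length_mean=4.2
                    )
                )
                for _ in range(40)
            ]
        )
        assert asl == pytest.approx(4.2, abs=0.3)

    def test_bad_threshold_rejected(self, seq_log):
        with pytest.raises(ParameterError):
            ps.average_sequence_length(seq_log(["responsive"] * 2), gap_threshold=0.0)


class TestCyclicity:
    def _tm(self, alphabet6, probs):
        return ps.TransitionMatrix(
            alphabet=alphabet6, counts=np.zeros((6, 6), dtype=int), probs=probs
        )

    def test_identity_matrix_fully_cyclic(self, alphabet6):
        c = ps.cyclicity(self._tm(alphabet6, np.eye(6)), weights=np.full(6, 1 / 6))
        assert c == pytest.approx(1.0)

    def test_zero_diagonal_fully_transitive(self, alphabet6):
        p = np.full((6, 6), 1 / 5)
        np.fill_diagonal(p, 0.0)
        assert ps.cyclicity(self._tm(alphabet6, p)) == pytest.approx(0.0)

    def test_two_state_hand_example(self, alphabet6):
        # P = [[0.7,0.3],[0.4,0.6]] has stationary (4/7, 3/7);
        # cyclicity = 4/7*0.7 + 3/7*0.6 = 23/35
        p = np.full((6, 6), 1e-12)
        p[0, 0], p[0, 1], p[1, 0], p[1, 1] = 0.7, 0.3, 0.4, 0.6
        p = p / p.sum(axis=1, keepdims=True)
        w = np.array([4 / 7, 3 / 7, 0, 0, 0, 0])
        assert ps.cyclicity(self._tm(alphabet6, p), weights=w) == pytest.approx(23 / 35, abs=1e-9)

    def test_complement_is_transitivity(self, alphabet6, rng):
        p = rng.dirichlet(np.ones(6), size=6)
        c = ps.cyclicity(self._tm(alphabet6, p))
        # transitivity = 1 - cyclicity exactly, both from the same weighting
        w = ps.stationary_distribution(p)
        trans = float(np.sum(w * (1 - np.diag(p))))
        assert c + trans == pytest.approx(1.0, abs=1e-10)


class TestMineChains:
    def test_deterministic_chain_probability_one(self, seq_log):
        log = seq_log(["nonverbal_initiation", "responsive"] * 5)
        table = ps.mine_chains(log, order=2)
        top = table.iloc[0]
        assert top["chain"] == "nonverbal_initiation -> responsive"
        assert top["probability"] == 1.0

    def test_order_beyond_sequence_is_empty(self, seq_log):
        assert ps.mine_chains(seq_log(["responsive", "avoidance"]), order=5).empty

    def test_support_filter(self, seq_log):
        a = seq_log(["responsive", "avoidance"], child="c1")
        b = seq_log(["responsive", "joint_attention"], child="c2")
        table = ps.mine_chains([a, b], order=2, min_support=0.6)
        assert table.empty  # each chain occurs in only one of two children

    def test_planted_asd_chain_recovered(self, alphabet7):
        from playseq.cohort import asd_kernel_7, simulate_event_log

        rng = np.random.default_rng(5)
        logs = [
            simulate_event_log(
                asd_kernel_7(), alphabet7, 200, rng, child_id=f"c{i}", jitter_concentration=200.0
            )
            for i in range(40)
        ]
        table = ps.mine_chains(logs, order=2, min_support=0.5)
        top = table.iloc[0]
        assert top["chain"] == "avoidance -> stereotypy"
        assert top["probability"] == pytest.approx(0.42, abs=0.03)

    def test_order_below_two_rejected(self, seq_log):
        with pytest.raises(ParameterError):
            ps.mine_chains(seq_log(["responsive", "avoidance"]), order=1)


class TestWelchT:
    def test_identical_groups(self):
        g = GroupSummary(mean=1.0, sd=0.5, n=10)
        t, df, p = ps.welch_t(g, g)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_entropy_group_comparison_matches_hand_formula(self):
        a = GroupSummary(mean=2.14, sd=0.32, n=60)
        b = GroupSummary(mean=3.08, sd=0.41, n=40)
        t, df, p = ps.welch_t(a, b)
        se = np.sqrt(0.32**2 / 60 + 0.41**2 / 40)
        assert t == pytest.approx((2.14 - 3.08) / se, abs=1e-9)
        assert t == pytest.approx(-12.228, abs=1e-3)
        assert p < 1e-10

    def test_doubling_sample_sizes_scales_t_by_sqrt2(self):
        a = GroupSummary(mean=1.0, sd=1.0, n=30)
        b = GroupSummary(mean=1.5, sd=1.2, n=40)
        t1, _, _ = ps.welch_t(a, b)
        t2, _, _ = ps.welch_t(
            GroupSummary(mean=1.0, sd=1.0, n=60), GroupSummary(mean=1.5, sd=1.2, n=80)
        )
        assert t2 == pytest.approx(np.sqrt(2) * t1)

    def test_pooled_variant_exposed(self):
        a = GroupSummary(mean=2.14, sd=0.32, n=60)
        b = GroupSummary(mean=3.08, sd=0.41, n=40)
        t_w, df_w, _ = ps.welch_t(a, b)
        t_p, df_p, _ = ps.welch_t(a, b, equal_var=True)
        assert df_p == 98.0 and t_p != t_w

    def test_zero_variance_rejected(self):
        g = GroupSummary(mean=1.0, sd=0.0, n=5)
        with pytest.raises(ParameterError):
            ps.welch_t(g, g)


class TestChiSquare:
    def test_perfect_independence(self):
        res = ps.chi_square([[10, 10], [10, 10]])
        assert res.chi2 == 0.0 and res.df == 1

    def test_perfectly_associated_2x2_equals_n(self):
        res = ps.chi_square([[20, 0], [0, 20]])
        assert res.chi2 == pytest.approx(40.0)
        assert res.p < 1e-9

    def test_expected_margins_match_observed(self, rng):
        obs = rng.integers(1, 30, size=(3, 2)).astype(float)
        res = ps.chi_square(obs)
        assert np.allclose(res.expected.sum(axis=0), obs.sum(axis=0))
        assert np.allclose(res.expected.sum(axis=1), obs.sum(axis=1))

    def test_adjusted_residuals_center(self, rng):
        obs = rng.integers(5, 50, size=(2, 2)).astype(float)
        res = ps.chi_square(obs)
        # in a 2x2 table all four adjusted residuals have equal magnitude
        assert np.allclose(np.abs(res.adjusted_residuals), np.abs(res.adjusted_residuals[0, 0]))

    def test_zero_margin_rejected(self):
        with pytest.raises(ParameterError):
            ps.chi_square([[0, 0], [5, 5]])
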