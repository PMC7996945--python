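"""Learning-curve and phase-comparison statistics."""

import math

import numpy as np
import pytest

from gstchunks import (
    GeneratorParams, KeypressEvent, Session, TrialRecord, build_report,
    chunk_reorganization_test, error_rate_curve, execution_time,
    friedman_execution, make_cohort, phase_rt_ttest, simulate_session,
    with_params,
)
from gstchunks.stats import friedman_permutation_p, sign_flip_p
from oracles import enum_friedman_p, enum_sign_flip_t_p, enum_wilcoxon_p


def _trial(attempt, timestamps, success=True, reward=100.0):
    events = [KeypressEvent(position=i + 1, key="5", timestamp_ms=float(ts))
              for i, ts in enumerate(timestamps)]
    return TrialRecord(attempt_index=attempt, success=success, reward=reward,
                       moves=len(timestamps), events=events)


def _session_from_rts(rt_matrix, subject_id="S01"):
    """One successful trial per row; timestamps are cumulative RTs."""
    trials = [_trial(i + 1, np.cumsum(row)) for i, row in enumerate(rt_matrix)]
    return Session(subject_id=subject_id, trials=trials,
                   locked_keys=tuple("5" * rt_matrix.shape[1]))


class TestExecutionTime:
    def test_last_minus_first_timestamp(self):
        assert execution_time(_trial(1, [400, 700, 1100])) == 700.0

    def test_single_keypress_undefined(self):
        with pytest.raises(ValueError):
            execution_time(_trial(1, [400]))

    def test_noise_free_closed_form(self, default_task):
        p = GeneratorParams(boundary_slowing=0.0, practice_amplitude=0.0,
                            rt_noise_sigma=0.0, asymptote=250.0,
                            error_rate_initial=0.0, n_successful_trials=6)
        s = simulate_session(default_task, p, seed=0)
        # 16 keypresses at 250 ms each: ET spans positions 2..16
        assert execution_time(s.trials[0]) == pytest.approx(15 * 250.0)


class TestErrorRateCurve:
    def test_error_free_cohort_gives_zero_curve(self, default_task):
        p = GeneratorParams(n_subjects=2, n_successful_trials=8,
                            error_rate_initial=0.0)
        curve = error_rate_curve(make_cohort(default_task, p, seed=4))
        assert np.all(curve.mean_error_rate == 0)
        assert curve.n_trials == 8

    def test_direct_count_before_first_success(self):
        bad = _trial(1, [500, 900], success=False, reward=0.0)
        bad2 = _trial(2, [500, 900], success=False, reward=0.0)
        good = [_trial(3 + i, np.cumsum([300] * 4) + i) for i in range(3)]
        s = Session("S01", [bad, bad2] + good)
        curve = error_rate_curve([s])
        assert curve.mean_error_rate.tolist() == [2.0, 0.0, 0.0]

    def test_error_mass_conserved(self, default_task, default_params):
        cohort = make_cohort(default_task, with_params(default_params, n_subjects=4),
                             seed=6)
        curve = error_rate_curve(cohort)
        total_errors = sum(s.n_error for s in cohort)
        assert curve.mean_error_rate.sum() * len(cohort) == pytest.approx(total_errors)

    def test_curve_decreases_on_average(self, default_task, default_params):
        cohort = make_cohort(default_task, with_params(default_params, n_subjects=8),
                             seed=13)
        curve = error_rate_curve(cohort)
        assert curve.mean_error_rate[:5].mean() > curve.mean_error_rate[-5:].mean()


class TestFriedman:
    def test_no_effect_gives_zero_statistic(self):
        rts = np.full((6, 4), 300.0)
        cohort = [_session_from_rts(rts, f"S{i}") for i in range(5)]
        res = friedman_execution(cohort)
        assert res.chi_square == 0.0 and res.p_value == 1.0

    def test_perfect_concordance_attains_maximum(self):
        # strictly decreasing ETs for every subject: chi2 = n * (k - 1)
        n, k = 13, 60
        cohort = []
        for i in range(n):
            base = 1000 - 10 * np.arange(k) + i  # ET decreases with trial
            rts = np.tile(base[:, None] / 4, (1, 5))
            cohort.append(_session_from_rts(rts, f"S{i:02d}"))
        res = friedman_execution(cohort)
        assert res.chi_square == pytest.approx(n * (k - 1))
        assert res.df == k - 1
        assert res.p_value < 0.001

    def test_permutation_p_matches_enumeration_oracle(self, rng):
        data = rng.normal(size=(4, 3)) * 10 + 100
        ours = friedman_permutation_p(data)
        oracle = enum_friedman_p(data)
        assert ours == pytest.approx(oracle, abs=0.005)

    def test_practice_effect_detected(self, default_task):
        p = GeneratorParams(n_subjects=6, n_successful_trials=20,
                            error_rate_initial=0.0)
        res = friedman_execution(make_cohort(default_task, p, seed=8))
        assert res.p_value < 0.001


class TestPhaseRTTest:
    def test_identical_phases_degenerate_zero(self):
        rts = np.tile(np.linspace(200, 400, 16), (20, 1))
        cohort = [_session_from_rts(rts + i, f"S{i}") for i in range(4)]
        res = phase_rt_ttest(cohort)
        assert res.degenerate
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_constant_difference_flagged_degenerate(self):
        cohort = []
        for i in range(4):
            early = np.tile(np.full(16, 400.0) + i, (10, 1))
            late = np.tile(np.full(16, 300.0) + i, (10, 1))
            cohort.append(_session_from_rts(np.vstack([early, late]), f"S{i}"))
        res = phase_rt_ttest(cohort)
        assert res.degenerate and math.isinf(res.statistic)

    def test_practice_speedup_direction(self, default_task, default_params):
        cohort = make_cohort(default_task, with_params(default_params, n_subjects=5),
                             seed=3)
        res = phase_rt_ttest(cohort)
        assert res.mean_late < res.mean_early
        assert res.statistic > 0 and res.p_value < 0.05

    def test_sign_flip_p_matches_enumeration_oracle(self, rng):
        diff = rng.normal(loc=0.8, size=8)
        assert sign_flip_p(diff) == pytest.approx(enum_sign_flip_t_p(diff), abs=1e-12)

    def test_fewer_than_two_subjects_rejected(self, quiet_session):
        with pytest.raises(ValueError):
            phase_rt_ttest([quiet_session])


class TestChunkReorganization:
    def test_identical_phases_give_p_one(self):
        rng = np.random.default_rng(0)
        # same planted boundary pattern throughout: no early/late change
        base = np.full(16, 250.0)
        base[[0, 7]] = 400.0
        rts = base * np.exp(0.05 * rng.standard_normal((20, 16)))
        cohort = [_session_from_rts(rts * (1 + 0.01 * i), f"S{i}") for i in range(6)]
        res = chunk_reorganization_test(cohort)
        assert res.n_chunks.p_exact == 1.0
        assert res.chunk_length.p_exact == 1.0

    def test_consolidation_direction_per_subject(self, default_task, default_params):
        cohort = make_cohort(default_task, default_params, seed=5)
        res = chunk_reorganization_test(cohort)
        deltas_n = [r["n_chunks_late"] - r["n_chunks_early"] for r in res.per_subject]
        deltas_l = [r["length_late"] - r["length_early"] for r in res.per_subject
                    if r["subject_id"] not in res.excluded_from_length]
        assert np.mean(deltas_n) < 0
        assert np.mean(deltas_l) > 0
        assert res.n_chunks.p_exact < 0.05
        assert res.chunk_length.p_exact < 0.05

    def test_wilcoxon_exact_matches_enumeration_oracle(self, rng):
        from gstchunks.chunking import paired_wilcoxon

        diff = rng.normal(loc=0.5, size=9)
        _, p, _ = paired_wilcoxon(diff)
        assert p == pytest.approx(enum_wilcoxon_p(diff), abs=1e-12)

    def test_subject_without_chunks_excluded_from_length_test(self):
        rng = np.random.default_rng(1)
        # subject A: normal chunk structure in both phases
        base = np.full(16, 250.0)
        base[[0, 7]] = 400.0
        rts_a = base * np.exp(0.03 * rng.standard_normal((20, 16)))
        # subject B: strictly increasing RTs -> every pair is a boundary ->
        # all singleton segments -> no chunks in either phase
        ramp = 100.0 * np.arange(1, 17)
        rts_b = ramp * (1 + 0.01 * np.arange(20)[:, None])
        cohort = [_session_from_rts(rts_a, "A"), _session_from_rts(rts_b, "B")]
        res = chunk_reorganization_test(cohort)
        assert res.excluded_from_length == ("B",)
        assert res.chunk_length.n_pairs == 1
        assert res.n_chunks.n_pairs == 2  # B retained with 0 chunks


class TestReport:
    def test_report_has_all_sections(self, default_task, default_params):
        cohort = make_cohort(default_task, with_params(default_params, n_subjects=4),
                             seed=12)
        d = build_report(cohort).to_dict()
        assert set(d) == {"alpha", "learning_curve", "friedman",
                          "phase_rt_ttest", "reorganization"}
        assert len(d["reorganization"]["per_subject"]) == 4
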