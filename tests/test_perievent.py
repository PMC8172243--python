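"""Bout merging, peri-event alignment, z-scoring and the pre/post t test."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as spstats

import photoscratch as ps
from photoscratch.errors import (
    ConfigurationError, EmptyResultError, ZeroVarianceError,
)
from conftest import bout_union_oracle, random_event_train


def train(onsets, duration=1000.0, durations=None):
    return ps.EventTrain(onsets_s=np.asarray(onsets, float),
                         session_duration_s=duration,
                         durations_s=durations)


class TestMergeBouts:
    def test_thirty_second_rule(self):
        bouts = ps.merge_bouts(train([0.0, 10.0, 50.0]), 30.0)
        np.testing.assert_array_equal(bouts.bout_onsets_s, [0.0, 50.0])
        np.testing.assert_array_equal(bouts.bout_offsets_s, [10.0, 50.0])
        np.testing.assert_array_equal(bouts.events_per_bout, [2, 1])

    def test_empty_train(self):
        bouts = ps.merge_bouts(train([]), 30.0)
        assert len(bouts) == 0 and bouts.n_events == 0

    def test_negative_window_rejected(self):
        with pytest.raises(ConfigurationError):
            ps.merge_bouts(train([1.0]), -1.0)

    def test_unsorted_events_rejected(self):
        with pytest.raises(ConfigurationError):
            train([5.0, 1.0])

    def test_matches_interval_union_oracle(self, rng):
        for _ in range(500):
            ev = random_event_train(rng)
            window = float(rng.uniform(0.0, 60.0))
            bouts = ps.merge_bouts(ev, window)
            oracle = bout_union_oracle(ev.onsets_s, window)
            assert len(bouts) == len(oracle)
            for (on, off, n), b_on, b_off, b_n in zip(
                oracle, bouts.bout_onsets_s, bouts.bout_offsets_s, bouts.events_per_bout
            ):
                assert on == b_on and off == b_off and n == b_n

    @given(st.lists(st.floats(0.0, 999.0), max_size=30, unique=True),
           st.floats(0.0, 120.0))
    def test_conservation_and_idempotence(self, onsets, window):
        ev = train(sorted(onsets))
        bouts = ps.merge_bouts(ev, window)
        assert bouts.n_events == len(ev)
        remerged = ps.merge_bouts(
            train(bouts.bout_onsets_s, duration=ev.session_duration_s), window)
        np.testing.assert_array_equal(remerged.bout_onsets_s, bouts.bout_onsets_s)
        assert len(remerged) == len(bouts)

    @given(st.lists(st.floats(0.0, 999.0), min_size=1, max_size=30, unique=True))
    def test_bout_count_monotone_in_window(self, onsets):
        ev = train(sorted(onsets))
        counts = [len(ps.merge_bouts(ev, w)) for w in (0.0, 5.0, 30.0, 120.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_offset_to_onset_mode_uses_durations(self):
        ev = train([0.0, 35.0], durations=np.array([10.0, 1.0]))
        # onset gap 35 > 30 but offset(10)→onset(35) gap 25 ≤ 30
        assert len(ps.merge_bouts(ev, 30.0)) == 2
        assert len(ps.merge_bouts(ev, 30.0, gap_mode="offset-to-onset")) == 1


def constant_trace(value=1.0, duration=100.0, fs=100.0):
    return ps.CorrectedTrace(dff=np.full(int(duration * fs), value),
                             mean_corrected=value, fit=None, source_rate_hz=fs)


def bouts_at(onsets, duration=100.0):
    return ps.merge_bouts(
        ps.EventTrain(onsets_s=np.asarray(onsets, float), session_duration_s=duration),
        0.0)


class TestBuildPeriEventMatrix:
    def test_boundary_exclusion(self):
        m = ps.build_perievent_matrix(constant_trace(), bouts_at([10.0, 95.0]),
                                      pre_s=5.0, post_s=10.0)
        assert m.n_trials == 1
        assert m.excluded_trials == [(1, "window exceeds recording")]

    def test_constant_trace_gives_constant_matrix(self):
        m = ps.build_perievent_matrix(constant_trace(1.0), bouts_at([50.0]),
                                      pre_s=5.0, post_s=5.0)
        np.testing.assert_allclose(m.values, 1.0)
        assert m.n_bins == round(10.0 / m.bin_s)

    def test_no_retained_trials_raises(self):
        with pytest.raises(EmptyResultError):
            ps.build_perievent_matrix(constant_trace(duration=20.0),
                                      bouts_at([1.0], duration=20.0),
                                      pre_s=5.0, post_s=10.0)

    def test_average_peak_at_kernel_latency(self):
        # transients locked to bout onsets: the column-mean peak sits within
        # one bin of the kernel's analytic peak latency
        onsets = 20.0 + 40.0 * np.arange(8)
        tr = ps.simulate_dff_trace(3, 360.0, onsets_s=onsets, amplitude=0.2,
                                   noise_sd=0.0)
        m = ps.build_perievent_matrix(tr, bouts_at(onsets, 360.0), pre_s=5.0, post_s=10.0)
        mean, _ = ps.perievent_average(m)
        t_peak = m.bin_times()[np.argmax(mean)]
        t_true = np.log(1.5 / 0.2) * 0.2 * 1.5 / 1.3
        assert abs(t_peak - t_true) <= m.bin_s + 1e-12

    def test_time_zero_column_is_onset(self):
        m = ps.build_perievent_matrix(constant_trace(), bouts_at([50.0]),
                                      pre_s=5.0, post_s=5.0)
        t = m.bin_times()
        k = np.searchsorted(t, 0.0)
        assert t[k - 1] < 0 <= t[k]
        assert k == pytest.approx(m.n_bins / 2, abs=1)


class TestZscore:
    def test_trial_reference_simple(self):
        m = ps.PeriEventMatrix(values=[[1.0, 2.0, 3.0]], pre_s=1.0, post_s=2.0, bin_s=1.0)
        z = ps.zscore_matrix(m, reference="trial")
        np.testing.assert_allclose(z.values, [[-1.0, 0.0, 1.0]])
        assert z.units == "zscore"

    def test_trial_reference_standardizes_rows(self, rng):
        m = ps.PeriEventMatrix(values=rng.normal(3.0, 2.0, (6, 50)),
                               pre_s=2.0, post_s=3.0, bin_s=0.1)
        z = ps.zscore_matrix(m)
        np.testing.assert_allclose(z.values.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.values.std(axis=1, ddof=1), 1.0, rtol=1e-12)

    def test_session_reference_on_null(self):
        # no transients: z across bins should be standard-normal-like; the
        # windows tile nearly the whole session so band-limited noise
        # correlations cannot bias the sampled subset
        tr = ps.simulate_dff_trace(17, 400.0, noise_sd=0.02)
        onsets = 10.0 + 11.0 * np.arange(35)
        m = ps.build_perievent_matrix(tr, bouts_at(onsets, 400.0),
                                      pre_s=5.0, post_s=5.9)
        z = ps.zscore_matrix(m, reference="session", session_trace=tr)
        flat = z.values.ravel()
        assert flat.size >= 2000
        assert abs(flat.mean()) < 0.02
        assert abs(flat.std(ddof=1) - 1.0) < 0.05

    def test_zero_variance_names_trial(self):
        m = ps.PeriEventMatrix(values=[[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]],
                               pre_s=1.0, post_s=2.0, bin_s=1.0)
        with pytest.raises(ZeroVarianceError, match="1"):
            ps.zscore_matrix(m)

    def test_baseline_reference(self):
        vals = np.tile([1.0, 3.0, 10.0, 10.0], (2, 1))
        m = ps.PeriEventMatrix(values=vals, pre_s=2.0, post_s=2.0, bin_s=1.0)
        z = ps.zscore_matrix(m, reference="trial_baseline")
        # baseline bins are the first two (mean 2, sd √2)
        np.testing.assert_allclose(z.values[:, :2].mean(axis=1), 0.0, atol=1e-12)


class TestAverageAndChange:
    def test_single_trial_sem_zero(self):
        m = ps.PeriEventMatrix(values=[[1.0, 2.0]], pre_s=1.0, post_s=1.0, bin_s=1.0)
        mean, sem = ps.perievent_average(m)
        np.testing.assert_array_equal(mean, [1.0, 2.0])
        np.testing.assert_array_equal(sem, [0.0, 0.0])

    def test_two_trial_sem(self):
        m = ps.PeriEventMatrix(values=[[0.0] * 3, [2.0] * 3], pre_s=1.0, post_s=2.0, bin_s=1.0)
        mean, sem = ps.perievent_average(m)
        np.testing.assert_allclose(mean, 1.0)
        np.testing.assert_allclose(sem, 1.0)

    def test_sem_matches_direct_oracle(self, rng):
        vals = rng.normal(0.0, 1.0, (1000, 20))
        m = ps.PeriEventMatrix(values=vals, pre_s=1.0, post_s=1.0, bin_s=0.1)
        _, sem = ps.perievent_average(m)
        oracle = vals.std(axis=0, ddof=1) / np.sqrt(1000)
        np.testing.assert_allclose(sem, oracle, rtol=1e-12)

    def test_constant_matrix_zero_change(self):
        m = ps.PeriEventMatrix(values=np.full((4, 100), 2.0), pre_s=5.0, post_s=5.0,
                               bin_s=0.1)
        pre, post = ps.pre_post_change(m)
        np.testing.assert_allclose(post - pre, 0.0)

    def test_amplitude_recovered_in_change(self):
        # injected transients of amplitude 0.2: post − pre mean ≈ kernel mean
        onsets = 20.0 + 30.0 * np.arange(8)
        tr = ps.simulate_dff_trace(5, 260.0, onsets_s=onsets, amplitude=0.2)
        m = ps.build_perievent_matrix(tr, bouts_at(onsets, 260.0), pre_s=5.0, post_s=10.0)
        pre, post = ps.pre_post_change(m)
        # mean of the peak-normalized kernel over the 5-s post window
        t = np.arange(0, 5, 0.001)
        expected = 0.2 * np.mean(ps.transient_kernel(t, 0.2, 1.5))
        assert np.mean(post - pre) == pytest.approx(expected, abs=0.05)

    def test_window_outside_span_rejected(self):
        m = ps.PeriEventMatrix(values=np.zeros((2, 100)), pre_s=5.0, post_s=5.0, bin_s=0.1)
        with pytest.raises(ConfigurationError):
            ps.pre_post_change(m, post_window_s=(6.0, 8.0))

    def test_null_type_one_error_quick(self):
        rejections = 0
        for seed in range(100):
            onsets = 15.0 + 20.0 * np.arange(8)
            tr = ps.simulate_dff_trace(seed, 170.0, onsets_s=onsets, amplitude=0.0)
            m = ps.build_perievent_matrix(tr, bouts_at(onsets, 170.0),
                                          pre_s=5.0, post_s=10.0)
            pre, post = ps.pre_post_change(m)
            rejections += ps.ttest_two_sample(post, pre).p < 0.05
        assert 100 - rejections >= 93


class TestTTest:
    def test_degrees_of_freedom(self, rng):
        res8 = ps.ttest_two_sample(rng.normal(size=8), rng.normal(size=8))
        assert res8.df == 14
        res6 = ps.ttest_two_sample(rng.normal(size=6), rng.normal(size=6))
        assert res6.df == 10

    def test_identical_groups(self):
        x = np.array([1.0, 2.0, 3.0])
        res = ps.ttest_two_sample(x, x)
        assert res.t == 0.0 and res.p == 1.0

    def test_matches_scipy_oracle(self, rng):
        for _ in range(100):
            x = rng.normal(size=int(rng.integers(2, 20)))
            y = rng.normal(loc=rng.normal(), size=int(rng.integers(2, 20)))
            for equal_var in (True, False):
                mine = ps.ttest_two_sample(x, y, equal_var=equal_var)
                ref = spstats.ttest_ind(x, y, equal_var=equal_var)
                assert mine.t == pytest.approx(ref.statistic, abs=1e-10)
                assert mine.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(ConfigurationError):
            ps.ttest_two_sample([1.0], [1.0, 2.0])
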