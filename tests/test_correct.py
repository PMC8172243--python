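"""Isosbestic scaling fit, motion correction and dF/F conventions."""

import numpy as np
import pytest

import photoscratch as ps
from photoscratch.errors import DegenerateBaselineError, DegenerateFitError


def trace(values, fs=100.0, **kw):
    return ps.ChannelTrace(values=np.asarray(values, float), sample_rate_hz=fs, **kw)


class TestFitIsosbestic:
    def test_identity(self, rng):
        x = trace(rng.normal(1.0, 0.1, 500))
        fit = ps.fit_isosbestic(x, x)
        assert fit.gain_a == pytest.approx(1.0)
        assert fit.offset_b == pytest.approx(0.0, abs=1e-12)
        assert fit.residual_rms == pytest.approx(0.0, abs=1e-12)

    def test_exact_affine_relation(self, rng):
        c = trace(rng.normal(1.0, 0.1, 500))
        s = trace(2.0 * c.values + 3.0)
        fit = ps.fit_isosbestic(c, s)
        assert fit.gain_a == pytest.approx(2.0)
        assert fit.offset_b == pytest.approx(3.0)
        assert fit.residual_rms < 1e-10

    def test_gain_recovery_within_ols_standard_error(self):
        # closed-form OLS sampling distribution as the oracle
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            c_vals = rng.normal(1.0, 0.2, 400)
            noise_sd = 0.05
            s_vals = 1.5 * c_vals + rng.normal(0.0, noise_sd, 400)
            fit = ps.fit_isosbestic(trace(c_vals), trace(s_vals))
            se = noise_sd / np.sqrt(np.sum((c_vals - c_vals.mean()) ** 2))
            hits += abs(fit.gain_a - 1.5) < 1.96 * se
        assert hits >= 93

    def test_constant_control_rejected(self):
        with pytest.raises(DegenerateFitError):
            ps.fit_isosbestic(trace(np.ones(100)), trace(np.arange(100.0)))

    def test_length_mismatch_rejected(self):
        with pytest.raises(DegenerateFitError):
            ps.fit_isosbestic(trace(np.ones(100)), trace(np.arange(50.0)))

    def test_gain_only_mode(self, rng):
        c = trace(rng.normal(2.0, 0.3, 300))
        s = trace(0.7 * c.values)
        fit = ps.fit_isosbestic(c, s, gain_only=True)
        assert fit.gain_a == pytest.approx(0.7)
        assert fit.offset_b == 0.0


class TestMotionCorrect:
    def test_shared_artifact_exactly_cancelled(self):
        # linear shared-artifact model, zero noise, equal bleach: affine fit
        # removes the artifact to machine precision (envelope level)
        cfg = ps.SimConfig(seed=4, duration_s=200.0, noise_sd=0.0,
                           transient_amplitude=0.0)
        _, truth = ps.simulate_session(cfg)
        tr = truth.channel_traces(100.0)
        fit = ps.fit_isosbestic(tr[405], tr[470])
        corrected = ps.motion_correct(tr[470], tr[405], fit)
        rel = np.ptp(corrected.values) / np.mean(tr[470].values)
        assert rel < 1e-6

    def test_motion_decorrelated_under_default_noise(self, default_session, demodulated):
        _, _, _, truth = default_session
        sig, ctl = demodulated[470], demodulated[405]
        fit = ps.fit_isosbestic(ctl, sig)
        corrected = ps.motion_correct(sig, ctl, fit)
        m = truth.motion_at(sig.sample_rate_hz)
        ok = ~corrected.settling_mask
        corr_raw = np.corrcoef(sig.values[ok], m[ok])[0, 1]
        corr_fix = np.corrcoef(corrected.values[ok], m[ok])[0, 1]
        assert abs(corr_raw) > 0.5
        assert abs(corr_fix) < 0.1

    def test_motion_variance_reduced_tenfold(self, default_session, demodulated):
        _, _, _, truth = default_session
        sig, ctl = demodulated[470], demodulated[405]
        corrected = ps.motion_correct(sig, ctl, ps.fit_isosbestic(ctl, sig))
        m = truth.motion_at(sig.sample_rate_hz)
        ok = ~corrected.settling_mask
        beta_raw = np.polyfit(m[ok], sig.values[ok], 1)[0]
        beta_fix = np.polyfit(m[ok], corrected.values[ok], 1)[0]
        assert beta_raw**2 / beta_fix**2 > 10

    def test_null_control_passthrough(self):
        s = trace(np.linspace(1, 2, 50))
        c = trace(np.zeros(50))
        out = ps.motion_correct(s, c, ps.ScalingFit(1.0, 0.0, 0.0, 50))
        np.testing.assert_array_equal(out.values, s.values)


class TestComputeDff:
    def test_direct_arithmetic(self):
        out = ps.compute_dff(trace([2.0, 4.0, 6.0]))
        np.testing.assert_allclose(out.dff, [0.5, 1.0, 1.5])
        assert out.mean_corrected == pytest.approx(4.0)

    def test_mean_exactly_one(self, rng):
        vals = rng.lognormal(0.0, 0.3, 1000)
        out = ps.compute_dff(trace(vals))
        assert np.mean(out.unmasked) == pytest.approx(1.0, abs=2e-16 * 1000)

    def test_degenerate_after_affine_subtraction(self, rng):
        # affine OLS residuals have mean zero, so session-mean-mode dF/F must refuse
        c = trace(rng.normal(1.0, 0.1, 500))
        s = trace(2.0 * c.values + rng.normal(0, 0.01, 500), fs=100.0)
        s.source_mean = float(np.mean(s.values))
        fit = ps.fit_isosbestic(c, s)
        corrected = ps.motion_correct(s, c, fit)
        with pytest.raises(DegenerateBaselineError, match="fitted-control"):
            ps.compute_dff(corrected)

    def test_transient_amplitude_propagates(self):
        # one transient of fractional amplitude 0.20 over baseline appears as
        # a 0.20 dF/F excursion after divide-by-mean normalization
        cfg = ps.SimConfig(seed=6, duration_s=120.0, noise_sd=0.0,
                           motion_gain={405: 0.0, 470: 0.0},
                           transient_jitter_s=0.0, event_rate_hz=0.0)
        ev = ps.EventTrain(onsets_s=np.array([60.0]), session_duration_s=120.0)
        _, truth = ps.simulate_session(cfg, ev)
        env = truth.channel_traces(100.0)[470]
        out = ps.compute_dff(env)
        i_onset = int(60.0 * 100)
        baseline = out.dff[i_onset - 10]
        peak = out.dff[i_onset:i_onset + 200].max()
        assert peak - baseline == pytest.approx(0.20, abs=0.03)

    def test_scale_invariance(self, rng):
        # multiplying the input(s) by a constant leaves dF/F unchanged
        vals = rng.lognormal(0.0, 0.2, 400)
        a = ps.compute_dff(trace(vals))
        b = ps.compute_dff(trace(7.0 * vals))
        np.testing.assert_allclose(a.dff, b.dff, rtol=1e-12)

        c_vals = rng.normal(1.0, 0.1, 400) + 1.0
        s_vals = 2.0 * c_vals + rng.normal(0, 0.02, 400) + 0.5
        x = ps.correct_session(trace(s_vals), trace(c_vals), dff_mode="fitted-control")
        y = ps.correct_session(trace(7.0 * s_vals), trace(7.0 * c_vals),
                               dff_mode="fitted-control")
        np.testing.assert_allclose(x.dff, y.dff, rtol=1e-9)

    def test_fitted_control_baseline_at_zero(self, default_session, demodulated):
        dff = ps.correct_session(demodulated[470], demodulated[405],
                                 dff_mode="fitted-control")
        assert abs(np.median(dff.unmasked)) < 0.05
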