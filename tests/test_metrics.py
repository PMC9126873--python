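"""Tests of the analysis layer: period estimators, phase metrics, return
maps, instantaneous refresh ratio, intensity normalization, Hill fits."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from zeitgeber import CalibrationError, EstimationError, ParameterError
from zeitgeber import metrics as M
from zeitgeber.synth import NoiseModel, generate_titration

DT = 0.25  # 15-min sampling, in hours


def cosine_trace(period_h=3.0, hours=24.0, dt=DT, phase=0.0, decay_h=None):
    t = np.arange(0.0, hours, dt)
    y = np.cos(2 * np.pi * t / period_h + phase)
    if decay_h is not None:
        y *= np.exp(-t / decay_h)
    return 5.0 + 2.0 * y


class TestAcfPeriod:
    def test_pure_cosine(self):
        est = M.acf_period(cosine_trace(3.0), dt_h=DT)
        assert est.period_h == pytest.approx(3.0, abs=0.03)
        assert est.method == "acf"

    def test_noisy_cosine_within_five_percent(self):
        rng = np.random.default_rng(7)
        y = cosine_trace(3.0) * rng.lognormal(0.0, 0.05, 96)
        est = M.acf_period(y, dt_h=DT)
        assert est.period_h == pytest.approx(3.0, rel=0.05)

    @given(scale=st.floats(0.1, 50.0), shift=st.floats(-100.0, 100.0))
    def test_affine_invariance(self, scale, shift):
        base = M.acf_period(cosine_trace(3.0), dt_h=DT)
        moved = M.acf_period(scale * cosine_trace(3.0) + shift, dt_h=DT)
        assert moved.period_h == pytest.approx(base.period_h, rel=1e-6)

    def test_non_oscillatory_returns_none(self):
        t = np.arange(96) * DT
        assert M.acf_period(np.exp(-t / 4.0), dt_h=DT) is None

    def test_uncertainty_scales_with_maxima_count(self):
        short = M.acf_period(cosine_trace(3.0, hours=9.0), dt_h=DT)
        long = M.acf_period(cosine_trace(3.0, hours=45.0), dt_h=DT)
        assert short.uncertainty_h > long.uncertainty_h
        assert long.uncertainty_h == pytest.approx(
            long.period_h / long.n_maxima_used)

    def test_too_short_rejected(self):
        with pytest.raises(ParameterError):
            M.acf_period(np.ones(4), dt_h=DT)


class TestDampedCosine:
    def test_self_fit_recovers_period(self):
        est = M.damped_cosine_period(cosine_trace(3.0, hours=36.0, decay_h=20.0),
                                     dt_h=DT)
        assert est.period_h == pytest.approx(3.0, abs=0.05)

    def test_agrees_with_acf_on_simulation(self, free_trace):
        acf = M.acf_period(free_trace, "a")
        dc = M.damped_cosine_period(free_trace, "a", exclude_initial_h=2.0)
        assert abs(dc.period_h - acf.period_h) <= acf.uncertainty_h

    def test_pure_decay_flagged(self):
        t = np.arange(96) * DT
        with pytest.raises(EstimationError):
            M.damped_cosine_period(np.exp(-t / 4.0), dt_h=DT)


class TestPhaseMetrics:
    def test_constant_amplitude_is_sustained(self):
        pm = M.phase_metrics(cosine_trace(3.0, hours=48.0), dt_h=DT)
        assert pm.regime == "sustained"
        assert pm.gamma == pytest.approx(1.0, abs=0.01)

    def test_hand_computed_damping_ratio(self):
        # maxima 8, 4, 2, 1 -> successive ratios all 2 (after overshoot drop
        # the sequence must still halve, so prepend a 16-overshoot)
        t = np.arange(0.0, 40.0, DT)
        y = np.zeros_like(t)
        for center, height in [(4, 16.0), (12, 8.0), (20, 4.0), (28, 2.0), (36, 1.0)]:
            y += height * np.exp(-0.5 * ((t - center) / 1.0) ** 2)
        pm = M.phase_metrics(y, dt_h=DT, horizon_h=40.0)
        assert pm.gamma == pytest.approx(2.0, abs=0.05)
        assert pm.regime == "damped"

    def test_no_maxima_gives_equilibration_time(self):
        t = np.arange(0.0, 24.0, DT)
        y = 10.0 - 8.0 * np.exp(-t / 3.0)
        pm = M.phase_metrics(y, dt_h=DT)
        assert pm.regime == "overdamped"
        assert pm.tau_eq_h == pytest.approx(3.0, rel=0.05)

    def test_flat_trace_overdamped_with_undefined_tau(self):
        pm = M.phase_metrics(np.full(96, 2.0), dt_h=DT)
        assert pm.regime == "overdamped"
        assert pm.tau_eq_h is None

    def test_regime_stable_under_sampling_phase_shift(self):
        regimes = {M.phase_metrics(cosine_trace(3.0, hours=48.0, phase=ph),
                                   dt_h=DT).regime
                   for ph in (0.0, 0.1, 0.2, 0.3)}
        assert regimes == {"sustained"}

    def test_expression_strength_and_dilution_favor_sustained(self, free_preset):
        """Qualitative phase-diagram structure on a small (α, R) grid."""
        from dataclasses import replace

        from zeitgeber import run_reactor

        params, proto = free_preset

        def regime(alpha, R):
            p = replace(params, alpha_a=alpha, alpha_h=alpha)
            return M.phase_metrics(
                run_reactor(p, replace(proto, R=R)), "a").regime

        assert regime(3.0, 0.25) == "sustained"
        assert regime(3.0, 0.1) == "damped"       # lower δ: damped
        assert regime(0.3, 0.25) == "overdamped"  # lower α: overdamped


class TestReturnMap:
    def test_pairs_in_order(self):
        pairs = M.return_map([3.0, 7.0, 3.0, 7.0])
        assert pairs.tolist() == [[3.0, 7.0], [7.0, 3.0], [3.0, 7.0]]

    def test_cycle_point_counts(self):
        from zeitgeber.bifurcation import count_return_points

        assert count_return_points(M.return_map([5.0] * 6)) == 1
        assert count_return_points(M.return_map([3.0, 7.0] * 5)) == 2

    def test_too_few_maxima(self):
        with pytest.raises(ParameterError):
            M.return_map([5.0])


class TestInstantaneousRefresh:
    def test_exact_geometric_decay(self):
        I = 100.0 * 0.8 ** np.arange(10)
        series = M.instantaneous_refresh(I, dt_h=DT, frac_threshold=0.0)
        assert np.allclose(series.R_t, 0.2)
        assert series.summary(0.0, 100.0) == pytest.approx(0.2)

    def test_spike_pairs_flagged_and_excluded(self):
        decay = 100.0 * 0.75 ** np.arange(8)
        I = np.concatenate([decay, [100.0], 100.0 * 0.75 ** np.arange(1, 8)])
        series = M.instantaneous_refresh(I, dt_h=DT, frac_threshold=0.0)
        spike_pair = 7  # pair (I_7, I_8) spans the re-spike
        assert series.flagged[spike_pair]
        assert series.summary(0.0, 100.0) == pytest.approx(0.25, abs=1e-9)

    def test_threshold_masks_dim_tail(self):
        I = 100.0 * 0.5 ** np.arange(8)
        series = M.instantaneous_refresh(I, dt_h=DT)
        assert series.mask.sum() == 2  # only 100 and 50 exceed 0.3*100

    def test_fatigue_lowers_late_summary(self):
        from zeitgeber import ReactorProtocol
        from zeitgeber.synth import FatigueModel, generate_reference_trace

        proto = ReactorProtocol(R=0.20, n_cycles=192, input_species="repressor",
                                A_in=50.0, k=16, ref_spike=500.0)
        _, clean = generate_reference_trace(
            proto, NoiseModel(cv_mult=0.0, sigma_add=0.0, background_level=0.0),
            FatigueModel(onset_h=36.0, drop=0.01))
        series = M.instantaneous_refresh(clean, "ref")
        early = series.summary(0.0, 24.0)
        late = series.summary(36.0, 48.0)
        assert early - late == pytest.approx(0.01, abs=2e-3)


class TestIntensityNormalization:
    def make_record(self, I, B=10.0):
        return M.IntensityRecord(I=I, B=B, I0=110.0, B0=10.0,
                                 I_ref=210.0, B_ref=10.0,
                                 I0_ref=110.0, B0_ref=10.0)

    def test_reference_identity(self):
        rec = M.IntensityRecord(I=210.0, B=10.0, I0=110.0, B0=10.0,
                                I_ref=210.0, B_ref=10.0, I0_ref=110.0, B0_ref=10.0)
        assert M.normalize_intensity(rec) == pytest.approx(1.0)

    def test_linearity(self):
        c1 = M.normalize_intensity(self.make_record(60.0))
        c2 = M.normalize_intensity(self.make_record(110.0))
        assert c2 == pytest.approx(2.0 * c1)

    def test_degenerate_calibration_rejected(self):
        rec = M.IntensityRecord(I=1.0, B=0.0, I0=5.0, B0=5.0,
                                I_ref=2.0, B_ref=1.0, I0_ref=2.0, B0_ref=1.0)
        with pytest.raises(CalibrationError):
            M.normalize_intensity(rec)


class TestHillFit:
    def test_noiseless_recovery(self):
        x, y = generate_titration("repression", 2.2, 2.1,
                                  np.geomspace(0.1, 50.0, 10),
                                  response_sigma=0.0)
        fit = M.fit_hill(x, y, "repression")
        assert fit.K == pytest.approx(2.2, rel=1e-4)
        assert fit.n == pytest.approx(2.1, rel=1e-4)

    def test_noisy_estimates_match_reported_precision(self):
        """Calibrated titration noise: the activation-curve parameters land
        within ±6 nM and ±0.6 of truth in at least 90 of 100 replicates."""
        grid = np.geomspace(5.0, 2000.0, 12)
        hits = 0
        for seed in range(100):
            x, y = generate_titration("activation", 115.0, 3.4, grid,
                                      NoiseModel(cv_mult=0.0, seed=seed),
                                      response_sigma=0.02)
            try:
                fit = M.fit_hill(x, y, "activation")
            except EstimationError:
                continue
            hits += (abs(fit.K - 115.0) <= 6.0 and abs(fit.n - 3.4) <= 0.6)
        assert hits >= 90

    def test_single_point_unidentifiable(self):
        with pytest.raises((EstimationError, ParameterError)):
            M.fit_hill([10.0], [0.5], "activation")

    def test_grid_below_transition_unidentifiable(self):
        x, y = generate_titration("activation", 115.0, 3.4,
                                  np.linspace(0.5, 10.0, 8),
                                  response_sigma=0.0)
        with pytest.raises(EstimationError):
            M.fit_hill(x, y, "activation")


class TestPeriodScalingFit:
    def test_exact_scaling_recovers_unit_slope(self):
        deltas = np.array([2e-4, 3e-4, 4e-4])
        estimates = [M.PeriodEstimate(np.pi / d / 3600.0, "acf",
                                      np.pi / d / 3600.0, 10,
                                      np.pi / d / 36000.0) for d in deltas]
        assert M.fit_period_scaling(deltas, estimates) == pytest.approx(1.0)

    def test_requires_two_points(self):
        with pytest.raises(EstimationError):
            M.fit_period_scaling([3e-4], [None])
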