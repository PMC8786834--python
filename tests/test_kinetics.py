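"""Two-site exchange model and kPL estimators."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from hpmri import (
    BolusInput,
    KineticParams,
    TimeSeriesPair,
    fit_kpl_frequency_domain,
    fit_kpl_time_domain,
    solve_two_site,
)
from hpmri.kinetics import UnidentifiableFitError

from conftest import make_series


def gamma_pyruvate(t, rho_p=0.05):
    """Smooth pyruvate curve: gamma-variate bolus through exponential decay."""
    return solve_two_site(KineticParams(1.0, rho_p), BolusInput()(t), t)


class TestSolveTwoSite:
    def test_zero_kpl_gives_zero_lactate(self):
        t = np.arange(20) * 4.0
        L = solve_two_site(KineticParams(0.0, 0.03), gamma_pyruvate(t), t)
        assert np.all(L == 0.0)

    def test_impulse_with_zero_decay_integrates_to_constant(self):
        # with rho_eff = 0, L(t) = kpl * cumulative trapezoid of P
        t = np.arange(10) * 2.0
        P = np.zeros(10)
        P[0] = 1.0
        L = solve_two_site(KineticParams(0.05, 0.0), P, t)
        area = np.trapezoid(P, t)
        assert np.allclose(L[1:], 0.05 * area)

    def test_matches_stiff_ode_solver(self):
        # fine grid so the trapezoidal accumulation resolves the kinetics
        t = np.arange(0, 80.0, 0.1)
        P = gamma_pyruvate(t)
        kpl, rho = 0.02, 0.03
        L = solve_two_site(KineticParams(kpl, rho), P, t)

        def rhs(ti, y):
            return [kpl * np.interp(ti, t, P) - rho * y[0]]

        sol = solve_ivp(rhs, (t[0], t[-1]), [0.0], t_eval=t, method="LSODA",
                        rtol=1e-9, atol=1e-12)
        ref = sol.y[0]
        scale = np.abs(ref).max()
        assert np.allclose(L, ref, rtol=1e-4, atol=1e-4 * scale)

    def test_rejects_non_uniform_grid(self):
        with pytest.raises(ValueError, match="uniform"):
            solve_two_site(KineticParams(0.01, 0.0), np.ones(4), np.array([0.0, 1.0, 3.0, 7.0]))


class TestFrequencyDomainFit:
    def test_zero_lactate_returns_zero_rates(self):
        t = np.arange(20) * 4.0
        pair = TimeSeriesPair(t, gamma_pyruvate(t), np.zeros(20))
        params, diag = fit_kpl_frequency_domain(pair)
        assert params.kpl == 0.0 and params.rho_eff == 0.0
        assert diag.residual_norm == 0.0

    @pytest.mark.parametrize("kpl", [0.003, 0.009, 0.015, 0.018])
    @pytest.mark.parametrize("rho", [0.02, 0.03, 0.05])
    def test_noiseless_recovery_within_5_percent(self, kpl, rho):
        t = np.arange(20) * 4.0
        P = gamma_pyruvate(t)
        L = solve_two_site(KineticParams(kpl, rho), P, t)
        params, _ = fit_kpl_frequency_domain(TimeSeriesPair(t, P, L))
        assert params.kpl == pytest.approx(kpl, rel=0.05)

    def test_zero_pyruvate_is_unidentifiable(self):
        t = np.arange(20) * 4.0
        with pytest.raises(UnidentifiableFitError):
            fit_kpl_frequency_domain(TimeSeriesPair(t, np.zeros(20), np.ones(20)))

    def test_scale_invariance(self, center_voxel_pair):
        p1, _ = fit_kpl_frequency_domain(center_voxel_pair)
        scaled = TimeSeriesPair(
            center_voxel_pair.times,
            1e3 * center_voxel_pair.pyruvate,
            1e3 * center_voxel_pair.lactate,
        )
        p2, _ = fit_kpl_frequency_domain(scaled)
        assert p2.kpl == pytest.approx(p1.kpl, rel=1e-9)
        assert p2.rho_eff == pytest.approx(p1.rho_eff, rel=1e-9)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            TimeSeriesPair(np.arange(3) * 4.0, np.ones(3), np.ones(3))


class TestTimeDomainFit:
    def test_noiseless_self_consistent_recovery(self):
        # pair generated by the same forward model on the same grid: the
        # nonlinear fit recovers the generating parameters near-exactly
        t = np.arange(20) * 4.0
        P = gamma_pyruvate(t)
        L = solve_two_site(KineticParams(0.012, 0.04), P, t)
        td, diag = fit_kpl_time_domain(TimeSeriesPair(t, P, L))
        assert diag.converged
        assert td.kpl == pytest.approx(0.012, rel=1e-3)
        assert td.rho_eff == pytest.approx(0.04, rel=1e-3)

    def test_cross_method_agreement_on_simulated_voxel(self, center_voxel_pair):
        td, _ = fit_kpl_time_domain(center_voxel_pair)
        fd, _ = fit_kpl_frequency_domain(center_voxel_pair)
        assert fd.kpl == pytest.approx(td.kpl, rel=0.10)
        assert td.kpl == pytest.approx(0.015, rel=0.02)

    def test_zero_lactate_returns_zero(self):
        t = np.arange(20) * 4.0
        params, _ = fit_kpl_time_domain(TimeSeriesPair(t, gamma_pyruvate(t), np.zeros(20)))
        assert params.kpl == 0.0

    def test_estimators_converge_with_finer_sampling(self):
        gaps = []
        for n_frames, dt in ((20, 4.0), (80, 1.0)):
            from hpmri import AcquisitionSchedule

            sch = AcquisitionSchedule(n_frames=n_frames, frame_interval=dt)
            s = make_series(0.015, schedule=sch)
            c = sch.matrix[0] // 2
            pair = TimeSeriesPair(s.times, s.signal[c, c, :, 0], s.signal[c, c, :, 1])
            fd, _ = fit_kpl_frequency_domain(pair)
            td, _ = fit_kpl_time_domain(pair)
            gaps.append(abs(fd.kpl - td.kpl) / td.kpl)
        assert gaps[1] < gaps[0]


@pytest.fixture(scope="module")
def noisy_pairs(single_lesion_series):
    s = single_lesion_series
    P, L = s.signal[16, 16, :, 0], s.signal[16, 16, :, 1]
    sigma = P.max() / (30 * np.sqrt(2))
    pairs = []
    for seed in range(200):
        g = np.random.default_rng(seed).standard_normal((2, 2, P.size)) * sigma
        pairs.append(
            TimeSeriesPair(s.times, np.hypot(P + g[0, 0], g[1, 0]), np.hypot(L + g[0, 1], g[1, 1]))
        )
    return pairs


class TestNoisyRecovery:
    """Parameter recovery under Rician noise at peak-pyruvate SNR ~ 30.

    The time-domain estimator is median-unbiased at this noise level; the
    frequency-domain linearisation carries a known attenuation (noise in
    the lactate transform enters the regressors), which is asserted as a
    documented negative bias rather than hidden.
    """

    def test_time_domain_median_within_15_percent(self, noisy_pairs):
        ks = np.array([fit_kpl_time_domain(p)[0].kpl for p in noisy_pairs])
        assert np.median(ks) == pytest.approx(0.015, rel=0.15)

    def test_frequency_domain_attenuation_is_negative_bias(self, noisy_pairs):
        with pytest.warns(UserWarning):
            ks = np.array([fit_kpl_frequency_domain(p)[0].kpl for p in noisy_pairs])
        assert np.median(ks) < 0.015  # documented attenuation at low lactate SNR
        assert np.median(ks) > 0.0

    def test_negative_solutions_are_clipped_with_warning(self):
        t = np.arange(20) * 4.0
        P = gamma_pyruvate(t)
        rng = np.random.default_rng(7)
        # lactate that is pure noise provokes negative unconstrained estimates
        L = np.abs(rng.standard_normal(20)) * 1e-3
        with pytest.warns(UserWarning, match="clipped"):
            for _ in range(20):
                params, diag = fit_kpl_frequency_domain(
                    TimeSeriesPair(t, P, rng.permutation(L))
                )
                if diag.clipped:
                    break
        assert params.kpl >= 0.0 and params.rho_eff >= 0.0
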