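"""Round-trip, uncertainty, and model-comparison tests for the fitting module."""

import warnings

import numpy as np
import pytest
from scipy import stats

from dktime import fitting as fit
from dktime import models as m
from dktime.errors import DomainError, InsufficientDataError
from dktime.models import DecayCurve


def make_series(td, D, K, species="water"):
    return m.CumulantSeries.from_arrays(td, D, K, species=species)


class TestCaic:
    def test_reference_value(self):
        assert fit.caic(6.0, 6, 2) == pytest.approx(8.0)

    def test_log_identity_in_rss(self):
        assert fit.caic(12.0, 6, 2) - fit.caic(6.0, 6, 2) == pytest.approx(6 * np.log(2.0))

    def test_penalty_monotone_in_k(self):
        assert fit.caic(6.0, 6, 3) > fit.caic(6.0, 6, 2)

    def test_undefined_cases(self):
        with pytest.raises(DomainError):
            fit.caic(1.0, 4, 3)
        with pytest.raises(DomainError):
            fit.caic(0.0, 6, 2)


class TestCumulantFit:
    def test_noiseless_round_trip(self, water_grid):
        _, b = water_grid
        S = m.kurtosis_signal(b, 0.6, 0.5)
        cp = fit.fit_cumulant(DecayCurve("s1", "water", 100.0, b, S))
        assert cp.D == pytest.approx(0.6, abs=1e-8)
        assert cp.K == pytest.approx(0.5, abs=1e-8)

    def test_monoexponential_degenerate(self, water_grid):
        _, b = water_grid
        S = m.kurtosis_signal(b, 0.6, 0.0)
        cp = fit.fit_cumulant(DecayCurve("s1", "water", 100.0, b, S))
        assert cp.K == pytest.approx(0.0, abs=1e-6)

    def test_insufficient_b_values(self):
        b = np.array([0.0, 1.0, 2.0])
        with pytest.raises(InsufficientDataError):
            fit.fit_cumulant(DecayCurve("s1", "water", 100.0, b, np.exp(-b)))

    def test_mean_bias_small_at_low_noise(self, water_grid, rng):
        # sigma = 0.5% of S0: mean bias of D-hat below 1% of truth
        _, b = water_grid
        S = m.kurtosis_signal(b, 0.6, 0.6)
        est = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(200):
                noisy = S + rng.normal(0.0, 0.005, b.size)
                est.append(fit.fit_cumulant(DecayCurve("s", "w", 100.0, b, noisy)).D)
        assert abs(np.mean(est) - 0.6) < 0.01 * 0.6

    def test_coverage_at_snr50(self, water_grid, rng):
        # nominal 95% t-intervals cover the truth in >= 85% of 200 replicates
        _, b = water_grid
        Dt, Kt = 0.6, 0.6
        S = m.kurtosis_signal(b, Dt, Kt)
        tq = stats.t.ppf(0.975, b.size - 3)
        hitD = hitK = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(200):
                noisy = S + rng.normal(0.0, 0.02, b.size)
                cp = fit.fit_cumulant(DecayCurve("s", "w", 100.0, b, noisy))
                hitD += abs(cp.D - Dt) <= tq * cp.D_se
                hitK += abs(cp.K - Kt) <= tq * cp.K_se
        assert hitD / 200 >= 0.85
        assert hitK / 200 >= 0.85


class TestPowerLawFits:
    def test_fixed_theta_round_trip_and_xi(self, water_grid):
        td, _ = water_grid
        D = m.powerlaw_value(td, m.PowerLawParams(0.5, 0.5, 0.5))
        K = m.powerlaw_value(td, m.PowerLawParams(0.25, 1.0, 0.5))
        fd, fk = fit.fit_powerlaw_fixed_theta(make_series(td, D, K), 0.5)
        assert fd.params["X_inf"] == pytest.approx(0.5, abs=1e-6)
        assert fd.params["C"] == pytest.approx(0.5, abs=1e-6)
        assert fk.params["X_inf"] == pytest.approx(0.25, abs=1e-6)
        assert fk.params["C"] == pytest.approx(1.0, abs=1e-6)
        # xi = C_K D_inf / C_D = 1.0 * 0.5 / 0.5 = 1
        assert fk.derived["xi"] == pytest.approx(1.0, abs=1e-6)

    def test_constant_series_zero_amplitude(self, water_grid):
        td, _ = water_grid
        fd, _ = fit.fit_powerlaw_fixed_theta(
            make_series(td, np.full_like(td, 0.5), np.full_like(td, 0.2)), 0.5
        )
        assert fd.params["C"] == pytest.approx(0.0, abs=1e-10)

    def test_wrong_theta_has_higher_caic(self, water_grid, rng):
        td, _ = water_grid
        D = m.powerlaw_value(td, m.PowerLawParams(0.5, 0.5, 0.5))
        K = m.powerlaw_value(td, m.PowerLawParams(0.25, 1.0, 0.5))
        s = make_series(td, D * (1 + rng.normal(0, 0.002, td.size)),
                        K * (1 + rng.normal(0, 0.002, td.size)))
        d05, k05 = fit.fit_powerlaw_fixed_theta(s, 0.5)
        d10, k10 = fit.fit_powerlaw_fixed_theta(s, 1.0)
        assert d05.caic + k05.caic < d10.caic + k10.caic

    def test_free_theta_round_trip(self, water_grid):
        td, _ = water_grid
        D = m.powerlaw_value(td, m.PowerLawParams(0.5, 0.5, 0.5))
        K = m.powerlaw_value(td, m.PowerLawParams(0.25, 1.0, 0.5))
        fj = fit.fit_powerlaw_free_theta(make_series(td, D, K))
        assert fj.params["theta"] == pytest.approx(0.5, abs=1e-6)
        assert fj.params["D_inf"] == pytest.approx(0.5, abs=1e-6)
        assert fj.derived["xi"] == pytest.approx(1.0, abs=1e-5)

    def test_free_theta_misspecified_intermediate(self, water_grid):
        # different true exponents for D and K: shared theta lands in between
        td, _ = water_grid
        D = m.powerlaw_value(td, m.PowerLawParams(0.5, 0.5, 0.3))
        K = m.powerlaw_value(td, m.PowerLawParams(0.25, 1.0, 0.9))
        fj = fit.fit_powerlaw_free_theta(make_series(td, D, K))
        assert 0.3 < fj.params["theta"] < 0.9
        assert fj.rss > 1e-8  # visibly elevated vs the separate-exponent truth


class TestLogSingularityFit:
    def test_round_trip(self, water_grid):
        td, _ = water_grid
        y = m.log_singularity_value(td, m.LogSingularityParams(1.0, 0.3, 5.0))
        s = make_series(td, np.full_like(td, 0.5), y)
        f = fit.fit_log_singularity(s, component="K")
        assert f.params["A"] == pytest.approx(1.0, abs=1e-4)
        assert f.params["tc"] == pytest.approx(5.0, abs=1e-3)
        assert f.params["B"] == pytest.approx(0.3, abs=1e-4)

    def test_constant_data(self, water_grid):
        td, _ = water_grid
        s = make_series(td, np.full_like(td, 0.5), np.full_like(td, 0.7))
        f = fit.fit_log_singularity(s, component="K")
        assert f.params["A"] == pytest.approx(0.0, abs=1e-8)
        assert f.params["B"] == pytest.approx(0.7, abs=1e-8)

    def test_comparable_caic_for_theta05_truth(self, water_grid, rng):
        # a theta=0.5 power law is approximated well: cAIC difference modest
        td, _ = water_grid
        K = m.powerlaw_value(td, m.PowerLawParams(0.25, 1.0, 0.5))
        s = make_series(td, np.full_like(td, 0.5),
                        K * (1 + rng.normal(0, 0.01, td.size)))
        f_log = fit.fit_log_singularity(s, component="K")
        _, f_pl = fit.fit_powerlaw_fixed_theta(s, 0.5)
        assert abs(f_log.caic - f_pl.caic) < 10.0


class TestKargerFit:
    def test_eq5_round_trip(self):
        td = np.array([42.5, 100.0, 250.0, 500.0])
        K = m.karger_kurtosis(td, m.KargerParams(1.2, 100.0))
        f = fit.fit_karger(make_series(td, np.full_like(td, 0.5), K), variant="eq5")
        assert f.params["K0"] == pytest.approx(1.2, rel=1e-6)
        assert f.params["tex"] == pytest.approx(100.0, rel=1e-6)

    def test_eq6_round_trip(self, water_grid):
        td, _ = water_grid
        K = m.karger_kurtosis(td, m.KargerParams(1.2, 100.0, 0.3))
        f = fit.fit_karger(make_series(td, np.full_like(td, 0.5), K),
                           variant="eq6", td_min=20.0)
        assert f.params["K0"] == pytest.approx(1.2, rel=1e-5)
        assert f.params["tex"] == pytest.approx(100.0, rel=1e-5)
        assert f.params["K_inf"] == pytest.approx(0.3, rel=1e-5)

    def test_eq5_misfit_of_offset_truth(self, water_grid, rng):
        # K_inf = 0.3 truth fitted with the offset-free variant: biased tex, worse cAIC
        td, _ = water_grid
        K = m.karger_kurtosis(td, m.KargerParams(1.2, 100.0, 0.3))
        s = make_series(td, np.full_like(td, 0.5), K * (1 + rng.normal(0, 0.005, td.size)))
        f5 = fit.fit_karger(s, variant="eq5", td_min=20.0)
        f6 = fit.fit_karger(s, variant="eq6", td_min=20.0)
        assert f5.params["tex"] > 150.0
        assert f6.caic < f5.caic

    def test_constant_series_flagged(self):
        td = np.array([42.5, 100.0, 250.0, 500.0])
        f = fit.fit_karger(make_series(td, np.full_like(td, 0.5),
                                       np.full_like(td, 0.8)), variant="eq5")
        assert "unidentifiable:tex" in f.flags

    def test_td_window_filtering(self, water_grid):
        td, _ = water_grid
        K = m.karger_kurtosis(td, m.KargerParams(1.2, 100.0))
        f = fit.fit_karger(make_series(td, np.full_like(td, 0.5), K), variant="eq5")
        assert f.n_obs == 4  # only td >= 42.5 ms enter

    def test_too_few_points(self):
        td = np.array([100.0, 250.0, 500.0])
        with pytest.raises(InsufficientDataError):
            fit.fit_karger(make_series(td, np.full_like(td, 0.5),
                                       np.full_like(td, 0.5)), variant="eq6")


class TestNexiFit:
    def test_noiseless_round_trip(self, water_grid):
        td, _ = water_grid
        proto = m.Protocol(diffusion_times=tuple(td),
                           b_values=(0.2, 0.7, 1.2, 2.0, 2.5, 4.0, 6.0), delta=3.0)
        b = np.array(proto.b_values)
        B = np.broadcast_to(b, (td.size, b.size))
        T = np.broadcast_to(td[:, None], B.shape)
        truth = m.NexiParams(0.64, 1.56, 0.75, 10.0)
        S = m.nexi_signal(B, T, truth)
        f = fit.fit_nexi(S, proto)
        assert f.params["f"] == pytest.approx(0.64, rel=1e-4)
        assert f.params["Di"] == pytest.approx(1.56, rel=1e-4)
        assert f.params["De"] == pytest.approx(0.75, rel=1e-4)
        assert f.params["tex"] == pytest.approx(10.0, rel=1e-4)

    def test_no_exchange_truth_flagged(self, water_grid):
        td = np.array([42.5, 100.0, 250.0, 500.0])
        proto = m.Protocol(diffusion_times=tuple(td),
                           b_values=(0.2, 1.0, 2.0, 3.2, 4.5, 6.0), delta=3.0)
        b = np.array(proto.b_values)
        B = np.broadcast_to(b, (td.size, b.size))
        T = np.broadcast_to(td[:, None], B.shape)
        S = m.nexi_signal(B, T, m.NexiParams(0.5, 2.0, 0.8, 1.0e6))
        f = fit.fit_nexi(S, proto)
        assert "unidentifiable:exchange" in f.flags
        assert f.params["tex"] == pytest.approx(1e3, rel=1e-3)  # upper bound


class TestGeometryFit:
    def test_noiseless_round_trip(self, metabolite_grid):
        td, _ = metabolite_grid
        truth = m.GeometryParams(5.0, 1.0, 0.5)
        s = m.geometry_model_series(td, truth)
        f = fit.fit_geometry(s)
        assert f.params["R_sphere"] == pytest.approx(5.0, rel=1e-2)
        assert f.params["R_cyl"] == pytest.approx(1.0, rel=1e-2)
        assert f.params["D0"] == pytest.approx(0.5, rel=1e-2)

    def test_sphere_radius_better_identified_than_cylinder(self, metabolite_grid, rng):
        # K SEM ~30%-style noise: relative error on R_sphere < on R_cyl
        td, _ = metabolite_grid
        truth = m.GeometryParams(5.0, 1.0, 0.5)
        s0 = m.geometry_model_series(td, truth)
        err_s, err_c = [], []
        for _ in range(5):
            s = m.CumulantSeries.from_arrays(
                td, s0.D * (1 + rng.normal(0, 0.05, td.size)),
                s0.K * (1 + rng.normal(0, 0.15, td.size)))
            f = fit.fit_geometry(s)
            err_s.append(abs(f.params["R_sphere"] - 5.0) / 5.0)
            err_c.append(abs(f.params["R_cyl"] - 1.0) / 1.0)
        assert np.median(err_s) < np.median(err_c)


class TestDeterminism:
    def test_repeat_fit_bit_identical(self, water_grid, rng):
        td, _ = water_grid
        D = m.powerlaw_value(td, m.PowerLawParams(0.5, 0.5, 0.5))
        K = m.powerlaw_value(td, m.PowerLawParams(0.25, 1.0, 0.5))
        s = make_series(td, D * (1 + rng.normal(0, 0.01, td.size)), K)
        f1 = fit.fit_powerlaw_free_theta(s)
        f2 = fit.fit_powerlaw_free_theta(s)
        assert f1.params == f2.params
        assert f1.rss == f2.rss
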