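"""Fluorescence-experiment fitting: titrations, transients, rate ratios."""

import numpy as np
import pytest

from darpflex.kinetics import (
    FitError,
    KineticTrace,
    NoTransitionError,
    TitrationDataset,
    consistency_check,
    fit_kobs_line,
    fit_monoexponential,
    fit_titration,
    rate_ratio_kd,
    read_titration_csv,
    read_trace_csv,
    write_titration_csv,
    write_trace_csv,
)
from darpflex.models import ode_oracle
from darpflex.synth import gen_association_series, gen_chase, gen_titration


class TestFitTitration:
    @pytest.mark.parametrize(
        "k_d,probe,rtol",
        [
            (127e-9, 100e-9, 1e-6),   # parent binder conditions
            (0.82e-9, 15e-9, 1e-4),   # strong-depletion (tight-binding) regime
        ],
    )
    def test_noiseless_recovery(self, k_d, probe, rtol):
        data = gen_titration(k_d, 1.0, probe, noise_sd=0.0, seed=5)
        fit = fit_titration(data)
        assert fit.converged
        assert fit.estimates["k_d"] == pytest.approx(k_d, rel=rtol)
        assert fit.estimates["fluo_max"] == pytest.approx(1.0, rel=rtol)

    def test_all_zero_signal_fails_gracefully(self):
        data = TitrationDataset(
            ligand_conc=np.linspace(0, 1e-6, 8),
            delta_fluo=np.zeros(8),
            probe_conc=100e-9,
        )
        fit = fit_titration(data)
        assert not fit.converged
        assert fit.warnings

    def test_point_order_invariance(self, rng):
        data = gen_titration(50e-9, 1.0, 30e-9, noise_sd=0.005, seed=7)
        fit1 = fit_titration(data)
        perm = rng.permutation(data.ligand_conc.size)
        shuffled = TitrationDataset(
            ligand_conc=data.ligand_conc[perm],
            delta_fluo=data.delta_fluo[perm],
            probe_conc=data.probe_conc,
        )
        fit2 = fit_titration(shuffled)
        assert fit2.estimates["k_d"] == pytest.approx(fit1.estimates["k_d"], rel=1e-6)

    def test_no_saturation_warning(self):
        # truncate the design well below saturation
        k_d = 100e-9
        conc = np.linspace(1e-9, 30e-9, 8)
        data = gen_titration(k_d, 1.0, 10e-9, ligand_conc=conc, seed=1)
        fit = fit_titration(data)
        assert any("saturation" in w for w in fit.warnings)


class TestFitMonoexponential:
    def test_exact_decay_recovery(self):
        trace = gen_chase(1.49, noise_sd=0.0, seed=3)
        fit = fit_monoexponential(trace, "decay")
        assert fit.estimates["k_obs"] == pytest.approx(1.49, rel=1e-8)

    def test_constant_trace_raises_no_transition(self):
        trace = KineticTrace(time=np.linspace(0, 5, 50), signal=np.full(50, 2.0))
        with pytest.raises(NoTransitionError):
            fit_monoexponential(trace, "decay")

    def test_rise_decay_time_reversal_symmetry(self):
        # a rise observed through a mirrored clock is the matching decay
        k = 0.5
        t = np.linspace(0, 12, 120)
        rise = KineticTrace(time=t, signal=1.0 - np.exp(-k * t))
        fit_rise = fit_monoexponential(rise, "rise")
        decay = KineticTrace(time=t, signal=np.exp(-k * t))
        fit_decay = fit_monoexponential(decay, "decay")
        assert fit_rise.estimates["k_obs"] == pytest.approx(
            fit_decay.estimates["k_obs"], rel=1e-9
        )

    def test_short_window_warns(self):
        k = 0.1
        t = np.linspace(0, 5.0, 40)  # 0.5 half-lives
        trace = KineticTrace(time=t, signal=np.exp(-k * t))
        fit = fit_monoexponential(trace, "decay")
        assert any("half-lives" in w for w in fit.warnings)

    def test_ode_association_trace_pseudo_first_order(self):
        # 10-fold ligand excess: fitted k_obs within 5% of k_on[T] + k_off
        k_on, k_off, probe = 1.3e7, 1.49, 50e-9
        ligand = 10 * probe
        k_obs_expected = k_on * ligand + k_off
        t = np.linspace(1e-4, 5.0 / k_obs_expected, 150)
        traj = ode_oracle(k_on, k_off, probe, ligand, t)
        trace = KineticTrace(time=t, signal=traj.complex / probe)
        fit = fit_monoexponential(trace, "rise")
        assert fit.estimates["k_obs"] == pytest.approx(k_obs_expected, rel=0.05)


class TestKobsLine:
    def test_exact_line_from_parent_constants(self):
        # k_obs grid for 0.25..4 uM at k_on 1.30e7, k_off 1.49
        concs = np.array([0.25e-6, 0.5e-6, 1e-6, 2e-6, 4e-6])
        kobs = 1.30e7 * concs + 1.49
        assert np.allclose(kobs, [4.74, 7.99, 14.49, 27.49, 53.49])
        fit = fit_kobs_line(list(zip(concs, kobs)))
        assert fit.estimates["k_on"] == pytest.approx(1.30e7, rel=1e-12)
        assert fit.estimates["intercept"] == pytest.approx(1.49, rel=1e-9)

    def test_two_points_rejected(self):
        with pytest.raises(FitError):
            fit_kobs_line([(1e-6, 10.0), (2e-6, 20.0)])

    def test_negative_slope_rejected(self):
        with pytest.raises(FitError):
            fit_kobs_line([(1e-6, 30.0), (2e-6, 20.0), (3e-6, 10.0)])

    def test_weighted_fit_downweights_outlier(self):
        concs = np.array([0.5e-6, 1e-6, 2e-6, 4e-6, 8e-6])
        kobs = 1.3e7 * concs + 1.5
        kobs_bad = kobs.copy()
        kobs_bad[2] *= 10.0  # gross outlier
        ses = np.full_like(concs, 0.05)
        ses[2] = 50.0  # with an honest (large) SE
        fit = fit_kobs_line(list(zip(concs, kobs_bad, ses)))
        assert fit.estimates["k_on"] == pytest.approx(1.3e7, rel=0.05)


class TestRateRatio:
    @pytest.mark.parametrize(
        "k_off,k_on,expected_nm",
        [
            (1.49, 1.30e7, 114.6),     # parent, fluorescence
            (0.0049, 1.82e7, 0.269),   # triple mutant, fluorescence
        ],
    )
    def test_published_pairs(self, k_off, k_on, expected_nm):
        k_d, _ = rate_ratio_kd(k_off, k_on)
        assert k_d * 1e9 == pytest.approx(expected_nm, rel=2e-3)

    def test_zero_ses_propagate_to_zero(self):
        _, se = rate_ratio_kd(1.0, 1e6, 0.0, 0.0)
        assert se == 0.0

    def test_se_propagation_first_order(self):
        k_d, se = rate_ratio_kd(2.0, 1e6, 0.2, 1e5)
        expected = k_d * np.sqrt((0.2 / 2.0) ** 2 + (1e5 / 1e6) ** 2)
        assert se == pytest.approx(expected, rel=1e-12)

    def test_unit_scale_consistency(self):
        # fitting in different unit systems and converting agrees exactly
        kd_si, _ = rate_ratio_kd(1.49, 1.30e7)
        kd_nm, _ = rate_ratio_kd(1.49, 1.30e7 * 1e-9)  # k_on per nM
        assert kd_si * 1e9 == pytest.approx(kd_nm, rel=1e-12)

    def test_invalid_kon_rejected(self):
        with pytest.raises(ValueError):
            rate_ratio_kd(1.0, 0.0)


class TestConsistency:
    def test_identical_values_pass(self):
        rep = consistency_check(1e-9, 1e-9)
        assert rep.ratio == pytest.approx(1.0)
        assert rep.passed

    def test_parent_titration_vs_kinetic(self):
        rep = consistency_check(127e-9, 114.6e-9)
        assert rep.ratio == pytest.approx(1.108, rel=1e-3)
        assert rep.passed

    def test_gross_disagreement_fails(self):
        rep = consistency_check(300e-9, 3e-9)
        assert rep.ratio == pytest.approx(100.0)
        assert not rep.passed


class TestCsvRoundTrip:
    def test_titration_round_trip(self):
        data = gen_titration(127e-9, 1.0, 100e-9, noise_sd=0.01, seed=9)
        back = read_titration_csv(write_titration_csv(data))
        assert np.array_equal(back.ligand_conc, data.ligand_conc)
        assert np.array_equal(back.delta_fluo, data.delta_fluo)
        assert back.probe_conc == data.probe_conc
        assert back.label == data.label

    def test_trace_round_trip(self):
        traces = gen_association_series(
            1.3e7, 1.49, 50e-9, np.array([0.5e-6, 1e-6, 2e-6]), noise_sd=0.01, seed=9
        )
        back = read_trace_csv(write_trace_csv(traces[0]))
        assert np.array_equal(back.time, traces[0].time)
        assert np.array_equal(back.signal, traces[0].signal)
        assert back.ligand_conc == traces[0].ligand_conc
        assert back.label == traces[0].label
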