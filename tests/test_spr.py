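"""1:1 Langmuir model, double referencing, global fits and Chi2 quality."""

import numpy as np
import pytest

from adc_target_vault import synth
from adc_target_vault.spr import (
    AlignmentError,
    DegenerateFitError,
    chi2,
    chi2_percent,
    double_reference,
    double_reference_series,
    fit_dissociation,
    fit_full_kinetics,
    model_association,
    model_dissociation,
)
from adc_target_vault.types import SensorgramCycle, ValidationError

from oracles import rk4_association

KA, KD_RATE = 3.68e5, 4e-4  # study-regime association/dissociation rates


class TestModels:
    def test_association_starts_at_r_init(self):
        assert model_association(0.0, KA, KD_RATE, 1e-8, 100.0) == 0.0
        assert model_association(0.0, KA, KD_RATE, 1e-8, 100.0, R_init=7.0) == 7.0

    def test_association_limit_at_kd_concentration_is_half_rmax(self):
        KD = KD_RATE / KA
        assert model_association(1e9, KA, KD_RATE, KD, 100.0) == pytest.approx(
            50.0, abs=1e-9)

    def test_association_agrees_with_rk4_integration(self):
        t = np.array([1.0, 10.0, 30.0, 60.0, 120.0])
        got = model_association(t, KA, KD_RATE, 62.5e-9, 100.0)
        expect = rk4_association(t, KA, KD_RATE, 62.5e-9, 100.0)
        np.testing.assert_allclose(got, expect, atol=1e-8)

    def test_dissociation_half_life(self):
        t_half = np.log(2) / KD_RATE  # ~1732.9 s at kd = 4e-4
        assert model_dissociation(t_half, KD_RATE, 80.0) == pytest.approx(40.0)

    def test_dissociation_slow_offrate_600s(self):
        # kd = 8e-5 1/s over 600 s decays by only exp(-0.048).
        assert model_dissociation(600.0, 8e-5, 1.0) == pytest.approx(
            np.exp(-0.048), rel=1e-12)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValidationError):
            model_association(1.0, -KA, KD_RATE, 1e-8, 100.0)
        with pytest.raises(ValidationError):
            model_dissociation(1.0, -1e-4, 10.0)


def _flat_cycle(cid, role, value=0.0, conc=0.0, blank=True, n=11):
    t = np.linspace(0, 10, n)
    r = np.full(n, value, dtype=float)
    return SensorgramCycle(cid, conc if not blank else 0.0, role, t, r, t, r,
                           is_blank=blank)


class TestDoubleReference:
    def test_identical_traces_cancel_to_zero(self):
        a = _flat_cycle("C1", "active", 5.0, conc=1e-8, blank=False)
        r = _flat_cycle("C1", "reference", 5.0, conc=1e-8, blank=False)
        ba = _flat_cycle("B", "active", 0.0)
        br = _flat_cycle("B", "reference", 0.0)
        out = double_reference(a, r, ba, br)
        assert np.all(out.r_assoc == 0) and np.all(out.r_dissoc == 0)

    def test_shared_linear_drift_cancels_exactly(self):
        t = np.linspace(0, 10, 21)
        drift = 0.7 * t + 3.0

        def cyc(cid, role, blank):
            return SensorgramCycle(cid, 0.0 if blank else 1e-8, role,
                                   t, drift.copy(), t, drift.copy(),
                                   is_blank=blank)

        out = double_reference(cyc("C1", "active", False),
                               cyc("C1", "reference", False),
                               cyc("B", "active", True),
                               cyc("B", "reference", True))
        np.testing.assert_allclose(out.r_assoc, 0.0, atol=1e-12)
        np.testing.assert_allclose(out.r_dissoc, 0.0, atol=1e-12)

    def test_simulator_artefacts_cancel_to_pure_model(self):
        cfg = synth.SimSensorgramConfig(
            seed=0, noise_sd=0.0, drift_slope=0.08, bulk_shift=30.0)
        corrected = double_reference_series(synth.simulate_sensorgram(cfg))
        for c in corrected:
            expect_a = model_association(c.t_assoc, cfg.ka, cfg.kd,
                                         c.concentration, cfg.Rmax)
            r0 = model_association(cfg.t_assoc, cfg.ka, cfg.kd,
                                   c.concentration, cfg.Rmax)
            expect_d = model_dissociation(c.t_dissoc, cfg.kd, float(r0))
            np.testing.assert_allclose(c.r_assoc, expect_a, atol=1e-9)
            np.testing.assert_allclose(c.r_dissoc, expect_d, atol=1e-9)

    def test_non_overlapping_time_ranges_raise(self):
        a = _flat_cycle("C1", "active", 1.0, conc=1e-8, blank=False)
        t2 = np.linspace(100, 110, 11)
        r = SensorgramCycle("C1", 1e-8, "reference", t2, np.zeros(11),
                            t2, np.zeros(11))
        with pytest.raises(AlignmentError):
            double_reference(a, r, _flat_cycle("B", "active"),
                             _flat_cycle("B", "reference"))


class TestChi2:
    def test_zero_residuals(self):
        assert chi2(np.zeros(10), 10, 2) == 0.0

    def test_dof_normalization(self):
        assert chi2([1, -1, 1, -1], 4, 2) == 2.0
        assert chi2([1, -1, 1, -1], 4, 2, normalize=False) == 4.0

    def test_underdetermined_rejected(self):
        with pytest.raises(ValidationError):
            chi2([1.0], 1, 1)

    def test_gaussian_residuals_estimate_variance(self):
        rng = np.random.default_rng(0)
        sigma = 1.3
        res = rng.normal(0, sigma, size=20000)
        c2 = chi2(res, res.size, 3)
        se = sigma**2 * np.sqrt(2 / res.size)
        assert abs(c2 - sigma**2) < 4 * se

    @pytest.mark.parametrize("c2,rmax,pct,high", [
        (2.0, 100.0, 2.0, True),
        (6.0, 100.0, 6.0, False),
        (0.0, 50.0, 0.0, True),
    ])
    def test_chi2_percent_rule(self, c2, rmax, pct, high):
        out = chi2_percent(c2, rmax)
        assert out.percent == pct and out.high_significance is high

    def test_chi2_percent_requires_positive_rmax(self):
        with pytest.raises(ValidationError):
            chi2_percent(1.0, 0.0)


def _noiseless_series(ka=KA, kd=KD_RATE, rmax=100.0, seed=0, noise=0.0):
    cfg = synth.SimSensorgramConfig(ka=ka, kd=kd, Rmax=rmax, seed=seed,
                                    noise_sd=noise, drift_slope=0.05,
                                    bulk_shift=20.0)
    return cfg, double_reference_series(synth.simulate_sensorgram(cfg))


class TestFullKinetics:
    def test_noiseless_recovery_to_1e6(self, noiseless_corrected):
        cfg, corrected = noiseless_corrected
        fit = fit_full_kinetics(corrected)
        assert fit.converged
        assert abs(fit.ka - cfg.ka) / cfg.ka < 1e-6
        assert abs(fit.kd - cfg.kd) / cfg.kd < 1e-6
        assert abs(fit.Rmax - cfg.Rmax) / cfg.Rmax < 1e-6
        assert fit.KD == fit.kd / fit.ka

    def test_slow_offrate_regime_recovery(self):
        # PCDHB10-like pair: ka 3.64e5 1/(M*s), kd at the slow end 8e-5 1/s.
        cfg, corrected = _noiseless_series(ka=3.64e5, kd=8e-5)
        fit = fit_full_kinetics(corrected)
        assert abs(fit.ka - 3.64e5) / 3.64e5 < 1e-6
        assert abs(fit.kd - 8e-5) / 8e-5 < 1e-6

    def test_kd_identity(self):
        assert 4e-4 / 3.68e5 == pytest.approx(1.087e-9, rel=1e-3)

    def test_response_scaling_leaves_rates_invariant(self, noiseless_corrected):
        cfg, corrected = noiseless_corrected
        scaled = [SensorgramCycle(c.cycle_id, c.concentration, c.role,
                                  c.t_assoc, 3.0 * c.r_assoc,
                                  c.t_dissoc, 3.0 * c.r_dissoc)
                  for c in corrected]
        base = fit_full_kinetics(corrected)
        fit = fit_full_kinetics(scaled)
        assert fit.ka == pytest.approx(base.ka, rel=1e-6)
        assert fit.kd == pytest.approx(base.kd, rel=1e-6)
        assert fit.Rmax == pytest.approx(3.0 * base.Rmax, rel=1e-6)

    def test_single_concentration_warns(self):
        cfg = synth.SimSensorgramConfig(concentrations=(5e-8,), seed=0)
        corrected = double_reference_series(synth.simulate_sensorgram(cfg))
        with pytest.warns(UserWarning, match="ill-posed"):
            fit_full_kinetics(corrected)

    def test_model_mismatch_raises_chi2_pct(self):
        """Data from a 2:1 heterogeneous surface fits 1:1 worse than 1:1 data."""
        cfg, corrected = _noiseless_series()
        good = fit_full_kinetics(corrected).chi2_pct
        hetero = []
        for c in corrected:
            # Second site: 10x slower off-rate, 40% of the surface.
            ra2 = 0.6 * c.r_assoc + 0.4 * np.asarray(model_association(
                c.t_assoc, cfg.ka, cfg.kd / 10, c.concentration, cfg.Rmax))
            r0_2 = model_association(cfg.t_assoc, cfg.ka, cfg.kd / 10,
                                     c.concentration, cfg.Rmax)
            rd2 = 0.6 * c.r_dissoc + 0.4 * np.asarray(model_dissociation(
                c.t_dissoc, cfg.kd / 10, float(r0_2)))
            hetero.append(SensorgramCycle(c.cycle_id, c.concentration, c.role,
                                          c.t_assoc, ra2, c.t_dissoc, rd2))
        bad = fit_full_kinetics(hetero).chi2_pct
        assert bad > good * 100


class TestDissociationFit:
    def test_noiseless_kd_recovery(self, noiseless_corrected):
        cfg, corrected = noiseless_corrected
        fit = fit_dissociation(corrected)
        assert fit.converged
        assert abs(fit.kd - cfg.kd) / cfg.kd < 1e-6

    def test_matches_full_fit_on_noiseless_data(self, noiseless_corrected):
        _, corrected = noiseless_corrected
        full = fit_full_kinetics(corrected)
        off = fit_dissociation(corrected, rmax_for_chi2=full.Rmax)
        assert abs(off.kd - full.kd) / full.kd < 1e-9
        assert off.rmax_source == "global_fit"

    def test_single_cycle_exact_exponential_chi2_zero(self):
        t = np.arange(0, 600.0, 1.0)
        r = 100.0 * np.exp(-KD_RATE * t)
        c = SensorgramCycle("C1", 5e-8, "active", [0, 1], [0, 0], t, r)
        fit = fit_dissociation([c], t_exclude=0.0)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-18)
        assert fit.kd == pytest.approx(KD_RATE, rel=1e-9)
        assert fit.rmax_source == "max_R0"

    def test_all_zero_traces_degenerate(self):
        t = np.arange(0, 10.0)
        z = np.zeros_like(t)
        c = SensorgramCycle("C1", 5e-8, "active", t, z, t, z)
        with pytest.raises(DegenerateFitError):
            fit_dissociation([c], t_exclude=0.0)

    def test_window_outside_data_rejected(self, noiseless_corrected):
        _, corrected = noiseless_corrected
        with pytest.raises(ValidationError, match="window"):
            fit_dissociation(corrected, window=(0.0, 1e5))
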