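"""Equilibrium models: normalization, saturation, 4PL, allosteric shift, Cheng-Prusoff."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moafit.equilibrium import (
    NormalizedCurve,
    allosteric_antag,
    cheng_prusoff,
    fit_allosteric_shift,
    fit_logistic4,
    fit_saturation,
    ki_to_ic50,
    logistic4,
    normalize_plate,
)


class TestNormalizePlate:
    def test_control_anchors_and_z_factor(self, example_plate):
        """Neutral mean -> 0%, inhibitor mean -> 100%; tight controls give Z' = 1."""
        plate = example_plate.copy()
        plate.loc[plate.index[-1], ["role", "signal"]] = ["sample", 6.0]
        curve = normalize_plate(plate)
        # the well moved to signal 6 sits midway between controls {10,10} and {2,2}
        assert curve.response[-1] == pytest.approx(50.0)
        assert curve.z_factor == pytest.approx(1.0)
        top = normalize_plate(example_plate)
        assert np.all(curve.response <= 100.0 + 1e-9)
        assert top.response.max() == pytest.approx(100.0 / 1.01, rel=1e-3)

    def test_identical_controls_rejected(self, example_plate):
        plate = example_plate.copy()
        plate.loc[plate["role"] == "inhibitor_control", "signal"] = 10.0
        with pytest.raises(ZeroDivisionError):
            normalize_plate(plate)

    def test_missing_control_class_rejected(self, example_plate):
        plate = example_plate[example_plate["role"] != "inhibitor_control"]
        with pytest.raises(ValueError, match="inhibitor_control"):
            normalize_plate(plate)

    def test_masked_wells_excluded(self, example_plate):
        plate = example_plate.copy()
        bad = plate.index[plate["role"] == "sample"][0]
        plate.loc[bad, ["signal", "masked"]] = [1e6, 1]
        curve = normalize_plate(plate)
        assert len(curve.doses) == 7
        assert np.all(np.abs(curve.response) < 200)

    @given(shift=st.floats(-50, 50), scale=st.floats(0.1, 20))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, shift, scale):
        """Adding a constant to or rescaling all raw signals leaves responses unchanged."""
        import pandas as pd

        rows = (
            [{"role": "neutral_control", "dose_M": np.nan, "signal": s} for s in (10.0, 10.4)]
            + [{"role": "inhibitor_control", "dose_M": np.nan, "signal": s} for s in (2.0, 2.2)]
            + [{"role": "sample", "compound_id": "c", "dose_M": d, "signal": s}
               for d, s in [(1e-9, 9.0), (1e-8, 6.0), (1e-7, 3.0)]]
        )
        plate = pd.DataFrame(rows)
        trans = plate.copy()
        trans["signal"] = trans["signal"] * scale + shift
        r0 = normalize_plate(plate, compound_id="c").response
        r1 = normalize_plate(trans, compound_id="c").response
        np.testing.assert_allclose(r1, r0, rtol=1e-9, atol=1e-9)


class TestSaturation:
    def test_noiseless_recovery_and_half_saturation(self):
        """Exact recovery of (Bmax, KD) at the probe's 1.1 nM affinity scenario."""
        kd, bmax = 1.1e-9, 1.0
        x = np.sort(2e-8 / 2.0 ** np.arange(12))
        fit = fit_saturation(x, bmax * x / (kd + x))
        assert fit.bmax == pytest.approx(bmax, rel=1e-6)
        assert fit.kd == pytest.approx(kd, rel=1e-6)
        # half-saturation identity at X = KD
        assert fit.bmax * kd / (fit.kd + kd) == pytest.approx(bmax / 2, rel=1e-6)

    def test_noisy_recovery_median(self):
        """1% multiplicative noise on a 12-point titration: median |KD err| < 5%."""
        kd, bmax = 1.1e-9, 1.0
        x = np.sort(2e-8 / 2.0 ** np.arange(12))
        errs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            y = bmax * x / (kd + x) * (1 + 0.01 * rng.standard_normal(x.shape))
            errs.append(abs(fit_saturation(x, y).kd / kd - 1.0))
        assert np.median(errs) < 0.05

    def test_depletion_flag(self):
        kd = 1.1e-9
        x = np.sort(2e-8 / 2.0 ** np.arange(8))
        y = x / (kd + x)
        assert fit_saturation(x, y, protein_conc=5e-10).ligand_depletion
        assert not fit_saturation(x, y, protein_conc=1e-11).ligand_depletion


class TestLogistic4:
    def test_noiseless_recovery_and_midpoint(self):
        doses = np.sort(1e-5 / 3.0 ** np.arange(10))
        y = logistic4(doses, 1e-7, 1.0, 100.0, 0.0)
        curve = NormalizedCurve(doses=doses, response=y)
        fit = fit_logistic4(curve)
        assert fit.ic50 == pytest.approx(1e-7, rel=1e-6)
        assert fit.hill == pytest.approx(1.0, rel=1e-6)
        assert fit.pic50 == pytest.approx(7.0, abs=1e-6)
        # dose = IC50 responds midway between Top and Bottom
        mid = logistic4(fit.ic50, fit.ic50, fit.hill, fit.top, fit.bottom)
        assert mid == pytest.approx((fit.top + fit.bottom) / 2, rel=1e-9)

    def test_mirrored_curves_same_potency(self):
        """Falling and rising conventions on mirrored data agree on |pIC50|."""
        doses = np.sort(1e-5 / 3.0 ** np.arange(10))
        rising = logistic4(doses, 1e-7, 1.2, 100.0, 0.0)
        fit_up = fit_logistic4(NormalizedCurve(doses=doses, response=rising))
        fit_dn = fit_logistic4(NormalizedCurve(doses=doses, response=100.0 - rising))
        assert abs(fit_dn.pic50) == pytest.approx(abs(fit_up.pic50), rel=1e-4)

    def test_shallow_curve_flagged_not_numeric(self):
        doses = np.sort(1e-5 / 3.0 ** np.arange(10))
        y = logistic4(doses, 1e-2, 1.0, 100.0, 0.0)  # IC50 far above range: <30% span
        fit = fit_logistic4(NormalizedCurve(doses=doses, response=y))
        assert not fit.determinable
        assert np.isnan(fit.ic50) and np.isnan(fit.pic50)

    def test_fixed_asymptotes(self):
        doses = np.sort(1e-5 / 3.0 ** np.arange(10))
        y = logistic4(doses, 1e-7, 1.0, 100.0, 0.0)
        fit = fit_logistic4(NormalizedCurve(doses=doses, response=y),
                            fix_top=100.0, fix_bottom=0.0, fix_hill=1.0)
        assert (fit.top, fit.bottom, fit.hill) == (100.0, 0.0, 1.0)
        assert fit.ic50 == pytest.approx(1e-7, rel=1e-8)


class TestAllostericShift:
    doses = np.sort(2e-8 / 2.0 ** np.arange(12))

    def _family(self, kb, alpha, noise_cv=0.0, seed=0, b_levels=(0.0, 1e-6, 3e-6, 1e-5)):
        rng = np.random.default_rng(seed)
        curves = []
        for B in b_levels:
            y = logistic4(self.doses, 1.1e-9 * allosteric_antag(B, kb, alpha),
                          1.0, 100.0, 0.0)
            y = y * (1 + noise_cv * rng.standard_normal(y.shape))
            curves.append(NormalizedCurve(doses=self.doses, response=y, modulator_conc=B))
        return curves

    def test_reduces_to_plain_logistic_at_b0(self):
        assert allosteric_antag(0.0, 2.1e-6, 2.75) == 1.0
        fit = fit_allosteric_shift(self._family(2.1e-6, 2.75))
        assert fit.apparent_ec50(0.0) == pytest.approx(fit.ec50)

    def test_kb_recovery_under_noise(self):
        """KB 2.1 µM scenario: median recovery error < 15% at 1% noise."""
        errs = []
        for seed in range(10):
            fit = fit_allosteric_shift(self._family(2.1e-6, 2.75, noise_cv=0.01, seed=seed))
            errs.append(abs(fit.kb / 2.1e-6 - 1.0))
        assert np.median(errs) < 0.15

    def test_apparent_ec50_monotone_with_limit(self):
        fit = fit_allosteric_shift(self._family(2.1e-6, 2.75))
        bs = np.logspace(-8, -2, 30)
        app = np.array([fit.apparent_ec50(b) for b in bs])
        assert np.all(np.diff(app) < 0)  # alpha > 1: potency strictly improves
        assert allosteric_antag(1e3, fit.kb, fit.alpha) == pytest.approx(
            1 / fit.alpha, rel=1e-3)

    def test_alpha_one_gives_no_shift_flag(self):
        fit = fit_allosteric_shift(self._family(2.1e-6, 1.0, noise_cv=0.005, seed=3))
        assert fit.no_shift_detected
        app = [fit.apparent_ec50(b) for b in (0.0, 1e-6, 1e-5)]
        assert np.ptp(app) / app[0] < 0.05


class TestChengPrusoff:
    def test_limits_and_arithmetic(self):
        assert cheng_prusoff(1e-8, 1e-15, 1e-9) == pytest.approx(1e-8, rel=1e-5)
        # probe at its own KD doubles the IC50
        assert cheng_prusoff(1e-8, 1e-9, 1e-9) == pytest.approx(5e-9)
        with pytest.raises(ValueError):
            cheng_prusoff(-1e-8, 1e-9, 1e-9)

    @given(ki=st.floats(1e-11, 1e-6), L=st.floats(1e-10, 1e-7), kd=st.floats(1e-10, 1e-7))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_identity(self, ki, L, kd):
        assert cheng_prusoff(ki_to_ic50(ki, L, kd), L, kd) == pytest.approx(ki, rel=1e-12)

    def test_forward_simulated_competition(self):
        """Exact-equilibrium ePCA data with true Ki 2.8 nM round-trips within 5%."""
        from moafit.synthetic import NOISELESS, EpcaDesign, simulate_epca_plate

        design = EpcaDesign()
        curve = simulate_epca_plate(2.8e-9, design=design, noise=NOISELESS)
        fit = fit_logistic4(curve)
        ki = cheng_prusoff(fit.ic50, design.probe_conc, design.probe_kd)
        assert ki == pytest.approx(2.8e-9, rel=0.05)
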