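"""Kinetic models: closed forms vs ODE oracles, global fits, derived tables."""

import numpy as np
import pytest

from moafit.kinetics import (
    CompoundKinetics,
    KineticTrace,
    assoc_dissoc_model,
    competition_ode_signal,
    fit_kpca,
    fit_probe_kinetics,
    koff_from_equilibrium,
    motulsky_mahan_signal,
    probe_ode_signal,
    rapid_table,
    single_trace_kobs,
)
from moafit.synthetic import (
    NOISELESS,
    NoiseModel,
    simulate_kpca_plate,
    simulate_probe_traces,
)

T600 = np.arange(0.0, 601.0, 10.0)


class TestAssocDissocModel:
    def test_boundary_plateau_continuity(self):
        y = assoc_dissoc_model(T600, 5e-9, 1e6, 1.1e-3, 1.0, t0=240.0)
        assert y[0] == 0.0
        # pre-chase plateau -> Bmax*L/(L+KD)
        eq = 1.0 * 5e-9 / (5e-9 + 1.1e-3 / 1e6)
        long_t = assoc_dissoc_model(np.array([1e6]), 5e-9, 1e6, 1.1e-3, 1.0)
        assert long_t[0] == pytest.approx(eq, rel=1e-12)
        # continuity at the chase boundary
        eps = 1e-9
        left = assoc_dissoc_model(np.array([240.0 - eps]), 5e-9, 1e6, 1.1e-3, 1.0, 240.0)
        right = assoc_dissoc_model(np.array([240.0 + eps]), 5e-9, 1e6, 1.1e-3, 1.0, 240.0)
        assert right[0] == pytest.approx(left[0], rel=1e-6)

    @pytest.mark.parametrize("k1", np.logspace(4, 7, 4))
    @pytest.mark.parametrize("k2", np.logspace(-4, -1, 4))
    def test_matches_ode_oracle(self, k1, k2):
        y_closed = assoc_dissoc_model(T600, 1e-8, k1, k2, 1.0, t0=300.0)
        y_ode = probe_ode_signal(T600, 1e-8, k1, k2, 1.0, t0=300.0)
        assert np.max(np.abs(y_closed - y_ode)) < 1e-8

    def test_rejects_negative_parameters(self):
        with pytest.raises(ValueError):
            assoc_dissoc_model(T600, 1e-8, -1e6, 1e-3, 1.0)


class TestMotulskyMahan:
    def test_reduces_to_association_at_zero_competitor(self):
        y_mm = motulsky_mahan_signal(T600, 1.5e-8, 0.0, 1e6, 1.1e-3, 1e5, 1e-2, 1.0)
        y_11 = assoc_dissoc_model(T600, 1.5e-8, 1e6, 1.1e-3, 1.0)
        np.testing.assert_allclose(y_mm, y_11, rtol=1e-12, atol=1e-15)

    def test_equilibrium_plateau_is_competition_isotherm(self):
        L, I = 1.5e-8, 2.5e-7
        k1, k2, k3, k4 = 1e6, 1.1e-3, 1e5, 1e-2
        kd_l, kd_i = k2 / k1, k4 / k3
        expected = 1.0 * (L / kd_l) / (1 + L / kd_l + I / kd_i)
        y = motulsky_mahan_signal(np.array([1e7]), L, I, k1, k2, k3, k4, 1.0)
        assert y[0] == pytest.approx(expected, rel=1e-9)

    def test_matches_ode_over_rate_grid(self):
        """Closed form vs coupled-ODE oracle within 1e-6*Bmax over 4 decades."""
        worst = 0.0
        for k3 in np.logspace(3, 7, 5):
            for k4 in np.logspace(-5, -1, 5):
                yc = motulsky_mahan_signal(T600, 1.5e-8, 2.5e-7, 1e6, 1.1e-3, k3, k4, 1.0)
                yo = competition_ode_signal(T600, 1.5e-8, 2.5e-7, 1e6, 1.1e-3, k3, k4, 1.0)
                worst = max(worst, float(np.max(np.abs(yc - yo))))
        assert worst < 1e-6

    def test_degenerate_repeated_root_continuous(self):
        """Near KF = KS the limit form joins the generic branch smoothly."""
        # I = 0 with k3*I + k4 == k1*L + k2 makes the roots collide
        k1, k2, L = 1e6, 1.1e-3, 1.5e-8
        k4 = k1 * L + k2
        y_deg = motulsky_mahan_signal(T600[1:], L, 0.0, k1, k2, 1e5, k4, 1.0)
        y_near = motulsky_mahan_signal(T600[1:], L, 0.0, k1, k2, 1e5, k4 * (1 + 1e-7), 1.0)
        np.testing.assert_allclose(y_deg, y_near, rtol=1e-5)
        y_ode = competition_ode_signal(T600[1:], L, 0.0, k1, k2, 1e5, k4, 1.0)
        np.testing.assert_allclose(y_deg, y_ode, rtol=1e-6, atol=1e-12)

    def test_monotone_rise_peak_bound_and_plateau_order(self):
        L, k1, k2 = 1.5e-8, 1e6, 1.1e-3
        t = np.linspace(0, 5000, 2000)
        peak_cap = 1.0 * L / (L + k2 / k1)
        plateaus = []
        for k4 in (1e-3, 1e-2, 1e-1):
            y = motulsky_mahan_signal(t, L, 2.5e-7, k1, k2, 1e5, k4, 1.0)
            ipeak = int(np.argmax(y))
            assert np.all(np.diff(y[: ipeak + 1]) >= -1e-12)  # monotone before peak
            assert y.max() <= peak_cap + 1e-9
            plateaus.append(y[-1])
        # a weaker competitor (larger k4) blocks less probe at equilibrium
        assert plateaus[0] < plateaus[1] < plateaus[2]


class TestProbeKinetics:
    def test_noiseless_global_recovery(self, probe):
        traces = simulate_probe_traces(probe, noise=NOISELESS)
        fit = fit_probe_kinetics(traces)
        assert fit.k1 == pytest.approx(probe.k1, rel=1e-5)
        assert fit.k2 == pytest.approx(probe.k2, rel=1e-5)
        assert fit.kd == pytest.approx(probe.kd, rel=1e-5)

    def test_kobs_regression_slope_intercept(self, probe):
        """Per-trace kobs regressed on L: slope = k1, intercept = k2."""
        traces = simulate_probe_traces(probe, noise=NOISELESS)
        L = np.array([tr.probe_conc for tr in traces])
        kobs = np.array([single_trace_kobs(tr) for tr in traces])
        slope, intercept = np.polyfit(L, kobs, 1)
        assert slope == pytest.approx(probe.k1, rel=0.01)
        assert intercept == pytest.approx(probe.k2, rel=0.05)

    def test_noisy_k2_recovery(self, probe):
        """2% noise, 8 concentrations: median relative k2 error < 10%."""
        errs = []
        for seed in range(15):
            traces = simulate_probe_traces(probe, noise=NoiseModel(cv=0.02), seed=seed)
            errs.append(abs(fit_probe_kinetics(traces).k2 / probe.k2 - 1))
        assert np.median(errs) < 0.10

    def test_short_dissociation_warns_wide_interval(self, probe):
        from moafit.synthetic import ProbeDesign

        design = ProbeDesign(chase_duration_s=60.0, chase_interval_s=10.0)
        traces = simulate_probe_traces(probe, design=design, noise=NOISELESS)
        fit = fit_probe_kinetics(traces)
        assert fit.k2_wide_interval  # 60 s << 0.5/k2 ~ 450 s


class TestFitKpca:
    def test_noiseless_exact_recovery(self, probe):
        fam = simulate_kpca_plate(1e5, 1e-2, probe, noise=NOISELESS, seed=0)
        ck = fit_kpca(fam, probe)
        assert ck.kon == pytest.approx(1e5, rel=1e-4)
        assert ck.koff == pytest.approx(1e-2, rel=1e-4)
        assert not ck.elusive_equilibrium

    def test_recovery_from_ode_generated_data(self, probe):
        """Fitting ODE-generated traces guards the closed form transcription."""
        fam = simulate_kpca_plate(1e6, 3e-3, probe, noise=NOISELESS, seed=0)
        ck = fit_kpca(fam, probe)
        assert ck.kon == pytest.approx(1e6, rel=1e-3)
        assert ck.koff == pytest.approx(3e-3, rel=1e-3)

    def test_slow_binder_flagged(self, probe):
        fam = simulate_kpca_plate(1e6, 1e-5, probe, noise=NOISELESS, seed=0)
        ck = fit_kpca(fam, probe)
        assert ck.elusive_equilibrium  # 1e-5 * 600 s << 0.1
        assert ck.koff_unreliable
        assert ck.kon == pytest.approx(1e6, rel=0.05)  # kon still informative

    def test_all_zero_competitor_rejected(self, probe):
        fam = simulate_kpca_plate(1e5, 1e-2, probe, noise=NOISELESS, seed=0)
        zeros = [tr for tr in fam if tr.competitor_conc == 0]
        with pytest.raises(ValueError, match="no competition"):
            fit_kpca(zeros, probe)


class TestDerived:
    def test_koff_from_equilibrium_product(self):
        ck = koff_from_equilibrium(1e5, 1e-9)
        assert ck.koff == pytest.approx(1e-4)
        assert ck.residence_time == pytest.approx(1e4)
        assert ck.koff_source == "equilibrium_product"

    def test_kinetic_identities(self):
        ck = CompoundKinetics(kon=2e5, koff=5e-3)
        assert ck.residence_time * ck.koff == pytest.approx(1.0, rel=1e-14)
        assert ck.kd * ck.kon == pytest.approx(ck.koff, rel=1e-14)

    def test_rapid_table_isoaffinity(self):
        panel = [
            CompoundKinetics(kon=1e6, koff=1e-3, compound_id="a", condition="apo"),
            CompoundKinetics(kon=1e4, koff=1e-5, compound_id="b", condition="apo"),
            CompoundKinetics(kon=1e6, koff=1e-3, compound_id="a", condition="peptide"),
        ]
        tab = rapid_table(panel)
        assert len(tab) == 3
        assert tab.loc[0, "log10_kd"] == pytest.approx(-9.0)
        same_kd = tab[np.isclose(tab["log10_kd"], -9.0)]
        # equal-KD points lie on a slope-1 diagonal in (log kon, log koff)
        d = same_kd["log10_koff"] - same_kd["log10_kon"]
        assert np.allclose(d, d.iloc[0])


class TestTraceValidation:
    def test_time_monotonicity_and_chase_bounds(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            KineticTrace(time=[0, 10, 10], signal=[0, 1, 1], probe_conc=1e-9)
        with pytest.raises(ValueError, match="chase_time"):
            KineticTrace(time=[0, 10, 20], signal=[0, 1, 1], probe_conc=1e-9,
                         chase_time=30.0)
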