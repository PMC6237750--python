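"""Burst / single-turnover / saturation fitting and fidelity arithmetic."""

import numpy as np
import pytest

from polb_landscape.kinetics import (
    FidelityTable,
    FitFailure,
    KineticsError,
    ProgressCurve,
    burst_model,
    fidelity_metrics,
    fit_burst,
    fit_saturation,
    fit_single_exponential,
    round_sig,
    x_fold,
)


class TestBurstModel:
    def test_zero_at_time_zero(self):
        assert burst_model(0.0, 100.0, 9.0, 1.2) == 0.0

    def test_amplitude_limit_without_steady_state(self):
        # k_ss = 0 reduces to E_app (1 - exp(-k_obs t))
        t = np.linspace(0, 5, 50)
        full = burst_model(t, 100.0, 9.0, 0.0)
        assert np.allclose(full, 100.0 * (1 - np.exp(-9.0 * t)))
        assert burst_model(10.0, 100.0, 9.0, 0.0) == pytest.approx(100.0, rel=1e-9)

    def test_steady_state_slope(self):
        E, ko, ks = 100.0, 9.0, 1.2
        t1, t2 = 20.0, 30.0
        slope = (burst_model(t2, E, ko, ks) - burst_model(t1, E, ko, ks)) / (t2 - t1)
        assert slope == pytest.approx(E * ko * ks / (ko + ks), rel=1e-9)

    def test_as_printed_differs_in_amplitude_only(self):
        t = np.linspace(0.01, 3, 20)
        std = burst_model(t, 100.0, 9.0, 1.2, form="standard")
        lit = burst_model(t, 100.0, 9.0, 1.2, form="as_printed")
        diff = std - lit
        # both share the linear term; the exponential amplitude differs by
        # the factor k_obs vs 1 in the numerator
        assert not np.allclose(std, lit)
        assert np.all(np.sign(diff[1:]) == np.sign(diff[1]))

    def test_negative_rates_rejected(self):
        with pytest.raises(KineticsError):
            burst_model(1.0, 100.0, -9.0, 1.2)


class TestFitBurst:
    def test_noise_free_recovery(self):
        t = np.geomspace(0.02, 3.0, 30)
        curve = ProgressCurve(t, burst_model(t, 100.0, 9.0, 1.2))
        fit = fit_burst(curve)
        assert fit.E_app == pytest.approx(100.0, rel=1e-3)
        assert fit.k_obs == pytest.approx(9.0, rel=1e-3)
        assert fit.k_ss == pytest.approx(1.2, rel=1e-3)

    def test_noisy_median_recovery(self):
        """3% amplitude noise, 50 replicates: median k_obs within 10%."""
        rng = np.random.default_rng(2024)
        t = np.geomspace(0.02, 3.0, 30)
        clean = burst_model(t, 100.0, 9.0, 1.2)
        recovered = []
        for _ in range(50):
            y = clean + rng.normal(0, 3.0, t.shape)
            try:
                recovered.append(fit_burst(ProgressCurve(t, y)).k_obs)
            except FitFailure:
                continue
        assert len(recovered) >= 40
        assert abs(np.median(recovered) - 9.0) / 9.0 < 0.10

    def test_linear_curve_fails(self):
        t = np.linspace(0.1, 3.0, 12)
        with pytest.raises(FitFailure):
            fit_burst(ProgressCurve(t, 5.0 * t))


class TestSingleExponentialAndSaturation:
    def test_single_exponential_exact(self):
        t = np.geomspace(0.01, 3.0, 25)
        A, k = fit_single_exponential(ProgressCurve(t, 100.0 * (1 - np.exp(-3.6 * t))))
        assert A == pytest.approx(100.0, rel=1e-6)
        assert k == pytest.approx(3.6, rel=1e-6)

    def test_plateau_equals_amplitude(self):
        t = np.linspace(0.01, 50.0, 40)  # t >> 1/k
        y = 80.0 * (1 - np.exp(-3.6 * t))
        assert y[-1] == pytest.approx(80.0, rel=1e-6)
        A, _ = fit_single_exponential(ProgressCurve(t, y))
        assert A == pytest.approx(80.0, rel=1e-6)

    def test_constant_zero_fails(self):
        t = np.linspace(0.01, 1.0, 10)
        with pytest.raises(FitFailure):
            fit_single_exponential(ProgressCurve(t, np.zeros_like(t)))

    def test_saturation_exact_recovery(self):
        c = np.geomspace(0.5, 1500.0, 10)
        pts = list(zip(c, 12.0 * c / (1.5 + c)))
        sat = fit_saturation(pts)
        assert sat.k_pol == pytest.approx(12.0, rel=1e-6)
        assert sat.K_d_dNTP == pytest.approx(1.5, rel=1e-6)
        assert not sat.ill_conditioned

    def test_half_saturation_point(self):
        assert 12.0 * 1.5 / (1.5 + 1.5) == pytest.approx(6.0)

    def test_all_concentrations_above_kd_flagged(self):
        c = np.array([100.0, 400.0, 1500.0])  # >> K_d = 1.5
        sat = fit_saturation(list(zip(c, 12.0 * c / (1.5 + c))))
        assert sat.ill_conditioned


class TestFidelity:
    def test_template_g_wt_as_printed(self):
        row = fidelity_metrics((12.0, 1.5), (0.134, 365.0))
        assert row.efficiency_correct == pytest.approx(8.0)
        assert row.efficiency_incorrect == pytest.approx(3.7e-4)
        assert row.fidelity == pytest.approx(21623, rel=2e-4)
        assert row.D_kpol == pytest.approx(90, rel=0.01)
        assert row.D_Kd == pytest.approx(243, rel=0.01)

    def test_template_g_variant_unrounded(self):
        row = fidelity_metrics((3.6, 0.6), (0.095, 16.0), rounding="none")
        assert row.fidelity == pytest.approx(1011, rel=1e-3)

    def test_equal_efficiencies_give_two(self):
        row = fidelity_metrics((1.0, 1.0), (2.0, 2.0), rounding="none")
        assert row.fidelity == pytest.approx(2.0)

    def test_fidelity_limit_for_small_incorrect_efficiency(self):
        # fidelity -> 1 + eff_c/eff_i when eff_i << eff_c
        row = fidelity_metrics((10.0, 1.0), (1e-6, 1.0), rounding="none")
        assert row.fidelity == pytest.approx(1.0 + 10.0 / 1e-6, rel=1e-9)
        assert row.fidelity > 1.0

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(KineticsError):
            fidelity_metrics((0.0, 1.0), (1.0, 1.0))

    @pytest.mark.parametrize(
        "wt,variant,expected",
        [(21623.0, 1011.0, 21.39), (6364.0, 372.0, 17.11), (5.0, 5.0, 1.0)],
    )
    def test_x_fold(self, wt, variant, expected):
        assert x_fold(wt, variant) == pytest.approx(expected, abs=0.01)

    def test_round_sig(self):
        assert round_sig(0.0003671) == pytest.approx(3.7e-4)
        assert round_sig(2.1034) == pytest.approx(2.1)
        assert round_sig(0.0) == 0.0

    def test_table_builder_attaches_x_fold(self):
        table = FidelityTable.from_measurements(
            [
                ("G", "WT", (12.0, 1.5), (0.134, 365.0)),
                ("G", "I260Q", (3.6, 0.6), (0.095, 16.0)),
            ]
        )
        wt, mut = table.rows
        assert wt.x_fold is None
        assert mut.x_fold == pytest.approx(wt.fidelity / mut.fidelity)
        assert mut.x_fold == pytest.approx(21.4, rel=0.02)
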